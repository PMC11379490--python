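"""Synthetic cohort generator for the PRS-integration pipeline.

Generates genotype matrices in Hardy–Weinberg proportions, a PRS weight set,
and a health-check-style participant table (ages 40–74, UK-like covariate
marginals) in which 10-year events are drawn from the *inverse* of the
integrated risk model: the event log-odds are the clinical-score log-odds
plus ``beta * PRS_z - beta**2 / 2``.  The mean-preserving offset makes the
marginal event odds equal the clinical odds when ``PRS_z ~ N(0, 1)``, so the
generator is the exact generative counterpart of the integrated risk tool and
parameter-recovery experiments are well-posed.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

__all__ = [
    "CovariateMarginals",
    "SimulationConfig",
    "GenotypeMatrix",
    "simulate_genotypes",
    "simulate_weights",
    "inject_qc_violations",
    "simulate_cohort",
]

# Outcome hierarchy labels in priority order, with the default case-mix
# proportions (CVD death, MI/ACS, coronary intervention, stroke).
EVENT_HIERARCHY = ("cvd_death", "mi_acs", "pci_cabg", "stroke")
DEFAULT_EVENT_TYPE_PROBS = (0.056, 0.579, 0.128, 0.235)

# Unambiguous effect/other allele pairs (no A/T or C/G strand ambiguity).
_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "T"))


@dataclass(frozen=True)
class CovariateMarginals:
    """Marginal distributions of the baseline covariates.

    Defaults emulate a middle-aged UK health-check population: mean age 57.5,
    62% male, 76.5% white ethnicity, ~31% current smokers, 10.5% already on a
    statin.  Covariates are drawn independently (only marginals are pinned
    down); a correlation hook can be added by callers post hoc.
    """

    age_mean: float = 57.5
    age_sd: float = 9.4
    age_range: tuple[float, float] = (40.0, 74.0)
    male_fraction: float = 0.62
    white_fraction: float = 0.765
    smoking_probs: tuple[float, float, float] = (0.31, 0.19, 0.50)  # current/ex/never
    sbp_mean: float = 133.2
    sbp_sd: float = 15.9
    dbp_mean: float = 80.7
    dbp_sd: float = 10.3
    bmi_mean: float = 27.9
    bmi_sd: float = 5.3
    tchol_mean: float = 5.5
    tchol_sd: float = 1.1
    hdl_mean: float = 1.4
    hdl_sd: float = 0.4
    diabetes_fraction: float = 0.024
    statin_fraction: float = 0.105

    def validate(self) -> None:
        for name in ("male_fraction", "white_fraction", "diabetes_fraction", "statin_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if abs(sum(self.smoking_probs) - 1.0) > 1e-9:
            raise ValueError("smoking_probs must sum to 1")
        if any(p < 0 for p in self.smoking_probs):
            raise ValueError("smoking_probs must be non-negative")


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of a synthetic cohort run.

    ``prs_beta`` is the log-odds-per-SD effect of the standardised PRS; its
    default, log(1.6), is an assumed odds ratio of 1.6 per SD, a typical
    published effect for genome-wide CVD scores.  ``baseline_event_rate`` is
    the population-mean 10-year event probability.
    """

    n_subjects: int
    n_variants: int
    allele_freq_range: tuple[float, float] = (0.05, 0.5)
    prs_beta: float = math.log(1.6)
    baseline_event_rate: float = 0.10
    covariate_marginals: CovariateMarginals = field(default_factory=CovariateMarginals)
    event_type_probs: tuple[float, ...] = DEFAULT_EVENT_TYPE_PROBS
    risk_model: str = "covariates"  # or "constant": everyone at baseline_event_rate
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.allele_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError(f"allele_freq_range must lie in (0,1), got {self.allele_freq_range}")
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if not 0.0 < self.baseline_event_rate < 1.0:
            raise ValueError("baseline_event_rate must be in (0, 1)")
        if not math.isfinite(self.prs_beta):
            raise ValueError("prs_beta must be finite")
        if self.risk_model not in ("covariates", "constant"):
            raise ValueError(f"unknown risk_model {self.risk_model!r}")
        if len(self.event_type_probs) != len(EVENT_HIERARCHY):
            raise ValueError("event_type_probs must have one entry per hierarchy label")
        self.covariate_marginals.validate()

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class GenotypeMatrix:
    """Effect-allele dosages with a missingness mask and variant metadata.

    ``dosages`` is n_subjects x n_variants in [0, 2]; entries under
    ``missing_mask`` are undefined.  ``variants`` carries id, chrom, pos,
    effect_allele, other_allele and the generating allele frequency.
    """

    dosages: np.ndarray
    missing_mask: np.ndarray
    variants: pd.DataFrame
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.dosages.shape != self.missing_mask.shape:
            raise ValueError("dosages and missing_mask shapes differ")
        if len(self.variants) != self.dosages.shape[1]:
            raise ValueError("variant metadata length != number of dosage columns")
        ok = self.dosages[~self.missing_mask]
        if ok.size and (ok.min() < 0 or ok.max() > 2):
            raise ValueError("non-missing dosages must lie in [0, 2]")
        if self.variants["id"].duplicated().any():
            dups = self.variants.loc[self.variants["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate variant ids: {dups}")
        if (self.variants["pos"].to_numpy() <= 0).any():
            raise ValueError("positions must be positive")
        if not self.sample_ids:
            self.sample_ids = [f"S{i:06d}" for i in range(self.dosages.shape[0])]

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def call_rate(self) -> np.ndarray:
        """Per-variant fraction of non-missing genotypes."""
        return 1.0 - self.missing_mask.mean(axis=0)

    def effect_allele_freq(self) -> np.ndarray:
        """Per-variant effect-allele frequency from non-missing dosages."""
        d = np.ma.masked_array(self.dosages, mask=self.missing_mask)
        return np.asarray(d.mean(axis=0) / 2.0)

    def genotype_counts(self) -> np.ndarray:
        """n_variants x 3 hard-call counts (hom-other, het, hom-effect).

        Dosages are rounded to the nearest integer genotype; missing entries
        are excluded.
        """
        g = np.clip(np.rint(self.dosages), 0, 2).astype(int)
        counts = np.zeros((self.n_variants, 3), dtype=int)
        for k in range(3):
            counts[:, k] = ((g == k) & ~self.missing_mask).sum(axis=0)
        return counts

    def subset_variants(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            dosages=self.dosages[:, keep].copy(),
            missing_mask=self.missing_mask[:, keep].copy(),
            variants=self.variants.iloc[keep].reset_index(drop=True).copy(),
            sample_ids=list(self.sample_ids),
        )


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw hard-call genotypes in Hardy–Weinberg proportions.

    Allele frequencies are uniform on ``config.allele_freq_range``; each
    genotype is Binomial(2, af), which is exactly HWE at the drawn frequency.
    Reproducible: identical config (including seed) gives identical output.
    """
    rng = np.random.default_rng(config.seed)
    af = rng.uniform(*config.allele_freq_range, size=config.n_variants)
    dosages = rng.binomial(2, af, size=(config.n_subjects, config.n_variants)).astype(float)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=config.n_variants)
    variants = pd.DataFrame(
        {
            "id": [f"snp{j + 1}" for j in range(config.n_variants)],
            "chrom": ["1"] * config.n_variants,
            "pos": np.arange(1, config.n_variants + 1) * 1000,
            "effect_allele": [_ALLELE_PAIRS[k][0] for k in pair_idx],
            "other_allele": [_ALLELE_PAIRS[k][1] for k in pair_idx],
            "af": af,
        }
    )
    mask = np.zeros_like(dosages, dtype=bool)
    return GenotypeMatrix(dosages, mask, variants)


def simulate_weights(gm: GenotypeMatrix, seed: int = 0, scale: float = 0.05):
    """Random per-allele log-odds weights for the matrix's variants.

    The raw score is standardised downstream, so the scale only sets the raw
    units; N(0, scale) is used.  Returns a :class:`cvdprs.prs_engine.PRSWeightSet`.
    """
    from .prs_engine import PRSWeightSet

    rng = np.random.default_rng(seed)
    tbl = gm.variants[["id", "chrom", "pos", "effect_allele", "other_allele"]].copy()
    tbl["weight"] = rng.normal(0.0, scale, size=len(tbl))
    return PRSWeightSet(tbl, build="synthetic")


def inject_qc_violations(
    gm: GenotypeMatrix,
    n_low_call_rate: int = 0,
    n_low_maf: int = 0,
    n_hwe: int = 0,
    seed: int = 0,
    call_rate: float = 0.90,
) -> tuple[GenotypeMatrix, dict[str, list[str]]]:
    """Plant variants that violate exactly one QC filter each.

    Disjoint variant sets are altered so that exactly ``n_low_call_rate``
    variants fall below 98% call rate, ``n_low_maf`` become (near-)monomorphic
    (MAF < 0.005) and ``n_hwe`` become all-heterozygote (gross HWE deviation;
    with >= ~60 subjects the exact test p-value is far below 1e-6).  Returns
    the modified copy and the planted-truth id lists.
    """
    total = n_low_call_rate + n_low_maf + n_hwe
    if total > gm.n_variants:
        raise ValueError(
            f"requested {total} violating variants but matrix has {gm.n_variants}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(gm.n_variants, size=total, replace=False)
    idx_call = chosen[:n_low_call_rate]
    idx_maf = chosen[n_low_call_rate : n_low_call_rate + n_low_maf]
    idx_hwe = chosen[n_low_call_rate + n_low_maf :]

    dos = gm.dosages.copy()
    mask = gm.missing_mask.copy()
    n = gm.n_subjects
    n_missing = max(int(math.ceil((1.0 - call_rate) * n)), int(math.floor(0.02 * n)) + 1)
    for j in idx_call:
        rows = rng.choice(n, size=min(n_missing, n), replace=False)
        mask[rows, j] = True
    for j in idx_maf:
        dos[:, j] = 0.0
        mask[:, j] = False
    for j in idx_hwe:
        dos[:, j] = 1.0
        mask[:, j] = False

    planted = {
        "call_rate": gm.variants["id"].iloc[idx_call].tolist(),
        "maf": gm.variants["id"].iloc[idx_maf].tolist(),
        "hwe": gm.variants["id"].iloc[idx_hwe].tolist(),
    }
    out = GenotypeMatrix(dos, mask, gm.variants.copy(), list(gm.sample_ids))
    return out, planted


def _draw_covariates(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    m = config.covariate_marginals
    n = config.n_subjects
    lo, hi = m.age_range
    age = np.clip(rng.normal(m.age_mean, m.age_sd, n), lo, hi)
    sex = np.where(rng.random(n) < m.male_fraction, "M", "F")
    eth = np.where(rng.random(n) < m.white_fraction, "white", "south_asian")
    smoking = rng.choice(["current", "ex", "never"], size=n, p=list(m.smoking_probs))
    sbp = np.clip(rng.normal(m.sbp_mean, m.sbp_sd, n), 80, 220)
    dbp = np.clip(rng.normal(m.dbp_mean, m.dbp_sd, n), 50, 140)
    bmi = np.clip(rng.normal(m.bmi_mean, m.bmi_sd, n), 15, 60)
    tchol = np.clip(rng.normal(m.tchol_mean, m.tchol_sd, n), 2.0, 12.0)
    hdl = np.clip(rng.normal(m.hdl_mean, m.hdl_sd, n), 0.5, 3.5)
    diabetes = rng.random(n) < m.diabetes_fraction
    statin = rng.random(n) < m.statin_fraction
    return pd.DataFrame(
        {
            "id": [f"S{i:06d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "ethnicity": eth,
            "white": eth == "white",
            "smoking": smoking,
            "sbp": sbp,
            "dbp": dbp,
            "bmi": bmi,
            "total_chol": tchol,
            "hdl": hdl,
            "diabetes": diabetes,
            "statin": statin,
            "bp_treated": np.zeros(n, dtype=bool),
        }
    )


def simulate_cohort(config: SimulationConfig, gm: GenotypeMatrix, weights) -> pd.DataFrame:
    """Generate a participant table whose events follow the integrated model.

    The clinical 10-year risk is the surrogate QRISK2-style logistic score of
    the drawn covariates, with its intercept calibrated by root finding so
    the population-mean risk equals ``baseline_event_rate`` (under
    ``risk_model='constant'`` every subject sits exactly at the baseline
    rate).  Event probabilities then multiply the clinical odds by
    ``exp(beta * PRS_z - beta**2 / 2)`` with PRS_z the cohort-standardised
    score of ``gm`` under ``weights``.
    """
    from .clinical_scores import qrisk2_surrogate_linpred
    from .prs_engine import score_prs

    rng = np.random.default_rng(config.seed + 1)
    table = _draw_covariates(config, rng)

    raw, _flagged = score_prs(gm, weights)
    sd = raw.std(ddof=1)
    prs_z = np.zeros_like(raw) if sd == 0 else (raw - raw.mean()) / sd

    if config.risk_model == "constant":
        clin = np.full(config.n_subjects, config.baseline_event_rate)
    else:
        lp = qrisk2_surrogate_linpred(table)
        # calibrate intercept: mean 10-year risk == baseline_event_rate
        c = brentq(
            lambda c0: expit(lp + c0).mean() - config.baseline_event_rate, -30.0, 30.0
        )
        clin = expit(lp + c)
    if np.any(clin <= 0) or np.any(clin >= 1):
        bad = int(np.argmax((clin <= 0) | (clin >= 1)))
        raise ValueError(
            f"clinical risk outside (0,1) for subject {table['id'].iloc[bad]}: {clin[bad]}"
        )

    beta = config.prs_beta
    p_event = expit(logit(clin) + beta * prs_z - beta**2 / 2.0)
    event = rng.random(config.n_subjects) < p_event

    probs = np.asarray(config.event_type_probs, dtype=float)
    probs = probs / probs.sum()
    types = np.full(config.n_subjects, None, dtype=object)
    n_ev = int(event.sum())
    if n_ev:
        types[event] = rng.choice(list(EVENT_HIERARCHY), size=n_ev, p=probs)
    etime = np.full(config.n_subjects, np.nan)
    if n_ev:
        etime[event] = rng.uniform(0.0, 10.0, size=n_ev)

    table["prs_z"] = prs_z
    table["qrisk2"] = 100.0 * clin
    table["event"] = event
    table["event_type"] = types
    table["event_time"] = etime
    return table
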