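"""Clinical 10-year CVD risk equations and guideline risk categories.

Implements the ASCVD Pooled Cohort Equations and SCORE2 from their published
coefficient tables (shipped as CSV data files with provenance headers), a
QRISK2 *passthrough* (QRISK2 is a licensed algorithm; in practice the score
arrives pre-computed from primary-care records and is treated as data), and a
clearly-labelled logistic surrogate used only to make synthetic cohorts
self-contained.

Categories follow the respective guidelines: QRISK2 <5 low, 5-10
intermediate, >=10 high; PCE <5 low, 5-7.5 intermediate (borderline), >=7.5
high; SCORE2 high at or above an age-banded threshold (default <50y: 2.5%,
50-69y: 5%, >=70y: 7.5%).  High-risk boundaries are closed (>=).
"""
from __future__ import annotations

import functools
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "RiskProfile",
    "ThresholdScheme",
    "get_scheme",
    "pce_risk",
    "score2_risk",
    "qrisk2_passthrough",
    "qrisk2_surrogate_linpred",
    "categorize",
]

MMOL_TO_MGDL_CHOL = 38.67  # cholesterol unit conversion


@dataclass(frozen=True)
class RiskProfile:
    """Inputs to the clinical risk equations (units as in the cohort table).

    Cholesterol in mmol/L, SBP in mmHg.  ``race`` follows the PCE grouping
    ('white' or 'black'); other ethnicities are scored with the white
    coefficients, the equation authors' stated fallback.
    """

    age: float
    sex: str  # 'M' | 'F'
    total_chol: float
    hdl: float
    sbp: float
    smoker: bool = False
    diabetes: bool = False
    bp_treated: bool = False
    race: str = "white"
    region: str = "low"  # SCORE2 calibration region


@functools.lru_cache(maxsize=1)
def _pce_tables() -> dict:
    with resources.files("cvdprs.data").joinpath("pce_coefficients.csv").open() as fh:
        df = pd.read_csv(fh, comment="#")
    out = {}
    for (sex, race), grp in df.groupby(["sex", "race"]):
        out[(sex, race)] = dict(zip(grp["term"], grp["value"]))
    return out


@functools.lru_cache(maxsize=1)
def _score2_tables() -> tuple[dict, dict]:
    with resources.files("cvdprs.data").joinpath("score2_coefficients.csv").open() as fh:
        coef = pd.read_csv(fh, comment="#")
    with resources.files("cvdprs.data").joinpath("score2_scales.csv").open() as fh:
        scales = pd.read_csv(fh, comment="#")
    coefs = {sex: dict(zip(g["term"], g["value"])) for sex, g in coef.groupby("sex")}
    sc = {(r, s): (v["scale1"], v["scale2"]) for (r, s), v in scales.set_index(["region", "sex"]).iterrows()}
    return coefs, sc


def pce_risk(profile: RiskProfile, chol_units: str = "mmol") -> float:
    """ASCVD-PCE 10-year risk in percent.

    ``risk = 100 * (1 - S0 ** exp(lp - mean_lp))`` with the race/sex-specific
    linear predictor on ln-transformed age, cholesterol (mg/dL) and SBP.
    Cholesterol inputs in mmol/L are converted internally; pass
    ``chol_units='mgdl'`` for pre-converted values.
    """
    if not 40 <= profile.age <= 79:
        raise ValueError(f"PCE is defined for ages 40-79, got {profile.age}")
    if chol_units not in ("mmol", "mgdl"):
        raise ValueError(f"unknown chol_units {chol_units!r}")
    factor = MMOL_TO_MGDL_CHOL if chol_units == "mmol" else 1.0
    tc, hdl = profile.total_chol * factor, profile.hdl * factor
    race = profile.race if profile.race == "black" else "white"
    c = _pce_tables()[(profile.sex, race)]
    la, ltc, lhdl, lsbp = math.log(profile.age), math.log(tc), math.log(hdl), math.log(profile.sbp)
    sbp_term = (
        c["ln_sbp_treated"] * lsbp + c["ln_age_ln_sbp_treated"] * la * lsbp
        if profile.bp_treated
        else c["ln_sbp_untreated"] * lsbp + c["ln_age_ln_sbp_untreated"] * la * lsbp
    )
    lp = (
        c["ln_age"] * la
        + c["ln_age_sq"] * la * la
        + c["ln_tc"] * ltc
        + c["ln_age_ln_tc"] * la * ltc
        + c["ln_hdl"] * lhdl
        + c["ln_age_ln_hdl"] * la * lhdl
        + sbp_term
        + (c["smoker"] + c["ln_age_smoker"] * la) * float(profile.smoker)
        + c["diabetes"] * float(profile.diabetes)
    )
    risk = 100.0 * (1.0 - c["baseline_survival"] ** math.exp(lp - c["mean_lp"]))
    return float(min(max(risk, 1e-9), 100.0 - 1e-9))


def score2_risk(profile: RiskProfile) -> float:
    """SCORE2 10-year risk in percent (ages 40-69, region-recalibrated).

    Sex-specific Cox linear predictor on centred age/SBP/cholesterol terms,
    baseline 10-year survival, then the published region recalibration
    ``1 - exp(-exp(s1 + s2 * ln(-ln(1 - u))))``.
    """
    if not 40 <= profile.age <= 69:
        raise ValueError(f"SCORE2 is defined for ages 40-69, got {profile.age}")
    coefs, scales = _score2_tables()
    if (profile.region, profile.sex) not in scales:
        raise ValueError(f"unknown SCORE2 region {profile.region!r}")
    c = coefs[profile.sex]
    cage = (profile.age - 60.0) / 5.0
    csbp = (profile.sbp - 120.0) / 20.0
    ctc = profile.total_chol - 6.0
    chdl = (profile.hdl - 1.3) / 0.5
    smo = float(profile.smoker)
    lp = (
        c["age"] * cage
        + c["smoking"] * smo
        + c["sbp"] * csbp
        + c["tchol"] * ctc
        + c["hdl"] * chdl
        + c["smoking_age"] * smo * cage
        + c["sbp_age"] * csbp * cage
        + c["tchol_age"] * ctc * cage
        + c["hdl_age"] * chdl * cage
    )
    u = 1.0 - c["baseline_survival"] ** math.exp(lp)
    s1, s2 = scales[(profile.region, profile.sex)]
    risk = 100.0 * (1.0 - math.exp(-math.exp(s1 + s2 * math.log(-math.log(1.0 - u)))))
    return float(min(max(risk, 1e-9), 100.0 - 1e-9))


def qrisk2_passthrough(table: pd.DataFrame, surrogate: bool = False) -> np.ndarray:
    """Return stored QRISK2 scores (percent) unchanged.

    QRISK2 itself is not re-implemented; scores are data, downloaded from GP
    records in the study design this pipeline mirrors.  With
    ``surrogate=True`` and no ``qrisk2`` column, the documented logistic
    surrogate is evaluated instead (synthetic cohorts only) — callers should
    label such scores as surrogate output.
    """
    if "qrisk2" in table.columns and table["qrisk2"].notna().all():
        return table["qrisk2"].to_numpy(dtype=float)
    if not surrogate:
        raise ValueError("no qrisk2 column present and surrogate mode disabled")
    from scipy.special import expit

    lp = qrisk2_surrogate_linpred(table)
    return 100.0 * expit(lp - 2.2)  # uncalibrated fallback intercept


#: Surrogate QRISK2 log-odds coefficients (per unit of the centred inputs).
#: These are plausible hand-chosen magnitudes for a 10-year CVD model — NOT
#: the licensed QRISK2 algorithm — and exist only so synthetic cohorts carry
#: a covariate-driven clinical score.
SURROGATE_COEFS = {
    "age": 0.085,  # per year from 57.5
    "male": 0.45,
    "south_asian": 0.30,
    "smoking_current": 0.55,
    "smoking_ex": 0.15,
    "sbp": 0.016,  # per mmHg from 133
    "bmi": 0.025,  # per kg/m2 from 28
    "chol_ratio": 0.18,  # per unit of TC/HDL from 4.0
    "diabetes": 0.90,
}


def qrisk2_surrogate_linpred(table: pd.DataFrame) -> np.ndarray:
    """Intercept-free linear predictor of the surrogate clinical score."""
    c = SURROGATE_COEFS
    ratio = table["total_chol"].to_numpy(float) / table["hdl"].to_numpy(float)
    return (
        c["age"] * (table["age"].to_numpy(float) - 57.5)
        + c["male"] * (table["sex"].to_numpy() == "M")
        + c["south_asian"] * (~table["white"].to_numpy(bool)).astype(float)
        + c["smoking_current"] * (table["smoking"].to_numpy() == "current")
        + c["smoking_ex"] * (table["smoking"].to_numpy() == "ex")
        + c["sbp"] * (table["sbp"].to_numpy(float) - 133.0)
        + c["bmi"] * (table["bmi"].to_numpy(float) - 28.0)
        + c["chol_ratio"] * (ratio - 4.0)
        + c["diabetes"] * table["diabetes"].to_numpy(bool).astype(float)
    )


@dataclass(frozen=True)
class ThresholdScheme:
    """Maps a (risk %, age) pair to {low, intermediate, high}."""

    name: str
    low_cut: float  # below -> low (QRISK2/PCE style); ignored for banded schemes
    high_cut: float | None  # fixed high threshold, or None for age bands
    age_bands: tuple[tuple[float, float], ...] = ()  # (min_age, threshold)

    def high_threshold(self, age: float) -> float:
        if self.high_cut is not None:
            return self.high_cut
        thr = self.age_bands[0][1]
        for min_age, t in self.age_bands:
            if age >= min_age:
                thr = t
        return thr


_SCHEMES = {
    "qrisk2": ThresholdScheme("qrisk2", low_cut=5.0, high_cut=10.0),
    "pce": ThresholdScheme("pce", low_cut=5.0, high_cut=7.5),
    "score2": ThresholdScheme(
        "score2", low_cut=math.nan, high_cut=None, age_bands=((0.0, 2.5), (50.0, 5.0), (70.0, 7.5))
    ),
}


def get_scheme(name: str) -> ThresholdScheme:
    try:
        return _SCHEMES[name]
    except KeyError:
        raise ValueError(f"unknown threshold scheme {name!r}; known: {sorted(_SCHEMES)}") from None


def categorize(score: float, age: float, scheme: ThresholdScheme | str) -> str:
    """Guideline category for a 10-year risk percentage.

    High-risk boundaries are closed on the high side (score >= threshold is
    high).  For the age-banded SCORE2 scheme, 'low' is below half the band
    threshold and 'intermediate' the remainder below it.
    """
    if isinstance(scheme, str):
        scheme = get_scheme(scheme)
    if not np.isfinite(score):
        raise ValueError(f"non-finite risk score {score}")
    hi = scheme.high_threshold(age)
    lo = scheme.low_cut if np.isfinite(scheme.low_cut) else hi / 2.0
    if score >= hi:
        return "high"
    if score >= lo:
        return "intermediate"
    return "low"
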