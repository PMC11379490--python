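"""Headline statistics for the paired high-risk classification comparison.

Everything is driven by the paired 2x2 reclassification counts among cases:
``a`` high by both scores, ``b`` up-classified (clinical low, IRT high), ``c``
down-classified, ``d`` low by both.  Provides single-proportion sensitivity
CIs (Clopper–Pearson default), the paired Wald difference in sensitivities
from the discordant counts, case-NRI, the exact-CI odds ratio of being
up-classified, PRS percentile enrichment, a baseline characteristics table
with t / chi-square tests, and a parameterised preventable-events model.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

__all__ = [
    "ReclassTable",
    "PreventionInputs",
    "sensitivity_ci",
    "paired_sensitivity_diff",
    "relative_increase",
    "case_nri",
    "upclass_odds_ratio",
    "percentile_enrichment",
    "baseline_table",
    "chi2_test",
    "preventable_events",
    "expected_random_upclassification",
    "evaluate_assessment",
]


@dataclass(frozen=True)
class ReclassTable:
    """Paired 2x2 classification counts among n cases."""

    n: int
    a: int  # high by clinical and by IRT
    b: int  # up-classified
    c: int  # down-classified
    d: int  # low by both

    def __post_init__(self) -> None:
        if min(self.n, self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d != self.n:
            raise ValueError(f"a+b+c+d = {self.a + self.b + self.c + self.d} != n = {self.n}")

    @classmethod
    def from_assessment(cls, assessment: pd.DataFrame) -> "ReclassTable":
        ch = assessment["clinical_high"].to_numpy(bool)
        ih = assessment["irt_high"].to_numpy(bool)
        return cls(
            n=len(assessment),
            a=int((ch & ih).sum()),
            b=int((~ch & ih).sum()),
            c=int((ch & ~ih).sum()),
            d=int((~ch & ~ih).sum()),
        )

    @property
    def clinical_positive(self) -> int:
        return self.a + self.c

    @property
    def combined_positive(self) -> int:
        """Union rule: high by clinical or by IRT."""
        return self.a + self.b + self.c

    def to_dict(self) -> dict:
        return {"n": self.n, "a": self.a, "b": self.b, "c": self.c, "d": self.d}


def sensitivity_ci(k: int, n: int, method: str = "clopper-pearson") -> tuple[float, float, float]:
    """Sensitivity percent with a 95% CI; Clopper–Pearson exact by default.

    Returns (point, lower, upper), all in percent.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    from statsmodels.stats.proportion import proportion_confint

    methods = {"clopper-pearson": "beta", "wilson": "wilson", "wald": "normal"}
    if method not in methods:
        raise ValueError(f"unknown CI method {method!r}")
    lo, hi = proportion_confint(k, n, alpha=0.05, method=methods[method])
    return 100.0 * k / n, 100.0 * float(lo), 100.0 * float(hi)


@dataclass(frozen=True)
class PairedDiff:
    diff_pct: float
    ci_low_pct: float
    ci_high_pct: float
    z: float
    p: float
    degenerate: bool = False


def paired_sensitivity_diff(b: int, c: int, n: int) -> PairedDiff:
    """Wald inference for the difference of paired sensitivities.

    ``diff = (b - c)/n`` with sampling variance ``(b + c - (b-c)^2/n) / n^2``
    (the standard result for the difference of two paired proportions);
    CI = diff +/- 1.96 SE, two-sided normal p.
    ``b = c = 0`` yields a degenerate zero-width interval flagged as such.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if b < 0 or c < 0 or b + c > n:
        raise ValueError("need b, c >= 0 and b + c <= n")
    diff = (b - c) / n
    var = (b + c - (b - c) ** 2 / n) / n**2
    if b == c == 0:
        return PairedDiff(0.0, 0.0, 0.0, 0.0, 1.0, degenerate=True)
    se = math.sqrt(var)
    z = diff / se if se > 0 else math.inf
    p = 2.0 * stats.norm.sf(abs(z)) if math.isfinite(z) else 0.0
    zc = stats.norm.ppf(0.975)
    return PairedDiff(
        100.0 * diff, 100.0 * (diff - zc * se), 100.0 * (diff + zc * se), z, p, se == 0.0
    )


def relative_increase(b: int, k_base: int) -> float:
    """Up-classified cases as a percent of the clinically identified cases."""
    if k_base < 1:
        raise ValueError("k_base must be >= 1")
    return 100.0 * b / k_base


def case_nri(b: int, c: int, n: int) -> float:
    """Case net reclassification index: 100 * (b - c) / n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return 100.0 * (b - c) / n


def _conditional_exact_ci(a: int, bb: int, c: int, d: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact CI for the 2x2 odds ratio from the noncentral hypergeometric tails."""
    M, nrow, ncol = a + bb + c + d, a + bb, a + c
    lo_support, hi_support = max(0, nrow + ncol - M), min(nrow, ncol)

    def sf_geq(psi: float) -> float:  # P(X >= a | psi)
        return float(stats.nchypergeom_fisher.sf(a - 1, M, nrow, ncol, psi))

    def cdf_leq(psi: float) -> float:  # P(X <= a | psi)
        return float(stats.nchypergeom_fisher.cdf(a, M, nrow, ncol, psi))

    if a == lo_support:
        lower = 0.0
    else:
        lower = brentq(lambda g: sf_geq(math.exp(g)) - alpha / 2, -50, 50, xtol=1e-10)
        lower = math.exp(lower)
    if a == hi_support:
        upper = math.inf
    else:
        upper = brentq(lambda g: cdf_leq(math.exp(g)) - alpha / 2, -50, 50, xtol=1e-10)
        upper = math.exp(upper)
    return lower, upper


@dataclass(frozen=True)
class OddsRatioResult:
    oddsratio: float
    ci_low: float
    ci_high: float
    p: float
    zero_cell: bool = False


def upclass_odds_ratio(case_up: int, case_low: int, ctrl_up: int, ctrl_low: int) -> OddsRatioResult:
    """Odds of up-classification in low-risk cases vs low-risk controls.

    ``case_low`` / ``ctrl_low`` are the *totals* of clinically low-risk
    subjects per group; the 2x2 is [[case_up, case_low - case_up],
    [ctrl_up, ctrl_low - ctrl_up]].  Point estimate is the cross-product
    ratio; the 95% CI is conditional exact (noncentral hypergeometric
    tails, i.e. the Fisher exact-test inversion); p from Fisher's exact test.
    """
    if min(case_up, ctrl_up) < 0 or case_low < case_up or ctrl_low < ctrl_up:
        raise ValueError("need 0 <= up counts <= low-risk totals")
    if case_low == 0 or ctrl_low == 0:
        raise ValueError("both groups must be non-empty")
    a, bcell = case_up, case_low - case_up
    c, dcell = ctrl_up, ctrl_low - ctrl_up
    zero = 0 in (a, bcell, c, dcell)
    point = math.inf if (bcell == 0 or c == 0) and not (a == 0 or dcell == 0) else (
        0.0 if a == 0 or dcell == 0 else (a * dcell) / (bcell * c)
    )
    lo, hi = _conditional_exact_ci(a, bcell, c, dcell)
    _, p = stats.fisher_exact([[a, bcell], [c, dcell]], alternative="two-sided")
    return OddsRatioResult(point, lo, hi, float(p), zero_cell=zero)


DEFAULT_ENRICHMENT_CUTS = (0.20, 0.10, 0.05, 0.03, 0.01)


def percentile_enrichment(
    case_z: np.ndarray, reference_z: np.ndarray, cuts=DEFAULT_ENRICHMENT_CUTS
) -> pd.DataFrame:
    """Fold over-representation of cases above upper PRS percentiles.

    For each upper-tail mass q the threshold is the (1-q) quantile of the
    reference distribution; fold = (fraction of cases at or above it) / q.
    """
    case_z = np.asarray(case_z, dtype=float)
    reference_z = np.asarray(reference_z, dtype=float)
    if reference_z.size == 0:
        raise ValueError("reference distribution is empty")
    rows = []
    for q in cuts:
        if not 0.0 < q < 1.0:
            raise ValueError(f"cut {q} outside (0, 1)")
        thr = float(np.quantile(reference_z, 1.0 - q))
        frac = float((case_z >= thr).mean()) if case_z.size else math.nan
        rows.append({"cut": q, "threshold": thr, "case_fraction": frac, "fold": frac / q})
    return pd.DataFrame(rows)


def baseline_table(
    cases: pd.DataFrame,
    controls: pd.DataFrame,
    continuous: tuple[str, ...] = (),
    categorical: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Table-1-style group comparison.

    Continuous rows: mean (SD) per group with a two-sample Student t-test
    (equal variances).  Categorical rows: level counts (%) with a Pearson
    chi-square test — Yates continuity correction applied for 2x2 tables
    only, the convention of standard statistical environments.  Constant
    continuous columns are reported without a p-value.
    """
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both groups must be non-empty")
    rows = []
    for col in continuous:
        x1, x0 = cases[col].astype(float), controls[col].astype(float)
        if x1.std(ddof=1) == 0 and x0.std(ddof=1) == 0:
            p, note = math.nan, "constant column; t-test skipped"
        else:
            p = float(stats.ttest_ind(x1, x0, equal_var=True).pvalue)
            note = ""
        rows.append(
            {
                "variable": col,
                "level": "",
                "cases": f"{x1.mean():.1f} ({x1.std(ddof=1):.1f})",
                "controls": f"{x0.mean():.1f} ({x0.std(ddof=1):.1f})",
                "p": p,
                "test": "t",
                "note": note,
            }
        )
    for col in categorical:
        levels = sorted(set(cases[col]) | set(controls[col]), key=str)
        counts = np.array(
            [[int((cases[col] == lev).sum()), int((controls[col] == lev).sum())] for lev in levels]
        )
        valid = counts.sum(axis=1) > 0
        tab = counts[valid]
        if tab.shape[0] >= 2:
            correction = tab.shape[0] == 2
            p = float(stats.chi2_contingency(tab, correction=correction).pvalue)
        else:
            p = math.nan
        for i, lev in enumerate(levels):
            n1, n0 = counts[i]
            rows.append(
                {
                    "variable": col,
                    "level": str(lev),
                    "cases": f"{n1} ({100 * n1 / len(cases):.1f})",
                    "controls": f"{n0} ({100 * n0 / len(controls):.1f})",
                    "p": p if i == 0 else math.nan,
                    "test": "chi2",
                    "note": "",
                }
            )
    return pd.DataFrame(rows)


def chi2_test(table, correction: str = "2x2-only") -> float:
    """Pearson chi-square p-value for a contingency table.

    ``correction='2x2-only'`` (default) applies the Yates correction only
    when the table is 2x2; 'never'/'always' force the alternatives.
    """
    tab = np.asarray(table)
    if correction == "2x2-only":
        corr = tab.shape == (2, 2)
    elif correction in ("never", "always"):
        corr = correction == "always"
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return float(stats.chi2_contingency(tab, correction=corr).pvalue)


@dataclass(frozen=True)
class PreventionInputs:
    """Inputs of the preventable-events model (all fractions in [0, 1])."""

    newly_high_fraction: float  # extra population fraction flagged high by the IRT
    statin_uptake: float  # fraction of the newly flagged starting treatment
    relative_risk_reduction: float  # treatment effect on events
    annual_event_rate: float  # annual event rate among the newly identified
    person_years_scale: float = 1e5

    def __post_init__(self) -> None:
        for name in ("newly_high_fraction", "statin_uptake", "relative_risk_reduction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.annual_event_rate < 0:
            raise ValueError("annual_event_rate must be >= 0")


def preventable_events(inp: PreventionInputs) -> float:
    """Events prevented per ``person_years_scale`` patient-years.

    Linear model: newly-flagged fraction x treatment uptake x relative risk
    reduction x annual event rate, scaled to the stated patient-year base.
    """
    return (
        inp.newly_high_fraction
        * inp.statin_uptake
        * inp.relative_risk_reduction
        * inp.annual_event_rate
        * inp.person_years_scale
    )


def expected_random_upclassification(case_low_fraction: float, population_up_rate: float) -> float:
    """Percent of cases up-classified if up-classification were random.

    The product of the fraction of cases sitting below the clinical
    threshold and the population rate of up-classification among low-risk
    subjects, in percent.
    """
    for v in (case_low_fraction, population_up_rate):
        if not 0.0 <= v <= 1.0:
            raise ValueError("fractions must be in [0, 1]")
    return 100.0 * case_low_fraction * population_up_rate


def evaluate_assessment(
    case_assessment: pd.DataFrame, control_assessment: pd.DataFrame | None = None
) -> dict:
    """Headline report from per-subject assessments of cases (and controls).

    Scores the union rule (high by clinical or IRT) against the clinical
    score alone, so the down-classified cell of that comparison is zero by
    construction and the uplift equals b/n.
    """
    rt = ReclassTable.from_assessment(case_assessment)
    clin = sensitivity_ci(rt.clinical_positive, rt.n)
    comb = sensitivity_ci(rt.combined_positive, rt.n)
    uplift = paired_sensitivity_diff(rt.b, 0, rt.n)  # union rule: c == 0
    report = {
        "n_cases": rt.n,
        "reclass_table": rt.to_dict(),
        "clinical_sensitivity_pct": clin[0],
        "clinical_sensitivity_ci_pct": [clin[1], clin[2]],
        "combined_sensitivity_pct": comb[0],
        "combined_sensitivity_ci_pct": [comb[1], comb[2]],
        "absolute_uplift_pct": uplift.diff_pct,
        "uplift_ci_pct": [uplift.ci_low_pct, uplift.ci_high_pct],
        "uplift_p": uplift.p,
        "relative_uplift_pct": (
            relative_increase(rt.b, rt.clinical_positive) if rt.clinical_positive else math.nan
        ),
        "case_nri_pct": case_nri(rt.b, rt.c, rt.n),
    }
    assert report["combined_sensitivity_pct"] >= report["clinical_sensitivity_pct"]
    if control_assessment is not None:
        rc = ReclassTable.from_assessment(control_assessment)
        case_low = rt.b + rt.d
        ctrl_low = rc.b + rc.d
        report["control_reclass_table"] = rc.to_dict()
        if case_low and ctrl_low:
            orr = upclass_odds_ratio(rt.b, case_low, rc.b, ctrl_low)
            report["upclass_odds_ratio"] = {
                "or": orr.oddsratio,
                "ci": [orr.ci_low, orr.ci_high],
                "p": orr.p,
            }
    return report
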