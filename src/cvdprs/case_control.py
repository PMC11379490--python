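"""Nested case-control construction: outcome hierarchy, propensity matching, SMD.

Cases take a single label by the fixed outcome priority (CVD death > MI/ACS >
PCI/CABG > stroke).  Controls are drawn without replacement in an
approximate ratio (default 2:1) by greedy nearest-neighbour matching on the
logit propensity score from a main-effects logistic model of case status on
age, sex, ethnicity, smoking status, BMI and the clinical risk score, with a
caliper of 0.2 SD of the logit propensity by default.  Balance is reported
as standardised mean differences before and after matching.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logit

from .synthetic_cohort import EVENT_HIERARCHY

__all__ = [
    "MatchedDesign",
    "DEFAULT_MATCH_COVARIATES",
    "resolve_hierarchy",
    "select_cases",
    "fit_propensity",
    "match",
    "smd",
    "smd_table",
]

DEFAULT_MATCH_COVARIATES = ("age", "sex", "white", "smoking", "bmi", "qrisk2")


def resolve_hierarchy(labels) -> str:
    """Single case label from possibly multiple event records."""
    labels = list(labels)
    for lab in labels:
        if lab not in EVENT_HIERARCHY:
            raise ValueError(f"unknown event label {lab!r}; known: {EVENT_HIERARCHY}")
    if not labels:
        raise ValueError("no event labels supplied")
    return min(labels, key=EVENT_HIERARCHY.index)


def select_cases(table: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Rows with an event, labelled by the hierarchy, plus per-label counts.

    ``event_type`` may hold a single label or a list of labels (resolved by
    priority).  Returns an empty frame with a warning-friendly zero count map
    when no events exist.
    """
    cases = table.loc[table["event"].astype(bool)].copy()
    if len(cases):
        cases["event_type"] = [
            resolve_hierarchy(t if isinstance(t, (list, tuple)) else [t])
            for t in cases["event_type"]
        ]
    counts = {lab: int((cases["event_type"] == lab).sum()) if len(cases) else 0 for lab in EVENT_HIERARCHY}
    return cases, counts


def fit_propensity(table: pd.DataFrame, covariates=DEFAULT_MATCH_COVARIATES) -> pd.Series:
    """Propensity of case status from a main-effects logistic model.

    Categorical covariates are dummy-coded; raises with diagnostics on
    (quasi-)separation.
    """
    import statsmodels.api as sm

    y = table["event"].astype(int).to_numpy()
    X = pd.get_dummies(table[list(covariates)], drop_first=True, dtype=float).astype(float)
    X = sm.add_constant(X, has_constant="add")
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # PerfectSeparationError and friends
        raise RuntimeError(f"propensity model failed ({exc}); check for separation in {list(covariates)}") from exc
    params = np.asarray(fit.params, dtype=float)
    if not np.all(np.isfinite(params)) or np.abs(params).max() > 1e3:
        raise RuntimeError("propensity model shows signs of separation (exploding coefficients)")
    return pd.Series(np.asarray(fit.predict(X), dtype=float), index=table.index, name="propensity")


@dataclass
class MatchedDesign:
    case_ids: list
    control_ids: list
    matches: dict  # case id -> list of control ids
    propensity: pd.Series
    ratio: int
    caliper: float
    smd_before: pd.Series | None = None
    smd_after: pd.Series | None = None
    unmatched_case_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.control_ids)) != len(self.control_ids):
            raise ValueError("matched controls are not unique (matching must be without replacement)")

    @property
    def achieved_ratio(self) -> float:
        return len(self.control_ids) / max(len(self.case_ids), 1)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"case_id": cid, "control_id": ctl, "order": k}
            for cid, ctls in self.matches.items()
            for k, ctl in enumerate(ctls)
        ]
        return pd.DataFrame(rows, columns=["case_id", "control_id", "order"])


def match(
    cases: pd.DataFrame,
    pool: pd.DataFrame,
    propensity: pd.Series,
    ratio: int = 2,
    caliper_sd: float = 0.2,
    seed: int = 0,
) -> MatchedDesign:
    """Greedy nearest-neighbour matching without replacement on logit-PS.

    Runs ``ratio`` passes of 1:1 matching; within each pass cases are
    processed in randomised order under ``seed`` and each takes its nearest
    still-unused pool subject within the caliper (``caliper_sd`` x SD of the
    logit propensity over cases plus pool).  Cases keep however many (<=
    ratio) controls land inside the caliper; zero-match cases are retained
    and listed.
    """
    if len(pool) == 0:
        raise ValueError("empty control pool")
    overlap = set(cases["id"]) & set(pool["id"])
    if overlap:
        raise ValueError(f"pool overlaps cases: {sorted(overlap)[:5]}...")
    eps = 1e-12
    lp = logit(np.clip(propensity, eps, 1 - eps))
    lp_cases = lp.loc[cases.index].to_numpy()
    lp_pool = lp.loc[pool.index].to_numpy()
    sd = np.concatenate([lp_cases, lp_pool]).std(ddof=1)
    caliper = caliper_sd * sd

    rng = np.random.default_rng(seed)
    order_pool = np.argsort(lp_pool, kind="stable")
    sorted_pool = lp_pool[order_pool]
    used = np.zeros(len(pool), dtype=bool)
    matches: dict = {cid: [] for cid in cases["id"]}
    case_ids = cases["id"].to_numpy()
    pool_ids = pool["id"].to_numpy()

    for _ in range(ratio):
        for i in rng.permutation(len(cases)):
            target = lp_cases[i]
            j = int(np.searchsorted(sorted_pool, target))
            best, best_d = -1, np.inf
            for step, rng_iter in ((-1, range(j - 1, -1, -1)), (1, range(j, len(sorted_pool)))):
                for k in rng_iter:
                    d = abs(sorted_pool[k] - target)
                    if d >= best_d:
                        break
                    if not used[order_pool[k]]:
                        best, best_d = order_pool[k], d
                        break
            if best >= 0 and best_d <= caliper:
                used[best] = True
                matches[case_ids[i]].append(pool_ids[best])

    control_ids = [c for ctls in matches.values() for c in ctls]
    unmatched = [cid for cid, ctls in matches.items() if not ctls]
    return MatchedDesign(
        case_ids=list(case_ids),
        control_ids=control_ids,
        matches=matches,
        propensity=propensity,
        ratio=ratio,
        caliper=float(caliper),
        unmatched_case_ids=unmatched,
    )


def smd(values, group) -> float:
    """Standardised mean difference between two groups.

    Continuous: ``|m1 - m0| / sqrt((s1^2 + s0^2) / 2)``.  Categorical (any
    non-numeric input): the per-level binary SMDs aggregated as their
    maximum.  Zero pooled variance with unequal means flags as inf.
    """
    values = pd.Series(list(values))
    group = np.asarray(list(group), dtype=bool)
    if group.all() or (~group).all():
        raise ValueError("both groups must be non-empty")
    if not pd.api.types.is_numeric_dtype(values) or values.dtype == bool:
        levels = values.unique()
        if len(levels) <= 1:
            return 0.0
        return max(smd((values == lev).astype(float), group) for lev in levels)
    x1 = values[group].to_numpy(dtype=float)
    x0 = values[~group].to_numpy(dtype=float)
    m1, m0 = x1.mean(), x0.mean()
    s1 = x1.var(ddof=1) if len(x1) > 1 else 0.0
    s0 = x0.var(ddof=1) if len(x0) > 1 else 0.0
    denom = np.sqrt((s1 + s0) / 2.0)
    if denom == 0.0:
        return 0.0 if m1 == m0 else float("inf")
    return float(abs(m1 - m0) / denom)


def smd_table(table: pd.DataFrame, case_ids, control_ids, covariates=DEFAULT_MATCH_COVARIATES) -> pd.Series:
    """SMD per covariate between the given case and control id sets."""
    idx = table.set_index("id")
    both = list(case_ids) + list(control_ids)
    grp = np.array([True] * len(list(case_ids)) + [False] * len(list(control_ids)))
    sub = idx.loc[both]
    return pd.Series({cov: smd(sub[cov], grp) for cov in covariates}, name="smd")
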