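"""The integrated risk tool (IRT): clinical risk plus PRS on the log-odds scale.

``irt = expit(logit(clinical) + beta * PRS_z - offset)``, reported on the
same percentage scale and against the same actionable threshold as the
clinical score.  The default calibration offset ``beta**2 / 2`` makes the
combination mean-preserving when ``PRS_z ~ N(0,1)`` independently of the
clinical score (E[exp(beta*Z - beta^2/2)] = 1), so the population-average
event odds are unchanged by the genetic update.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .clinical_scores import ThresholdScheme, categorize, get_scheme

__all__ = ["IRTConfig", "integrate", "assess"]


@dataclass(frozen=True)
class IRTConfig:
    """beta: log-odds per PRS SD; offset defaults to beta**2/2 (None)."""

    beta: float = math.log(1.6)
    calibration_offset: float | None = None
    scheme: str = "qrisk2"

    def __post_init__(self) -> None:
        if not math.isfinite(self.beta):
            raise ValueError("beta must be finite")
        if self.calibration_offset is not None and not math.isfinite(self.calibration_offset):
            raise ValueError("calibration_offset must be finite")

    @property
    def offset(self) -> float:
        return self.beta**2 / 2.0 if self.calibration_offset is None else self.calibration_offset


def integrate(clinical_pct, prs_z, cfg: IRTConfig) -> np.ndarray:
    """IRT 10-year risk percent; strictly increasing in both arguments.

    Raises when any clinical risk touches 0 or 100 (logit undefined).
    """
    clinical_pct = np.asarray(clinical_pct, dtype=float)
    prs_z = np.asarray(prs_z, dtype=float)
    if np.any(clinical_pct <= 0.0) or np.any(clinical_pct >= 100.0):
        raise ValueError("clinical risk must lie strictly inside (0, 100)%")
    if not np.all(np.isfinite(prs_z)):
        raise ValueError("PRS_z contains non-finite values")
    return 100.0 * expit(logit(clinical_pct / 100.0) + cfg.beta * prs_z - cfg.offset)


def assess(
    table: pd.DataFrame,
    prs_z: np.ndarray,
    cfg: IRTConfig,
    clinical_col: str = "qrisk2",
    scheme: ThresholdScheme | str | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-subject clinical/IRT categories and reclassification direction.

    direction is 'up' iff clinically non-high but IRT-high, 'down' iff the
    reverse, else 'none'; ``combined_high`` is the union rule (high by either
    score).  Subjects with missing PRS are excluded and their ids returned.
    """
    scheme = get_scheme(cfg.scheme) if scheme is None else (get_scheme(scheme) if isinstance(scheme, str) else scheme)
    prs_z = np.asarray(prs_z, dtype=float)
    if len(prs_z) != len(table):
        raise ValueError("prs_z length does not match table")
    ok = np.isfinite(prs_z)
    excluded = table.loc[~ok, "id"].tolist() if "id" in table.columns else list(np.where(~ok)[0])
    sub = table.loc[ok].reset_index(drop=True)
    z = prs_z[ok]

    clin = sub[clinical_col].to_numpy(dtype=float)
    irt = integrate(clin, z, cfg)
    ages = sub["age"].to_numpy(dtype=float)
    clin_cat = np.array([categorize(s, a, scheme) for s, a in zip(clin, ages)])
    irt_cat = np.array([categorize(s, a, scheme) for s, a in zip(irt, ages)])
    clin_high = clin_cat == "high"
    irt_high = irt_cat == "high"
    direction = np.where(
        ~clin_high & irt_high, "up", np.where(clin_high & ~irt_high, "down", "none")
    )
    out = pd.DataFrame(
        {
            "id": sub["id"] if "id" in sub.columns else np.arange(len(sub)),
            "clinical_pct": clin,
            "irt_pct": irt,
            "clinical_cat": clin_cat,
            "irt_cat": irt_cat,
            "clinical_high": clin_high,
            "irt_high": irt_high,
            "combined_high": clin_high | irt_high,
            "direction": direction,
        }
    )
    # union-rule sanity: combined sensitivity can never fall below clinical
    assert (out["combined_high"] >= out["clinical_high"]).all()
    return out, excluded
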