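"""Polygenic score computation and ancestry standardisation.

A PRS is the weighted sum of effect-allele dosages over the variants shared
between a weight set and a genotype matrix.  Raw scores are put on the
analysis scale by regressing out genetic-ancestry principal components fitted
on a reference sample and dividing by the residual SD, so that reference
subjects have approximately zero mean and unit variance (K = 0 degenerates to
plain z-scoring).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_cohort import GenotypeMatrix

__all__ = [
    "PRSWeightSet",
    "VariantAlignment",
    "AncestryModel",
    "StandardizedPRS",
    "align_weights",
    "score_prs",
    "compute_pcs",
    "fit_ancestry_model",
    "standardize_prs",
]

WEIGHT_COLUMNS = ["id", "chrom", "pos", "effect_allele", "other_allele", "weight"]
_AMBIGUOUS = {frozenset({"A", "T"}), frozenset({"C", "G"})}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class PRSWeightSet:
    """Per-variant effect alleles and per-allele log-odds weights."""

    table: pd.DataFrame
    build: str = "unknown"

    def __post_init__(self) -> None:
        missing = [c for c in WEIGHT_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"weight table missing columns: {missing}")
        if self.table["id"].duplicated().any():
            dups = sorted(self.table.loc[self.table["id"].duplicated(), "id"].unique())
            raise ValueError(f"duplicate variant ids in weight set: {dups}")
        w = self.table["weight"].to_numpy(dtype=float)
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class VariantAlignment:
    """Map from weight rows to genotype columns with orientation flags."""

    variant_idx: np.ndarray  # columns of the genotype matrix
    weight_idx: np.ndarray  # rows of the weight table
    flipped: np.ndarray  # True where the dosage counts the *other* allele
    ambiguous_ids: list[str] = field(default_factory=list)
    unmatched_ids: list[str] = field(default_factory=list)

    @property
    def n_matched(self) -> int:
        return len(self.variant_idx)


def align_weights(gm: GenotypeMatrix, weights: PRSWeightSet) -> VariantAlignment:
    """Match weight-set variants to genotype columns by id (chrom:pos fallback).

    A match is *direct* when the weight's effect allele is the dosage-counted
    allele and *flipped* when it is the other allele (effective dosage 2-d).
    Strand-ambiguous A/T and C/G variants are excluded and reported, as are
    weights with no matching variant or inconsistent allele pairs.
    """
    gv = gm.variants
    if gv["id"].duplicated().any():
        raise ValueError("duplicate variant ids in genotype matrix")
    by_id = {v: j for j, v in enumerate(gv["id"])}
    by_pos = {(c, p): j for j, (c, p) in enumerate(zip(gv["chrom"].astype(str), gv["pos"]))}

    vi, wi, fl = [], [], []
    ambiguous, unmatched = [], []
    for i, row in weights.table.iterrows():
        j = by_id.get(row["id"])
        if j is None:
            j = by_pos.get((str(row["chrom"]), row["pos"]))
        if j is None:
            unmatched.append(row["id"])
            continue
        ea, oa = gv["effect_allele"].iloc[j], gv["other_allele"].iloc[j]
        if frozenset({ea, oa}) in _AMBIGUOUS:
            ambiguous.append(row["id"])
            continue
        if (row["effect_allele"], row["other_allele"]) == (ea, oa):
            flip = False
        elif (row["effect_allele"], row["other_allele"]) == (oa, ea):
            flip = True
        else:
            unmatched.append(row["id"])
            continue
        vi.append(j)
        wi.append(i)
        fl.append(flip)
    return VariantAlignment(
        np.asarray(vi, dtype=int),
        np.asarray(wi, dtype=int),
        np.asarray(fl, dtype=bool),
        ambiguous,
        unmatched,
    )


def score_prs(
    gm: GenotypeMatrix,
    weights: PRSWeightSet,
    alignment: VariantAlignment | None = None,
    missing_policy: str = "mean",
) -> tuple[np.ndarray, list[str]]:
    """Raw scores: sum over matched variants of weight x effective dosage.

    Missing dosages are imputed as twice the effect-allele frequency of the
    variant's non-missing calls (``missing_policy='mean'``) or dropped with
    per-subject weight renormalisation (``'skip'``).  Subjects missing every
    matched variant get NaN and are returned in the flagged list rather than
    silently scored 0.
    """
    if alignment is None:
        alignment = align_weights(gm, weights)
    if missing_policy not in ("mean", "skip"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    if alignment.n_matched == 0:
        return np.full(gm.n_subjects, np.nan), list(gm.sample_ids)

    d = gm.dosages[:, alignment.variant_idx].copy()
    miss = gm.missing_mask[:, alignment.variant_idx]
    d[:, alignment.flipped] = 2.0 - d[:, alignment.flipped]
    w = weights.table["weight"].to_numpy(dtype=float)[alignment.weight_idx]

    all_missing = miss.all(axis=1)
    if missing_policy == "mean":
        with np.errstate(invalid="ignore"):
            col_mean = np.nanmean(np.where(miss, np.nan, d), axis=0)
        col_mean = np.where(np.isnan(col_mean), 1.0, col_mean)  # fully missing column
        d = np.where(miss, col_mean[None, :], d)
        scores = d @ w
    else:
        dw = np.where(miss, 0.0, d) @ w
        wt_present = (~miss) @ np.abs(w)
        wt_total = np.abs(w).sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            scores = dw * (wt_total / wt_present)
        scores[wt_present == 0] = np.nan
    scores = np.asarray(scores, dtype=float)
    scores[all_missing] = np.nan
    flagged = [gm.sample_ids[i] for i in np.where(all_missing)[0]]
    return scores, flagged


def compute_pcs(gm: GenotypeMatrix, k: int = 4, seed: int = 0) -> np.ndarray:
    """Subject scores on the top-k PCs of the centred dosage matrix.

    Missing dosages are mean-filled before the truncated SVD.  Intended as a
    convenience for synthetic references; real analyses typically supply PCs
    from an external panel.
    """
    from sklearn.decomposition import TruncatedSVD

    if k <= 0:
        return np.empty((gm.n_subjects, 0))
    d = gm.dosages.copy()
    col_mean = np.ma.masked_array(d, mask=gm.missing_mask).mean(axis=0)
    d = np.where(gm.missing_mask, np.asarray(col_mean)[None, :], d)
    d = d - d.mean(axis=0)
    k = min(k, min(d.shape) - 1)
    svd = TruncatedSVD(n_components=k, random_state=seed)
    return svd.fit_transform(d)


@dataclass
class AncestryModel:
    """Mean-only PC regression: PRS_z = (raw - Xb) / residual SD."""

    coef: np.ndarray  # intercept followed by K PC coefficients
    residual_sd: float
    k: int

    def __post_init__(self) -> None:
        if self.residual_sd <= 0:
            raise ValueError("residual SD must be positive")

    def predict_mean(self, pcs: np.ndarray | None) -> np.ndarray:
        pcs = _as_pcs(pcs, self.k)
        X = np.column_stack([np.ones(len(pcs)), pcs]) if self.k else np.ones((len(pcs), 1))
        return X @ self.coef

    def to_dict(self) -> dict:
        return {"coef": list(map(float, self.coef)), "residual_sd": float(self.residual_sd), "k": self.k}


@dataclass
class StandardizedPRS:
    raw: np.ndarray
    prs_z: np.ndarray

    def to_frame(self, ids=None) -> pd.DataFrame:
        out = pd.DataFrame({"raw": self.raw, "prs_z": self.prs_z})
        if ids is not None:
            out.insert(0, "id", list(ids))
        return out


def _as_pcs(pcs, k: int) -> np.ndarray:
    if k == 0:
        if pcs is None:
            raise ValueError("need at least the number of subjects; pass an (n,0) array or raw length via pcs")
        pcs = np.asarray(pcs, dtype=float)
        return pcs.reshape(len(pcs), -1)[:, :0]
    pcs = np.asarray(pcs, dtype=float)
    if pcs.ndim != 2 or pcs.shape[1] < k:
        raise ValueError(f"expected >= {k} PC columns, got shape {pcs.shape}")
    return pcs[:, :k]


def fit_ancestry_model(raw_ref: np.ndarray, pcs_ref: np.ndarray | None, k: int) -> AncestryModel:
    """Least-squares fit of the raw reference scores on K PCs.

    K = 0 reduces to plain (mean, SD) z-scoring.  Raises on collinear PCs or
    on an (effectively) zero residual SD, which would make standardisation
    ill-defined.
    """
    raw_ref = np.asarray(raw_ref, dtype=float)
    n = len(raw_ref)
    if n <= k + 1:
        raise ValueError(f"reference size {n} too small for K={k}")
    if k == 0:
        X = np.ones((n, 1))
    else:
        X = np.column_stack([np.ones(n), _as_pcs(pcs_ref, k)])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("collinear principal components")
    coef, *_ = np.linalg.lstsq(X, raw_ref, rcond=None)
    resid = raw_ref - X @ coef
    sd = float(np.sqrt((resid**2).sum() / max(n - (k + 1), 1)))
    if sd < 1e-12 * max(1.0, float(np.abs(raw_ref).max())):
        raise ValueError("residual SD is (near) zero; scores are deterministic in the PCs")
    return AncestryModel(coef=np.asarray(coef, dtype=float), residual_sd=sd, k=k)


def standardize_prs(raw: np.ndarray, pcs: np.ndarray | None, model: AncestryModel) -> StandardizedPRS:
    """Apply a fitted ancestry model: subtract the PC-predicted mean, scale."""
    raw = np.asarray(raw, dtype=float)
    if model.k == 0:
        mean = np.full(len(raw), model.coef[0])
    else:
        mean = model.predict_mean(pcs)
    z = (raw - mean) / model.residual_sd
    return StandardizedPRS(raw=raw, prs_z=z)
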