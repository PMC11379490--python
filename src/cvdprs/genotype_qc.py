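"""Pre-imputation variant QC: call rate, minor allele frequency, HWE.

Filters are applied in the fixed order call-rate -> MAF -> HWE and each
removed variant is attributed to the first filter it fails.  Defaults are
the conventional array-QC thresholds: call rate >= 98%, MAF >= 0.005 and
Hardy–Weinberg exact p >= 1e-6.  HWE is tested on all subjects (not controls
only) using hard-called genotypes (dosages rounded to the nearest integer).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthetic_cohort import GenotypeMatrix

__all__ = ["QCThresholds", "QCReport", "hwe_exact_test", "apply_qc"]


@dataclass(frozen=True)
class QCThresholds:
    min_call_rate: float = 0.98
    min_maf: float = 0.005
    hwe_p_floor: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "min_maf", "hwe_p_floor"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")


@dataclass
class QCReport:
    """Removed-variant ids per filter plus the surviving count."""

    removed_call_rate: list[str] = field(default_factory=list)
    removed_maf: list[str] = field(default_factory=list)
    removed_hwe: list[str] = field(default_factory=list)
    n_input: int = 0
    n_surviving: int = 0

    @property
    def counts(self) -> tuple[int, int, int]:
        return (len(self.removed_call_rate), len(self.removed_maf), len(self.removed_hwe))

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_surviving": self.n_surviving,
            "removed": {
                "call_rate": self.removed_call_rate,
                "maf": self.removed_maf,
                "hwe": self.removed_hwe,
            },
            "counts": {
                "call_rate": len(self.removed_call_rate),
                "maf": len(self.removed_maf),
                "hwe": len(self.removed_hwe),
            },
        }


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact test for Hardy–Weinberg proportions.

    Conditional on the observed allele counts, the p-value is the summed
    probability of all heterozygote counts whose conditional probability does
    not exceed that of the observed count (the standard SNP exact-test
    construction).  Symmetric in the two homozygote counts.

    Returns a p-value in (0, 1].
    """
    for v in (n_AA, n_Aa, n_aa):
        if v < 0 or v != int(v):
            raise ValueError("genotype counts must be non-negative integers")
    n_AA, n_Aa, n_aa = int(n_AA), int(n_Aa), int(n_aa)
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("all genotype counts are zero")

    n_rare = 2 * min(n_AA, n_aa) + n_Aa  # minor allele count
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0  # monomorphic: single attainable table

    # Heterozygote counts share the parity of the minor allele count.
    het_obs = n_Aa
    # Unnormalised probabilities over all attainable het counts, built by the
    # standard recurrences outward from the (near-)modal count.
    mid = int(round(n_rare * (2 * n - n_rare) / (2.0 * n)))
    if mid % 2 != n_rare % 2:
        mid += 1 if mid < n_rare else -1
    probs = {mid: 1.0}
    # downward recurrence: P(h-2)/P(h) = h(h-1) / (4 * nAA(h-2+..) ...)
    h = mid
    hom_r = (n_rare - h) // 2  # rare homozygotes
    hom_c = n - h - hom_r
    while h >= 2:
        nxt = probs[h] * h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        h -= 2
        hom_r += 1
        hom_c += 1
        probs[h] = nxt
    h = mid
    hom_r = (n_rare - h) // 2
    hom_c = n - h - hom_r
    while h <= n_rare - 2 and hom_r >= 1 and hom_c >= 1:
        nxt = probs[h] * 4.0 * hom_r * hom_c / ((h + 2.0) * (h + 1.0))
        h += 2
        hom_r -= 1
        hom_c -= 1
        probs[h] = nxt
    total = sum(probs.values())
    p_obs = probs.get(het_obs)
    if p_obs is None:  # inconsistent table (e.g. het count parity impossible)
        raise ValueError(f"heterozygote count {het_obs} unattainable for allele count {n_rare}")
    tol = 1e-12 * p_obs
    p = sum(v for v in probs.values() if v <= p_obs + tol) / total
    return min(p, 1.0)


def apply_qc(gm: GenotypeMatrix, thresholds: QCThresholds | None = None) -> tuple[GenotypeMatrix, QCReport]:
    """Filter variants by call rate, then MAF, then HWE.

    MAF uses non-missing dosages folded to the minor allele; HWE uses rounded
    genotype counts of non-missing calls.  Idempotent: surviving variants
    pass all three filters, so a second application removes nothing.
    """
    if gm.n_variants == 0:
        raise ValueError("empty genotype matrix")
    thr = thresholds or QCThresholds()

    call = gm.call_rate()
    af = gm.effect_allele_freq()
    maf = np.minimum(af, 1.0 - af)
    counts = gm.genotype_counts()

    report = QCReport(n_input=gm.n_variants)
    keep = np.ones(gm.n_variants, dtype=bool)
    ids = gm.variants["id"].to_numpy()
    for j in range(gm.n_variants):
        if call[j] < thr.min_call_rate:
            report.removed_call_rate.append(ids[j])
            keep[j] = False
        elif maf[j] < thr.min_maf:
            report.removed_maf.append(ids[j])
            keep[j] = False
        else:
            n0, n1, n2 = counts[j]
            if (n0 + n1 + n2) > 0 and hwe_exact_test(n2, n1, n0) < thr.hwe_p_floor:
                report.removed_hwe.append(ids[j])
                keep[j] = False
    report.n_surviving = int(keep.sum())
    return gm.subset_variants(np.where(keep)[0]), report
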