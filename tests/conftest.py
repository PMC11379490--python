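import math

import numpy as np
import pandas as pd
import pytest

from cvdprs.prs_engine import PRSWeightSet
from cvdprs.synthetic_cohort import (
    GenotypeMatrix,
    SimulationConfig,
    simulate_cohort,
    simulate_genotypes,
    simulate_weights,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_subjects=2000, n_variants=30, seed=7)


@pytest.fixture(scope="session")
def small_gm(small_config):
    return simulate_genotypes(small_config)


@pytest.fixture(scope="session")
def small_weights(small_gm):
    return simulate_weights(small_gm, seed=17)


@pytest.fixture(scope="session")
def small_cohort(small_config, small_gm, small_weights):
    return simulate_cohort(small_config, small_gm, small_weights)


def make_gm(dosages, missing=None, effect="A", other="G", ids=None):
    """Hand-build a GenotypeMatrix from a dense dosage array."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    if missing is None:
        missing = np.zeros_like(dosages, dtype=bool)
    effect = [effect] * m if isinstance(effect, str) else list(effect)
    other = [other] * m if isinstance(other, str) else list(other)
    variants = pd.DataFrame(
        {
            "id": ids or [f"v{j}" for j in range(m)],
            "chrom": ["1"] * m,
            "pos": np.arange(1, m + 1) * 10,
            "effect_allele": effect,
            "other_allele": other,
            "af": np.full(m, np.nan),
        }
    )
    return GenotypeMatrix(dosages, np.asarray(missing, dtype=bool), variants)


def make_weights(gm, weights, flip=None):
    """Weight set matching gm's variants; flip swaps effect/other alleles."""
    tbl = gm.variants[["id", "chrom", "pos", "effect_allele", "other_allele"]].copy()
    if flip is not None:
        for j in np.where(flip)[0]:
            ea, oa = tbl.loc[j, "effect_allele"], tbl.loc[j, "other_allele"]
            tbl.loc[j, "effect_allele"], tbl.loc[j, "other_allele"] = oa, ea
    tbl["weight"] = np.asarray(weights, dtype=float)
    return PRSWeightSet(tbl)


def hwe_enumeration_oracle(n_AA, n_Aa, n_aa):
    """Brute-force exact HWE p-value by full enumeration over het counts.

    Integer arithmetic: the number of genotype assignments with h hets given
    n diploids and n_rare minor alleles is C(n, h) * C(n-h, (n_rare-h)/2) * 2^h.
    """
    n = n_AA + n_Aa + n_aa
    n_rare = 2 * min(n_AA, n_aa) + n_Aa
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0
    weights = {}
    for h in range(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2):
        hr = (n_rare - h) // 2
        if hr < 0 or h + hr > n:
            continue
        weights[h] = math.comb(n, h) * math.comb(n - h, hr) * (2**h)
    total = sum(weights.values())
    w_obs = weights[n_Aa]
    return sum(w for w in weights.values() if w <= w_obs) / total
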