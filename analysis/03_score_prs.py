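"""Score the PRS and standardise it for ancestry.

Aligns the weight file to the QC'd dosages (reporting strand-ambiguous and
unmatched variants), computes raw scores, fits the PC-regression ancestry
model (2 PCs) on the cohort as its own reference, and writes id/raw/prs_z.
After standardisation the cohort PRS should sit at ~0 mean, ~1 SD.
"""
import argparse
from pathlib import Path

import numpy as np

from cvdprs import io as cio
from cvdprs.prs_engine import (
    align_weights,
    compute_pcs,
    fit_ancestry_model,
    score_prs,
    standardize_prs,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--pcs", type=int, default=2)
    ap.add_argument("--seed", type=int, default=42)
    args = ap.parse_args()

    gm = cio.read_genotypes(args.datadir / "genotypes_qc.tsv")
    weights = cio.read_weights(args.datadir / "weights.tsv")
    aln = align_weights(gm, weights)
    raw, flagged = score_prs(gm, weights, aln)
    pcs = compute_pcs(gm, k=args.pcs, seed=args.seed)
    ok = np.isfinite(raw)
    model = fit_ancestry_model(raw[ok], pcs[ok], args.pcs)
    std = standardize_prs(raw, pcs, model)
    std.to_frame(gm.sample_ids).to_csv(args.datadir / "prs_scores.csv", index=False)
    print(
        f"scored {aln.n_matched} variants ({len(aln.ambiguous_ids)} ambiguous, "
        f"{len(aln.unmatched_ids)} unmatched, {len(flagged)} subjects flagged); "
        f"PRS_z mean {np.nanmean(std.prs_z):+.3f}, SD {np.nanstd(std.prs_z, ddof=1):.3f}"
    )


if __name__ == "__main__":
    main()
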