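"""Simulate the study cohort: genotypes, PRS weights and a health-check table.

Generates a 20 000-subject cohort (ages 40-74, UK-like covariate marginals,
10-year event probability 10% on average, PRS odds ratio 1.6 per SD) and a
150-variant genotype matrix, then plants a known set of QC violations
(5 low-call-rate, 3 low-MAF, 2 HWE-deviant variants) so the next stage can
demonstrate planted-truth recovery.  Writes cohort.csv, genotypes.tsv,
weights.tsv, the planted-truth JSON and the config YAML under results/data/.
"""
import argparse
import json
from pathlib import Path

from cvdprs import io as cio
from cvdprs.synthetic_cohort import (
    SimulationConfig,
    inject_qc_violations,
    simulate_cohort,
    simulate_genotypes,
    simulate_weights,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--outdir", type=Path, default=Path("results/data"))
    ap.add_argument("--n-subjects", type=int, default=20000)
    ap.add_argument("--n-variants", type=int, default=150)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    cfg = SimulationConfig(
        n_subjects=args.n_subjects, n_variants=args.n_variants, seed=args.seed
    )
    gm = simulate_genotypes(cfg)
    weights = simulate_weights(gm, seed=args.seed + 10)
    table = simulate_cohort(cfg, gm, weights)
    gm_dirty, planted = inject_qc_violations(gm, 5, 3, 2, seed=args.seed + 20)

    meta = {"seed": args.seed, "n_subjects": args.n_subjects, "n_variants": args.n_variants}
    cio.write_dosage_tsv(gm_dirty, args.outdir / "genotypes.tsv", meta)
    cio.write_weights(weights, args.outdir / "weights.tsv", meta)
    cio.write_participants(table, args.outdir / "cohort.csv", meta)
    (args.outdir / "planted_qc_truth.json").write_text(json.dumps(planted, indent=2))
    cio.dump_yaml(
        {
            "seed": args.seed,
            "n_subjects": args.n_subjects,
            "n_variants": args.n_variants,
            "prs_beta": cfg.prs_beta,
            "baseline_event_rate": cfg.baseline_event_rate,
        },
        args.outdir / "config.yaml",
    )
    n_ev = int(table["event"].sum())
    print(
        f"cohort: {args.n_subjects} subjects, {n_ev} events "
        f"({100 * n_ev / args.n_subjects:.1f}%), mean clinical risk "
        f"{table['qrisk2'].mean():.1f}%; planted QC violations 5/3/2"
    )


if __name__ == "__main__":
    main()
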