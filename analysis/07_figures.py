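"""Figures: PRS distributions by case status, percentile enrichment,
clinical-vs-combined sensitivity bars.  Writes PNGs under results/figures/.
"""
import argparse
import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from cvdprs import io as cio


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results/figures"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    table = cio.read_participants(args.datadir / "cohort.csv")
    scores = pd.read_csv(args.datadir / "prs_scores.csv")
    table = table.drop(columns=["prs_z"]).merge(scores[["id", "prs_z"]], on="id")
    design = pd.read_csv(args.datadir / "matched_design.csv")
    report = json.loads(Path("results/evaluation.json").read_text())

    cases = table.loc[table["event"]]
    controls = table.set_index("id").loc[design["control_id"]].reset_index()

    fig, ax = plt.subplots(figsize=(6, 4))
    for grp, lab in ((cases, "cases"), (controls, "matched controls")):
        ax.hist(grp["prs_z"], bins=40, density=True, alpha=0.5, label=lab)
        ax.axvline(grp["prs_z"].mean(), ls="--", lw=1)
    ax.set_xlabel("standardised PRS")
    ax.set_ylabel("density")
    ax.legend()
    fig.savefig(args.outdir / "prs_distribution.png", dpi=150, bbox_inches="tight")

    enr = pd.DataFrame(report["enrichment"])
    fig, ax = plt.subplots(figsize=(5, 4))
    labels = [f"top {int(100 * c)}%" for c in enr["cut"]]
    ax.bar(labels, 100 * enr["case_fraction"])
    for x, c in zip(labels, enr["cut"]):
        ax.hlines(100 * c, x, x, color="orange", lw=3)
    ax.set_ylabel("% of cases above PRS percentile")
    fig.savefig(args.outdir / "enrichment.png", dpi=150, bbox_inches="tight")

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.bar(
        ["clinical", "clinical or IRT"],
        [report["clinical_sensitivity_pct"], report["combined_sensitivity_pct"]],
        color=["purple", "steelblue"],
    )
    ax.set_ylabel("% of cases flagged high risk")
    fig.savefig(args.outdir / "sensitivity.png", dpi=150, bbox_inches="tight")
    print(f"wrote 3 figures to {args.outdir}")


if __name__ == "__main__":
    main()
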