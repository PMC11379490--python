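"""Combine clinical risk and PRS into the integrated risk tool (IRT).

Takes the stored clinical 10-year score (QRISK2 passthrough), adds
beta * PRS_z - beta^2/2 on the log-odds scale (beta = log 1.6), categorises
both scores against the >=10% high-risk threshold and writes the per-subject
assessment with reclassification directions.
"""
import argparse
from pathlib import Path

import pandas as pd

from cvdprs import io as cio
from cvdprs.clinical_scores import qrisk2_passthrough
from cvdprs.integrated_risk import IRTConfig, assess


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    args = ap.parse_args()

    table = cio.read_participants(args.datadir / "cohort.csv")
    scores = pd.read_csv(args.datadir / "prs_scores.csv")
    table = table.drop(columns=["prs_z"]).merge(
        scores.rename(columns={"prs_z": "prs_z"})[["id", "prs_z"]], on="id"
    )
    table["qrisk2"] = qrisk2_passthrough(table)
    assessment, excluded = assess(table, table["prs_z"].to_numpy(float), IRTConfig())
    assessment.to_csv(args.datadir / "assessment.csv", index=False)
    up = (assessment["direction"] == "up").sum()
    down = (assessment["direction"] == "down").sum()
    print(
        f"assessed {len(assessment)} subjects ({len(excluded)} excluded): "
        f"{up} up-classified, {down} down-classified by the IRT"
    )


if __name__ == "__main__":
    main()
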