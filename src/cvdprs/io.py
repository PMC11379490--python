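"""File formats: VCF / dosage-TSV genotypes, PGS-style weight files, cohort CSV.

VCF reading goes through cyvcf2 and takes per-sample dosages from the DS
FORMAT field, falling back to hard-call GT dosages (logged) where DS is
absent.  Positions are 1-based throughout.  Writers emit plain text with a
provenance header line (tool version + config hash) on our own outputs.
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .prs_engine import WEIGHT_COLUMNS, PRSWeightSet
from .synthetic_cohort import GenotypeMatrix

__all__ = [
    "read_genotypes",
    "write_genotypes_vcf",
    "write_dosage_tsv",
    "read_weights",
    "write_weights",
    "read_participants",
    "write_participants",
    "load_yaml",
    "dump_yaml",
    "provenance_line",
]

log = logging.getLogger("cvdprs")

PGS_COLUMNS = {
    "rsID": "id",
    "chr_name": "chrom",
    "chr_position": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "effect_weight": "weight",
}


def provenance_line(config: dict | None = None) -> str:
    from . import __version__

    h = hashlib.sha1(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12] if config else "none"
    return f"# cvdprs v{__version__} config_hash={h}"


def read_genotypes(path, fmt: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from VCF (.vcf) or a dosage TSV.

    The TSV layout is one variant per row: the five metadata columns
    id/chrom/pos/effect_allele/other_allele followed by one numeric column
    per sample (empty or 'NA' for missing).
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix == ".vcf" or path.name.endswith(".vcf.gz") else "dosage-tsv"
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "dosage-tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    dosage_rows, mask_rows, meta = [], [], []
    gt_fallbacks = 0
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1:
            raise ValueError(f"record {i + 1} ({var.CHROM}:{var.POS}): expected exactly one ALT allele")
        ds = None
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            row = np.asarray(ds, dtype=float).reshape(-1)
            miss = ~np.isfinite(row) | (row < 0)
        else:
            gt_fallbacks += 1
            alleles = np.asarray(var.genotypes, dtype=object)[:, :2].astype(int)
            miss = (alleles < 0).any(axis=1)
            row = np.where(miss, 0.0, (alleles == 1).sum(axis=1)).astype(float)
        dosage_rows.append(np.where(miss, 0.0, row))
        mask_rows.append(miss)
        meta.append(
            {
                "id": var.ID or f"{var.CHROM}:{var.POS}:{var.REF}:{var.ALT[0]}",
                "chrom": str(var.CHROM),
                "pos": int(var.POS),
                "effect_allele": var.ALT[0],  # dosage counts ALT copies
                "other_allele": var.REF,
                "af": np.nan,
            }
        )
    if not meta:
        raise ValueError(f"no variant records in {path}")
    if gt_fallbacks:
        log.warning("%d VCF records lacked DS; used GT hard-call dosages", gt_fallbacks)
    dosages = np.vstack(dosage_rows).T
    mask = np.vstack(mask_rows).T
    variants = pd.DataFrame(meta)
    variants["af"] = np.ma.masked_array(dosages, mask=mask).mean(axis=0) / 2.0
    return GenotypeMatrix(dosages, mask, variants, samples)


def write_genotypes_vcf(gm: GenotypeMatrix, path, config: dict | None = None) -> None:
    """Write the matrix as an uncompressed VCF with a DS FORMAT field.

    The effect allele is written as ALT so that DS keeps its meaning of
    effect-allele copy count; dosages use shortest round-trippable decimal
    representation (read->write->read is bit-identical).
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={provenance_line(config)[2:]}\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Effect allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(gm.sample_ids) + "\n")
        v = gm.variants
        for j in range(gm.n_variants):
            cells = [
                "." if gm.missing_mask[i, j] else repr(float(gm.dosages[i, j]))
                for i in range(gm.n_subjects)
            ]
            fh.write(
                "\t".join(
                    [
                        str(v["chrom"].iloc[j]),
                        str(int(v["pos"].iloc[j])),
                        str(v["id"].iloc[j]),
                        str(v["other_allele"].iloc[j]),
                        str(v["effect_allele"].iloc[j]),
                        ".",
                        "PASS",
                        ".",
                        "DS",
                    ]
                    + cells
                )
                + "\n"
            )


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", comment="#")
    meta_cols = ["id", "chrom", "pos", "effect_allele", "other_allele"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise ValueError(f"dosage TSV missing columns: {missing}")
    sample_cols = [c for c in df.columns if c not in meta_cols]
    dosages = df[sample_cols].to_numpy(dtype=float).T
    mask = ~np.isfinite(dosages)
    dosages = np.where(mask, 0.0, dosages)
    variants = df[meta_cols].copy()
    variants["chrom"] = variants["chrom"].astype(str)
    variants["af"] = np.ma.masked_array(dosages, mask=mask).mean(axis=0) / 2.0
    return GenotypeMatrix(dosages, mask, variants, sample_cols)


def write_dosage_tsv(gm: GenotypeMatrix, path, config: dict | None = None) -> None:
    path = Path(path)
    v = gm.variants[["id", "chrom", "pos", "effect_allele", "other_allele"]].copy()
    data = pd.DataFrame(
        np.where(gm.missing_mask, np.nan, gm.dosages).T, columns=gm.sample_ids
    )
    out = pd.concat([v.reset_index(drop=True), data], axis=1)
    with path.open("w") as fh:
        fh.write(provenance_line(config) + "\n")
        out.to_csv(fh, sep="\t", index=False)


def read_weights(path) -> PRSWeightSet:
    """Read a tab-delimited PGS-Catalog-compatible weight file.

    Header required; '#' comment lines skipped; both the PGS column names
    (rsID, chr_name, ...) and our internal ones are accepted.  Duplicate
    variant ids are rejected.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    df = df.rename(columns=PGS_COLUMNS)
    missing = [c for c in WEIGHT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"weight file {path} missing required column(s): {missing}")
    df["chrom"] = df["chrom"].astype(str)
    return PRSWeightSet(df[WEIGHT_COLUMNS].copy(), build=str(path))


def write_weights(weights: PRSWeightSet, path, config: dict | None = None) -> None:
    tbl = weights.table.rename(columns={v: k for k, v in PGS_COLUMNS.items()})
    with Path(path).open("w") as fh:
        fh.write(provenance_line(config) + "\n")
        tbl.to_csv(fh, sep="\t", index=False)


def read_participants(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    for col in ("event", "diabetes", "statin", "white", "bp_treated"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df


def write_participants(table: pd.DataFrame, path, config: dict | None = None) -> None:
    with Path(path).open("w") as fh:
        fh.write(provenance_line(config) + "\n")
        table.to_csv(fh, index=False)


def load_yaml(path) -> dict:
    with Path(path).open() as fh:
        return yaml.safe_load(fh)


def dump_yaml(obj: dict, path) -> None:
    with Path(path).open("w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
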