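"""Readers and writers for the pipeline's file formats.

Conventions: internal coordinates are 1-based inclusive everywhere;
conversions happen only at file boundaries (BED is 0-based half-open on
disk, VCF is 1-based). TSVs are tab-separated UTF-8 with mandatory
headers and ``.`` for missing values; every written table starts with a
comment line embedding the run-configuration hash so outputs from
different configurations are detectable when mixed.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, HRSDPanel, ITEM_COLUMNS

MISSING_TOKEN = "."


# ---------------------------------------------------------------------------
# TSV plumbing
# ---------------------------------------------------------------------------

def write_tsv(frame: pd.DataFrame, path, config_hash: str | None = None, index=True) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        if config_hash:
            fh.write(f"# run_config_hash={config_hash}\n")
        frame.to_csv(fh, sep="\t", na_rep=MISSING_TOKEN, index=index)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", comment="#", na_values=[MISSING_TOKEN], **kwargs
    )


def read_config_hash(path) -> str | None:
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    if first.startswith("# run_config_hash="):
        return first.strip().split("=", 1)[1]
    return None


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

_GT_BY_DOSAGE = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Write diploid GT calls, one biallelic record per variant.

    The counted (minor) allele is emitted as ALT, so a write/read cycle
    preserves dosages exactly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    gm = genotypes.sorted_by_position()
    samples = list(gm.sample_ids)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(gm.variants["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        ref = gm.variants.get("ref", pd.Series("A", index=gm.variant_ids))
        alt = gm.variants.get("alt", pd.Series("C", index=gm.variant_ids))
        for vid in gm.variant_ids:
            row = gm.variants.loc[vid]
            calls = [
                _GT_BY_DOSAGE.get(d, "./.") if not np.isnan(d) else "./."
                for d in gm.dosages[vid]
            ]
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{vid}\t{ref[vid]}\t{alt[vid]}"
                f"\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Read diploid biallelic GT calls into a minor-allele dosage matrix.

    Multiallelic records and duplicated variant ids are rejected with
    record-level diagnostics. If the ALT allele turns out to be the major
    allele in this sample, the dosage is folded to the minor allele and
    the variant is flagged ``flipped``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols: dict[str, np.ndarray] = {}
    meta = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"multiallelic record at {var.CHROM}:{var.POS} "
                f"(ALT={var.ALT}); split or drop it first"
            )
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        if vid in cols:
            raise ValueError(f"duplicated variant id {vid!r}")
        dos = np.empty(len(samples))
        for i, gt in enumerate(var.genotypes):
            a, b = gt[0], gt[1]
            dos[i] = np.nan if (a < 0 or b < 0) else float(a + b)
        alt_freq = np.nanmean(dos) / 2.0 if np.isfinite(dos).any() else np.nan
        flipped = bool(np.isfinite(alt_freq) and alt_freq > 0.5)
        if flipped:
            dos = 2.0 - dos
            ref, alt = var.ALT[0], var.REF
        else:
            ref, alt = var.REF, var.ALT[0]
        cols[vid] = dos
        meta.append(
            {
                "variant_id": vid,
                "chrom": str(var.CHROM),
                "pos": int(var.POS),
                "ref": ref,
                "alt": alt,
                "flipped": flipped,
            }
        )
    if not meta:
        raise ValueError(f"no records in {path}")
    dosages = pd.DataFrame(cols, index=pd.Index(samples, name="sample_id"))
    variants = pd.DataFrame(meta).set_index("variant_id")
    return GenotypeMatrix(dosages, variants)


def write_dosage_tsv(genotypes: GenotypeMatrix, path, config_hash=None) -> None:
    """Variants-as-rows dosage table: metadata columns then one column
    per sample."""
    gm = genotypes.sorted_by_position()
    meta_cols = [c for c in ("chrom", "pos", "ref", "alt", "gene") if c in gm.variants]
    frame = pd.concat([gm.variants[meta_cols], gm.dosages.T], axis=1)
    frame.index.name = "variant_id"
    write_tsv(frame, path, config_hash)


def read_dosage_tsv(path) -> GenotypeMatrix:
    frame = read_tsv(path, index_col="variant_id")
    meta_cols = [c for c in ("chrom", "pos", "ref", "alt", "gene") if c in frame.columns]
    sample_cols = [c for c in frame.columns if c not in meta_cols]
    dosages = frame[sample_cols].T.astype(float)
    dosages.index.name = "sample_id"
    dosages.columns.name = None
    return GenotypeMatrix(dosages, frame[meta_cols].copy())


# ---------------------------------------------------------------------------
# gene intervals (BED)
# ---------------------------------------------------------------------------

def read_genes(path) -> pd.DataFrame:
    """Read gene intervals from 0-based half-open BED into 1-based
    inclusive coordinates; the name column is required."""
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4 or not parts[3] or parts[3] == MISSING_TOKEN:
                raise ValueError(f"{path}:{lineno}: BED record needs a name column")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            rows.append({"gene": name, "chrom": chrom, "start": start + 1, "end": end})
    if not rows:
        raise ValueError(f"no intervals in {path}")
    return pd.DataFrame(rows).set_index("gene")


def write_genes(genes: pd.DataFrame, path) -> None:
    """Write 1-based inclusive intervals as 0-based half-open BED."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for name, row in genes.iterrows():
            fh.write(f"{row['chrom']}\t{row['start'] - 1}\t{row['end']}\t{name}\n")


# ---------------------------------------------------------------------------
# HRSD panel and sample table
# ---------------------------------------------------------------------------

def write_hrsd_tsv(panel: HRSDPanel, path, config_hash=None) -> None:
    write_tsv(panel.data, path, config_hash, index=False)


def read_hrsd_tsv(path) -> HRSDPanel:
    frame = read_tsv(path, dtype={"subject_id": str, "timepoint": str})
    return HRSDPanel(frame)


def write_samples_tsv(samples: pd.DataFrame, path, config_hash=None) -> None:
    write_tsv(samples, path, config_hash)


def read_samples_tsv(path) -> pd.DataFrame:
    return read_tsv(path, index_col="subject_id", dtype={"subject_id": str})
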