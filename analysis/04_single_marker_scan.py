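#!/usr/bin/env python
"""Per-site and pooled additive single-marker scans, Rubin-pooled over
imputations, for the continuous response outcome.

Writes per-site and mega-analysis association tables to
results/assoc/ and prints the strongest signals.
"""

import argparse
from pathlib import Path

from ssri_pgx import io as pgx_io
from ssri_pgx.assoc import scan_mi
from ssri_pgx.phenotypes import derive_phenotypes, multiple_impute


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--m", type=int, default=10)
    ap.add_argument("--outcome", default="response_pct")
    ap.add_argument("--cohort-dir", type=Path, default=Path("results/cohort"))
    ap.add_argument("--qc-dir", type=Path, default=Path("results/qc"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/assoc"))
    args = ap.parse_args()

    gm = pgx_io.read_dosage_tsv(args.qc_dir / "dosages_qc.tsv")
    samples = pgx_io.read_samples_tsv(args.cohort_dir / "samples.tsv")
    samples = samples.loc[gm.sample_ids]
    panel = pgx_io.read_hrsd_tsv(args.cohort_dir / "hrsd.tsv")

    mi = multiple_impute(panel, samples, m=args.m, seed=args.seed)
    tables = [derive_phenotypes(c) for c in mi.completed]
    cov = samples[["age", "sex"]]

    out = args.out_dir
    for site in samples["site"].unique():
        ids = samples.index[samples["site"] == site]
        tab = scan_mi(gm, tables, args.outcome, cov, samples=ids, site=site)
        pgx_io.write_tsv(tab, out / f"scan_{args.outcome}_{site}.tsv")
        best = tab.nsmallest(1, "p")
        print(f"{site}: top marker {best.index[0]} p={best['p'].iloc[0]:.2e}")
    mega = scan_mi(gm, tables, args.outcome, cov, site="mega")
    pgx_io.write_tsv(mega, out / f"scan_{args.outcome}_mega.tsv")
    top = mega.nsmallest(3, "p")
    print("mega-analysis top markers:")
    print(top[["maf", "effect", "se", "p"]].to_string())


if __name__ == "__main__":
    main()
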