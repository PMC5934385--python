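#!/usr/bin/env python
"""Combine the per-site scans by Fisher's method, contrast with the
pooled mega-analysis, and classify significance tiers.

Also reports the LD-adjusted effective number of tests. Writes
results/meta/variants_<outcome>.tsv.
"""

import argparse
from pathlib import Path

from ssri_pgx import io as pgx_io
from ssri_pgx.meta import classify_significance, combine_sites, effective_tests


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outcome", default="response_pct")
    ap.add_argument("--assoc-dir", type=Path, default=Path("results/assoc"))
    ap.add_argument("--qc-dir", type=Path, default=Path("results/qc"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/meta"))
    args = ap.parse_args()

    site_tables = {}
    for path in sorted(args.assoc_dir.glob(f"scan_{args.outcome}_*.tsv")):
        name = path.stem.rsplit("_", 1)[1]
        if name == "mega":
            continue
        site_tables[name] = pgx_io.read_tsv(path, index_col=0)
    mega = pgx_io.read_tsv(args.assoc_dir / f"scan_{args.outcome}_mega.tsv",
                           index_col=0)

    combined = combine_sites(site_tables, mega, args.outcome)
    tiers = classify_significance(
        combined.dropna(subset=["meta_p", "mega_p"]), level="variant"
    )
    pgx_io.write_tsv(tiers, args.out_dir / f"variants_{args.outcome}.tsv")

    gm = pgx_io.read_dosage_tsv(args.qc_dir / "dosages_qc.tsv")
    meff, thresholds = effective_tests(gm)

    reported = tiers[tiers["reported"]]
    print(f"combined {len(tiers)} markers across {list(site_tables)}")
    print(f"reported (suggestive or better in either analysis): {len(reported)}")
    if len(reported):
        cols = ["meta_p", "mega_p", "meta_tier", "mega_tier", "both_significant"]
        print(reported.sort_values("meta_p")[cols].head(10).to_string())
    print(f"Meff = {meff}; LD-adjusted alpha = {thresholds['adjusted_alpha']:.2e}")


if __name__ == "__main__":
    main()
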