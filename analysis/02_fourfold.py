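"""Extract and concatenate fourfold-degenerate sites.

Applies the <100 bp filter, builds the all-sites and 4D-only
concatenations for both simulated gene sets, writes PHYLIP supermatrices
and RAxML partition files under scratch/, and a length table (with the 4D
percentage of total, the statistic the study reports as 12.92 % nuclear /
10.45 % mitochondrial) to results/fourfold_lengths.tsv.
"""

from pathlib import Path

import pandas as pd

from quartetphylo.codon4d import concatenate, filter_short, length_ratio_percent
from quartetphylo.io_formats import load_manifest, write_phylip

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    simdata = ROOT / "scratch" / "simdata"
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    rows = []
    for label in ("nuclear", "mito"):
        genes = filter_short(load_manifest(simdata / label / "manifest.tsv"))
        full = concatenate(genes, "all_sites")
        fourfold = concatenate(genes, "fourfold_only")
        for mode, cat in (("all_sites", full), ("fourfold_only", fourfold)):
            path = simdata / f"{label}_{mode}.phy"
            path.write_text(write_phylip(cat.alignment))
            (simdata / f"{label}_{mode}.partitions").write_text(
                cat.partition_table()
            )
        rows.append(
            {
                "set": label,
                "n_genes": len(genes),
                "total_bp": full.length,
                "fourfold_bp": fourfold.length,
                "fourfold_pct": length_ratio_percent(fourfold.length, full.length),
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(results / "fourfold_lengths.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    print("\npublished-length cross-check:",
          f"715762/5541534 = {length_ratio_percent(715762, 5541534)}%,",
          f"1182/11307 = {length_ratio_percent(1182, 11307)}%")


if __name__ == "__main__":
    main()
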