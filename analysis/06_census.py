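"""Gene-tree census: the headline discordance statistic.

Tallies the per-gene winners from 04_infer.py at the >50 % and >70 %
support cutoffs, tests the counts against a uniform null, and — as a
cross-check of the statistical machinery — recomputes the published
census chi-squares and percentages from the printed Table counts, which
are inputs here.  Outputs: results/census.tsv, results/census_published.tsv.
"""

from pathlib import Path

import pandas as pd

from quartetphylo.census import chisq_uniform, percentages, tally
from quartetphylo.io_formats import write_census_report

ROOT = Path(__file__).resolve().parents[1]

#: Published per-gene census counts (T1, T2, T3) by data set and cutoff.
PUBLISHED = {
    ("nuclear_ML", ">50%"): (1676, 1445, 1162),
    ("nuclear_BI", ">50%"): (1629, 1497, 1132),
    ("nuclear_ML", ">70%"): (835, 732, 514),
    ("nuclear_BI", ">70%"): (1048, 958, 662),
    ("mito_ML", ">50%"): (6, 3, 3),
    ("mito_BI", ">50%"): (5, 4, 2),
}


def main() -> None:
    results = ROOT / "results"
    df = pd.read_csv(results / "gene_trees.tsv", sep="\t")
    tables, stats = [], []
    for cutoff in (0.5, 0.7):
        table = tally(df[["gene_id", "best_topology", "support"]], cutoff)
        tables.append(table)
        stats.append(chisq_uniform(table.counts))
    report = write_census_report(tables, stats)
    (results / "census.tsv").write_text(report)
    print("--- simulated census ---")
    print(report)
    for table in tables:
        print(f"cutoff {table.label}: {table.n_uncounted} genes below cutoff")

    rows = []
    for (dataset, cutoff), counts in PUBLISHED.items():
        chi = chisq_uniform(counts)
        pct = percentages(counts)
        rows.append(
            {
                "dataset": dataset, "cutoff": cutoff,
                "T1": counts[0], "T2": counts[1], "T3": counts[2],
                "pct_T1": pct[0], "pct_T2": pct[1], "pct_T3": pct[2],
                "chi2": round(chi.statistic, 2), "df": chi.df,
                "p": round(chi.p, 3),
            }
        )
    pub = pd.DataFrame(rows)
    pub.to_csv(results / "census_published.tsv", sep="\t", index=False)
    print("--- published counts recomputed ---")
    print(pub.to_string(index=False))


if __name__ == "__main__":
    main()
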