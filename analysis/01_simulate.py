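"""Simulate the study's gene sets.

Generates a nuclear-like set (100 genes at the observed topology mixture
0.39/0.34/0.27, mean length ~1,083 bp, short internal branch) and the
mitochondrial-like preset (13 genes, 11,307 bp total, 5x branch lengths).
FASTA files and manifests go under scratch/simdata/ (regenerable, not part
of the deliverable); a summary table goes to results/.
"""

import sys
from pathlib import Path

import pandas as pd

from quartetphylo.io_formats import write_manifest
from quartetphylo.synthetic_data import SimulationConfig, mito_config, simulate_gene_set

ROOT = Path(__file__).resolve().parents[1]
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
N_NUCLEAR = 100


def main() -> None:
    out = ROOT / "scratch" / "simdata"
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    nuc_cfg = SimulationConfig(n_genes=N_NUCLEAR, seed=SEED)
    nuc, nuc_truth = simulate_gene_set(nuc_cfg)
    write_manifest(nuc, out / "nuclear")
    nuc_truth.to_csv(out / "nuclear" / "truth.tsv", sep="\t", index=False)

    mito, mito_truth = simulate_gene_set(mito_config(SimulationConfig(seed=SEED)))
    write_manifest(mito, out / "mito")
    mito_truth.to_csv(out / "mito" / "truth.tsv", sep="\t", index=False)

    truth = pd.concat([nuc_truth, mito_truth], ignore_index=True)
    summary = (
        truth.groupby("source")
        .agg(n_genes=("gene_id", "count"), total_bp=("length_bp", "sum"),
             mean_bp=("length_bp", "mean"))
        .reset_index()
    )
    summary.to_csv(results / "simulation_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    mix = nuc_truth["topology"].value_counts(normalize=True).sort_index()
    print(f"\nnuclear generating-topology mixture (target 0.39/0.34/0.27):")
    print(mix.to_string())
    print(f"\nwrote FASTA + manifests under {out}")


if __name__ == "__main__":
    main()
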