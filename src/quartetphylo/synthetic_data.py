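"""Simulation of quartet gene sets with the structure the analysis assumes.

The generator produces per-gene codon alignments for the four roles
(Z, B, S, O) by Markov simulation along a quartet tree: a root sequence is
drawn codon-wise from a stop-free codon distribution, then evolved along
the five branches under a reversible nucleotide model, with per-codon-
position rate multipliers standing in for coding constraint (position 3
fastest, position 2 slowest).  Each gene's generating topology is drawn
from a mixture over T1/T2/T3, which is how the observed gene-tree
discordance is emulated without modelling its cause.

Defaults mirror the study conditions: ~1,083 bp mean gene length, topology
mixture (0.39, 0.34, 0.27), short internal branch, and a "mitochondrial-
like" preset with 5x branch lengths and 13 genes totalling 11,307 bp.

Reproducibility: one generator per gene, keyed by (seed, gene index), so a
gene's sequences do not depend on how many genes are simulated.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import PAIRINGS, CodonAlignment, Gene, GeneSet, ROLES, Topology
from .submodel import ModelParams, ModelSpec, _Eigen, build_rate_matrix

STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS: tuple[str, ...] = tuple(
    "".join(c) for c in itertools.product("TCAG", repeat=3)
    if "".join(c) not in STOP_CODONS
)
_BASE_IDX = {b: i for i, b in enumerate("ACGT")}


@dataclass(frozen=True)
class SimModel:
    """Generating substitution model: reversible exchangeabilities + freqs.

    Default: kappa = 4 transition bias with uniform base frequencies.
    Uniform frequencies keep the fourfold codon families at ~52% of root
    codons, which puts the realized nuclear 4D-site fraction near the
    ~13% the pipeline expects from real coding alignments; strongly
    skewed compositions would push it well below that.
    """

    exch: tuple[float, ...] = (1.0, 4.0, 1.0, 1.0, 4.0, 1.0)  # kappa = 4
    freqs: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)

    def engine(self) -> _Eigen:
        pi = np.asarray(self.freqs)
        return _Eigen(build_rate_matrix(np.asarray(self.exch), pi), pi)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters of the generator.

    ``length_law`` is (mean codons, dispersion): per-gene codon counts are
    gamma-distributed with shape ``dispersion`` and the given mean, rounded
    and floored at 34 codons so the 100-bp alignment filter can pass.
    ``fixed_codon_lengths``, when set, overrides the law (mitochondrial
    preset).  Branch lengths are expected substitutions per site at codon
    position 1 (multipliers scale the other positions).
    """

    n_genes: int = 200
    length_law: tuple[float, float] = (361.0, 6.0)  # mean 1,083 bp
    topology_mix: tuple[float, float, float] = (0.39, 0.34, 0.27)
    branch_lengths: tuple[float, float, float, float] = (0.05, 0.05, 0.05, 0.10)
    internal_branch: float = 0.02
    model: SimModel = field(default_factory=SimModel)
    codon_position_rates: tuple[float, float, float] = (1.0, 0.5, 2.5)
    seed: int = 0
    source: str = "nuclear"
    gene_prefix: str = "gene"
    fixed_codon_lengths: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if abs(sum(self.topology_mix) - 1.0) > 1e-12:
            raise ValueError("topology_mix must sum to 1")
        if any(p < 0 for p in self.topology_mix):
            raise ValueError("negative mixture weight")
        if any(b < 0 for b in self.branch_lengths) or self.internal_branch < 0:
            raise ValueError("negative branch length")
        if any(r <= 0 for r in self.codon_position_rates):
            raise ValueError("codon position rates must be positive")
        if self.fixed_codon_lengths is None and self.length_law[0] < 34:
            raise ValueError("mean length must be >= 34 codons")


#: Fixed mitochondrial-like codon lengths (13 genes, 3,769 codons = 11,307 bp),
#: shaped after the relative sizes of the 13 vertebrate mt protein genes.
MITO_CODON_LENGTHS: tuple[int, ...] = (
    318, 347, 515, 228, 68, 227, 261, 115, 99, 459, 607, 176, 349
)


def mito_config(base: SimulationConfig | None = None, seed: int | None = None) -> SimulationConfig:
    """Mitochondrial-like preset: 13 fixed-length genes, branch lengths x5."""
    base = base or SimulationConfig()
    return replace(
        base,
        n_genes=13,
        fixed_codon_lengths=MITO_CODON_LENGTHS,
        branch_lengths=tuple(5 * b for b in base.branch_lengths),
        internal_branch=5 * base.internal_branch,
        source="mitochondrial",
        gene_prefix="mito",
        seed=base.seed if seed is None else seed,
    )


def codon_frequencies_from_bases(freqs: Sequence[float]) -> dict[str, float]:
    """Stop-free codon law proportional to the product of base frequencies."""
    f = {b: float(freqs[i]) for b, i in _BASE_IDX.items()}
    raw = {c: f[c[0]] * f[c[1]] * f[c[2]] for c in SENSE_CODONS}
    total = sum(raw.values())
    return {c: v / total for c, v in raw.items()}


def sample_root_codons(
    frequencies: Mapping[str, float], n_codons: int, rng: np.random.Generator
) -> str:
    """Draw a stop-free root sequence of ``n_codons`` codons."""
    for stop in STOP_CODONS:
        if frequencies.get(stop, 0.0) > 0:
            raise ValueError(f"stop codon in root law: {stop}")
    codons = list(frequencies)
    probs = np.array([frequencies[c] for c in codons], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("codon frequencies must sum to 1")
    draws = rng.choice(len(codons), size=n_codons, p=probs)
    return "".join(codons[i] for i in draws)


def _seq_to_codes(seq: str) -> np.ndarray:
    lut = np.zeros(256, dtype=np.int8)
    for b, i in _BASE_IDX.items():
        lut[ord(b)] = i
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _codes_to_seq(codes: np.ndarray) -> str:
    return "".join("ACGT"[i] for i in codes)


def _evolve_branch(
    parent: np.ndarray,
    t: float,
    engine: _Eigen,
    site_rates: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One branch of Markov evolution with per-site rate multipliers."""
    child = parent.copy()
    if t == 0:
        return child
    for r in np.unique(site_rates):
        P = engine.P(t * float(r))
        C = np.cumsum(P, axis=1)
        C[:, -1] = 1.0
        pos = np.nonzero(site_rates == r)[0]
        u = rng.random(pos.size)
        child[pos] = (u[:, None] > C[parent[pos]]).sum(axis=1)
    return child


def evolve_alignment(
    root: str,
    topology: Topology,
    branches: Sequence[float],
    model: SimModel,
    codon_position_rates: Sequence[float],
    rng: np.random.Generator,
) -> CodonAlignment:
    """Evolve a root sequence along a quartet tree.

    ``branches`` is (bZ, bB, bS, bO, internal).  The root sequence sits at
    internal node *u* (the one joining the first cherry of the topology);
    the other internal node *v* is reached across the internal branch.
    Returns a gap-free quartet alignment with taxa named by role.
    """
    b = np.asarray(branches, dtype=float)
    if b.shape != (5,) or np.any(b < 0):
        raise ValueError("need 5 non-negative branch lengths")
    codes = _seq_to_codes(root)
    n = codes.size
    site_rates = np.asarray(codon_position_rates, dtype=float)[np.arange(n) % 3]
    engine = model.engine()
    (i1, i2), (j1, j2) = PAIRINGS[topology]
    v = _evolve_branch(codes, b[4], engine, site_rates, rng)
    leaves: dict[int, np.ndarray] = {
        i1: _evolve_branch(codes, b[i1], engine, site_rates, rng),
        i2: _evolve_branch(codes, b[i2], engine, site_rates, rng),
        j1: _evolve_branch(v, b[j1], engine, site_rates, rng),
        j2: _evolve_branch(v, b[j2], engine, site_rates, rng),
    }
    rows = tuple(_codes_to_seq(leaves[i]) for i in range(4))
    return CodonAlignment(names=ROLES, rows=rows, frame_offset=0)


def _gene_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, index)))


def simulate_gene(config: SimulationConfig, index: int) -> Gene:
    """Simulate gene ``index`` of the configured set (order-independent)."""
    rng = _gene_rng(config.seed, index)
    topo = Topology(1 + rng.choice(3, p=np.asarray(config.topology_mix)))
    if config.fixed_codon_lengths is not None:
        n_codons = int(config.fixed_codon_lengths[index % len(config.fixed_codon_lengths)])
    else:
        mean, disp = config.length_law
        n_codons = max(34, int(round(rng.gamma(disp, mean / disp))))
    law = codon_frequencies_from_bases(config.model.freqs)
    root = sample_root_codons(law, n_codons, rng)
    branches = (*config.branch_lengths, config.internal_branch)
    aln = evolve_alignment(
        root, topo, branches, config.model, config.codon_position_rates, rng
    )
    width = 4 if config.fixed_codon_lengths is None else 2
    return Gene(
        gene_id=f"{config.gene_prefix}{index + 1:0{width}d}",
        alignment=aln,
        source=config.source,
        truth=topo,
    )


def simulate_gene_set(config: SimulationConfig) -> tuple[GeneSet, pd.DataFrame]:
    """Simulate the configured gene set; returns (genes, truth table).

    The truth table has one row per gene: gene_id, topology (1/2/3), and
    realized alignment length in bp.  Identical (config, seed) gives
    byte-identical output.
    """
    genes = [simulate_gene(config, i) for i in range(config.n_genes)]
    truth = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "topology": [int(g.truth) for g in genes],
            "length_bp": [g.alignment.length for g in genes],
            "source": [g.source for g in genes],
        }
    )
    return GeneSet(genes), truth


def sample_topologies(
    mix: Sequence[float], n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` generating topologies (1/2/3) from a mixture."""
    p = np.asarray(mix, dtype=float)
    if abs(p.sum() - 1.0) > 1e-12:
        raise ValueError("mixture must sum to 1")
    return rng.choice(3, size=n, p=p) + 1
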