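"""Per-gene quartet topology inference with bootstrap support, and the
concatenated partitioned analysis.

Because only four taxa are involved, tree search is exhaustive: the three
unrooted topologies are each optimized under a substitution model selected
once per gene, and the winner is the maximum-likelihood topology.
Nonparametric bootstrap support is the fraction of column-resampled
pseudo-replicates in which each topology wins; resampling is of nucleotide
columns (implemented as a multinomial redraw of site-pattern counts, which
is distributionally identical and fast).

The concatenated analysis shares one topology and one set of branch
lengths across all gene partitions while giving each partition its own
model parameters (GTR+G by default), mirroring a partitioned supermatrix
analysis.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize

from .core import CodonAlignment, Gene, GeneSet, Topology
from .submodel import (
    BRANCH_MIN,
    ModelFit,
    ModelParams,
    ModelSpec,
    PartitionData,
    QuartetLikelihood,
    _pack,
    _unpack,
    compress_alignment,
    default_params,
    fit_model,
    model_catalog,
    optimize_branches,
    select_model,
)

logger = logging.getLogger(__name__)

_TIE_TOL = 1e-9


@dataclass
class QuartetResult:
    """Per-gene inference outcome."""

    gene_id: str
    lnl: tuple[float, float, float]      # lnL of T1, T2, T3
    best: Topology
    supports: tuple[float, float, float]  # bootstrap support per topology
    model_label: str
    n_bootstrap: int
    branches: tuple[float, ...] = ()      # winner's branch lengths


def _winners(lnls: Sequence[float]) -> list[int]:
    """Indices tied (within tolerance) for the maximum log-likelihood."""
    m = max(lnls)
    return [i for i, v in enumerate(lnls) if m - v <= _TIE_TOL]


def infer_gene_tree(
    gene: Gene | CodonAlignment,
    catalog: str | Iterable = "jmt88",
    criterion: str = "BIC",
    n_bootstrap: int = 100,
    seed: int = 0,
    *,
    fast: bool = False,
    role_map: Mapping[str, str] | None = None,
) -> QuartetResult:
    """ML topology inference for one gene with bootstrap support.

    The model family is selected once, on the topology with the best
    preliminary JC log-likelihood, and reused for all three topologies
    and all bootstrap replicates.  ``fast=True`` freezes the continuous
    model parameters at their full-data estimates during the bootstrap
    (branch lengths are still re-optimized per replicate).  Exact
    likelihood ties share credit equally, so a signal-free alignment
    reports supports (1/3, 1/3, 1/3).
    """
    if isinstance(gene, CodonAlignment):
        gene = Gene(gene_id="gene", alignment=gene)
    part = compress_alignment(gene.alignment, role_map)
    rng = np.random.default_rng(seed)

    if part.n_patterns <= 1:
        # degenerate: no information, all topologies identical by symmetry
        fit0 = fit_model(part, Topology.T1, ModelSpec("JC"), max_rounds=1)
        third = 1.0 / 3.0
        return QuartetResult(
            gene.gene_id, (fit0.lnL,) * 3, Topology.T1, (third,) * 3,
            "JC", n_bootstrap, tuple(fit0.branches),
        )

    # 1) preliminary JC screen to pick the topology used for selection
    jc = ModelSpec("JC")
    prelim = [
        fit_model(part, t, jc, max_rounds=3, tol=1e-4, branch_xtol=1e-4)
        for t in Topology
    ]
    screen_topo = Topology(1 + int(np.argmax([f.lnL for f in prelim])))

    # 2) model selection once per gene (moderate optimization settings: the
    # winning family is refitted to convergence below)
    sel = select_model(
        part, screen_topo, catalog=catalog, criterion=criterion,
        branches0=prelim[screen_topo - 1].branches, max_rounds=8, tol=1e-5,
    )
    spec = sel.spec

    # 3) full optimization of all three topologies under the selected family
    fits: list[ModelFit] = []
    for i, t in enumerate(Topology):
        fits.append(
            fit_model(
                part, t, spec,
                params0=sel.params, branches0=prelim[i].branches,
            )
        )
    lnls = tuple(f.lnL for f in fits)
    tied = _winners(lnls)
    best = Topology(1 + tied[0])

    # 4) bootstrap: multinomial resample of pattern counts.  One likelihood
    # object per topology keeps each topology's fitted parameters (and their
    # eigendecompositions) installed across replicates.
    qls = []
    for i in range(3):
        ql = QuartetLikelihood([part])
        ql.set_models(spec, [fits[i].params])
        qls.append(ql)
    probs = part.counts / part.counts.sum()
    wins = np.zeros(3)
    for _ in range(n_bootstrap):
        counts = rng.multinomial(part.n_sites, probs).astype(float)
        rep_lnls = []
        for i, t in enumerate(Topology):
            fit = fits[i]
            if fast:
                qls[i].set_counts(counts)
                _, lnl = optimize_branches(
                    qls[i], t, fit.branches, max_rounds=1, xtol=2e-3, maxiter=8
                )
            else:
                rep_fit = fit_model(
                    PartitionData(part.codes, counts, part.n_sites, part.freqs_emp),
                    t, spec, params0=fit.params, branches0=fit.branches,
                    max_rounds=3, tol=1e-4, branch_xtol=1e-4,
                )
                lnl = rep_fit.lnL
            rep_lnls.append(lnl)
        rep_tied = _winners(rep_lnls)
        for i in rep_tied:
            wins[i] += 1.0 / len(rep_tied)
    supports = tuple(wins / n_bootstrap) if n_bootstrap else (0.0, 0.0, 0.0)
    return QuartetResult(
        gene.gene_id, lnls, best, supports, spec.label, n_bootstrap,
        tuple(fits[best - 1].branches),
    )


@dataclass
class ConcatenatedResult:
    """Outcome of the partitioned supermatrix analysis."""

    lnl: tuple[float, float, float]
    best: Topology
    supports: tuple[float, float, float]
    branches: tuple[float, ...]
    per_partition_lnl: np.ndarray  # winner topology, one value per partition
    model_label: str
    n_bootstrap: int

    @property
    def total_lnL(self) -> float:
        return self.lnl[self.best - 1]


def _fit_partitioned(
    ql: QuartetLikelihood,
    single_qls: Sequence[QuartetLikelihood],
    spec: ModelSpec,
    topology: Topology,
    params: list[ModelParams],
    branches: np.ndarray,
    *,
    max_rounds: int = 8,
    tol: float = 1e-4,
) -> tuple[list[ModelParams], np.ndarray, float]:
    """Coordinate ascent: shared branches, then per-partition parameters.

    Branch lengths are optimized on the total likelihood; each partition's
    continuous parameters are then optimized independently at the shared
    branch lengths (the total likelihood is separable given the branches).
    """
    ql.set_models(spec, params)
    best = ql.lnL(topology, branches)
    dim = _pack(spec, params[0]).size
    for _ in range(max_rounds):
        prev = best
        branches, best = optimize_branches(
            ql, topology, branches, max_rounds=2, xtol=1e-4
        )
        if dim:
            for j, sq in enumerate(single_qls):
                theta0 = _pack(spec, params[j])
                sq.set_models(spec, [params[j]])
                base = sq.lnL(topology, branches)

                def neg(th: np.ndarray, j=j, sq=sq) -> float:
                    sq.set_models(spec, [_unpack(spec, th, params[j].freqs)])
                    return -sq.lnL(topology, branches)

                res = optimize.minimize(
                    neg, theta0, method="Nelder-Mead",
                    options={"maxiter": 50 * dim, "xatol": 1e-3, "fatol": 1e-6},
                )
                if -res.fun > base:
                    params[j] = _unpack(spec, res.x, params[j].freqs)
            ql.set_models(spec, params)
            best = ql.lnL(topology, branches)
        if best - prev < tol:
            break
    return params, branches, best


def concatenated_analysis(
    genes: GeneSet | Sequence[Gene],
    mode: str = "per_gene_partitions",
    model_family: str | ModelSpec = "GTR+G",
    n_bootstrap: int = 100,
    seed: int = 0,
    *,
    role_map: Mapping[str, str] | None = None,
    fast: bool = True,
) -> ConcatenatedResult:
    """Partitioned ML analysis of a concatenated gene set.

    ``mode="per_gene_partitions"`` keeps one parameter set per gene
    (shared topology and branch lengths); ``mode="single_partition"``
    pools all sites under one parameter set.  The bootstrap resamples
    sites within partitions and, in fast mode, re-optimizes only the
    shared branch lengths.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene set")
    if mode not in ("per_gene_partitions", "single_partition"):
        raise ValueError(f"unknown mode {mode!r}")
    spec = (
        model_family
        if isinstance(model_family, ModelSpec)
        else ModelSpec.from_label(model_family)
    )
    names = genes[0].alignment.names
    for g in genes:
        if g.alignment.names != names:
            raise ValueError(f"taxon-role mismatch in gene {g.gene_id}")
    parts = [compress_alignment(g.alignment, role_map) for g in genes]
    if mode == "single_partition":
        merged = CodonAlignment(
            names,
            tuple("".join(g.alignment.rows[i] for g in genes) for i in range(4)),
        )
        parts = [compress_alignment(merged, role_map)]
    ql = QuartetLikelihood(parts)
    single_qls = [QuartetLikelihood([p]) for p in parts]

    results: dict[Topology, tuple[list[ModelParams], np.ndarray, float]] = {}
    for t in Topology:
        params = [default_params(spec, p.freqs_emp) for p in parts]
        branches = np.full(5, 0.1)
        results[t] = _fit_partitioned(ql, single_qls, spec, t, params, branches)
    lnls = tuple(results[t][2] for t in Topology)
    best = Topology(1 + _winners(lnls)[0])

    # per-topology likelihood objects with the fitted parameters installed
    boot_qls = []
    for t in Topology:
        q = QuartetLikelihood(parts)
        q.set_models(spec, results[t][0])
        boot_qls.append(q)
    rng = np.random.default_rng(seed)
    wins = np.zeros(3)
    for _ in range(n_bootstrap):
        counts = ql.resample_counts(rng)
        rep_lnls = []
        for i, t in enumerate(Topology):
            params, branches, _ = results[t]
            boot_qls[i].set_counts(counts)
            b, lnl = optimize_branches(
                boot_qls[i], t, branches, max_rounds=1, xtol=1e-3, maxiter=10
            )
            if not fast:
                start = 0
                for j, p in enumerate(parts):
                    single_qls[j].set_counts(counts[start:start + p.n_patterns])
                    start += p.n_patterns
                boot_ql = boot_qls[i]
                _, _, lnl = _fit_partitioned(
                    boot_ql, single_qls, spec, t, [p.copy() for p in params], b,
                    max_rounds=2, tol=1e-3,
                )
                boot_ql.set_models(spec, params)
            rep_lnls.append(lnl)
        rep_tied = _winners(rep_lnls)
        for i in rep_tied:
            wins[i] += 1.0 / len(rep_tied)
    supports = tuple(wins / n_bootstrap) if n_bootstrap else (0.0, 0.0, 0.0)

    params, branches, _ = results[best]
    ql.set_models(spec, params)
    per_part = ql.per_partition_lnL(best, branches)
    return ConcatenatedResult(
        lnl=lnls,
        best=best,
        supports=supports,
        branches=tuple(branches),
        per_partition_lnl=per_part,
        model_label=spec.label,
        n_bootstrap=n_bootstrap,
    )


def infer_gene_set(
    genes: GeneSet | Sequence[Gene],
    catalog: str | Iterable = "small",
    criterion: str = "BIC",
    n_bootstrap: int = 100,
    seed: int = 0,
    *,
    fast: bool = True,
    role_map: Mapping[str, str] | None = None,
) -> list[QuartetResult]:
    """Run infer_gene_tree over a gene set with per-gene derived seeds.

    Seeds are keyed by (seed, crc32(gene_id)), so per-gene results do not
    depend on the order genes appear in the manifest.
    """
    out = []
    for i, g in enumerate(genes):
        key = zlib.crc32(g.gene_id.encode())
        gene_seed = int(np.random.SeedSequence((seed, key)).generate_state(1)[0] % (2**31))
        out.append(
            infer_gene_tree(
                g, catalog=catalog, criterion=criterion,
                n_bootstrap=n_bootstrap, seed=gene_seed,
                fast=fast, role_map=role_map,
            )
        )
        if (i + 1) % 50 == 0:
            logger.info("inferred %d/%d genes", i + 1, len(list(genes)))
    return out
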