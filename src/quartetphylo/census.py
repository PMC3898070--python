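"""Gene-tree topology census and the chi-square test against a uniform null.

The headline statistic of the analysis: over many loci, count which quartet
topology each gene tree supports above a (strict) support cutoff, and test
the three counts against the uniform 1/3-1/3-1/3 expectation with a
goodness-of-fit chi-square (df = 2).  A significant excess of one topology
across independent loci is the evidence for the species-tree resolution.

Support values may come from this package's bootstrap (``QuartetResult``)
or from an external table (e.g. Bayesian posterior probabilities produced
by other software); both flow through the same tally/chi-square path.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import Topology


@dataclass(frozen=True)
class CensusTable:
    """Per-topology counts at a strict support cutoff."""

    cutoff: float
    counts: tuple[int, int, int]  # (n_T1, n_T2, n_T3)
    n_uncounted: int = 0          # genes whose max support failed the cutoff

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts):
            raise ValueError("negative count")

    @property
    def total(self) -> int:
        return sum(self.counts)

    @property
    def label(self) -> str:
        return f">{self.cutoff:.0%}"


@dataclass(frozen=True)
class ChiSquareResult:
    """Goodness-of-fit chi-square of three counts against uniform."""

    statistic: float
    df: int
    p: float


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def tally(
    results: Iterable, cutoff: float
) -> CensusTable:
    """Count genes per topology at a strict support cutoff.

    ``results`` is an iterable of objects with ``best`` (Topology) and
    ``supports`` (3 fractions) attributes — e.g. ``QuartetResult`` — or a
    pandas DataFrame with columns ``best_topology`` (1/2/3) and
    ``support``.  A gene is counted for topology i iff i is its best
    topology *and* its support exceeds the cutoff strictly; a gene at
    exactly the cutoff is uncounted.
    """
    counts = [0, 0, 0]
    uncounted = 0
    if isinstance(results, pd.DataFrame):
        for _, row in results.iterrows():
            s = float(row["support"])
            if not (0.0 <= s <= 1.0):
                raise ValueError(f"support outside [0,1] for gene {row.get('gene_id')}")
            if s > cutoff:
                counts[int(row["best_topology"]) - 1] += 1
            else:
                uncounted += 1
    else:
        for r in results:
            sup = np.asarray(r.supports, dtype=float)
            if np.any((sup < 0) | (sup > 1)):
                raise ValueError(f"support outside [0,1] for gene {r.gene_id}")
            best = Topology(r.best)
            if sup[best - 1] > cutoff:
                counts[best - 1] += 1
            else:
                uncounted += 1
    return CensusTable(cutoff=cutoff, counts=tuple(counts), n_uncounted=uncounted)


def chisq_uniform(counts: Sequence[int]) -> ChiSquareResult:
    """Chi-square test of 3 topology counts against the uniform null."""
    c = np.asarray(counts, dtype=float)
    if c.shape != (3,):
        raise ValueError("need exactly 3 counts")
    if np.any(c < 0):
        raise ValueError("negative count")
    total = c.sum()
    if total == 0:
        raise ValueError("empty census")
    expected = total / 3.0
    stat = float(((c - expected) ** 2 / expected).sum())
    df = 2
    return ChiSquareResult(statistic=stat, df=df, p=float(stats.chi2.sf(stat, df)))


def percentages(table: CensusTable | Sequence[int]) -> tuple[float, float, float]:
    """Per-topology percentages of the counted total, half-up to 2 dp."""
    counts = table.counts if isinstance(table, CensusTable) else tuple(table)
    total = sum(counts)
    if total == 0:
        raise ValueError("empty census")
    out = tuple(
        float(
            (Decimal(100 * c) / Decimal(total)).quantize(
                Decimal("0.01"), rounding=ROUND_HALF_UP
            )
        )
        for c in counts
    )
    return out  # type: ignore[return-value]
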