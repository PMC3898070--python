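"""Shared domain objects for the quartet phylogenomics pipeline.

The analysis revolves around four taxa playing fixed *roles*:

====  =========================================
role  taxon
====  =========================================
Z     zokor (subfamily Myospalacinae)
B     bamboo rat (subfamily Rhizomyinae)
S     blind mole rat (subfamily Spalacinae)
O     outgroup (mouse)
====  =========================================

An unrooted tree on four taxa has exactly three topologies, identified by
the leaf pair that sits on the same side of the internal branch as Z:

* ``T1`` = ``ZB|SO`` — zokor and bamboo rat are sisters (the resolution
  supported by the gene-tree census),
* ``T2`` = ``ZS|BO`` — zokor and blind mole rat are sisters,
* ``T3`` = ``BS|ZO`` — bamboo rat and blind mole rat are sisters, the
  zokor basal with the outgroup.

Which sequence in an input file plays which role is configuration, not
name matching: functions that need roles accept a ``role_map`` from taxon
name to role letter.  When ``role_map`` is omitted, taxon names must
themselves be the role letters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Iterable, Mapping, Sequence

ROLES: tuple[str, str, str, str] = ("Z", "B", "S", "O")


class Topology(IntEnum):
    """The three unrooted quartet topologies, by the pair grouped with Z."""

    T1 = 1  # ZB|SO
    T2 = 2  # ZS|BO
    T3 = 3  # BS|ZO

    @property
    def split(self) -> str:
        return {Topology.T1: "ZB|SO", Topology.T2: "ZS|BO", Topology.T3: "BS|ZO"}[self]

    @property
    def partner_of_z(self) -> str:
        """The role letter grouped with Z across the internal branch."""
        return {Topology.T1: "B", Topology.T2: "S", Topology.T3: "O"}[self]

    @classmethod
    def from_pair(cls, pair: Iterable[str]) -> "Topology":
        """Topology identified by any one of its two cherry role-pairs."""
        p = frozenset(pair)
        table = {
            frozenset("ZB"): cls.T1, frozenset("SO"): cls.T1,
            frozenset("ZS"): cls.T2, frozenset("BO"): cls.T2,
            frozenset("BS"): cls.T3, frozenset("ZO"): cls.T3,
        }
        try:
            return table[p]
        except KeyError:
            raise ValueError(f"not a role pair: {sorted(p)}") from None


#: For each topology, the two cherries as indices into role order (Z,B,S,O).
#: The first cherry hangs below internal node *u* (where the likelihood is
#: rooted), the second below internal node *v*.
PAIRINGS: dict[Topology, tuple[tuple[int, int], tuple[int, int]]] = {
    Topology.T1: ((0, 1), (2, 3)),
    Topology.T2: ((0, 2), (1, 3)),
    Topology.T3: ((1, 2), (0, 3)),
}

#: Human-readable labels used in reports (mirrors the census table rows).
TOPOLOGY_LABELS: dict[Topology, str] = {
    Topology.T1: "((Zokor, bamboo rat), blind mole rat)",
    Topology.T2: "((Zokor, blind mole rat), bamboo rat)",
    Topology.T3: "((Bamboo rat, blind mole rat), zokor)",
}


@dataclass(frozen=True)
class CodonAlignment:
    """An aligned set of nucleotide sequences with a reading frame.

    Parameters
    ----------
    names
        Taxon labels, in file order.  Must be unique and non-empty.
    rows
        Aligned sequences (one per taxon), uppercase IUPAC with ``-`` for
        gaps.  All the same length.
    frame_offset
        0-based nucleotide index where codon 1 starts.  Inputs are assumed
        in frame; ORF detection is upstream of this package.
    """

    names: tuple[str, ...]
    rows: tuple[str, ...]
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise ValueError("names and rows differ in number")
        if len(self.names) == 0:
            raise ValueError("no records")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate taxon")
        if any(not n for n in self.names):
            raise ValueError("empty taxon name")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("ragged alignment")
        if self.frame_offset < 0:
            raise ValueError("frame_offset must be >= 0")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def n_taxa(self) -> int:
        return len(self.names)

    def row(self, name: str) -> str:
        try:
            return self.rows[self.names.index(name)]
        except ValueError:
            raise KeyError(f"no taxon named {name!r}") from None

    def select_columns(self, positions: Sequence[int]) -> "CodonAlignment":
        """New alignment keeping the given 0-based columns, in order."""
        L = self.length
        for p in positions:
            if not (0 <= p < L):
                raise IndexError(f"column {p} out of range for length {L}")
        rows = tuple("".join(r[p] for p in positions) for r in self.rows)
        return CodonAlignment(self.names, rows, frame_offset=0)


def role_ordered_rows(
    aln: CodonAlignment, role_map: Mapping[str, str] | None = None
) -> tuple[str, str, str, str]:
    """Return the alignment rows reordered as (Z, B, S, O).

    ``role_map`` maps taxon name -> role letter; if None the taxon names
    are taken to be the role letters themselves.
    """
    if aln.n_taxa != 4:
        raise ValueError(f"quartet required, got {aln.n_taxa} taxa")
    if role_map is None:
        role_map = {n: n for n in aln.names}
    by_role: dict[str, str] = {}
    for name, row in zip(aln.names, aln.rows):
        role = role_map.get(name)
        if role is None:
            raise ValueError(f"taxon {name!r} has no role in role_map")
        if role in by_role:
            raise ValueError(f"role {role!r} assigned to more than one taxon")
        by_role[role] = row
    missing = [r for r in ROLES if r not in by_role]
    if missing:
        raise ValueError(f"roles not covered by alignment: {missing}")
    return tuple(by_role[r] for r in ROLES)  # type: ignore[return-value]


@dataclass
class Gene:
    """One orthologous gene alignment plus provenance."""

    gene_id: str
    alignment: CodonAlignment
    source: str = "nuclear"  # "nuclear" | "mitochondrial"
    truth: Topology | None = None  # generating topology (simulations only)


class GeneSet:
    """An ordered collection of genes with unique ids.

    Thin list wrapper; order is manifest order and is preserved through
    filtering and concatenation.
    """

    def __init__(self, genes: Iterable[Gene] = ()):  # noqa: D401
        self.genes: list[Gene] = list(genes)
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene_id in gene set")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __getitem__(self, i):
        return self.genes[i]

    def ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def subset(self, ids: Iterable[str]) -> "GeneSet":
        wanted = set(ids)
        return GeneSet(g for g in self.genes if g.gene_id in wanted)


@dataclass(frozen=True)
class QuartetTree:
    """A quartet topology with its five branch lengths.

    ``branches`` is ordered (bZ, bB, bS, bO, internal), in expected
    substitutions per site.
    """

    topology: Topology
    branches: tuple[float, float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.branches) != 5:
            raise ValueError("quartet tree needs 5 branch lengths")
        if any(b < 0 for b in self.branches):
            raise ValueError("negative branch length")

    @property
    def internal(self) -> float:
        return self.branches[4]
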