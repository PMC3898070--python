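"""Codon degeneracy, fourfold-degenerate (4D) site extraction, length
filtering, and concatenation with partition bookkeeping.

A 4D-site is the third position of a codon at which any of the four bases
encodes the same amino acid.  Across an alignment, a third-position column
qualifies only when every taxon's codon is unambiguous, the first two
codon positions are identical across taxa, and that shared 2-mer is one of
the eight fourfold codon families — the strict reading under which *all*
third-position differences are guaranteed synonymous.  Codons containing
gaps or ambiguity codes in any taxon are disqualified (conservative,
"cleandata"-style).

Coordinates are 0-based half-open internally; partition files use 1-based
inclusive coordinates (RAxML convention).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

from Bio.Data import CodonTable

from .core import CodonAlignment, Gene, GeneSet

logger = logging.getLogger(__name__)

#: The eight fourfold codon families (first two codon bases).
FOURFOLD_PREFIXES = frozenset({"TC", "CT", "CC", "CG", "AC", "GT", "GC", "GG"})

_STANDARD = CodonTable.unambiguous_dna_by_id[1]


def third_position_degeneracy(codon: str) -> int | None:
    """Degeneracy class {1,2,3,4} of a codon's third position.

    The class is the number of third-position bases (including the codon's
    own) that keep the amino acid unchanged under the standard genetic
    code.  Stop codons and codons containing anything outside ACGT are
    undefined (``None``) — signalled, not raised.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        return None
    if codon in _STANDARD.stop_codons:
        return None
    aa = _STANDARD.forward_table[codon]
    return sum(
        1
        for b in "ACGT"
        if _STANDARD.forward_table.get(codon[:2] + b) == aa
    )


@dataclass(frozen=True)
class SiteMask:
    """Ordered, strictly increasing 0-based column indices."""

    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError("mask positions must be strictly increasing")
        if self.positions and self.positions[0] < 0:
            raise ValueError("negative column index")

    def __len__(self) -> int:
        return len(self.positions)


def identify_4d_columns(aln: CodonAlignment) -> SiteMask:
    """Third-position columns whose differences are all guaranteed synonymous.

    For every in-frame codon, require for all taxa: no gap/ambiguity in
    the codon, first two positions identical across taxa, shared 2-mer in
    a fourfold family.  A trailing partial codon is ignored with a warning.
    """
    L = aln.length
    start = aln.frame_offset
    n_codons, trailing = divmod(L - start, 3)
    if trailing:
        warnings.warn(
            f"alignment length {L} leaves a partial codon of {trailing} nt; ignored",
            stacklevel=2,
        )
    selected: list[int] = []
    rows = aln.rows
    for c in range(n_codons):
        p = start + 3 * c
        codons = [r[p:p + 3] for r in rows]
        if any(b not in "ACGT" for cd in codons for b in cd):
            continue
        prefix = codons[0][:2]
        if any(cd[:2] != prefix for cd in codons[1:]):
            continue
        if prefix in FOURFOLD_PREFIXES:
            selected.append(p + 2)
    return SiteMask(tuple(selected))


def extract_sites(aln: CodonAlignment, mask: SiteMask) -> CodonAlignment:
    """Keep only the masked columns (output is frameless)."""
    return aln.select_columns(mask.positions)


def extract_4d(aln: CodonAlignment) -> CodonAlignment:
    """Convenience: identify and extract the 4D-sites of an alignment."""
    return extract_sites(aln, identify_4d_columns(aln))


def filter_short(genes: GeneSet, min_len: int = 100) -> GeneSet:
    """Drop genes whose aligned length is strictly below ``min_len`` bp.

    Mirrors the "<100 bp discarded" rule: a 99-bp gene is dropped, a
    100-bp gene retained.  Dropped ids are logged.
    """
    kept, dropped = [], []
    for g in genes:
        (kept if g.alignment.length >= min_len else dropped).append(g)
    if dropped:
        logger.info(
            "filter_short dropped %d gene(s): %s",
            len(dropped),
            ", ".join(g.gene_id for g in dropped),
        )
    return GeneSet(kept)


@dataclass(frozen=True)
class PartitionedAlignment:
    """A concatenated super-alignment with per-gene partition bounds.

    ``partitions`` holds (gene_id, start, end) in 1-based inclusive
    coordinates, tiling [1, length] without gaps or overlaps.  Genes whose
    masked length is zero contribute no partition.
    """

    alignment: CodonAlignment
    partitions: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        expect = 1
        for gid, start, end in self.partitions:
            if start != expect or end < start:
                raise ValueError(f"partitions do not tile: {gid} [{start}-{end}]")
            expect = end + 1
        if self.partitions and expect != self.alignment.length + 1:
            raise ValueError("partitions do not cover the alignment")

    @property
    def length(self) -> int:
        return self.alignment.length

    def partition_table(self) -> str:
        """RAxML-style partition file text ("DNA, gene1 = 1-1083")."""
        return "".join(
            f"DNA, {gid} = {start}-{end}\n" for gid, start, end in self.partitions
        )


def concatenate(genes: GeneSet, mask_mode: str = "all_sites") -> PartitionedAlignment:
    """Concatenate a gene set into a partitioned super-alignment.

    ``mask_mode`` is ``"all_sites"`` or ``"fourfold_only"`` (concatenate the
    4D-sites only).  All genes must carry the same four taxa in the same
    order; gene order follows the gene set (manifest order).
    """
    if mask_mode not in ("all_sites", "fourfold_only"):
        raise ValueError(f"unknown mask_mode {mask_mode!r}")
    if len(genes) == 0:
        raise ValueError("empty gene set")
    names = genes[0].alignment.names
    pieces: list[tuple[str, CodonAlignment]] = []
    for g in genes:
        if g.alignment.names != names:
            raise ValueError(
                f"taxon-role mismatch in gene {g.gene_id}: "
                f"{g.alignment.names} vs {names}"
            )
        aln = g.alignment if mask_mode == "all_sites" else extract_4d(g.alignment)
        pieces.append((g.gene_id, aln))
    rows = tuple(
        "".join(aln.rows[i] for _, aln in pieces) for i in range(len(names))
    )
    partitions: list[tuple[str, int, int]] = []
    pos = 1
    for gid, aln in pieces:
        if aln.length == 0:
            logger.info("gene %s contributes no sites under %s", gid, mask_mode)
            continue
        partitions.append((gid, pos, pos + aln.length - 1))
        pos += aln.length
    return PartitionedAlignment(
        CodonAlignment(names, rows, frame_offset=0), tuple(partitions)
    )


def length_ratio_percent(part_length: int, total_length: int) -> float:
    """Percentage one length is of another, half-up rounded to 2 dp.

    This is the report computation behind statements like "715,762 bp,
    12.92% of the total 5,541,534 bp".
    """
    if total_length <= 0:
        raise ValueError("total length must be positive")
    pct = Decimal(100 * part_length) / Decimal(total_length)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
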