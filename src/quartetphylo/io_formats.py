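"""Readers and writers for the formats the pipeline touches.

FASTA in (via Biopython), relaxed sequential PHYLIP out (no 10-character
name truncation), Newick quartet trees (via dendropy), RAxML-style
partition files, the gene-set manifest (TSV), and the census report.
"""

from __future__ import annotations

import io
import os
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
import dendropy

from .census import CensusTable, ChiSquareResult, percentages
from .core import (
    CodonAlignment,
    Gene,
    GeneSet,
    TOPOLOGY_LABELS,
    Topology,
)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_alignment(source: str | os.PathLike | io.TextIOBase) -> CodonAlignment:
    """Parse a FASTA alignment into a CodonAlignment.

    ``source`` may be FASTA text, a path, or an open text handle.  Taxa
    keep file order; residues are uppercased.  Raises on ragged rows,
    duplicate names, fewer than two records, or an empty file.
    """
    if isinstance(source, io.TextIOBase):
        handle = source
    else:
        s = str(source)
        if s.lstrip().startswith(">"):
            handle = io.StringIO(s)
        else:
            handle = open(s)
    try:
        records = list(SeqIO.parse(handle, "fasta"))
    finally:
        if handle is not source:
            handle.close()
    if not records:
        raise ValueError("no records")
    names = [r.id for r in records]
    if len(set(names)) != len(names):
        raise ValueError("duplicate taxon")
    rows = [str(r.seq).upper() for r in records]
    if len({len(r) for r in rows}) > 1:
        raise ValueError("ragged alignment")
    if len(records) < 2:
        raise ValueError("alignment needs at least 2 records")
    return CodonAlignment(tuple(names), tuple(rows))


def write_fasta(aln: CodonAlignment, width: int = 70) -> str:
    out = []
    for name, row in zip(aln.names, aln.rows):
        out.append(f">{name}")
        out.extend(row[i:i + width] for i in range(0, len(row), width))
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# PHYLIP (relaxed, sequential)
# ---------------------------------------------------------------------------

def write_phylip(aln: CodonAlignment) -> str:
    """Relaxed sequential PHYLIP: "ntaxa nsites" header, one line per taxon.

    Names may be any length but must contain no whitespace.
    """
    for name in aln.names:
        if any(ch.isspace() for ch in name):
            raise ValueError(f"illegal name: {name!r}")
    lines = [f"{aln.n_taxa} {aln.length}"]
    lines += [f"{name}  {row}" for name, row in zip(aln.names, aln.rows)]
    return "\n".join(lines) + "\n"


def read_phylip(text: str | os.PathLike) -> CodonAlignment:
    """Parse relaxed sequential PHYLIP as written by :func:`write_phylip`."""
    s = str(text)
    if "\n" not in s and Path(s).exists():
        s = Path(s).read_text()
    lines = [ln for ln in s.splitlines() if ln.strip()]
    if not lines:
        raise ValueError("no records")
    header = lines[0].split()
    if len(header) != 2:
        raise ValueError("bad PHYLIP header")
    ntaxa, nsites = int(header[0]), int(header[1])
    if len(lines) - 1 != ntaxa:
        raise ValueError(f"expected {ntaxa} sequence lines, found {len(lines) - 1}")
    names, rows = [], []
    for ln in lines[1:]:
        parts = ln.split(None, 1)
        if len(parts) != 2:
            raise ValueError(f"bad PHYLIP line: {ln!r}")
        name, seq = parts
        seq = "".join(seq.split())
        if len(seq) != nsites:
            raise ValueError("ragged alignment")
        names.append(name)
        rows.append(seq.upper())
    if len(set(names)) != len(names):
        raise ValueError("duplicate taxon")
    return CodonAlignment(tuple(names), tuple(rows))


# ---------------------------------------------------------------------------
# Newick quartets
# ---------------------------------------------------------------------------

def parse_newick(
    text: str, role_map: Mapping[str, str] | None = None
) -> tuple[Topology, dict[str, float | None]]:
    """Identify the unrooted topology of a quartet Newick string.

    Returns (topology, branch lengths keyed by leaf label, plus
    ``"internal"``).  ``role_map`` maps leaf labels to roles Z/B/S/O; if
    None, leaf labels must be the role letters.  Rotation-invariant: any
    rooted rendering of the same unrooted tree maps to the same topology.
    """
    tree = dendropy.Tree.get(data=text, schema="newick")
    leaves = list(tree.leaf_node_iter())
    if len(leaves) != 4:
        raise ValueError("not a quartet")
    labels = [lf.taxon.label if lf.taxon else None for lf in leaves]
    if any(l is None for l in labels):
        raise ValueError("unlabeled leaf")
    if role_map is None:
        role_map = {l: l for l in labels}
    roles = {}
    for l in labels:
        r = role_map.get(l)
        if r not in ("Z", "B", "S", "O"):
            raise ValueError(f"leaf {l!r} has no role")
        roles[l] = r
    if len(set(roles.values())) != 4:
        raise ValueError("roles not distinct")
    lengths: dict[str, float | None] = {
        lf.taxon.label: lf.edge.length for lf in leaves
    }
    # find a cherry (internal node with exactly two leaf children)
    cherry = None
    internal_len: float | None = None
    for node in tree.preorder_internal_node_iter():
        kids = node.child_nodes()
        leaf_kids = [k for k in kids if k.is_leaf()]
        if len(kids) == 2 and len(leaf_kids) == 2:
            cherry = tuple(roles[k.taxon.label] for k in leaf_kids)
            internal_len = node.edge.length
            break
    if cherry is None:
        raise ValueError("not a quartet")  # unresolved (star) tree
    lengths["internal"] = internal_len
    return Topology.from_pair(cherry), lengths


def write_newick(
    topology: Topology,
    branches: Sequence[float] | None = None,
    names: Mapping[str, str] | None = None,
) -> str:
    """Newick string for a quartet topology, role order (Z,B,S,O).

    ``branches`` is (bZ, bB, bS, bO, internal); ``names`` maps roles to
    output labels (defaults to the role letters).
    """
    names = dict(names or {})
    lab = {r: names.get(r, r) for r in "ZBSO"}
    pair = topology.partner_of_z
    other = [r for r in "BSO" if r != pair]

    def leaf(role: str, idx: int) -> str:
        if branches is None:
            return lab[role]
        return f"{lab[role]}:{branches[idx]:.6f}"

    idx = {"Z": 0, "B": 1, "S": 2, "O": 3}
    inner = f"({leaf('Z', idx['Z'])},{leaf(pair, idx[pair])})"
    if branches is not None:
        inner += f":{branches[4]:.6f}"
    return f"({inner},{leaf(other[0], idx[other[0]])},{leaf(other[1], idx[other[1]])});"


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

def write_manifest(genes: GeneSet, directory: str | os.PathLike) -> pd.DataFrame:
    """Write one FASTA per gene plus a manifest TSV; returns the manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for g in genes:
        path = directory / f"{g.gene_id}.fasta"
        path.write_text(write_fasta(g.alignment))
        rows.append(
            {
                "gene_id": g.gene_id,
                "path": str(path),
                "class": g.source,
                "truth": int(g.truth) if g.truth is not None else "",
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(directory / "manifest.tsv", sep="\t", index=False)
    return manifest


def load_manifest(path: str | os.PathLike) -> GeneSet:
    """Load a gene set from a manifest TSV (gene_id, path, class[, truth])."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if df["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_id in manifest")
    genes = []
    for _, row in df.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = path.parent / p
        if not p.exists():
            raise FileNotFoundError(f"gene file missing: {p}")
        aln = read_alignment(p)
        truth = row.get("truth")
        topo = (
            Topology(int(truth))
            if truth not in (None, "") and not pd.isna(truth)
            else None
        )
        genes.append(
            Gene(
                gene_id=row["gene_id"],
                alignment=aln,
                source=row.get("class", "nuclear"),
                truth=topo,
            )
        )
    return GeneSet(genes)


# ---------------------------------------------------------------------------
# Census report
# ---------------------------------------------------------------------------

def write_census_report(
    tables: Sequence[CensusTable], stats: Sequence[ChiSquareResult]
) -> str:
    """Census TSV: one row per (cutoff, topology) with count and percentage
    (2 dp), a Total row per cutoff, then a chi-square block."""
    lines = ["cutoff\ttopology\tcount\tpercent"]
    for table in tables:
        if table.total > 0:
            pcts = percentages(table)
        else:
            pcts = (0.0, 0.0, 0.0)
        for topo, count, pct in zip(Topology, table.counts, pcts):
            lines.append(
                f"{table.label}\t{TOPOLOGY_LABELS[topo]}\t{count}\t{pct:.2f}"
            )
        lines.append(f"{table.label}\tTotal\t{table.total}\t")
    lines.append("")
    lines.append("cutoff\tchi_square\tdf\tp")
    for table, st in zip(tables, stats):
        p_txt = f"{st.p:.3f}"
        lines.append(f"{table.label}\t{st.statistic:.2f}\t{st.df}\t{p_txt}")
    return "\n".join(lines) + "\n"


def results_to_frame(results: Iterable) -> pd.DataFrame:
    """QuartetResult list -> tidy per-gene results table."""
    rows = []
    for r in results:
        rows.append(
            {
                "gene_id": r.gene_id,
                "lnL_T1": r.lnl[0],
                "lnL_T2": r.lnl[1],
                "lnL_T3": r.lnl[2],
                "best_topology": int(r.best),
                "support_T1": r.supports[0],
                "support_T2": r.supports[1],
                "support_T3": r.supports[2],
                "support": r.supports[int(r.best) - 1],
                "model": r.model_label,
                "n_bootstrap": r.n_bootstrap,
            }
        )
    return pd.DataFrame(rows)
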