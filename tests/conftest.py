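"""Shared fixtures: tiny hand-built alignments and small simulated gene sets."""

from __future__ import annotations

import numpy as np
import pytest

from quartetphylo.core import CodonAlignment, ROLES
from quartetphylo.synthetic_data import SimulationConfig, simulate_gene_set


def make_alignment(*rows: str, names=None, frame_offset: int = 0) -> CodonAlignment:
    """Quartet alignment from raw sequence strings (names default Z,B,S,O)."""
    names = tuple(names) if names is not None else ROLES[: len(rows)]
    return CodonAlignment(names=names, rows=tuple(r.upper() for r in rows),
                          frame_offset=frame_offset)


@pytest.fixture(scope="session")
def small_gene_set():
    """Six simulated genes under the default study conditions (seeded)."""
    cfg = SimulationConfig(n_genes=6, seed=11)
    genes, truth = simulate_gene_set(cfg)
    return genes, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
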