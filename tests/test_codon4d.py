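"""Degeneracy table, 4D-column identification, filtering, concatenation."""

import numpy as np
import pytest

from quartetphylo.codon4d import (
    PartitionedAlignment,
    SiteMask,
    concatenate,
    extract_4d,
    extract_sites,
    filter_short,
    identify_4d_columns,
    length_ratio_percent,
    third_position_degeneracy,
)
from quartetphylo.core import Gene, GeneSet
from quartetphylo.synthetic_data import SimulationConfig, simulate_gene_set

from conftest import make_alignment


@pytest.mark.parametrize(
    "codon, expected",
    [
        ("GCT", 4),   # Ala: fourfold family
        ("GGA", 4),   # Gly
        ("TGG", 1),   # Trp: unique
        ("ATG", 1),   # Met
        ("AGA", 2),   # Arg AGR family
        ("AAT", 2),   # Asn
        ("ATA", 3),   # Ile: threefold
        ("TAA", None),  # stop
        ("TGA", None),  # stop
        ("GC-", None),  # gap
        ("GNC", None),  # ambiguity
        ("gct", 4),   # case-insensitive
    ],
)
def test_third_position_degeneracy(codon, expected):
    assert third_position_degeneracy(codon) == expected


def test_fourfold_families_are_exactly_the_degeneracy_4_codons():
    """The 8-family prefix set must agree with the genetic-code scan."""
    from itertools import product

    from quartetphylo.codon4d import FOURFOLD_PREFIXES

    for b1, b2 in product("ACGT", repeat=2):
        codons = [b1 + b2 + b3 for b3 in "ACGT"]
        degs = {third_position_degeneracy(c) for c in codons}
        if b1 + b2 in FOURFOLD_PREFIXES:
            assert degs == {4}
        else:
            assert 4 not in degs


class TestIdentify4D:
    def test_all_gly_column_selected(self):
        aln = make_alignment("GGA", "GGC", "GGG", "GGT")
        assert identify_4d_columns(aln).positions == (2,)

    def test_first_position_difference_disqualifies(self):
        aln = make_alignment("GGA", "AGA", "GGA", "GGA")
        assert identify_4d_columns(aln).positions == ()

    def test_gap_disqualifies(self):
        aln = make_alignment("GC-", "GCT", "GCT", "GCT")
        assert identify_4d_columns(aln).positions == ()

    def test_non_fourfold_family_not_selected(self):
        aln = make_alignment("TGG", "TGG", "TGG", "TGG")  # Trp
        assert identify_4d_columns(aln).positions == ()

    def test_nine_codon_toy_two_qualifying(self):
        # codons per taxon: GGx (4D, identical prefix), TGG (not 4D),
        # ACx (4D), AGA (twofold), GCT vs ACT (prefix differs), ATG, CCC (4D
        # but taxon 4 prefix differs), TTT, GTx (4D)
        rows = [
            "GGA TGG ACT AGA GCT ATG CCC TTT GTA",
            "GGC TGG ACC AGA GCT ATG CCC TTT GTC",
            "GGG TGG ACA AGA GCT ATG CCC TTT GTG",
            "GGT TGG ACG AGA ACT ATG CCG TTT GTT",
        ]
        aln = make_alignment(*[r.replace(" ", "") for r in rows])
        mask = identify_4d_columns(aln)
        # hand-derived: codons 1 (GGx), 3 (ACx), 9 (GTx) qualify... but codon
        # 7 (CCC/CCC/CCC/CCG) also has identical CC prefix -> qualifies.
        assert mask.positions == (2, 8, 20, 26)
        assert extract_sites(aln, mask).length == 4

    def test_trailing_partial_codon_warns(self):
        aln = make_alignment("GGAA", "GGCA", "GGGA", "GGTA")
        with pytest.warns(UserWarning, match="partial codon"):
            mask = identify_4d_columns(aln)
        assert mask.positions == (2,)

    def test_frame_offset_respected(self):
        aln = make_alignment("TGGA", "TGGC", "TGGG", "TGGT", frame_offset=1)
        assert identify_4d_columns(aln).positions == (3,)

    def test_never_selects_codon_position_1_or_2(self, small_gene_set):
        genes, _ = small_gene_set
        for g in genes:
            for p in identify_4d_columns(g.alignment).positions:
                assert (p - g.alignment.frame_offset) % 3 == 2


class TestExtract:
    def test_empty_mask(self):
        aln = make_alignment("ACGGGG", "ACGGGG", "ACGGGG", "ACGGGG")
        out = extract_sites(aln, SiteMask(()))
        assert out.length == 0 and out.n_taxa == 4

    def test_full_mask_identity(self):
        aln = make_alignment("ACGGGT", "ACGGGA", "ACGGGC", "ACGGGG")
        out = extract_sites(aln, SiteMask(tuple(range(6))))
        assert out.rows == aln.rows

    def test_out_of_range(self):
        aln = make_alignment("ACG", "ACG", "ACG", "ACG")
        with pytest.raises(IndexError):
            extract_sites(aln, SiteMask((5,)))


class TestFilterShort:
    def test_strict_boundary(self):
        g99 = Gene("g99", make_alignment(*["A" * 99] * 4))
        g100 = Gene("g100", make_alignment(*["A" * 100] * 4))
        kept = filter_short(GeneSet([g99, g100]), min_len=100)
        assert kept.ids() == ["g100"]

    def test_empty_set(self):
        assert len(filter_short(GeneSet([]))) == 0


class TestConcatenate:
    def _gene(self, gid, n):
        rows = ["ACG" * (n // 3)] * 4
        return Gene(gid, make_alignment(*rows))

    def test_partition_arithmetic(self):
        gs = GeneSet([self._gene("g1", 300), self._gene("g2", 150)])
        cat = concatenate(gs, "all_sites")
        assert cat.length == 450
        assert cat.partitions == (("g1", 1, 300), ("g2", 301, 450))
        assert "DNA, g1 = 1-300" in cat.partition_table()

    def test_single_gene_identity(self):
        g = self._gene("solo", 30)
        cat = concatenate(GeneSet([g]), "all_sites")
        assert cat.alignment.rows == g.alignment.rows

    def test_role_mismatch_names_gene(self):
        g1 = self._gene("g1", 30)
        bad = Gene("gBAD", make_alignment("ACG", "ACG", "ACG", "ACG",
                                          names=("a", "b", "c", "d")))
        with pytest.raises(ValueError, match="gBAD"):
            concatenate(GeneSet([g1, bad]), "all_sites")

    def test_4d_mask_commutes_with_concatenation(self, small_gene_set):
        genes, _ = small_gene_set
        cat_then_mask = extract_4d(concatenate(genes, "all_sites").alignment)
        mask_then_cat = concatenate(genes, "fourfold_only").alignment
        assert cat_then_mask.rows == mask_then_cat.rows

    def test_4d_fraction_shrinks_with_divergence(self):
        """More substitutions disqualify more codons from 4D status."""
        fractions = []
        for scale in (0.3, 1.0, 3.0):
            cfg = SimulationConfig(
                n_genes=30, length_law=(150.0, 1e9), seed=19,
                branch_lengths=tuple(scale * b for b in (0.05, 0.05, 0.05, 0.10)),
                internal_branch=scale * 0.02,
            )
            genes, _ = simulate_gene_set(cfg)
            total = sum(g.alignment.length for g in genes)
            n4d = sum(len(identify_4d_columns(g.alignment)) for g in genes)
            fractions.append(n4d / total)
        assert fractions[0] > fractions[1] > fractions[2]
        assert all(0 < f < 1 / 3 for f in fractions)


@pytest.mark.parametrize(
    "part, total, expected",
    [
        (715762, 5541534, 12.92),   # nuclear 4D share of the supermatrix
        (1182, 11307, 10.45),       # mitochondrial 4D share
        (1, 3, 33.33),
    ],
)
def test_length_ratio_percent(part, total, expected):
    assert length_ratio_percent(part, total) == expected
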