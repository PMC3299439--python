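"""JC transition matrix, pruning likelihood with gap marginalization,
alignment-level treatments, monotypic predicate, gap coding."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gapml import (
    Alignment,
    DegenerateAlignmentWarning,
    GapTreatment,
    alignment_log_likelihood,
    column_likelihood,
    enumerate_unrooted_topologies,
    gap_code,
    is_monotypic,
    jc_edge_transition,
    parse_newick,
    strip_gapped_sites,
)
from gapml.likelihood import TreeLikelihood
from oracles import brute_force_column_likelihood

NUCS = "ACGT"


class TestJCTransition:
    def test_zero_probability_is_identity(self):
        assert np.array_equal(jc_edge_transition(0.0), np.eye(4))

    def test_saturation_is_exactly_uniform(self):
        m = jc_edge_transition(0.75)
        assert np.all(m == 0.25)

    def test_intermediate_value(self):
        m = jc_edge_transition(0.3)
        assert np.allclose(np.diag(m), 0.7)
        off = m[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 0.1)

    @given(st.floats(min_value=0.0, max_value=0.75, allow_nan=False))
    def test_rows_sum_to_one(self, p):
        assert np.allclose(jc_edge_transition(p).sum(axis=1), 1.0, atol=1e-14)

    @pytest.mark.parametrize("p", [-0.01, 0.7500001, 1.0])
    def test_out_of_range_rejected(self, p):
        with pytest.raises(ValueError):
            jc_edge_transition(p)


class TestColumnLikelihood:
    def test_two_leaf_identical_states_no_change(self):
        t = parse_newick("(a:0.0,b:0.0);")
        assert column_likelihood(t, {"a": "A", "b": "A"}) == 0.25

    @pytest.mark.parametrize("p", [0.0, 0.2, 0.75])
    def test_gapped_leaf_marginalizes_to_root_prior(self, p):
        t = parse_newick(f"(a:{p},b:0.0);")
        assert column_likelihood(t, {"a": "-", "b": "A"}) == pytest.approx(0.25)

    def test_monotypic_column_on_seven_taxa_at_zero(self, printed_alignment):
        topo = next(enumerate_unrooted_topologies(printed_alignment.taxa))
        col = printed_alignment.column(0)  # (A,-,A,-,-,-,A)
        assert column_likelihood(topo, col) == 0.25

    def test_label_mismatch_rejected(self, quartet):
        with pytest.raises(ValueError, match="taxa"):
            column_likelihood(quartet, {"a": "A", "b": "C", "c": "G", "x": "T"})

    def test_marginalization_identity(self, quartet):
        """A gapped leaf's likelihood equals the sum over its four nucleotides."""
        base = {"a": "A", "b": "C", "c": "G"}
        gapped = column_likelihood(quartet, {**base, "d": "-"})
        summed = sum(
            column_likelihood(quartet, {**base, "d": x}) for x in NUCS
        )
        assert gapped == pytest.approx(summed, abs=1e-12)


def _random_gapped_column(taxa, rng):
    col = {t: "ACGT-"[rng.integers(0, 5)] for t in taxa}
    if all(c == "-" for c in col.values()):
        col[taxa[0]] = "A"
    return col


@pytest.mark.parametrize("n_taxa", [4, 5])
def test_pruning_matches_brute_force_on_all_topologies(n_taxa, rng):
    """Pruning equals explicit summation over internal-node states (<=1e-12)."""
    taxa = [f"t{i}" for i in range(n_taxa)]
    for topo in enumerate_unrooted_topologies(taxa):
        topo = topo.with_edge_params(
            {s: float(rng.uniform(0, 0.75)) for s in topo.edge_params}
        )
        for _ in range(3):
            col = _random_gapped_column(taxa, rng)
            assert column_likelihood(topo, col) == pytest.approx(
                brute_force_column_likelihood(topo, col), abs=1e-12
            )


def test_gap_free_likelihoods_normalize(rng, five_taxon_tree):
    """Sum over all 4^n leaf assignments of the column likelihood is 1."""
    tree = five_taxon_tree.with_edge_params(
        {s: float(rng.uniform(0, 0.75)) for s in five_taxon_tree.edge_params}
    )
    taxa = tree.taxa
    cols = ["".join(c) for c in itertools.product(NUCS, repeat=len(taxa))]
    aln = Alignment(taxa, tuple("".join(col[i] for col in cols) for i in range(len(taxa))))
    tl = TreeLikelihood.from_alignment(tree, aln)
    total = np.exp(tl.site_log_likelihoods(tl.params_vector())).sum()
    assert total == pytest.approx(1.0, abs=1e-12)


def test_root_invariance(rng, five_taxon_tree):
    """The likelihood is identical for every choice of rooting node."""
    tree = five_taxon_tree.with_edge_params(
        {s: float(rng.uniform(0, 0.75)) for s in five_taxon_tree.edge_params}
    )
    aln = Alignment(
        tuple(tree.taxa),
        tuple("ACG-T"[rng.integers(0, 5)] + "AC-GT"[rng.integers(0, 5)] for _ in tree.taxa),
    )
    codes = aln.codes()
    ref = None
    for root in tree.nodes():
        tl = TreeLikelihood(tree, codes, root=root)
        val = tl.exact_log_likelihood(tl.params_vector())
        if ref is None:
            ref = val
        assert val == pytest.approx(ref, abs=1e-12)


class TestAlignmentLevel:
    def test_printed_alignment_at_zero_parameters(self, printed_alignment):
        topo = next(enumerate_unrooted_topologies(printed_alignment.taxa))
        ll = alignment_log_likelihood(topo, printed_alignment)
        assert ll == 3 * math.log(0.25)

    def test_empty_alignment_is_degenerate_probability_one(self, quartet):
        empty = Alignment(("a", "b", "c", "d"), ("", "", "", ""))
        with pytest.warns(DegenerateAlignmentWarning):
            assert alignment_log_likelihood(quartet, empty) == 0.0

    def test_strip_treatment_equals_manual_strip(self, quartet):
        aln = Alignment(("a", "b", "c", "d"), ("AC-G", "ACAG", "AC-G", "ACCG"))
        ll_strip = alignment_log_likelihood(
            quartet, aln, GapTreatment.STRIP_GAPPED_SITES
        )
        ll_manual = alignment_log_likelihood(quartet, strip_gapped_sites(aln))
        assert ll_strip == ll_manual

    def test_gap_code_treatment_rejected_for_likelihood(self, quartet):
        aln = Alignment(("a", "b", "c", "d"), ("A-", "AC", "AC", "AC"))
        with pytest.raises(ValueError, match="gap_code"):
            alignment_log_likelihood(quartet, aln, GapTreatment.GAP_CODE)

    def test_taxa_mismatch_rejected(self, quartet):
        aln = Alignment(("a", "b", "c", "x"), ("A", "A", "A", "A"))
        with pytest.raises(ValueError, match="taxa"):
            alignment_log_likelihood(quartet, aln)


class TestAlignmentValidation:
    def test_ambiguity_codes_rejected(self):
        with pytest.raises(ValueError, match="ACGT-"):
            Alignment(("a", "b"), ("AN", "AC"))
        with pytest.raises(ValueError, match="ACGT-"):
            Alignment(("a", "b"), ("A?", "AC"))

    def test_ragged_rows_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            Alignment(("a", "b"), ("AC", "A"))


class TestStripGappedSites:
    def test_printed_alignment_strips_to_empty(self, printed_alignment):
        assert strip_gapped_sites(printed_alignment).n_sites == 0

    def test_gap_free_alignment_unchanged(self):
        aln = Alignment(("a", "b"), ("ACGT", "ACGA"))
        assert strip_gapped_sites(aln) == aln

    def test_single_gapped_column_removed(self):
        aln = Alignment(("a", "b"), ("A-G", "ACG"))
        out = strip_gapped_sites(aln)
        assert out.rows == ("AG", "AG") or out.rows == ("AG", "AG")
        assert out.n_sites == 2


class TestIsMonotypic:
    def test_printed_alignment_is_monotypic(self, printed_alignment):
        assert is_monotypic(printed_alignment)

    def test_two_nucleotide_types_in_a_column(self):
        assert not is_monotypic(Alignment(("a", "b"), ("A", "C")))

    def test_fully_gapped_column_disallowed(self):
        assert not is_monotypic(Alignment(("a", "b"), ("A-", "A-")))

    def test_all_gap_rows_are_legal(self):
        aln = Alignment(("a", "b", "c"), ("A", "A", "-"))
        assert is_monotypic(aln)


class TestGapCode:
    def test_printed_alignment_patterns(self, printed_alignment):
        m = gap_code(printed_alignment)
        assert m.n_characters == 3
        assert m.site_index == (0, 1, 2)
        by_site = [tuple(m.characters[j][k] for j in range(7)) for k in range(3)]
        assert by_site[0] == (1, 0, 1, 0, 0, 0, 1)
        assert by_site[1] == (0, 1, 0, 0, 0, 0, 0)
        assert by_site[2] == (0, 0, 0, 0, 0, 1, 0)

    def test_gap_free_alignment_codes_nothing(self):
        m = gap_code(Alignment(("a", "b"), ("ACG", "ACG")))
        assert m.n_characters == 0

    def test_fully_gapped_column_codes_all_zero(self):
        m = gap_code(Alignment(("a", "b"), ("A-", "A-")))
        assert m.n_characters == 1
        assert m.presence_set(0) == frozenset()
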