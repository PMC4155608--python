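import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famtrend.errors import FamtrendError
from famtrend.residue_schemes import get_scheme
from famtrend.sequence_io import AlignedFamily
from famtrend.similarity import (
    MetricSpec,
    common_residues,
    edit_distance,
    fragment_frequency_weight,
    ngram_common,
    selected_edit_distance,
    sort_family,
    weighted_edit_distance,
)

from oracles import (
    brute_compositional_common,
    brute_levenshtein,
    brute_ngrams,
    brute_positional_common,
)

seqs = st.text(alphabet="ACD", max_size=8)
rows = st.text(alphabet="ACD-", min_size=1, max_size=10)


class TestEditDistance:
    def test_identity(self):
        assert edit_distance("AAAA", "AAAA") == 0

    def test_kitten_sitting(self):
        assert edit_distance("KITTEN", "SITTING") == 3

    def test_empty(self):
        assert edit_distance("ACD", "") == 3
        assert edit_distance("", "") == 0

    def test_degaps_inputs(self):
        assert edit_distance("A-C-D", "ACD") == 0

    def test_x_never_matches(self):
        assert edit_distance("X", "X") == 1

    @given(seqs, seqs)
    @settings(max_examples=150, deadline=None)
    def test_matches_brute_force(self, a, b):
        assert edit_distance(a, b) == brute_levenshtein(a, b)


class TestWeightedEditDistance:
    def test_identity(self):
        assert weighted_edit_distance("ACDE", "ACDE", "polarity") == 0.0

    def test_same_polarity_class_half_cost(self):
        assert weighted_edit_distance("L", "I", "polarity") == 0.5

    def test_cross_charge_class_full_cost(self):
        assert weighted_edit_distance("K", "D", "charge") == 1.0

    def test_x_costs_full(self):
        assert weighted_edit_distance("X", "X", "polarity") == 1.0

    def test_fragment_frequency_rejected(self):
        with pytest.raises(FamtrendError, match="partition"):
            weighted_edit_distance("A", "C", "fragment_frequency")

    @given(st.text(alphabet="LIK", max_size=6), st.text(alphabet="LIK", max_size=6))
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_with_class_costs(self, a, b):
        scheme = get_scheme("polarity")

        def cost(x, y):
            if x == y:
                return 0.0
            if scheme.class_of(x) is scheme.class_of(y):
                return 0.5
            return 1.0

        assert weighted_edit_distance(a, b, scheme) == brute_levenshtein(a, b, cost)

    @given(seqs, seqs)
    @settings(max_examples=100, deadline=None)
    def test_never_exceeds_plain_edit(self, a, b):
        for name in ("chemical", "polarity", "charge", "solvent_contact"):
            assert weighted_edit_distance(a, b, name) <= edit_distance(a, b)


class TestMetricAxioms:
    """Identity, symmetry and triangle inequality on a small exhaustive set."""

    STRINGS = [
        "".join(t)
        for n in range(4)
        for t in itertools.product("ACD", repeat=n)
    ]

    @pytest.mark.parametrize("dist", [
        edit_distance,
        lambda a, b: weighted_edit_distance(a, b, "polarity"),
    ], ids=["edit", "weighted_edit"])
    def test_axioms_exhaustive(self, dist):
        S = self.STRINGS
        for a in S:
            assert dist(a, a) == 0
        for a, b in itertools.combinations(S, 2):
            d = dist(a, b)
            assert d > 0
            assert d == dist(b, a)
        for a, b, c in itertools.islice(itertools.permutations(S, 3), 2000):
            assert dist(a, c) <= dist(a, b) + dist(b, c) + 1e-12


class TestCommonResidues:
    def test_positional_with_gaps(self):
        count, _ = common_residues("A-CD", "A-CE", positional=True)
        assert count == 2  # columns 1 and 3; the gap-gap column never matches

    def test_positional_vs_compositional(self):
        assert common_residues("AC", "CA", positional=True)[0] == 0
        assert common_residues("AC", "CA", positional=False)[0] == 2

    def test_identical_rows_100_pct(self):
        count, pct = common_residues("ACDEFGH", "ACDEFGH")
        assert (count, pct) == (7, 100.0)

    def test_length_mismatch(self):
        with pytest.raises(FamtrendError):
            common_residues("AC", "ACD")

    def test_empty_denominator(self):
        assert common_residues("--", "AC")[1] == 0.0

    @given(rows, rows)
    @settings(max_examples=150, deadline=None)
    def test_matches_oracles_and_ordering(self, a, b):
        if len(a) != len(b):
            b = (b + "-" * len(a))[: len(a)]
        pos = common_residues(a, b, positional=True)[0]
        comp = common_residues(a, b, positional=False)[0]
        assert pos == brute_positional_common(a, b)
        assert comp == brute_compositional_common(a, b)
        assert pos <= comp


class TestNgramCommon:
    def test_shared_bigrams(self):
        assert ngram_common("ACDE", "GCDE", 2) == 2  # {"CD", "DE"}

    def test_repeats_counted_once(self):
        assert ngram_common("AAAA", "AAAA", 2) == 1

    def test_disjoint(self):
        assert ngram_common("AAAA", "CCCC", 2) == 0

    def test_short_sequence_contributes_empty_set(self):
        assert ngram_common("A", "ACD", 2) == 0

    def test_bad_n(self):
        with pytest.raises(FamtrendError):
            ngram_common("ACD", "ACD", 0)

    @given(seqs, seqs, st.integers(min_value=1, max_value=4))
    @settings(max_examples=150, deadline=None)
    def test_matches_set_oracle(self, a, b, n):
        assert ngram_common(a, b, n) == len(brute_ngrams(a, n) & brute_ngrams(b, n))

    @given(seqs, st.integers(min_value=1, max_value=3))
    @settings(max_examples=100, deadline=None)
    def test_self_comparison_counts_distinct_ngrams(self, a, n):
        assert ngram_common(a, a, n) == len(brute_ngrams(a, n))


class TestSelectedEditDistance:
    def test_all_columns_equals_plain(self):
        a, b = "KITTEN", "SITTEN"
        cols = range(1, 7)
        assert selected_edit_distance(a, b, cols) == edit_distance(a, b)

    def test_single_column(self):
        assert selected_edit_distance("AKCD", "AYCD", {2}) == 1

    def test_difference_outside_selection(self):
        assert selected_edit_distance("AKCD", "AYCD", {1, 3, 4}) == 0

    def test_empty_selection_rejected(self):
        with pytest.raises(FamtrendError):
            selected_edit_distance("AC", "AC", set())

    def test_gaps_dropped_per_projection(self):
        assert selected_edit_distance("A-C", "AGC", {1, 2, 3}) == 1


class TestFragmentFrequencyWeight:
    def test_all_identical(self):
        fam = AlignedFamily(ids=list("abc"), rows=["ACD"] * 3)
        for i in range(3):
            assert fragment_frequency_weight(fam, i) == 1.0

    def test_unique_substring(self):
        rows = ["AAAA"] * 9 + ["AATA"]
        fam = AlignedFamily(ids=[f"s{i}" for i in range(10)], rows=rows)
        assert fragment_frequency_weight(fam, 9, (2, 4)) == pytest.approx(0.1)

    def test_two_of_four(self):
        fam = AlignedFamily(
            ids=list("abcd"), rows=["ACAA", "ACAA", "AGAA", "ATAA"]
        )
        assert fragment_frequency_weight(fam, 0, (1, 2)) == pytest.approx(0.5)
        assert fragment_frequency_weight(fam, 2, (1, 2)) == pytest.approx(0.25)

    def test_bad_window(self):
        fam = AlignedFamily(ids=["a"], rows=["ACD"])
        with pytest.raises(FamtrendError):
            fragment_frequency_weight(fam, 0, (3, 2))


class TestSortFamily:
    def test_reference_first_with_weight_zero(self, tiny_family):
        result = sort_family(tiny_family, "s2", MetricSpec(name="edit"))
        assert result.order[0] == tiny_family.index("s2")
        assert result.weights[tiny_family.index("s2")] == 0.0

    def test_orders_by_recomputed_distances(self):
        fam = AlignedFamily(
            ids=["ref", "far", "near"],
            rows=["ACDEF", "ACWWW", "ACDEW"],
        )
        result = sort_family(fam, "ref", MetricSpec(name="edit"))
        expected = {
            i: brute_levenshtein(fam.rows[0], fam.rows[i]) for i in range(3)
        }
        assert result.weights == [expected[i] for i in range(3)]
        assert result.order == [0, 2, 1]

    def test_stable_ties(self):
        fam = AlignedFamily(
            ids=["ref", "t1", "t2"], rows=["AAAA", "AAAC", "AAAD"]
        )
        result = sort_family(fam, "ref", MetricSpec(name="edit"))
        assert result.order == [0, 1, 2]

    def test_similarity_metric_sorts_descending(self, tiny_family):
        result = sort_family(
            tiny_family, "s1", MetricSpec(name="common_positional")
        )
        ordered = [result.weights[i] for i in result.order]
        assert ordered == sorted(ordered, reverse=True)

    def test_unknown_reference(self, tiny_family):
        with pytest.raises(FamtrendError):
            sort_family(tiny_family, "nope", MetricSpec(name="edit"))

    def test_unknown_metric(self):
        with pytest.raises(FamtrendError, match="unknown metric"):
            MetricSpec(name="bogus")

    def test_weights_invariant_under_row_permutation(self, tiny_family):
        spec = MetricSpec(name="edit")
        base = sort_family(tiny_family, "s3", spec)
        perm = [2, 0, 3, 1]
        shuffled = AlignedFamily(
            ids=[tiny_family.ids[i] for i in perm],
            rows=[tiny_family.rows[i] for i in perm],
        )
        other = sort_family(shuffled, "s3", spec)
        for new_idx, old_idx in enumerate(perm):
            assert other.weights[new_idx] == base.weights[old_idx]
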