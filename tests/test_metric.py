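import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from smets import (
    MultivariateSeries,
    PipelineSettings,
    UnivariateSeries,
    dimension_penalty,
    entropy,
    entropy_penalty,
    greedy_match,
    p_norm_distance,
    smets_breakdown,
    smets_distance,
)
from smets.metric import MatchResult
from smets.synthetic import random_model, similar_models_trio

from conftest import mv, uv


def greedy_oracle(matrix):
    """Brute-force greedy: full re-scan of the distance matrix each round."""
    D = [list(map(float, row)) for row in matrix]
    n, m = len(D), len(D[0])
    rows, cols = set(range(n)), set(range(m))
    pairs = []
    for _ in range(n):
        best = None
        for i in sorted(rows):
            for j in sorted(cols):
                if best is None or D[i][j] < best[2]:
                    best = (i, j, D[i][j])
        pairs.append(best)
        rows.remove(best[0])
        cols.remove(best[1])
    unmatched = [(j, min(D[i][j] for i in range(n))) for j in sorted(cols)]
    return pairs, unmatched


class TestGreedyMatch:
    def test_explicit_matrix_trace(self):
        # A has 2 components, B has 3; smallest distance first, then repeat
        D = np.array([[1.0, 0.5, 4.0], [2.0, 3.0, 0.1]])
        match = greedy_match(D)
        expected_pairs, expected_unmatched = greedy_oracle(D)
        assert list(match.pairs) == expected_pairs
        assert list(match.unmatched) == expected_unmatched
        # frozen trace: global minimum 0.1 at (A2,B3), then 0.5 at (A1,B2);
        # unmatched B1 keeps its pre-removal column minimum min(1,2)=1
        assert match.pairs == ((1, 2, 0.1), (0, 1, 0.5))
        assert match.unmatched == ((0, 1.0),)

    def test_identity_matches_at_zero(self, rng):
        reps = rng.uniform(1, 2, size=(4, 4))
        D = np.linalg.norm(reps[:, None, :] - reps[None, :, :], axis=-1)
        match = greedy_match(D)
        assert np.all(match.d == 0.0) and not match.unmatched

    def test_single_row_takes_global_minimum(self):
        match = greedy_match(np.array([[3.0, 0.2, 5.0]]))
        assert match.pairs == ((0, 1, 0.2),)
        assert match.unmatched == ((0, 3.0), (2, 5.0))

    def test_agrees_with_bruteforce_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 9))
            m = int(rng.integers(n, 9))
            D = rng.uniform(size=(n, m))
            match = greedy_match(D)
            pairs, unmatched = greedy_oracle(D)
            assert list(match.pairs) == pairs
            assert list(match.unmatched) == unmatched

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            greedy_match(np.empty((0, 0)))
        with pytest.raises(ValueError):
            greedy_match(np.ones((3, 2)))  # rows must be the smaller series
        with pytest.raises(ValueError):
            greedy_match(np.array([[1.0, -0.5]]))


class TestPNorm:
    def test_examples(self):
        assert p_norm_distance(np.zeros(3), 3) == 0.0
        assert p_norm_distance(np.array([3.0, 4.0]), 2) == pytest.approx(5.0)
        assert p_norm_distance(np.array([7.5]), 1) == pytest.approx(7.5)

    def test_stable_for_huge_values_and_large_p(self):
        d = np.full(5, 1e200)
        out = p_norm_distance(d, 5)
        assert np.isfinite(out) and out == pytest.approx(1e200 * 5 ** (1 / 5))

    def test_match_result_uses_p_equals_n(self):
        match = MatchResult(
            pairs=((0, 0, 3.0), (1, 1, 4.0)),
            d=np.array([3.0, 4.0]),
            unmatched=(),
            n=2,
            m=2,
        )
        assert p_norm_distance(match) == pytest.approx(5.0)


class TestEntropy:
    def test_constant_has_zero_entropy(self):
        assert entropy(uv([2.0] * 10)).entropy == 0.0

    def test_two_equifrequent_values(self):
        prof = entropy(uv([1.0, 2.0, 1.0, 2.0]))
        assert prof.entropy == pytest.approx(np.log(2))
        assert prof.frequencies == {1.0: 0.5, 2.0: 0.5}

    def test_all_distinct_values_reach_ln_q(self, rng):
        q = 50
        assert entropy(uv(rng.normal(size=q))).entropy == pytest.approx(np.log(q))

    def test_quantization_coarsens(self, rng):
        s = uv(rng.uniform(size=200))
        assert entropy(s, bins=4).entropy < entropy(s).entropy

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.floats(min_value=-100, max_value=100, allow_nan=False, width=64),
            min_size=2,
            max_size=40,
        )
    )
    def test_bounded_by_ln_q(self, values):
        h = entropy(uv(values)).entropy
        assert -1e-12 <= h <= np.log(len(values)) + 1e-12


class TestEntropyPenalty:
    def make_match(self, unmatched, m):
        n = m - len(unmatched)
        return MatchResult(
            pairs=tuple((i, i, 0.0) for i in range(n)),
            d=np.zeros(n),
            unmatched=tuple(unmatched),
            n=n,
            m=m,
        )

    def test_empty_unmatched(self):
        assert entropy_penalty(self.make_match([], 3), np.ones(3)) == 0.0

    def test_constant_unmatched_costs_nothing(self):
        match = self.make_match([(2, 5.0), (3, 9.0)], 4)
        assert entropy_penalty(match, np.array([1.0, 1.0, 0.0, 0.0])) == 0.0

    def test_equal_entropies_average_the_distances(self):
        match = self.make_match([(1, 1.0), (2, 3.0)], 3)
        H = np.array([0.7, np.log(2), np.log(2)])
        assert entropy_penalty(match, H) == pytest.approx(2.0)

    def test_high_information_dominates(self):
        match = self.make_match([(1, 1.0), (2, 3.0)], 3)
        H = np.array([0.0, 0.01, 10.0])
        assert entropy_penalty(match, H) == pytest.approx(3.0, abs=0.01)

    def test_profile_length_checked(self):
        with pytest.raises(ValueError):
            entropy_penalty(self.make_match([(1, 1.0)], 2), np.ones(5))


class TestDimensionPenalty:
    def test_worked_example_values(self):
        assert dimension_penalty(3, 5) == pytest.approx(0.25)
        assert dimension_penalty(4, 4) == 0.0
        assert dimension_penalty(3, 10) == pytest.approx(7 / 13)

    def test_rejects_bad_dimensions(self):
        with pytest.raises(ValueError):
            dimension_penalty(0, 3)
        with pytest.raises(ValueError):
            dimension_penalty(5, 3)

    @settings(derandomize=True, max_examples=60)
    @given(st.integers(1, 40), st.integers(1, 40))
    def test_strictly_increasing_in_m(self, n, extra):
        m = n + extra
        assert dimension_penalty(n, m) < dimension_penalty(n, m + 1) < 1.0


class TestSmetsDistance:
    def test_identical_series_distance_zero(self, rng):
        a = random_model(rng, 4, 64, "a")
        assert smets_distance(a, a) == 0.0

    def test_worked_trio_isolates_dimension_penalty(self):
        a, b, c = similar_models_trio(length=100)
        assert smets_distance(a, b) == pytest.approx(0.25)
        assert smets_distance(b, c) == pytest.approx(1 / 3)
        assert smets_distance(a, c) == pytest.approx(7 / 13)

    def test_equal_dimension_reduces_to_matched_norm(self, rng):
        a = random_model(rng, 3, 64, "a")
        b = random_model(rng, 3, 64, "b")
        bd = smets_breakdown(a, b)
        assert bd.entropy_penalty == 0.0 and bd.dimension_penalty == 0.0
        assert bd.value == pytest.approx(bd.matched_norm)

    def test_axioms_on_random_pairs(self, rng):
        for _ in range(60):
            a = random_model(rng, int(rng.integers(1, 6)), 64, "a")
            b = random_model(rng, int(rng.integers(1, 6)), 64, "b")
            dab = smets_distance(a, b)
            assert dab >= 0.0
            assert dab == pytest.approx(smets_distance(b, a), abs=1e-9)
            assert dab > 0.0  # independent random models never coincide

    def test_triangle_holds_on_equal_dimensions_sample(self, rng):
        for _ in range(50):
            dim = int(rng.integers(1, 5))
            a, b, c = (random_model(rng, dim, 32, n) for n in "abc")
            dab, dbc, dac = (
                smets_distance(a, b),
                smets_distance(b, c),
                smets_distance(a, c),
            )
            assert dac <= dab + dbc + 1e-9

    def test_triangle_violated_on_mixed_dimensions(self, rng):
        t = np.arange(100, dtype=float)
        base = np.sin(2 * np.pi * t / 20)
        near = base + 0.05 * rng.normal(size=100)
        a = mv("A", uv(base, "osc"), uv(near, "osc2"))
        b = mv("B", uv(base, "osc"))
        c = mv("C", uv(base, "osc"), uv(np.full(100, 2.0), "flat"))
        assert smets_distance(a, c) > smets_distance(a, b) + smets_distance(b, c)

    def test_component_order_irrelevant(self, rng):
        a = random_model(rng, 5, 64, "a")
        b = random_model(rng, 3, 64, "b")
        shuffled = MultivariateSeries("a2", tuple(a.components[::-1]))
        assert smets_distance(a, b) == pytest.approx(smets_distance(shuffled, b))

    def test_different_lengths_share_padded_space(self, rng):
        a = random_model(rng, 2, 100, "a")
        b = random_model(rng, 3, 300, "b")
        assert np.isfinite(smets_distance(a, b))

    def test_moderately_large_comparison_smoke(self, rng):
        a = random_model(rng, 20, 128, "a")
        b = random_model(rng, 30, 128, "b")
        assert np.isfinite(smets_distance(a, b))

    def test_entropy_bins_setting_changes_penalty_only(self, rng):
        a = random_model(rng, 2, 64, "a")
        b = random_model(rng, 4, 64, "b")
        plain = smets_breakdown(a, b)
        binned = smets_breakdown(a, b, PipelineSettings(entropy_bins=8))
        assert plain.matched_norm == pytest.approx(binned.matched_norm)
        assert plain.dimension_penalty == binned.dimension_penalty
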