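"""Maximal information coefficient: grid MI, search, oracle and invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sleepcoupling.mic import (
    GridPartition,
    MICParams,
    backward_prune,
    compute_mic,
    exhaustive_mic_oracle,
    grid_mutual_information,
    optimize_axis_partition,
)

ALPHA_B6_N16 = math.log(6) / math.log(16) + 1e-9  # floor(16**alpha) == 6
P_OFF = MICParams(alpha=ALPHA_B6_N16, chi2_p_threshold=None)


def _naive_mi_bits(x, y, part):
    ix = np.searchsorted(part.x_edges, x, side="right")
    iy = np.searchsorted(part.y_edges, y, side="right")
    n = len(x)
    mi = 0.0
    for a in np.unique(ix):
        for b in np.unique(iy):
            p = np.mean((ix == a) & (iy == b))
            if p > 0:
                mi += p * np.log2(p / (np.mean(ix == a) * np.mean(iy == b)))
    return mi


class TestGridMutualInformation:
    def test_diagonal_two_by_two_is_one_bit(self):
        x = np.arange(20.0)
        part = GridPartition(np.array([9.5]), np.array([9.5]))
        assert grid_mutual_information(x, x, part) == pytest.approx(1.0, abs=1e-12)

    def test_product_form_counts_give_zero(self):
        # 2x2 grid with one point in every cell: independence
        x = np.array([0.0, 0.0, 1.0, 1.0])
        y = np.array([0.0, 1.0, 0.0, 1.0])
        part = GridPartition(np.array([0.5]), np.array([0.5]))
        assert grid_mutual_information(x, y, part) == pytest.approx(0.0, abs=1e-12)

    def test_matches_naive_summation_on_random_grid(self, rng):
        x = rng.random(30)
        y = rng.random(30)
        part = GridPartition(np.sort(rng.choice(x, 2, replace=False)), np.sort(rng.choice(y, 3, replace=False)))
        assert grid_mutual_information(x, y, part) == pytest.approx(
            _naive_mi_bits(x, y, part), abs=1e-12
        )

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            grid_mutual_information(np.arange(5.0), np.arange(6.0), GridPartition(np.array([1.0]), np.array([1.0])))


class TestSearchAgainstOracle:
    def test_equals_exhaustive_enumeration_small_n(self, rng):
        for _ in range(25):
            x = rng.random(16)
            y = rng.random(16)
            heur = compute_mic(x, y, P_OFF).mic
            orac = exhaustive_mic_oracle(x, y, 6)
            assert heur == pytest.approx(orac, abs=1e-12)

    def test_oracle_dominates_terminated_search(self, rng):
        # with the chi-square termination on, the search can only see fewer grids
        p_on = MICParams(alpha=ALPHA_B6_N16, chi2_p_threshold=0.01)
        for _ in range(25):
            x = rng.random(14)
            y = rng.random(14)
            assert compute_mic(x, y, p_on).mic <= exhaustive_mic_oracle(x, y, 6) + 1e-12

    def test_oracle_identity_line(self):
        x = np.arange(12.0)
        assert exhaustive_mic_oracle(x, x, 4) == pytest.approx(1.0, abs=1e-12)

    def test_oracle_guard(self):
        with pytest.raises(ValueError):
            exhaustive_mic_oracle(np.arange(100.0), np.arange(100.0), 6)
        with pytest.raises(ValueError):
            exhaustive_mic_oracle(np.arange(10.0), np.arange(10.0), 10)


class TestComputeMic:
    def test_noiseless_monotone_relation_saturates(self):
        x = np.arange(1.0, 301.0)
        res = compute_mic(x, x, MICParams())
        assert res.mic == 1.0
        assert res.normalizer >= 1.0

    def test_constant_input_degenerate(self):
        x = np.arange(1.0, 301.0)
        res = compute_mic(x, np.ones(300), MICParams())
        assert res.mic == 0.0 and res.degenerate

    @pytest.mark.parametrize(
        "f",
        [lambda x: 2 * x + 1, lambda x: (x - 0.5) ** 2, lambda x: np.sin(4 * np.pi * x)],
        ids=["linear", "quadratic", "sine2"],
    )
    def test_functional_saturation(self, f):
        x = np.linspace(0.0, 1.0, 100)
        assert compute_mic(x, f(x), MICParams()).mic >= 0.99

    def test_symmetry(self, rng):
        x = rng.random(80)
        y = rng.random(80) ** 2 + 0.3 * x
        assert compute_mic(x, y).mic == compute_mic(y, x).mic

    def test_monotone_transform_invariance_exact(self, rng):
        x = rng.random(90)
        y = rng.standard_normal(90) + x
        base = compute_mic(x, y).mic
        assert compute_mic(np.exp(x), y).mic == base
        assert compute_mic(x, y**3).mic == base

    def test_input_validation(self):
        with pytest.raises(ValueError):
            compute_mic(np.arange(5.0), np.arange(5.0))
        with pytest.raises(ValueError):
            compute_mic(np.arange(10.0), np.arange(11.0))
        bad = np.arange(10.0)
        bad[3] = np.nan
        with pytest.raises(ValueError):
            compute_mic(bad, np.arange(10.0))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(
                st.floats(-1e6, 1e6, allow_nan=False),
                st.integers(min_value=-5, max_value=5),
            ),
            min_size=8,
            max_size=40,
        )
    )
    def test_range_property_fuzz(self, data):
        """MIC of arbitrary finite inputs (incl. heavy ties) stays in [0, 1]."""
        x = np.array([a for a, _ in data])
        y = np.array([float(b) for _, b in data])
        res = compute_mic(x, y)
        assert 0.0 <= res.mic <= 1.0


class TestAxisOptimisation:
    def test_noiseless_growth_matches_dp_scores(self):
        # y = x: every cut aligned with an x boundary is hugely significant
        x = np.arange(64.0)
        sols = optimize_axis_partition(x, x, x_edges=np.array([20.5, 41.5]), max_bins=3)
        assert set(sols) == {2, 3}
        # pure 3x3 diagonal: I_G = H(X) for bin sizes 21/21/22
        h = -(2 * (21 / 64) * np.log2(21 / 64) + (22 / 64) * np.log2(22 / 64))
        assert sols[3][1] == pytest.approx(h, abs=1e-12)
        sols2 = optimize_axis_partition(x, x, x_edges=np.array([31.5]), max_bins=3)
        # a third y-cut cannot separate the two x-bins further: chi-square stops it
        assert set(sols2) == {2}
        assert sols2[2][1] == pytest.approx(1.0, abs=1e-12)  # I_G = 1 bit at 2x2

    def test_independent_accepts_fewer_cuts_than_dependent(self, rng):
        dep = indep = 0
        for _ in range(30):
            x = rng.random(300)
            sols_d = optimize_axis_partition(x, x + 0.01 * rng.random(300), np.array([np.median(x)]), 8)
            sols_i = optimize_axis_partition(x, rng.random(300), np.array([np.median(x)]), 8)
            dep += max(sols_d) if sols_d else 1
            indep += max(sols_i) if sols_i else 1
        assert indep < dep

    def test_single_candidate_cut_matches_enumeration(self):
        # n=8 with only one admissible cut on y
        x = np.arange(8.0)
        y = np.array([0.0, 0.0, 0.0, 0.0, 1.0, 1.0, 1.0, 1.0])
        sols = optimize_axis_partition(x, y, x_edges=np.array([3.5]), max_bins=4)
        assert list(sols) == [2]
        assert sols[2][1] == pytest.approx(1.0, abs=1e-12)

    def test_max_bins_validation(self):
        with pytest.raises(ValueError):
            optimize_axis_partition(np.arange(10.0), np.arange(10.0), np.array([4.5]), 1)


class TestBackwardPrune:
    def test_noop_on_already_optimal_equipartition(self):
        x = np.arange(40.0)
        edges = np.array([19.5])
        out = backward_prune(x, x, edges)
        assert out.size == 1 and abs(out[0] - 19.5) < 10  # boundary stays interior

    def test_two_clumps_pruned_to_separating_boundary(self):
        # x clusters at 0 and 100; a 4-bin equipartition collapses to 2 bins
        x = np.concatenate([np.linspace(0, 1, 20), np.linspace(100, 101, 20)])
        y = (x > 50).astype(float) + np.linspace(0, 0.4, 40)
        eq = np.quantile(x, [0.25, 0.5, 0.75])
        out = backward_prune(x, y, eq, MICParams(chi2_p_threshold=None))
        assert out.size < 3

    def test_score_never_decreases(self, rng):
        from sleepcoupling.mic import _score_positions  # white-box paired check

        for _ in range(20):
            x = rng.random(40)
            y = rng.random(40) + 0.5 * x
            med = np.quantile(x, [1 / 3, 2 / 3])
            p = MICParams(chi2_p_threshold=None)
            sols = optimize_axis_partition(x, y, med, 3, p)
            if not sols:
                continue
            k = max(sols, key=lambda kk: sols[kk][1])
            y_edges = sols[k][0]

            def score(edges):
                lab = np.searchsorted(np.asarray(y_edges), y, side="right")
                ky = lab.max() + 1
                ox = np.argsort(x, kind="mergesort")
                Cx = np.zeros((ky, 41))
                np.add.at(Cx, (lab[ox], np.arange(40) + 1), 1.0)
                Cx = np.cumsum(Cx, axis=1)
                xs = x[ox]
                pos = [int(np.searchsorted(xs, e, side="right")) for e in edges]
                return _score_positions(Cx, pos, 40)[1]

            pruned = backward_prune(x, y, med, p, y_edges=y_edges)
            assert score(pruned) >= score(med) - 1e-12
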