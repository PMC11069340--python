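import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isocat import FormatError, analyze_growth, auc_trapezoid, bh_adjust, inhibition_index, welch_t_test
from isocat.simulate import simulate_growth, simulate_panel
from conftest import small_config
from oracles import welch_p_from_betainc


class TestAucTrapezoid:
    @pytest.mark.parametrize(
        "times,od,expected",
        [
            ([0, 1, 2], [0, 1, 2], 2.0),
            ([0, 10], [1.0, 1.0], 10.0),
            ([0, 1, 2, 3], [0, 0, 0, 0], 0.0),
        ],
    )
    def test_examples(self, times, od, expected):
        assert auc_trapezoid(times, od) == expected

    def test_unsorted_times_rejected(self):
        with pytest.raises(FormatError):
            auc_trapezoid([0, 2, 1], [1, 1, 1])

    def test_length_mismatch_rejected(self):
        with pytest.raises(FormatError):
            auc_trapezoid([0, 1], [1, 1, 1])

    @given(
        st.lists(st.floats(0, 100, allow_nan=False), min_size=3, max_size=12,
                 unique=True),
        st.data(),
    )
    @settings(deadline=None, max_examples=100)
    def test_exact_on_piecewise_linear_curves(self, times, data):
        times = sorted(times)
        od = [data.draw(st.floats(0, 5)) for _ in times]
        # closed form: sum of trapezoid areas between breakpoints
        closed = sum(
            (times[i + 1] - times[i]) * (od[i] + od[i + 1]) / 2
            for i in range(len(times) - 1)
        )
        assert auc_trapezoid(times, od) == pytest.approx(closed, rel=1e-12, abs=1e-12)

    def test_additive_over_grid_split(self):
        times = [0.0, 0.5, 1.0, 2.0, 4.0, 8.0]
        od = [0.1, 0.3, 0.9, 1.0, 1.0, 0.8]
        whole = auc_trapezoid(times, od)
        left = auc_trapezoid(times[:4], od[:4])
        right = auc_trapezoid(times[3:], od[3:])
        assert whole == pytest.approx(left + right, rel=1e-12)


class TestInhibitionIndex:
    def test_control_like_is_zero(self):
        assert inhibition_index(10.0, [9.0, 11.0]) == 0.0

    def test_no_growth_is_one(self):
        assert inhibition_index(0.0, [5.0, 5.0]) == 1.0

    def test_half_growth_is_half(self):
        assert inhibition_index(5.0, [10.0, 10.0]) == 0.5

    def test_ratio_variant(self):
        assert inhibition_index(5.0, [10.0], variant="ratio") == 0.5

    def test_nonpositive_control_rejected(self):
        with pytest.raises(FormatError):
            inhibition_index(1.0, [0.0, 0.0])


class TestWelch:
    def test_identical_samples(self):
        t, df, p = welch_t_test([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_hand_computed_example(self):
        t, df, p = welch_t_test([10, 11, 12], [1, 2, 3])
        assert t == pytest.approx(9 * np.sqrt(3 / 2), rel=1e-12)
        assert df == pytest.approx(4.0, rel=1e-12)

    def test_zero_variance_equal_means(self):
        t, df, p = welch_t_test([2, 2], [2, 2])
        assert (t, p) == (0.0, 1.0)

    def test_zero_variance_different_means_sentinel(self):
        with pytest.warns(UserWarning):
            t, df, p = welch_t_test([2, 2], [3, 3])
        assert p == 0.0

    def test_matches_incomplete_beta_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            x = rng.normal(0, 1, size=rng.integers(2, 8))
            y = rng.normal(0.5, 2, size=rng.integers(2, 8))
            t, df, p = welch_t_test(x, y)
            assert p == pytest.approx(welch_p_from_betainc(t, df), rel=1e-10)


class TestBHAdjust:
    def test_single_p(self):
        assert bh_adjust([0.03]) == [0.03]

    def test_step_up_flooring(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(FormatError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=100)
    def test_permutation_invariant_and_dominates_raw(self, ps):
        adj = np.asarray(bh_adjust(ps))
        assert (adj >= np.asarray(ps) - 1e-12).all()
        assert (adj <= 1.0).all()
        perm = np.random.default_rng(0).permutation(len(ps))
        adj_perm = np.asarray(bh_adjust(list(np.asarray(ps)[perm])))
        assert np.allclose(adj_perm, adj[perm])


@pytest.fixture(scope="module")
def small_run():
    cfg = small_config(seed=4)
    panel, _ = simulate_panel(cfg)
    growth = simulate_growth(panel, config=cfg)
    results, tests = analyze_growth(growth)
    return cfg, panel, results, tests


class TestGrowthAssay:

    def test_control_indices_mean_zero_by_construction(self, small_run):
        _, _, results, _ = small_run
        ctrl = results[results.dose_uM == 0].groupby("strain_id")["inhibition_index"].mean()
        assert np.allclose(ctrl, 0.0, atol=1e-12)

    def test_adjusted_p_dominates_raw(self, small_run):
        _, _, _, tests = small_run
        assert (tests["p_adj"] >= tests["p"] - 1e-12).all()

    def test_nondegrader_inhibition_increases_with_dose(self, small_run):
        _, panel, results, _ = small_run
        for strain in [s for s, ph in panel.phenotypes.items() if not ph.degrader]:
            means = (
                results[results.strain_id == strain]
                .groupby("dose_uM")["inhibition_index"].mean()
            )
            assert (np.diff(means.sort_index()) > 0).all(), strain

    def test_degrader_shows_no_dose_effect(self, small_run):
        # |mean effect| < 2 standard errors of the dose-vs-control
        # difference, i.e. |Welch t| < 2, for every degrader/dose
        _, panel, _, tests = small_run
        degraders = [s for s, ph in panel.phenotypes.items() if ph.degrader]
        sub = tests[tests.strain_id.isin(degraders)]
        assert (sub["t"].abs() < 2).all()

    def test_zero_inhibition_slope_abolishes_dose_response(self):
        from isocat.simulate import GrowthParams

        cfg = small_config(
            seed=6, growth=GrowthParams(t_max=24, dt=1.0, n_replicates=4,
                                        inhibition_slope=0.0),
        )
        panel, _ = simulate_panel(cfg)
        _, tests = analyze_growth(simulate_growth(panel, config=cfg))
        assert not tests["significant"].any()

    def test_missing_control_dose_rejected(self):
        cfg = small_config(seed=7)
        panel, _ = simulate_panel(cfg)
        with pytest.raises(Exception):
            simulate_growth(panel, doses=(10.0, 30.0), config=cfg)
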