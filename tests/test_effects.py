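"""AUEC, A/B change ratio, paired test and RSD% summaries."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dipyrone_pd import (
    ab_ratio,
    make_effect_table,
    paired_baseline_effect_test,
    rsd_percent,
    simulate_cohort,
    trapezoid_auec,
)
from dipyrone_pd.effects import DegenerateVarianceError, effect_table_frame
from dipyrone_pd.reference import STUDY_AUEC_ROWS


def dense_interp_area(t, v, t0, t1, step=1e-4):
    """Independent oracle: fine-grid integration of the linear interpolant."""
    grid = np.arange(t0, t1 + step, step)
    grid = grid[grid <= t1]
    if grid[-1] != t1:
        grid = np.append(grid, t1)
    return float(np.trapezoid(np.interp(grid, t, v), grid))


series_strategy = st.integers(3, 12).flatmap(
    lambda n: st.tuples(
        st.lists(st.floats(-36, 72, allow_nan=False), min_size=n, max_size=n,
                 unique=True),
        st.lists(st.floats(0.1, 200), min_size=n, max_size=n),
    )
)


class TestTrapezoidAUEC:
    def test_rectangle(self):
        samples = [(0.0, 10.0), (72.0, 10.0)]
        assert trapezoid_auec(samples, (0, 72)) == pytest.approx(720.0)

    def test_zero_series(self):
        assert trapezoid_auec([(0.0, 0.0), (72.0, 0.0)], (0, 72)) == 0.0

    def test_known_polyline(self):
        samples = list(zip([0, 1, 2, 4], [1, 3, 2, 4]))
        assert trapezoid_auec(samples, (0, 4)) == pytest.approx(10.5)

    def test_window_edge_between_samples_interpolates(self):
        # linear from (0,0) to (4,4); window [1,3] => trapezoid of y=t => 4
        samples = [(0.0, 0.0), (4.0, 4.0)]
        assert trapezoid_auec(samples, (1, 3)) == pytest.approx(4.0)

    @pytest.mark.parametrize(
        "samples, window",
        [
            ([(0.0, 1.0)], (0, 1)),               # single point
            ([(0.0, 1.0), (2.0, 1.0)], (0, 3)),   # window beyond samples
            ([(0.0, 1.0), (2.0, 1.0)], (2, 2)),   # empty window
        ],
    )
    def test_invalid_inputs_rejected(self, samples, window):
        with pytest.raises(ValueError):
            trapezoid_auec(samples, window)

    def test_matches_dense_oracle_on_random_series(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = rng.integers(3, 15)
            t = np.sort(rng.uniform(-36, 72, size=n))
            while np.any(np.diff(t) <= 0):
                t = np.sort(rng.uniform(-36, 72, size=n))
            v = rng.uniform(0.1, 100, size=n)
            t0, t1 = sorted(rng.uniform(t[0], t[-1], size=2))
            if t1 - t0 < 1e-3:
                continue
            area = trapezoid_auec(list(zip(t, v)), (t0, t1))
            oracle = dense_interp_area(t, v, t0, t1)
            assert area == pytest.approx(oracle, rel=1e-6, abs=1e-6)

    @given(series_strategy, st.floats(0.05, 0.95), st.floats(0.05, 0.95))
    def test_additive_over_abutting_windows(self, tv, f1, f2):
        t, v = np.sort(np.array(tv[0])), np.array(tv[1])
        if np.any(np.diff(t) < 1e-6):
            return
        lo, hi = t[0], t[-1]
        mid = lo + min(f1, f2) * (hi - lo)
        if mid <= lo or mid >= hi:
            return
        samples = list(zip(t, v))
        whole = trapezoid_auec(samples, (lo, hi))
        split = trapezoid_auec(samples, (lo, mid)) + trapezoid_auec(samples, (mid, hi))
        assert split == pytest.approx(whole, rel=1e-9, abs=1e-9)


class TestABRatio:
    @pytest.mark.parametrize(
        "row", STUDY_AUEC_ROWS, ids=[r.parameter for r in STUDY_AUEC_ROWS]
    )
    def test_reported_pairs_close(self, row):
        """Each reported (A, B) pair reproduces its reported ratio to 3 d.p."""
        assert round(ab_ratio(row.a_mean, row.b_mean), 3) == row.ab_ratio

    def test_no_change_gives_zero(self):
        assert ab_ratio(720.0, 360.0) == 0.0  # A/72 == B/36

    def test_sign_convention(self):
        # positive when the time-averaged level fell after dosing
        assert ab_ratio(600.0, 360.0) > 0
        assert ab_ratio(800.0, 360.0) < 0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ZeroDivisionError):
            ab_ratio(1.0, 0.0)
        with pytest.raises(ValueError):
            ab_ratio(1.0, 1.0, t_a=0.0)


class TestPairedTest:
    def test_identical_pairs_give_p_one(self):
        assert paired_baseline_effect_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_hand_computed_t_statistic(self):
        """Differences [1,2,3,4]: t = 2.5 / (sd/sqrt(4)) = 3.873, df = 3."""
        from scipy import stats

        b = [10.0, 10.0, 10.0, 10.0]
        a = [11.0, 12.0, 13.0, 14.0]
        p = paired_baseline_effect_test(a, b)
        t_hand = 2.5 / (np.std([1, 2, 3, 4], ddof=1) / 2.0)
        assert t_hand == pytest.approx(3.873, abs=5e-4)
        assert p == pytest.approx(2 * stats.t.sf(t_hand, df=3), rel=1e-9)

    def test_single_animal_rejected(self):
        with pytest.raises(ValueError):
            paired_baseline_effect_test([1.0], [2.0])

    def test_constant_nonzero_differences_degenerate(self):
        with pytest.raises(DegenerateVarianceError):
            paired_baseline_effect_test([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])


class TestRSD:
    def test_constant_list_is_zero(self):
        assert rsd_percent([5.0, 5.0, 5.0]) == 0.0

    def test_hand_computed_value(self):
        assert rsd_percent([8.0, 10.0, 12.0]) == pytest.approx(20.0)

    @given(st.lists(st.floats(1.0, 100.0), min_size=2, max_size=20),
           st.floats(0.1, 50.0))
    def test_scale_invariance(self, values, c):
        if np.mean(values) == 0:
            return
        assert rsd_percent(values) == pytest.approx(
            rsd_percent([c * v for v in values]), rel=1e-9
        )

    def test_zero_mean_rejected(self):
        with pytest.raises(ZeroDivisionError):
            rsd_percent([-1.0, 1.0])


class TestEffectTable:
    def test_null_noise_free_cohort_all_zero_ratios(self):
        from dipyrone_pd import null_study_config

        cfg = replace(null_study_config(), noise_rsd_pct={})
        rows = make_effect_table(simulate_cohort(cfg))
        for row in rows:
            assert row.ab_ratio == pytest.approx(0.0, abs=1e-12)
            assert row.degenerate  # zero-variance paired differences
            assert row.p_value == 1.0  # identical pairs: t = 0

    def test_noise_free_default_reproduces_reported_extrema(self, noise_free_config):
        """Hb row extrema equal the calibrated template levels (12.35, 9.14)."""
        cfg = replace(noise_free_config,
                      templates=tuple(replace(tp, baseline_sd=0.0)
                                      for tp in noise_free_config.templates))
        rows = {r.parameter: r for r in make_effect_table(simulate_cohort(cfg))}
        assert rows["Hb"].dynamic_max_mean == pytest.approx(12.35)
        assert rows["Hb"].dynamic_min_mean == pytest.approx(9.14)

    def test_table_ratio_matches_external_recomputation(self, noisy_dataset):
        rows = make_effect_table(noisy_dataset)
        for row in rows:
            assert row.ab_ratio == pytest.approx(
                ab_ratio(row.a_mean, row.b_mean), rel=1e-12
            )

    def test_frame_has_reportable_columns(self, noisy_dataset):
        frame = effect_table_frame(make_effect_table(noisy_dataset))
        assert {"parameter", "ab_ratio", "p_value", "rsd_baseline_pct",
                "rsd_effect_pct"} <= set(frame.columns)
        assert frame.p_value.between(0, 1).all()
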