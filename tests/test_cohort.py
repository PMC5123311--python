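"""Synthetic-cohort generator: kinetics, effect templates, reproducibility."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from dipyrone_pd import (
    EffectTemplate,
    PKConfig,
    conc_one_compartment,
    default_study_config,
    make_effect_table,
    null_study_config,
    simulate_cohort,
    template_ab_ratio,
)
from dipyrone_pd.cohort import simulate_metabolite_index_relation, template_profile
from dipyrone_pd.datamodel import SamplingSchedule


class TestMetaboliteKinetics:
    def test_no_drug_before_or_at_dose_time(self):
        pk = PKConfig()
        for analyte in ("4MAA", "4AA"):
            assert conc_one_compartment(0.0, pk, analyte) == 0.0
            assert conc_one_compartment(-12.0, pk, analyte) == 0.0

    def test_washout_to_zero(self):
        pk = PKConfig()
        assert conc_one_compartment(5000.0, pk, "4MAA") < 1e-9
        assert conc_one_compartment(5000.0, pk, "4AA") < 1e-9

    @pytest.mark.parametrize(
        "pk",
        [
            PKConfig(),
            PKConfig(ka=0.35, ke_4maa=0.35),            # absorption = elimination
            PKConfig(ka=0.2, ke_4maa=0.2, ke_4aa=0.2),  # fully degenerate rates
        ],
        ids=["distinct", "ka_eq_ke", "all_equal"],
    )
    def test_matches_ode_integration(self, pk):
        """Catenary solution agrees with dense numerical integration."""
        t = np.linspace(0.05, 72.0, 300)

        def rhs(_, x):
            return [
                -pk.ka * x[0],
                pk.ka * x[0] - pk.ke_4maa * x[1],
                pk.fm * pk.ke_4maa * x[1] - pk.ke_4aa * x[2],
            ]

        sol = solve_ivp(rhs, (0.0, 72.0), [pk.dose_mg_per_kg, 0.0, 0.0],
                        t_eval=t, rtol=1e-11, atol=1e-13)
        for analyte, row in (("4MAA", 1), ("4AA", 2)):
            c = conc_one_compartment(t, pk, analyte)
            cmax = c.max()
            assert cmax > 0
            assert np.abs(c - sol.y[row] / pk.v_l_per_kg).max() < 1e-6 * cmax

    def test_nonpositive_rates_rejected(self):
        with pytest.raises(ValueError):
            PKConfig(ka=0.0)


class TestEffectTemplates:
    def test_profile_zero_before_onset_and_bounded(self):
        tp = EffectTemplate("WBC", 15.0, 1.0, "increase", 0.5, onset_h=1.0,
                            peak_h=8.0, recovery_h=48.0, shape="fluctuating")
        t = np.linspace(-36.0, 72.0, 500)
        g = template_profile(tp, t)
        assert np.all(g[t <= 1.0] == 0.0)
        assert np.all((g >= 0.0) & (g <= 1.0))
        assert g[np.argmin(np.abs(t - 8.0))] == pytest.approx(1.0, abs=0.02)

    def test_sustained_profile_holds_at_peak_level(self):
        tp = EffectTemplate("Hb", 12.0, 0.5, "decrease", 0.3, onset_h=0.25, peak_h=12.0)
        assert template_profile(tp, np.array([72.0]))[0] == 1.0

    def test_invalid_templates_rejected(self):
        with pytest.raises(ValueError):
            EffectTemplate("Hb", 12.0, 0.5, "decrease", 1.2)  # >= 1 decrease
        with pytest.raises(ValueError):
            EffectTemplate("Hb", 12.0, 0.5, peak_h=0.0)       # onset !< peak
        with pytest.raises(ValueError):
            EffectTemplate("Hb", 12.0, 0.5, peak_h=4.0, recovery_h=2.0)


class TestSimulateCohort:
    def test_fixed_seed_is_bit_identical(self, study_config):
        a = simulate_cohort(study_config).to_frame()
        b = simulate_cohort(study_config).to_frame()
        assert a.equals(b)

    def test_different_seed_differs(self, study_config):
        a = simulate_cohort(study_config).to_frame()
        b = simulate_cohort(replace(study_config, seed=study_config.seed + 1)).to_frame()
        assert not a.equals(b)

    def test_null_effect_no_noise_is_flat(self):
        cfg = replace(null_study_config(), noise_rsd_pct={})
        ds = simulate_cohort(cfg)
        for s in ds.series:
            assert len(set(s.values)) == 1

    def test_step_decrease_gives_exact_ratio(self):
        """Instant-onset sustained 30% drop => A/B change ratio 0.300 exactly.

        The first post-dose sample sits at t -> 0+ so the trapezoid sees the
        full post-dose plateau: (B/36 - A/72)/(B/36) = 0.30.
        """
        tp = EffectTemplate("Hb", 12.0, 0.0, "decrease", 0.30,
                            onset_h=1e-9, peak_h=5e-8)
        sched = SamplingSchedule(baseline_times=(-36.0, 0.0),
                                 post_times=(1e-7, 36.0, 72.0))
        cfg = replace(null_study_config(), templates=(tp,), noise_rsd_pct={},
                      schedule=sched)
        row = make_effect_table(simulate_cohort(cfg))[0]
        assert row.ab_ratio == pytest.approx(0.30, abs=1e-9)

    def test_noise_free_extrema_match_template_levels(self, noise_free_config):
        """Construction check: per-parameter extrema equal the template levels."""
        cfg = replace(noise_free_config,
                      templates=tuple(replace(tp, baseline_sd=0.0)
                                      for tp in noise_free_config.templates))
        ds = simulate_cohort(cfg)
        rows = {r.parameter: r for r in make_effect_table(ds)}
        for tp in cfg.templates:
            row = rows[tp.parameter]
            lo = tp.baseline_mean * (1 - tp.fractional_change)
            hi = tp.baseline_mean * (1 + tp.fractional_change)
            if tp.direction == "decrease":
                assert row.dynamic_min_mean == pytest.approx(lo, rel=1e-12)
            else:
                assert row.dynamic_max_mean == pytest.approx(hi, rel=0.02)

    def test_configured_rsd_recovered_at_large_n(self):
        """Pooled post-dose RSD% converges to the configured residual noise.

        Uses a null-effect, zero between-animal-SD cohort so the pooled RSD%
        isolates the residual component.
        """
        cfg = null_study_config(noise_rsd=12.0, parameters=("Hb",))
        cfg = replace(
            cfg,
            n_animals=200,
            templates=tuple(replace(tp, baseline_sd=0.0) for tp in cfg.templates),
            seed=42,
        )
        row = make_effect_table(simulate_cohort(cfg))[0]
        assert row.rsd_effect_pct == pytest.approx(12.0, rel=0.15)

    def test_missing_template_is_an_error(self, study_config):
        with pytest.raises(KeyError):
            study_config.template_for("CT_ADP")


class TestDefaultStudyConfig:
    def test_reported_calibration(self, study_config):
        """Template extrema and timings follow the reported study values."""
        tps = {tp.parameter: tp for tp in study_config.templates}
        assert study_config.n_animals == 8
        assert tps["Hb"].baseline_mean == 12.35
        assert tps["Hb"].baseline_mean * (1 - tps["Hb"].fractional_change) == pytest.approx(9.14)
        assert tps["Hct"].baseline_mean * (1 - tps["Hct"].fractional_change) == pytest.approx(26.64)
        assert tps["WBC"].direction == "increase"
        assert tps["WBC"].baseline_mean * (1 + tps["WBC"].fractional_change) == pytest.approx(24.67)
        assert tps["Plt"].peak_h == 10.0 and tps["Plt"].recovery_h == 24.0
        assert tps["fibrinogen"].peak_h == 6.0 and tps["fibrinogen"].recovery_h == 24.0
        assert tps["RBC"].recovery_h is None and tps["Hb"].recovery_h is None
        for rsd in study_config.noise_rsd_pct.values():
            assert 5.02 <= rsd <= 26.34

    def test_template_ratio_matches_dense_integration(self, study_config):
        """Grid closed form vs 1e-4-step trapezoid of the continuous profile."""
        for tp in study_config.templates:
            t = np.arange(0.0, 72.0001, 1e-3)
            g = template_profile(tp, t)
            dense = np.trapezoid(g, t) / 72.0
            sign = -1.0 if tp.direction == "increase" else 1.0
            grid = template_ab_ratio(tp, study_config.schedule)
            # the sparse late grid (24, 48, 72 h) bounds the discretisation gap
            assert grid == pytest.approx(sign * tp.fractional_change * dense, abs=0.03)


class TestIndexRelationGenerator:
    def test_recovers_configured_r2_on_average(self):
        from dipyrone_pd.indices import pearson_r2

        vals = [
            pearson_r2(*simulate_metabolite_index_relation(0.6, 14, seed=s)).r_squared
            for s in range(500)
        ]
        assert np.mean(vals) == pytest.approx(0.6, abs=0.05)
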