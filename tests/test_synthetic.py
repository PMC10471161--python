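"""Generator contracts: state machine, determinism, rate laws, cohort bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from m2afc.behavior import summarize_session
from m2afc.synthetic import (CELL_OVERRIDES, ConfigError, GenerationError,
                             GeneratorConfig, generate_cohort, generate_session,
                             generate_unit_population)


class TestConfigValidation:
    @pytest.mark.parametrize("field,value", [
        ("p_premature", 1.5), ("p_correct", -0.1), ("session_duration", 0.0),
        ("hold_range", (0.0, 0.7)), ("hold_range", (0.2, 6.0)),
        ("gain_preferred", 0.8), ("gain_nonpreferred", 0.0),
        ("iti_press_rate", float("nan")), ("treatment", "sham"),
    ])
    def test_bad_values_name_the_field(self, field, value):
        with pytest.raises(ConfigError):
            GeneratorConfig().with_overrides(**{field: value}).validate()

    def test_unknown_field_rejected(self):
        with pytest.raises(ConfigError, match="unknown"):
            GeneratorConfig().with_overrides(nonexistent=1)


class TestSessionStateMachine:
    def test_degenerate_probabilities_all_correct(self):
        cfg = GeneratorConfig(p_premature=0.0, p_omit=0.0, p_correct=1.0)
        session = generate_session(cfg, seed=0)
        assert (session.trials["outcome"] == "correct").all()
        assert summarize_session(session).accuracy == 100.0

    def test_same_seed_same_events(self):
        cfg = GeneratorConfig(seed=5)
        a = generate_session(cfg, seed=5)
        b = generate_session(cfg, seed=5)
        pd.testing.assert_frame_equal(a.trials, b.trials)

    def test_event_order_within_trials(self):
        cfg = GeneratorConfig()
        for seed in range(5):
            t = generate_session(cfg, seed=seed).trials
            completed = t[t["outcome"].isin(("correct", "incorrect"))]
            assert (completed["t_init_s"] < completed["t_cue_s"]).all()
            assert (completed["t_cue_s"] < completed["t_well_exit_s"]).all()
            assert (completed["t_well_exit_s"] <= completed["t_press_s"]).all()
            prem = t[t["outcome"] == "premature"]
            assert prem["t_cue_s"].isna().all() and prem["t_press_s"].isna().all()
            assert (prem["t_well_exit_s"] < prem["t_init_s"] + prem["hold_s"]).all()

    def test_omission_fraction_matches_parameter(self):
        # law-of-large-numbers check at 10,000 cued trials
        cfg = GeneratorConfig(p_premature=0.0, p_omit=0.29, max_trials=10_000,
                              session_duration=1e9, init_delay_mean=0.0,
                              iti_press_rate=0.0)
        t = generate_session(cfg, seed=42).trials
        assert len(t) == 10_000
        frac = (t["outcome"] == "omission").mean()
        assert frac == pytest.approx(0.29, abs=0.01)

    def test_respects_session_duration_and_max_trials(self):
        t_short = generate_session(GeneratorConfig(session_duration=300.0), seed=1).trials
        assert t_short["t_init_s"].max() < 300.0
        t_cap = generate_session(
            GeneratorConfig(max_trials=15, session_duration=1e6), seed=1).trials
        assert len(t_cap) == 15

    def test_outcome_timestamps_consistent(self):
        t = generate_session(GeneratorConfig(), seed=9).trials
        omitted = t[t["outcome"] == "omission"]
        assert omitted["t_well_exit_s"].notna().all()
        assert omitted["t_press_s"].isna().all()


class TestUnitPopulation:
    def test_homogeneous_units_rarely_flagged(self, small_session):
        # gains of 1 and no ramp: task-locked units carry no modulation
        from m2afc.screening import screen_task_relevance
        cfg = GeneratorConfig(n_units=120, frac_task_locked=1.0,
                              gain_preferred=1.0, gain_nonpreferred=1.0,
                              ramp_amplitude=0.0, baseline_log_sd=0.0,
                              baseline_log_mean=float(np.log(5.0)))
        units, _ = generate_unit_population(cfg, small_session, seed=3)
        flagged = sum(screen_task_relevance(u, small_session).task_locked for u in units)
        assert flagged / len(units) <= 0.08  # ~alpha under Bonferroni

    def test_thinned_rate_matches_analytic_mean(self, small_session):
        # 5 Hz baseline with 3x preferred gain -> ~15 Hz in the post-cue second
        cfg = GeneratorConfig(n_units=30, frac_task_locked=1.0, gain_preferred=3.0,
                              gain_nonpreferred=1.0, ramp_amplitude=0.0,
                              baseline_log_sd=0.0, baseline_log_mean=float(np.log(5.0)))
        units, truth = generate_unit_population(cfg, small_session, seed=4)
        t = small_session.trials
        rates = []
        for u, pref in zip(units, truth["cue_pref"]):
            anchors = t.loc[(t["cue_side"] == pref) & t["t_cue_s"].notna(),
                            "t_cue_s"].to_numpy()
            n = sum(np.searchsorted(u.times, a + 1.0) - np.searchsorted(u.times, a)
                    for a in anchors)
            rates.append(n / len(anchors))
        assert np.mean(rates) == pytest.approx(15.0, rel=0.05)

    def test_full_disinhibition_restores_nonpreferred_baseline(self, small_session):
        cfg = GeneratorConfig(n_units=30, frac_task_locked=1.0, ramp_amplitude=0.0,
                              baseline_log_sd=0.0, baseline_log_mean=float(np.log(8.0)),
                              treatment="propranolol", treatment_disinhibition=1.0)
        units, truth = generate_unit_population(cfg, small_session, seed=5)
        t = small_session.trials
        rates = []
        for u, pref in zip(units, truth["cue_pref"]):
            other = "right" if pref == "left" else "left"
            anchors = t.loc[(t["cue_side"] == other) & t["t_cue_s"].notna(),
                            "t_cue_s"].to_numpy()
            n = sum(np.searchsorted(u.times, a + 1.0) - np.searchsorted(u.times, a)
                    for a in anchors)
            rates.append(n / len(anchors))
        assert np.mean(rates) == pytest.approx(8.0, rel=0.05)

    def test_determinism_bitwise(self, small_session):
        cfg = GeneratorConfig(n_units=6)
        a, _ = generate_unit_population(cfg, small_session, seed=7)
        b, _ = generate_unit_population(cfg, small_session, seed=7)
        for ua, ub in zip(a, b):
            assert np.array_equal(ua.times, ub.times)

    def test_spike_counts_poisson_distributed(self, small_session):
        # chi-square goodness of fit of 1 s window counts for a 6 Hz unit
        from scipy.stats import chisquare, poisson
        cfg = GeneratorConfig(n_units=1, frac_task_locked=0.0, baseline_log_sd=0.0,
                              baseline_log_mean=float(np.log(6.0)))
        (unit,), _ = generate_unit_population(cfg, small_session, seed=8)
        edges = np.arange(0.0, small_session.session_duration, 1.0)
        counts = np.diff(np.searchsorted(unit.times, edges))
        kmax = 14
        observed = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1)
        expected = poisson(6.0).pmf(np.arange(kmax + 1))
        expected[-1] = 1.0 - expected[:-1].sum()
        stat, p = chisquare(observed, expected * observed.sum())
        assert p > 0.01

    def test_empty_session_rejected(self):
        cfg = GeneratorConfig(p_premature=1.0, max_trials=5, session_duration=200.0)
        session = generate_session(cfg, seed=0)
        with pytest.raises(GenerationError):
            generate_unit_population(cfg, session, seed=0)


class TestCohort:
    def test_counts_and_manifest(self):
        cfg = GeneratorConfig(n_subjects_per_group=1, n_units=5,
                              session_duration=600.0)
        cohort = generate_cohort(cfg)
        assert len(cohort.sessions) == 4
        assert len(cohort.spikes) == 20
        assert len(cohort.manifest) == 20
        assert cohort.manifest["unit_id"].is_unique

    def test_task_locked_fraction_exact(self):
        cfg = GeneratorConfig(n_subjects_per_group=1, n_units=10,
                              frac_task_locked=0.7, session_duration=600.0)
        cohort = generate_cohort(cfg)
        per_subject = cohort.manifest.groupby("subject")["is_task_locked"].mean()
        assert (per_subject == 0.7).all()

    def test_preferences_none_iff_not_task_locked(self):
        cohort = generate_cohort(GeneratorConfig(n_subjects_per_group=1, n_units=8,
                                                 session_duration=600.0))
        m = cohort.manifest
        assert ((m["cue_pref"] == "none") == ~m["is_task_locked"]).all()

    def test_treatment_rate_shift_visible_in_expectation(self):
        # female propranolol cell carries a positive baseline shift
        shifts = []
        for seed in range(25):
            cfg = GeneratorConfig(n_subjects_per_group=1, n_units=6,
                                  session_duration=600.0, seed=seed)
            m = generate_cohort(cfg).manifest
            f = m[m["sex"] == "F"]
            shifts.append(f[f["treatment"] == "propranolol"]["baseline_rate_hz"].mean()
                          - f[f["treatment"] == "vehicle"]["baseline_rate_hz"].mean())
        assert np.mean(shifts) > 0

    def test_cohort_determinism(self):
        cfg = GeneratorConfig(n_subjects_per_group=1, n_units=4,
                              session_duration=600.0, seed=3)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        pd.testing.assert_frame_equal(a.manifest, b.manifest)
        for ua, ub in zip(a.spikes, b.spikes):
            assert np.array_equal(ua.times, ub.times)

    def test_behavioral_means_near_study_conditions(self):
        # vehicle females initiate ~144 trials at full session length
        cfg = GeneratorConfig(n_subjects_per_group=4, seed=1, n_units=1)
        cohort = generate_cohort(cfg)
        inits = [s.n_trials for s in cohort.sessions
                 if s.sex == "F" and s.treatment == "vehicle"]
        assert np.mean(inits) == pytest.approx(144.0, rel=0.15)
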