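"""Behavioral metric definitions, conservation laws, and group inference."""

import math

import numpy as np
import pandas as pd
import pytest

from m2afc.behavior import (BehaviorSummary, group_behavior_table,
                            latency_distributions, percent_reduction,
                            summaries_frame, summarize_session)
from m2afc.synthetic import GeneratorConfig, SessionEvents, generate_session


def make_session(rows, **meta):
    cols = ["trial_index", "t_init_s", "hold_s", "cue_side", "t_cue_s",
            "t_well_exit_s", "t_press_s", "press_side", "outcome", "iti_press_count"]
    defaults = dict(subject="s0", sex="F", treatment="vehicle", session_id="sess",
                    session_duration=1000.0)
    defaults.update(meta)
    return SessionEvents(trials=pd.DataFrame(rows, columns=cols), **defaults)


def trial(i, outcome, t0, iti_presses=0):
    nan = math.nan
    if outcome == "premature":
        return (i, t0, 0.5, "none", nan, t0 + 0.2, nan, "none", outcome, iti_presses)
    if outcome == "omission":
        return (i, t0, 0.5, "left", t0 + 0.5, t0 + 1.1, nan, "none", outcome, iti_presses)
    side = "left"
    press = side if outcome == "correct" else "right"
    return (i, t0, 0.5, side, t0 + 0.5, t0 + 1.1, t0 + 2.0, press, outcome, iti_presses)


class TestSummaries:
    def test_outcome_percentages(self):
        rows = ([trial(i, "premature", 20 * i) for i in range(2)]
                + [trial(i + 2, "correct", 20 * (i + 2)) for i in range(5)]
                + [trial(i + 7, "incorrect", 20 * (i + 7)) for i in range(2)]
                + [trial(9, "omission", 180)])
        s = summarize_session(make_session(rows))
        assert s.trials_initiated == 10
        assert s.pct_premature == pytest.approx(20.0)
        assert s.accuracy == pytest.approx(62.5)
        assert s.pct_omission == pytest.approx(12.5)

    def test_lever_press_index(self):
        # 30 in-trial presses (completed trials) + 10 ITI presses -> 0.25
        rows = [trial(i, "correct", 20 * i) for i in range(30)]
        rows[0] = trial(0, "correct", 0, iti_presses=10)
        s = summarize_session(make_session(rows))
        assert s.lever_press_index == pytest.approx(0.25)

    def test_no_cued_trials_gives_undefined_not_zero(self):
        rows = [trial(i, "premature", 20 * i) for i in range(3)]
        s = summarize_session(make_session(rows))
        assert math.isnan(s.accuracy) and math.isnan(s.pct_omission)
        assert s.pct_premature == pytest.approx(100.0)

    def test_outcome_conservation(self, small_session):
        s = summarize_session(small_session)
        t = small_session.trials["outcome"].value_counts()
        assert int(t.sum()) == s.trials_initiated
        assert s.accuracy + s.pct_omission + s.pct_incorrect == pytest.approx(100.0)

    def test_time_translation_invariance(self, small_session):
        shifted = SessionEvents(
            subject=small_session.subject, sex=small_session.sex,
            treatment=small_session.treatment, session_id=small_session.session_id,
            trials=small_session.trials.assign(**{
                c: small_session.trials[c] + 500.0
                for c in ("t_init_s", "t_cue_s", "t_well_exit_s", "t_press_s")}),
            session_duration=small_session.session_duration + 500.0)
        a, b = summarize_session(small_session), summarize_session(shifted)
        for f in ("accuracy", "pct_omission", "lever_press_index",
                  "median_decision_time", "median_reaction_time"):
            assert getattr(a, f) == pytest.approx(getattr(b, f))


class TestLatencies:
    def test_decision_time_definition(self):
        rows = [trial(0, "correct", 10.0)]
        rows[0] = (0, 10.0, 0.5, "left", 12.0, 12.618, 13.5, "left", "correct", 0)
        d, r = latency_distributions(make_session(rows))
        assert d[0] == pytest.approx(0.618)
        assert r[0] == pytest.approx(1.5)

    def test_omission_contributes_decision_only(self):
        d, r = latency_distributions(make_session([trial(0, "omission", 5.0)]))
        assert len(d) == 1 and len(r) == 0

    def test_median_invariant_to_trial_order(self, small_session):
        shuffled = SessionEvents(
            subject="x", sex="F", treatment="vehicle", session_id="x",
            trials=small_session.trials.sample(frac=1.0, random_state=0)
            .reset_index(drop=True),
            session_duration=small_session.session_duration)
        a = summarize_session(small_session)
        b = summarize_session(shuffled)
        assert a.median_decision_time == pytest.approx(b.median_decision_time)

    def test_spread_difference_detected(self, rng):
        # twofold log-scale spread difference is detected by the robust
        # spread test in most simulations at n=100 per group
        from m2afc.stats import robust_spread_test
        hits = 0
        for _ in range(200):
            a = np.exp(0.4 * rng.standard_normal(100))
            b = np.exp(0.8 * rng.standard_normal(100))
            hits += robust_spread_test(a, b).p < 0.05
        assert hits / 200 > 0.90


class TestPercentReduction:
    def test_reported_reductions_from_group_means(self):
        assert percent_reduction(144.00, 52.90) == pytest.approx(63.0, abs=0.5)
        assert percent_reduction(128.33, 80.89) == pytest.approx(37.0, abs=0.5)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            percent_reduction(0.0, 5.0)


def _summary(subject, sex, treatment, **kw):
    base = dict(subject=subject, sex=sex, treatment=treatment, session_id="s",
                trials_initiated=100, pct_premature=10.0, accuracy=90.0,
                pct_omission=5.0, pct_incorrect=5.0, lever_press_index=0.2,
                median_decision_time=0.6, median_reaction_time=1.5)
    base.update(kw)
    return BehaviorSummary(**base)


class TestGroupTable:
    def test_two_cell_closed_form(self):
        sums = ([_summary(f"a{i}", "F", "vehicle", accuracy=v)
                 for i, v in enumerate((1.0, 2.0, 3.0))]
                + [_summary(f"b{i}", "F", "propranolol", accuracy=v)
                   for i, v in enumerate((11.0, 12.0, 13.0))])
        desc = group_behavior_table(sums, metrics=["accuracy"])["descriptives"]
        means = desc.set_index("treatment")["mean"]
        assert means["propranolol"] - means["vehicle"] == pytest.approx(10.0)
        # sample SD of {1,2,3} is 1, so the per-cell SEM is 1/sqrt(3)
        assert desc["sem"].iloc[0] == pytest.approx(1.0 / math.sqrt(3), rel=1e-6)

    def test_null_alpha_control(self, rng):
        # identical groups: interaction p < 0.05 in at most ~6% of simulations
        false_hits = 0
        n_sims = 200
        for _ in range(n_sims):
            sums = [_summary(f"s{i}{sex}{trt}", sex, trt,
                             accuracy=float(rng.normal(90, 5)))
                    for sex in ("F", "M") for trt in ("vehicle", "propranolol")
                    for i in range(5)]
            eff = group_behavior_table(sums, metrics=["accuracy"])["effects"]
            p = eff.loc[eff["effect"] == "sex:treatment", "p"].iloc[0]
            false_hits += p < 0.05
        assert false_hits / n_sims <= 0.10

    def test_built_in_interaction_detected(self, rng):
        # treatment effect present only in females
        hits = 0
        n_sims = 60
        for _ in range(n_sims):
            sums = []
            for sex in ("F", "M"):
                for trt in ("vehicle", "propranolol"):
                    shift = -30.0 if (sex == "F" and trt == "propranolol") else 0.0
                    sums += [_summary(f"s{i}{sex}{trt}", sex, trt,
                                      accuracy=float(rng.normal(90 + shift, 8)))
                             for i in range(8)]
            eff = group_behavior_table(sums, metrics=["accuracy"])["effects"]
            p = eff.loc[eff["effect"] == "sex:treatment", "p"].iloc[0]
            hits += p < 0.05
        assert hits / n_sims > 0.80

    def test_underfilled_cell_flagged_unavailable(self):
        sums = ([_summary("a", "F", "vehicle"), _summary("b", "F", "vehicle"),
                 _summary("c", "F", "propranolol")])
        eff = group_behavior_table(sums, metrics=["accuracy"])["effects"]
        assert eff["p"].isna().all()

    def test_round_trip_with_generator(self):
        cfg = GeneratorConfig()
        sums = [summarize_session(generate_session(cfg, subject_id=f"s{i}",
                                                   seed=100 + i))
                for i in range(6)]
        df = summaries_frame(sums)
        assert df["trials_initiated"].mean() == pytest.approx(144.0, rel=0.15)
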