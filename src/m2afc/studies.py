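"""Reference simulation studies exercising the pipeline end to end.

Each function here defines one named study — a generator configuration plus
the analysis run on it — so that tests, scripts, and documentation all run
the identical conditions.  The studies cover: screening false-positive
calibration and power, side-preference-index recovery, population
action-plan separation under vehicle-like vs disinhibited conditions, and
decoding calibration/contrast.

The separation study deliberately runs in a low-rate, moderate-trial regime
(three ~12 min sessions, ~1.3 Hz baselines, 10 units each) calibrated so the
vehicle-like population shows sustained separation on the ~1.3 s scale that
motivates the analysis; cleaner, longer sessions saturate the paired tests
and separation simply tracks the press-time tail.
"""

from __future__ import annotations

import numpy as np

from .decoding import bin_unit_cue_trials, decode_timecourse, permutation_significance
from .peth import build_population_peth, separation_profile
from .screening import screen_task_relevance, screen_units
from .synthetic import (CELL_OVERRIDES, GeneratorConfig, generate_session,
                        generate_unit_population)

__all__ = [
    "screening_null_rate",
    "screening_power",
    "spi_recovery",
    "separation_study_config",
    "separation_run_lengths",
    "decoding_null_study",
    "decoding_signal_study",
]


def _seq(seed) -> np.random.SeedSequence:
    return seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)


# ---------------------------------------------------------------------------
# screening calibration / power


def screening_null_rate(n_units: int = 1000, n_trials: int = 100,
                        rate_hz: float = 5.0, alpha: float = 0.05,
                        seed=0) -> float:
    """Fraction of homogeneous-Poisson units flagged task-locked.

    Bonferroni over the four epochs controls the family-wise error, so the
    flagged fraction should not exceed ``alpha``.
    """
    ss = _seq(seed)
    s_session, s_units = ss.spawn(2)
    cfg = GeneratorConfig(session_duration=n_trials * 16.0, max_trials=n_trials,
                          p_premature=0.1, n_units=n_units, frac_task_locked=0.0,
                          baseline_log_mean=float(np.log(rate_hz)), baseline_log_sd=0.0)
    session = generate_session(cfg, seed=s_session)
    units, _ = generate_unit_population(cfg, session, seed=s_units)
    flagged = sum(screen_task_relevance(u, session, alpha=alpha).task_locked
                  for u in units)
    return flagged / n_units


def screening_power(n_units: int = 200, n_trials: int = 100,
                    rate_hz: float = 5.0, gain: float = 3.0,
                    alpha: float = 0.05, seed=0) -> float:
    """Detection rate for units with a genuine gain-times-baseline cue response."""
    ss = _seq(seed)
    s_session, s_units = ss.spawn(2)
    cfg = GeneratorConfig(session_duration=n_trials * 16.0, max_trials=n_trials,
                          p_premature=0.1, n_units=n_units, frac_task_locked=1.0,
                          baseline_log_mean=float(np.log(rate_hz)), baseline_log_sd=0.0,
                          gain_preferred=gain, gain_nonpreferred=1.0, ramp_amplitude=0.0)
    session = generate_session(cfg, seed=s_session)
    units, _ = generate_unit_population(cfg, session, seed=s_units)
    detected = sum(screen_task_relevance(u, session, alpha=alpha).task_locked
                   for u in units)
    return detected / n_units


def spi_recovery(n_units: int = 100, seed=0, gain_preferred: float = 2.5,
                 gain_nonpreferred: float = 0.4) -> float:
    """Fraction of task-locked units whose SPI sign matches ground truth.

    Uses a session long enough for >=50 cued trials per side.
    """
    ss = _seq(seed)
    s_session, s_units = ss.spawn(2)
    cfg = GeneratorConfig(session_duration=2400.0, max_trials=160, p_premature=0.1,
                          p_omit=0.05, init_delay_mean=2.0, n_units=n_units,
                          frac_task_locked=1.0, gain_preferred=gain_preferred,
                          gain_nonpreferred=gain_nonpreferred)
    session = generate_session(cfg, seed=s_session)
    units, truth = generate_unit_population(cfg, session, seed=s_units)
    df = screen_units(units, {(session.subject, session.session_id): session})
    merged = df.merge(truth[["unit_id", "cue_pref"]].rename(columns={"cue_pref": "true_pref"}),
                      on="unit_id")
    locked = merged[merged["task_locked"] & (merged["cue_pref"] != "none")]
    if len(locked) == 0:
        return 0.0
    return float((locked["cue_pref"] == locked["true_pref"]).mean())


# ---------------------------------------------------------------------------
# population separation


def separation_study_config(disinhibited: bool = False) -> GeneratorConfig:
    """Conditions for the action-plan separation study.

    Vehicle-female behavioral parameters with three adjustments that put the
    population analysis on the empirically relevant scale: short sessions
    (~45 trials), low baseline rates (median 1.25 Hz), broader latency
    spreads, and a small pre-press ramp.  The disinhibited variant switches
    the treatment on with full disinhibition (nonpreferred gain pulled to 1)
    and no baseline shift, isolating the loss of active inhibition.
    """
    overrides = dict(CELL_OVERRIDES[("F", "vehicle")])
    overrides.update(
        session_duration=730.0, n_units=10, frac_task_locked=0.7,
        baseline_log_mean=float(np.log(1.25)), ramp_amplitude=0.5,
        decision_time_spread=0.8, press_latency_spread=0.9)
    cfg = GeneratorConfig().with_overrides(**overrides)
    if disinhibited:
        cfg = cfg.with_overrides(treatment="propranolol",
                                 treatment_disinhibition=1.0,
                                 treatment_rate_shift=0.0)
    return cfg


def separation_run_lengths(n_sims: int, seed=0, disinhibited: bool = False,
                           n_subjects: int = 3, alpha: float = 0.05) -> np.ndarray:
    """Longest significant-separation run (s) per simulated pooled cohort.

    Each simulation pools task-locked, side-preferring units from
    ``n_subjects`` independent sessions (10 units each) into one cue-aligned
    population PETH, mirroring how recorded populations combine animals.
    """
    cfg = separation_study_config(disinhibited)
    ss = _seq(seed)
    runs = np.empty(n_sims)
    for i, sim_ss in enumerate(ss.spawn(n_sims)):
        triples = []
        for j, sub_ss in enumerate(sim_ss.spawn(n_subjects)):
            s1, s2 = sub_ss.spawn(2)
            session = generate_session(cfg, subject_id=f"s{j}", seed=s1)
            units, _ = generate_unit_population(cfg, session, seed=s2)
            df = screen_units(units, {(session.subject, session.session_id): session})
            by_id = {u.unit_id: u for u in units}
            sel = df[df["task_locked"] & (df["cue_pref"] != "none")]
            triples += [(by_id[r.unit_id], session, r.cue_pref)
                        for r in sel.itertuples()]
        if len(triples) < 2:
            runs[i] = 0.0
            continue
        pop = build_population_peth(triples, alignment="cue")
        runs[i] = separation_profile(pop, alpha=alpha).longest_run_s
    return runs


# ---------------------------------------------------------------------------
# decoding


def _signal_cohort(seed, n_units: int = 18):
    # strongly separable regime: ~12.5 Hz preferred vs ~2 Hz nonpreferred
    cfg = GeneratorConfig().with_overrides(**CELL_OVERRIDES[("F", "vehicle")],
                                           n_units=n_units)
    cfg = cfg.with_overrides(baseline_log_mean=float(np.log(5.0)),
                             baseline_log_sd=0.3)
    ss = _seq(seed)
    s1, s2 = ss.spawn(2)
    session = generate_session(cfg, seed=s1)
    units, truth = generate_unit_population(cfg, session, seed=s2)
    locked = [u for u, t in zip(units, truth["is_task_locked"]) if t]
    return [bin_unit_cue_trials(u, session) for u in locked]


def _null_cohort(seed, n_units: int = 14):
    cfg = GeneratorConfig().with_overrides(**CELL_OVERRIDES[("F", "vehicle")],
                                           n_units=n_units, frac_task_locked=0.0)
    ss = _seq(seed)
    s1, s2 = ss.spawn(2)
    session = generate_session(cfg, seed=s1)
    units, _ = generate_unit_population(cfg, session, seed=s2)
    return [bin_unit_cue_trials(u, session) for u in units]


def decoding_null_study(seed=0, n_resamples: int = 20, n_shuffles: int = 50,
                        alpha: float = 0.05):
    """Decode a signal-free cohort and test it against its shuffle null.

    Returns the :class:`~m2afc.decoding.DecodingResult`; accuracy should sit
    at chance and the per-bin significant fraction should not exceed alpha on
    average.
    """
    ss = _seq(seed)
    s_data, s_obs, s_null = ss.spawn(3)
    counts = _null_cohort(s_data)
    acc = decode_timecourse(counts, n_resamples=n_resamples, seed=s_obs)
    return permutation_significance(counts, acc, n_shuffles=n_shuffles,
                                    alpha=alpha, seed=s_null,
                                    n_resamples=n_resamples)


def decoding_signal_study(seed=0, n_resamples: int = 20, n_shuffles: int = 50,
                          alpha: float = 0.05):
    """Decode a strongly cue-modulated cohort against its shuffle null.

    Post-cue accuracy should exceed 0.95 with significance onset at the
    first post-cue bin.
    """
    ss = _seq(seed)
    s_data, s_obs, s_null = ss.spawn(3)
    counts = _signal_cohort(s_data)
    acc = decode_timecourse(counts, n_resamples=n_resamples, seed=s_obs)
    return permutation_significance(counts, acc, n_shuffles=n_shuffles,
                                    alpha=alpha, seed=s_null,
                                    n_resamples=n_resamples)
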