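"""Synthetic 2AFC sessions and task-modulated spike trains with known ground truth.

The generator emulates a rodent two-alternative forced-choice (2AFC) operant
session: self-initiated trials with a variable nosepoke hold (200–700 ms), a
left/right LED cue, a response window, and outcome-dependent intertrial
intervals (5 s after correct, 10 s otherwise).  On top of the behavioral
stream it simulates premotor-cortex-like single units as inhomogeneous
Poisson processes: task-locked units fire above baseline after their
preferred cue, are actively inhibited after the nonpreferred cue, and ramp up
in the second before the lever press.  A "propranolol" treatment condition
removes part of the nonpreferred inhibition (disinhibition) and can shift
baseline rates, reproducing the sex-by-treatment contrasts the downstream
analyses are designed to detect.

Everything is driven by a single integer seed which fans out to per-subject
and per-unit child seeds through :class:`numpy.random.SeedSequence`, so any
subject or unit can be regenerated in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "GeneratorConfig",
    "SessionEvents",
    "SpikeTrain",
    "Cohort",
    "ConfigError",
    "GenerationError",
    "generate_session",
    "generate_unit_population",
    "generate_cohort",
    "CELL_OVERRIDES",
]

OUTCOMES = ("correct", "incorrect", "omission", "premature")
SIDES = ("left", "right")


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the field."""


class GenerationError(RuntimeError):
    """Raised when a session cannot support the requested generation step."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of one simulated subject-session.

    Probabilities are per-trial; durations in seconds; rates in Hz.  Latency
    medians/spreads parameterize log-normal draws (spread = SD on the log
    scale).  ``baseline_log_mean``/``baseline_log_sd`` are the log-normal
    parameters of per-unit baseline firing rates.  ``treatment`` switches the
    disinhibition and rate-shift knobs on ("propranolol") or off ("vehicle").
    """

    n_subjects_per_group: int = 5
    session_duration: float = 2400.0
    max_trials: int = 250
    hold_range: tuple[float, float] = (0.200, 0.700)
    response_window: float = 5.0
    iti_correct: float = 5.0
    iti_error: float = 10.0
    p_premature: float = 0.20
    p_correct: float = 0.92
    p_omit: float = 0.08
    decision_time_median: float = 0.62
    decision_time_spread: float = 0.45
    press_latency_median: float = 0.93
    press_latency_spread: float = 0.45
    init_delay_mean: float = 8.5
    iti_press_rate: float = 0.04
    n_units: int = 20
    frac_task_locked: float = 0.70
    baseline_log_mean: float = 1.044  # log-scale mean; exp(mu + sd^2/2) ~ 3.4 Hz
    baseline_log_sd: float = 0.60
    gain_preferred: float = 2.5
    gain_nonpreferred: float = 0.4
    ramp_amplitude: float = 3.0
    treatment: str = "vehicle"
    treatment_disinhibition: float = 0.0
    treatment_rate_shift: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("p_premature", "p_correct", "p_omit", "frac_task_locked",
                     "treatment_disinhibition"):
            v = getattr(self, name)
            if not np.isfinite(v) or not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be a probability in [0, 1], got {v!r}")
        for name in ("session_duration", "response_window", "iti_correct", "iti_error",
                     "decision_time_median", "decision_time_spread",
                     "press_latency_median", "press_latency_spread"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ConfigError(f"{name} must be positive and finite, got {v!r}")
        for name in ("init_delay_mean", "iti_press_rate", "ramp_amplitude",
                     "baseline_log_sd"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ConfigError(f"{name} must be nonnegative and finite, got {v!r}")
        lo, hi = self.hold_range
        if not (0.0 < lo <= hi < self.response_window):
            raise ConfigError(
                f"hold_range must lie within (0, response_window), got {self.hold_range!r}")
        if not (self.gain_preferred >= 1.0 >= self.gain_nonpreferred > 0.0):
            raise ConfigError(
                "gains must satisfy gain_preferred >= 1 >= gain_nonpreferred > 0, "
                f"got {self.gain_preferred!r}/{self.gain_nonpreferred!r}")
        for name in ("max_trials", "n_units", "n_subjects_per_group"):
            v = getattr(self, name)
            if int(v) != v or v < 1:
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")
        if self.treatment not in ("vehicle", "propranolol"):
            raise ConfigError(f"treatment must be 'vehicle' or 'propranolol', got {self.treatment!r}")
        if not np.isfinite(self.treatment_rate_shift):
            raise ConfigError(f"treatment_rate_shift must be finite, got {self.treatment_rate_shift!r}")

    def with_overrides(self, **kwargs) -> "GeneratorConfig":
        unknown = set(kwargs) - {f.name for f in fields(self)}
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        return replace(self, **kwargs)


TRIAL_COLUMNS = [
    "trial_index", "t_init_s", "hold_s", "cue_side", "t_cue_s", "t_well_exit_s",
    "t_press_s", "press_side", "outcome", "iti_press_count",
]


@dataclass
class SessionEvents:
    """One behavioral session: per-trial event table plus subject metadata.

    ``trials`` columns follow :data:`TRIAL_COLUMNS`; absent timestamps are
    NaN, absent sides are "none".  ``response_window``/``iti_correct``/
    ``iti_error`` are carried so ITI intervals can be reconstructed from
    outcomes alone.
    """

    subject: str
    sex: str
    treatment: str
    session_id: str
    trials: pd.DataFrame
    session_duration: float
    response_window: float = 5.0
    iti_correct: float = 5.0
    iti_error: float = 10.0

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def cued_trials(self) -> pd.DataFrame:
        return self.trials[self.trials["outcome"] != "premature"]

    def completed_trials(self) -> pd.DataFrame:
        return self.trials[self.trials["outcome"].isin(("correct", "incorrect"))]

    def trial_end_times(self) -> np.ndarray:
        """When each trial's ITI begins: press, end of response window, or well exit."""
        t = self.trials
        end = t["t_press_s"].to_numpy(dtype=float).copy()
        omit = (t["outcome"] == "omission").to_numpy()
        prem = (t["outcome"] == "premature").to_numpy()
        end[omit] = t["t_well_exit_s"].to_numpy(dtype=float)[omit] + self.response_window
        end[prem] = t["t_well_exit_s"].to_numpy(dtype=float)[prem]
        return end

    def iti_durations(self) -> np.ndarray:
        correct = (self.trials["outcome"] == "correct").to_numpy()
        return np.where(correct, self.iti_correct, self.iti_error)


@dataclass
class SpikeTrain:
    """Sorted spike times for one unit plus subject metadata."""

    unit_id: str
    subject: str
    session_id: str
    sex: str
    treatment: str
    times: np.ndarray
    t_stop: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and (np.any(np.diff(self.times) < 0) or self.times[0] < 0):
            raise ValueError(f"unit {self.unit_id}: spike times must be nonnegative and sorted")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def mean_rate(self) -> float:
        return self.n_spikes / self.t_stop if self.t_stop > 0 else math.nan


def _lognormal(rng: np.random.Generator, median: float, spread: float, size=None):
    return np.exp(np.log(median) + spread * rng.standard_normal(size))


def generate_session(config: GeneratorConfig, subject_id: str = "s0",
                     seed: int | np.random.SeedSequence | None = None,
                     sex: str = "F", session_id: str | None = None) -> SessionEvents:
    """Simulate one session through the trial state machine.

    Each trial: initiation (IR-beam break) → uniform hold draw → with
    probability ``p_premature`` an early well exit (no cue, error ITI);
    otherwise a Bernoulli(0.5) cue side, a log-normal decision time to well
    exit, then either an omission (no press within the response window) or a
    press whose correctness is Bernoulli(``p_correct``).  ITI lever presses
    are Poisson at ``iti_press_rate``.  Generation stops at
    ``session_duration`` or ``max_trials``, whichever comes first.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    lo, hi = config.hold_range
    rows = []
    t = float(rng.exponential(config.init_delay_mean))
    k = 0
    while t < config.session_duration and k < config.max_trials:
        t_init = t
        hold = float(rng.uniform(lo, hi))
        t_cue = t_well_exit = t_press = math.nan
        cue_side = press_side = "none"
        if rng.random() < config.p_premature:
            outcome = "premature"
            t_well_exit = t_init + hold * float(rng.uniform(0.1, 0.95))
            end = t_well_exit
            iti = config.iti_error
        else:
            t_cue = t_init + hold
            cue_side = SIDES[int(rng.random() < 0.5)]
            decision = float(_lognormal(rng, config.decision_time_median,
                                        config.decision_time_spread))
            t_well_exit = t_cue + decision
            if rng.random() < config.p_omit:
                outcome = "omission"
                end = t_well_exit + config.response_window
                iti = config.iti_error
            else:
                lat = float(_lognormal(rng, config.press_latency_median,
                                       config.press_latency_spread))
                lat = min(lat, 0.99 * config.response_window)
                t_press = t_well_exit + lat
                if rng.random() < config.p_correct:
                    outcome = "correct"
                    press_side = cue_side
                    iti = config.iti_correct
                else:
                    outcome = "incorrect"
                    press_side = SIDES[1 - SIDES.index(cue_side)]
                    iti = config.iti_error
                end = t_press
        iti_presses = int(rng.poisson(config.iti_press_rate * iti))
        rows.append((k, t_init, hold, cue_side, t_cue, t_well_exit, t_press,
                     press_side, outcome, iti_presses))
        t = end + iti + float(rng.exponential(config.init_delay_mean))
        k += 1
    trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    return SessionEvents(
        subject=subject_id, sex=sex, treatment=config.treatment,
        session_id=session_id or f"{subject_id}-{config.treatment}",
        trials=trials, session_duration=config.session_duration,
        response_window=config.response_window,
        iti_correct=config.iti_correct, iti_error=config.iti_error,
    )


def _assign_ground_truth(config: GeneratorConfig, n_units: int) -> pd.DataFrame:
    """Deterministic task-locked assignment and round-robin side preferences.

    The first ``round(frac_task_locked * n_units)`` units are task-locked and
    alternate left/right preference so small cohorts stay balanced; press
    preference matches cue preference for generated units.
    """
    n_locked = int(round(config.frac_task_locked * n_units))
    recs = []
    for i in range(n_units):
        locked = i < n_locked
        pref = SIDES[i % 2] if locked else "none"
        recs.append((locked, pref, pref))
    return pd.DataFrame(recs, columns=["is_task_locked", "cue_pref", "press_pref"])


def _modulation_intervals(session: SessionEvents):
    """Per-trial modulation spans: (start, stop, cue_side, t_press or nan)."""
    spans = []
    for row in session.cued_trials().itertuples(index=False):
        start = row.t_cue_s
        if row.outcome == "omission":
            stop = row.t_well_exit_s + session.response_window
            t_press = math.nan
        else:
            stop = row.t_press_s
            t_press = row.t_press_s
        spans.append((start, stop, row.cue_side, t_press, row.press_side))
    return spans


def _unit_rate(times: np.ndarray, spans, pref: str, base: float,
               g_pref: float, g_nonpref: float, ramp: float) -> np.ndarray:
    """Instantaneous firing rate at candidate spike times for one task unit."""
    rate = np.full(times.shape, base)
    for start, stop, cue_side, t_press, press_side in spans:
        m = (times >= start) & (times < stop)
        if not m.any():
            continue
        rate[m] = base * (g_pref if cue_side == pref else g_nonpref)
        if np.isfinite(t_press) and press_side == pref:
            r = m & (times >= t_press - 1.0)
            rate[r] += ramp * (1.0 - (t_press - times[r]))
    return rate


def generate_unit_population(config: GeneratorConfig, session: SessionEvents,
                             seed: int | np.random.SeedSequence | None = None,
                             ) -> tuple[list[SpikeTrain], pd.DataFrame]:
    """Simulate a unit population for one session by Poisson thinning.

    Task-locked units multiply their baseline by ``gain_preferred`` between
    preferred-cue onset and press (or well exit + response window on
    omissions), by ``gain_nonpreferred`` on nonpreferred-cue trials, and add a
    linear ramp of ``ramp_amplitude`` over the final second before a
    preferred-side press.  Non-task units are homogeneous Poisson.  Under the
    propranolol condition ``treatment_disinhibition`` pulls the nonpreferred
    gain toward 1 and ``treatment_rate_shift`` is added to every baseline.

    Returns the spike trains and a ground-truth table (one row per unit).
    """
    config.validate()
    if session.n_trials == 0:
        raise GenerationError("session has no trials")
    if len(session.cued_trials()) == 0:
        raise GenerationError("session has no cued trials; cannot place task modulation")
    if seed is None:
        seed = config.seed
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    child_seeds = ss.spawn(config.n_units + 1)
    rng0 = np.random.default_rng(child_seeds[0])

    truth = _assign_ground_truth(config, config.n_units)
    baselines = np.exp(config.baseline_log_mean
                       + config.baseline_log_sd * rng0.standard_normal(config.n_units))
    treated = config.treatment == "propranolol"
    if treated:
        baselines = np.maximum(baselines + config.treatment_rate_shift, 0.05)
    g_nonpref = config.gain_nonpreferred
    if treated:
        g_nonpref = g_nonpref + config.treatment_disinhibition * (1.0 - g_nonpref)

    spans = _modulation_intervals(session)
    T = session.session_duration
    trains = []
    truth_rows = []
    for i in range(config.n_units):
        rng = np.random.default_rng(child_seeds[i + 1])
        base = float(baselines[i])
        locked = bool(truth.at[i, "is_task_locked"])
        pref = truth.at[i, "cue_pref"]
        if locked:
            rate_max = base * max(1.0, config.gain_preferred) + config.ramp_amplitude
            n_cand = rng.poisson(rate_max * T)
            cand = np.sort(rng.uniform(0.0, T, n_cand))
            rate = _unit_rate(cand, spans, pref, base, config.gain_preferred,
                              g_nonpref, config.ramp_amplitude)
            keep = rng.random(n_cand) < rate / rate_max
            times = cand[keep]
        else:
            n = rng.poisson(base * T)
            times = np.sort(rng.uniform(0.0, T, n))
        uid = f"{session.subject}_{session.session_id}_u{i:03d}"
        trains.append(SpikeTrain(unit_id=uid, subject=session.subject,
                                 session_id=session.session_id, sex=session.sex,
                                 treatment=session.treatment, times=times, t_stop=T))
        truth_rows.append((uid, session.subject, session.sex, session.treatment,
                           locked, pref, truth.at[i, "press_pref"], base))
    manifest = pd.DataFrame(truth_rows, columns=[
        "unit_id", "subject", "sex", "treatment", "is_task_locked",
        "cue_pref", "press_pref", "baseline_rate_hz"])
    return trains, manifest


# Per-cell condition overrides for the 2x2 (sex x treatment) cohort design.
# Behavioral values follow the group-level outcome mixes and latency medians
# the analyses are meant to recover: vehicle females initiate ~144 trials with
# ~8% omissions and a 0.62 s median decision time, propranolol females drop to
# ~53 initiations with ~29% omissions and 1.19 s decisions, etc.  Baseline
# firing is ~3.4 Hz (F) vs ~5.25 Hz (M); propranolol shifts female baselines
# upward and disinhibits nonpreferred responses (fully in females, partially
# in males).
CELL_OVERRIDES: dict[tuple[str, str], dict] = {
    ("F", "vehicle"): dict(
        treatment="vehicle", init_delay_mean=8.3, p_premature=0.20, p_omit=0.0773,
        decision_time_median=0.6185, press_latency_median=0.93,
        iti_press_rate=0.04, baseline_log_mean=float(np.log(3.40)) - 0.18),
    ("F", "propranolol"): dict(
        treatment="propranolol", init_delay_mean=32.8, p_premature=0.20, p_omit=0.2906,
        decision_time_median=1.189, press_latency_median=1.30,
        iti_press_rate=0.10, baseline_log_mean=float(np.log(3.40)) - 0.18,
        treatment_rate_shift=1.11, treatment_disinhibition=1.0),
    ("M", "vehicle"): dict(
        treatment="vehicle", init_delay_mean=11.4, p_premature=0.15, p_omit=0.0413,
        decision_time_median=0.4345, press_latency_median=0.71,
        iti_press_rate=0.04, baseline_log_mean=float(np.log(5.25)) - 0.18),
    ("M", "propranolol"): dict(
        treatment="propranolol", init_delay_mean=21.3, p_premature=0.15, p_omit=0.0657,
        decision_time_median=0.6761, press_latency_median=0.80,
        iti_press_rate=0.10, baseline_log_mean=float(np.log(5.25)) - 0.18,
        treatment_rate_shift=0.13, treatment_disinhibition=0.8),
}


@dataclass
class Cohort:
    """Generated 2x2 cohort: sessions, spike trains, and ground-truth manifest."""

    sessions: list[SessionEvents]
    spikes: list[SpikeTrain]
    manifest: pd.DataFrame

    def session_for(self, subject: str, session_id: str) -> SessionEvents:
        for s in self.sessions:
            if s.subject == subject and s.session_id == session_id:
                return s
        raise KeyError((subject, session_id))


def generate_cohort(config: GeneratorConfig,
                    cell_overrides: dict[tuple[str, str], dict] | None = None) -> Cohort:
    """Generate a full 2x2 (female/male x vehicle/propranolol) cohort.

    Each cell gets ``n_subjects_per_group`` subjects; per-cell parameter
    overrides default to :data:`CELL_OVERRIDES`.  Subject ids are unique
    across cells and every unit appears exactly once in the manifest.
    """
    config.validate()
    if cell_overrides is None:
        cell_overrides = CELL_OVERRIDES
    ss = np.random.SeedSequence(config.seed)
    cells = list(cell_overrides.keys())
    n_subj = config.n_subjects_per_group
    subject_seeds = ss.spawn(len(cells) * n_subj)
    sessions, all_spikes, manifests = [], [], []
    seen_subjects = set()
    for ci, (sex, treatment) in enumerate(cells):
        cell_cfg = config.with_overrides(**cell_overrides[(sex, treatment)])
        for j in range(n_subj):
            subject = f"{sex.lower()}{treatment[:4]}{j:02d}"
            if subject in seen_subjects:
                raise GenerationError(f"duplicate subject id {subject!r}")
            seen_subjects.add(subject)
            s_seed, u_seed = subject_seeds[ci * n_subj + j].spawn(2)
            session = generate_session(cell_cfg, subject_id=subject, seed=s_seed, sex=sex)
            trains, manifest = generate_unit_population(cell_cfg, session, seed=u_seed)
            sessions.append(session)
            all_spikes.extend(trains)
            manifests.append(manifest)
    return Cohort(sessions=sessions, spikes=all_spikes,
                  manifest=pd.concat(manifests, ignore_index=True))
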