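"""Task-relevance screening and side-preference classification of single units.

A unit is *task-locked* when its spike counts in at least one of four 1 s
task epochs — [0, +1) s after the left cue, after the right cue, and
[-1, 0) s before the left press and right press — differ from paired 1 s
mid-ITI baseline counts by a paired t-test, Bonferroni-corrected over the
four epochs.  Units from sessions with fewer than 20 trials are excluded.
Side preference is summarized by the side preference index
SPI = (L - R) / (L + R) on summed epoch counts: positive = left-preferring,
negative = right-preferring.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats as _stats
from .synthetic import SessionEvents, SpikeTrain

__all__ = [
    "EpochSpec",
    "UnitScreenResult",
    "TASK_EPOCHS",
    "MIN_TRIALS",
    "epoch_counts",
    "screen_task_relevance",
    "side_preference_index",
    "classify_preferences",
    "unit_summary_stats",
    "screen_units",
    "proportion_pct",
]

log = logging.getLogger(__name__)

MIN_TRIALS = 20  # session inclusion rule


@dataclass(frozen=True)
class EpochSpec:
    """A 1 s counting epoch anchored to a task event."""

    alignment: str  # cue_left | cue_right | press_left | press_right | iti_mid
    window: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.window
        if not math.isclose(hi - lo, 1.0, abs_tol=1e-9):
            raise ValueError("screening epochs are 1.0 s long")


TASK_EPOCHS = (
    EpochSpec("cue_left", (0.0, 1.0)),
    EpochSpec("cue_right", (0.0, 1.0)),
    EpochSpec("press_left", (-1.0, 0.0)),
    EpochSpec("press_right", (-1.0, 0.0)),
)
ITI_EPOCH = EpochSpec("iti_mid", (-0.5, 0.5))


@dataclass(frozen=True)
class UnitScreenResult:
    """Screening outcome for one unit."""

    unit_id: str
    subject: str
    sex: str
    treatment: str
    p_cue_left: float
    p_cue_right: float
    p_press_left: float
    p_press_right: float
    p_adj_cue_left: float
    p_adj_cue_right: float
    p_adj_press_left: float
    p_adj_press_right: float
    task_locked: bool
    spi_cue: float
    spi_press: float
    cue_pref: str
    press_pref: str
    mean_rate_hz: float


def _epoch_anchor_trials(events: SessionEvents, spec: EpochSpec) -> tuple[np.ndarray, np.ndarray]:
    """Trial indices and anchor times for an epoch.

    Cue epochs use every cued trial of that side (omissions included); press
    epochs use completed trials of that side; the ITI epoch anchors at the
    middle of the ITI that follows each trial.
    """
    t = events.trials
    if spec.alignment.startswith("cue_"):
        side = spec.alignment.removeprefix("cue_")
        m = (t["cue_side"] == side) & t["t_cue_s"].notna()
        return t.index[m].to_numpy(), t.loc[m, "t_cue_s"].to_numpy(dtype=float)
    if spec.alignment.startswith("press_"):
        side = spec.alignment.removeprefix("press_")
        m = (t["press_side"] == side) & t["t_press_s"].notna()
        return t.index[m].to_numpy(), t.loc[m, "t_press_s"].to_numpy(dtype=float)
    if spec.alignment == "iti_mid":
        mids = events.trial_end_times() + events.iti_durations() / 2.0
        return t.index.to_numpy(), mids
    raise ValueError(f"unknown epoch alignment {spec.alignment!r}")


def epoch_counts(spikes: SpikeTrain, events: SessionEvents,
                 spec: EpochSpec) -> pd.Series:
    """Spike counts per qualifying trial in the epoch's half-open window.

    The counting interval is [anchor + lo, anchor + hi): a spike exactly on
    the end boundary is excluded.  Indexed by trial index.  Sessions below
    the trial-count inclusion rule raise no error here; exclusion is handled
    by :func:`screen_task_relevance`.
    """
    idx, anchors = _epoch_anchor_trials(events, spec)
    lo, hi = spec.window
    starts = anchors + lo
    stops = anchors + hi
    counts = (np.searchsorted(spikes.times, stops, side="left")
              - np.searchsorted(spikes.times, starts, side="left"))
    return pd.Series(counts, index=idx, name=spec.alignment)


def side_preference_index(count_left_total: float, count_right_total: float) -> float:
    """SPI = (L - R) / (L + R); NaN when both totals are zero."""
    if count_left_total < 0 or count_right_total < 0:
        raise ValueError("spike count totals must be nonnegative")
    total = count_left_total + count_right_total
    if total == 0:
        return math.nan
    return (count_left_total - count_right_total) / total


def _pref_label(spi: float) -> str:
    if math.isnan(spi) or spi == 0.0:
        return "none"
    return "left" if spi > 0 else "right"


def screen_task_relevance(spikes: SpikeTrain, events: SessionEvents,
                          alpha: float = 0.05) -> UnitScreenResult | None:
    """Run the four-epoch paired screening on one unit.

    Each task epoch's counts are paired with the mid-ITI counts of the same
    trials; Bonferroni correction is applied over the family of four epochs.
    Epochs with fewer than two paired trials, or with identically zero
    differences, are recorded as unavailable (NaN).  Returns ``None`` (with a
    logged reason) for units from sessions below ``MIN_TRIALS`` trials.
    """
    if events.n_trials < MIN_TRIALS:
        log.info("unit %s excluded: session has %d < %d trials",
                 spikes.unit_id, events.n_trials, MIN_TRIALS)
        return None
    iti = epoch_counts(spikes, events, ITI_EPOCH)
    raw_p = []
    epoch_totals: dict[str, float] = {}
    for spec in TASK_EPOCHS:
        task = epoch_counts(spikes, events, spec)
        epoch_totals[spec.alignment] = float(task.sum())
        paired = pd.concat([task, iti.reindex(task.index)], axis=1).dropna()
        if len(paired) < 2:
            raw_p.append(math.nan)
            continue
        a = paired.iloc[:, 0].to_numpy(dtype=float)
        b = paired.iloc[:, 1].to_numpy(dtype=float)
        if np.all(a == b):
            raw_p.append(math.nan)  # zero-variance differences: test unavailable
            continue
        raw_p.append(float(sps.ttest_rel(a, b).pvalue))
    adj = _stats.bonferroni_adjust(raw_p, m=len(TASK_EPOCHS))
    task_locked = bool(np.nanmin(adj) < alpha) if np.isfinite(adj).any() else False
    spi_cue = side_preference_index(epoch_totals["cue_left"], epoch_totals["cue_right"])
    spi_press = side_preference_index(epoch_totals["press_left"], epoch_totals["press_right"])
    return UnitScreenResult(
        unit_id=spikes.unit_id, subject=spikes.subject, sex=spikes.sex,
        treatment=spikes.treatment,
        p_cue_left=raw_p[0], p_cue_right=raw_p[1],
        p_press_left=raw_p[2], p_press_right=raw_p[3],
        p_adj_cue_left=float(adj[0]), p_adj_cue_right=float(adj[1]),
        p_adj_press_left=float(adj[2]), p_adj_press_right=float(adj[3]),
        task_locked=task_locked, spi_cue=spi_cue, spi_press=spi_press,
        cue_pref=_pref_label(spi_cue), press_pref=_pref_label(spi_press),
        mean_rate_hz=spikes.mean_rate,
    )


def screen_units(units: list[SpikeTrain], sessions: dict[tuple[str, str], SessionEvents],
                 alpha: float = 0.05) -> pd.DataFrame:
    """Screen a list of units against their sessions; excluded units are dropped."""
    rows = []
    for u in units:
        ev = sessions[(u.subject, u.session_id)]
        res = screen_task_relevance(u, ev, alpha=alpha)
        if res is not None:
            rows.append(asdict(res))
    return pd.DataFrame(rows)


def proportion_pct(count: int, total: int) -> float:
    """A count as a percentage of a total (e.g. task-locked units of all units)."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError("count must lie in [0, total]")
    return 100.0 * count / total


def classify_preferences(results: pd.DataFrame) -> dict[str, pd.DataFrame | float]:
    """Preference labels and bookkeeping tables for a screened population.

    Returns per-(sex, treatment) counts of screened and task-locked units,
    left/right preference counts at cue and press (task-locked units only),
    and the cue<->press consistency fraction (units whose defined cue and
    press preferences agree).
    """
    if len(results) == 0:
        empty = pd.DataFrame()
        return {"group_counts": empty, "preference_counts": empty,
                "consistency_fraction": math.nan}
    grp = results.groupby(["sex", "treatment"], observed=True)
    group_counts = grp.agg(
        n_units=("unit_id", "size"),
        n_task_locked=("task_locked", "sum"),
    ).reset_index()
    group_counts["pct_task_locked"] = [
        proportion_pct(int(k), int(n))
        for k, n in zip(group_counts["n_task_locked"], group_counts["n_units"])]

    locked = results[results["task_locked"]]
    pref_rows = []
    for (sex, trt), g in locked.groupby(["sex", "treatment"], observed=True):
        for align in ("cue", "press"):
            col = f"{align}_pref"
            pref_rows.append((sex, trt, align,
                              int((g[col] == "left").sum()),
                              int((g[col] == "right").sum()),
                              int((g[col] == "none").sum())))
    preference_counts = pd.DataFrame(
        pref_rows, columns=["sex", "treatment", "alignment", "n_left", "n_right", "n_none"])

    defined = locked[(locked["cue_pref"] != "none") & (locked["press_pref"] != "none")]
    consistency = (float((defined["cue_pref"] == defined["press_pref"]).mean())
                   if len(defined) else math.nan)
    return {"group_counts": group_counts, "preference_counts": preference_counts,
            "consistency_fraction": consistency}


def unit_summary_stats(results: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Basal firing-rate and proportion comparisons across treatment, per sex.

    Per (sex, treatment): mean rate +/- SEM.  Per sex: a Mann–Whitney test on
    the firing-rate distributions (vehicle vs propranolol) and a Fisher exact
    test on the task-locked 2x2 proportion table.  Comparisons involving an
    empty group are reported NaN.
    """
    if len(results) == 0:
        raise ValueError("no screened units")
    desc = results.groupby(["sex", "treatment"], observed=True)["mean_rate_hz"].agg(
        mean="mean", sem="sem", n="size").reset_index()
    rows = []
    for sex, g in results.groupby("sex", observed=True):
        veh = g[g["treatment"] == "vehicle"]
        pro = g[g["treatment"] == "propranolol"]
        if len(veh) and len(pro):
            mw = _stats.rank_sum_test(veh["mean_rate_hz"], pro["mean_rate_hz"])
            table = [[int(veh["task_locked"].sum()), int((~veh["task_locked"]).sum())],
                     [int(pro["task_locked"].sum()), int((~pro["task_locked"]).sum())]]
            fe = _stats.fisher_exact_2x2(table)
            rows.append((sex, "rate_distribution", mw.statistic, mw.p))
            rows.append((sex, "task_locked_proportion", fe.statistic, fe.p))
        else:
            rows.append((sex, "rate_distribution", math.nan, math.nan))
            rows.append((sex, "task_locked_proportion", math.nan, math.nan))
    comparisons = pd.DataFrame(rows, columns=["sex", "comparison", "statistic", "p"])
    return {"rate_descriptives": desc, "comparisons": comparisons}
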