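"""Session-normalized population peri-event time histograms (PETHs).

Each unit's firing is binned at 100 ms across the whole session; the session
mean and SD of the binned rate define a z-transform that is then applied to
event-aligned activity.  For every task-locked unit with a defined side
preference the analysis produces two rows: the mean z-scored trace on
preferred-side trials and on nonpreferred-side trials.  Separation of the
two population traces is tested per time bin with paired t-tests across
units, corrected over all bins in the window with the Holm–Sidak step-down
procedure; the headline quantity is the longest contiguous run of
significant bins.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats as _stats
from .synthetic import SessionEvents, SpikeTrain

__all__ = [
    "SessionZScore",
    "PopulationPETH",
    "SeparationProfile",
    "ALIGNMENT_WINDOWS",
    "session_zscore",
    "build_population_peth",
    "separation_profile",
    "event_latency_histograms",
    "longest_true_run",
]

log = logging.getLogger(__name__)

DEFAULT_BIN = 0.1
ALIGNMENT_WINDOWS = {"cue": (-1.0, 3.0), "press": (-3.0, 1.0)}


@dataclass(frozen=True)
class SessionZScore:
    """Whole-session normalization for one unit: z(r) = (r - mu) / sigma."""

    mu: float     # mean binned rate, Hz
    sigma: float  # SD of binned rate, Hz
    bin_width: float

    @property
    def degenerate(self) -> bool:
        return not (self.sigma > 0)

    def z(self, rates: np.ndarray) -> np.ndarray:
        if self.degenerate:
            raise ValueError("sigma is zero; unit has no rate variability to normalize by")
        return (np.asarray(rates, dtype=float) - self.mu) / self.sigma


def session_zscore(spikes: SpikeTrain, span: tuple[float, float] | None = None,
                   bin_width: float = DEFAULT_BIN) -> SessionZScore:
    """Compute a unit's session mean/SD of binned firing rate.

    ``span`` defaults to the full recording [0, t_stop); statistics cover
    every bin, task and ITI alike.
    """
    if span is None:
        span = (0.0, spikes.t_stop)
    t0, t1 = span
    if not t1 > t0:
        raise ValueError("session span must have positive length")
    n_bins = int(round((t1 - t0) / bin_width))
    edges = t0 + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(spikes.times, bins=edges)
    rates = counts / bin_width
    return SessionZScore(mu=float(rates.mean()), sigma=float(rates.std(ddof=0)),
                         bin_width=bin_width)


@dataclass
class PopulationPETH:
    """Preferred / nonpreferred z-score matrices (units x bins)."""

    alignment: str
    window: tuple[float, float]
    bin_width: float
    z_preferred: np.ndarray
    z_nonpreferred: np.ndarray
    unit_ids: list[str]
    norms: list[SessionZScore]

    def __post_init__(self) -> None:
        if self.z_preferred.shape != self.z_nonpreferred.shape:
            raise ValueError("preferred and nonpreferred matrices must share shape")
        lo, hi = self.window
        expected = int(round((hi - lo) / self.bin_width))
        if self.z_preferred.shape[1] != expected:
            raise ValueError("bin count does not match window length / bin width")

    @property
    def bin_centers(self) -> np.ndarray:
        lo, _ = self.window
        n = self.z_preferred.shape[1]
        return lo + self.bin_width * (np.arange(n) + 0.5)

    def long_table(self) -> pd.DataFrame:
        """Plot-ready long table of population mean +/- SEM per condition."""
        rows = []
        for cond, mat in (("preferred", self.z_preferred),
                          ("nonpreferred", self.z_nonpreferred)):
            mean = mat.mean(axis=0)
            sem = mat.std(axis=0, ddof=1) / math.sqrt(mat.shape[0]) if mat.shape[0] > 1 \
                else np.full(mat.shape[1], np.nan)
            for c, m, s in zip(self.bin_centers, mean, sem):
                rows.append((self.alignment, cond, c, m, s))
        return pd.DataFrame(rows, columns=["alignment", "condition", "bin_center_s",
                                           "mean_z", "sem_z"])


def _aligned_mean_rate(spikes: SpikeTrain, anchors: np.ndarray,
                       window: tuple[float, float], bin_width: float) -> np.ndarray:
    """Mean event-aligned binned rate (Hz) across trials."""
    lo, hi = window
    n_bins = int(round((hi - lo) / bin_width))
    rel_edges = lo + bin_width * np.arange(n_bins + 1)
    acc = np.zeros(n_bins)
    for a in anchors:
        counts, _ = np.histogram(spikes.times, bins=a + rel_edges)
        acc += counts
    return acc / (len(anchors) * bin_width)


def _trial_anchors(events: SessionEvents, alignment: str, side: str) -> np.ndarray:
    t = events.trials
    if alignment == "cue":
        m = (t["cue_side"] == side) & t["t_cue_s"].notna()
        return t.loc[m, "t_cue_s"].to_numpy(dtype=float)
    if alignment == "press":
        m = (t["press_side"] == side) & t["t_press_s"].notna()
        return t.loc[m, "t_press_s"].to_numpy(dtype=float)
    raise ValueError(f"unknown alignment {alignment!r}")


def build_population_peth(units: list[tuple[SpikeTrain, SessionEvents, str]],
                          alignment: str = "cue",
                          window: tuple[float, float] | None = None,
                          bin_width: float = DEFAULT_BIN) -> PopulationPETH:
    """Assemble the preferred/nonpreferred population z-PETH.

    ``units`` holds ``(spike_train, session, preferred_side)`` triples —
    preferred side from the cue SPI for cue alignment, the press SPI for
    press alignment.  Cue alignment averages over all cued trials of a side
    (omissions included); press alignment uses completed trials.  Units with
    zero session rate variability or zero trials on either side are excluded
    with a logged reason.
    """
    if window is None:
        window = ALIGNMENT_WINDOWS[alignment]
    pref_rows, nonpref_rows, ids, norms = [], [], [], []
    for spikes, events, pref in units:
        if pref not in ("left", "right"):
            log.info("unit %s excluded from PETH: undefined preference", spikes.unit_id)
            continue
        nonpref = "right" if pref == "left" else "left"
        norm = session_zscore(spikes, bin_width=bin_width)
        if norm.degenerate:
            log.info("unit %s excluded from PETH: zero session rate SD", spikes.unit_id)
            continue
        a_pref = _trial_anchors(events, alignment, pref)
        a_non = _trial_anchors(events, alignment, nonpref)
        if len(a_pref) == 0 or len(a_non) == 0:
            log.info("unit %s excluded from PETH: no trials on one side", spikes.unit_id)
            continue
        pref_rows.append(norm.z(_aligned_mean_rate(spikes, a_pref, window, bin_width)))
        nonpref_rows.append(norm.z(_aligned_mean_rate(spikes, a_non, window, bin_width)))
        ids.append(spikes.unit_id)
        norms.append(norm)
    if not ids:
        raise ValueError("no units eligible for the population PETH")
    return PopulationPETH(alignment=alignment, window=window, bin_width=bin_width,
                          z_preferred=np.vstack(pref_rows),
                          z_nonpreferred=np.vstack(nonpref_rows),
                          unit_ids=ids, norms=norms)


def longest_true_run(mask: np.ndarray) -> int:
    """Length of the longest contiguous run of True values."""
    best = cur = 0
    for v in np.asarray(mask, dtype=bool):
        cur = cur + 1 if v else 0
        best = max(best, cur)
    return best


@dataclass(frozen=True)
class SeparationProfile:
    """Per-bin preferred-vs-nonpreferred inference over a PETH window."""

    bin_centers: np.ndarray
    raw_p: np.ndarray
    adjusted_p: np.ndarray
    significant: np.ndarray
    longest_run_s: float
    total_significant_s: float
    alpha: float

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_center_s": self.bin_centers, "raw_p": self.raw_p,
            "adjusted_p": self.adjusted_p, "significant": self.significant,
        })


def separation_profile(peth: PopulationPETH, alpha: float = 0.05) -> SeparationProfile:
    """Per-bin paired t-tests across units with Holm–Sidak correction.

    The correction family is every bin in the displayed window.  Bins where
    all units show identical preferred/nonpreferred values get p = 1.
    """
    n_units = peth.z_preferred.shape[0]
    if n_units < 2:
        raise ValueError("separation profile needs at least 2 units")
    diffs = peth.z_preferred - peth.z_nonpreferred
    raw = np.ones(diffs.shape[1])
    for b in range(diffs.shape[1]):
        d = diffs[:, b]
        if np.allclose(d.std(ddof=1), 0.0):
            raw[b] = 1.0
            continue
        raw[b] = float(sps.ttest_rel(peth.z_preferred[:, b],
                                     peth.z_nonpreferred[:, b]).pvalue)
    adjusted, reject = _stats.holm_sidak_adjust(raw, alpha=alpha)
    return SeparationProfile(
        bin_centers=peth.bin_centers, raw_p=raw, adjusted_p=adjusted,
        significant=reject,
        longest_run_s=longest_true_run(reject) * peth.bin_width,
        total_significant_s=int(reject.sum()) * peth.bin_width,
        alpha=alpha,
    )


def event_latency_histograms(events: SessionEvents, alignment: str = "cue",
                             window: tuple[float, float] | None = None,
                             ) -> dict[str, np.ndarray]:
    """Relative times of well exit and lever press within the analysis window.

    Cue alignment: well-exit offsets are exactly the decision times, press
    offsets the reaction times.  Press alignment: presses sit at 0 and well
    exits at minus the press latency.
    """
    if window is None:
        window = ALIGNMENT_WINDOWS[alignment]
    lo, hi = window
    t = events.cued_trials()
    if alignment == "cue":
        anchor = t["t_cue_s"]
    elif alignment == "press":
        anchor = t["t_press_s"]
    else:
        raise ValueError(f"unknown alignment {alignment!r}")
    out = {}
    for name, col in (("well_exit", "t_well_exit_s"), ("press", "t_press_s")):
        rel = (t[col] - anchor).dropna().to_numpy(dtype=float)
        out[name] = rel[(rel >= lo) & (rel < hi)]
    return out
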