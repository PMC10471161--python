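"""Pseudo-population decoding of cue identity with a label-shuffle null.

Units recorded in different sessions are combined into pseudo-populations:
for each resample, ``n_neurons`` units are drawn without replacement and each
contributes independently sampled left- and right-cue trials, so pseudo-trial
k pairs unrelated real trials across units.  Spike counts are taken in
150 ms bins over a window around cue onset, and an independent linear
maximum-margin classifier (linear SVM, unit cost) is trained per bin on
standardized counts, then scored on held-out pseudo-trials.  Chance is
exactly 0.5 by balanced design; per-bin significance comes from a
permutation null in which cue labels are shuffled and the whole decoding
analysis repeated (default 50 iterations), with the add-one p-value
estimator p = (1 + #null >= observed) / (1 + #null).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import LinearSVC

from .synthetic import SessionEvents, SpikeTrain

__all__ = [
    "DecodingWindow",
    "UnitCueCounts",
    "PseudoPopulation",
    "DecodingResult",
    "CapacityError",
    "bin_unit_cue_trials",
    "build_pseudopopulation",
    "decode_timecourse",
    "permutation_significance",
    "decoding_analysis",
]

log = logging.getLogger(__name__)

DEFAULT_WINDOW = (-0.6, 1.5)
DEFAULT_BIN = 0.15
SIDES = ("left", "right")


class CapacityError(ValueError):
    """Not enough units or trials to build the requested pseudo-population."""


@dataclass(frozen=True)
class DecodingWindow:
    window: tuple[float, float] = DEFAULT_WINDOW
    bin_width: float = DEFAULT_BIN

    @property
    def n_bins(self) -> int:
        lo, hi = self.window
        return int(round((hi - lo) / self.bin_width))

    @property
    def edges(self) -> np.ndarray:
        lo, _ = self.window
        return lo + self.bin_width * np.arange(self.n_bins + 1)

    @property
    def centers(self) -> np.ndarray:
        return self.edges[:-1] + self.bin_width / 2.0


@dataclass
class UnitCueCounts:
    """One unit's cue-aligned binned counts, split by cue side.

    ``counts[side]`` has shape (n_trials_of_side, n_bins).
    """

    unit_id: str
    counts: dict[str, np.ndarray]
    win: DecodingWindow


def bin_unit_cue_trials(spikes: SpikeTrain, events: SessionEvents,
                        win: DecodingWindow = DecodingWindow()) -> UnitCueCounts:
    """Bin a unit's spikes around every cued trial, split by cue side."""
    t = events.cued_trials()
    out = {}
    for side in SIDES:
        anchors = t.loc[t["cue_side"] == side, "t_cue_s"].to_numpy(dtype=float)
        mat = np.empty((len(anchors), win.n_bins), dtype=int)
        for i, a in enumerate(anchors):
            mat[i], _ = np.histogram(spikes.times, bins=a + win.edges)
        out[side] = mat
    return UnitCueCounts(unit_id=spikes.unit_id, counts=out, win=win)


@dataclass
class PseudoPopulation:
    """Train/test pseudo-trial tensors (units x pseudo-trials x bins)."""

    tensor: np.ndarray
    labels: np.ndarray        # 0 = left, 1 = right, per training pseudo-trial
    test_tensor: np.ndarray
    test_labels: np.ndarray
    bin_edges: np.ndarray
    unit_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for tens, lab in ((self.tensor, self.labels), (self.test_tensor, self.test_labels)):
            if tens.shape[1] != len(lab):
                raise ValueError("label count must match pseudo-trial count")
            vals, counts = np.unique(lab, return_counts=True)
            if len(vals) == 2 and counts[0] != counts[1]:
                raise ValueError("pseudo-trial labels must be balanced")


def build_pseudopopulation(unit_counts: list[UnitCueCounts],
                           n_neurons: int = 10, n_trials_per_cue: int = 10,
                           n_test_per_cue: int | None = None,
                           rng: np.random.Generator | None = None,
                           shuffle_labels: bool = False) -> PseudoPopulation:
    """Sample one pseudo-population: units and, per unit, trials, without replacement.

    Each sampled unit needs at least ``n_trials_per_cue + 1`` trials per cue
    side: ``n_trials_per_cue`` train the classifier and the remainder (capped
    at ``n_test_per_cue``, default ``n_trials_per_cue``) are held out for
    testing.  With ``shuffle_labels`` the cue labels of each unit's sampled
    trials are permuted, preserving marginal rates while destroying the
    label-activity association.
    """
    rng = rng or np.random.default_rng()
    if n_test_per_cue is None:
        n_test_per_cue = n_trials_per_cue
    need = n_trials_per_cue + 1
    eligible = [u for u in unit_counts
                if all(u.counts[s].shape[0] >= need for s in SIDES)]
    if len(eligible) < n_neurons:
        raise CapacityError(
            f"need {n_neurons} units with >= {need} trials per cue side, "
            f"have {len(eligible)} of {len(unit_counts)}")
    unit_idx = rng.choice(len(eligible), size=n_neurons, replace=False)
    units = [eligible[i] for i in unit_idx]
    n_test = min(n_test_per_cue,
                 min(u.counts[s].shape[0] - n_trials_per_cue for u in units for s in SIDES))
    win = units[0].win
    n_bins = win.n_bins
    train = np.empty((n_neurons, 2 * n_trials_per_cue, n_bins))
    test = np.empty((n_neurons, 2 * n_test, n_bins))
    for ui, u in enumerate(units):
        per_unit_rows_train, per_unit_rows_test = [], []
        for side in SIDES:
            avail = u.counts[side]
            pick = rng.choice(avail.shape[0], size=n_trials_per_cue + n_test, replace=False)
            per_unit_rows_train.append(avail[pick[:n_trials_per_cue]])
            per_unit_rows_test.append(avail[pick[n_trials_per_cue:]])
        tr = np.concatenate(per_unit_rows_train, axis=0)
        te = np.concatenate(per_unit_rows_test, axis=0)
        if shuffle_labels:
            tr = tr[rng.permutation(tr.shape[0])]
            te = te[rng.permutation(te.shape[0])]
        train[ui] = tr
        test[ui] = te
    labels = np.repeat([0, 1], n_trials_per_cue)
    test_labels = np.repeat([0, 1], n_test)
    return PseudoPopulation(tensor=train, labels=labels, test_tensor=test,
                            test_labels=test_labels, bin_edges=win.edges,
                            unit_ids=[u.unit_id for u in units])


def _decode_bins(pop: PseudoPopulation) -> np.ndarray:
    """Per-bin held-out accuracy of a linear SVM on standardized counts."""
    n_bins = pop.tensor.shape[2]
    acc = np.empty(n_bins)
    for b in range(n_bins):
        X = pop.tensor[:, :, b].T
        Xt = pop.test_tensor[:, :, b].T
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Xs = (X - mu) / sd
        Xts = (Xt - mu) / sd
        if np.all(Xs == Xs[0]):
            acc[b] = 0.5  # constant features: majority class on a balanced design
            continue
        clf = LinearSVC(C=1.0, max_iter=10000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            clf.fit(Xs, pop.labels)
        acc[b] = float(np.mean(clf.predict(Xts) == pop.test_labels))
    return acc


def decode_timecourse(unit_counts: list[UnitCueCounts], n_resamples: int = 50,
                      seed: int | np.random.SeedSequence | None = None,
                      n_neurons: int = 10, n_trials_per_cue: int = 10,
                      shuffle_labels: bool = False) -> np.ndarray:
    """Per-bin decoding accuracy averaged over freshly sampled pseudo-populations."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    acc = np.zeros(unit_counts[0].win.n_bins)
    for _ in range(n_resamples):
        pop = build_pseudopopulation(unit_counts, n_neurons=n_neurons,
                                     n_trials_per_cue=n_trials_per_cue,
                                     rng=rng, shuffle_labels=shuffle_labels)
        acc += _decode_bins(pop)
    return acc / n_resamples


@dataclass
class DecodingResult:
    """Observed accuracy time course with its permutation null."""

    bin_centers: np.ndarray
    accuracy: np.ndarray
    null: np.ndarray          # (n_shuffles, n_bins)
    p: np.ndarray
    significant: np.ndarray
    onset_bin: int | None     # first significant bin index, None if never
    alpha: float
    settings: dict

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_center_s": self.bin_centers,
            "accuracy": self.accuracy,
            "null_mean": self.null.mean(axis=0),
            "null_q95": np.quantile(self.null, 0.95, axis=0),
            "p": self.p,
            "significant": self.significant,
        })


def permutation_significance(unit_counts: list[UnitCueCounts],
                             observed: np.ndarray, n_shuffles: int = 50,
                             alpha: float = 0.05,
                             seed: int | np.random.SeedSequence | None = None,
                             n_resamples: int = 50, n_neurons: int = 10,
                             n_trials_per_cue: int = 10) -> DecodingResult:
    """Label-shuffle permutation test of a decoding time course.

    Each shuffle permutes cue labels and repeats the full resampled decode;
    per-bin p = (1 + #null >= observed) / (1 + n_shuffles).
    """
    if n_shuffles < 20:
        log.warning("n_shuffles=%d gives p-value resolution of only %.3f",
                    n_shuffles, 1.0 / (n_shuffles + 1))
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    shuffle_seeds = ss.spawn(n_shuffles)
    null = np.empty((n_shuffles, observed.shape[0]))
    for i in range(n_shuffles):
        null[i] = decode_timecourse(unit_counts, n_resamples=n_resamples,
                                    seed=shuffle_seeds[i], n_neurons=n_neurons,
                                    n_trials_per_cue=n_trials_per_cue,
                                    shuffle_labels=True)
    p = (1.0 + (null >= observed[None, :]).sum(axis=0)) / (1.0 + n_shuffles)
    sig = p < alpha
    onset = int(np.argmax(sig)) if sig.any() else None
    win = unit_counts[0].win
    return DecodingResult(
        bin_centers=win.centers, accuracy=observed, null=null, p=p,
        significant=sig, onset_bin=onset, alpha=alpha,
        settings=dict(n_shuffles=n_shuffles, n_resamples=n_resamples,
                      n_neurons=n_neurons, n_trials_per_cue=n_trials_per_cue,
                      window=win.window, bin_width=win.bin_width, alpha=alpha))


def decoding_analysis(units: list[SpikeTrain],
                      sessions: dict[tuple[str, str], SessionEvents],
                      win: DecodingWindow = DecodingWindow(),
                      n_neurons: int = 10, n_trials_per_cue: int = 10,
                      n_resamples: int = 50, n_shuffles: int = 50,
                      alpha: float = 0.05,
                      seed: int | np.random.SeedSequence | None = None) -> DecodingResult:
    """End-to-end decode: bin units, compute the time course, test vs the null."""
    counts = [bin_unit_cue_trials(u, sessions[(u.subject, u.session_id)], win)
              for u in units]
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    obs_seed, null_seed = ss.spawn(2)
    observed = decode_timecourse(counts, n_resamples=n_resamples, seed=obs_seed,
                                 n_neurons=n_neurons, n_trials_per_cue=n_trials_per_cue)
    return permutation_significance(counts, observed, n_shuffles=n_shuffles,
                                    alpha=alpha, seed=null_seed,
                                    n_resamples=n_resamples, n_neurons=n_neurons,
                                    n_trials_per_cue=n_trials_per_cue)
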