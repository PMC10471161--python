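"""Session-level 2AFC behavioral metrics and group comparisons.

Metrics per session: trials initiated, percent premature, overall accuracy
(correct / cued, so omissions count against accuracy), percent omissions,
lever press index (ITI presses / total presses — an index near 1 means the
animal pressed mostly outside trials), and median decision / reaction times.
Group-level inference (2x2 sex-by-treatment ANOVA with pairwise post hocs) is
delegated to statsmodels; distribution-spread contrasts use the
Brown–Forsythe test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import stats as _stats
from .synthetic import SessionEvents

__all__ = [
    "BehaviorSummary",
    "summarize_session",
    "latency_distributions",
    "percent_reduction",
    "group_behavior_table",
]


@dataclass(frozen=True)
class BehaviorSummary:
    """Per-session behavioral measures; NaN marks undefined quantities."""

    subject: str
    sex: str
    treatment: str
    session_id: str
    trials_initiated: int
    pct_premature: float
    accuracy: float
    pct_omission: float
    pct_incorrect: float
    lever_press_index: float
    median_decision_time: float
    median_reaction_time: float


def summarize_session(events: SessionEvents) -> BehaviorSummary:
    """Collapse one session's event table into a :class:`BehaviorSummary`.

    Percentages of cued trials (accuracy, omission, incorrect) are NaN when no
    trial reached cue presentation; they are never silently reported as zero.
    """
    trials = events.trials
    if len(trials) == 0:
        raise ValueError("session has no trials")
    outcome = trials["outcome"]
    initiated = len(trials)
    n_prem = int((outcome == "premature").sum())
    cued = initiated - n_prem
    n_correct = int((outcome == "correct").sum())
    n_incorrect = int((outcome == "incorrect").sum())
    n_omit = int((outcome == "omission").sum())
    if cued > 0:
        accuracy = 100.0 * n_correct / cued
        pct_omit = 100.0 * n_omit / cued
        pct_incorrect = 100.0 * n_incorrect / cued
    else:
        accuracy = pct_omit = pct_incorrect = math.nan
    in_trial_presses = n_correct + n_incorrect  # one press ends each completed trial
    iti_presses = int(trials["iti_press_count"].sum())
    total = in_trial_presses + iti_presses
    lpi = iti_presses / total if total > 0 else math.nan
    decision, reaction = latency_distributions(events)
    return BehaviorSummary(
        subject=events.subject, sex=events.sex, treatment=events.treatment,
        session_id=events.session_id,
        trials_initiated=initiated,
        pct_premature=100.0 * n_prem / initiated,
        accuracy=accuracy, pct_omission=pct_omit, pct_incorrect=pct_incorrect,
        lever_press_index=lpi,
        median_decision_time=float(np.median(decision)) if decision.size else math.nan,
        median_reaction_time=float(np.median(reaction)) if reaction.size else math.nan,
    )


def latency_distributions(events: SessionEvents) -> tuple[np.ndarray, np.ndarray]:
    """Decision times (cue -> well exit; every cued trial, omissions included)
    and reaction times (cue -> lever press; completed trials only)."""
    cued = events.cued_trials()
    decision = (cued["t_well_exit_s"] - cued["t_cue_s"]).dropna().to_numpy(dtype=float)
    pressed = cued.dropna(subset=["t_press_s"])
    reaction = (pressed["t_press_s"] - pressed["t_cue_s"]).to_numpy(dtype=float)
    return decision, reaction


def percent_reduction(before: float, after: float) -> float:
    """Percent decrease from ``before`` to ``after`` (positive = reduction)."""
    if before == 0:
        raise ValueError("baseline value is zero; percent reduction undefined")
    return 100.0 * (before - after) / before


_METRICS = ["trials_initiated", "pct_premature", "accuracy", "pct_omission",
            "lever_press_index", "median_decision_time", "median_reaction_time"]


def summaries_frame(summaries: list[BehaviorSummary]) -> pd.DataFrame:
    return pd.DataFrame([asdict(s) for s in summaries])


def group_behavior_table(summaries: list[BehaviorSummary],
                         metrics: list[str] | None = None) -> dict[str, pd.DataFrame]:
    """Descriptives and sex-by-treatment inference for each behavioral metric.

    Returns ``{"descriptives": ..., "effects": ...}``.  Descriptives give
    mean, SEM and n per (sex, treatment) cell.  Effects hold the two-way ANOVA
    main effects and interaction plus Sidak-adjusted within-sex treatment post
    hocs; cells with n < 2 mark the metric's inferential entries NaN rather
    than fabricating them.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = summaries_frame(summaries)
    if df[["sex", "treatment"]].drop_duplicates().shape[0] < 2:
        raise ValueError("need at least two (sex, treatment) groups")
    metrics = metrics or _METRICS

    desc_rows, eff_rows = [], []
    for metric in metrics:
        sub = df[["sex", "treatment", metric]].rename(columns={metric: "y"}).dropna()
        cells = sub.groupby(["sex", "treatment"], observed=True)["y"]
        for (sex, trt), vals in cells:
            desc_rows.append((metric, sex, trt, vals.mean(),
                              vals.sem() if len(vals) > 1 else math.nan, len(vals)))
        counts = cells.size()
        if len(counts) < 2 or (counts < 2).any() or sub["sex"].nunique() < 2 \
                or sub["treatment"].nunique() < 2:
            for eff in ("sex", "treatment", "sex:treatment"):
                eff_rows.append((metric, eff, math.nan, math.nan, math.nan))
            continue
        model = ols("y ~ C(sex) * C(treatment)", data=sub).fit()
        table = sm.stats.anova_lm(model, typ=2)
        label = {"C(sex)": "sex", "C(treatment)": "treatment",
                 "C(sex):C(treatment)": "sex:treatment"}
        for row_name, eff in label.items():
            eff_rows.append((metric, eff, float(table.loc[row_name, "F"]),
                             float(table.loc[row_name, "PR(>F)"]), math.nan))
        # within-sex treatment post hocs, Sidak-adjusted over the two sexes
        from scipy import stats as sps
        posthoc = []
        for sex in sorted(sub["sex"].unique()):
            a = sub[(sub["sex"] == sex) & (sub["treatment"] == "vehicle")]["y"]
            b = sub[(sub["sex"] == sex) & (sub["treatment"] == "propranolol")]["y"]
            if len(a) >= 2 and len(b) >= 2:
                t, p = sps.ttest_ind(a, b)
                posthoc.append((sex, float(t), float(p)))
        m = len(posthoc)
        for sex, t, p in posthoc:
            p_adj = 1.0 - (1.0 - p) ** m
            eff_rows.append((metric, f"posthoc[{sex}]", t, p, min(1.0, p_adj)))
    descriptives = pd.DataFrame(
        desc_rows, columns=["metric", "sex", "treatment", "mean", "sem", "n"])
    effects = pd.DataFrame(
        eff_rows, columns=["metric", "effect", "statistic", "p", "adjusted_p"])
    return {"descriptives": descriptives, "effects": effects}


def compare_latency_spread(groups: dict[str, np.ndarray]) -> _stats.TestResult:
    """Brown–Forsythe spread comparison across named latency samples."""
    return _stats.robust_spread_test([np.asarray(v) for v in groups.values()])
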