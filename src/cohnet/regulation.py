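"""Feedback-signal computation, Learner classification and supporting stats.

The feedback signal of the neurofeedback loop is the %BOLD signal change of
the target ROI minus that of the control ROI (UNR), averaged over the
regulation samples of a trial. A subject is a Learner for a condition when
the per-trial feedback difference has the condition's sign in at least 4 of
the 6 training trials and the signed modulation at trial 6 exceeds that at
trial 1; everyone else is a non-Learner.

Supporting statistics: paired t-tests of target-vs-UNR regulation, and
one-way ANOVAs of pain intensity/unpleasantness ratings by Learner status
per condition. Both are computed from their sums-of-squares definitions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import f as _f_dist
from scipy.stats import t as _t_dist

from .cohort import (
    CONTROL_ROI,
    AcquisitionConfig,
    Condition,
    RoiTimeSeriesSet,
    TrialDesign,
)
from .errors import DegenerateInputError, InputError

__all__ = [
    "RegulationSummary",
    "LearnerLabel",
    "percent_signal_change",
    "feedback_difference",
    "regulation_summary",
    "classify_learner",
    "paired_t",
    "oneway_anova_f",
    "ratings_comparison",
    "load_reference_ratings",
]

#: Default haemodynamic-delay shift before phase attribution (samples).
DEFAULT_DELAY_SAMPLES = 3


@dataclass(frozen=True)
class RegulationSummary:
    """Per-trial feedback differences (target - UNR, % BOLD) of one subject."""

    subject_id: int
    condition: Condition
    trial_diffs: tuple[float, ...]

    def __post_init__(self) -> None:
        if not all(math.isfinite(d) for d in self.trial_diffs):
            raise InputError("trial differences must be finite")


@dataclass(frozen=True)
class LearnerLabel:
    """Classification outcome with the criteria trace that produced it."""

    subject_id: int
    condition: Condition
    label: str  # "Learner" | "nonLearner"
    sign_correct_count: int
    improved: bool


def percent_signal_change(
    ts: np.ndarray,
    design: TrialDesign,
    delay_samples: int = DEFAULT_DELAY_SAMPLES,
) -> np.ndarray:
    """Series as % change from the trial's non-regulation baseline mean.

    The baseline is the mean over non-regulation samples after shifting
    phase attribution by the haemodynamic delay, so the sluggish onset of a
    regulation block is not counted against the baseline.
    """
    x = np.asarray(ts, float)
    if len(x) != design.n_samples:
        raise InputError("series length does not match the trial design")
    reg = design.regulation_mask(delay_samples)
    baseline_samples = x[~reg]
    if baseline_samples.size == 0:
        raise DegenerateInputError("no non-regulation samples to form a baseline")
    b = baseline_samples.mean()
    if b == 0:
        raise DegenerateInputError("baseline mean is zero; %BOLD undefined")
    return 100.0 * (x - b) / b


def feedback_difference(
    target: np.ndarray,
    unr: np.ndarray,
    design: TrialDesign,
    acq: AcquisitionConfig | None = None,
    delay_samples: int = DEFAULT_DELAY_SAMPLES,
) -> float:
    """Mean regulation-phase %BOLD difference (target - UNR) of one trial."""
    target = np.asarray(target, float)
    unr = np.asarray(unr, float)
    if len(target) != len(unr):
        raise InputError("target and control series lengths differ")
    if acq is not None and len(target) != acq.n_samples:
        raise InputError("series length does not match acquisition")
    psc_t = percent_signal_change(target, design, delay_samples)
    psc_u = percent_signal_change(unr, design, delay_samples)
    reg = design.regulation_mask(delay_samples)
    return float((psc_t[reg] - psc_u[reg]).mean())


def regulation_summary(
    trials: Sequence[RoiTimeSeriesSet],
    design: TrialDesign,
    delay_samples: int = DEFAULT_DELAY_SAMPLES,
) -> RegulationSummary:
    """Per-trial feedback differences of one subject's training trials."""
    if not trials:
        raise InputError("no trials given")
    condition = trials[0].condition
    diffs = []
    for ts in sorted(trials, key=lambda t: t.trial_index):
        diffs.append(
            feedback_difference(
                ts.series(condition.target_roi),
                ts.series(CONTROL_ROI),
                design,
                delay_samples=delay_samples,
            )
        )
    return RegulationSummary(
        subject_id=trials[0].subject_id,
        condition=condition,
        trial_diffs=tuple(diffs),
    )


def classify_learner(summary: RegulationSummary) -> LearnerLabel:
    """Apply the Learner rule to a subject's per-trial feedback differences.

    Learner iff (a) the difference has the condition's sign in >= 4 of 6
    trials and (b) the signed modulation strictly improves from trial 1 to
    trial 6 (equality is not improvement). Scaling every difference by a
    positive constant cannot change the outcome.
    """
    d = summary.condition.direction
    diffs = summary.trial_diffs
    if len(diffs) != 6:
        raise InputError("classification requires exactly 6 trial differences")
    sign_correct = sum(1 for v in diffs if d * v > 0)
    improved = d * diffs[5] > d * diffs[0]
    label = "Learner" if (sign_correct >= 4 and improved) else "nonLearner"
    return LearnerLabel(
        subject_id=summary.subject_id,
        condition=summary.condition,
        label=label,
        sign_correct_count=sign_correct,
        improved=improved,
    )


def paired_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, int]:
    """Paired t statistic: t = mean(d) / (sd(d)/sqrt(n)), df = n - 1."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("paired samples must be 1-d and of equal length")
    n = len(x)
    if n < 2:
        raise InputError("need at least two pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("zero-variance differences: t undefined")
    return float(d.mean() / (sd / math.sqrt(n))), n - 1


def paired_t_pvalue(t: float, df: int) -> float:
    """Two-sided p-value for a paired t statistic."""
    return float(2.0 * _t_dist.sf(abs(t), df))


def oneway_anova_f(groups: Sequence[Sequence[float]]) -> tuple[float, int, int]:
    """One-way ANOVA F from the standard between/within sums of squares.

    Returns ``(F, df_between, df_within)``. A zero within-group sum of
    squares with non-zero between-group spread yields infinite F, reported
    with a warning rather than raising.
    """
    if len(groups) < 2:
        raise InputError("ANOVA needs at least two groups")
    arrays = [np.asarray(g, float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise InputError("every group must be nonempty")
    n = sum(a.size for a in arrays)
    g = len(arrays)
    if n < 3:
        raise InputError("total sample size must be at least 3")
    grand = np.concatenate(arrays).mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b, df_w = g - 1, n - g
    if ssw == 0:
        if ssb == 0:
            return 0.0, df_b, df_w
        warnings.warn("zero within-group variance: F is infinite", stacklevel=2)
        return math.inf, df_b, df_w
    f = (ssb / df_b) / (ssw / df_w)
    return float(f), df_b, df_w


def ratings_comparison(table: pd.DataFrame) -> pd.DataFrame:
    """Learner-vs-non-Learner one-way ANOVA of ratings, per condition.

    ``table`` needs columns subject, condition, learner (0/1), intensity,
    unpleasantness. Returns one row per (condition, measure) with F,
    degrees of freedom and p; conditions with an empty group are skipped
    with a warning.
    """
    required = {"subject", "condition", "learner", "intensity", "unpleasantness"}
    missing = required - set(table.columns)
    if missing:
        raise InputError(f"ratings table missing columns: {sorted(missing)}")
    rows = []
    for cond, sub in table.groupby("condition", sort=False):
        learners = sub[sub["learner"] == 1]
        nonlearners = sub[sub["learner"] == 0]
        if learners.empty or nonlearners.empty:
            warnings.warn(f"condition {cond}: one group empty, skipped", stacklevel=2)
            continue
        for measure in ("intensity", "unpleasantness"):
            f, df_b, df_w = oneway_anova_f(
                [learners[measure].to_numpy(), nonlearners[measure].to_numpy()]
            )
            rows.append(
                {
                    "condition": cond,
                    "measure": measure,
                    "F": f,
                    "df_between": df_b,
                    "df_within": df_w,
                    "p": float(_f_dist.sf(f, df_b, df_w)) if math.isfinite(f) else 0.0,
                }
            )
    return pd.DataFrame(rows)


def load_reference_ratings() -> pd.DataFrame:
    """Published pain intensity/unpleasantness ratings, 10 subjects x 4 conditions."""
    ref = resources.files("cohnet.data") / "reference_ratings.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
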