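"""Synthetic neurofeedback cohorts with analytically known coupling structure.

The study design emulated here: subjects attempt to up- or down-regulate the
%BOLD signal of a target region (rACC or left posterior insula) relative to a
control region (UNR) across six training trials. Each trial alternates
non-regulation (22.5 s) and regulation (45 s) phases, sampled at TR = 1.5 s
for 258 samples. Connectivity among six pain-related ROIs is analysed by
band-averaged magnitude-squared coherence.

Because no raw recordings accompany that design, this module generates ROI
time series from a shared-latent factor model,

    x_i(t) = b + m_i(t) + sum_k a_ik * s_k(t) + e_i(t),

with white Gaussian latents ``s_k`` and noise ``e_i`` and a haemodynamically
smoothed block modulation ``m_i``. White latents make the pairwise
magnitude-squared coherence frequency-flat with a closed form
(:func:`theoretical_coherence`), so the spectral estimator can be validated
against an exact oracle.
"""

from __future__ import annotations

import math
from collections import namedtuple
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gamma as _gamma_dist

from .errors import ConfigurationError, InputError

__all__ = [
    "ANALYSIS_ROIS",
    "CONTROL_ROI",
    "ALL_ROIS",
    "MNI_COORDS",
    "CONDITIONS",
    "DEFAULT_LEARNER_SPLIT",
    "AcquisitionConfig",
    "Condition",
    "Phase",
    "TrialDesign",
    "RoiSet",
    "CouplingModel",
    "RoiTimeSeriesSet",
    "CohortSpec",
    "Cohort",
    "build_trial_design",
    "double_gamma_hrf",
    "theoretical_coherence",
    "simulate_subject",
    "simulate_cohort",
    "coupling_model_for",
]

# ---------------------------------------------------------------------------
# ROI bookkeeping
# ---------------------------------------------------------------------------

#: The six regions entering the connectivity analysis, in canonical order.
ANALYSIS_ROIS: tuple[str, ...] = ("rACC", "pInsL", "pInsR", "MCC", "aInsL", "SII")

#: Control region used only for the feedback signal (target - UNR).
CONTROL_ROI: str = "UNR"

ALL_ROIS: tuple[str, ...] = ANALYSIS_ROIS + (CONTROL_ROI,)

#: MNI coordinates of each region (x, y, z).
MNI_COORDS: dict[str, tuple[int, int, int]] = {
    "rACC": (-1, 36, 6),
    "pInsL": (-42, -20, 9),
    "pInsR": (40, -13, 6),
    "MCC": (-3, -25, 38),
    "aInsL": (-45, 6, -6),
    "SII": (-58, -29, 23),
    "UNR": (-42, -61, 29),
}


@dataclass(frozen=True)
class RoiSet:
    """Ordered set of ROI labels with their MNI coordinates."""

    labels: tuple[str, ...] = ALL_ROIS
    mni_coords: Mapping[str, tuple[int, int, int]] = field(
        default_factory=lambda: dict(MNI_COORDS)
    )

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ConfigurationError("ROI labels must be unique")

    @property
    def analysis_labels(self) -> tuple[str, ...]:
        """Labels entering the connectivity matrix (control ROI excluded)."""
        return tuple(l for l in self.labels if l != CONTROL_ROI)


# ---------------------------------------------------------------------------
# Acquisition and trial design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AcquisitionConfig:
    """Sampling bookkeeping for one trial.

    Parameters
    ----------
    tr_seconds
        Repetition time (sampling interval), seconds.
    n_samples
        Number of volumes per trial.
    """

    tr_seconds: float = 1.5
    n_samples: int = 258

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0:
            raise ConfigurationError("tr_seconds must be positive")
        if self.n_samples < 2:
            raise ConfigurationError("n_samples must be at least 2")

    @property
    def sampling_freq_hz(self) -> float:
        return 1.0 / self.tr_seconds

    @property
    def nyquist_hz(self) -> float:
        return self.sampling_freq_hz / 2.0

    def freq_step_hz(self, segment_length: int) -> float:
        """Frequency-grid step of a segmented spectral estimator."""
        if segment_length < 2:
            raise ConfigurationError("segment_length must be at least 2")
        return 1.0 / (segment_length * self.tr_seconds)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.tr_seconds


@dataclass(frozen=True)
class Condition:
    """One feedback condition: which ROI is regulated and in which direction.

    ``direction`` is +1 for up-regulation (target - UNR > 0 is success)
    and -1 for down-regulation.
    """

    name: str
    target_roi: str
    direction: int

    def __post_init__(self) -> None:
        if self.direction not in (-1, 1):
            raise ConfigurationError("direction must be -1 or +1")
        if self.target_roi == CONTROL_ROI:
            raise ConfigurationError("target ROI cannot be the control ROI")


#: The four feedback conditions: down/up regulation of rACC or pInsL vs UNR.
CONDITIONS: dict[str, Condition] = {
    "ACCD": Condition("ACCD", "rACC", -1),
    "ACCU": Condition("ACCU", "rACC", +1),
    "INSD": Condition("INSD", "pInsL", -1),
    "INSU": Condition("INSU", "pInsL", +1),
}


Phase = namedtuple("Phase", ["kind", "duration_s"])

REGULATION = "regulation"
NON_REGULATION = "non_regulation"


@dataclass(frozen=True, eq=False)
class TrialDesign:
    """Ordered phase schedule of one trial plus the sample-to-phase map.

    ``phases`` holds the nominal schedule (alternating, starting and ending
    with a non-regulation phase). ``sample_map[i]`` is the index into
    ``phases`` of the phase containing sample i; when the nominal schedule
    is longer than ``n_samples * TR`` the trailing phases simply receive no
    samples.
    """

    phases: tuple[Phase, ...]
    condition: Condition
    sample_map: np.ndarray
    tr_seconds: float

    @property
    def n_samples(self) -> int:
        return len(self.sample_map)

    def regulation_mask(self, delay_samples: int = 0) -> np.ndarray:
        """Boolean mask of samples attributed to regulation phases.

        ``delay_samples`` shifts the attribution to account for
        haemodynamic lag: sample i is attributed to the phase of sample
        i - delay (the first ``delay`` samples stay in the opening phase).
        """
        if delay_samples < 0:
            raise ConfigurationError("delay_samples must be >= 0")
        idx = np.maximum(np.arange(self.n_samples) - delay_samples, 0)
        shifted = self.sample_map[idx]
        kinds = np.array([p.kind == REGULATION for p in self.phases])
        return kinds[shifted]

    def boxcar(self) -> np.ndarray:
        """Regulation indicator (1 during regulation phases), no delay."""
        return self.regulation_mask(0).astype(float)


def build_trial_design(
    acq: AcquisitionConfig,
    condition: Condition,
    *,
    n_regulation: int = 6,
    regulation_s: float = 45.0,
    non_regulation_s: float = 22.5,
) -> TrialDesign:
    """Lay out the alternating phase schedule and map samples onto it.

    The nominal schedule (6 x 45 s regulation interleaved with 7 x 22.5 s
    non-regulation) lasts 427.5 s, slightly longer than the 258 samples x
    1.5 s = 387 s actually acquired; the sample count is authoritative and
    the schedule is truncated at the final sample.
    """
    if n_regulation < 1:
        raise ConfigurationError("need at least one regulation phase")
    phases: list[Phase] = [Phase(NON_REGULATION, non_regulation_s)]
    for _ in range(n_regulation):
        phases.append(Phase(REGULATION, regulation_s))
        phases.append(Phase(NON_REGULATION, non_regulation_s))

    onsets = np.concatenate([[0.0], np.cumsum([p.duration_s for p in phases])])
    total_s = onsets[-1]
    if acq.n_samples * acq.tr_seconds < non_regulation_s + regulation_s:
        raise ConfigurationError(
            "n_samples too small to contain one full regulation phase"
        )
    t = np.arange(acq.n_samples) * acq.tr_seconds
    if t[-1] >= total_s:
        raise ConfigurationError(
            f"acquisition ({t[-1] + acq.tr_seconds:g} s) outlasts the "
            f"nominal phase schedule ({total_s:g} s)"
        )
    sample_map = np.searchsorted(onsets[1:], t, side="right")
    return TrialDesign(
        phases=tuple(phases),
        condition=condition,
        sample_map=sample_map,
        tr_seconds=acq.tr_seconds,
    )


# ---------------------------------------------------------------------------
# Haemodynamics and coupling model
# ---------------------------------------------------------------------------


def double_gamma_hrf(
    acq: AcquisitionConfig,
    *,
    peak_s: float = 6.0,
    undershoot_s: float = 16.0,
    undershoot_ratio: float = 1.0 / 6.0,
    duration_s: float = 32.0,
) -> np.ndarray:
    """Canonical double-gamma haemodynamic response sampled at TR.

    The kernel is normalised to unit sum (unit DC gain) so that convolving
    a unit boxcar yields a plateau of 1 in the block interior - block
    amplitudes then carry through to the simulated signal unchanged.
    """
    t = np.arange(0.0, duration_s + acq.tr_seconds / 2, acq.tr_seconds)
    h = _gamma_dist.pdf(t, peak_s) - undershoot_ratio * _gamma_dist.pdf(t, undershoot_s)
    s = h.sum()
    if s <= 0:  # pragma: no cover - only reachable with absurd parameters
        raise ConfigurationError("HRF parameters yield a non-positive-gain kernel")
    return h / s


@dataclass(frozen=True, eq=False)
class CouplingModel:
    """Shared-latent generative model for one subject.

    ``loadings[i, k]`` couples ROI i to latent factor k; latents and ROI
    noise are white Gaussian with standard deviations ``latent_sd[k]`` and
    ``noise_sd[i]``. ``modulation_amp[i, t]`` is the signed %BOLD block
    amplitude of ROI i in trial t, applied through the HRF.
    """

    roi_labels: tuple[str, ...]
    loadings: np.ndarray
    latent_sd: np.ndarray
    noise_sd: np.ndarray
    modulation_amp: np.ndarray
    baseline_level: float = 100.0
    smooth_latents: bool = False

    def __post_init__(self) -> None:
        n_roi = len(self.roi_labels)
        if self.loadings.shape[0] != n_roi:
            raise ConfigurationError("loadings row count must match ROI count")
        if self.latent_sd.shape != (self.loadings.shape[1],):
            raise ConfigurationError("latent_sd length must match factor count")
        if self.noise_sd.shape != (n_roi,):
            raise ConfigurationError("noise_sd length must match ROI count")
        if np.any(self.noise_sd <= 0):
            raise ConfigurationError("noise_sd must be strictly positive")
        if self.modulation_amp.shape[0] != n_roi:
            raise ConfigurationError("modulation_amp row count must match ROI count")
        if self.baseline_level <= 0:
            raise ConfigurationError("baseline_level must be positive")

    @property
    def n_trials(self) -> int:
        return self.modulation_amp.shape[1]

    def roi_index(self, roi: str | int) -> int:
        if isinstance(roi, str):
            try:
                return self.roi_labels.index(roi)
            except ValueError:
                raise InputError(f"unknown ROI label {roi!r}") from None
        return int(roi)


def theoretical_coherence(model: CouplingModel, i: str | int, j: str | int) -> float:
    """Closed-form magnitude-squared coherence between two model ROIs.

    With white latents and noise the cross- and auto-spectra are flat, so

        Coh2_ij = (sum_k a_ik a_jk s_k^2)^2
                  / ((sum_k a_ik^2 s_k^2 + n_i^2)(sum_k a_jk^2 s_k^2 + n_j^2))

    at every frequency. Cauchy-Schwarz bounds the value in [0, 1]. The block
    modulation term is deterministic and excluded; it only perturbs
    frequencies near the block fundamental (~0.015 Hz), far below the
    default analysis band.
    """
    ii, jj = model.roi_index(i), model.roi_index(j)
    if ii == jj:
        raise InputError("self-coherence is handled by the estimator, not the oracle")
    s2 = model.latent_sd**2
    a_i, a_j = model.loadings[ii], model.loadings[jj]
    cross = float(np.sum(a_i * a_j * s2))
    p_i = float(np.sum(a_i**2 * s2) + model.noise_sd[ii] ** 2)
    p_j = float(np.sum(a_j**2 * s2) + model.noise_sd[jj] ** 2)
    return cross**2 / (p_i * p_j)


# ---------------------------------------------------------------------------
# Time-series containers and per-subject simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True, eq=False)
class RoiTimeSeriesSet:
    """ROI-by-sample data matrix for one trial of one subject."""

    values: np.ndarray
    roi_labels: tuple[str, ...]
    subject_id: int
    trial_index: int  # 1-based
    condition: Condition

    def __post_init__(self) -> None:
        if self.values.shape[0] != len(self.roi_labels):
            raise InputError("row count must equal number of ROI labels")
        if not np.all(np.isfinite(self.values)):
            raise InputError("time series contain non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def series(self, roi: str) -> np.ndarray:
        try:
            return self.values[self.roi_labels.index(roi)]
        except ValueError:
            raise InputError(f"ROI {roi!r} not present") from None


def _seed_rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def simulate_subject(
    model: CouplingModel,
    designs: Sequence[TrialDesign],
    acq: AcquisitionConfig,
    roi_set: RoiSet | None = None,
    seed=0,
    subject_id: int = 1,
) -> list[RoiTimeSeriesSet]:
    """Simulate all trials of one subject under the coupling model.

    Each ROI series is ``baseline + amp*(boxcar (*) HRF) + latents + noise``
    in arbitrary signal units scaled so that ``amp`` is the plateau %BOLD
    change relative to baseline. Output is a pure function of
    (model, designs, acq, seed).
    """
    roi_set = roi_set or RoiSet()
    if tuple(model.roi_labels) != tuple(roi_set.labels):
        raise ConfigurationError("model ROI labels do not match the ROI set")
    if len(designs) != model.n_trials:
        raise ConfigurationError(
            f"model defines {model.n_trials} trials but {len(designs)} designs given"
        )
    rng = _seed_rng(seed)
    hrf = double_gamma_hrf(acq)
    n_roi = len(model.roi_labels)
    unit = model.baseline_level / 100.0  # signal units per %BOLD
    out: list[RoiTimeSeriesSet] = []
    for t_idx, design in enumerate(designs):
        if design.n_samples != acq.n_samples:
            raise ConfigurationError("design sample count does not match acquisition")
        conv = np.convolve(design.boxcar(), hrf)[: acq.n_samples]
        latents = rng.standard_normal((len(model.latent_sd), acq.n_samples))
        latents *= model.latent_sd[:, None]
        if model.smooth_latents:
            latents = np.apply_along_axis(
                lambda s: np.convolve(s, hrf)[: acq.n_samples], 1, latents
            )
        noise = rng.standard_normal((n_roi, acq.n_samples)) * model.noise_sd[:, None]
        values = (
            model.baseline_level
            + unit * model.modulation_amp[:, t_idx, None] * conv[None, :]
            + unit * (model.loadings @ latents + noise)
        )
        out.append(
            RoiTimeSeriesSet(
                values=values,
                roi_labels=tuple(model.roi_labels),
                subject_id=subject_id,
                trial_index=t_idx + 1,
                condition=design.condition,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Cohort-level simulation
# ---------------------------------------------------------------------------

#: Learner subject ids per condition (splits 6/4, 5/5, 8/2, 5/5 over ten
#: subjects), mirroring the study's observed classification.
DEFAULT_LEARNER_SPLIT: dict[str, tuple[int, ...]] = {
    "ACCD": (3, 4, 5, 6, 7, 10),
    "ACCU": (1, 2, 4, 6, 9),
    "INSD": (2, 3, 4, 5, 6, 8, 9, 10),
    "INSU": (1, 2, 4, 6, 7),
}

_TRIANGLE = ("pInsL", "pInsR", "SII")  # pain-network triad coupled in everyone


@dataclass(frozen=True)
class CohortSpec:
    """Study-level parameters of the synthetic cohort.

    Defaults reproduce the study conditions: 10 subjects, 4 feedback
    conditions, 6 trials each. Learners receive a monotonically improving
    modulation profile in the condition's direction plus an extra latent
    factor coupling rACC and pInsL; non-learners get a profile with the
    wrong sign in half the trials and no improvement, and no extra factor.
    Amplitudes are in %BOLD; the default scale (2%) sits well above the
    per-trial noise floor so ground-truth labels are recoverable.
    """

    n_subjects: int = 10
    n_trials: int = 6
    conditions: tuple[str, ...] = ("ACCD", "ACCU", "INSD", "INSU")
    learner_subjects: Mapping[str, tuple[int, ...]] = field(
        default_factory=lambda: dict(DEFAULT_LEARNER_SPLIT)
    )
    amp_scale: float = 2.0
    learner_profile: tuple[float, ...] = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
    nonlearner_profile: tuple[float, ...] = (0.9, -0.7, 0.5, -0.6, 0.4, -0.8)
    global_loading: float = 0.3
    triangle_loading: float = 0.8
    learner_coupling: float = 1.5
    nonlearner_coupling: float = 1.2
    latent_sd: float = 1.0
    noise_sd: float = 1.0
    baseline_level: float = 100.0
    rating_mean: float = 5.5
    rating_sd: float = 1.2

    def __post_init__(self) -> None:
        if len(self.learner_profile) != self.n_trials:
            raise ConfigurationError("learner_profile length must equal n_trials")
        if len(self.nonlearner_profile) != self.n_trials:
            raise ConfigurationError("nonlearner_profile length must equal n_trials")
        for cond in self.conditions:
            if cond not in CONDITIONS:
                raise ConfigurationError(f"unknown condition {cond!r}")


def coupling_model_for(
    spec: CohortSpec, condition: Condition, learner: bool, roi_set: RoiSet | None = None
) -> CouplingModel:
    """Build the per-subject coupling model for one condition and group.

    Three latent factors: a weak global factor on every ROI (baseline
    coherence floor), a pain-network factor on the pInsL-pInsR-SII triad
    present in both groups, and a group-specific factor - rACC-pInsL for
    Learners (the connection successful regulation recruits), aInsL-pInsL
    for non-Learners (the anterior-insula coupling that marks unsuccessful
    regulation). Each group therefore carries a distinctive fourth strong
    connection next to the shared triad.
    """
    roi_set = roi_set or RoiSet()
    labels = roi_set.labels
    n = len(labels)
    loadings = np.zeros((n, 3))
    loadings[:, 0] = spec.global_loading
    for roi in _TRIANGLE:
        if roi in labels:
            loadings[labels.index(roi), 1] = spec.triangle_loading
    extra_rois = ("rACC", "pInsL") if learner else ("aInsL", "pInsL")
    extra_loading = spec.learner_coupling if learner else spec.nonlearner_coupling
    for roi in extra_rois:
        loadings[labels.index(roi), 2] = extra_loading
    profile = np.asarray(
        spec.learner_profile if learner else spec.nonlearner_profile, dtype=float
    )
    amp = np.zeros((n, spec.n_trials))
    amp[labels.index(condition.target_roi)] = (
        condition.direction * spec.amp_scale * profile
    )
    return CouplingModel(
        roi_labels=tuple(labels),
        loadings=loadings,
        latent_sd=np.full(3, spec.latent_sd),
        noise_sd=np.full(n, spec.noise_sd),
        modulation_amp=amp,
        baseline_level=spec.baseline_level,
    )


@dataclass(frozen=True, eq=False)
class Cohort:
    """Simulated cohort: trials, ground-truth labels and ratings."""

    spec: CohortSpec
    acq: AcquisitionConfig
    roi_set: RoiSet
    seed: int
    trials: Mapping[tuple[int, str], tuple[RoiTimeSeriesSet, ...]]
    true_labels: Mapping[tuple[int, str], str]
    ratings: pd.DataFrame

    @property
    def subject_ids(self) -> tuple[int, ...]:
        return tuple(range(1, self.spec.n_subjects + 1))

    def design(self, condition_name: str) -> TrialDesign:
        return build_trial_design(self.acq, CONDITIONS[condition_name])


def _simulate_ratings(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Verbal-rating-scale draws: half-point resolution, clipped to [0, 10]."""
    raw = rng.normal(spec.rating_mean, spec.rating_sd, size=2)
    return np.clip(np.round(2.0 * raw) / 2.0, 0.0, 10.0)


def simulate_cohort(
    spec: CohortSpec | None = None,
    acq: AcquisitionConfig | None = None,
    seed: int = 0,
) -> Cohort:
    """Simulate the full cohort: every subject x condition x trial.

    Ratings are drawn from the same distribution in both groups, matching
    the study's null finding that pain ratings do not separate Learners
    from non-Learners. Child seeds are derived per (subject, condition)
    from the master seed, so subjects are independent yet reproducible.
    """
    spec = spec or CohortSpec()
    acq = acq or AcquisitionConfig()
    roi_set = RoiSet()
    trials: dict[tuple[int, str], tuple[RoiTimeSeriesSet, ...]] = {}
    labels: dict[tuple[int, str], str] = {}
    rating_rows = []
    for ci, cond_name in enumerate(spec.conditions):
        cond = CONDITIONS[cond_name]
        design = build_trial_design(acq, cond)
        designs = [design] * spec.n_trials
        learner_ids = set(spec.learner_subjects.get(cond_name, ()))
        for sid in range(1, spec.n_subjects + 1):
            learner = sid in learner_ids
            model = coupling_model_for(spec, cond, learner, roi_set)
            subject_trials = simulate_subject(
                model, designs, acq, roi_set, seed=(seed, ci, sid), subject_id=sid
            )
            trials[(sid, cond_name)] = tuple(subject_trials)
            labels[(sid, cond_name)] = "Learner" if learner else "nonLearner"
            intensity, unpleasant = _simulate_ratings(
                spec, _seed_rng((seed, 1_000_000 + ci, sid))
            )
            rating_rows.append(
                {
                    "subject": sid,
                    "condition": cond_name,
                    "learner": int(learner),
                    "intensity": intensity,
                    "unpleasantness": unpleasant,
                }
            )
    ratings = pd.DataFrame(rating_rows)
    return Cohort(
        spec=spec,
        acq=acq,
        roi_set=roi_set,
        seed=seed,
        trials=trials,
        true_labels=labels,
        ratings=ratings,
    )
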