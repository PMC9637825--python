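"""End-to-end pipeline: simulate -> coherence -> network -> classify -> report.

The runner ties the stages together for the default study layout: for each
(subject, condition) it classifies the subject from the six training trials,
computes band-averaged connectivity matrices for trials 1 and 6, normalises
them per subject, averages by classified group, and thresholds each group
matrix into a weighted graph. Everything is a deterministic function of the
configuration and its seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import io as cio
from .cohort import (
    CONDITIONS,
    AcquisitionConfig,
    Cohort,
    CohortSpec,
    simulate_cohort,
)
from .errors import ConfigurationError, DegenerateInputError, InputError
from .network import WeightedGraph, group_average, normalize_cm, percentile_threshold
from .regulation import (
    DEFAULT_DELAY_SAMPLES,
    classify_learner,
    ratings_comparison,
    regulation_summary,
)
from .spectral import (
    DEFAULT_BAND_HZ,
    ConnectivityMatrix,
    SpectralConfig,
    connectivity_matrix,
)

logger = logging.getLogger("cohnet")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_config"]

SCHEMA_VERSION = "1"


class AcquisitionSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    tr_seconds: float = 1.5
    n_samples: int = 258

    def build(self) -> AcquisitionConfig:
        return AcquisitionConfig(self.tr_seconds, self.n_samples)


class SpectralSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    segment_length: int = 64
    overlap_fraction: float = 0.5
    window: str = "hann"
    detrend: Literal["none", "mean", "linear"] = "mean"

    def build(self) -> SpectralConfig:
        return SpectralConfig(
            self.segment_length, self.overlap_fraction, self.window, self.detrend
        )


class CohortSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_subjects: int = 10
    amp_scale: float = 2.0
    learner_coupling: float = 1.5
    triangle_loading: float = 0.8
    global_loading: float = 0.3
    noise_sd: float = 1.0

    def build(self) -> CohortSpec:
        return CohortSpec(
            n_subjects=self.n_subjects,
            amp_scale=self.amp_scale,
            learner_coupling=self.learner_coupling,
            triangle_loading=self.triangle_loading,
            global_loading=self.global_loading,
            noise_sd=self.noise_sd,
        )


class PipelineConfig(BaseModel):
    """Validated, round-trippable configuration of one pipeline run."""

    model_config = ConfigDict(extra="forbid")
    schema_version: str = SCHEMA_VERSION
    seed: int = 0
    acquisition: AcquisitionSettings = Field(default_factory=AcquisitionSettings)
    spectral: SpectralSettings = Field(default_factory=SpectralSettings)
    cohort: CohortSettings = Field(default_factory=CohortSettings)
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ
    percentile: float = 70.0
    delay_samples: int = DEFAULT_DELAY_SAMPLES
    out_dir: str | None = None

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        if self.schema_version != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema_version {self.schema_version!r}")
        if not self.band_hz[0] < self.band_hz[1]:
            raise ValueError("band_hz must satisfy low < high")
        if not 0 < self.percentile <= 100:
            raise ValueError("percentile must lie in (0, 100]")
        if self.delay_samples < 0:
            raise ValueError("delay_samples must be >= 0")
        return self


def load_config(path: Path) -> PipelineConfig:
    """Load a YAML or JSON configuration file (unknown keys rejected)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ConfigurationError(f"{path}: expected a mapping at top level")
    try:
        return PipelineConfig.model_validate(dict(data))
    except Exception as exc:
        raise ConfigurationError(f"{path}: invalid configuration: {exc}") from exc


@dataclass
class PipelineResult:
    """In-memory bundle of every artifact one run produces."""

    config: PipelineConfig
    cohort: Cohort
    classification: pd.DataFrame
    labels: dict[tuple[int, str], str]
    subject_cms: dict[tuple[int, str, int], ConnectivityMatrix]
    normalized_cms: dict[tuple[int, str, int], ConnectivityMatrix]
    group_graphs: dict[tuple[str, int, str], WeightedGraph]
    ratings_stats: pd.DataFrame
    manifest_path: Path | None = None


GRAPH_TRIALS = (1, 6)


def _log_config(config: PipelineConfig) -> None:
    for key, value in config.model_dump().items():
        logger.info("config %s = %r", key, value)


def run_pipeline(config: PipelineConfig, out_dir: Path | None = None) -> PipelineResult:
    """Run the full analysis on a freshly simulated cohort.

    Group graphs use the *classified* labels, not the generator's ground
    truth, so a planted group difference must survive the whole pipeline to
    show up in a group graph. When ``out_dir`` (or ``config.out_dir``) is
    set, all artifacts are written there along with a checksum manifest.
    """
    _log_config(config)
    acq = config.acquisition.build()
    spec_cfg = config.spectral.build()
    spec_cfg.require_averaging(acq.n_samples)
    cohort_spec = config.cohort.build()
    if out_dir is None and config.out_dir:
        out_dir = Path(config.out_dir)

    logger.info("stage simulate: %d subjects x %d conditions",
                cohort_spec.n_subjects, len(cohort_spec.conditions))
    cohort = simulate_cohort(cohort_spec, acq, seed=config.seed)

    # --- classification ---------------------------------------------------
    labels: dict[tuple[int, str], str] = {}
    class_rows = []
    for cond_name in cohort_spec.conditions:
        design = cohort.design(cond_name)
        for sid in cohort.subject_ids:
            try:
                summary = regulation_summary(
                    cohort.trials[(sid, cond_name)], design, config.delay_samples
                )
                lab = classify_learner(summary)
            except (InputError, DegenerateInputError) as exc:
                raise type(exc)(
                    f"stage classify, subject {sid}, condition {cond_name}: {exc}"
                ) from exc
            labels[(sid, cond_name)] = lab.label
            class_rows.append(
                {
                    "subject": sid,
                    "condition": cond_name,
                    **{f"trial_{k+1}": v for k, v in enumerate(summary.trial_diffs)},
                    "sign_correct_count": lab.sign_correct_count,
                    "improvement": lab.improved,
                    "label": lab.label,
                    "true_label": cohort.true_labels[(sid, cond_name)],
                }
            )
    classification = pd.DataFrame(class_rows)

    # --- per-subject connectivity matrices (trials 1 and 6) ---------------
    subject_cms: dict[tuple[int, str, int], ConnectivityMatrix] = {}
    normalized_cms: dict[tuple[int, str, int], ConnectivityMatrix] = {}
    for cond_name in cohort_spec.conditions:
        for sid in cohort.subject_ids:
            for trial in GRAPH_TRIALS:
                ts = cohort.trials[(sid, cond_name)][trial - 1]
                try:
                    cm = connectivity_matrix(ts, spec_cfg, acq, config.band_hz)
                    subject_cms[(sid, cond_name, trial)] = cm
                    normalized_cms[(sid, cond_name, trial)] = normalize_cm(cm)
                except DegenerateInputError as exc:
                    logger.warning(
                        "stage coherence: subject %s condition %s trial %s "
                        "dropped (%s)", sid, cond_name, trial, exc,
                    )

    # --- group graphs ------------------------------------------------------
    group_graphs: dict[tuple[str, int, str], WeightedGraph] = {}
    for cond_name in cohort_spec.conditions:
        for trial in GRAPH_TRIALS:
            for group in ("Learner", "nonLearner"):
                members = [
                    normalized_cms[(sid, cond_name, trial)]
                    for sid in cohort.subject_ids
                    if labels[(sid, cond_name)] == group
                    and (sid, cond_name, trial) in normalized_cms
                ]
                if not members:
                    logger.warning(
                        "stage network: empty group %s / trial %s / %s, skipped",
                        cond_name, trial, group,
                    )
                    continue
                avg = group_average(members)
                group_graphs[(cond_name, trial, group)] = percentile_threshold(
                    avg, config.percentile
                )

    ratings_stats = ratings_comparison(cohort.ratings)

    result = PipelineResult(
        config=config,
        cohort=cohort,
        classification=classification,
        labels=labels,
        subject_cms=subject_cms,
        normalized_cms=normalized_cms,
        group_graphs=group_graphs,
        ratings_stats=ratings_stats,
    )
    if out_dir is not None:
        result.manifest_path = _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, out_dir: Path) -> Path:
    """Persist every artifact and return the manifest path."""
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    p = out_dir / "classification.tsv"
    cio.atomic_write_text(p, result.classification.to_csv(sep="\t", index=False))
    written.append(p)

    p = out_dir / "ratings_stats.tsv"
    cio.atomic_write_text(p, result.ratings_stats.to_csv(sep="\t", index=False))
    written.append(p)

    p = out_dir / "ratings.tsv"
    cio.atomic_write_text(p, result.cohort.ratings.to_csv(sep="\t", index=False))
    written.append(p)

    cm_dir = out_dir / "cm"
    for (sid, cond, trial), cm in sorted(result.normalized_cms.items()):
        path = cm_dir / f"sub-{sid:02d}_cond-{cond}_trial-{trial}_cm-norm.tsv"
        cio.write_cm_tsv(cm, path)
        written.append(path)
    for (sid, cond, trial), cm in sorted(result.subject_cms.items()):
        path = cm_dir / f"sub-{sid:02d}_cond-{cond}_trial-{trial}_cm-raw.tsv"
        cio.write_cm_tsv(cm, path)
        written.append(path)

    graph_dir = out_dir / "graphs"
    for (cond, trial, group), graph in sorted(result.group_graphs.items()):
        base = graph_dir / f"cond-{cond}_trial-{trial}_group-{group}"
        written.extend(cio.write_graph(graph, base))

    p = out_dir / "config.json"
    cio.atomic_write_text(
        p, json.dumps(result.config.model_dump(), indent=2, sort_keys=True) + "\n"
    )
    written.append(p)

    labels_payload = {
        f"sub-{sid:02d}/{cond}": {
            "classified": result.labels[(sid, cond)],
            "ground_truth": result.cohort.true_labels[(sid, cond)],
        }
        for (sid, cond) in sorted(result.labels)
    }
    p = out_dir / "cohort_manifest.json"
    cio.atomic_write_text(
        p,
        json.dumps(
            {
                "seed": result.cohort.seed,
                "n_subjects": result.cohort.spec.n_subjects,
                "conditions": list(result.cohort.spec.conditions),
                "labels": labels_payload,
            },
            indent=2,
            sort_keys=True,
        )
        + "\n",
    )
    written.append(p)

    return cio.write_manifest(out_dir, written, extra={"schema_version": SCHEMA_VERSION})
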