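"""On-disk formats: TSV time series and matrices, GraphML graphs, manifests.

All writes go through an atomic write-temp-then-rename helper so an aborted
run never leaves a partial artifact behind. Floats are serialised with
``%.17g`` so a write/read round trip is bit-exact.
"""

from __future__ import annotations

import hashlib
import json
import os
import re
import tempfile
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .cohort import CONDITIONS, Condition, RoiTimeSeriesSet
from .errors import InputError
from .network import WeightedGraph
from .spectral import ConnectivityMatrix

__all__ = [
    "atomic_write_text",
    "write_timeseries_tsv",
    "read_timeseries_tsv",
    "timeseries_filename",
    "write_cm_tsv",
    "read_cm_tsv",
    "write_graph",
    "write_manifest",
]

_FLOAT_FMT = "%.17g"
_TS_NAME_RE = re.compile(r"sub-(?P<sub>\d+)_cond-(?P<cond>[A-Za-z]+)_trial-(?P<trial>\d+)\.tsv$")


def atomic_write_text(path: Path, text: str) -> None:
    """Write text to ``path`` via a temp file in the same directory + rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _fmt(v: float) -> str:
    return _FLOAT_FMT % v


def timeseries_filename(subject_id: int, condition: str, trial_index: int) -> str:
    return f"sub-{subject_id:02d}_cond-{condition}_trial-{trial_index}.tsv"


def write_timeseries_tsv(ts: RoiTimeSeriesSet, path: Path, tr_seconds: float) -> None:
    """One trial as TSV: column time_s, then one column per ROI."""
    lines = ["\t".join(("time_s",) + tuple(ts.roi_labels))]
    times = np.arange(ts.n_samples) * tr_seconds
    for i in range(ts.n_samples):
        row = [_fmt(times[i])] + [_fmt(v) for v in ts.values[:, i]]
        lines.append("\t".join(row))
    atomic_write_text(Path(path), "\n".join(lines) + "\n")


def read_timeseries_tsv(
    path: Path,
    roi_labels: Iterable[str] | None = None,
    subject_id: int | None = None,
    trial_index: int | None = None,
    condition: Condition | None = None,
) -> RoiTimeSeriesSet:
    """Read a trial TSV back into a time-series set.

    Metadata not passed explicitly is parsed from a
    ``sub-<id>_cond-<name>_trial-<k>.tsv`` file name. Any NaN or
    non-numeric cell is rejected with its row and column named.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except Exception as exc:
        raise InputError(f"{path}: cannot parse TSV ({exc})") from exc
    if "time_s" not in df.columns:
        raise InputError(f"{path}: missing required column 'time_s'")
    available = [c for c in df.columns if c != "time_s"]
    labels = tuple(roi_labels) if roi_labels is not None else tuple(available)
    missing = [l for l in labels if l not in df.columns]
    if missing:
        raise InputError(f"{path}: missing ROI column(s) {missing}")
    for col in labels:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.index[numeric.isna()]
        if len(bad):
            raise InputError(
                f"{path}: non-numeric or NaN value at row {int(bad[0]) + 2}, "
                f"column {col!r}"
            )
    m = _TS_NAME_RE.search(path.name)
    if subject_id is None:
        subject_id = int(m.group("sub")) if m else 0
    if trial_index is None:
        trial_index = int(m.group("trial")) if m else 1
    if condition is None:
        cond_name = m.group("cond") if m else None
        condition = CONDITIONS.get(cond_name, CONDITIONS["ACCD"]) if cond_name else CONDITIONS["ACCD"]
    values = df[list(labels)].to_numpy(float).T
    return RoiTimeSeriesSet(
        values=values,
        roi_labels=labels,
        subject_id=subject_id,
        trial_index=trial_index,
        condition=condition,
    )


def write_cm_tsv(cm: ConnectivityMatrix, path: Path) -> None:
    """Connectivity matrix as a labelled full square TSV."""
    lines = ["\t".join(("roi",) + tuple(cm.roi_labels))]
    for i, label in enumerate(cm.roi_labels):
        lines.append("\t".join([label] + [_fmt(v) for v in cm.values[i]]))
    atomic_write_text(Path(path), "\n".join(lines) + "\n")


def read_cm_tsv(
    path: Path,
    band_hz: tuple[float, float],
    normalized: bool = False,
) -> ConnectivityMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    labels = tuple(df.columns)
    if tuple(df.index) != labels:
        raise InputError(f"{path}: row and column labels differ")
    values = df.to_numpy(float)
    return ConnectivityMatrix(
        values=values, roi_labels=labels, band_hz=band_hz, normalized=normalized
    )


def write_graph(graph: WeightedGraph, base_path: Path) -> list[Path]:
    """Write a graph as edge-list TSV + GraphML + threshold sidecar JSON.

    ``base_path`` is the stem; returns the three paths written.
    """
    base = Path(base_path)
    edge_path = base.with_suffix(".edges.tsv")
    lines = ["roi_a\troi_b\tweight"]
    for a, b, w in graph.edges:
        lines.append(f"{a}\t{b}\t{_fmt(w)}")
    atomic_write_text(edge_path, "\n".join(lines) + "\n")

    gml_path = base.with_suffix(".graphml")
    gml_path.parent.mkdir(parents=True, exist_ok=True)
    tmp = gml_path.with_name(f".{gml_path.name}.tmp")
    nx.write_graphml(graph.to_networkx(), tmp)
    os.replace(tmp, gml_path)

    meta_path = base.with_suffix(".threshold.json")
    atomic_write_text(
        meta_path,
        json.dumps(
            {
                "threshold_value": graph.threshold_value,
                "percentile": graph.percentile,
                "n_edges": len(graph.edges),
            },
            indent=2,
        )
        + "\n",
    )
    return [edge_path, gml_path, meta_path]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: Path, files: Iterable[Path], extra: Mapping | None = None) -> Path:
    """JSON manifest of every artifact with its sha256 checksum."""
    out_dir = Path(out_dir)
    entries = {
        str(Path(f).relative_to(out_dir)): _sha256(Path(f)) for f in sorted(set(map(Path, files)))
    }
    payload = {"artifacts": entries}
    if extra:
        payload.update(extra)
    manifest_path = out_dir / "manifest.json"
    atomic_write_text(manifest_path, json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return manifest_path
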