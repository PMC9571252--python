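"""Recording readers/writers, annotation sidecars, and JSON reports.

The dependency-free interchange format is a TSV matrix: comment header lines
carrying the sampling rate, one tab-separated label row, then one row per
sample (columns = channels; the in-memory orientation is channel-major, so
the boundary transposes).  ``.npz`` is the compact binary alternative.  EDF
and EEGLAB ``.set`` containers are read through :mod:`mne` when it is
installed.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .containers import ChannelMatrix
from .detect import DetectionResult
from .errors import AnnotationError, RecordingIOError
from .simulate import SimulatedRecording

__all__ = [
    "RecordingBundle",
    "read_recording",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_recording_npz",
    "write_simulated_recording",
    "read_annotations",
    "detection_report",
]

REPORT_SCHEMA_VERSION = 1


@dataclass
class RecordingBundle:
    matrix: ChannelMatrix
    source_path: str = ""
    annotations: Optional[list[str]] = None  # labels of annotated bad channels
    group_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.annotations is not None:
            unknown = set(self.annotations) - set(self.matrix.labels)
            if unknown:
                raise AnnotationError(
                    f"annotated channels not in the recording: {sorted(unknown)}"
                )

    @property
    def truth(self) -> Optional[np.ndarray]:
        if self.annotations is None:
            return None
        bad = set(self.annotations)
        return np.array([lb in bad for lb in self.matrix.labels])


def write_matrix_tsv(X: ChannelMatrix, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# srate={X.srate}\n")
        fh.write("\t".join(X.labels) + "\n")
        np.savetxt(fh, X.data.T, fmt="%.8g", delimiter="\t")


def read_matrix_tsv(path) -> ChannelMatrix:
    path = Path(path)
    srate = None
    labels = None
    skip = 0
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            skip += 1
            if line.startswith("#"):
                body = line.lstrip("# ").strip()
                if body.startswith("srate"):
                    srate = float(body.split("=", 1)[1])
                continue
            labels = line.split("\t")
            break
    if srate is None:
        raise RecordingIOError(f"{path}: missing '# srate=' header line")
    if not labels:
        raise RecordingIOError(f"{path}: missing label header row")
    data = np.loadtxt(path, skiprows=skip, delimiter="\t", ndmin=2)
    if data.shape[1] != len(labels):
        raise RecordingIOError(
            f"{path}: {data.shape[1]} columns but {len(labels)} labels"
        )
    return ChannelMatrix(data=data.T, srate=srate, labels=labels)


def write_recording_npz(X: ChannelMatrix, path) -> None:
    np.savez(path, data=X.data, srate=X.srate, labels=np.array(X.labels))


def _read_npz(path) -> ChannelMatrix:
    with np.load(path, allow_pickle=False) as z:
        for key in ("data", "srate", "labels"):
            if key not in z:
                raise RecordingIOError(f"{path}: missing array {key!r}")
        return ChannelMatrix(
            data=z["data"], srate=float(z["srate"]), labels=[str(x) for x in z["labels"]]
        )


def _read_mne(path, kind: str) -> tuple[ChannelMatrix, Optional[list[str]]]:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise RecordingIOError(
            f"reading {kind} files requires the optional 'mne' dependency"
        ) from exc
    if kind == "edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    else:
        raw = mne.io.read_raw_eeglab(path, preload=True, verbose="error")
    data = raw.get_data(units="uV")
    matrix = ChannelMatrix(data=data, srate=float(raw.info["sfreq"]), labels=list(raw.ch_names))
    bads = list(raw.info.get("bads", [])) or None
    return matrix, bads


_SUFFIX_FORMAT = {
    ".tsv": "matrix_tsv",
    ".txt": "matrix_tsv",
    ".npz": "package_binary",
    ".edf": "edf",
    ".set": "eeglab_set",
}


def read_recording(path, fmt: Optional[str] = None, group_id: Optional[str] = None) -> RecordingBundle:
    """Read a recording (TSV, npz, EDF, or EEGLAB .set) into a bundle.

    A sidecar ``<stem>.badchannels.txt`` (one label per line) or container
    bad-channel annotations, when present, populate ``annotations``.
    """
    path = Path(path)
    if not path.exists():
        raise RecordingIOError(f"no such recording: {path}")
    if fmt is None:
        fmt = _SUFFIX_FORMAT.get(path.suffix.lower())
        if fmt is None:
            raise RecordingIOError(f"cannot infer format from suffix {path.suffix!r}")
    annotations = None
    if fmt == "matrix_tsv":
        matrix = read_matrix_tsv(path)
    elif fmt == "package_binary":
        matrix = _read_npz(path)
    elif fmt in ("edf", "eeglab_set"):
        matrix, annotations = _read_mne(path, "edf" if fmt == "edf" else "set")
    else:
        raise RecordingIOError(f"unknown format {fmt!r}")
    sidecar = path.with_suffix(".badchannels.txt")
    if sidecar.exists():
        annotations = read_annotations(sidecar, matrix)
    return RecordingBundle(matrix=matrix, source_path=str(path),
                           annotations=annotations, group_id=group_id)


def read_annotations(path, matrix: Optional[ChannelMatrix] = None) -> list[str]:
    """Bad-channel labels: one label per line, or a JSON list / mapping."""
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        return []
    if text.startswith(("[", "{")):
        loaded = json.loads(text)
        labels = list(loaded) if isinstance(loaded, list) else [k for k, v in loaded.items() if v]
    else:
        labels = [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if matrix is not None:
        unknown = set(labels) - set(matrix.labels)
        if unknown:
            raise AnnotationError(f"{path}: unknown channels {sorted(unknown)}")
    return labels


def write_simulated_recording(rec: SimulatedRecording, directory) -> dict[str, str]:
    """Write a simulated recording as TSV plus a JSON ground-truth sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    data_path = directory / "recording.tsv"
    truth_path = directory / "truth.json"
    write_matrix_tsv(rec.data, data_path)
    truth = {
        "seed": rec.seed,
        "bad_channels": [rec.data.labels[i] for i in rec.bad_indices],
        "artifact_kind": dict(zip(rec.data.labels, rec.artifact_kind)),
    }
    truth_path.write_text(json.dumps(truth, indent=2) + "\n")
    return {"data": str(data_path), "truth": str(truth_path)}


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def detection_report(result: DetectionResult, source_path: str = "") -> dict:
    """JSON-serializable, versioned report of one detection run."""
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "source": source_path,
        "threshold": result.threshold_used,
        "k": result.k_used,
        "metric": result.metric_used.metric,
        "n_channels": int(result.bad_flags.size),
        "bad_channels": result.bad_labels,
        "provenance": result.provenance,
        "channels": [
            {
                "label": result.labels[i] if result.labels else str(i),
                "bad": bool(result.bad_flags[i]),
                "flatline": bool(result.flatline_flags[i]),
                "lof": None if np.isnan(result.lof[i]) else round(float(result.lof[i]), 6),
            }
            for i in range(result.bad_flags.size)
        ],
    }
    if source_path and Path(source_path).exists():
        report["source_sha256_16"] = _digest(source_path)
    return report
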