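"""Reading and writing signal segments and configuration.

The native segment format is inspectable delimited text: one header row of
channel labels, one column per channel, tab separated, with a JSON sidecar
(same path, ``.json`` suffix) holding the sampling rate and labels.  The
round trip is lossless to full float64 precision.  EDF recordings can be
imported (never written) through ``mne`` when it is installed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .neural_mass import SignalSegment

__all__ = [
    "SegmentFormatError",
    "read_segment",
    "write_segment",
    "read_edf",
    "load_config",
]


class SegmentFormatError(ValueError):
    """Malformed segment file or missing/inconsistent sidecar."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_segment(segment: SignalSegment, path) -> Path:
    """Write a segment as tab-separated text plus a JSON sidecar; returns the
    data path.  Values use repr-exact float formatting ('%.17g')."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("\t".join(segment.labels) + "\n")
        np.savetxt(fh, segment.data.T, fmt="%.17g", delimiter="\t")
    sidecar = {
        "fs": segment.fs,
        "labels": list(segment.labels),
        "n_samples": segment.n_samples,
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
    return path


def read_segment(path, channels=None) -> SignalSegment:
    """Read a segment written by :func:`write_segment`.

    Requires the sidecar (explicit error otherwise -- no silent defaults).
    ``channels`` restricts the result to a labelled subset, e.g. to drop a
    reference electrode excluded from analysis.  Parse errors name the
    offending line number.
    """
    path = Path(path)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise SegmentFormatError(
            f"missing sidecar {sidecar_path} (holds fs and labels); "
            "refusing to guess a sampling rate"
        )
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    for key in ("fs", "labels"):
        if key not in meta:
            raise SegmentFormatError(f"sidecar {sidecar_path} lacks required key {key!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        labels = header.split("\t")
        if labels != list(meta["labels"]):
            raise SegmentFormatError(
                f"{path}:1: header labels {labels} do not match sidecar {meta['labels']}"
            )
        rows = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != len(labels):
                raise SegmentFormatError(
                    f"{path}:{lineno}: expected {len(labels)} columns, found {len(parts)}"
                )
            try:
                rows.append([float(v) for v in parts])
            except ValueError as e:
                raise SegmentFormatError(f"{path}:{lineno}: {e}") from None
    if not rows:
        raise SegmentFormatError(f"{path}: no data rows")
    segment = SignalSegment(np.asarray(rows).T, float(meta["fs"]), tuple(labels))
    if channels is not None:
        segment = segment.select(channels)
    return segment


def read_edf(path, channels=None) -> SignalSegment:
    """Import an EDF recording (requires the optional ``mne`` dependency);
    channel labels are mapped verbatim."""
    try:
        import mne
    except ImportError as e:  # pragma: no cover
        raise ImportError(
            "EDF import needs the optional dependency 'mne' (pip install ssvepflow[edf])"
        ) from e
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    segment = SignalSegment(raw.get_data(), float(raw.info["sfreq"]), tuple(raw.ch_names))
    if channels is not None:
        segment = segment.select(channels)
    return segment


def load_config(path) -> dict:
    """Load a YAML or JSON configuration mapping."""
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"configuration {path} must be a mapping")
    return cfg
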