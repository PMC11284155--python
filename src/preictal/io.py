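"""Reading and writing recordings, segment sets, features, and models.

Continuous fixtures are stored as a ``.npy`` signal array plus a JSON
sidecar with the sampling rate and annotations. Segmented datasets are
written one file per clip with a manifest table (clip id, label, group id),
mirroring competition-style layouts. Real continuous EEG is read from EDF
via :mod:`mne` (optional dependency).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DataError
from .features import FeatureMatrix, FeatureRegistry
from .model import ModelSpec
from .simulate import Recording, Segment, SegmentedDataset


def save_recording(recording: Recording, path: str | Path) -> None:
    """Write ``<path>.npy`` (channels x samples) and ``<path>.json`` metadata."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), recording.signal)
    meta = {
        "fs": recording.fs,
        "channel_names": recording.channel_names,
        "start_time": recording.start_time,
        "seizure_onsets": recording.seizure_onsets.tolist(),
        "seizure_offsets": None
        if recording.seizure_offsets is None
        else recording.seizure_offsets.tolist(),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_recording(path: str | Path) -> Recording:
    path = Path(path)
    signal = np.load(path.with_suffix(".npy"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return Recording(
        signal=signal,
        fs=meta["fs"],
        channel_names=meta["channel_names"],
        seizure_onsets=np.asarray(meta["seizure_onsets"], dtype=float),
        seizure_offsets=None
        if meta.get("seizure_offsets") is None
        else np.asarray(meta["seizure_offsets"], dtype=float),
        start_time=meta.get("start_time", 0.0),
    )


def save_segmented(dataset: SegmentedDataset, directory: str | Path) -> None:
    """One ``clip_<id>.npy`` per segment plus ``manifest.csv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, seg in enumerate(dataset.segments):
        np.save(directory / f"clip_{i:05d}.npy", seg.data)
        rows.append({"clip_id": i, "label": seg.label, "group_id": seg.group_id})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(directory / "manifest.csv", index=False)
    (directory / "meta.json").write_text(
        json.dumps({"fs": dataset.fs, "segment_duration": dataset.segment_duration})
    )


def load_segmented(directory: str | Path) -> SegmentedDataset:
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    meta = json.loads((directory / "meta.json").read_text())
    segments = [
        Segment(
            data=np.load(directory / f"clip_{int(r.clip_id):05d}.npy"),
            label=str(r.label),
            group_id=int(r.group_id),
        )
        for r in manifest.itertuples()
    ]
    return SegmentedDataset(segments=segments, fs=meta["fs"], segment_duration=meta["segment_duration"])


def read_edf(
    path: str | Path,
    channels: list[str] | None = None,
    annotation_keyword: str = "seiz",
) -> Recording:
    """Read a continuous EDF recording (requires the optional ``mne`` extra).

    Seizure onsets are taken from annotations whose description contains
    ``annotation_keyword`` (case-insensitive).
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading EDF requires the optional dependency mne") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if channels is not None:
        missing = [c for c in channels if c not in raw.ch_names]
        if missing:
            raise DataError(f"channels not in EDF: {missing}")
        raw.pick(channels)
    onsets = [
        float(onset)
        for onset, desc in zip(raw.annotations.onset, raw.annotations.description)
        if annotation_keyword.lower() in str(desc).lower()
    ]
    return Recording(
        signal=raw.get_data() * 1e6,  # volts -> microvolts
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        seizure_onsets=np.asarray(sorted(onsets), dtype=float),
    )


def feature_matrix_to_csv(fm: FeatureMatrix, path: str | Path) -> None:
    fm.to_dataframe().to_csv(path, index=False)


def registry_to_json(registry: FeatureRegistry, path: str | Path) -> None:
    payload = [
        {"name": d.name, "family": d.family, "parameters": d.parameters}
        for d in registry.descriptors
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def model_to_json(model: ModelSpec, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=2))
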