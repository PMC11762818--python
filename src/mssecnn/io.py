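"""HDF5/CSV/EDF exchange for recordings, datasets and feature tensors.

Layout of a dataset container:

    /recordings/<name>        float64 dataset, channels × samples
        attrs: fs, label, subject_id, channel_labels, seed (optional)

Feature containers hold one dataset per segment with attrs label, subject_id,
band_order and the PCMI parameters, so a training run is fully reconstructable
from the file alone.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .pcmi import FeatureTensor, PcmiParams
from .synthgen import LabeledDataset, RawRecording

__all__ = [
    "write_recording",
    "read_recording",
    "write_dataset",
    "read_dataset",
    "write_feature_tensors",
    "read_feature_tensors",
    "read_edf",
]


def write_recording(group: h5py.Group, rec: RawRecording, seed: int | None = None):
    d = group.create_dataset("data", data=rec.data)
    d.attrs["fs"] = rec.fs
    d.attrs["label"] = rec.label
    d.attrs["subject_id"] = rec.subject_id
    d.attrs["channel_labels"] = [s.encode() for s in rec.channel_labels]
    if seed is not None:
        d.attrs["seed"] = seed


def read_recording(group: h5py.Group) -> RawRecording:
    d = group["data"]
    return RawRecording(
        data=d[...],
        fs=float(d.attrs["fs"]),
        channel_labels=[
            s.decode() if isinstance(s, bytes) else str(s)
            for s in d.attrs["channel_labels"]
        ],
        label=str(d.attrs["label"]),
        subject_id=str(d.attrs["subject_id"]),
    )


def write_dataset(path: str | Path, ds: LabeledDataset) -> None:
    """Dataset to HDF5 (one group per recording) plus a CSV manifest alongside."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        grp = f.create_group("recordings")
        for i, rec in enumerate(ds.recordings):
            seed = int(ds.manifest.iloc[i]["seed"]) if "seed" in ds.manifest else None
            write_recording(grp.create_group(f"rec{i:04d}"), rec, seed=seed)
    ds.manifest.to_csv(path.with_suffix(".manifest.csv"), index=False)


def read_dataset(path: str | Path) -> LabeledDataset:
    path = Path(path)
    recs = []
    with h5py.File(path, "r") as f:
        grp = f["recordings"]
        for name in sorted(grp):
            recs.append(read_recording(grp[name]))
    mpath = path.with_suffix(".manifest.csv")
    if mpath.exists():
        manifest = pd.read_csv(mpath)
    else:
        manifest = pd.DataFrame(
            [{"subject_id": r.subject_id, "label": r.label, "seed": -1} for r in recs]
        )
    return LabeledDataset(recordings=recs, manifest=manifest)


def write_segments(path: str | Path, segments) -> None:
    """Band-decomposed analysis windows to HDF5 (one group per segment)."""
    with h5py.File(path, "w") as f:
        for i, seg in enumerate(segments):
            g = f.create_group(f"seg{i:05d}")
            g.attrs["fs"] = seg.fs
            g.attrs["window_s"] = seg.window_s
            g.attrs["start_s"] = seg.start_s
            g.attrs["label"] = seg.label
            g.attrs["subject_id"] = seg.subject_id
            g.attrs["band_names"] = [b.encode() for b in seg.band_names]
            for band in seg.band_names:
                g.create_dataset(band, data=seg.data[band])


def read_segments(path: str | Path):
    from .preprocess import Segment

    out = []
    with h5py.File(path, "r") as f:
        for name in sorted(f):
            g = f[name]
            bands = [
                b.decode() if isinstance(b, bytes) else str(b)
                for b in g.attrs["band_names"]
            ]
            out.append(
                Segment(
                    data={b: g[b][...] for b in bands},
                    fs=float(g.attrs["fs"]),
                    band_names=bands,
                    window_s=float(g.attrs["window_s"]),
                    start_s=float(g.attrs["start_s"]),
                    label=str(g.attrs["label"]),
                    subject_id=str(g.attrs["subject_id"]),
                )
            )
    return out


def write_feature_tensors(path: str | Path, tensors: list[FeatureTensor]) -> None:
    with h5py.File(path, "w") as f:
        for i, t in enumerate(tensors):
            d = f.create_dataset(f"seg{i:05d}", data=t.values)
            d.attrs["label"] = t.label
            d.attrs["subject_id"] = t.subject_id
            d.attrs["band_order"] = [b.encode() for b in t.band_order]
            d.attrs["pcmi_params"] = json.dumps(
                {
                    "m": t.params.m,
                    "tau": t.params.tau,
                    "delta_set": list(t.params.delta_set),
                    "pseudo_count": t.params.pseudo_count,
                }
            )


def read_feature_tensors(path: str | Path) -> list[FeatureTensor]:
    out = []
    with h5py.File(path, "r") as f:
        for name in sorted(f):
            d = f[name]
            pp = json.loads(d.attrs["pcmi_params"])
            pp["delta_set"] = tuple(pp["delta_set"])
            out.append(
                FeatureTensor(
                    values=d[...],
                    band_order=tuple(
                        b.decode() if isinstance(b, bytes) else str(b)
                        for b in d.attrs["band_order"]
                    ),
                    label=str(d.attrs["label"]),
                    subject_id=str(d.attrs["subject_id"]),
                    params=PcmiParams(**pp),
                )
            )
    return out


def tensors_to_arrays(
    tensors: list[FeatureTensor],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack tensors into (X, y, subjects); label 'post' maps to class 1."""
    X = np.stack([t.values for t in tensors])
    y = np.array([1 if t.label == "post" else 0 for t in tensors])
    subjects = np.array([t.subject_id for t in tensors])
    return X, y, subjects


def read_edf(path: str | Path, label: str = "unknown", subject_id: str = "edf") -> RawRecording:
    """Entry point for real EEG: load an EDF file as a RawRecording (µV)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> µV
    return RawRecording(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        label=label,
        subject_id=subject_id,
    )
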