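"""Serialization: portable array bundles (NPZ + JSON sidecar) and an
MNE FIF epochs dialect for interoperability with standard EEG tooling.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .containers import ChannelLayout, EpochSet, StandardizationRecord
from .decoding import TemporalGeneralizationMatrix
from .forward_model import TopographyMap
from .group_stats import StatResult

__all__ = [
    "save_epochs_bundle",
    "load_epochs_bundle",
    "save_epochs_fif",
    "load_epochs_fif",
    "load_epochs",
    "save_tgm",
    "load_tgm",
    "save_topography",
    "save_stat_result",
]

PathLike = Union[str, Path]


def save_epochs_bundle(epochs: EpochSet, path: PathLike) -> Path:
    """Write an EpochSet as ``<path>.npz`` plus ``<path>.json`` sidecar."""
    path = Path(path)
    base = path.with_suffix("") if path.suffix == ".npz" else path
    arrays = {
        "data": epochs.data,
        "times": epochs.times,
        "labels": epochs.labels,
        "positions": epochs.layout.positions,
    }
    if epochs.standardization is not None:
        rec = epochs.standardization
        arrays.update(std_means=rec.means, std_scales=rec.scales,
                      std_flagged=rec.flagged)
    np.savez_compressed(base.with_suffix(".npz"), **arrays)
    sidecar = {
        "state": epochs.state,
        "subject": int(epochs.subject),
        "sfreq": float(epochs.sfreq),
        "contrast": epochs.contrast,
        "channel_names": list(epochs.layout.names),
        "units": "uV" if epochs.standardization is None else "standardized",
        "log": list(epochs.log),
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return base.with_suffix(".npz")


def load_epochs_bundle(path: PathLike) -> EpochSet:
    base = Path(path)
    if base.suffix == ".npz":
        base = base.with_suffix("")
    with np.load(base.with_suffix(".npz")) as z:
        arrays = {k: z[k] for k in z.files}
    meta = json.loads(base.with_suffix(".json").read_text())
    layout = ChannelLayout(arrays["positions"], tuple(meta["channel_names"]))
    std = None
    if "std_means" in arrays:
        std = StandardizationRecord(
            means=arrays["std_means"], scales=arrays["std_scales"],
            flagged=arrays["std_flagged"].astype(bool),
        )
    return EpochSet(
        data=arrays["data"], times=arrays["times"], labels=arrays["labels"],
        state=meta["state"], subject=meta["subject"], sfreq=meta["sfreq"],
        layout=layout, contrast=meta.get("contrast"),
        standardization=std, log=list(meta.get("log", [])),
    )


def save_epochs_fif(epochs: EpochSet, path: PathLike) -> Path:
    """Write as an MNE epochs FIF file (data converted from µV to V).

    Condition labels are stored as event codes 1 (label 0) and 2
    (label 1); 2-D disc positions become head-frame digitization points
    at z = 0.
    """
    import mne

    path = Path(path)
    if not path.name.endswith("-epo.fif"):
        path = path.with_name(path.stem + "-epo.fif")
    info = mne.create_info(list(epochs.layout.names), epochs.sfreq, "eeg")
    montage = mne.channels.make_dig_montage(
        ch_pos={
            name: np.array([p[0] * 0.1, p[1] * 0.1, 0.0])
            for name, p in zip(epochs.layout.names, epochs.layout.positions)
        },
        coord_frame="head",
    )
    events = np.column_stack([
        np.arange(epochs.n_trials) * epochs.n_samples,
        np.zeros(epochs.n_trials, dtype=int),
        epochs.labels + 1,
    ]).astype(int)
    ep = mne.EpochsArray(
        epochs.data * 1e-6, info, events=events, tmin=float(epochs.times[0]),
        event_id={"cond0": 1, "cond1": 2}, verbose="error",
    )
    ep.set_montage(montage, verbose="error")
    ep.save(path, overwrite=True, verbose="error")
    return path


def load_epochs_fif(
    path: PathLike, state: str = "WAKE", subject: int = 0,
    contrast: Optional[str] = None,
) -> EpochSet:
    """Read an MNE FIF epochs file back into an EpochSet (µV).

    State/subject/contrast metadata are not part of the FIF dialect and
    must be supplied by the caller (or recovered from the filename).
    """
    import mne

    ep = mne.read_epochs(Path(path), preload=True, verbose="error")
    montage = ep.get_montage()
    pos3d = np.array([montage.get_positions()["ch_pos"][ch] for ch in ep.ch_names])
    layout = ChannelLayout(pos3d[:, :2] / 0.1, tuple(ep.ch_names))
    labels = ep.events[:, 2] - 1
    return EpochSet(
        data=ep.get_data(copy=True) * 1e6, times=ep.times, labels=labels,
        state=state, subject=subject, sfreq=float(ep.info["sfreq"]),
        layout=layout, contrast=contrast,
    )


def load_epochs(path: PathLike, **meta) -> EpochSet:
    """Dispatch on extension: .npz/.json bundle or -epo.fif."""
    path = Path(path)
    if path.name.endswith(".fif"):
        return load_epochs_fif(path, **meta)
    return load_epochs_bundle(path)


def save_tgm(tgm: TemporalGeneralizationMatrix, path: PathLike) -> Path:
    base = Path(path)
    if base.suffix == ".npz":
        base = base.with_suffix("")
    np.savez_compressed(
        base.with_suffix(".npz"), scores=tgm.scores,
        train_times=tgm.train_times, test_times=tgm.test_times,
    )
    base.with_suffix(".json").write_text(json.dumps({
        "train_state": tgm.train_state, "test_state": tgm.test_state,
        "subject": int(tgm.subject), "n_folds": tgm.n_folds,
        "contrast": tgm.contrast,
    }, indent=1))
    return base.with_suffix(".npz")


def load_tgm(path: PathLike) -> TemporalGeneralizationMatrix:
    base = Path(path)
    if base.suffix == ".npz":
        base = base.with_suffix("")
    with np.load(base.with_suffix(".npz")) as z:
        scores, tr, te = z["scores"], z["train_times"], z["test_times"]
    meta = json.loads(base.with_suffix(".json").read_text())
    return TemporalGeneralizationMatrix(
        scores=scores, train_times=tr, test_times=te,
        train_state=meta["train_state"], test_state=meta["test_state"],
        subject=meta["subject"], n_folds=meta["n_folds"],
        contrast=meta.get("contrast"),
    )


def save_topography(topo: TopographyMap, path: PathLike) -> Path:
    base = Path(path)
    if base.suffix == ".npz":
        base = base.with_suffix("")
    np.savez_compressed(
        base.with_suffix(".npz"), patterns=topo.patterns, times=topo.times,
        positions=topo.layout.positions,
    )
    base.with_suffix(".json").write_text(json.dumps({
        "state": topo.state, "contrast": topo.contrast, "units": topo.units,
        "channel_names": list(topo.layout.names),
    }, indent=1))
    return base.with_suffix(".npz")


def save_stat_result(stat: StatResult, path: PathLike) -> Path:
    base = Path(path)
    if base.suffix == ".npz":
        base = base.with_suffix("")
    np.savez_compressed(base.with_suffix(".npz"), pvals=stat.pvals, mask=stat.mask)
    base.with_suffix(".json").write_text(json.dumps({
        "q": stat.q, "test_name": stat.test_name,
        "n_subjects": stat.n_subjects, "family_size": stat.family_size,
    }, indent=1))
    return base.with_suffix(".npz")
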