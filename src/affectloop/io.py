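"""HDF5 persistence for trial datasets.

Layout of a task file::

    /participant            group, attrs: participant parameters
    /trials/trial_000       dataset (channels, samples) float32 EEG
        attrs: fs, pre_listen_duration, listen_duration,
               generator_input, sam_label, markers_json, channels

EEG is stored as float32 with gzip compression; everything else round
trips exactly.  ``load_task`` reconstructs a :class:`TaskDataset`,
including the participant's generative parameters, so a saved synthetic
cohort can later be re-featurized or extended.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .autodiff import Tensor
from .cohort import EmotionPoint, ParticipantModel, TaskDataset, TrialRecord
from .nets import CnnParams, FusionParams

__all__ = [
    "save_task", "load_task", "save_cohort", "load_cohort",
    "save_models", "load_models",
]

_PARTICIPANT_ARRAYS = ("gain", "baseline_logvar", "affect_gain",
                       "affect_offset", "rest_emotion")


def _write_participant(grp, p: ParticipantModel) -> None:
    grp.attrs["participant_id"] = p.participant_id
    grp.attrs["noise_scale"] = p.noise_scale
    grp.attrs["label_noise"] = p.label_noise
    grp.attrs["seed"] = p.seed
    for name in _PARTICIPANT_ARRAYS:
        grp.create_dataset(name, data=getattr(p, name))


def _read_participant(grp) -> ParticipantModel:
    arrays = {name: np.asarray(grp[name]) for name in _PARTICIPANT_ARRAYS}
    return ParticipantModel(
        participant_id=str(grp.attrs["participant_id"]),
        noise_scale=float(grp.attrs["noise_scale"]),
        label_noise=float(grp.attrs["label_noise"]),
        seed=int(grp.attrs["seed"]),
        **arrays,
    )


def _write_trial(grp, name, t: TrialRecord) -> None:
    ds = grp.create_dataset(
        name, data=t.eeg.astype(np.float32), compression="gzip", compression_opts=4
    )
    ds.attrs["fs"] = t.fs
    ds.attrs["pre_listen_duration"] = t.pre_listen_duration
    ds.attrs["listen_duration"] = t.listen_duration
    ds.attrs["generator_input"] = t.generator_input.as_array()
    ds.attrs["sam_label"] = t.sam_label.as_array()
    ds.attrs["markers_json"] = json.dumps({k: int(v) for k, v in t.markers.items()})
    ds.attrs["channels"] = [str(c) for c in t.channels]


def _read_trial(ds) -> TrialRecord:
    gi = np.asarray(ds.attrs["generator_input"], float)
    lab = np.asarray(ds.attrs["sam_label"], float)
    return TrialRecord(
        eeg=np.asarray(ds, dtype=float),
        fs=float(ds.attrs["fs"]),
        pre_listen_duration=float(ds.attrs["pre_listen_duration"]),
        listen_duration=float(ds.attrs["listen_duration"]),
        generator_input=EmotionPoint.from_array(gi),
        sam_label=EmotionPoint.from_array(lab),
        markers=json.loads(ds.attrs["markers_json"]),
        channels=[str(c) for c in ds.attrs["channels"]],
    )


def _write_task(root, task: TaskDataset) -> None:
    _write_participant(root.create_group("participant"), task.participant)
    trials = root.create_group("trials")
    for i, t in enumerate(task.trials):
        _write_trial(trials, f"trial_{i:03d}", t)


def _read_task(root) -> TaskDataset:
    participant = _read_participant(root["participant"])
    trials = [_read_trial(root["trials"][k]) for k in sorted(root["trials"])]
    return TaskDataset(participant=participant, trials=trials)


def save_task(path, task: TaskDataset) -> None:
    """Write one participant's trials to an HDF5 file."""
    with h5py.File(path, "w") as fh:
        _write_task(fh, task)


def load_task(path) -> TaskDataset:
    with h5py.File(path, "r") as fh:
        return _read_task(fh)


def save_cohort(path, tasks) -> None:
    """Write a list of tasks to one HDF5 file (groups task_000, ...)."""
    with h5py.File(path, "w") as fh:
        for i, task in enumerate(tasks):
            _write_task(fh.create_group(f"task_{i:03d}"), task)


def load_cohort(path) -> list:
    with h5py.File(path, "r") as fh:
        return [_read_task(fh[k]) for k in sorted(fh)]


# ---------------------------------------------------------------------
# trained models (npz)


def save_models(path, cnn: CnnParams | None = None,
                fusion: FusionParams | None = None) -> None:
    """Write CNN and/or fusion parameters to one ``.npz`` file."""
    if cnn is None and fusion is None:
        raise ValueError("nothing to save")
    arrays = {}
    if cnn is not None:
        for i, t in enumerate(cnn.tensors):
            arrays[f"cnn_t{i:02d}"] = t.data
        for i, (m, v) in enumerate(cnn.running):
            arrays[f"cnn_rm{i:02d}"] = m
            arrays[f"cnn_rv{i:02d}"] = v
    if fusion is not None:
        for i, t in enumerate(fusion.tensors):
            arrays[f"fus_t{i:02d}"] = t.data
        arrays["fus_dropout"] = np.asarray(fusion.dropout_rate)
    np.savez(path, **arrays)


def load_models(path):
    """Read ``(cnn, fusion)`` from an ``.npz`` written by :func:`save_models`.

    Either element is None when absent from the file.
    """
    with np.load(path) as z:
        keys = sorted(z.files)
        cnn = fusion = None
        cnn_t = [k for k in keys if k.startswith("cnn_t")]
        if cnn_t:
            tensors = [Tensor(z[k].copy(), requires_grad=True) for k in cnn_t]
            rm = [k for k in keys if k.startswith("cnn_rm")]
            rv = [k for k in keys if k.startswith("cnn_rv")]
            running = [(z[m].copy(), z[v].copy()) for m, v in zip(rm, rv)]
            cnn = CnnParams(tensors=tensors, running=running)
        fus_t = [k for k in keys if k.startswith("fus_t")]
        if fus_t:
            tensors = [Tensor(z[k].copy(), requires_grad=True) for k in fus_t]
            fusion = FusionParams(
                tensors=tensors, dropout_rate=float(z["fus_dropout"])
            )
    return cnn, fusion
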