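"""Core data containers: single-subject recordings and co-registered ensembles.

A :class:`Recording` is one subject's multichannel voltage time series plus
the metadata needed to align it to a common stimulus time base.  A
:class:`StimulusEnsemble` is the co-registered set of speaker and listener
recordings for one stimulus, together with the listener -> attended-speaker
assignment that defines the two attention groups.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Any, Mapping, Sequence

import h5py
import numpy as np

__all__ = ["Recording", "StimulusEnsemble"]


@dataclass
class Recording:
    """One subject's aligned multichannel voltage time series.

    Parameters
    ----------
    data : ndarray, shape (n_times, n_channels)
        Voltages in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
        Unique channel labels (10/20 names for real EEG).
    subject_id : str
        Subject identifier.
    role : {"speaker", "listener"}
    t0_offset : float
        Start time of this recording relative to the stimulus reference, in
        seconds.  Positive means the recording starts later.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    subject_id: str
    role: str = "listener"
    t0_offset: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (time x channels) array")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length must match channel count")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel_names must be unique")
        if self.role not in ("speaker", "listener"):
            raise ValueError(f"role must be 'speaker' or 'listener', got {self.role!r}")

    @property
    def n_times(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_times / self.fs

    def copy_with(self, **kwargs: Any) -> "Recording":
        return replace(self, **kwargs)


@dataclass
class StimulusEnsemble:
    """Co-registered speaker and listener recordings for one stimulus.

    All recordings share the sampling rate, channel count and (after
    trimming) length.  ``group_assignment`` maps each listener id to the id
    of the speaker that listener attended; it partitions the listeners into
    the two attention groups.

    ``ground_truth`` is only populated by the synthetic generator and holds
    the planted components for recovery tests.
    """

    speakers: dict[str, Recording]
    listeners: dict[str, Recording]
    group_assignment: dict[str, str]
    manifest: Any = None
    ground_truth: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.group_assignment) != set(self.listeners):
            raise ValueError("group_assignment must cover exactly the listeners")
        unknown = set(self.group_assignment.values()) - set(self.speakers)
        if unknown:
            raise ValueError(f"group_assignment targets unknown speakers: {unknown}")
        lengths = {r.n_times for r in self.all_recordings()}
        if len(lengths) > 1:
            raise ValueError("all recordings in an ensemble must share a length")
        rates = {r.fs for r in self.all_recordings()}
        if len(rates) > 1:
            raise ValueError("all recordings in an ensemble must share a sampling rate")

    # -- convenience accessors ------------------------------------------------

    def all_recordings(self) -> list[Recording]:
        return list(self.speakers.values()) + list(self.listeners.values())

    @property
    def fs(self) -> float:
        return next(iter(self.speakers.values())).fs

    @property
    def n_times(self) -> int:
        return next(iter(self.speakers.values())).n_times

    @property
    def n_channels(self) -> int:
        return next(iter(self.speakers.values())).n_channels

    @property
    def speaker_ids(self) -> list[str]:
        return sorted(self.speakers)

    @property
    def listener_ids(self) -> list[str]:
        return sorted(self.listeners)

    def listener_array(self) -> np.ndarray:
        """Stack listeners as (n_listeners, n_times, n_channels), sorted by id."""
        return np.stack([self.listeners[lid].data for lid in self.listener_ids])

    def group_labels(self) -> np.ndarray:
        """Attended-speaker id per listener, aligned with :meth:`listener_array`."""
        return np.asarray([self.group_assignment[lid] for lid in self.listener_ids])

    def group_members(self) -> dict[str, list[str]]:
        groups: dict[str, list[str]] = {sid: [] for sid in self.speaker_ids}
        for lid in self.listener_ids:
            groups[self.group_assignment[lid]].append(lid)
        return groups

    # -- construction ---------------------------------------------------------

    @classmethod
    def from_recordings(
        cls,
        recordings: Sequence[Recording],
        group_assignment: Mapping[str, str],
        manifest: Any = None,
    ) -> "StimulusEnsemble":
        """Build an ensemble from offset-annotated recordings, trimming to overlap."""
        from .preprocess import trim_to_overlap

        trimmed = trim_to_overlap(recordings)
        speakers = {r.subject_id: r for r in trimmed if r.role == "speaker"}
        listeners = {r.subject_id: r for r in trimmed if r.role == "listener"}
        return cls(speakers, listeners, dict(group_assignment), manifest=manifest)

    # -- HDF5 container -------------------------------------------------------
    #
    # Layout:  /speakers/<id>/data, /listeners/<id>/data,
    #          /meta  with attrs fs, channels, group assignment, manifest JSON.

    def to_hdf5(self, path: str) -> None:
        from .synthetic import PlantManifest

        with h5py.File(path, "w") as f:
            for group_name, recs in (("speakers", self.speakers), ("listeners", self.listeners)):
                g = f.create_group(group_name)
                for sid, rec in recs.items():
                    gg = g.create_group(sid)
                    gg.create_dataset("data", data=rec.data)
                    gg.attrs["t0_offset"] = rec.t0_offset
            meta = f.create_group("meta")
            meta.attrs["fs"] = self.fs
            meta.attrs["channels"] = json.dumps(
                next(iter(self.speakers.values())).channel_names
            )
            meta.attrs["group_assignment"] = json.dumps(self.group_assignment)
            if self.manifest is not None:
                m = self.manifest
                manifest_dict = m.to_dict() if isinstance(m, PlantManifest) else dict(m)
                meta.attrs["manifest"] = json.dumps(manifest_dict)

    @classmethod
    def from_hdf5(cls, path: str) -> "StimulusEnsemble":
        from .synthetic import PlantManifest

        with h5py.File(path, "r") as f:
            meta = f["meta"]
            fs = float(meta.attrs["fs"])
            channels = json.loads(meta.attrs["channels"])
            assignment = json.loads(meta.attrs["group_assignment"])
            manifest = None
            if "manifest" in meta.attrs:
                manifest = PlantManifest.from_dict(json.loads(meta.attrs["manifest"]))

            def load(group_name: str, role: str) -> dict[str, Recording]:
                out = {}
                for sid in f[group_name]:
                    gg = f[group_name][sid]
                    out[sid] = Recording(
                        data=gg["data"][()],
                        fs=fs,
                        channel_names=channels,
                        subject_id=sid,
                        role=role,
                        t0_offset=float(gg.attrs.get("t0_offset", 0.0)),
                    )
                return out

            return cls(load("speakers", "speaker"), load("listeners", "listener"),
                       assignment, manifest=manifest)
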