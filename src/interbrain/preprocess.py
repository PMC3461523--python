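"""Temporal alignment, nuisance removal, filtering, and ICA-ratings cleanup.

Speaker and listener EEG are recorded separately; they are brought onto a
common stimulus time base by cross-correlating a low-quality audio copy
embedded in the EEG amplifier with the reference audio track.  The audio is
then regressed out of the EEG channels (amplifier cross-talk), line noise
is notched out, and recordings are trimmed to their overlapping segment.

Artifactual ICA components are removed through a ratings-driven harness:
human raters score each component on a 1-4 contamination scale and
components rated strictly above threshold (default 3.0, "predominantly
artifact") are zeroed before back-projection.  Inter-rater reliability is
summarized by the intraclass correlation coefficient ICC(2,1) (two-way
random effects, absolute agreement, single rater).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .containers import Recording
from .exceptions import DegenerateInputError, NoOverlapError

__all__ = [
    "ComponentRatings", "estimate_audio_offset", "regress_out", "notch_filter",
    "trim_to_overlap", "remove_rated_components", "icc", "read_wav",
    "read_eeg", "read_ratings_csv",
]


@dataclass
class ComponentRatings:
    """Per-ICA-component mean contamination rating on the 1-4 scale.

    The rating scheme is a 7-point scale in increments of 0.5 from
    1 ("pure neurogenic") to 4 ("pure artifact"); means of several raters
    therefore also live in [1, 4].
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("ratings must be a 1-D array (one value per component)")
        if np.any(self.values < 1.0) or np.any(self.values > 4.0):
            raise ValueError("ratings must lie in [1, 4]")

    def __len__(self) -> int:
        return len(self.values)


def estimate_audio_offset(eeg_audio: np.ndarray, reference_audio: np.ndarray,
                          fs: float) -> float:
    """Estimate the start-time offset of ``eeg_audio`` relative to the reference.

    The offset is the lag maximizing the absolute value of the full
    cross-correlation (absolute value, so a polarity-inverted audio channel
    aligns identically).  Positive return value means the EEG recording
    started *later* than the reference.

    Both signals must already share the sampling rate ``fs``.
    """
    x = np.asarray(eeg_audio, dtype=float).ravel()
    y = np.asarray(reference_audio, dtype=float).ravel()
    if min(len(x), len(y)) < fs:
        raise ValueError("signals must overlap by at least 1 s")
    if not np.any(x) or not np.any(y):
        raise DegenerateInputError("all-zero audio signal")
    x = x - x.mean()
    y = y - y.mean()
    c = sps.correlate(x, y, mode="full")
    lags = sps.correlation_lags(len(x), len(y), mode="full")
    # c peaks at lag L with eeg[n + L] ~ ref[n]; an EEG started D seconds
    # late satisfies eeg[n - D*fs] ~ ref[n], hence offset = -L / fs
    best = lags[np.argmax(np.abs(c))]
    return -float(best) / fs


def regress_out(recording: Recording, nuisance: np.ndarray) -> Recording:
    """Remove a nuisance signal (e.g. the stimulus audio) from every channel.

    Each channel is replaced by its least-squares residual after projecting
    onto the nuisance (plus an intercept), so the residual has exactly zero
    sample covariance with the nuisance.
    """
    z = np.asarray(nuisance, dtype=float).ravel()
    if len(z) != recording.n_times:
        raise ValueError("nuisance length must match the recording")
    if np.std(z) == 0:
        raise ValueError("constant nuisance signal cannot be regressed out")
    design = np.column_stack([np.ones_like(z), z])
    coef, *_ = np.linalg.lstsq(design, recording.data, rcond=None)
    return recording.copy_with(data=recording.data - design @ coef)


def notch_filter(recording: Recording, base_hz: float = 50.0,
                 n_harmonics: int = 1, q: float = 35.0) -> Recording:
    """Zero-phase IIR notch at ``base_hz`` and its first harmonics.

    Second-order notches (quality factor ``q``) applied forward-backward,
    so phase is preserved and stop-band attenuation doubles in dB.
    """
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    if base_hz * n_harmonics >= recording.fs / 2:
        raise ValueError("highest notch frequency must be below Nyquist")
    data = recording.data
    for m in range(1, n_harmonics + 1):
        b, a = sps.iirnotch(m * base_hz, q, fs=recording.fs)
        data = sps.filtfilt(b, a, data, axis=0)
    return recording.copy_with(data=data)


def trim_to_overlap(recordings: Sequence[Recording]) -> list[Recording]:
    """Trim offset-annotated recordings to their common time segment.

    The overlap is ``[max start, min end)`` in stimulus time.  All returned
    recordings have identical length and ``t0_offset`` equal to the overlap
    start, so the operation is idempotent.
    """
    if len(recordings) < 2:
        raise ValueError("need at least two recordings to align")
    if len({r.fs for r in recordings}) != 1:
        raise ValueError("recordings must share a sampling rate")
    fs = recordings[0].fs
    start = max(r.t0_offset for r in recordings)
    end = min(r.t0_offset + r.duration for r in recordings)
    if end <= start:
        raise NoOverlapError("recordings share no common time segment")
    starts = [int(round((start - r.t0_offset) * fs)) for r in recordings]
    n_keep = min(r.n_times - i0 for r, i0 in zip(recordings, starts))
    return [
        r.copy_with(data=r.data[i0:i0 + n_keep], t0_offset=start)
        for r, i0 in zip(recordings, starts)
    ]


def remove_rated_components(recording: Recording, unmixing: np.ndarray,
                            mixing: np.ndarray, ratings: ComponentRatings,
                            threshold: float = 3.0,
                            eog_channel: str | None = None) -> Recording:
    """Zero artifact-rated ICA components and back-project.

    Components with mean rating strictly greater than ``threshold``
    ("purely or predominantly artifact") are removed; a component rated
    exactly at threshold is retained.  If ``eog_channel`` is given, that
    channel is discarded from the reconstructed recording.
    """
    unmixing = np.asarray(unmixing, dtype=float)
    mixing = np.asarray(mixing, dtype=float)
    k, c = unmixing.shape
    if c != recording.n_channels or mixing.shape != (c, k):
        raise ValueError("unmixing must be (components x channels) and "
                         "mixing (channels x components) matching the recording")
    if len(ratings) != k:
        raise ValueError("one rating per component is required")
    sources = recording.data @ unmixing.T
    sources[:, ratings.values > threshold] = 0.0
    data = sources @ mixing.T
    names = list(recording.channel_names)
    if eog_channel is not None:
        if eog_channel not in names:
            raise ValueError(f"unknown EOG channel {eog_channel!r}")
        idx = names.index(eog_channel)
        data = np.delete(data, idx, axis=1)
        names.remove(eog_channel)
    return recording.copy_with(data=data, channel_names=names)


def icc(ratings: np.ndarray) -> float:
    """Intraclass correlation ICC(2,1): two-way random effects, absolute
    agreement, single rater (Shrout & Fleiss convention).

    Parameters
    ----------
    ratings : ndarray, shape (n_raters, n_items)
    """
    r = np.asarray(ratings, dtype=float)
    if r.ndim != 2 or r.shape[0] < 2 or r.shape[1] < 2:
        raise ValueError("need at least 2 raters and 2 items")
    x = r.T  # items x raters
    n, k = x.shape
    gm = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - gm) ** 2)
    ssc = n * np.sum((col_means - gm) ** 2)
    sse = np.sum((x - gm) ** 2) - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    scale = max(1.0, gm ** 2)
    if msr < 1e-12 * scale and mse < 1e-12 * scale:
        raise DegenerateInputError(
            "no between-item variance beyond rater offsets; ICC undefined")
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    return float((msr - mse) / denom)


# -- file readers -------------------------------------------------------------

def read_wav(path: str) -> tuple[float, np.ndarray]:
    """Read a WAV audio file as (fs, mono float signal)."""
    from scipy.io import wavfile

    fs, data = wavfile.read(path)
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data.mean(axis=1)
    return float(fs), data


def read_eeg(path: str, subject_id: str, role: str = "listener") -> Recording:
    """Read a BrainVision (.vhdr) or EDF recording into a :class:`Recording`.

    Requires the optional ``mne`` dependency.  Voltages are returned in
    microvolts.
    """
    import mne  # optional dependency, imported lazily

    if path.endswith(".vhdr"):
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    elif path.endswith((".edf", ".EDF")):
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    else:
        raise ValueError("expected a .vhdr (BrainVision) or .edf file")
    return Recording(
        data=raw.get_data().T * 1e6,
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        subject_id=subject_id,
        role=role,
    )


def read_ratings_csv(path: str) -> tuple[ComponentRatings, np.ndarray]:
    """Read a ratings CSV (component_id, rater_id, rating).

    Returns the per-component mean ratings (ordered by component id) and
    the raters x items matrix for reliability assessment.
    """
    df = pd.read_csv(path)
    required = {"component_id", "rater_id", "rating"}
    if not required.issubset(df.columns):
        raise ValueError(f"ratings CSV must have columns {sorted(required)}")
    pivot = df.pivot_table(index="rater_id", columns="component_id",
                           values="rating").sort_index(axis=1)
    if pivot.isna().any().any():
        raise ValueError("every rater must rate every component")
    means = ComponentRatings(pivot.mean(axis=0).to_numpy())
    return means, pivot.to_numpy()
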