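"""Synthetic dual-EEG ensembles with planted speaker-listener coupling.

No public data accompany the experimental design this package analyses, so
every downstream stage is exercised on generated ensembles whose structure
is known exactly.  The generator emulates the design's key manipulation:
all listeners receive identical sensory input, but the two listener groups
attend to different speakers.  Each listener's signal is a sum of

* a low-variance *content* component -- the attended speaker's latent
  story signal, delayed by a configurable lag and mixed into the scalp
  channels through a group-level spatial pattern (homologous to the
  speaker's own pattern, or an unrelated random one);
* a *sensory* component built from both speakers' latents, identical
  across ALL listeners regardless of attention (stimulus-driven activity);
* dominant spatially-correlated background noise.

Variance fractions are enforced by post-hoc scaling against the realized
noise power, so ``effect_fraction`` is interpretable directly as the
proportion of a listener's total variance contributed by content.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .containers import Recording, StimulusEnsemble

__all__ = ["LatentContent", "PlantManifest", "generate_latent", "generate_ensemble"]

_SPECTRA = ("white", "pink", "brown")


@dataclass
class LatentContent:
    """A latent multivariate story signal: time x d, standardized columns."""

    samples: np.ndarray
    fs: float
    seed: int

    @property
    def n_times(self) -> int:
        return self.samples.shape[0]

    @property
    def d(self) -> int:
        return self.samples.shape[1]


@dataclass
class PlantManifest:
    """Ground-truth parameters of a synthetic ensemble.

    Parameters
    ----------
    effect_fraction : float
        Target fraction of each listener's variance contributed by the
        content component (the attended speaker's delayed latent).
    lag_s : float
        Planted speaker -> listener delay in seconds.  Rounded to the
        nearest sample at generation time.
    mixing_mode : {"homologous", "random"}
        Whether listeners receive the content through the same spatial
        pattern as the speaker's own EEG ("homologous": one-to-one channel
        correlations exist) or through an unrelated random pattern
        ("random": only the multivariate analysis can detect coupling).
    sensory_fraction : float
        Fraction of listener variance from the group-independent
        stimulus-driven component shared by ALL listeners.
    noise_spectrum : {"white", "pink", "brown"}
        Spectral shape of the background noise sources.
    group_assignment : dict or None
        Optional explicit listener id -> speaker id map; by default the
        first half of the listeners attends speaker "S1", the rest "S2".
    d : int
        Latent dimensionality per speaker.
    speaker_content_fraction : float
        Fraction of each speaker's own EEG variance carried by their
        latent (the speaker produces the story, so this is sizeable).
    """

    effect_fraction: float = 0.05
    lag_s: float = 5.0
    mixing_mode: str = "random"
    sensory_fraction: float = 0.2
    noise_spectrum: str = "pink"
    group_assignment: dict[str, str] | None = None
    d: int = 5
    speaker_content_fraction: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 <= self.effect_fraction <= 1.0:
            raise ValueError("effect_fraction must be in [0, 1]")
        if not 0.0 <= self.sensory_fraction <= 1.0:
            raise ValueError("sensory_fraction must be in [0, 1]")
        if self.effect_fraction + self.sensory_fraction >= 1.0:
            raise ValueError("effect_fraction + sensory_fraction must be < 1")
        if self.mixing_mode not in ("homologous", "random"):
            raise ValueError("mixing_mode must be 'homologous' or 'random'")
        if self.noise_spectrum not in _SPECTRA:
            raise ValueError(f"noise_spectrum must be one of {_SPECTRA}")
        if self.d < 1:
            raise ValueError("latent dimensionality d must be >= 1")
        if not 0.0 < self.speaker_content_fraction < 1.0:
            raise ValueError("speaker_content_fraction must be in (0, 1)")

    def to_dict(self) -> dict[str, Any]:
        return {
            "effect_fraction": self.effect_fraction,
            "lag_s": self.lag_s,
            "mixing_mode": self.mixing_mode,
            "sensory_fraction": self.sensory_fraction,
            "noise_spectrum": self.noise_spectrum,
            "group_assignment": self.group_assignment,
            "d": self.d,
            "speaker_content_fraction": self.speaker_content_fraction,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PlantManifest":
        return cls(**d)


def _shaped_noise(rng: np.random.Generator, n: int, cols: int, fs: float,
                  spectrum: str) -> np.ndarray:
    """Column-independent noise with the requested spectral shape.

    Shaping is done in the frequency domain: the rFFT of white noise is
    weighted by an amplitude profile (flat, 1/sqrt(f), or 1/f), with the
    lowest resolvable frequency as a floor so the variance stays finite.
    """
    x = rng.standard_normal((n, cols))
    if spectrum == "white":
        return x
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    f0 = max(fs / n, 1e-12)  # lowest nonzero bin as regularizer
    with np.errstate(divide="ignore"):
        if spectrum == "pink":
            amp = 1.0 / np.sqrt(np.maximum(freqs, f0))
        else:  # brown
            amp = 1.0 / np.maximum(freqs, f0)
    amp[0] = 0.0  # kill DC; signals are mean-free by construction
    spec = np.fft.rfft(x, axis=0) * amp[:, None]
    return np.fft.irfft(spec, n=n, axis=0)


def _standardize(x: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return x / sd


def generate_latent(duration_s: float, fs: float, d: int, seed: int,
                    spectrum: str = "pink") -> LatentContent:
    """Generate a standardized latent story signal.

    Columns have zero mean and unit variance (within 1e-6 after
    standardization); identical arguments give bit-identical output.
    """
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    if d < 1:
        raise ValueError("d must be >= 1")
    n = int(round(duration_s * fs))
    if n < 2:
        raise ValueError("duration_s * fs must be at least 2 samples")
    if spectrum not in _SPECTRA:
        raise ValueError(f"spectrum must be one of {_SPECTRA}")
    rng = np.random.default_rng(seed)
    samples = _standardize(_shaped_noise(rng, n, d, fs, spectrum))
    return LatentContent(samples=samples, fs=fs, seed=seed)


def _mixing(rng: np.random.Generator, n_channels: int, d: int) -> np.ndarray:
    """Random dense mixing with unit-norm columns."""
    a = rng.standard_normal((n_channels, d))
    return a / np.linalg.norm(a, axis=0)


def _spatially_correlated_noise(rng: np.random.Generator, n: int,
                                n_channels: int, fs: float,
                                spectrum: str) -> np.ndarray:
    """Full-rank spatially correlated background noise, unit channel power."""
    sources = _shaped_noise(rng, n, n_channels, fs, spectrum)
    sources /= np.maximum(sources.std(axis=0), 1e-30)
    # smooth random mixing: full rank, correlated channels
    mix = rng.standard_normal((n_channels, n_channels)) / np.sqrt(n_channels)
    mix += 0.5 * np.eye(n_channels)  # keep it comfortably full rank
    noise = sources @ mix.T
    return noise / np.maximum(noise.std(axis=0), 1e-30)


def generate_ensemble(manifest: PlantManifest, n_listeners: int = 12,
                      n_channels: int = 63, duration_s: float = 120.0,
                      fs: float = 100.0, seed: int = 0) -> StimulusEnsemble:
    """Generate a co-registered 2-speaker / ``n_listeners``-listener ensemble.

    The returned ensemble records the manifest and, under
    ``ensemble.ground_truth``, the planted component arrays and realized
    variance fractions for recovery tests.
    """
    if n_listeners < 2 or n_listeners % 2:
        raise ValueError("n_listeners must be even and >= 2")
    n = int(round(duration_s * fs))
    lag_n = int(round(manifest.lag_s * fs))
    if abs(lag_n) >= n:
        raise ValueError("planted lag must be shorter than the recording")
    rng = np.random.default_rng(seed)
    speaker_ids = ["S1", "S2"]
    listener_ids = [f"L{i + 1:02d}" for i in range(n_listeners)]
    if manifest.group_assignment is not None:
        assignment = dict(manifest.group_assignment)
        if sorted(assignment) != listener_ids:
            raise ValueError("group_assignment must cover the generated listeners")
    else:
        half = n_listeners // 2
        assignment = {lid: ("S1" if i < half else "S2")
                      for i, lid in enumerate(listener_ids)}

    d = manifest.d
    n_ext = n + abs(lag_n)
    # latents: extended so the lagged listener copy needs no wrap-around
    latents_ext = {
        sid: _standardize(_shaped_noise(rng, n_ext, d, fs, "pink"))
        for sid in speaker_ids
    }
    # speaker sees samples [lag:], listener the same latent [: n] ->
    # listener trails the speaker by exactly lag_n samples
    if lag_n >= 0:
        latent_speaker = {s: latents_ext[s][lag_n:lag_n + n] for s in speaker_ids}
        latent_listener = {s: latents_ext[s][:n] for s in speaker_ids}
    else:
        latent_speaker = {s: latents_ext[s][:n] for s in speaker_ids}
        latent_listener = {s: latents_ext[s][-lag_n:-lag_n + n] for s in speaker_ids}

    mix_speaker = {s: _mixing(rng, n_channels, d) for s in speaker_ids}
    if manifest.mixing_mode == "homologous":
        mix_listener = {s: mix_speaker[s] for s in speaker_ids}
    else:
        mix_listener = {s: _mixing(rng, n_channels, d) for s in speaker_ids}

    # group-independent stimulus-driven component, built from both latents
    # at presentation (speaker) time
    mix_sensory = _mixing(rng, n_channels, 2 * d)
    sensory_raw = np.concatenate(
        [latent_speaker[s] for s in speaker_ids], axis=1) @ mix_sensory.T

    content_raw = {s: latent_listener[s] @ mix_listener[s].T for s in speaker_ids}
    speaker_content_raw = {s: latent_speaker[s] @ mix_speaker[s].T
                           for s in speaker_ids}

    noise_listener = {lid: _spatially_correlated_noise(
        rng, n, n_channels, fs, manifest.noise_spectrum) for lid in listener_ids}
    noise_speaker = {sid: _spatially_correlated_noise(
        rng, n, n_channels, fs, manifest.noise_spectrum) for sid in speaker_ids}

    # post-hoc scaling so effect_fraction / sensory_fraction hold against
    # the realized (mean) noise power
    p_noise = float(np.mean([noise_listener[lid].var() for lid in listener_ids]))
    total = p_noise / (1.0 - manifest.effect_fraction - manifest.sensory_fraction)
    content = {}
    for s in speaker_ids:
        p_raw = content_raw[s].var()
        scale = (np.sqrt(manifest.effect_fraction * total / p_raw)
                 if manifest.effect_fraction > 0 else 0.0)
        content[s] = scale * content_raw[s]
    p_sens_raw = sensory_raw.var()
    sens_scale = (np.sqrt(manifest.sensory_fraction * total / p_sens_raw)
                  if manifest.sensory_fraction > 0 else 0.0)
    sensory = sens_scale * sensory_raw

    channel_names = [f"ch{i + 1:02d}" for i in range(n_channels)]
    listeners = {}
    realized = {}
    for lid in listener_ids:
        s = assignment[lid]
        data = content[s] + sensory + noise_listener[lid]
        listeners[lid] = Recording(data=data, fs=fs, channel_names=channel_names,
                                   subject_id=lid, role="listener")
        p_c, p_s, p_n = (content[s].var(), sensory.var(),
                         noise_listener[lid].var())
        realized[lid] = p_c / (p_c + p_s + p_n)

    speakers = {}
    for sid in speaker_ids:
        p_n = noise_speaker[sid].var()
        tot_s = p_n / (1.0 - manifest.speaker_content_fraction)
        scale = np.sqrt(manifest.speaker_content_fraction * tot_s
                        / speaker_content_raw[sid].var())
        data = scale * speaker_content_raw[sid] + noise_speaker[sid]
        speakers[sid] = Recording(data=data, fs=fs, channel_names=channel_names,
                                  subject_id=sid, role="speaker")

    ensemble = StimulusEnsemble(speakers=speakers, listeners=listeners,
                                group_assignment=assignment, manifest=manifest)
    ensemble.ground_truth = {
        "content": content,
        "sensory": sensory,
        "noise": noise_listener,
        "lag_samples": lag_n,
        "realized_effect_fraction": realized,
        "mix_listener": mix_listener,
        "mix_speaker": mix_speaker,
    }
    return ensemble
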