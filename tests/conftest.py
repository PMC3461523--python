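"""Shared fixtures: small synthetic ensembles and hand-built toys."""

import numpy as np
import pytest

from interbrain.containers import Recording, StimulusEnsemble
from interbrain.synthetic import PlantManifest, generate_ensemble


def make_toy_ensemble(listener_signals, speaker_signals=None, fs=10.0,
                      group=None):
    """Build an ensemble from explicit per-listener (time x channels) arrays.

    ``listener_signals`` maps listener id -> array; ``group`` maps listener
    id -> speaker id (defaults to first half -> S1, rest -> S2).
    """
    lids = sorted(listener_signals)
    arrs = {k: np.atleast_2d(np.asarray(v, dtype=float)) for k, v in
            listener_signals.items()}
    n_t, n_c = next(iter(arrs.values())).shape
    channels = [f"ch{i + 1:02d}" for i in range(n_c)]
    if speaker_signals is None:
        rng = np.random.default_rng(99)
        speaker_signals = {sid: rng.standard_normal((n_t, n_c))
                           for sid in ("S1", "S2")}
    speakers = {sid: Recording(np.asarray(d, dtype=float), fs, channels, sid,
                               role="speaker")
                for sid, d in speaker_signals.items()}
    listeners = {lid: Recording(arrs[lid], fs, channels, lid, role="listener")
                 for lid in lids}
    if group is None:
        half = len(lids) // 2
        group = {lid: ("S1" if i < half else "S2")
                 for i, lid in enumerate(lids)}
    return StimulusEnsemble(speakers=speakers, listeners=listeners,
                            group_assignment=group)


@pytest.fixture(scope="session")
def planted_ensemble():
    """Small non-homologous ensemble with planted coupling at 2.0 s."""
    manifest = PlantManifest(effect_fraction=0.08, lag_s=2.0,
                             mixing_mode="random", sensory_fraction=0.2)
    return generate_ensemble(manifest, n_listeners=8, n_channels=12,
                             duration_s=40.0, fs=50.0, seed=7)


@pytest.fixture(scope="session")
def null_ensemble():
    """Ensemble with sensory drive but no content effect."""
    manifest = PlantManifest(effect_fraction=0.0, lag_s=2.0,
                             sensory_fraction=0.2)
    return generate_ensemble(manifest, n_listeners=8, n_channels=12,
                             duration_s=40.0, fs=50.0, seed=8)
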