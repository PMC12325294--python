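import inspect

import numpy as np
import pytest

from precue_erd.features import compute_trial_features
from precue_erd.preprocess import EpochSet, preprocess_session
from precue_erd.synthetic import SynthConfig, generate_session


def make_epochs(
    signal_fn,
    fs: float = 250.0,
    window: tuple[float, float] = (-2.5, 3.5),
    channels: tuple[str, ...] = ("C3", "C4", "Pz"),
    labels: tuple[str, ...] = ("right",),
) -> EpochSet:
    """Build an EpochSet whose every channel carries ``signal_fn(t)``.

    ``signal_fn`` maps time (s, relative to the cue) to amplitude (µV); a
    function with a second *required* parameter receives the trial index.
    """
    required = [
        p
        for p in inspect.signature(signal_fn).parameters.values()
        if p.kind in (p.POSITIONAL_ONLY, p.POSITIONAL_OR_KEYWORD)
        and p.default is inspect.Parameter.empty
    ]
    takes_trial = len(required) >= 2
    n = int(round((window[1] - window[0]) * fs))
    t = np.arange(n) / fs + window[0]
    trials = []
    for l in range(len(labels)):
        sig = signal_fn(t, l) if takes_trial else signal_fn(t)
        trials.append(np.tile(sig, (len(channels), 1)))
    return EpochSet(
        data=np.stack(trials),
        t0_offset=window[0],
        fs=fs,
        labels=np.asarray(labels),
        channel_labels=list(channels),
    )


@pytest.fixture(scope="session")
def coupled_session():
    """One moderately noisy coupled session, preprocessed, with features."""
    cfg = SynthConfig(n_trials=30, noise_sd=1.5, artifact_rate=0.05, seed=11)
    recording, truth = generate_session(cfg)
    epochs = preprocess_session(recording)
    features = compute_trial_features(epochs)
    return cfg, epochs, features, truth


@pytest.fixture(scope="session")
def kept_session(coupled_session):
    """Retained trials of the coupled session plus their relative alpha."""
    _, epochs, features, _ = coupled_session
    kept = epochs.select(epochs.retained)
    rel_alpha = features.loc[features["retained"], "rel_alpha"].to_numpy()
    return kept, rel_alpha
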