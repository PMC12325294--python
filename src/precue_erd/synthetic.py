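"""Synthetic cue-paced motor-imagery EEG with a known alpha->ERD coupling.

The generator emulates the structure of a Graz-protocol MI session: a
parietal (Pz) alpha oscillation whose amplitude varies from trial to trial,
central mu/beta rhythms at C3/C4 that desynchronize during the imagery
interval, broadband 1/f background noise, and occasional high-amplitude
artifacts.  The depth of the motor-channel desynchronization is tied to the
trial's pre-cue alpha amplitude through a tunable coupling parameter, so the
strength of the association recovered downstream is known by construction.

Model per trial ``l``::

    d_l = min_erd_depth
          + (max_erd_depth - min_erd_depth) * (kappa * rank(A_l) + (1 - kappa) * u_l)

where ``A_l`` is the trial's alpha amplitude, ``rank(A_l)`` its rank across
the session mapped to (0, 1), and ``u_l`` independent uniform noise.  During
the imagery interval the contralateral central channel's mu/beta amplitude
is scaled by ``1 - d_l`` (the ipsilateral one by ``1 - lateralization*d_l``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import rankdata

from .preprocess import ConfigError, SessionRecording

#: imagery interval (s, relative to cue) in which desynchronization is applied
MI_WINDOW = (0.5, 2.5)
#: inter-trial rest inserted between consecutive epochs (s)
INTER_TRIAL_GAP = 6.0

ALPHA_FREQ = 10.0
MU_FREQ = 10.0
BETA_FREQ = 20.0


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic session.

    Amplitudes are in microvolts.  ``alpha_amp_dist`` holds the (mu, sigma)
    of the log-normal trial alpha amplitude.  ``coupling`` is the
    alpha->ERD-depth link strength kappa in [0, 1]; ``max_erd_depth`` the
    largest fractional amplitude attenuation; ``lateralization`` the fraction
    of the depth applied on the ipsilateral central channel.
    """

    n_trials: int = 60  # per class
    fs: float = 250.0
    channels: tuple[str, ...] = (
        "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
        "T7", "C3", "Cz", "C4", "T8",
        "P3", "Pz", "P4", "Oz",
    )
    epoch_window: tuple[float, float] = (-2.5, 3.5)
    alpha_amp_dist: tuple[float, float] = (math.log(3.0), 0.4)
    mu_amp: float = 2.0
    beta_amp: float = 1.0
    coupling: float = 0.8
    max_erd_depth: float = 0.7
    min_erd_depth: float = 0.0
    noise_sd: float = 3.0
    lateralization: float = 0.3
    artifact_rate: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_trials < 1:
            raise ConfigError("n_trials must be >= 1")
        if self.fs <= 0:
            raise ConfigError("fs must be positive")
        if not 0.0 <= self.coupling <= 1.0:
            raise ConfigError("coupling must lie in [0, 1]")
        if not 0.0 < self.max_erd_depth <= 1.0:
            raise ConfigError("max_erd_depth must lie in (0, 1]")
        if not 0.0 <= self.min_erd_depth <= self.max_erd_depth:
            raise ConfigError("min_erd_depth must lie in [0, max_erd_depth]")
        if not self.epoch_window[0] < 0.0 < self.epoch_window[1]:
            raise ConfigError("epoch_window must straddle the cue (start < 0 < end)")
        if not 0.0 <= self.lateralization <= 1.0:
            raise ConfigError("lateralization must lie in [0, 1]")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ConfigError("artifact_rate must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        if self.mu_amp < 0 or self.beta_amp < 0:
            raise ConfigError("mu_amp/beta_amp must be non-negative")
        for required in ("Pz", "C3", "C4"):
            if list(self.channels).count(required) != 1:
                raise ConfigError(f"channels must contain {required} exactly once")


@dataclass
class GroundTruth:
    """Per-trial hidden state of a generated session."""

    alpha_amp: np.ndarray  # A_l, microvolts
    erd_depth: np.ndarray  # d_l, fraction in [0, max_erd_depth]
    labels: np.ndarray  # "left" / "right"
    artifact: np.ndarray  # bool

    def __post_init__(self) -> None:
        n = len(self.alpha_amp)
        if not (len(self.erd_depth) == len(self.labels) == len(self.artifact) == n):
            raise ConfigError("ground-truth arrays must share one length")


def inject_artifact(
    epoch_samples: np.ndarray,
    amplitude: float,
    channel: int = 0,
    start: int = 0,
    length: int = 5,
) -> np.ndarray:
    """Return a copy with a rectangular >±120 µV excursion written in.

    ``amplitude`` must exceed the 120 µV rejection threshold, so the
    returned trial is rejected by amplitude screening by construction.
    Only ``length`` samples on one channel are touched.
    """
    if amplitude <= 120.0:
        raise ConfigError(
            f"artifact amplitude must exceed 120 µV (got {amplitude})"
        )
    out = np.array(epoch_samples, dtype=float, copy=True)
    stop = min(start + length, out.shape[-1])
    out[channel, start:stop] = amplitude
    return out


def _pink_noise(rng: np.random.Generator, n_ch: int, n_samp: int, fs: float, sd: float) -> np.ndarray:
    """Gaussian 1/f (power) noise, flattened below 1 Hz, unit-free scale ``sd``."""
    if sd == 0:
        return np.zeros((n_ch, n_samp))
    white = rng.standard_normal((n_ch, n_samp))
    freqs = np.fft.rfftfreq(n_samp, d=1.0 / fs)
    shaping = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    shaping[0] = 0.0
    spec = np.fft.rfft(white, axis=-1) * shaping
    pink = np.fft.irfft(spec, n=n_samp, axis=-1)
    pink *= sd / pink.std(axis=-1, keepdims=True)
    return pink


def _raised_cosine_gate(t: np.ndarray, on: float, off: float, ramp: float = 0.1) -> np.ndarray:
    """0->1->0 gate over [on, off] with raised-cosine ramps inside the window."""
    g = np.zeros_like(t)
    rise = (t >= on) & (t < on + ramp)
    g[rise] = 0.5 * (1 - np.cos(np.pi * (t[rise] - on) / ramp))
    g[(t >= on + ramp) & (t <= off - ramp)] = 1.0
    fall = (t > off - ramp) & (t <= off)
    g[fall] = 0.5 * (1 - np.cos(np.pi * (off - t[fall]) / ramp))
    return g


def generate_session(config: SynthConfig) -> tuple[SessionRecording, GroundTruth]:
    """Generate one synthetic MI session; bit-identical for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    w0, w1 = config.epoch_window
    n_tot = 2 * config.n_trials

    labels = np.array(["left"] * config.n_trials + ["right"] * config.n_trials)
    rng.shuffle(labels)

    mu_a, sigma_a = config.alpha_amp_dist
    alpha_amp = rng.lognormal(mean=mu_a, sigma=sigma_a, size=n_tot)
    rank_norm = (rankdata(alpha_amp) - 0.5) / n_tot
    u = rng.uniform(size=n_tot)
    depth = config.min_erd_depth + (config.max_erd_depth - config.min_erd_depth) * (
        config.coupling * rank_norm + (1 - config.coupling) * u
    )
    artifact = rng.uniform(size=n_tot) < config.artifact_rate

    spacing = (w1 - w0) + INTER_TRIAL_GAP
    pad = 3.0
    cue_samples = np.array(
        [int(round((pad - w0 + k * spacing) * fs)) for k in range(n_tot)]
    )
    n_samples = cue_samples[-1] + int(round((w1 + pad) * fs))
    n_ch = len(config.channels)
    data = _pink_noise(rng, n_ch, n_samples, fs, config.noise_sd)

    ch_index = {lab: i for i, lab in enumerate(config.channels)}
    i_pz, i_c3, i_c4 = ch_index["Pz"], ch_index["C3"], ch_index["C4"]
    s0, s1 = int(round(w0 * fs)), int(round(w1 * fs))
    t_epoch = np.arange(s0, s1) / fs  # time relative to cue

    for l in range(n_tot):
        sl = slice(cue_samples[l] + s0, cue_samples[l] + s1)
        # parietal alpha carrying the trial's pre-cue state
        phase = rng.uniform(0, 2 * np.pi)
        data[i_pz, sl] += alpha_amp[l] * np.sin(2 * np.pi * ALPHA_FREQ * t_epoch + phase)

        # central mu + beta with class-lateralized desynchronization
        contra = i_c3 if labels[l] == "right" else i_c4
        ipsi = i_c4 if labels[l] == "right" else i_c3
        gate = _raised_cosine_gate(t_epoch, *MI_WINDOW)
        for ch, ch_depth in ((contra, depth[l]), (ipsi, config.lateralization * depth[l])):
            env = 1.0 - ch_depth * gate
            ph_mu, ph_beta = rng.uniform(0, 2 * np.pi, size=2)
            data[ch, sl] += env * (
                config.mu_amp * np.sin(2 * np.pi * MU_FREQ * t_epoch + ph_mu)
                + config.beta_amp * np.sin(2 * np.pi * BETA_FREQ * t_epoch + ph_beta)
            )

        if artifact[l]:
            # large slow excursion that survives 1-40 Hz filtering and CAR
            ch = int(rng.integers(0, n_ch))
            offset = int(rng.integers(0, (s1 - s0) - int(0.2 * fs)))
            seg = inject_artifact(
                data[:, sl], amplitude=300.0, channel=ch,
                start=offset, length=int(0.2 * fs),
            )
            data[:, sl] = seg

    events = [(int(c), str(lab)) for c, lab in zip(cue_samples, labels)]
    recording = SessionRecording(
        samples=data,
        fs=fs,
        channel_labels=list(config.channels),
        events=events,
    )
    truth = GroundTruth(alpha_amp=alpha_amp, erd_depth=depth, labels=labels, artifact=artifact)
    return recording, truth


@dataclass(frozen=True)
class CohortMember:
    participant: int
    config: SynthConfig
    alpha_scale: float


def generate_cohort(
    n_participants: int,
    base: SynthConfig | None = None,
    alpha_scale_range: tuple[float, float] = (0.6, 1.8),
    depth_range: tuple[float, float] = (0.1, 0.8),
    seed: int = 0,
) -> list[CohortMember]:
    """Configs for a cohort in which the resting alpha level drives ERD depth.

    Participant alpha amplitude scales sit on a log-spaced grid over
    ``alpha_scale_range`` (a fixed dose-response-style design rather than
    random draws, so every cohort spans the full range); the participant's
    maximum ERD depth increases linearly with the log of the scale over
    ``depth_range``.  This builds the mechanism chain alpha level -> ERD
    depth -> class separability at the cohort level, on top of the
    within-session trial coupling.  The seed drives the per-participant
    session seeds.
    """
    if base is None:
        base = SynthConfig()
    rng = np.random.default_rng(seed)
    lo, hi = np.log(alpha_scale_range[0]), np.log(alpha_scale_range[1])
    members = []
    for p in range(n_participants):
        pos = p / (n_participants - 1) if n_participants > 1 else 0.5
        log_scale = lo + pos * (hi - lo)
        depth = depth_range[0] + pos * (depth_range[1] - depth_range[0])
        cfg = replace(
            base,
            alpha_amp_dist=(base.alpha_amp_dist[0] + log_scale, base.alpha_amp_dist[1]),
            max_erd_depth=float(depth),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        members.append(CohortMember(participant=p, config=cfg, alpha_scale=float(np.exp(log_scale))))
    return members
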