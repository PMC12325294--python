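"""Per-trial features: pre-cue parietal alpha power and ERD strength.

Alpha power is the mean squared amplitude of the 8-12 Hz band-passed Pz
signal over the -2..0 s pre-cue baseline.  To keep filter edge effects out
of that window, the filter is run over -2.5..0.5 s and 0.5 s is trimmed
from each end before averaging.  ERD is the percentage change of
instantaneous 8-30 Hz power during imagery relative to the same baseline:

    ERD(s) = 100 * (x(s)^2 - BL) / BL

with BL the mean squared band-passed amplitude over -2..0 s; negative
values are desynchronization, positive values synchronization.  The mean
over 0.5..2.5 s summarizes a trial's ERD strength.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .preprocess import ConfigError, DataError, EpochSet, bandpass_filter

ALPHA_BAND = (8.0, 12.0)
BROAD_BAND = (8.0, 40.0)
ERD_BAND = (8.0, 30.0)
BASELINE_WINDOW = (-2.0, 0.0)
MI_WINDOW = (0.5, 2.5)
EDGE_TRIM = 0.5


def _window_slice(epochs: EpochSet, start: float, stop: float) -> slice:
    i0 = epochs.time_to_sample(start)
    i1 = epochs.time_to_sample(stop)
    if i0 < 0 or i1 > epochs.n_samples:
        raise DataError(f"epoch does not cover window {start}..{stop} s")
    return slice(i0, i1)


def _band_power(
    epochs: EpochSet,
    channel: str,
    band: tuple[float, float],
    filter_window: tuple[float, float],
    mean_window: tuple[float, float],
) -> np.ndarray:
    """Mean squared band-passed amplitude over ``mean_window``, per trial.

    The filter runs over ``filter_window`` only; ``mean_window`` must lie
    strictly inside it so the trimmed edges never reach the average.
    """
    ch = epochs.channel_index(channel)
    seg = epochs.data[:, ch, _window_slice(epochs, *filter_window)]
    filtered = bandpass_filter(seg, *band, epochs.fs)
    off = int(round((mean_window[0] - filter_window[0]) * epochs.fs))
    n = int(round((mean_window[1] - mean_window[0]) * epochs.fs))
    return np.mean(filtered[:, off : off + n] ** 2, axis=-1)


def precue_alpha_power(epochs: EpochSet, channel: str = "Pz") -> np.ndarray:
    """Pre-cue 8-12 Hz power at ``channel`` (µV²), one value per trial."""
    return _band_power(
        epochs,
        channel,
        ALPHA_BAND,
        filter_window=(BASELINE_WINDOW[0] - EDGE_TRIM, BASELINE_WINDOW[1] + EDGE_TRIM),
        mean_window=BASELINE_WINDOW,
    )


def relative_alpha(epochs: EpochSet, channel: str = "Pz") -> np.ndarray:
    """Pre-cue alpha power as a fraction of 8-40 Hz power, same window/channel.

    The ratio is dimensionless and robust to between-session gain
    differences.  Filter leakage can push it marginally above 1; values up
    to 1.02 are clipped to 1, anything larger raises — except on trials
    already flagged as artifacts, whose broadband excursions can leak
    arbitrarily through the two stopbands and which never enter the
    analysis.  A zero denominator yields NaN for that trial.
    """
    alpha = precue_alpha_power(epochs, channel)
    total = _band_power(
        epochs,
        channel,
        BROAD_BAND,
        filter_window=(BASELINE_WINDOW[0] - EDGE_TRIM, BASELINE_WINDOW[1] + EDGE_TRIM),
        mean_window=BASELINE_WINDOW,
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(total > 0, alpha / total, np.nan)
    if np.nanmax(ratio[epochs.retained], initial=0.0) > 1.02:
        raise DataError("relative alpha exceeds 1 beyond filter-leakage tolerance")
    return np.clip(ratio, None, 1.0)


def erd_percent(mi_power: np.ndarray, baseline_power: float | np.ndarray) -> np.ndarray:
    """Percentage power change relative to baseline (negative = ERD)."""
    baseline_power = np.asarray(baseline_power, dtype=float)
    if np.any(baseline_power == 0):
        raise DataError("baseline power is zero; ERD undefined")
    return 100.0 * (np.asarray(mi_power, dtype=float) - baseline_power) / baseline_power


def erd_timecourse(
    epochs: EpochSet,
    channel: str,
    band: tuple[float, float] = ERD_BAND,
    baseline: tuple[float, float] = BASELINE_WINDOW,
    mi_window: tuple[float, float] = MI_WINDOW,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample-wise ERD percentage during the imagery interval.

    Returns ``(times, erd)`` with ``times`` in seconds relative to the cue
    and ``erd`` of shape (n_trials, n_window_samples).  The band-pass runs
    over the full epoch and 0.5 s is trimmed at each end before any power
    is read out, so both baseline and imagery samples are edge-free.
    """
    ch = epochs.channel_index(channel)
    filtered = bandpass_filter(epochs.data[:, ch, :], *band, epochs.fs)
    trim = int(round(EDGE_TRIM * epochs.fs))
    usable = slice(trim, epochs.n_samples - trim)
    power = filtered[:, usable] ** 2
    t_usable = (np.arange(epochs.n_samples)[usable]) / epochs.fs + epochs.t0_offset

    bl_mask = (t_usable >= baseline[0]) & (t_usable < baseline[1])
    mi_mask = (t_usable >= mi_window[0]) & (t_usable < mi_window[1])
    if not bl_mask.any() or not mi_mask.any():
        raise DataError("epoch too short for baseline/imagery windows after trimming")
    bl = power[:, bl_mask].mean(axis=-1)
    if np.any(bl == 0):
        bad = np.nonzero(bl == 0)[0].tolist()
        raise DataError(f"zero baseline power for trials {bad}; ERD undefined")
    erd = erd_percent(power[:, mi_mask], bl[:, None])
    return t_usable[mi_mask], erd


def mean_erd(timecourse: np.ndarray, axis: int = -1) -> np.ndarray:
    """Arithmetic mean of the ERD time course over the imagery window."""
    timecourse = np.asarray(timecourse, dtype=float)
    if timecourse.shape[axis] == 0:
        raise DataError("empty ERD window")
    return timecourse.mean(axis=axis)


def contralateral_channel(label: str) -> str:
    """Central channel contralateral to the imagined hand."""
    mapping = {"right": "C3", "left": "C4"}
    try:
        return mapping[label]
    except KeyError:
        raise ConfigError(
            f"class {label!r} not supported; expected 'left' or 'right'"
        ) from None


def compute_trial_features(
    epochs: EpochSet,
    participant: int = 0,
    session: int = 0,
    alpha_channel: str = "Pz",
) -> pd.DataFrame:
    """Tidy per-trial feature table for one session.

    Columns: participant, session, trial, class, retained, alpha_power,
    rel_alpha, mean_erd, erd_channel.  The ERD channel is the central
    electrode contralateral to the imagined hand.  All trials are listed;
    downstream statistics filter on ``retained``.
    """
    alpha = precue_alpha_power(epochs, alpha_channel)
    rel = relative_alpha(epochs, alpha_channel)
    erd_by_channel = {}
    for ch in ("C3", "C4"):
        _, tc = erd_timecourse(epochs, ch)
        erd_by_channel[ch] = mean_erd(tc)
    erd_channels = np.array([contralateral_channel(lab) for lab in epochs.labels])
    erd_vals = np.array(
        [erd_by_channel[ch][l] for l, ch in enumerate(erd_channels)]
    )
    return pd.DataFrame(
        {
            "participant": participant,
            "session": session,
            "trial": np.arange(epochs.n_trials),
            "class": epochs.labels,
            "retained": epochs.retained,
            "alpha_power": alpha,
            "rel_alpha": rel,
            "mean_erd": erd_vals,
            "erd_channel": erd_channels,
        }
    )


def channel_alpha_powers(epochs: EpochSet) -> pd.DataFrame:
    """Pre-cue alpha power at every channel (trials x channels table)."""
    return pd.DataFrame(
        {ch: precue_alpha_power(epochs, ch) for ch in epochs.channel_labels}
    )
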