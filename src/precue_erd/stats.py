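"""Nonparametric trial-level and group-level statistics.

The analysis chain mirrors common practice for trial-level EEG metrics
whose distributions fail normality checks: Spearman rank correlation
between pre-cue alpha power and mean ERD within each session, a
median-split Mann-Whitney comparison of ERD between high- and low-alpha
trials, participant-level aggregation by medians, and Benjamini-Hochberg
FDR control over each family of session-level tests.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sst

from .preprocess import DataError

EXACT_SPEARMAN_MAX_N = 9
EXACT_MW_MAX_N = 16


# ---------------------------------------------------------------------------
# elementary tests


@lru_cache(maxsize=8)
def _permutation_matrix(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))))


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with midranks for ties.

    p-value from the t approximation, or by exhaustive permutation of one
    rank vector for n <= 9 where the approximation is poor.  Constant input
    yields (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise DataError("spearman needs two equal-length vectors of n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan, math.nan
    rx = sst.rankdata(x)
    ry = sst.rankdata(y)
    r = float(np.corrcoef(rx, ry)[0, 1])
    n = len(x)
    if n <= EXACT_SPEARMAN_MAX_N:
        perms = _permutation_matrix(n)
        ry_perm = ry[perms]
        rx_c = rx - rx.mean()
        ry_c = ry_perm - ry_perm.mean(axis=1, keepdims=True)
        denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum(axis=1))
        r_perm = (ry_c @ rx_c) / denom
        p = float(np.mean(np.abs(r_perm) >= abs(r) - 1e-12))
    else:
        if abs(r) == 1.0:
            p = 0.0
        else:
            t = r * math.sqrt((n - 2) / (1 - r * r))
            p = float(2 * sst.t.sf(abs(t), df=n - 2))
    return r, min(p, 1.0)


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with midrank tie handling.

    Exact enumeration when the pooled sample is small (n_a + n_b <= 16) and
    tie-free; otherwise the normal approximation with tie correction.
    Returns (U of the first sample, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise DataError("mann_whitney requires two non-empty samples")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(pooled) <= EXACT_MW_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sst.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def shapiro_wilk(x) -> tuple[float, float]:
    """Shapiro-Wilk normality test (gate/report only; the pipeline's
    inferential tests are nonparametric regardless of the outcome)."""
    x = np.asarray(x, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise DataError("shapiro_wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise DataError("shapiro_wilk undefined for constant input")
    res = sst.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(pvals, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at level ``q``.

    Finds the largest rank i with p_(i) <= (i/m) q and rejects all
    hypotheses of rank <= i, reported in the original order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise DataError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    thresholds = (np.arange(1, m + 1) / m) * q
    passed = np.nonzero(p[order] <= thresholds)[0]
    flags = np.zeros(m, dtype=bool)
    if passed.size:
        flags[order[: passed[-1] + 1]] = True
    return flags


# ---------------------------------------------------------------------------
# session-level analysis


def median_split(alpha: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split trials on the session median of pre-cue alpha power.

    Returns boolean masks (upper, lower); trials exactly at the median go
    to the lower set.  Raises if all values are identical (no split).
    """
    alpha = np.asarray(alpha, dtype=float)
    if len(alpha) < 4:
        raise DataError("median split needs at least 4 trials")
    med = np.median(alpha)
    upper = alpha > med
    lower = ~upper
    if not upper.any() or not lower.any():
        raise DataError("all alpha values identical; median split impossible")
    return upper, lower


def analyze_session(
    features: pd.DataFrame,
    by_class: bool = True,
) -> pd.DataFrame:
    """Per-condition trial-level statistics for one session.

    For each hand condition (or the pooled session when ``by_class`` is
    False): Spearman correlation of pre-cue alpha power with mean ERD, and
    a Mann-Whitney comparison of mean ERD between trials above and below
    the session-condition median alpha.  Only retained trials enter.
    Conditions with fewer than 4 retained trials are skipped.
    """
    rows = []
    retained = features[features["retained"]]
    groups = retained.groupby("class") if by_class else [("pooled", retained)]
    for condition, grp in groups:
        if len(grp) < 4:
            continue
        alpha = grp["alpha_power"].to_numpy()
        erd = grp["mean_erd"].to_numpy()
        r, p_r = spearman(alpha, erd)
        try:
            upper, lower = median_split(alpha)
            u_stat, u_p = mann_whitney(erd[upper], erd[lower])
            n_up, n_lo = int(upper.sum()), int(lower.sum())
        except DataError:
            u_stat, u_p, n_up, n_lo = math.nan, math.nan, 0, len(grp)
        rows.append(
            {
                "participant": grp["participant"].iloc[0],
                "session": grp["session"].iloc[0],
                "condition": condition,
                "n_trials": len(grp),
                "r": r,
                "p_r": p_r,
                "u_stat": u_stat,
                "u_p": u_p,
                "median_alpha": float(np.median(alpha)),
                "n_upper": n_up,
                "n_lower": n_lo,
            }
        )
    return pd.DataFrame(rows)


def add_fdr_flags(
    session_stats: pd.DataFrame,
    q: float = 0.05,
    family: tuple[str, ...] = ("condition",),
) -> pd.DataFrame:
    """Append BH-FDR significance flags for the correlation and the
    median-split test, corrected within each family of sessions.

    ``family`` names the columns that define a correction family (default:
    one family per condition across sessions, mirroring per-condition
    reporting of session-level tests).
    """
    out = session_stats.copy()
    out["significant_fdr"] = False
    out["u_significant_fdr"] = False
    grouping = out.groupby(list(family)).groups if family else {None: out.index}
    for _, idx in grouping.items():
        idx = pd.Index(idx)
        p_r = out.loc[idx, "p_r"].to_numpy()
        ok = np.isfinite(p_r)
        flags = np.zeros(len(idx), dtype=bool)
        flags[ok] = bh_fdr(p_r[ok], q)
        out.loc[idx, "significant_fdr"] = flags
        u_p = out.loc[idx, "u_p"].to_numpy()
        ok = np.isfinite(u_p)
        uflags = np.zeros(len(idx), dtype=bool)
        uflags[ok] = bh_fdr(u_p[ok], q)
        out.loc[idx, "u_significant_fdr"] = uflags
    return out


# ---------------------------------------------------------------------------
# group-level analysis


def participant_aggregate(
    features: pd.DataFrame,
    by_class: bool = True,
) -> dict[str, dict[str, float]]:
    """Group-level Spearman correlation of participant median alpha vs
    median ERD.

    Per participant and condition: the median alpha power and median mean
    ERD are computed within each session, then averaged across the
    participant's sessions so each participant contributes one independent
    observation.  Requires at least 5 participants.
    """
    retained = features[features["retained"]]
    keys = ["participant", "session"] + (["class"] if by_class else [])
    per_session = retained.groupby(keys)[["alpha_power", "mean_erd"]].median().reset_index()
    per_participant = (
        per_session.groupby(["participant"] + (["class"] if by_class else []))[
            ["alpha_power", "mean_erd"]
        ]
        .mean()
        .reset_index()
    )
    results: dict[str, dict[str, float]] = {}
    groups = (
        per_participant.groupby("class") if by_class else [("pooled", per_participant)]
    )
    for condition, grp in groups:
        if len(grp) < 5:
            raise DataError(
                f"participant aggregation for {condition!r} needs >= 5 participants"
            )
        r, p = spearman(grp["alpha_power"].to_numpy(), grp["mean_erd"].to_numpy())
        results[str(condition)] = {"r": r, "p": p, "n_participants": len(grp)}
    return results


def localize(
    channel_alpha: pd.DataFrame,
    erd: np.ndarray,
    participant_ids: np.ndarray,
    q: float = 0.05,
) -> pd.DataFrame:
    """Channel-wise localization of the alpha-ERD association.

    ``channel_alpha`` holds pre-cue alpha power per trial at every channel;
    ``erd`` the contralateral mean ERD per trial; ``participant_ids`` maps
    trials to participants.  Per participant and channel a Spearman r and p
    are computed over that participant's trials (multi-session trials are
    pooled per participant here); per channel the table reports the median
    r across participants and the fraction of participants significant
    after BH correction across channels within participant.
    """
    participants = np.unique(participant_ids)
    channels = list(channel_alpha.columns)
    r_mat = np.full((len(participants), len(channels)), np.nan)
    p_mat = np.full_like(r_mat, np.nan)
    for i, p_id in enumerate(participants):
        mask = participant_ids == p_id
        for j, ch in enumerate(channels):
            r_mat[i, j], p_mat[i, j] = spearman(
                channel_alpha[ch].to_numpy()[mask], erd[mask]
            )
    sig = np.zeros_like(r_mat, dtype=bool)
    for i in range(len(participants)):
        ok = np.isfinite(p_mat[i])
        sig[i, ok] = bh_fdr(p_mat[i, ok], q)
    return pd.DataFrame(
        {
            "channel": channels,
            "median_r": np.nanmedian(r_mat, axis=0),
            "fraction_significant": sig.mean(axis=0),
        }
    )


def accuracy_association(
    alpha_metric: np.ndarray,
    accuracy: np.ndarray,
) -> dict[str, float]:
    """Association between participant alpha metric and CV accuracy.

    Spearman r and p across participants plus the descriptive R^2 of the
    least-squares line of accuracy on the alpha metric.  Fewer than 5
    participants is reported but flagged as low-n.
    """
    alpha_metric = np.asarray(alpha_metric, dtype=float)
    accuracy = np.asarray(accuracy, dtype=float)
    if len(alpha_metric) != len(accuracy):
        raise DataError("alpha metric and accuracy must be paired per participant")
    low_n = len(alpha_metric) < 5
    r, p = spearman(alpha_metric, accuracy)
    if np.ptp(accuracy) == 0 or np.ptp(alpha_metric) == 0:
        r2 = math.nan
    else:
        fit = sst.linregress(alpha_metric, accuracy)
        r2 = float(fit.rvalue**2)
    return {"r": r, "p": p, "r_squared": r2, "n": len(alpha_metric), "low_n": low_n}
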