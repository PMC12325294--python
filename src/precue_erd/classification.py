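"""Two-class motor-imagery decoding: CSP spatial filters, log-variance
features, LDA, stratified 10-fold cross-validation.

CSP solves the generalized eigenproblem ``C1 w = lambda (C1 + C2) w`` on
the class-average trace-normalized spatial covariances of the band-passed
imagery window.  Eigenvalues are the fraction of (whitened) variance the
component assigns to class 1, so the two ends of the spectrum carry the
discriminative components; three are kept from each end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold

from .features import EDGE_TRIM, ERD_BAND, MI_WINDOW
from .preprocess import DataError, EpochSet, bandpass_filter

logger = logging.getLogger(__name__)

N_COMPONENTS = 6
LOG_VAR_FLOOR = 1e-12  # zero-variance components map to log of this sentinel


@dataclass
class CSPModel:
    """Fitted spatial filters.

    filters : (n_selected, n_channels); rows are the selected components,
        ordered by descending eigenvalue.
    eigenvalues : class-1 variance ratio per selected component, in [0, 1].
    """

    filters: np.ndarray
    eigenvalues: np.ndarray
    channel_labels: list[str]
    class_order: tuple[str, str]


@dataclass
class CVResult:
    fold_accuracies: np.ndarray
    mean_accuracy: float
    fold_train_median_rel_alpha: np.ndarray
    participant_alpha_metric: float
    seed: int
    fold_train_indices: list[np.ndarray]
    fold_filters: list[np.ndarray]


def mi_window_data(
    epochs: EpochSet,
    band: tuple[float, float] = ERD_BAND,
    mi_window: tuple[float, float] = MI_WINDOW,
) -> np.ndarray:
    """Band-passed imagery-window samples, (trials, channels, samples).

    Filtering runs over the full epoch per trial (a purely trial-local
    operation, so precomputing it introduces no train/test leakage) and the
    0.5..2.5 s window is cut out afterwards, clear of the trimmed edges.
    """
    filtered = bandpass_filter(epochs.data, *band, epochs.fs)
    i0 = epochs.time_to_sample(mi_window[0])
    i1 = epochs.time_to_sample(mi_window[1])
    trim = int(round(EDGE_TRIM * epochs.fs))
    if i0 < trim or i1 > epochs.n_samples - trim:
        raise DataError("imagery window reaches into filter edge region")
    return filtered[:, :, i0:i1]


def _mean_normalized_cov(x: np.ndarray) -> np.ndarray:
    """Average of per-trial spatial covariances, each trace-normalized."""
    covs = np.einsum("tcs,tds->tcd", x, x)
    traces = np.trace(covs, axis1=1, axis2=2)
    return (covs / traces[:, None, None]).mean(axis=0)


def fit_csp(
    x1: np.ndarray,
    x2: np.ndarray,
    channel_labels: list[str] | None = None,
    class_order: tuple[str, str] = ("left", "right"),
    n_components: int = N_COMPONENTS,
) -> CSPModel:
    """Fit CSP from band-passed imagery-window trials of the two classes.

    ``x1``/``x2`` are (trials, channels, samples) arrays (see
    :func:`mi_window_data`).  Filters satisfy ``W (C1+C2) W^T = I`` on the
    retained subspace and are sorted by descending class-1 eigenvalue;
    ``n_components/2`` filters are taken from each end of the spectrum.
    """
    if len(x1) < 2 or len(x2) < 2:
        raise DataError("CSP needs at least 2 trials per class")
    c1 = _mean_normalized_cov(x1)
    c2 = _mean_normalized_cov(x2)
    return fit_csp_from_covariances(
        c1, c2, channel_labels=channel_labels, class_order=class_order,
        n_components=n_components,
    )


def fit_csp_from_covariances(
    c1: np.ndarray,
    c2: np.ndarray,
    channel_labels: list[str] | None = None,
    class_order: tuple[str, str] = ("left", "right"),
    n_components: int = N_COMPONENTS,
) -> CSPModel:
    """CSP from class-average spatial covariances (see :func:`fit_csp`)."""
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    n_ch = c1.shape[0]
    composite = c1 + c2

    # Whiten on the principal subspace of the composite covariance.  After
    # common-average referencing the composite is singular by one dimension;
    # directions carrying (numerically) no variance are excluded rather than
    # regularized, so no spurious null-space component can rank among the
    # discriminative ends of the spectrum.
    d, e = linalg.eigh(composite)
    keep = d > max(1e-10 * d[-1], 0.0)
    rank = int(keep.sum())
    if rank < n_ch:
        logger.debug("composite covariance rank %d < %d channels", rank, n_ch)
    if rank < 2:
        ridge = 1e-8 * np.trace(composite) / n_ch
        logger.warning("degenerate composite covariance; ridge %g added", ridge)
        d, e = linalg.eigh(composite + ridge * np.eye(n_ch))
        keep = np.ones(n_ch, dtype=bool)
        rank = n_ch
    whiten = (e[:, keep] / np.sqrt(d[keep])).T  # (rank, n_ch)
    evals, rot = linalg.eigh(whiten @ c1 @ whiten.T)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    filters = (rot[:, order].T @ whiten)  # rows: components, desc eigenvalue

    if rank < n_components:
        logger.warning(
            "covariance rank %d below %d requested CSP components; reducing",
            rank, n_components,
        )
        n_components = rank
    half = n_components // 2
    pick = np.r_[np.arange(half), np.arange(rank - (n_components - half), rank)]
    return CSPModel(
        filters=filters[pick],
        eigenvalues=np.clip(evals[pick], 0.0, 1.0),
        channel_labels=list(channel_labels) if channel_labels else [],
        class_order=class_order,
    )


def csp_features(model: CSPModel, x: np.ndarray) -> np.ndarray:
    """Log-variance of each CSP component, (trials, n_selected).

    ``x`` is (trials, channels, samples) band-passed imagery-window data.
    Zero-variance components are floored before the log and logged as
    degenerate rather than propagating -inf.
    """
    projected = np.einsum("kc,tcs->tks", model.filters, x)
    var = projected.var(axis=-1, ddof=0)
    if np.any(var <= 0):
        logger.warning("degenerate zero-variance CSP component encountered")
    return np.log(np.maximum(var, LOG_VAR_FLOOR))


def fit_lda(features: np.ndarray, labels: np.ndarray) -> LinearDiscriminantAnalysis:
    """Two-class LDA with pooled covariance (SVD solver, tolerant of
    collinear features)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) != 2:
        raise DataError("LDA training set must contain both classes")
    model = LinearDiscriminantAnalysis(solver="svd")
    model.fit(np.asarray(features, dtype=float), labels)
    return model


def predict(model: LinearDiscriminantAnalysis, features: np.ndarray) -> np.ndarray:
    return model.predict(np.asarray(features, dtype=float))


def crossvalidate(
    epochs: EpochSet,
    trial_rel_alpha: np.ndarray,
    k: int = 10,
    seed: int = 0,
    band: tuple[float, float] = ERD_BAND,
    mi_window: tuple[float, float] = MI_WINDOW,
    n_components: int = N_COMPONENTS,
) -> CVResult:
    """Stratified k-fold CV with CSP and LDA refit inside every fold.

    ``epochs`` must already be restricted to retained trials.  The spatial
    filters and the classifier are fitted on each fold's training trials
    only.  Alongside the accuracy, each fold records the median relative
    alpha over its *training* trials; the mean of those medians is the
    participant-level alpha metric paired with CV accuracy downstream.
    """
    labels = np.asarray(epochs.labels)
    trial_rel_alpha = np.asarray(trial_rel_alpha, dtype=float)
    if len(trial_rel_alpha) != epochs.n_trials:
        raise DataError("rel_alpha length must equal trial count")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise DataError("cross-validation requires exactly two classes")
    if counts.min() < k:
        raise DataError(f"each class needs at least k={k} trials")

    x = mi_window_data(epochs, band=band, mi_window=mi_window)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs, medians, train_idx_list, filters_list = [], [], [], []
    for train_idx, test_idx in skf.split(np.zeros(len(labels)), labels):
        y_train = labels[train_idx]
        assert len(np.unique(y_train)) == 2  # guaranteed by stratification
        c1_mask = y_train == classes[0]
        model = fit_csp(
            x[train_idx][c1_mask],
            x[train_idx][~c1_mask],
            channel_labels=epochs.channel_labels,
            class_order=(str(classes[0]), str(classes[1])),
            n_components=n_components,
        )
        lda = fit_lda(csp_features(model, x[train_idx]), y_train)
        pred = predict(lda, csp_features(model, x[test_idx]))
        accs.append(float(np.mean(pred == labels[test_idx])))
        medians.append(float(np.nanmedian(trial_rel_alpha[train_idx])))
        train_idx_list.append(train_idx)
        filters_list.append(model.filters)

    accs = np.asarray(accs)
    medians = np.asarray(medians)
    return CVResult(
        fold_accuracies=accs,
        mean_accuracy=float(accs.mean()),
        fold_train_median_rel_alpha=medians,
        participant_alpha_metric=float(medians.mean()),
        seed=seed,
        fold_train_indices=train_idx_list,
        fold_filters=filters_list,
    )
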