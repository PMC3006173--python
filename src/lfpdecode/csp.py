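"""Common Spatial Patterns: class covariances, filters, log-variance features.

CSP finds linear channel combinations w whose variance fraction
``w' S1 w / w' (S1 + S2) w`` is extremal between two classes. The
filters solve the generalized eigenproblem

    S1 w = lambda (S1 + S2) w,

whose eigenvalues lie in [0, 1]: lambda near 1 marks a projection with
almost all composite variance coming from class 1, lambda near 0 from
class 2. The m largest and m smallest eigenvectors (m = 3 by default)
give a 2m-dimensional projection; the log of each projection's variance
is the feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .errors import EstimationError, ValidationError
from .preprocess import SubbandTensor

__all__ = [
    "CovarianceEstimate",
    "CSPModel",
    "trial_covariances",
    "class_covariance",
    "csp_fit",
    "csp_project",
    "log_variance_features",
]


@dataclass
class CovarianceEstimate:
    """Class-conditional spatial covariance (trial-averaged, trace-normalized)."""

    sigma: np.ndarray  # C x C, symmetric PSD
    class_label: object = None
    n_trials: int = 0
    shrinkage: float = 0.0

    def validate(self, tol: float = 1e-8) -> None:
        s = self.sigma
        if s.ndim != 2 or s.shape[0] != s.shape[1]:
            raise ValidationError("covariance must be square")
        if not np.allclose(s, s.T, atol=tol * max(1.0, np.abs(s).max())):
            raise ValidationError("covariance not symmetric")
        if np.trace(s) <= 0:
            raise ValidationError("covariance trace must be positive")


@dataclass
class CSPModel:
    """Fitted spatial filters for one binary contrast in one band.

    ``W`` holds all C filters as columns, ordered by descending
    eigenvalue; ``selected`` indexes the m largest and m smallest.
    """

    W: np.ndarray          # C x C
    eigenvalues: np.ndarray  # length C, descending, in [0, 1]
    selected: np.ndarray   # 2m column indices
    band_name: str = ""
    contrast_id: int = -1
    shrinkage: float = 0.0  # applied to covariances at feature time too

    @property
    def n_channels(self) -> int:
        return self.W.shape[0]

    @property
    def W_selected(self) -> np.ndarray:
        return self.W[:, self.selected]


# ------------------------------------------------------------------
# covariance estimation
# ------------------------------------------------------------------

def trial_covariances(data: np.ndarray, window: slice | None = None) -> np.ndarray:
    """Per-trial channel covariance over a sample window.

    *data* is [trials, channels, samples]; returns [trials, C, C] with
    the window mean removed per trial/channel and ddof = 1 (matching
    :func:`log_variance_features`, so ``w' Sigma w`` equals the sample
    variance of the projected signal).
    """
    x = data[:, :, window] if window is not None else data
    n = x.shape[-1]
    if n < 2:
        raise ValidationError("covariance window must hold at least 2 samples")
    xc = x - x.mean(axis=-1, keepdims=True)
    return np.einsum("tcn,tdn->tcd", xc, xc, optimize=True) / (n - 1)


def _average_normalized(covs: np.ndarray, trace_norm: bool = True) -> np.ndarray:
    if trace_norm:
        tr = np.trace(covs, axis1=1, axis2=2)
        tr = np.where(tr > 0, tr, 1.0)
        covs = covs / tr[:, None, None]
    return covs.mean(axis=0)


def shrink(sigma: np.ndarray, gamma: float) -> np.ndarray:
    """Shrink toward the scaled identity: (1-g) S + g (tr S / C) I."""
    if gamma == 0.0:
        return sigma
    c = sigma.shape[0]
    return (1.0 - gamma) * sigma + gamma * (np.trace(sigma) / c) * np.eye(c)


def class_covariance(
    S: SubbandTensor | np.ndarray,
    trial_indices,
    window: slice | tuple[float, float] | None = None,
    shrinkage: float = 0.0,
    trace_norm: bool = True,
    class_label=None,
) -> CovarianceEstimate:
    """Average of per-trial (trace-normalized) covariances for one class side.

    *S* may be a :class:`SubbandTensor` (window given in ms) or a plain
    [trials, C, samples] array (window given as a sample slice).
    """
    if isinstance(S, SubbandTensor):
        data = S.data
        if isinstance(window, tuple):
            window = S.window_slice(*window)
    else:
        data = np.asarray(S)
    idx = np.asarray(trial_indices)
    if idx.size < 2:
        raise EstimationError("need at least 2 trials to estimate a covariance")
    covs = trial_covariances(data[idx], window)
    sigma = shrink(_average_normalized(covs, trace_norm), shrinkage)
    est = CovarianceEstimate(
        sigma=sigma, class_label=class_label, n_trials=idx.size, shrinkage=shrinkage
    )
    est.validate()
    return est


# ------------------------------------------------------------------
# fitting and projection
# ------------------------------------------------------------------

def csp_fit(
    sigma1: CovarianceEstimate | np.ndarray,
    sigma2: CovarianceEstimate | np.ndarray,
    m: int = 3,
    band_name: str = "",
    contrast_id: int = -1,
) -> CSPModel:
    """Solve S1 w = lambda (S1 + S2) w and select the 2m extremal filters.

    Columns are scaled so that ``W' (S1 + S2) W = I`` and sign-fixed so
    each column's largest-magnitude entry is positive (deterministic
    across linear-algebra backends).
    """
    s1 = sigma1.sigma if isinstance(sigma1, CovarianceEstimate) else np.asarray(sigma1)
    s2 = sigma2.sigma if isinstance(sigma2, CovarianceEstimate) else np.asarray(sigma2)
    if s1.shape != s2.shape:
        raise ValidationError("covariance dimensions do not match")
    c = s1.shape[0]
    if 2 * m > c:
        raise ValidationError(f"2m={2*m} filters requested but only {c} channels")
    comp = s1 + s2
    try:
        evals, evecs = scipy.linalg.eigh(s1, comp)
    except scipy.linalg.LinAlgError as e:
        raise EstimationError(
            "composite covariance is singular; increase shrinkage"
        ) from e
    if not np.all(np.isfinite(evals)):
        raise EstimationError(
            "generalized eigendecomposition failed; increase shrinkage"
        )
    order = np.argsort(evals)[::-1]  # descending
    evals = np.clip(evals[order], 0.0, 1.0)
    W = evecs[:, order]
    # deterministic sign: largest-|.| element of each column positive
    flips = np.sign(W[np.abs(W).argmax(axis=0), np.arange(c)])
    flips[flips == 0] = 1.0
    W = W * flips
    selected = np.concatenate([np.arange(m), np.arange(c - m, c)])
    return CSPModel(
        W=W, eigenvalues=evals, selected=selected,
        band_name=band_name, contrast_id=contrast_id,
    )


def csp_project(trial: np.ndarray, model: CSPModel) -> np.ndarray:
    """Project one trial [C x n] onto the selected filters -> [2m x n]."""
    trial = np.asarray(trial)
    if trial.shape[0] != model.n_channels:
        raise ValidationError(
            f"trial has {trial.shape[0]} channels, model expects {model.n_channels}"
        )
    return model.W_selected.T @ trial


def log_variance_features(
    projected: np.ndarray, valid_window: slice | None = None
) -> np.ndarray:
    """Log of the per-row sample variance over the window.

    The log transform normalizes the right-skewed variance distribution
    before the linear discriminant stage.
    """
    x = projected[:, valid_window] if valid_window is not None else projected
    if x.shape[-1] < 2:
        raise ValidationError("variance window must hold at least 2 samples")
    v = x.var(axis=-1, ddof=1)
    if np.any(v <= 0):
        raise ValidationError("degenerate (constant) projection row")
    return np.log(v)


def features_from_covariances(covs: np.ndarray, model: CSPModel) -> np.ndarray:
    """Log-variance features for a batch of per-trial covariances.

    ``var(w'X) = w' Sigma w`` with matching ddof, so features can be read
    directly off precomputed covariances: *covs* [trials, C, C] ->
    [trials, 2m]. Used on the hot path of training and prediction.

    The model's covariance shrinkage is applied here as well, so a filter
    lying in the null space of a rank-deficient trial covariance (e.g.
    duplicated channels in a resampled subset) still has positive
    variance: ``v = (1-g) w' S w + g (tr S / C) ||w||^2``.
    """
    ws = model.W_selected
    v = np.einsum("tij,ik,jk->tk", covs, ws, ws, optimize=True)
    g = model.shrinkage
    if g > 0:
        c = covs.shape[1]
        tr = np.trace(covs, axis1=1, axis2=2) / c
        v = (1.0 - g) * v + g * tr[:, None] * np.sum(ws**2, axis=0)[None, :]
    if np.any(v <= 0):
        raise ValidationError("degenerate projection variance")
    return np.log(v)
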