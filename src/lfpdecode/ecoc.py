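"""Redundant multi-class direction decoding: CSP + FLD banks fused by ECOC.

For K = 8 directions the system trains L = 40 binary classifiers:

* 28 pairwise contrasts — every unordered pair of directions;
* 12 group contrasts — every contiguous arc of 2..K/2 directions versus
  the diametrically opposite arc (a contrast and its side-swap count once).

Each contrast gets one CSP model per sub-band (fitted on that contrast's
trials only, group sides pooled); the per-band 2m log-variance features
are concatenated and fed to a Fisher linear discriminant. At test time
the L signed margins y are fused through the K x L code matrix M with
entries in {-1, 0, +1}: the score of class k is ``s_k = -sum_l M[k,l] y_l``
and the predicted class is argmin_k s_k (ties -> lowest index).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import List, Sequence

import h5py
import numpy as np

from .errors import ConfigurationError, TrainingError, ValidationError
from .csp import (
    CSPModel,
    class_covariance,
    csp_fit,
    features_from_covariances,
    shrink,
    trial_covariances,
    _average_normalized,
)
from .preprocess import SubBandSpec, SubbandTensor

__all__ = [
    "Contrast",
    "FLD",
    "ECOCModel",
    "DecoderConfig",
    "enumerate_contrasts",
    "build_code_matrix",
    "fld_fit",
    "fld_margin",
    "ecoc_fit",
    "ecoc_predict",
    "ecoc_predict_batch",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class Contrast:
    """One binary classification problem over direction classes."""

    positive_set: frozenset
    negative_set: frozenset
    kind: str  # "pair" | "group"
    id: int

    def __post_init__(self):
        if self.positive_set & self.negative_set:
            raise ValidationError("contrast sides must be disjoint")
        if not self.positive_set or not self.negative_set:
            raise ValidationError("contrast sides must be non-empty")

    def members(self) -> frozenset:
        return self.positive_set | self.negative_set


@dataclass
class FLD:
    """Fisher linear discriminant: margin(f) = w'f - b, positive side = +1."""

    w: np.ndarray
    b: float

    def validate(self):
        if not np.all(np.isfinite(self.w)) or not np.any(self.w):
            raise ValidationError("FLD weights must be finite and not all zero")


@dataclass
class DecoderConfig:
    """Tunables of the CSP+ECOC decoder.

    m : filters kept from each end of the eigenvalue spectrum (2m features
        per band per contrast).
    csp_shrinkage : covariance shrinkage toward scaled identity; None =
        automatic (0.05 when channels exceed the per-side trial count).
    fld_shrinkage : within-class covariance shrinkage of the FLD.
    trace_norm : normalize each trial covariance by its trace before
        averaging.
    """

    m: int = 3
    csp_shrinkage: float | None = None
    fld_shrinkage: float = 0.1
    trace_norm: bool = True


@dataclass
class ECOCModel:
    """The trained 40-classifier decoding system."""

    contrasts: List[Contrast]
    M: np.ndarray  # K x L
    csp_models: List[List[CSPModel]]  # [contrast][band]
    flds: List[FLD]
    bands: List[SubBandSpec]
    window_ms: tuple
    K: int
    config: DecoderConfig = field(default_factory=DecoderConfig)
    channel_indices: np.ndarray | None = None

    @property
    def L(self) -> int:
        return len(self.contrasts)


# ------------------------------------------------------------------
# code construction
# ------------------------------------------------------------------

def enumerate_contrasts(K: int = 8) -> List[Contrast]:
    """All pairwise contrasts, then contiguous-group-vs-opposite contrasts.

    Groups span 2..K/2 contiguous directions; the negative side is the
    diametric opposite arc (start shifted by K/2). A contrast equal to
    another with sides swapped is kept once. Order: pairs lexicographic,
    then groups by (size, start index). K=8 gives 28 + 12 = 40.
    """
    if K % 2 or K < 4:
        raise ConfigurationError("grouping scheme needs an even K >= 4")
    contrasts: List[Contrast] = []
    for a, b in itertools.combinations(range(K), 2):
        contrasts.append(
            Contrast(frozenset({a}), frozenset({b}), "pair", len(contrasts))
        )
    seen = set()
    for size in range(2, K // 2 + 1):
        for start in range(K):
            pos = frozenset((start + i) % K for i in range(size))
            neg = frozenset((start + K // 2 + i) % K for i in range(size))
            key = frozenset({pos, neg})
            if key in seen:
                continue
            seen.add(key)
            contrasts.append(Contrast(pos, neg, "group", len(contrasts)))
    return contrasts


def build_code_matrix(contrasts: Sequence[Contrast], K: int) -> np.ndarray:
    """K x L matrix: +1 where class in positive set, -1 negative, else 0."""
    M = np.zeros((K, len(contrasts)), dtype=np.int8)
    for j, c in enumerate(contrasts):
        for k in c.positive_set:
            M[k, j] = 1
        for k in c.negative_set:
            M[k, j] = -1
    return M


# ------------------------------------------------------------------
# Fisher linear discriminant
# ------------------------------------------------------------------

def fld_fit(features: np.ndarray, y: np.ndarray, shrinkage: float = 0.0) -> FLD:
    """w ~ (pooled within-class cov + shrinkage)^-1 (mu+ - mu-).

    Bias puts the boundary at the midpoint of the class means; the sign
    convention makes ``w' mu+ - b > 0``.
    """
    features = np.asarray(features, dtype=float)
    y = np.asarray(y)
    pos, neg = features[y > 0], features[y < 0]
    if len(pos) == 0 or len(neg) == 0:
        raise TrainingError("both classes must be present to fit an FLD")
    if len(features) <= 2:
        raise TrainingError("need more than 2 samples to fit an FLD")
    mu_p, mu_n = pos.mean(axis=0), neg.mean(axis=0)
    xp, xn = pos - mu_p, neg - mu_n
    sw = (xp.T @ xp + xn.T @ xn) / max(len(features) - 2, 1)
    sw = shrink(sw, shrinkage)
    try:
        w = np.linalg.solve(sw, mu_p - mu_n)
    except np.linalg.LinAlgError:
        w = np.linalg.lstsq(sw, mu_p - mu_n, rcond=None)[0]
    b = float(w @ (mu_p + mu_n) / 2.0)
    model = FLD(w=w, b=b)
    model.validate()
    return model


def fld_margin(model: FLD, feature: np.ndarray) -> float:
    """Signed distance w'f - b; positive favors the positive set."""
    feature = np.asarray(feature)
    if feature.shape[-1] != model.w.shape[0]:
        raise ValidationError(
            f"feature dim {feature.shape[-1]} != model dim {model.w.shape[0]}"
        )
    return feature @ model.w - model.b


# ------------------------------------------------------------------
# training
# ------------------------------------------------------------------

def _auto_shrinkage(cfg: DecoderConfig, n_side: int, C: int) -> float:
    if cfg.csp_shrinkage is not None:
        return cfg.csp_shrinkage
    return 0.05 if C > n_side else 0.0


def ecoc_fit_covs(
    covs_per_band: Sequence[np.ndarray],
    labels: np.ndarray,
    bands: Sequence[SubBandSpec],
    window_ms: tuple,
    config: DecoderConfig | None = None,
    K: int = 8,
    channel_indices=None,
) -> ECOCModel:
    """Fit from precomputed per-trial covariances (one [T,C,C] per band)."""
    config = config or DecoderConfig()
    labels = np.asarray(labels)
    counts = np.bincount(labels, minlength=K)
    if np.any(counts < 2):
        bad = int(np.argmin(counts))
        raise TrainingError(f"class {bad} has {counts[bad]} trials; need >= 2")
    contrasts = enumerate_contrasts(K)
    M = build_code_matrix(contrasts, K)
    C = covs_per_band[0].shape[1]

    norm_covs = [
        _average_normalized_keep(c, config.trace_norm) for c in covs_per_band
    ]
    csp_models: List[List[CSPModel]] = []
    flds: List[FLD] = []
    for con in contrasts:
        pos_idx = np.flatnonzero(np.isin(labels, list(con.positive_set)))
        neg_idx = np.flatnonzero(np.isin(labels, list(con.negative_set)))
        gamma = _auto_shrinkage(config, min(pos_idx.size, neg_idx.size), C)
        both = np.concatenate([pos_idx, neg_idx])
        y = np.concatenate([np.ones(pos_idx.size), -np.ones(neg_idx.size)])
        per_band = []
        feats = []
        for bi, band in enumerate(bands):
            s1 = shrink(norm_covs[bi][pos_idx].mean(axis=0), gamma)
            s2 = shrink(norm_covs[bi][neg_idx].mean(axis=0), gamma)
            model = csp_fit(s1, s2, m=config.m,
                            band_name=band.name, contrast_id=con.id)
            model.shrinkage = gamma
            per_band.append(model)
            feats.append(features_from_covariances(covs_per_band[bi][both], model))
        csp_models.append(per_band)
        flds.append(fld_fit(np.hstack(feats), y, shrinkage=config.fld_shrinkage))
    return ECOCModel(
        contrasts=contrasts, M=M, csp_models=csp_models, flds=flds,
        bands=list(bands), window_ms=tuple(window_ms), K=K, config=config,
        channel_indices=None if channel_indices is None else np.asarray(channel_indices),
    )


def _average_normalized_keep(covs: np.ndarray, trace_norm: bool) -> np.ndarray:
    """Trace-normalize each trial covariance (kept per-trial, not averaged)."""
    if not trace_norm:
        return covs
    tr = np.trace(covs, axis1=1, axis2=2)
    tr = np.where(tr > 0, tr, 1.0)
    return covs / tr[:, None, None]


def ecoc_fit(
    banded: Sequence[SubbandTensor],
    labels: np.ndarray,
    window_ms: tuple,
    config: DecoderConfig | None = None,
    K: int = 8,
) -> ECOCModel:
    """Train the full decoding system on per-band tensors.

    All tensors must share trial order; *window_ms* is the feature window
    (start, end) relative to the alignment event.
    """
    covs = [trial_covariances(b.data, b.window_slice(*window_ms)) for b in banded]
    return ecoc_fit_covs(
        covs, labels, [b.band for b in banded], window_ms, config, K,
        channel_indices=banded[0].channel_indices,
    )


# ------------------------------------------------------------------
# prediction
# ------------------------------------------------------------------

def ecoc_margins_covs(covs_per_band: Sequence[np.ndarray], model: ECOCModel) -> np.ndarray:
    """Margins of all L classifiers for a batch of trials -> [T, L]."""
    T = covs_per_band[0].shape[0]
    Y = np.empty((T, model.L))
    for j, con in enumerate(model.contrasts):
        feats = [
            features_from_covariances(covs_per_band[bi], model.csp_models[j][bi])
            for bi in range(len(model.bands))
        ]
        Y[:, j] = np.hstack(feats) @ model.flds[j].w - model.flds[j].b
    return Y


def decode_margins(Y: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Fuse margins through the code matrix: argmin_k of -M y (ties -> lowest k)."""
    scores = -(Y @ M.T)  # T x K
    return np.argmin(scores, axis=1)


def ecoc_predict_batch(
    covs_per_band: Sequence[np.ndarray], model: ECOCModel
) -> np.ndarray:
    """Predicted class per trial from precomputed window covariances."""
    C = covs_per_band[0].shape[1]
    if C != model.csp_models[0][0].n_channels:
        raise ValidationError("channel count does not match the model")
    return decode_margins(ecoc_margins_covs(covs_per_band, model), model.M)


def ecoc_predict(trial_bands: Sequence[np.ndarray], model: ECOCModel) -> int:
    """Predict one trial given its per-band [C x n] windows."""
    if len(trial_bands) != len(model.bands):
        raise ValidationError("band count does not match the model")
    covs = [trial_covariances(np.asarray(x)[None]) for x in trial_bands]
    return int(ecoc_predict_batch(covs, model)[0])


# ------------------------------------------------------------------
# model store
# ------------------------------------------------------------------

def save_model(model: ECOCModel, path):
    """Persist a trained model to a single HDF5 file."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = MODEL_FORMAT_VERSION
        f.attrs["K"] = model.K
        f.attrs["L"] = model.L
        f.attrs["window_ms"] = list(model.window_ms)
        f.attrs["m"] = model.config.m
        f.attrs["fld_shrinkage"] = model.config.fld_shrinkage
        f.attrs["csp_shrinkage"] = (
            -1.0 if model.config.csp_shrinkage is None else model.config.csp_shrinkage
        )
        f.attrs["trace_norm"] = model.config.trace_norm
        f.create_dataset("M", data=model.M)
        if model.channel_indices is not None:
            f.create_dataset("channel_indices", data=model.channel_indices)
        gb = f.create_group("bands")
        for i, b in enumerate(model.bands):
            g = gb.create_group(str(i))
            g.attrs.update(
                low=b.low, high=b.high, use_envelope=b.use_envelope,
                name=b.name, filter_order=-1 if b.filter_order is None else b.filter_order,
            )
        gc = f.create_group("contrasts")
        for j, con in enumerate(model.contrasts):
            g = gc.create_group(str(j))
            g.attrs["kind"] = con.kind
            g.create_dataset("positive", data=sorted(con.positive_set))
            g.create_dataset("negative", data=sorted(con.negative_set))
            g.create_dataset("fld_w", data=model.flds[j].w)
            g.attrs["fld_b"] = model.flds[j].b
            for bi, cm in enumerate(model.csp_models[j]):
                gbm = g.create_group(f"band{bi}")
                gbm.create_dataset("W", data=cm.W)
                gbm.create_dataset("eigenvalues", data=cm.eigenvalues)
                gbm.create_dataset("selected", data=cm.selected)
                gbm.attrs["shrinkage"] = cm.shrinkage
    return path


def load_model(path) -> ECOCModel:
    with h5py.File(path, "r") as f:
        K = int(f.attrs["K"])
        L = int(f.attrs["L"])
        gamma = float(f.attrs["csp_shrinkage"])
        config = DecoderConfig(
            m=int(f.attrs["m"]),
            csp_shrinkage=None if gamma < 0 else gamma,
            fld_shrinkage=float(f.attrs["fld_shrinkage"]),
            trace_norm=bool(f.attrs["trace_norm"]),
        )
        bands = []
        gb = f["bands"]
        for i in range(len(gb)):
            a = gb[str(i)].attrs
            order = int(a["filter_order"])
            bands.append(
                SubBandSpec(
                    low=float(a["low"]), high=float(a["high"]),
                    use_envelope=bool(a["use_envelope"]),
                    filter_order=None if order < 0 else order,
                    name=str(a["name"]),
                )
            )
        contrasts, csp_models, flds = [], [], []
        gc = f["contrasts"]
        for j in range(L):
            g = gc[str(j)]
            contrasts.append(
                Contrast(
                    frozenset(int(k) for k in g["positive"][()]),
                    frozenset(int(k) for k in g["negative"][()]),
                    str(g.attrs["kind"]),
                    j,
                )
            )
            flds.append(FLD(w=g["fld_w"][()], b=float(g.attrs["fld_b"])))
            per_band = []
            for bi in range(len(bands)):
                gbm = g[f"band{bi}"]
                per_band.append(
                    CSPModel(
                        W=gbm["W"][()],
                        eigenvalues=gbm["eigenvalues"][()],
                        selected=gbm["selected"][()],
                        band_name=bands[bi].name,
                        contrast_id=j,
                        shrinkage=float(gbm.attrs.get("shrinkage", 0.0)),
                    )
                )
            csp_models.append(per_band)
        return ECOCModel(
            contrasts=contrasts,
            M=f["M"][()],
            csp_models=csp_models,
            flds=flds,
            bands=bands,
            window_ms=tuple(f.attrs["window_ms"]),
            K=K,
            config=config,
            channel_indices=(
                f["channel_indices"][()] if "channel_indices" in f else None
            ),
        )
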