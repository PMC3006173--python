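"""Decoder evaluation: metrics, cross-validation and the study protocols.

Two complementary accuracy measures are used throughout:

* decoding power (DP) — the fraction of correctly classified trials;
* circular correlation (rho_T) — the Fisher–Lee T-linear association
  between predicted and actual direction angles, which credits near
  misses on the circle (45 deg off is better than 180 deg off) and is
  invariant to a common rotation of both sequences.

Cross-validated scores are compared with the Nadeau–Bengio corrected
resampled t-test, which widens the naive standard error by the
train/test overlap factor sqrt(1/J + n_test/n_train).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .errors import ValidationError
from .csp import trial_covariances
from .ecoc import DecoderConfig, ecoc_fit_covs, ecoc_predict_batch
from .io import TrialSet
from .preprocess import SubbandTensor, preprocess_bands

__all__ = [
    "EvaluationResult",
    "WindowSweepResult",
    "decoding_power",
    "circular_correlation",
    "cross_validate",
    "corrected_ttest",
    "corrected_ci",
    "sliding_timecourse",
    "rate_of_change_summary",
    "delay_period_test",
    "cross_session_validate",
    "subset_curves",
]


# ------------------------------------------------------------------
# metrics
# ------------------------------------------------------------------

def decoding_power(pred: np.ndarray, actual: np.ndarray) -> float:
    """Fraction of trials whose predicted class equals the true class."""
    pred, actual = np.asarray(pred), np.asarray(actual)
    if pred.shape != actual.shape or pred.size == 0:
        raise ValidationError("pred and actual must be equal-length, non-empty")
    return float(np.mean(pred == actual))


class CircularCorrelation(float):
    """rho_T value; ``degenerate`` is True when either sequence was constant."""

    degenerate: bool = False

    def __new__(cls, value: float, degenerate: bool = False):
        obj = super().__new__(cls, value)
        obj.degenerate = degenerate
        return obj


def circular_correlation(pred_angles, actual_angles) -> CircularCorrelation:
    """Fisher–Lee T-linear association between two angle sequences (radians).

    rho_T = sum_{i<j} sin(a_i - a_j) sin(b_i - b_j)
            / sqrt(sum_{i<j} sin^2(a_i - a_j) * sum_{i<j} sin^2(b_i - b_j))

    A constant sequence makes the denominator vanish; that case returns
    0 flagged as degenerate rather than raising, so sweep series stay
    plottable.
    """
    a = np.asarray(pred_angles, dtype=float)
    b = np.asarray(actual_angles, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValidationError("need two equal-length sequences of >= 3 angles")
    sa = np.sin(a[:, None] - a[None, :])
    sb = np.sin(b[:, None] - b[None, :])
    num = np.sum(sa * sb) / 2.0
    da = np.sum(sa**2) / 2.0
    db = np.sum(sb**2) / 2.0
    if da <= 0 or db <= 0:
        return CircularCorrelation(0.0, degenerate=True)
    return CircularCorrelation(float(num / np.sqrt(da * db)))


@dataclass
class EvaluationResult:
    """Cross-validated decoding outcome.

    ``confusion`` accumulates counts over every fold and repetition, so
    ``dp == trace(confusion) / confusion.sum()`` exactly. ``fold_dp``
    and ``fold_rho`` hold one score per fold x repetition (length
    folds*reps; 100 for the default 10x10 scheme).
    """

    dp: float
    rho_t: float
    confusion: np.ndarray
    fold_dp: np.ndarray
    fold_rho: np.ndarray
    seed: int
    n_train: int = 0
    n_test: int = 0

    @property
    def fold_scores(self) -> np.ndarray:
        return self.fold_dp


@dataclass
class WindowSweepResult:
    """One cross-validated evaluation per sliding-window position."""

    window_end_times: np.ndarray  # ms, ascending
    rho_series: np.ndarray
    dp_series: np.ndarray
    rate_of_change: np.ndarray  # d(rho)/d(100 ms), aligned to end_times[1:]
    ci_low: np.ndarray
    ci_high: np.ndarray
    results: List[EvaluationResult] = field(default_factory=list)
    window_ms: float = 0.0


# ------------------------------------------------------------------
# cross-validation
# ------------------------------------------------------------------

def _angles(labels: np.ndarray, K: int) -> np.ndarray:
    return np.asarray(labels) * (2.0 * np.pi / K)


def cross_validate(
    banded: Sequence[SubbandTensor],
    labels: np.ndarray,
    window_ms: tuple,
    config: DecoderConfig | None = None,
    folds: int = 10,
    reps: int = 10,
    seed: int = 0,
    K: int = 8,
) -> EvaluationResult:
    """Repeated stratified K-fold evaluation of the full pipeline.

    CSP and FLD fitting happen strictly inside each fold's training
    partition. All randomness (fold assignment across repetitions)
    derives from *seed*.
    """
    covs = [trial_covariances(b.data, b.window_slice(*window_ms)) for b in banded]
    return cross_validate_covs(
        covs, labels, [b.band for b in banded], window_ms,
        config, folds, reps, seed, K,
    )


def cross_validate_covs(
    covs_per_band: Sequence[np.ndarray],
    labels: np.ndarray,
    bands,
    window_ms: tuple,
    config: DecoderConfig | None = None,
    folds: int = 10,
    reps: int = 10,
    seed: int = 0,
    K: int = 8,
) -> EvaluationResult:
    """As :func:`cross_validate`, from precomputed window covariances."""
    labels = np.asarray(labels)
    counts = np.bincount(labels, minlength=K)
    if np.any(counts[np.unique(labels)] < folds):
        raise ValidationError(
            f"every class needs >= {folds} trials for {folds}-fold stratification"
        )
    rng = np.random.default_rng(seed)
    fold_dp, fold_rho = [], []
    confusion = np.zeros((K, K), dtype=np.int64)
    n_train = n_test = 0
    for _ in range(reps):
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True,
            random_state=int(rng.integers(2**31 - 1)),
        )
        for train_idx, test_idx in skf.split(np.zeros(labels.size), labels):
            model = ecoc_fit_covs(
                [c[train_idx] for c in covs_per_band],
                labels[train_idx], bands, window_ms, config, K,
            )
            pred = ecoc_predict_batch([c[test_idx] for c in covs_per_band], model)
            actual = labels[test_idx]
            fold_dp.append(decoding_power(pred, actual))
            fold_rho.append(float(circular_correlation(
                _angles(pred, K), _angles(actual, K))))
            np.add.at(confusion, (actual, pred), 1)
            n_train, n_test = train_idx.size, test_idx.size
    return EvaluationResult(
        dp=float(np.trace(confusion) / confusion.sum()),
        rho_t=float(np.mean(fold_rho)),
        confusion=confusion,
        fold_dp=np.asarray(fold_dp),
        fold_rho=np.asarray(fold_rho),
        seed=seed,
        n_train=n_train,
        n_test=n_test,
    )


# ------------------------------------------------------------------
# corrected resampled t-test
# ------------------------------------------------------------------

def corrected_ttest(
    scores_a: np.ndarray,
    scores_b_or_null,
    n_train: int,
    n_test: int,
) -> Dict[str, float]:
    """Nadeau–Bengio corrected t-test on per-fold score differences.

    The variance of the mean of J cross-validation scores is estimated
    as ``sigma^2 * (1/J + n_test/n_train)`` — wider than the naive 1/J
    because folds share training data. Returns t, two-sided p, df and
    the corrected 95% CI of the mean difference.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b_or_null, dtype=float)
    d = a - b  # broadcasts over a scalar null
    J = d.size
    if J < 2:
        raise ValidationError("need at least 2 scores")
    mean = float(d.mean())
    var = float(d.var(ddof=1))
    se = np.sqrt(var * (1.0 / J + n_test / n_train))
    df = J - 1
    if se <= 1e-12 * max(1.0, abs(mean)):  # zero variance up to fp rounding
        t = 0.0 if mean == 0.0 else np.inf * np.sign(mean)
        p = 1.0 if mean == 0.0 else 0.0
        return {"t": t, "p": p, "df": df, "ci95": (mean, mean), "mean": mean}
    t = mean / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    tc = stats.t.ppf(0.975, df)
    return {
        "t": float(t), "p": p, "df": df,
        "ci95": (mean - tc * se, mean + tc * se), "mean": mean,
    }


def corrected_ci(scores: np.ndarray, n_train: int, n_test: int):
    """Corrected 95% CI of the mean of one cross-validated score vector."""
    r = corrected_ttest(scores, 0.0, n_train, n_test)
    return r["ci95"]


# ------------------------------------------------------------------
# sliding-window time courses
# ------------------------------------------------------------------

CUE_PROTOCOL = dict(window_ms=500.0, start_ms=-500.0, step_ms=100.0, end_ms=1200.0)
MOVEMENT_PROTOCOL = dict(window_ms=1000.0, start_ms=-1400.0, step_ms=100.0, end_ms=1000.0)


def sliding_timecourse(
    banded: Sequence[SubbandTensor],
    labels: np.ndarray,
    window_ms: float,
    start_ms: float,
    step_ms: float,
    end_ms: float,
    config: DecoderConfig | None = None,
    folds: int = 10,
    reps: int = 10,
    seed: int = 0,
    K: int = 8,
) -> WindowSweepResult:
    """Cross-validated evaluation at every window position.

    Windows start at *start_ms* and advance by *step_ms* while their end
    stays <= *end_ms*; the pipeline (CSP included) is retrained for
    every position and fold. The rate of change is the first difference
    of rho_T per 100 ms.
    """
    starts = []
    s = start_ms
    while s + window_ms <= end_ms + 1e-9:
        starts.append(s)
        s += step_ms
    if not starts:
        raise ValidationError("no window fits between start_ms and end_ms")
    for s in starts:
        # validates position against the epoch, naming the offender
        try:
            banded[0].window_slice(s, s + window_ms)
        except ValidationError as e:
            raise ValidationError(f"window starting at {s} ms: {e}") from e
    results = [
        cross_validate(banded, labels, (s, s + window_ms),
                       config, folds, reps, seed, K)
        for s in starts
    ]
    rho = np.array([r.rho_t for r in results])
    dp = np.array([r.dp for r in results])
    ci = np.array([
        corrected_ci(r.fold_rho, r.n_train, r.n_test) for r in results
    ])
    rate = np.diff(rho) / (step_ms / 100.0)
    return WindowSweepResult(
        window_end_times=np.asarray(starts) + window_ms,
        rho_series=rho,
        dp_series=dp,
        rate_of_change=rate,
        ci_low=ci[:, 0],
        ci_high=ci[:, 1],
        results=results,
        window_ms=window_ms,
    )


def rate_of_change_summary(sweep: WindowSweepResult) -> Dict[str, float | None]:
    """Peak of the rho_T rate of change and the 50%-of-peak decay latency.

    ``half_decay_time`` is the first post-peak window end at which the
    rate falls below half the peak; None when the series never decays.
    """
    rate = np.asarray(sweep.rate_of_change, dtype=float)
    if rate.size < 2:
        raise ValidationError("need >= 3 sweep points for a rate summary")
    times = np.asarray(sweep.window_end_times)[1:]
    i_peak = int(np.argmax(rate))
    peak = float(rate[i_peak])
    half_decay = None
    for i in range(i_peak + 1, rate.size):
        if rate[i] < 0.5 * peak:
            half_decay = float(times[i])
            break
    return {
        "peak_value": peak,
        "peak_time": float(times[i_peak]),
        "half_decay_time": half_decay,
    }


def delay_period_test(
    sweep: WindowSweepResult, delay_interval_ms: tuple
) -> Dict[str, float]:
    """Test whether delay-period direction information is above chance.

    Sums per-fold rho_T over the sweep positions whose windows end inside
    *delay_interval_ms* and tests the sum against zero with the corrected
    t-test.
    """
    lo, hi = delay_interval_ms
    sel = [
        i for i, t in enumerate(sweep.window_end_times) if lo <= t <= hi
    ]
    if not sel:
        raise ValidationError("no sweep window ends inside the delay interval")
    summed = np.sum([sweep.results[i].fold_rho for i in sel], axis=0)
    r0 = sweep.results[sel[0]]
    out = corrected_ttest(summed, 0.0, r0.n_train, r0.n_test)
    out["n_windows"] = len(sel)
    return out


# ------------------------------------------------------------------
# cross-session transfer
# ------------------------------------------------------------------

def cross_session_validate(
    train: Sequence[TrialSet],
    test: Sequence[TrialSet],
    bands,
    window_ms: tuple,
    config: DecoderConfig | None = None,
    K: int = 8,
) -> Dict[str, float]:
    """Train once on pooled training sessions, test once on the others."""
    from .ecoc import ecoc_fit

    ref = np.flatnonzero(train[0].channel_mask)
    for T in list(train) + list(test):
        if not np.array_equal(np.flatnonzero(T.channel_mask), ref):
            raise ValidationError("sessions have different usable channel sets")
    def pooled(sessions):
        per_band, labels = [], np.concatenate([s.labels for s in sessions])
        processed = [preprocess_bands(s, bands) for s in sessions]
        for bi in range(len(bands)):
            per_band.append(
                SubbandTensor(
                    data=np.concatenate([p[bi].data for p in processed]),
                    fs_out=processed[0][bi].fs_out,
                    band=processed[0][bi].band,
                    t0_ms=processed[0][bi].t0_ms,
                    channel_indices=processed[0][bi].channel_indices,
                    edge_ms=processed[0][bi].edge_ms,
                )
            )
        return per_band, labels

    tr_bands, tr_labels = pooled(train)
    te_bands, te_labels = pooled(test)
    model = ecoc_fit(tr_bands, tr_labels, window_ms, config, K)
    covs = [
        trial_covariances(b.data, b.window_slice(*window_ms)) for b in te_bands
    ]
    pred = ecoc_predict_batch(covs, model)
    return {
        "dp": decoding_power(pred, te_labels),
        "rho_t": float(circular_correlation(_angles(pred, K), _angles(te_labels, K))),
    }


# ------------------------------------------------------------------
# channel- and trial-subset curves
# ------------------------------------------------------------------

def subset_curves(
    banded: Sequence[SubbandTensor],
    labels: np.ndarray,
    channel_counts: Sequence[int] = (),
    trial_counts: Sequence[int] = (),
    draws: int = 3,
    seed: int = 0,
    window_ms: tuple = (0.0, 1000.0),
    config: DecoderConfig | None = None,
    folds: int = 10,
    reps: int = 2,
    K: int = 8,
) -> Dict[str, pd.DataFrame]:
    """Mean rho_T as a function of channel count and of training-set size.

    Channel subsets are drawn with replacement (duplicated channels are
    tolerated through covariance shrinkage); trial subsets are balanced
    across directions. Each count is evaluated over *draws* random draws.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    n_ch = banded[0].data.shape[1]
    config = config or DecoderConfig()
    if config.csp_shrinkage is None and channel_counts:
        config = DecoderConfig(
            m=config.m, csp_shrinkage=0.05,
            fld_shrinkage=config.fld_shrinkage, trace_norm=config.trace_norm,
        )
    covs_full = [
        trial_covariances(b.data, b.window_slice(*window_ms)) for b in banded
    ]
    bands = [b.band for b in banded]

    ch_rows = []
    for count in channel_counts:
        if count > n_ch:
            raise ValidationError(f"channel count {count} exceeds {n_ch}")
        for d in range(draws):
            sub = (
                np.arange(n_ch) if count == n_ch
                else rng.integers(0, n_ch, size=count)
            )
            m_eff = min(config.m, count // 2)
            cfg = DecoderConfig(
                m=max(1, m_eff), csp_shrinkage=config.csp_shrinkage,
                fld_shrinkage=config.fld_shrinkage, trace_norm=config.trace_norm,
            )
            cv_seed = int(rng.integers(2**31 - 1))
            res = cross_validate_covs(
                [c[:, sub][:, :, sub] for c in covs_full],
                labels, bands, window_ms, cfg, folds, reps,
                seed=cv_seed, K=K,
            )
            ch_rows.append({"n_channels": count, "draw": d,
                            "rho_t": res.rho_t, "dp": res.dp,
                            "cv_seed": cv_seed})

    tr_rows = []
    per_class = np.bincount(labels, minlength=K)
    for count in trial_counts:
        k_per = count // K
        if k_per < folds or k_per > per_class.min():
            raise ValidationError(
                f"trial count {count} needs {folds}..{per_class.min()} per class"
            )
        for d in range(draws):
            idx = np.concatenate([
                rng.choice(np.flatnonzero(labels == k), size=k_per, replace=False)
                for k in range(K)
            ])
            cv_seed = int(rng.integers(2**31 - 1))
            res = cross_validate_covs(
                [c[idx] for c in covs_full], labels[idx], bands, window_ms,
                config, folds, reps, seed=cv_seed, K=K,
            )
            tr_rows.append({"n_trials": count, "draw": d,
                            "rho_t": res.rho_t, "dp": res.dp,
                            "cv_seed": cv_seed})
    return {
        "channels": pd.DataFrame(ch_rows),
        "trials": pd.DataFrame(tr_rows),
    }
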