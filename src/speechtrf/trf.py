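"""Forward temporal response function (TRF) estimation.

Lagged ridge regression from stimulus regressors to multichannel EEG:

* :func:`preprocess_eeg` -- zero-phase 15 Hz low-pass plus a single
  z-scoring pooled over all channels and trials jointly, which preserves
  the relative power across channels.
* :func:`build_lagged_design` -- samples x (features x lags) design with a
  trailing bias column; pre-trial stimulus history is zero-padded.
* :func:`ridge_fit` / :func:`crossval_trf` / :func:`crossval_submodels` --
  penalized normal-equations solve, leave-one-trial-out cross-validation,
  and the shared-covariance fast path for nested feature subsets.
* :func:`valid_sample_mask` / :func:`valid_sample_correlation` -- scoring
  restricted to samples 0-500 ms after an onset, where the onset-train
  model can make a prediction.
* :func:`tune_lambda` -- grid search minimizing cross-validated MSE.

Weights are always stored in the units of the *unscaled* regressors: when
per-feature standardization is enabled the ridge penalty acts in the scaled
space, but the returned weight tensor is mapped back, so noiseless kernel
recovery is exact regardless of the flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import linalg as spla
from scipy import signal as sps

from .features import ONSET_FEATURE_SUFFIX, StimulusFeatureSet

logger = logging.getLogger(__name__)

DEFAULT_LAMBDA_GRID = tuple(10.0 ** np.arange(-6, 7))  # 13 decade steps


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class EEGTrialSet:
    """Continuous EEG split into trials of shape (channels, samples)."""

    trials: list[np.ndarray]
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    layout: np.ndarray | None = None  # (n_channels, 2) 2-D positions
    normalized: bool = False

    def __post_init__(self) -> None:
        self.trials = [np.asarray(t, dtype=float) for t in self.trials]
        if not self.trials:
            raise ValueError("EEGTrialSet needs at least one trial")
        n_ch = self.trials[0].shape[0]
        for t in self.trials:
            if t.ndim != 2 or t.shape[0] != n_ch:
                raise ValueError("all trials must share the channel count")
            if not np.all(np.isfinite(t)):
                raise ValueError("EEG contains non-finite values")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i:02d}" for i in range(n_ch)]
        if len(self.channel_labels) != n_ch:
            raise ValueError("channel_labels length mismatch")
        if self.layout is not None:
            self.layout = np.asarray(self.layout, dtype=float)
            if self.layout.shape != (n_ch, 2):
                raise ValueError("layout must be (n_channels, 2)")

    @property
    def n_channels(self) -> int:
        return self.trials[0].shape[0]

    @property
    def n_trials(self) -> int:
        return len(self.trials)


@dataclass(frozen=True)
class LagSpec:
    """Post-onset lag window of the forward model (default 0-500 ms)."""

    fs: float
    lag_min_ms: float = 0.0
    lag_max_ms: float = 500.0

    def __post_init__(self) -> None:
        if self.lag_min_ms > self.lag_max_ms:
            raise ValueError("lag_min_ms must not exceed lag_max_ms")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def lag_samples(self) -> np.ndarray:
        lo = int(round(self.lag_min_ms * self.fs / 1000.0))
        hi = int(round(self.lag_max_ms * self.fs / 1000.0))
        return np.arange(lo, hi + 1)

    @property
    def n_lags(self) -> int:
        return len(self.lag_samples)

    @property
    def lag_times_ms(self) -> np.ndarray:
        return self.lag_samples * 1000.0 / self.fs


@dataclass
class RidgeConfig:
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    penalize_bias: bool = False  # fixed: bias is never penalized
    per_feature_standardize: bool = True

    def __post_init__(self) -> None:
        grid = tuple(float(g) for g in self.lambda_grid)
        if any(g <= 0 for g in grid) or any(
            a >= b for a, b in zip(grid, grid[1:])
        ):
            raise ValueError("lambda_grid must be strictly increasing and positive")
        self.lambda_grid = grid


@dataclass
class TRFModel:
    """Estimated forward model: feature x lag x channel weights plus bias."""

    weights: np.ndarray  # (n_features, n_lags, n_channels)
    bias: np.ndarray  # (n_channels,)
    lambda_used: float
    lag_spec: LagSpec
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.bias = np.asarray(self.bias, dtype=float)
        nf, nl, nc = self.weights.shape
        if nf != len(self.feature_names) or nl != self.lag_spec.n_lags:
            raise ValueError("weight tensor inconsistent with features/lag_spec")
        if self.bias.shape != (nc,):
            raise ValueError("bias shape inconsistent with weights")
        if not (np.all(np.isfinite(self.weights)) and np.all(np.isfinite(self.bias))):
            raise ValueError("non-finite TRF weights")

    @property
    def n_channels(self) -> int:
        return self.weights.shape[2]


@dataclass
class AccuracyTable:
    """Cross-validated per-trial, per-channel correlations on valid samples."""

    r: np.ndarray  # (n_trials, n_channels); NaN marks undefined entries
    valid_sample_fraction: np.ndarray  # (n_trials,)
    model_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.valid_sample_fraction = np.asarray(self.valid_sample_fraction, dtype=float)
        finite = self.r[np.isfinite(self.r)]
        if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("correlations outside [-1, 1]")

    def grand_mean(self, channels: Sequence[int] | None = None) -> float:
        r = self.r if channels is None else self.r[:, list(channels)]
        return float(np.nanmean(r))


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess_eeg(
    raw: EEGTrialSet, lowpass_hz: float = 15.0, filter_order: int = 100
) -> EEGTrialSet:
    """Zero-phase FIR low-pass then joint z-scoring across channels and trials.

    The low-pass is a Hann-windowed linear-phase FIR applied forward and
    backward. Normalization uses a single mean and standard deviation pooled
    over all channels and trials, so relative channel power is preserved.
    """
    if raw.fs <= 2 * lowpass_hz:
        raise ValueError("sampling rate too low for the requested low-pass")
    taps = sps.firwin(filter_order + 1, lowpass_hz, fs=raw.fs, window="hann")
    filtered = [sps.filtfilt(taps, 1.0, t, axis=1) for t in raw.trials]
    pooled = np.concatenate([t.ravel() for t in filtered])
    mu = pooled.mean()
    sd = pooled.std()
    if sd == 0:
        raise ValueError("EEG is constant; cannot z-score")
    trials = [(t - mu) / sd for t in filtered]
    return EEGTrialSet(
        trials=trials, fs=raw.fs, channel_labels=list(raw.channel_labels),
        layout=None if raw.layout is None else raw.layout.copy(), normalized=True,
    )


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def _as_feature_dict(features) -> dict[str, np.ndarray]:
    if isinstance(features, StimulusFeatureSet):
        return features.features
    return {k: np.asarray(v, dtype=float) for k, v in features.items()}


def build_lagged_design(
    features, lag_spec: LagSpec, feature_names: Sequence[str] | None = None,
    scales: Mapping[str, float] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Samples x (features*lags + 1) design matrix; last column is the bias.

    Column (f, tau) holds feature f delayed by tau samples; rows with
    ``t - tau < 0`` are zero-padded. ``scales`` optionally divides each
    feature's columns (per-feature standardization).
    """
    feats = _as_feature_dict(features)
    names = list(feature_names) if feature_names is not None else list(feats)
    lags = lag_spec.lag_samples
    n_lags = len(lags)
    n = len(next(iter(feats.values())))
    if n_lags > n:
        raise ValueError(f"lag window ({n_lags} samples) longer than trial ({n})")
    X = np.zeros((n, len(names) * n_lags + 1))
    for fi, name in enumerate(names):
        x = feats[name]
        if scales is not None:
            x = x / scales[name]
        base = fi * n_lags
        for li, tau in enumerate(lags):
            if tau >= 0:
                X[tau:, base + li] = x[: n - tau] if tau > 0 else x
            else:
                X[: n + tau, base + li] = x[-tau:]
    X[:, -1] = 1.0
    return X, names


def feature_scales(
    feats_per_trial: Sequence, feature_names: Sequence[str]
) -> dict[str, float]:
    """Per-feature standard deviation pooled over trials (0 maps to scale 1)."""
    out = {}
    for name in feature_names:
        pooled = np.concatenate([_as_feature_dict(f)[name] for f in feats_per_trial])
        sd = float(pooled.std())
        out[name] = sd if sd > 0 else 1.0
    return out


# ---------------------------------------------------------------------------
# ridge solve
# ---------------------------------------------------------------------------

def _ridge_solve(XtX: np.ndarray, XtY: np.ndarray, lam: float) -> np.ndarray:
    """Solve (XtX + lam*I')W = XtY with the identity zeroed at the bias column."""
    if lam <= 0:
        raise ValueError(
            "lambda must be positive; lambda=0 is not supported -- use a value "
            "from the tuning grid (e.g. 1e-6)"
        )
    A = XtX.copy()
    idx = np.arange(A.shape[0] - 1)
    A[idx, idx] += lam
    try:
        return spla.solve(A, XtY, assume_a="pos")
    except np.linalg.LinAlgError:  # pragma: no cover - degenerate fallback
        return np.linalg.lstsq(A, XtY, rcond=None)[0]


def ridge_fit(
    design: np.ndarray,
    eeg_trial: np.ndarray,
    lam: float,
    lag_spec: LagSpec,
    feature_names: Sequence[str],
) -> TRFModel:
    """Ridge regression of one trial on an explicit lagged design.

    ``design`` is samples x (features*lags + bias); ``eeg_trial`` is
    channels x samples. The bias column is unpenalized.
    """
    Y = np.asarray(eeg_trial, dtype=float).T
    if design.shape[0] != Y.shape[0]:
        raise ValueError("design rows must equal EEG samples")
    W = _ridge_solve(design.T @ design, design.T @ Y, lam)
    n_lags = lag_spec.n_lags
    weights = W[:-1].reshape(len(feature_names), n_lags, -1)
    return TRFModel(
        weights=weights, bias=W[-1], lambda_used=float(lam),
        lag_spec=lag_spec, feature_names=list(feature_names),
    )


def predict_eeg(model: TRFModel, features) -> np.ndarray:
    """Predicted EEG (channels x samples) for a stimulus feature set."""
    feats = _as_feature_dict(features)
    missing = [n for n in model.feature_names if n not in feats]
    if missing:
        raise ValueError(f"features missing for prediction: {missing}")
    if isinstance(features, StimulusFeatureSet) and features.fs != model.lag_spec.fs:
        raise ValueError("feature sampling rate does not match the model")
    X, _ = build_lagged_design(feats, model.lag_spec, model.feature_names)
    W = np.vstack([
        model.weights.reshape(-1, model.n_channels),
        model.bias[None, :],
    ])
    return (X @ W).T


# ---------------------------------------------------------------------------
# valid-sample scoring
# ---------------------------------------------------------------------------

def valid_sample_mask(
    features, lag_spec: LagSpec, n_samples: int | None = None,
    onset_feature_names: Sequence[str] | None = None,
) -> np.ndarray:
    """Boolean mask of samples within 0-500 ms after any onset impulse.

    The mask is the union over all onset-type features of the window
    ``[onset_sample, onset_sample + n_lags - 1]``. Envelope-type features
    contribute nothing; a model with no onset features gets an all-true
    mask (every sample is predictable from a continuous regressor).
    """
    feats = _as_feature_dict(features)
    if n_samples is None:
        n_samples = len(next(iter(feats.values())))
    if onset_feature_names is None:
        onset_feature_names = [n for n in feats if n.endswith(ONSET_FEATURE_SUFFIX)]
    if not onset_feature_names:
        return np.ones(n_samples, dtype=bool)
    mask = np.zeros(n_samples, dtype=bool)
    width = lag_spec.n_lags
    for name in onset_feature_names:
        for s in np.flatnonzero(feats[name]):
            mask[s : s + width] = True
    return mask


def valid_sample_correlation(
    pred: np.ndarray, actual: np.ndarray, mask: np.ndarray
) -> np.ndarray:
    """Per-channel Pearson r between prediction and EEG on masked samples.

    Channels whose masked segment is constant (zero variance) get NaN --
    the correlation is undefined, recorded as missing rather than 0.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 3:
        raise ValueError("valid-sample mask must select at least 3 samples")
    P = np.asarray(pred, dtype=float)[:, mask]
    A = np.asarray(actual, dtype=float)[:, mask]
    P = P - P.mean(axis=1, keepdims=True)
    A = A - A.mean(axis=1, keepdims=True)
    denom = np.sqrt((P**2).sum(axis=1) * (A**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (P * A).sum(axis=1) / denom, np.nan)
    return r


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def _trial_stats(feats_per_trial, eeg, lag_spec, names, scales):
    """Per-trial (XtX, XtY) for the union design, computed trial by trial."""
    xtx, xty = [], []
    for feats, trial in zip(feats_per_trial, eeg.trials):
        X, _ = build_lagged_design(feats, lag_spec, names, scales)
        if X.shape[0] != trial.shape[1]:
            raise ValueError("trial sample count does not match its features")
        Y = trial.T
        xtx.append(X.T @ X)
        xty.append(X.T @ Y)
    return xtx, xty


def _model_columns(names: Sequence[str], model_names: Sequence[str], n_lags: int):
    cols = []
    for name in model_names:
        fi = list(names).index(name)
        cols.extend(range(fi * n_lags, (fi + 1) * n_lags))
    cols.append(len(names) * n_lags)  # bias
    return np.asarray(cols)


@dataclass
class CrossValResult:
    model: TRFModel
    accuracy: AccuracyTable
    mse: float  # valid-sample MSE averaged over test trials and channels


def crossval_submodels(
    feats_per_trial: Sequence,
    eeg: EEGTrialSet,
    lam: float,
    lag_spec: LagSpec,
    models: Mapping[str, Sequence[str]],
    per_feature_standardize: bool = True,
    condition: str = "",
) -> dict[str, CrossValResult]:
    """Leave-one-trial-out CV for several nested feature subsets at once.

    The union design's per-trial covariance is computed once; every
    requested model is an exact column subset of it, so fitting all three
    onset models (word / phoneme / word+phoneme) costs one covariance pass.
    Returns, per model, the fold-averaged TRF, the trial x channel accuracy
    table, and the valid-sample MSE used for lambda tuning.
    """
    if len(feats_per_trial) != eeg.n_trials:
        raise ValueError("one feature set per EEG trial is required")
    if eeg.n_trials < 2:
        raise ValueError("cross-validation needs at least 2 trials")
    names = list(_as_feature_dict(feats_per_trial[0]))
    for feats in feats_per_trial:
        if list(_as_feature_dict(feats)) != names:
            raise ValueError("trials carry mismatched feature names")
    scales = (
        feature_scales(feats_per_trial, names) if per_feature_standardize
        else {n: 1.0 for n in names}
    )
    xtx, xty = _trial_stats(feats_per_trial, eeg, lag_spec, names, scales)
    xtx_tot = np.sum(xtx, axis=0)
    xty_tot = np.sum(xty, axis=0)
    n_lags = lag_spec.n_lags

    out: dict[str, CrossValResult] = {}
    for model_id, model_names in models.items():
        cols = _model_columns(names, model_names, n_lags)
        fold_weights = []
        fold_bias = []
        r_rows = []
        frac_rows = []
        sq_err, n_pts = 0.0, 0
        for ti, (feats, trial) in enumerate(zip(feats_per_trial, eeg.trials)):
            A = (xtx_tot - xtx[ti])[np.ix_(cols, cols)]
            B = (xty_tot - xty[ti])[cols]
            W = _ridge_solve(A, B, lam)
            sub = (
                feats.subset(model_names) if isinstance(feats, StimulusFeatureSet)
                else {n: _as_feature_dict(feats)[n] for n in model_names}
            )
            Xt, _ = build_lagged_design(sub, lag_spec, model_names, scales)
            pred = (Xt @ W).T
            mask = valid_sample_mask(sub, lag_spec, Xt.shape[0])
            r_rows.append(valid_sample_correlation(pred, trial, mask))
            frac_rows.append(mask.mean())
            diff = pred[:, mask] - trial[:, mask]
            sq_err += float((diff**2).sum())
            n_pts += diff.size
            fold_weights.append(W[:-1])
            fold_bias.append(W[-1])
        mean_w = np.mean(fold_weights, axis=0)
        weights = mean_w.reshape(len(model_names), n_lags, -1)
        # map back to unscaled-regressor units
        for fi, name in enumerate(model_names):
            weights[fi] /= scales[name]
        model = TRFModel(
            weights=weights, bias=np.mean(fold_bias, axis=0),
            lambda_used=float(lam), lag_spec=lag_spec,
            feature_names=list(model_names),
        )
        acc = AccuracyTable(
            r=np.vstack(r_rows), valid_sample_fraction=np.asarray(frac_rows),
            model_id=model_id, condition=condition,
        )
        out[model_id] = CrossValResult(model=model, accuracy=acc, mse=sq_err / n_pts)
    return out


def crossval_trf(
    feats_per_trial: Sequence,
    eeg: EEGTrialSet,
    lam: float,
    lag_spec: LagSpec,
    per_feature_standardize: bool = True,
    condition: str = "",
) -> tuple[TRFModel, AccuracyTable]:
    """Leave-one-trial-out CV of the full feature set; see crossval_submodels."""
    names = list(_as_feature_dict(feats_per_trial[0]))
    res = crossval_submodels(
        feats_per_trial, eeg, lam, lag_spec, {"full": names},
        per_feature_standardize=per_feature_standardize, condition=condition,
    )["full"]
    return res.model, res.accuracy


def tune_lambda(
    feats_per_trial: Sequence,
    eeg: EEGTrialSet,
    grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    lag_spec: LagSpec | None = None,
    per_feature_standardize: bool = True,
) -> tuple[float, np.ndarray]:
    """Grid-search lambda by cross-validated valid-sample MSE.

    The MSE is averaged across test trials and channels; ties resolve to
    the smaller lambda (the grid is ascending and argmin takes the first).
    Returns (lambda_opt, mse_per_grid_value).
    """
    grid = [float(g) for g in grid]
    if not grid:
        raise ValueError("empty lambda grid")
    if lag_spec is None:
        lag_spec = LagSpec(fs=eeg.fs)
    names = list(_as_feature_dict(feats_per_trial[0]))
    scales = (
        feature_scales(feats_per_trial, names) if per_feature_standardize
        else {n: 1.0 for n in names}
    )
    xtx, xty = _trial_stats(feats_per_trial, eeg, lag_spec, names, scales)
    xtx_tot = np.sum(xtx, axis=0)
    xty_tot = np.sum(xty, axis=0)
    sq_err = np.zeros(len(grid))
    n_pts = np.zeros(len(grid))
    for ti, (feats, trial) in enumerate(zip(feats_per_trial, eeg.trials)):
        Xt, _ = build_lagged_design(feats, lag_spec, names, scales)
        mask = valid_sample_mask(feats, lag_spec, Xt.shape[0])
        A = xtx_tot - xtx[ti]
        B = xty_tot - xty[ti]
        for gi, lam in enumerate(grid):
            W = _ridge_solve(A, B, lam)
            pred = (Xt @ W).T
            diff = pred[:, mask] - trial[:, mask]
            sq_err[gi] += float((diff**2).sum())
            n_pts[gi] += diff.size
    mse = sq_err / n_pts
    return grid[int(np.argmin(mse))], mse
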