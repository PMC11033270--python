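"""Sliding-window segmentation and per-window MVAR estimation.

Each window is modelled as a vector autoregression
``x_t = v + sum_{k=1..p} A_k x_{t-k} + u_t`` fitted by per-equation ordinary
least squares after per-window mean removal (so the estimated intercept is
~0; the field is retained for completeness). Model order is chosen by the
Akaike information criterion, and fitted models are checked with three
diagnostics: residual whiteness (Ljung-Box), a consistency percentage
comparing the lagged correlation structure of the data with that of data
simulated from the fitted model, and companion-matrix stability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.diagnostic import acorr_ljungbox

from .synthetic import Recording, VARTruth, simulate_recording

DEFAULT_WIN_S = 6.0
DEFAULT_STEP_S = 4.0
DEFAULT_P_MAX = 12


@dataclass
class WindowSet:
    windows: list[np.ndarray]
    starts: np.ndarray
    win_s: float
    step_s: float
    source: str = ""

    def __len__(self) -> int:
        return len(self.windows)


@dataclass
class MVARModel:
    order: int
    coefficients: tuple[np.ndarray, ...]
    intercept: np.ndarray
    noise_covariance: np.ndarray
    residuals: np.ndarray
    n_samples_effective: int

    @property
    def n_channels(self) -> int:
        return self.coefficients[0].shape[0]

    def as_truth(self) -> VARTruth:
        return VARTruth(self.order, self.coefficients,
                        self.noise_covariance, self.intercept)

    def companion_radius(self) -> float:
        return self.as_truth().spectral_radius()


@dataclass
class ModelDiagnostics:
    whiteness_pvalue: float
    consistency_percent: float
    stable: bool
    companion_radius: float
    aic_curve: dict[int, float] | None = None


def window_count(n_samples: int, win_samples: int, step_samples: int) -> int:
    """Number of full windows: floor((T - T_w)/step) + 1; remainder dropped."""
    if win_samples > n_samples:
        raise ValueError("window longer than recording")
    return (n_samples - win_samples) // step_samples + 1


def segment_windows(recording: Recording, win_s: float = DEFAULT_WIN_S,
                    step_s: float = DEFAULT_STEP_S) -> WindowSet:
    """Slide a win_s window along the recording with step step_s.

    At the study geometry (150 s, 128 Hz, 6-s window, 4-s step) this yields
    37 windows per recording.
    """
    if step_s <= 0:
        raise ValueError("step_s must be positive")
    w = int(round(win_s * recording.fs))
    s = int(round(step_s * recording.fs))
    n = window_count(recording.n_samples, w, s)
    starts = np.arange(n) * s
    windows = [recording.data[st:st + w] for st in starts]
    return WindowSet(windows, starts, win_s, step_s, source=recording.subject_id)


def _lagged_design(x: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Response x_t (t >= p) and regressor matrix [x_{t-1}, ..., x_{t-p}]."""
    T, m = x.shape
    Y = x[order:]
    Z = np.hstack([x[order - k - 1:T - k - 1] for k in range(order)])
    return Y, Z


def _common_mode_basis(order: int, m: int) -> np.ndarray:
    """Orthonormal basis of the common-mode regressor directions (one per lag)."""
    B = np.zeros((order, order * m))
    for k in range(order):
        B[k, k * m:(k + 1) * m] = 1.0 / np.sqrt(m)
    return B


def fit_mvar(window: np.ndarray, order: int) -> MVARModel:
    """Least-squares VAR(p) fit on one window (mean removed first).

    Average-referenced data are exactly rank-deficient along the channel
    common mode; that known, benign deficiency is tolerated via the
    minimum-norm solution (unique on the data subspace). Any other rank
    deficiency — duplicated or constant channels — raises a singular-fit
    error.
    """
    x = np.asarray(window, dtype=float)
    T, m = x.shape
    if T - order < m * order + 1:
        raise ValueError("window too short for the requested order")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite data")
    mean = x.mean(axis=0)
    xc = x - mean
    Y, Z = _lagged_design(xc, order)
    coef, _, rank, sv = np.linalg.lstsq(Z, Y, rcond=None)
    if rank < Z.shape[1]:
        u_, s_, vt = np.linalg.svd(Z, full_matrices=False)
        tol = s_[0] * max(Z.shape) * np.finfo(float).eps
        null = vt[(s_ > tol).sum():]
        B = _common_mode_basis(order, m)
        outside = null - (null @ B.T) @ B
        if null.size == 0 or np.abs(outside).max() > 1e-6:
            raise np.linalg.LinAlgError(
                "singular fit: rank-deficient regressor matrix (duplicated or constant channels?)")
    resid = Y - Z @ coef
    n_eff = T - order
    sigma = resid.T @ resid / n_eff
    # coef rows are stacked [A_1'; A_2'; ...]: slice back into M x M lags
    A = tuple(coef[k * m:(k + 1) * m].T for k in range(order))
    intercept = mean - sum(Ak @ mean for Ak in A)
    return MVARModel(order, A, intercept, sigma, resid, n_eff)


def aic(model: MVARModel) -> float:
    """AIC(p) = N_eff ln det(Sigma_hat) + 2 p M^2."""
    m = model.n_channels
    sign, logdet = np.linalg.slogdet(model.noise_covariance)
    if sign <= 0:
        return np.inf
    return model.n_samples_effective * logdet + 2 * model.order * m * m


def select_order_aic(window: np.ndarray, p_max: int = DEFAULT_P_MAX) -> tuple[int, dict[int, float]]:
    """Pick the VAR order minimising AIC over 1..p_max (ties -> smaller p)."""
    if p_max < 1:
        raise ValueError("p_max must be >= 1")
    curve: dict[int, float] = {}
    for p in range(1, p_max + 1):
        curve[p] = aic(fit_mvar(window, p))
    best = min(curve, key=lambda p: (curve[p], p))
    return best, curve


def _lagged_correlations(x: np.ndarray, n_lags: int) -> np.ndarray:
    """Stacked cross-correlation matrices R(0..L) of a demeaned series."""
    xc = x - x.mean(axis=0)
    T, m = xc.shape
    sd = xc.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    xs = xc / sd
    out = np.empty((n_lags + 1, m, m))
    for lag in range(n_lags + 1):
        out[lag] = xs[lag:].T @ xs[:T - lag] / T
    return out


def validate_model(model: MVARModel, window: np.ndarray, n_lags: int = 20,
                   seed: int = 0) -> ModelDiagnostics:
    """The three standard MVAR diagnostics.

    Whiteness: per-channel Ljung-Box portmanteau on the residuals at lags
    1..n_lags, combined by the worst-case (minimum) p-value. Consistency:
    100 * (1 - ||R_data - R_model||_F / ||R_data||_F) where R collects the
    lag-0..n_lags correlation matrices of the window and of an equally long
    simulation from the fitted model. Stability: companion spectral radius < 1.
    """
    radius = model.companion_radius()
    stable = radius < 1.0
    lb_lags = min(n_lags, max(1, model.residuals.shape[0] // 2 - 1))
    pvals = []
    for ch in range(model.n_channels):
        lb = acorr_ljungbox(model.residuals[:, ch], lags=[lb_lags], return_df=False)
        pvals.append(float(lb["lb_pvalue"].iloc[0]))
    whiteness = float(min(pvals))

    if stable:
        T = window.shape[0]
        sigma = model.noise_covariance
        # tiny ridge keeps the Cholesky factor well-defined on near-singular fits
        truth = VARTruth(model.order, model.coefficients,
                         sigma + 1e-10 * np.trace(sigma) / model.n_channels * np.eye(model.n_channels),
                         model.intercept)
        sim = simulate_recording(truth, duration_s=T, fs=1.0,
                                 seed=seed, burn_in=max(100, 10 * model.order),
                                 scale_uv=1.0)
        r_data = _lagged_correlations(np.asarray(window, float), n_lags)
        r_model = _lagged_correlations(sim.data, n_lags)
        denom = np.linalg.norm(r_data)
        consistency = 100.0 * (1.0 - np.linalg.norm(r_data - r_model) / denom) if denom > 0 else 0.0
    else:
        consistency = 0.0
    return ModelDiagnostics(whiteness, float(consistency), stable, float(radius))
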