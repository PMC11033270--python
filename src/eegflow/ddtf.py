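"""Frequency-domain VAR transforms and the direct directed transfer function.

From a fitted VAR(p) the characteristic matrix is
``A(f) = I - sum_{k=1..p} A_k exp(-i 2 pi f k / fs)`` (the standard sign
convention; an overall sign flip leaves every magnitude-based quantity below
unchanged); the transfer matrix is ``H(f) = A(f)^-1`` and the spectral
density matrix is ``S(f) = H(f) Sigma H(f)*``.

The dDTF from channel j to channel i at frequency f multiplies a
full-frequency-normalised DTF factor by a coherence factor:

    dDTF_ij(f) = |H_ij(f)|^2 / (sum_f sum_k |H_ik(f)|^2)
                 x |S_ij(f)| / sqrt(S_ii(f) S_jj(f))

The first factor's denominator runs over the whole frequency grid, so summing
it over sources j and frequencies gives exactly 1 per target i. The coherence
factor uses the magnitude of the (complex) cross-spectrum; by Cauchy-Schwarz
it lies in [0, 1], hence dDTF in [0, 1]. A ``partial`` coherence mode replaces
S with the partial cross-spectrum (from the inverse spectral matrix), the
variant that suppresses indirect cascades more aggressively; the default mode
uses the ordinary spectral matrix.

Index convention: dDTF[i, j] is flow j -> i (source = column, target = row);
exports label edges "source=>target".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mvar import MVARModel, fit_mvar, select_order_aic, validate_model, segment_windows
from .synthetic import Recording

BANDS: dict[str, tuple[float, float]] = {
    "delta": (2.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 32.0),
    "gamma": (32.0, 50.0),
}
BAND_NAMES = tuple(BANDS)
DEFAULT_FREQS = np.arange(1.0, 51.0)  # 1..50 Hz inclusive, 1 Hz spacing


@dataclass
class SpectralSet:
    freqs: np.ndarray
    A_f: np.ndarray            # (F, M, M) complex
    H_f: np.ndarray            # (F, M, M) complex
    S_f: np.ndarray | None = None
    coherence_basis: str = "plain"


@dataclass
class BandSpec:
    """Named frequency intervals; all but the last are half-open [lo, hi)."""

    bands: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(BANDS))

    def members(self, freqs: np.ndarray) -> dict[str, np.ndarray]:
        out = {}
        names = list(self.bands)
        for i, name in enumerate(names):
            lo, hi = self.bands[name]
            if i == len(names) - 1:
                mask = (freqs >= lo) & (freqs <= hi)
            else:
                mask = (freqs >= lo) & (freqs < hi)
            if not mask.any():
                raise ValueError(f"band {name!r} contains no grid frequency")
            out[name] = np.flatnonzero(mask)
        return out


@dataclass
class ConnectivityTensor:
    """Band-averaged dDTF per window: values[window, band, target i, source j]."""

    values: np.ndarray
    channel_names: tuple[str, ...]
    band_names: tuple[str, ...]
    recording_id: str = ""
    condition: str | None = None
    valid: np.ndarray | None = None  # per-window validity mask

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]


def transfer_function(model: MVARModel, freqs: np.ndarray = DEFAULT_FREQS,
                      fs: float = 128.0) -> SpectralSet:
    """Evaluate A(f) and H(f) = A(f)^-1 on the frequency grid."""
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs >= fs / 2):
        raise ValueError("frequencies must lie below Nyquist")
    m = model.n_channels
    F = len(freqs)
    A_f = np.empty((F, m, m), dtype=complex)
    phase = np.exp(-2j * np.pi * np.outer(freqs / fs, np.arange(1, model.order + 1)))
    for fi in range(F):
        acc = np.eye(m, dtype=complex)
        for k in range(model.order):
            acc -= phase[fi, k] * model.coefficients[k]
        A_f[fi] = acc
    H_f = np.empty_like(A_f)
    for fi in range(F):
        try:
            H_f[fi] = np.linalg.inv(A_f[fi])
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"singular A(f) at f = {freqs[fi]:g} Hz") from err
    return SpectralSet(freqs, A_f, H_f)


def spectral_density(spectral: SpectralSet, noise_covariance: np.ndarray) -> SpectralSet:
    """Fill in S(f) = H(f) Sigma H(f)^*."""
    sigma = np.asarray(noise_covariance, dtype=float)
    if np.any(np.linalg.eigvalsh((sigma + sigma.T) / 2) < -1e-10 * max(1.0, np.trace(sigma))):
        raise ValueError("noise covariance must be positive semidefinite")
    H = spectral.H_f
    S = H @ sigma @ np.conj(np.swapaxes(H, 1, 2))
    spectral.S_f = S
    return spectral


def _partial_spectrum(S: np.ndarray) -> np.ndarray:
    """Partial cross-spectra via the inverse spectral matrix at each frequency."""
    P = np.linalg.inv(S)
    # partial coherence between i and j given the rest: -P_ij / sqrt(P_ii P_jj)
    d = np.sqrt(np.einsum("fii->fi", P).real)
    out = -P / (d[:, :, None] * d[:, None, :])
    idx = np.arange(S.shape[1])
    out[:, idx, idx] = 1.0
    return out


def ddtf_matrix(spectral: SpectralSet) -> np.ndarray:
    """dDTF values on the frequency grid: array (F, M, M), [f, target, source]."""
    if spectral.S_f is None:
        raise ValueError("spectral density not computed; call spectral_density first")
    H2 = np.abs(spectral.H_f) ** 2                       # (F, M, M)
    denom = H2.sum(axis=(0, 2))                          # per target i: sum_f sum_k
    if np.any(denom <= 0):
        raise ValueError("degenerate channel: zero total transfer power")
    ff_dtf = H2 / denom[None, :, None]

    if spectral.coherence_basis == "partial":
        coh = np.abs(_partial_spectrum(spectral.S_f))
    else:
        S = spectral.S_f
        diag = np.einsum("fii->fi", S).real
        if np.any(diag <= 0):
            raise ValueError("degenerate channel: zero diagonal spectral power")
        coh = np.abs(S) / np.sqrt(diag[:, :, None] * diag[:, None, :])
    return ff_dtf * np.clip(coh, 0.0, 1.0)


def band_average(ddtf: np.ndarray, freqs: np.ndarray = DEFAULT_FREQS,
                 bands: BandSpec | None = None) -> np.ndarray:
    """Arithmetic mean of dDTF over grid frequencies inside each band -> (B, M, M)."""
    spec = bands or BandSpec()
    members = spec.members(np.asarray(freqs, float))
    return np.stack([ddtf[idx].mean(axis=0) for idx in members.values()])


@dataclass(frozen=True)
class ConnectivityConfig:
    win_s: float = 6.0
    step_s: float = 4.0
    order: int | None = None       # None -> per-window AIC selection
    p_max: int = 12
    freqs: tuple[float, ...] = tuple(DEFAULT_FREQS)
    coherence_basis: str = "plain"
    run_diagnostics: bool = False
    exclude_invalid: bool = False  # diagnostics are advisory by default


def connectivity_for_recording(recording: Recording,
                               config: ConnectivityConfig | None = None) -> ConnectivityTensor:
    """Per window: fit MVAR -> spectra -> dDTF -> band average.

    Windows whose fit fails are marked invalid and left as NaN; at the study
    geometry (150 s, 14 channels) the tensor is 37 x 5 x 14 x 14.
    """
    cfg = config or ConnectivityConfig()
    ws = segment_windows(recording, cfg.win_s, cfg.step_s)
    freqs = np.asarray(cfg.freqs, float)
    bands = BandSpec()
    m = recording.n_channels
    n_b = len(bands.bands)
    values = np.full((len(ws), n_b, m, m), np.nan)
    valid = np.zeros(len(ws), dtype=bool)
    for wi, window in enumerate(ws.windows):
        try:
            if cfg.order is not None:
                p = cfg.order
            else:
                p, _ = select_order_aic(window, cfg.p_max)
            model = fit_mvar(window, p)
            if cfg.run_diagnostics:
                diag = validate_model(model, window, seed=wi)
                if cfg.exclude_invalid and not diag.stable:
                    continue
            spec = transfer_function(model, freqs, fs=recording.fs)
            spec.coherence_basis = cfg.coherence_basis
            spectral_density(spec, model.noise_covariance)
            values[wi] = band_average(ddtf_matrix(spec), freqs, bands)
            valid[wi] = True
        except np.linalg.LinAlgError:
            continue
    return ConnectivityTensor(values, recording.channel_names, tuple(bands.bands),
                              recording_id=recording.subject_id,
                              condition=recording.condition, valid=valid)
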