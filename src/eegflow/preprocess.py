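"""Four-step EEG cleaning pipeline.

Order of operations: 1 Hz high-pass (drift, sweat, movement), narrowband line-
noise removal, simplified artifact subspace reconstruction (ASR) for large-
amplitude transients, and average re-referencing. All steps preserve the
T x M shape; ASR reconstructs rather than drops samples, so downstream window
counts stay deterministic.

The ASR here is a deliberate simplification of the published algorithm: the
calibration segment is the RMS-quietest contiguous stretch, thresholds are
``cutoff_k`` times the calibration component standard deviation along each
block's principal axes, and offending components are attenuated to the
threshold and reconstructed. Parity with the EEGLAB implementation is a
non-goal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .synthetic import Recording


@dataclass(frozen=True)
class PreprocessConfig:
    highpass_hz: float = 1.0
    line_freq_hz: float = 50.0
    notch_width_hz: float = 1.0
    asr_cutoff_k: float = 20.0
    asr_calibration_s: float = 10.0
    asr_window_s: float = 0.5
    rereference: bool = True

    def __post_init__(self):
        if self.highpass_hz is not None and self.highpass_hz <= 0:
            raise ValueError("highpass_hz must be positive")
        if self.asr_cutoff_k <= 0:
            raise ValueError("asr_cutoff_k must be positive")


def highpass(recording: Recording, cutoff_hz: float = 1.0, order: int = 4) -> Recording:
    """Zero-phase Butterworth high-pass (forward-backward, -3 dB at cutoff)."""
    nyq = recording.fs / 2
    if not (0 < cutoff_hz < nyq):
        raise ValueError(f"cutoff {cutoff_hz} Hz must lie in (0, {nyq}) Hz")
    sos = signal.butter(order, cutoff_hz, btype="highpass", fs=recording.fs, output="sos")
    out = signal.sosfiltfilt(sos, recording.data, axis=0)
    return recording.copy_with(out, step=f"highpass({cutoff_hz} Hz)")


def remove_line_noise(
    recording: Recording,
    line_freq_hz: float = 50.0,
    width_hz: float = 1.0,
    harmonics: bool = True,
) -> Recording:
    """Zero-phase IIR notch at the line frequency (and in-band harmonics).

    Width defaults to 1 Hz so that, at fs = 128 with the gamma band ending at
    50 Hz, the notch distorts as little of the band edge as possible.
    Harmonics at or above Nyquist are skipped.
    """
    nyq = recording.fs / 2
    if line_freq_hz >= nyq:
        raise ValueError(f"line frequency {line_freq_hz} Hz is not below Nyquist {nyq} Hz")
    freqs = [line_freq_hz]
    if harmonics:
        k = 2
        while k * line_freq_hz < nyq:
            freqs.append(k * line_freq_hz)
            k += 1
    data = recording.data
    for f0 in freqs:
        # forward-backward filtering squares the response, doubling the
        # effective notch width: design at half the nominal width
        q = f0 / (width_hz / 2)
        b, a = signal.iirnotch(f0, q, fs=recording.fs)
        # narrow notch -> long impulse response: pad well beyond the default
        padlen = min(data.shape[0] - 1, int(10 * recording.fs / width_hz))
        data = signal.filtfilt(b, a, data, axis=0, padlen=padlen)
    return recording.copy_with(data, step=f"remove_line_noise({line_freq_hz} Hz)")


def _quietest_segment(data: np.ndarray, n: int) -> np.ndarray:
    """Contiguous stretch of n samples with the smallest total RMS."""
    power = np.sum(data ** 2, axis=1)
    csum = np.concatenate([[0.0], np.cumsum(power)])
    window_power = csum[n:] - csum[:-n]
    start = int(np.argmin(window_power))
    return data[start:start + n]


def asr_clean(
    recording: Recording,
    cutoff_k: float = 20.0,
    calibration_s: float = 10.0,
    window_s: float = 0.5,
) -> Recording:
    """Simplified artifact subspace reconstruction.

    Calibrates on the RMS-quietest ``calibration_s`` stretch, then processes
    consecutive ``window_s`` blocks: each block's principal components whose
    standard deviation exceeds ``cutoff_k`` times the calibration-projected
    component std are attenuated to the threshold and the block reconstructed.
    ``cutoff_k = inf`` disables cleaning entirely.
    """
    if math.isinf(cutoff_k):
        return recording.copy_with(recording.data.copy(), step="asr_clean(disabled)")
    if cutoff_k <= 0:
        raise ValueError("cutoff_k must be positive")
    T, m = recording.data.shape
    n_cal = int(round(calibration_s * recording.fs))
    if T < n_cal:
        raise ValueError("recording shorter than the ASR calibration segment")
    calib = _quietest_segment(recording.data, n_cal)
    calib = calib - calib.mean(axis=0)
    C_cal = calib.T @ calib / max(1, len(calib) - 1)

    w = max(m + 1, int(round(window_s * recording.fs)))
    out = recording.data.copy()
    for start in range(0, T, w):
        block = out[start:start + w]
        if len(block) <= m:
            continue
        # no block demeaning: a local mean is itself artifact-contaminated
        # inside a burst; ASR runs after the high-pass, so data are centred
        C = block.T @ block / (len(block) - 1)
        evals, evecs = np.linalg.eigh(C)
        comp_std = np.sqrt(np.maximum(evals, 0.0))
        # calibration-derived threshold along this block's axes
        thr = cutoff_k * np.sqrt(np.maximum(np.einsum("im,ij,jm->m", evecs, C_cal, evecs), 1e-12))
        scale = np.where(comp_std > thr, thr / np.maximum(comp_std, 1e-12), 1.0)
        if np.all(scale == 1.0):
            continue
        proj = block @ evecs
        out[start:start + w] = (proj * scale) @ evecs.T
    return recording.copy_with(out, step=f"asr_clean(k={cutoff_k})")


def rereference_average(recording: Recording) -> Recording:
    """Subtract the per-sample channel mean (common average reference)."""
    if recording.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    data = recording.data - recording.data.mean(axis=1, keepdims=True)
    return recording.copy_with(data, step="rereference_average")


def preprocess_pipeline(recording: Recording, config: PreprocessConfig | None = None) -> Recording:
    """Apply the cleaning steps in order: high-pass, line noise, ASR, re-reference.

    Each enabled step appends its tag to the recording's provenance log; a step
    is skipped when its config field is None / inf / False.
    """
    cfg = config or PreprocessConfig()
    rec = recording
    if cfg.highpass_hz is not None:
        rec = highpass(rec, cfg.highpass_hz)
    if cfg.line_freq_hz is not None:
        rec = remove_line_noise(rec, cfg.line_freq_hz, cfg.notch_width_hz)
    if cfg.asr_cutoff_k is not None and not math.isinf(cfg.asr_cutoff_k):
        rec = asr_clean(rec, cfg.asr_cutoff_k, cfg.asr_calibration_s, cfg.asr_window_s)
    if cfg.rereference:
        rec = rereference_average(rec)
    return rec
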