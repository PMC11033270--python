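"""Two-class synthetic multichannel EEG from stable VAR processes.

Recordings are drawn from vector-autoregressive (VAR) processes with a known
directed coupling topology, so every downstream stage — cleaning, windowed MVAR
estimation, dDTF connectivity, feature ranking and classification — can be
tested against ground truth. The generator emulates the geometry of the STEW
mental-workload corpus: 48 subjects, two conditions (low / high workload),
14 channels at 128 Hz, 150 s per recording.

Class structure is encoded as class-dependent gains on a fixed set of directed
edges: both classes share the coupling topology, but the strength of the
couplings differs, which is exactly the kind of contrast a directed-connectivity
measure should pick up.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

STEW_CHANNELS = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)
STEW_FS = 128.0
STEW_DURATION_S = 150.0
STEW_N_SUBJECTS = 48

LOW, HIGH = "low", "high"


@dataclass(frozen=True)
class CouplingSpec:
    """Directed coupling topology with class-dependent edge gains.

    ``edges`` are ordered (source, target) channel-index pairs; ``class_gains``
    maps each class label to a per-edge gain vector (dimensionless multipliers
    on the base coupling coefficient). ``edge_freqs`` optionally gives each
    edge a resonant centre frequency in Hz: such couplings act through a
    damped-cosine lag kernel, concentrating the transmitted power near that
    frequency, so different frequency bands carry different parts of the class
    contrast (band-specific workload signatures). ``None`` entries (or
    ``edge_freqs=None``) mean broadband coupling.
    """

    n_channels: int
    edges: tuple[tuple[int, int], ...]
    class_gains: dict[str, np.ndarray]
    edge_freqs: tuple[float | None, ...] | None = None

    def __post_init__(self):
        if self.edge_freqs is not None and len(self.edge_freqs) != len(self.edges):
            raise ValueError("edge_freqs must have one entry per edge")
        if self.n_channels < 1:
            raise ValueError("n_channels must be positive")
        for s, t in self.edges:
            if s == t:
                raise ValueError(f"self-edge ({s},{t}) not allowed")
            if not (0 <= s < self.n_channels and 0 <= t < self.n_channels):
                raise ValueError(f"edge ({s},{t}) out of range [0,{self.n_channels})")
        if len(self.class_gains) < 2:
            raise ValueError("both class labels must be present in class_gains")
        for label, g in self.class_gains.items():
            g = np.asarray(g, dtype=float)
            if g.shape != (len(self.edges),):
                raise ValueError(f"class {label!r}: need one gain per edge")
            object.__setattr__(self, "class_gains",
                               {**self.class_gains, label: g})

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(sorted(self.class_gains))


@dataclass(frozen=True)
class VARTruth:
    """Ground-truth VAR(p) parameters: x_t = v + sum_k A_k x_{t-k} + u_t."""

    order: int
    coefficients: tuple[np.ndarray, ...]  # p matrices, each M x M
    noise_covariance: np.ndarray          # M x M, symmetric positive definite
    intercept: np.ndarray                 # length M

    @property
    def n_channels(self) -> int:
        return self.coefficients[0].shape[0]

    def companion(self) -> np.ndarray:
        """Companion (stacked) form of the coefficient matrices."""
        p, m = self.order, self.n_channels
        C = np.zeros((m * p, m * p))
        C[:m, :] = np.hstack(self.coefficients)
        if p > 1:
            C[m:, :-m] = np.eye(m * (p - 1))
        return C

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.companion()))))

    def is_stable(self) -> bool:
        return self.spectral_radius() < 1.0


@dataclass
class Recording:
    """A single multichannel recording: T samples x M channels, in microvolts."""

    data: np.ndarray
    fs: float
    channel_names: tuple[str, ...]
    condition: str | None = None
    subject_id: str = ""
    log: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a T x M matrix")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel_names length must match column count")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray, step: str | None = None) -> "Recording":
        out = replace(self, data=np.asarray(data, dtype=float))
        out.log = list(self.log)
        if step is not None:
            out.log.append(step)
        return out


@dataclass
class LabeledDataset:
    """A two-class collection of recordings plus the generating truth per class."""

    recordings: list[Recording]
    truth: dict[str, VARTruth]
    seed: int

    def __post_init__(self):
        labels = {r.condition for r in self.recordings}
        if None in labels:
            raise ValueError("every recording must carry a condition label")
        if len(labels) < 2:
            raise ValueError("both classes must be non-empty")


def _rescale_to_radius(coeffs: list[np.ndarray], target_radius: float) -> tuple[np.ndarray, ...]:
    """Uniformly shrink all A_k until the companion spectral radius <= target.

    Uniform rescaling (same factor on every lag) preserves the requested
    coupling topology and the relative strength of every edge.
    """
    truth = VARTruth(len(coeffs), tuple(coeffs),
                     np.eye(coeffs[0].shape[0]), np.zeros(coeffs[0].shape[0]))
    rho = truth.spectral_radius()
    if rho <= target_radius:
        return tuple(coeffs)
    # bisection on the scale factor; radius is continuous and monotone enough
    lo, hi = 0.0, 1.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        scaled = [mid * A for A in coeffs]
        t = VARTruth(len(coeffs), tuple(scaled), truth.noise_covariance, truth.intercept)
        if t.spectral_radius() <= target_radius:
            lo = mid
        else:
            hi = mid
    return tuple(lo * A for A in coeffs)


def make_var_coefficients(
    spec: CouplingSpec,
    order: int = 2,
    target_radius: float = 0.9,
    seed: int = 0,
    self_coupling: float = 0.4,
    edge_coupling: float = 0.5,
    fs: float = STEW_FS,
    damping: float = 0.85,
) -> dict[str, VARTruth]:
    """Build one stable VAR truth per class from a coupling topology.

    Each A_k gets a diagonal self-dependence (decaying with lag) plus nonzero
    off-diagonal entries exactly on ``spec.edges``, scaled by the class gain.
    Broadband edges use a geometrically decaying lag kernel; edges with a
    resonant centre frequency f0 use the damped cosine
    ``cos(2 pi f0 k / fs) * damping**k`` over lags k = 1..order, which shapes
    the transmitted spectrum around f0. The whole coefficient set is then
    uniformly rescaled so the companion spectral radius does not exceed
    ``target_radius`` (rescaling preserves the coupling topology).

    The construction is deterministic; ``seed`` is accepted for interface
    symmetry with the other generator operations.
    """
    del seed  # construction is deterministic given the spec
    if order < 1:
        raise ValueError("order must be >= 1")
    if not (0 < target_radius < 1):
        raise ValueError("target_radius must lie in (0, 1): an unstable process was requested")
    m = spec.n_channels
    lag_weights = np.array([0.6 ** k for k in range(order)])
    freqs = spec.edge_freqs or (None,) * len(spec.edges)
    out: dict[str, VARTruth] = {}
    for label in spec.labels:
        gains = spec.class_gains[label]
        coeffs = []
        for k in range(order):
            A = np.eye(m) * self_coupling * lag_weights[k]
            for e, (s, t) in enumerate(spec.edges):
                if freqs[e] is None:
                    g = lag_weights[k]
                else:
                    g = np.cos(2 * np.pi * freqs[e] * (k + 1) / fs) * damping ** (k + 1)
                # A[t, s]: channel t depends on lagged channel s (flow s -> t)
                A[t, s] += edge_coupling * gains[e] * g
            coeffs.append(A)
        coeffs = list(_rescale_to_radius(coeffs, target_radius))
        out[label] = VARTruth(order, tuple(coeffs), np.eye(m), np.zeros(m))
    return out


def simulate_recording(
    truth: VARTruth,
    duration_s: float = STEW_DURATION_S,
    fs: float = STEW_FS,
    seed: int = 0,
    burn_in: int = 500,
    scale_uv: float = 10.0,
    channel_names: tuple[str, ...] | None = None,
    condition: str | None = None,
    subject_id: str = "",
) -> Recording:
    """Run the VAR process forward with Gaussian innovations.

    The first ``burn_in`` samples are discarded so the returned series is a
    draw from the stationary distribution; ``scale_uv`` puts the output on a
    microvolt-like scale (innovation std in microvolts).
    """
    if not truth.is_stable():
        raise ValueError("unstable VAR truth: companion spectral radius >= 1")
    if burn_in < 100:
        raise ValueError("burn_in must be >= 100")
    T = int(round(duration_s * fs))
    if T < 10 * truth.order:
        raise ValueError("recording too short for the requested order")
    m, p = truth.n_channels, truth.order
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(truth.noise_covariance)
    innov = rng.standard_normal((T + burn_in, m)) @ L.T * scale_uv
    x = np.zeros((T + burn_in, m))
    v = truth.intercept
    for t in range(p, T + burn_in):
        acc = v + innov[t]
        for k in range(p):
            acc = acc + truth.coefficients[k] @ x[t - k - 1]
        x[t] = acc
    names = channel_names if channel_names is not None else _default_names(m)
    return Recording(x[burn_in:], fs=fs, channel_names=names,
                     condition=condition, subject_id=subject_id)


def _default_names(m: int) -> tuple[str, ...]:
    if m == len(STEW_CHANNELS):
        return STEW_CHANNELS
    return tuple(f"CH{i + 1}" for i in range(m))


def inject_artifacts(
    recording: Recording,
    n_bursts: int,
    amplitude: float = 500.0,
    duration_s: float = 1.0,
    seed: int = 0,
    channel_fraction: float = 0.5,
) -> Recording:
    """Add square-windowed high-amplitude low-frequency bursts.

    Emulates the large-amplitude transients (movement, electrode pops) that
    artifact subspace reconstruction targets; each burst hits a random subset
    of channels at a seeded position. Bursts are disjoint by construction.
    """
    if n_bursts == 0:
        return recording.copy_with(recording.data.copy())
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    T, m = recording.data.shape
    w = int(round(duration_s * recording.fs))
    if n_bursts * w > T:
        raise ValueError("bursts do not fit inside the recording")
    rng = np.random.default_rng(seed)
    # choose disjoint slots: partition the recording into n_bursts stripes and
    # place one burst uniformly inside each stripe
    stripe = T // n_bursts
    data = recording.data.copy()
    starts = []
    for b in range(n_bursts):
        lo = b * stripe
        hi = min((b + 1) * stripe, T) - w
        start = int(rng.integers(lo, max(lo + 1, hi + 1)))
        starts.append(start)
        n_ch = max(1, int(round(channel_fraction * m)))
        chans = rng.choice(m, size=n_ch, replace=False)
        t = np.arange(w) / recording.fs
        f0 = rng.uniform(0.5, 3.0)  # low-frequency content, like a motion artifact
        burst = amplitude * np.sin(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))
        for c in chans:
            data[start:start + w, c] += burst
    out = recording.copy_with(data, step=f"inject_artifacts(n={n_bursts})")
    out.log.append({"burst_starts": starts, "burst_len": w})
    return out


def burst_windows(recording: Recording) -> list[tuple[int, int]]:
    """Recover (start, stop) sample spans of injected bursts from the log."""
    spans = []
    for entry in recording.log:
        if isinstance(entry, dict) and "burst_starts" in entry:
            w = entry["burst_len"]
            spans.extend((s, s + w) for s in entry["burst_starts"])
    return spans


def make_two_class_dataset(
    spec: CouplingSpec,
    n_subjects: int = STEW_N_SUBJECTS,
    duration_s: float = STEW_DURATION_S,
    fs: float = STEW_FS,
    seed: int = 0,
    order: int = 2,
    target_radius: float = 0.9,
    subject_jitter: float = 0.10,
    sensor_noise_uv: float = 0.0,
    self_coupling: float = 0.4,
    edge_coupling: float = 0.5,
    artifact_bursts: int = 0,
    artifact_amplitude: float = 500.0,
) -> LabeledDataset:
    """Simulate one recording per condition per subject.

    Per-subject heterogeneity is a multiplicative jitter (default +/-10%) on
    the coefficient matrices. The jitter field is drawn once per *subject* and
    applied to both conditions' coefficients — a subject's individual dynamics
    are a property of the subject, not of the condition — so with equal class
    gains the two conditions of a subject are generated by an identical
    process (a true null). Jittered coefficients are re-stabilized by uniform
    rescaling if needed. ``sensor_noise_uv`` adds white measurement noise on
    top of the VAR signal.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    ss = np.random.SeedSequence(seed)
    truth = make_var_coefficients(spec, order=order, target_radius=target_radius,
                                  fs=fs, self_coupling=self_coupling,
                                  edge_coupling=edge_coupling)
    child_seeds = ss.spawn(n_subjects * (1 + 2 * len(truth)))
    recs: list[Recording] = []
    i = 0
    for subj in range(n_subjects):
        jit_seed = int(child_seeds[i].generate_state(1)[0] % 2**31)
        i += 1
        jitter_field = np.random.default_rng(jit_seed).uniform(
            -1, 1, size=(order, spec.n_channels, spec.n_channels))
        for label in sorted(truth):
            base = truth[label]
            sim_seed = int(child_seeds[i].generate_state(1)[0] % 2**31)
            noise_seed = int(child_seeds[i + 1].generate_state(1)[0] % 2**31)
            i += 2
            coeffs = [A * (1.0 + subject_jitter * jitter_field[k])
                      for k, A in enumerate(base.coefficients)]
            coeffs = list(_rescale_to_radius(coeffs, target_radius))
            subj_truth = VARTruth(base.order, tuple(coeffs),
                                  base.noise_covariance, base.intercept)
            rec = simulate_recording(subj_truth, duration_s=duration_s, fs=fs,
                                     seed=sim_seed, condition=label,
                                     subject_id=f"s{subj:02d}")
            if sensor_noise_uv > 0:
                nrng = np.random.default_rng(noise_seed)
                rec = rec.copy_with(
                    rec.data + nrng.standard_normal(rec.data.shape) * sensor_noise_uv)
            if artifact_bursts:
                rec = inject_artifacts(rec, artifact_bursts,
                                       amplitude=artifact_amplitude,
                                       seed=sim_seed + 1)
            recs.append(rec)
    return LabeledDataset(recs, truth, seed)


# ---------------------------------------------------------------------------
# STEW text dialect I/O: whitespace-delimited sample x channel matrix, no
# header, plus a JSON sidecar with sampling rate / labels / provenance.
# ---------------------------------------------------------------------------

def write_stew(recording: Recording, path: str | Path) -> Path:
    path = Path(path)
    np.savetxt(path, recording.data, fmt="%.6f")
    meta = {
        "fs": recording.fs,
        "channel_names": list(recording.channel_names),
        "condition": recording.condition,
        "subject_id": recording.subject_id,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))
    return path


def read_stew(path: str | Path, fs: float = STEW_FS,
              channel_names: tuple[str, ...] | None = None) -> Recording:
    path = Path(path)
    data = np.loadtxt(path)
    if data.ndim == 1:
        data = data[:, None]
    meta_path = path.with_suffix(path.suffix + ".json")
    condition = None
    subject_id = path.stem
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        fs = meta.get("fs", fs)
        channel_names = tuple(meta.get("channel_names") or ()) or channel_names
        condition = meta.get("condition")
        subject_id = meta.get("subject_id") or subject_id
    names = channel_names if channel_names else _default_names(data.shape[1])
    return Recording(data, fs=fs, channel_names=names,
                     condition=condition, subject_id=subject_id)


# centre frequencies assigned to successive differential edges: one per band
# (delta, theta, alpha, beta, gamma), then a second theta edge, cycling
DIFFERENTIAL_EDGE_FREQS = (3.0, 6.0, 10.0, 20.0, 40.0, 6.0)


def default_coupling_spec(
    n_differential_edges: int = 6,
    gain_ratio: float = 2.0,
    n_common_edges: int = 4,
    seed: int = 12345,
) -> CouplingSpec:
    """Default two-class study topology on the 14 STEW channels.

    A handful of couplings are shared by both classes at unit gain and a set
    of differential edges carry ``gain_ratio`` times more coupling in the
    high-workload class — the structural premise the whole analysis is built
    to detect. Each differential edge resonates in a different frequency band
    (damped-cosine kernel), so the bands carry complementary parts of the
    class contrast, as band-specific workload signatures do in real EEG.
    Edge endpoints are drawn once from a fixed seed so the topology is a
    constant of the package, not of the caller's seed.
    """
    m = len(STEW_CHANNELS)
    rng = np.random.default_rng(seed)
    edges: list[tuple[int, int]] = []
    while len(edges) < n_differential_edges + n_common_edges:
        s, t = (int(v) for v in rng.integers(0, m, size=2))
        if s != t and (s, t) not in edges:
            edges.append((s, t))
    n_e = len(edges)
    low = np.ones(n_e)
    high = np.ones(n_e)
    high[:n_differential_edges] = gain_ratio
    freqs: list[float | None] = [
        DIFFERENTIAL_EDGE_FREQS[e % len(DIFFERENTIAL_EDGE_FREQS)]
        for e in range(n_differential_edges)]
    freqs += [None] * n_common_edges
    return CouplingSpec(m, tuple(edges), {LOW: low, HIGH: high}, tuple(freqs))


def make_study_dataset(
    n_subjects: int = 12,
    duration_s: float = 90.0,
    seed: int = 0,
    gain_ratio: float = 2.0,
    artifact_bursts: int = 0,
) -> LabeledDataset:
    """The package's frozen desk-scale study conditions.

    Two classes differing by a 2x coupling gain on six band-resonant edges,
    order-6 VAR with self-coupling 0.35 / edge coupling 0.7 rescaled to
    companion radius 0.92, +/-10% per-subject coefficient jitter, and 10 uV
    white sensor noise on a 10 uV-innovation signal. ``gain_ratio=1`` gives
    the matched null dataset (no class difference).
    """
    spec = default_coupling_spec(gain_ratio=gain_ratio)
    return make_two_class_dataset(
        spec, n_subjects=n_subjects, duration_s=duration_s, fs=STEW_FS,
        seed=seed, order=6, target_radius=0.92, subject_jitter=0.10,
        sensor_noise_uv=10.0, self_coupling=0.35, edge_coupling=0.7,
        artifact_bursts=artifact_bursts)
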