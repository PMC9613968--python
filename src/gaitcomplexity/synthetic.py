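"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators:

* multi-joint periodic gait with controllable latent rank, amplitude
  scale, stride-to-stride latent deviation, stride-timing jitter and an
  optional chaotic (logistic-map) modulation of stride durations;
* two-dimensional Gaussian "toy clouds" for illustrating how variance- and
  dimensionality-based complexity measures can disagree;
* canonical benchmark signals (sine, white/pink noise, logistic map,
  Lorenz system) with known properties, used as oracles for the nonlinear
  estimators.

Every generator is a pure function of its configuration and seed: the same
seed yields bitwise-identical output.

The gait generator builds each joint's waveform inside the span of a p x r
loading matrix: with g_1..g_r fixed Fourier base waveforms of cycle phase
and f_i a per-stride latent deviation,

    angle(t) = amplitude * L @ [g(phase) + f_i * sin^2(pi * phase)] + sensor noise

so the frame-level covariance has exact latent rank r (plus an isotropic
sensor-noise floor) and downstream rank recovery is well-posed. The
sin^2 envelope keeps stride boundaries continuous so concatenation does not
inject discontinuity spikes into the entropy estimators. Waveform realism is
deliberately loose (2-4 harmonics shaped like sagittal hip/knee/ankle
curves): the analysis depends on rank, variance and regularity, not on
biomechanical fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .kinematics import CANONICAL_CHANNELS, FootContactSeries, KinematicsTrial

BENCHMARK_KINDS = ("sine", "white", "pink", "logistic", "lorenz")


# ------------------------------------------------------------------ gait


@dataclass
class GaitGenConfig:
    """Configuration of the synthetic gait generator.

    cycle_noise_sd is the SD (degrees) of the per-stride latent deviation;
    sensor_noise_sd the SD of iid per-frame noise; chaos_mod the depth of a
    logistic-map modulation of stride durations (0 = regular timing).
    """

    seed: int
    p: int = 18
    n_strides: int = 50
    stride_duration_mean: float = 1.1  # s
    stride_duration_cv: float = 0.02
    fs: float = 60.0
    latent_rank: int = 3
    amplitude: float = 1.0
    loading_matrix: np.ndarray | None = None  # p x r, orthonormal columns if None
    latent_process: str = "iid_per_stride"  # or "smooth" (AR(1) across strides)
    cycle_noise_sd: float = 1.0  # degrees
    sensor_noise_sd: float = 0.3  # degrees
    chaos_mod: float = 0.0
    trial_id: str = "synthetic"
    activity_label: str = "synthetic"

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("field seed: a seed is mandatory")
        for name in ("cycle_noise_sd", "sensor_noise_sd", "stride_duration_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"field {name}: must be >= 0")
        if self.p < 1:
            raise ValueError("field p: need >= 1 joint")
        if not 0 <= self.latent_rank <= self.p:
            raise ValueError("field latent_rank: need 0 <= r <= p")
        if self.fs <= 0:
            raise ValueError("field fs: must be positive")
        if self.n_strides < 1:
            raise ValueError("field n_strides: need >= 1 stride")
        if self.stride_duration_mean <= 0:
            raise ValueError("field stride_duration_mean: must be positive")
        if not 0 <= self.chaos_mod < 1:
            raise ValueError("field chaos_mod: must be in [0, 1)")
        if self.latent_process not in ("iid_per_stride", "smooth"):
            raise ValueError("field latent_process: iid_per_stride or smooth")
        if self.loading_matrix is not None:
            lm = np.asarray(self.loading_matrix, dtype=float)
            if lm.shape != (self.p, self.latent_rank):
                raise ValueError("field loading_matrix: shape must be p x r")


# Fourier base waveforms of cycle phase, loosely shaped like sagittal hip /
# knee / ankle angle curves; higher latents use distinct single harmonics so
# the set is linearly independent over phase.
def _base_waveform(m: int, phase: np.ndarray) -> np.ndarray:
    tp = 2.0 * np.pi * phase
    if m == 0:  # hip-like: one big flexion-extension arc
        return 30.0 * np.cos(tp) + 5.0 * np.sin(2 * tp)
    if m == 1:  # knee-like: stance + swing flexion bumps
        return 25.0 * np.sin(tp) - 15.0 * np.cos(2 * tp) + 5.0 * np.sin(3 * tp)
    if m == 2:  # ankle-like: smaller, multi-harmonic
        return 10.0 * np.sin(tp + 1.0) + 8.0 * np.cos(2 * tp)
    return np.sin((m + 1) * tp + 0.5 * m)


# Latent m is rescaled to a phase-SD of 14 x 0.95^m degrees: every latent
# keeps a non-negligible variance share, so the frame-level covariance rank
# is recoverable by a 95% cumulative-variance cut for r well beyond 8.
_LATENT_SD0 = 14.0
_LATENT_SD_DECAY = 0.95
_REF_PHASE = np.arange(1000) / 1000.0


def _latent_waveforms(r: int, phase: np.ndarray) -> np.ndarray:
    """r x len(phase) matrix of base waveforms with controlled phase-SD."""
    rows = []
    for m in range(r):
        ref_sd = _base_waveform(m, _REF_PHASE).std()
        scale = _LATENT_SD0 * _LATENT_SD_DECAY**m / ref_sd
        rows.append(scale * _base_waveform(m, phase))
    return np.vstack(rows)


def _stride_durations(cfg: GaitGenConfig, rng: np.random.Generator) -> np.ndarray:
    dur = np.full(cfg.n_strides, cfg.stride_duration_mean)
    if cfg.stride_duration_cv > 0:
        dur *= 1.0 + cfg.stride_duration_cv * rng.standard_normal(cfg.n_strides)
    if cfg.chaos_mod > 0:
        z = 0.37  # fixed interior start for the logistic modulation
        zs = np.empty(cfg.n_strides)
        for i in range(cfg.n_strides):
            z = 4.0 * z * (1.0 - z)
            zs[i] = z
        dur *= 1.0 + cfg.chaos_mod * (2.0 * zs - 1.0)
    return np.clip(dur, 2.0 / cfg.fs, None)


def generate_gait(
    cfg: GaitGenConfig,
) -> tuple[KinematicsTrial, FootContactSeries, dict]:
    """Simulate one trial; returns (trial, right-foot contacts, ground truth).

    Contacts mark stride starts plus the final boundary, so segmentation
    recovers exactly ``n_strides`` cycles whose frame counts equal the
    generator's stride durations (recorded in the ground-truth dict).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    r = cfg.latent_rank
    durations = _stride_durations(cfg, rng)
    frames = np.maximum(2, np.round(durations * cfg.fs).astype(int))
    events = np.concatenate([[0], np.cumsum(frames)])
    total = int(events[-1])

    if r == 0:
        # pure periodic trial: fixed 3-template waveform, no stochastic part
        fixed_loading = np.tile(np.eye(3), (int(np.ceil(cfg.p / 3)), 1))[: cfg.p]
        blocks = []
        for nf in frames:
            phase = np.arange(nf) / nf
            blocks.append(cfg.amplitude * (fixed_loading @ _latent_waveforms(3, phase)).T)
        tail = cfg.amplitude * (fixed_loading @ _latent_waveforms(3, np.zeros(1))).T
        samples = np.vstack(blocks + [tail])
    else:
        if cfg.loading_matrix is not None:
            loading = np.asarray(cfg.loading_matrix, dtype=float)
        else:
            raw = rng.standard_normal((cfg.p, r))
            loading, _ = np.linalg.qr(raw)
            loading = loading[:, :r]
        # per-stride latent deviations
        f = rng.normal(0.0, cfg.cycle_noise_sd, size=(cfg.n_strides, r))
        if cfg.latent_process == "smooth":
            rho = 0.7
            for i in range(1, cfg.n_strides):
                f[i] = rho * f[i - 1] + np.sqrt(1 - rho**2) * f[i]
        blocks = []
        for i, nf in enumerate(frames):
            phase = np.arange(nf) / nf
            g = _latent_waveforms(r, phase)  # r x nf
            envelope = np.sin(np.pi * phase) ** 2
            latent = g + f[i][:, None] * envelope[None, :]
            blocks.append(cfg.amplitude * (loading @ latent).T)
        samples = np.vstack(blocks)
        # final boundary frame at phase 0 of a virtual next stride
        tail = cfg.amplitude * (loading @ _latent_waveforms(r, np.zeros(1))).T
        samples = np.vstack([samples, tail])

    if cfg.sensor_noise_sd > 0:
        samples = samples + rng.normal(0.0, cfg.sensor_noise_sd, samples.shape)

    channels = CANONICAL_CHANNELS[: cfg.p]
    if cfg.p > len(CANONICAL_CHANNELS):
        channels = tuple(
            list(CANONICAL_CHANNELS)
            + [f"extra_{k}" for k in range(cfg.p - len(CANONICAL_CHANNELS))]
        )
    trial = KinematicsTrial(
        samples=samples,
        fs=cfg.fs,
        channels=channels,
        trial_id=cfg.trial_id,
        activity_label=cfg.activity_label,
    )
    contacts = FootContactSeries(events=events, foot="R")
    ground_truth = {
        "latent_rank": r,
        "stride_frames": frames.tolist(),
        "stride_durations_s": (frames / cfg.fs).tolist(),
        "cycle_noise_sd": cfg.cycle_noise_sd,
        "sensor_noise_sd": cfg.sensor_noise_sd,
        "amplitude": cfg.amplitude,
        "chaos_mod": cfg.chaos_mod,
        "seed": cfg.seed,
    }
    return trial, contacts, ground_truth


# Designed activity suite: four synthetic "activities" whose complexity
# orderings provably disagree across measure families — a plain-walking
# analog (low rank, low variance, regular timing), a high-dimensional
# activity (rank 8), a high-variance activity (large amplitude and lifted
# noise floor) and an irregular-timing activity (chaotic stride-duration
# modulation). Dimensionality crowns the high-rank activity, generalized
# variance the high-variance one, multiscale entropy the irregular one,
# and the walking analog comes last under all three.
ACTIVITY_DESIGNS: dict[str, dict] = {
    "walking": dict(
        latent_rank=2, amplitude=0.6, cycle_noise_sd=0.3,
        sensor_noise_sd=0.15, stride_duration_cv=0.01,
    ),
    "high_dim": dict(
        latent_rank=8, amplitude=1.0, cycle_noise_sd=0.4,
        sensor_noise_sd=0.3, stride_duration_cv=0.01,
    ),
    "high_var": dict(
        latent_rank=3, amplitude=2.0, cycle_noise_sd=1.0,
        sensor_noise_sd=2.0, stride_duration_cv=0.02,
    ),
    "irregular": dict(
        latent_rank=3, amplitude=1.0, cycle_noise_sd=3.0,
        sensor_noise_sd=0.5, stride_duration_cv=0.0, chaos_mod=0.25,
    ),
}


def activity_suite(
    seed: int, n_trials: int = 2, n_strides: int = 60
) -> dict[str, list[tuple[KinematicsTrial, FootContactSeries, dict]]]:
    """Generate the designed four-activity suite; trials seeded from ``seed``."""
    suite: dict[str, list] = {}
    for i, (label, kw) in enumerate(ACTIVITY_DESIGNS.items()):
        trials = []
        for j in range(n_trials):
            cfg = GaitGenConfig(
                seed=int(seed) + 100 * (j + 1) + i,
                n_strides=n_strides,
                trial_id=f"{label}-{j}",
                activity_label=label,
                **kw,
            )
            trials.append(generate_gait(cfg))
        suite[label] = trials
    return suite


# ------------------------------------------------------------ toy clouds


@dataclass
class ToyCloudConfig:
    """Two 2-D Gaussian clouds, as in the variance-vs-dimensionality toy example."""

    seed: int
    n_points: int = 5000
    mean1: tuple[float, float] = (0.0, 0.0)
    mean2: tuple[float, float] = (0.0, 0.0)
    cov1: np.ndarray = field(default_factory=lambda: np.eye(2))
    cov2: np.ndarray = field(default_factory=lambda: 4.0 * np.eye(2))

    def validate(self) -> None:
        if self.n_points < 1:
            raise ValueError("field n_points: need >= 1 point")
        for name in ("cov1", "cov2"):
            c = np.asarray(getattr(self, name), dtype=float)
            if c.shape != (2, 2) or not np.allclose(c, c.T):
                raise ValueError(f"field {name}: must be symmetric 2 x 2")
            if np.linalg.eigvalsh(c).min() < -1e-12:
                raise ValueError(f"field {name}: must be positive semi-definite")


def generate_toy_clouds(cfg: ToyCloudConfig) -> tuple[np.ndarray, np.ndarray]:
    """Sample the two Gaussian clouds; returns (cloud1, cloud2), each n x 2."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    c1 = rng.multivariate_normal(cfg.mean1, np.asarray(cfg.cov1, float), cfg.n_points)
    c2 = rng.multivariate_normal(cfg.mean2, np.asarray(cfg.cov2, float), cfg.n_points)
    return c1, c2


# ------------------------------------------------------------- benchmarks


def _lorenz_series(
    n: int,
    dt: float,
    sigma: float,
    rho: float,
    beta: float,
    x0: tuple[float, float, float],
    transient_time: float,
) -> np.ndarray:
    def rhs(_t, s):
        x, y, z = s
        return [sigma * (y - x), x * (rho - z) - y, x * y - beta * z]

    t_end = transient_time + n * dt
    t_eval = transient_time + dt * np.arange(n)
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        list(x0),
        t_eval=t_eval,
        rtol=1e-9,
        atol=1e-9,
        method="RK45",
    )
    return sol.y[0]


def generate_benchmark(
    kind: str, n: int, params: dict | None = None, seed: int | None = None
) -> np.ndarray:
    """Canonical scalar test signals for validating the nonlinear estimators.

    kinds: ``sine`` (period in samples), ``white`` (iid Gaussian), ``pink``
    (1/f noise via spectral 1/sqrt(f) shaping, unit SD), ``logistic``
    (r = 4 map; ``transient`` iterations discarded, default 0), ``lorenz``
    (sigma=10, rho=28, beta=8/3 integrated at fixed step, x component).
    """
    if kind not in BENCHMARK_KINDS:
        raise ValueError(f"unknown kind {kind!r}; valid kinds: {list(BENCHMARK_KINDS)}")
    if n < 100:
        raise ValueError("need n >= 100 samples")
    p = dict(params or {})
    if kind == "sine":
        period = float(p.get("period", 60.0))
        amplitude = float(p.get("amplitude", 1.0))
        phase = float(p.get("phase", 0.0))
        return amplitude * np.sin(2.0 * np.pi * np.arange(n) / period + phase)
    if kind == "white":
        rng = np.random.default_rng(seed)
        return rng.normal(0.0, float(p.get("sd", 1.0)), n)
    if kind == "pink":
        rng = np.random.default_rng(seed)
        white = rng.standard_normal(n)
        spec = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n)
        scale = np.ones_like(freqs)
        scale[1:] = 1.0 / np.sqrt(freqs[1:])
        scale[0] = 0.0
        x = np.fft.irfft(spec * scale, n)
        return x / x.std()
    if kind == "logistic":
        x = float(p.get("x0", 0.2))
        transient = int(p.get("transient", 0))
        out = np.empty(n)
        for _ in range(transient):
            x = 4.0 * x * (1.0 - x)
        for i in range(n):
            out[i] = x
            x = 4.0 * x * (1.0 - x)
        return out
    # lorenz
    return _lorenz_series(
        n=n,
        dt=float(p.get("dt", 0.01)),
        sigma=float(p.get("sigma", 10.0)),
        rho=float(p.get("rho", 28.0)),
        beta=float(p.get("beta", 8.0 / 3.0)),
        x0=tuple(p.get("x0", (1.0, 1.0, 1.0))),
        transient_time=float(p.get("transient_time", 20.0)),
    )
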