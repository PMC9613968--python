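"""State-space and self-similarity measures for scalar gait series.

The chain for the largest Lyapunov exponent follows standard nonlinear
time-series practice: the embedding delay is the first local minimum of the
average mutual information (AMI) between the series and its lagged copy;
the embedding dimension is the smallest one for which the global false
nearest neighbor (FNN) fraction drops below 10% (Kennel criteria); the
scalar series is then delay-embedded (Takens) and the largest Lyapunov
exponent is the slope of the mean log divergence of initially nearest
neighbor pairs (Rosenstein's method), with a Theiler window of one mean
period excluding temporally correlated neighbors.

Irregularity is measured by sample entropy, SampEn = -ln(A/B) with A and B
the counts of Chebyshev-matching template pairs of lengths m+1 and m
(self-matches excluded), and by its composite multiscale variant: at scale
tau the series is coarse-grained by non-overlapping means at each of the
tau possible offsets, SampEn is averaged over offsets, and the Complexity
Index (CI) is the sum over scales tau = 1..20 with the tolerance r held at
0.2 x SD of the original series.

All estimators are deterministic functions of their inputs and settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .kinematics import KinematicsTrial

__all__ = [
    "AMICurve",
    "FNNCurve",
    "EmbeddingSpec",
    "LyEResult",
    "CMSEProfile",
    "JointNLDResult",
    "average_mutual_information",
    "gfnn",
    "delay_embed",
    "dominant_period",
    "lyapunov_rosenstein",
    "sample_entropy",
    "composite_multiscale_entropy",
    "joint_nld_summary",
]


# ---------------------------------------------------------------- delay (AMI)


@dataclass
class AMICurve:
    lags: np.ndarray
    ami: np.ndarray  # nats
    selected_delay: int
    fallback_used: bool  # no local minimum within max_lag; argmin used


def average_mutual_information(
    x: np.ndarray,
    max_lag: int = 100,
    n_bins: int | None = None,
    min_window: int = 3,
    flat_tol: float = 0.05,
) -> AMICurve:
    """Histogram AMI between x(t) and x(t+lag) for lag = 0..max_lag.

    The delay is the first local minimum of the curve, where "local minimum"
    means lowest within ``min_window`` lags on either side — the histogram
    estimator wiggles by a fraction of a bin on noiseless periodic signals,
    and the windowed rule recovers the analytic quarter-period minimum of a
    sinusoid where a strict three-point rule locks onto estimator jitter.
    A featureless curve (range of ami over lags >= 1 below ``flat_tol`` of
    ami[0], e.g. white noise) or one with no minimum falls back to the
    argmin over lags >= 1, flagged.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if max_lag < 1 or max_lag >= n - 1:
        raise ValueError("max_lag must be in [1, len(x) - 2]")
    if np.ptp(x) == 0.0:
        raise ValueError("zero-entropy input: series is constant")
    if n_bins is None:
        n_bins = max(16, int(np.ceil(n ** (1.0 / 3.0))))
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    ami = np.empty(max_lag + 1)
    for lag in range(max_lag + 1):
        a = x[: n - lag]
        b = x[lag:]
        joint, _, _ = np.histogram2d(a, b, bins=(edges, edges))
        pj = joint / joint.sum()
        px = pj.sum(axis=1)
        py = pj.sum(axis=0)
        nz = pj > 0
        outer = np.outer(px, py)
        ami[lag] = float(np.sum(pj[nz] * np.log(pj[nz] / outer[nz])))
    selected, fallback = None, False
    featureless = np.ptp(ami[1:]) < flat_tol * ami[0]
    if not featureless:
        for lag in range(1, max_lag):
            lo = max(0, lag - min_window)
            hi = min(max_lag, lag + min_window)
            window = ami[lo : hi + 1]
            if ami[lag] <= window.min() and ami[lag] < ami[lo] and ami[lag] < ami[hi]:
                selected = lag
                break
    if selected is None:
        selected = int(np.argmin(ami[1:])) + 1
        fallback = True
    return AMICurve(
        lags=np.arange(max_lag + 1),
        ami=ami,
        selected_delay=int(selected),
        fallback_used=fallback,
    )


# ------------------------------------------------------- embedding dimension


@dataclass
class FNNCurve:
    dims: np.ndarray
    fnn_fraction: np.ndarray  # in [0, 1]
    selected_dim: int
    saturated: bool  # never dropped below threshold within max_dim
    threshold: float


def delay_embed(x: np.ndarray, delay: int, dim: int) -> np.ndarray:
    """Takens delay embedding: row i = [x(i), x(i+delay), ..., x(i+(dim-1)delay)]."""
    x = np.asarray(x, dtype=float).ravel()
    if delay < 1 or dim < 1:
        raise ValueError("delay and dim must be >= 1")
    m = x.size - (dim - 1) * delay
    if m < 1:
        raise ValueError(
            f"series of length {x.size} too short for dim={dim}, delay={delay} "
            f"(needs > {(dim - 1) * delay})"
        )
    idx = np.arange(m)[:, None] + delay * np.arange(dim)[None, :]
    return x[idx]


def gfnn(
    x: np.ndarray,
    delay: int,
    max_dim: int = 10,
    r_tol: float = 15.0,
    a_tol: float = 2.0,
    threshold: float = 0.10,
    theiler: int | None = None,
) -> FNNCurve:
    """Global false nearest neighbors over dims 1..max_dim (Kennel criteria).

    A nearest neighbor in dimension d is false if the extra coordinate at
    d+1 inflates its distance by more than ``r_tol`` relative to the d-dim
    distance, or beyond ``a_tol`` times the attractor size (SD of x). The
    selected dimension is the first with false fraction < ``threshold``;
    for noise the fraction never drops and the saturation flag is set.

    Neighbors within ``theiler`` samples (default: the delay) are excluded
    so densely sampled flows do not pick trivially correlated neighbors;
    near-zero neighbor distances (exact periodic repeats) are clamped at
    1e-9 of the attractor size before the ratio test.
    """
    x = np.asarray(x, dtype=float).ravel()
    min_len = max_dim * delay + 2
    if x.size < min_len:
        raise ValueError(
            f"series of length {x.size} too short for max_dim={max_dim} at "
            f"delay={delay}; needs at least {min_len}"
        )
    if theiler is None:
        theiler = delay
    attractor_size = float(x.std())
    if attractor_size == 0.0:
        raise ValueError("constant series has no neighbors to test")
    dims = np.arange(1, max_dim + 1)
    fracs = np.empty(max_dim)
    for d in dims:
        emb = delay_embed(x, delay, d)
        n_next = x.size - d * delay  # points that also exist in dim d+1
        pts = emb[:n_next]
        if n_next < 2 + theiler:
            fracs[d - 1] = 1.0
            continue
        tree = cKDTree(pts)
        k = min(n_next, 2 * theiler + 3)
        dist_all, neigh_all = tree.query(pts, k=k)
        nn = np.full(n_next, -1)
        dist = np.zeros(n_next)
        for i in range(n_next):
            ok = np.abs(neigh_all[i] - i) > theiler
            if ok.any():
                nn[i] = neigh_all[i][ok][0]
                dist[i] = dist_all[i][ok][0]
        valid = nn >= 0
        idx = np.arange(n_next)[valid]
        nnv = nn[valid]
        extra = np.abs(x[idx + d * delay] - x[nnv + d * delay])
        dv = np.maximum(dist[valid], 1e-9 * attractor_size)
        false_1 = extra / dv > r_tol
        false_2 = np.sqrt(dist[valid] ** 2 + extra**2) / attractor_size > a_tol
        fracs[d - 1] = float(np.mean(false_1 | false_2))
    below = np.nonzero(fracs < threshold)[0]
    if below.size:
        return FNNCurve(dims, fracs, int(dims[below[0]]), False, threshold)
    return FNNCurve(dims, fracs, int(max_dim), True, threshold)


@dataclass
class EmbeddingSpec:
    delay: int
    dim: int
    series_id: str = ""

    def __post_init__(self) -> None:
        if self.delay < 1 or self.dim < 1:
            raise ValueError("delay and dim must be >= 1")


# -------------------------------------------------- largest Lyapunov exponent


@dataclass
class LyEResult:
    lye: float  # per second (slope per sample x fs)
    divergence_curve: np.ndarray  # <ln d_j(i)> per forward step i
    fit_window: tuple[int, int]  # [start, end) steps used for the slope
    theiler_window: int
    n_pairs: int


def dominant_period(x: np.ndarray) -> float:
    """Period (in samples) of the dominant spectral peak of a detrended series."""
    x = np.asarray(x, dtype=float).ravel()
    x = x - x.mean()
    power = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size)
    power[0] = 0.0
    k = int(np.argmax(power))
    if freqs[k] == 0.0:
        raise ValueError("no dominant spectral peak (flat spectrum)")
    return 1.0 / freqs[k]


def lyapunov_rosenstein(
    trajectory: np.ndarray,
    fs: float,
    mean_period: float,
    fit_window: tuple[int, int] | None = None,
    theiler: int | None = None,
    max_steps: int | None = None,
) -> LyEResult:
    """Largest Lyapunov exponent from mean log divergence of nearest neighbors.

    For each trajectory point the nearest neighbor outside a Theiler window
    (default: one mean period, in samples) is found; pair separations are
    tracked forward and the mean of ln d over pairs with d > 0 forms the
    divergence curve. The exponent is the least-squares slope over
    ``fit_window`` (default: steps 0 to half a mean period) times ``fs``.
    """
    traj = np.atleast_2d(np.asarray(trajectory, dtype=float))
    if traj.shape[0] < traj.shape[1]:
        raise ValueError("trajectory must be (points x dim)")
    m = traj.shape[0]
    if mean_period <= 0:
        raise ValueError("mean_period must be positive")
    if theiler is None:
        theiler = int(round(mean_period))
    if fit_window is None:
        fit_window = (0, max(2, int(round(mean_period / 2.0))))
    if max_steps is None:
        max_steps = max(fit_window[1], int(round(mean_period)))
    if m <= theiler + 2:
        raise ValueError("trajectory too short for the Theiler window")

    tree = cKDTree(traj)
    # query enough neighbors to find one outside the Theiler exclusion zone
    k = min(m, 2 * theiler + 3)
    idx_all = np.arange(m)
    nn = np.full(m, -1)
    dist, neigh = tree.query(traj, k=k)
    for j in range(m):
        ok = np.abs(neigh[j] - j) > theiler
        if ok.any():
            nn[j] = neigh[j][ok][0]
    valid = nn >= 0
    if not valid.any():
        raise ValueError("no valid neighbor pairs outside the Theiler window")
    j_idx = idx_all[valid]
    n_idx = nn[valid]

    n_steps = int(max_steps) + 1
    curve = np.full(n_steps, np.nan)
    for i in range(n_steps):
        keep = (j_idx + i < m) & (n_idx + i < m)
        if not keep.any():
            break
        d = np.linalg.norm(traj[j_idx[keep] + i] - traj[n_idx[keep] + i], axis=1)
        d = d[d > 0]
        if d.size == 0:
            continue
        curve[i] = np.mean(np.log(d))

    lo, hi = int(fit_window[0]), int(fit_window[1])
    if not (0 <= lo < hi <= n_steps):
        raise ValueError(f"fit window {fit_window} outside divergence curve")
    seg = curve[lo:hi]
    steps = np.arange(lo, hi)
    ok = np.isfinite(seg)
    if ok.sum() < 2:
        raise ValueError("divergence curve undefined over the fit window")
    slope = np.polyfit(steps[ok], seg[ok], 1)[0]
    return LyEResult(
        lye=float(slope * fs),
        divergence_curve=curve,
        fit_window=(lo, hi),
        theiler_window=int(theiler),
        n_pairs=int(valid.sum()),
    )


# --------------------------------------------------------------- sample entropy


def _template_pairs_within(templates: np.ndarray, r: float) -> int:
    """Count unordered template pairs with Chebyshev distance <= r."""
    tree = cKDTree(templates)
    total = tree.count_neighbors(tree, r, p=np.inf)  # ordered pairs incl. self
    return (int(total) - templates.shape[0]) // 2


def sample_entropy(x: np.ndarray, m: int = 2, r_abs: float | None = None) -> float:
    """SampEn = -ln(A/B); NaN when no template pairs match (flagged undefined).

    B counts matching pairs of length-m templates, A of length m+1, both
    over the first n-m template start points with self-matches excluded
    (Richman-Moorman convention). ``r_abs`` is the absolute Chebyshev
    tolerance; the conventional default is 0.2 x SD of x.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n <= m + 1:
        raise ValueError(f"series of length {n} too short for m={m}")
    if r_abs is None:
        r_abs = 0.2 * float(x.std())
    if not r_abs > 0:
        raise ValueError("tolerance r must be positive")
    temp_m = delay_embed(x, 1, m)[: n - m]
    temp_m1 = delay_embed(x, 1, m + 1)
    b = _template_pairs_within(temp_m, r_abs)
    if b == 0:
        return float("nan")
    a = _template_pairs_within(temp_m1, r_abs)
    if a == 0:
        return float("nan")
    return float(-np.log(a / b))


# ------------------------------------------------- composite multiscale entropy


@dataclass
class CMSEProfile:
    scales: np.ndarray  # tau = 1..n_scales
    cmse: np.ndarray  # mean SampEn over coarse-graining offsets; NaN if undefined
    m: int
    r: float  # absolute tolerance (r_factor x SD of the raw series)
    ci: float  # sum of cmse over scales; NaN if any scale undefined
    scale_defined: np.ndarray = field(default_factory=lambda: np.array([], bool))
    ci_defined: bool = True


def _coarse_grain(x: np.ndarray, tau: int, offset: int) -> np.ndarray:
    """Non-overlapping window means of width tau starting at ``offset``."""
    n_win = (x.size - offset) // tau
    return x[offset : offset + n_win * tau].reshape(n_win, tau).mean(axis=1)


def composite_multiscale_entropy(
    x: np.ndarray, m: int = 2, r_factor: float = 0.2, n_scales: int = 20
) -> CMSEProfile:
    """CMSE profile over scales 1..n_scales and the Complexity Index.

    At scale tau, SampEn is computed on each of the tau offset
    coarse-grainings and averaged over the offsets where it is defined;
    the tolerance r stays fixed at ``r_factor`` x SD of the raw series.
    CI is the sum over scales; an undefined scale makes CI undefined
    (flagged, never an infinity).
    """
    x = np.asarray(x, dtype=float).ravel()
    sd = float(x.std())
    if sd == 0.0:
        raise ValueError("constant series: entropy tolerance would be zero")
    r_abs = r_factor * sd
    scales = np.arange(1, n_scales + 1)
    cmse = np.empty(n_scales)
    defined = np.empty(n_scales, dtype=bool)
    for i, tau in enumerate(scales):
        vals = []
        for offset in range(tau):
            cg = _coarse_grain(x, int(tau), offset)
            if cg.size <= m + 1:
                continue
            vals.append(sample_entropy(cg, m=m, r_abs=r_abs))
        vals = np.asarray(vals, dtype=float)
        ok = np.isfinite(vals)
        defined[i] = bool(ok.any())
        cmse[i] = float(vals[ok].mean()) if defined[i] else float("nan")
    ci_defined = bool(defined.all())
    ci = float(cmse.sum()) if ci_defined else float("nan")
    return CMSEProfile(
        scales=scales,
        cmse=cmse,
        m=m,
        r=r_abs,
        ci=ci,
        scale_defined=defined,
        ci_defined=ci_defined,
    )


# -------------------------------------------------------- per-joint pipeline


@dataclass
class JointNLDResult:
    channel: str
    embedding: EmbeddingSpec
    ami: AMICurve
    fnn: FNNCurve
    lye: LyEResult
    cmse: CMSEProfile

    @property
    def warnings(self) -> list[str]:
        w = []
        if self.ami.fallback_used:
            w.append(f"{self.channel}: AMI had no local minimum; argmin used")
        if self.fnn.saturated:
            w.append(f"{self.channel}: FNN never dropped below threshold")
        if not self.cmse.ci_defined:
            w.append(f"{self.channel}: CI undefined (entropy had no matches)")
        return w


def joint_nld_summary(
    trial: KinematicsTrial,
    joints: list[str] | None = None,
    max_lag: int | None = None,
    max_dim: int = 8,
    n_scales: int = 20,
    m: int = 2,
    r_factor: float = 0.2,
    min_samples: int = 500,
) -> dict[str, JointNLDResult]:
    """AMI -> FNN -> embed -> LyE, plus CMSE/CI, per sagittal joint channel."""
    if trial.n_frames < min_samples:
        raise ValueError(
            f"trial has {trial.n_frames} frames; nonlinear measures need >= "
            f"{min_samples}"
        )
    available = list(trial.sagittal_channels())
    if joints is None:
        joints = available
    missing = [c for c in joints if c not in trial.channels]
    if missing:
        raise KeyError(
            f"channel(s) {missing} not in trial; sagittal channels available: "
            f"{available}"
        )
    if max_lag is None:
        max_lag = min(int(2 * trial.fs), trial.n_frames // 4)
    out: dict[str, JointNLDResult] = {}
    for ch in joints:
        x = trial.channel(ch)
        ami = average_mutual_information(x, max_lag=max_lag)
        delay = ami.selected_delay
        usable_dim = min(max_dim, (x.size - 2) // max(delay, 1))
        fnn = gfnn(x, delay=delay, max_dim=max(2, usable_dim))
        spec = EmbeddingSpec(delay=delay, dim=fnn.selected_dim, series_id=ch)
        traj = delay_embed(x, spec.delay, spec.dim)
        period = dominant_period(x)
        lye = lyapunov_rosenstein(traj, fs=trial.fs, mean_period=period)
        cmse = composite_multiscale_entropy(
            x, m=m, r_factor=r_factor, n_scales=n_scales
        )
        out[ch] = JointNLDResult(
            channel=ch, embedding=spec, ami=ami, fnn=fnn, lye=lye, cmse=cmse
        )
    return out
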