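"""Variability measures: generalized variance and stride-to-stride GaitSD.

Generalized variance (GV) is the determinant of the p x p joint-angle
covariance — a volume-like measure of how much of configuration space an
activity occupies. Because det of an 18 x 18 covariance in degrees^2 easily
under/overflows doubles, the log determinant and the p-th root (the
geometric mean of per-component variances) are carried alongside.

GaitSD measures waveform consistency across strides: with X_ij the value of
one joint at phase j of cycle i (cycles time-normalized to T=101 points,
X̄_j the across-cycle mean curve),

    GVSD_k^2 = sum_j sum_i (X_ij - X̄_j)^2 / (T (N - 1))

and GaitSD combines per-joint values, by default as the mean of per-joint
SDs, (1/p) sum_k sqrt(GVSD_k^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinematics import NormalizedCycleSet

COMBINERS = ("mean_of_sd", "sqrt_of_mean")


@dataclass
class GeneralizedVarianceResult:
    gv: float  # det of sample covariance, degrees^(2p)
    log_gv: float  # natural log; -inf when rank deficient
    normalized_gv: float  # gv**(1/p), degrees^2 (geometric-mean variance)
    rank_deficient: bool
    p: int


@dataclass
class GaitSDResult:
    gvsd_sq_per_joint: np.ndarray  # degrees^2, one per joint
    gait_sd: float  # degrees
    n_cycles: int
    combiner: str


def generalized_variance(
    data: np.ndarray, eps_rank: float = 1e-10
) -> GeneralizedVarianceResult:
    """Determinant of the mean-centered sample covariance of frames x p data.

    If the smallest eigenvalue is below ``eps_rank`` times the largest the
    covariance is treated as singular: gv is reported as 0 with the
    rank-deficient flag set.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be 2-D (frames x channels)")
    if data.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    p = data.shape[1]
    cov = np.atleast_2d(np.cov(data, rowvar=False, ddof=1))
    eig = np.clip(np.linalg.eigvalsh(cov), 0.0, None)
    if eig.max() == 0.0 or eig.min() < eps_rank * eig.max():
        return GeneralizedVarianceResult(
            gv=0.0, log_gv=-np.inf, normalized_gv=0.0, rank_deficient=True, p=p
        )
    log_gv = float(np.log(eig).sum())
    return GeneralizedVarianceResult(
        gv=float(np.exp(log_gv)),
        log_gv=log_gv,
        normalized_gv=float(np.exp(log_gv / p)),
        rank_deficient=False,
        p=p,
    )


def gait_sd(cycles: NormalizedCycleSet, combiner: str = "mean_of_sd") -> GaitSDResult:
    """Stride-to-stride waveform variability over a normalized cycle set."""
    if combiner not in COMBINERS:
        raise ValueError(f"combiner must be one of {COMBINERS}")
    X = cycles.cycles  # N x T x p
    n, t, p = X.shape
    if n < 2:
        raise ValueError("need >= 2 cycles for stride-to-stride variability")
    mean_curve = X.mean(axis=0)  # T x p
    dev_sq = (X - mean_curve[None]) ** 2
    gvsd_sq = dev_sq.sum(axis=(0, 1)) / (t * (n - 1))  # per joint
    if combiner == "mean_of_sd":
        value = float(np.sqrt(gvsd_sq).mean())
    else:
        value = float(np.sqrt(gvsd_sq.mean()))
    return GaitSDResult(
        gvsd_sq_per_joint=gvsd_sq, gait_sd=value, n_cycles=n, combiner=combiner
    )
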