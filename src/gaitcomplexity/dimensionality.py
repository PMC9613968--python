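"""PCA-based dimensionality of joint kinematics.

The dimensionality of an activity is summarized as N95%: the number of
principal components of the frame-level joint-angle covariance needed to
reach 95% cumulative explained variance. Covariance-PCA (not correlation)
is used because all channels share units (degrees); the absolute variance
per component (eigenvalue, degrees^2) is kept alongside the percent view,
since relative-variance thresholds can hide large trailing-component
variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinematics import KinematicsTrial


@dataclass
class VarianceSpectrum:
    """Eigenvalues of the sample covariance, descending, with percent views."""

    eigenvalues: np.ndarray  # degrees^2
    percent: np.ndarray
    cumulative_percent: np.ndarray
    degenerate: bool = False  # constant (zero-variance) input

    @property
    def n_components(self) -> int:
        return self.eigenvalues.size


def variance_spectrum(data: np.ndarray) -> VarianceSpectrum:
    """Eigen-decompose the sample covariance (divisor n-1) of a frames x p matrix.

    Columns are mean-centered; eigenvalues are clipped at zero (round-off)
    and sorted descending. A constant matrix yields an all-zero, degenerate
    spectrum.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be 2-D (frames x channels)")
    if data.shape[0] < 2:
        raise ValueError("need at least 2 frames for a covariance")
    cov = np.cov(data, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    eig = np.linalg.eigvalsh(cov)[::-1]
    eig = np.clip(eig, 0.0, None)
    total = eig.sum()
    if total == 0.0:
        p = eig.size
        return VarianceSpectrum(
            eigenvalues=eig,
            percent=np.zeros(p),
            cumulative_percent=np.zeros(p),
            degenerate=True,
        )
    percent = eig / total * 100.0
    return VarianceSpectrum(
        eigenvalues=eig,
        percent=percent,
        cumulative_percent=np.cumsum(percent),
        degenerate=False,
    )


def n95(spectrum: VarianceSpectrum, threshold: float = 0.95) -> int:
    """Smallest k whose cumulative explained variance reaches ``threshold``.

    For a perfectly isotropic p-channel spectrum this returns p whenever
    (p-1)/p falls below the threshold (e.g. 17/18 = 94.4% < 95%).
    """
    if spectrum.degenerate:
        raise ValueError("degenerate data: zero-variance spectrum has no N95%")
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    target = threshold * 100.0
    # tolerate float round-off at the top of the cumulative sum
    hits = np.nonzero(spectrum.cumulative_percent >= target - 1e-9)[0]
    return int(hits[0]) + 1


def activity_n95(
    trials: list[KinematicsTrial], threshold: float = 0.95
) -> tuple[float, float, list[int]]:
    """Per-trial N95%, aggregated to (mean, SD, per-trial values).

    SD is the sample SD across trials (0.0 for a single trial).
    """
    if not trials:
        raise ValueError("need at least one trial")
    values = [n95(variance_spectrum(t.samples), threshold) for t in trials]
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd, values


def pooled_variance_spectrum(trials: list[KinematicsTrial]) -> VarianceSpectrum:
    """Spectrum of all trials' frames pooled into one matrix (per-activity view)."""
    if not trials:
        raise ValueError("need at least one trial")
    return variance_spectrum(np.vstack([t.samples for t in trials]))
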