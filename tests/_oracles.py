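"""Independent reference implementations used only to cross-check the package.

These deliberately share no code with gaitcomplexity's fast paths: SampEn is
counted by explicit O(n^2) template-pair loops, and the Lorenz largest
Lyapunov exponent is measured by Benettin's two-trajectory
perturbation-growth method on the exact equations (not from an embedded
scalar series).
"""

from __future__ import annotations

import numpy as np


def sample_entropy_bruteforce(x: np.ndarray, m: int, r: float) -> float:
    """Direct pair count over all templates (Richman-Moorman convention)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    n_templates = n - m  # same count for lengths m and m+1
    b = a = 0
    for i in range(n_templates):
        for j in range(i + 1, n_templates):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
                if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) <= r:
                    a += 1
    if a == 0 or b == 0:
        return float("nan")
    return -np.log(a / b)


def _lorenz_rhs(s: np.ndarray, sigma=10.0, rho=28.0, beta=8.0 / 3.0) -> np.ndarray:
    x, y, z = s
    return np.array([sigma * (y - x), x * (rho - z) - y, x * y - beta * z])


def _rk4(s: np.ndarray, dt: float, steps: int) -> np.ndarray:
    for _ in range(steps):
        k1 = _lorenz_rhs(s)
        k2 = _lorenz_rhs(s + dt / 2 * k1)
        k3 = _lorenz_rhs(s + dt / 2 * k2)
        k4 = _lorenz_rhs(s + dt * k3)
        s = s + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    return s


def lorenz_lyapunov_benettin(
    seed: int = 0,
    d0: float = 1e-8,
    dt: float = 1e-3,
    inner_steps: int = 50,
    n_renorm: int = 2000,
) -> float:
    """Largest Lyapunov exponent of the Lorenz system by repeated
    renormalization of a perturbed companion trajectory (per time unit)."""
    rng = np.random.default_rng(seed)
    s = _rk4(np.array([1.0, 1.0, 1.0]), dt, 20000)  # settle onto the attractor
    pert = rng.standard_normal(3)
    s2 = s + pert * (d0 / np.linalg.norm(pert))
    total = 0.0
    for _ in range(n_renorm):
        s = _rk4(s, dt, inner_steps)
        s2 = _rk4(s2, dt, inner_steps)
        d = np.linalg.norm(s2 - s)
        total += np.log(d / d0)
        s2 = s + (s2 - s) * (d0 / d)
    return total / (n_renorm * inner_steps * dt)
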