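"""Synthetic VAR data: the 6-node order-2 benchmark network and a generic
coefficient-specified vector-autoregression generator.

The benchmark model is a six-variable VAR(2) with nine directed
cross-node influences (reciprocal pairs 1<->2 and 4<->5, the chains
1->3->6 and 2->5->6, and 2->4).  Innovations are independent zero-mean
Gaussians; each node's noise *variance* is drawn uniformly from a
configurable range per replicate, with the stock ranges LOW = [1.5, 2],
MODERATE = [2.5, 3] and HIGH = [5.5, 6].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .var_core import TimeSeriesPanel

__all__ = [
    "VarModel",
    "NOISE_RANGES",
    "benchmark_coefficients",
    "benchmark_model",
    "simulate",
    "ground_truth",
    "companion_matrix",
    "stationary_covariance",
]

#: Stock noise-variance ranges for the benchmark, by level name.
NOISE_RANGES: dict[str, tuple[float, float]] = {
    "low": (1.5, 2.0),
    "moderate": (2.5, 3.0),
    "high": (5.5, 6.0),
}


@dataclass(frozen=True)
class VarModel:
    """A vector autoregression of order p.

    ``coeffs[l][i, j]`` is the effect of node ``j`` at lag ``l+1`` on
    node ``i``; ``noise_sd[i]`` the innovation standard deviation of
    node ``i``.
    """

    m: int
    p: int
    coeffs: np.ndarray  # shape (p, m, m)
    noise_sd: np.ndarray  # shape (m,)

    def __post_init__(self) -> None:
        coeffs = np.asarray(self.coeffs, dtype=float)
        if coeffs.shape != (self.p, self.m, self.m):
            raise ValueError("coeffs must have shape (p, m, m)")
        sd = np.asarray(self.noise_sd, dtype=float)
        if sd.shape != (self.m,) or np.any(sd < 0):
            raise ValueError("noise_sd must be a nonnegative vector of length m")
        object.__setattr__(self, "coeffs", coeffs)
        object.__setattr__(self, "noise_sd", sd)

    @property
    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(companion_matrix(self)))))

    @property
    def is_stationary(self) -> bool:
        return self.spectral_radius < 1.0


def companion_matrix(model: VarModel) -> np.ndarray:
    """Block companion form rewriting the order-p VAR as order 1 (mp x mp)."""
    m, p = model.m, model.p
    C = np.zeros((m * p, m * p))
    C[:m, :] = np.concatenate(list(model.coeffs), axis=1)
    if p > 1:
        C[m:, : m * (p - 1)] = np.eye(m * (p - 1))
    return C


def stationary_covariance(model: VarModel) -> np.ndarray:
    """Stationary covariance of the stacked state, via the discrete
    Lyapunov equation ``Sigma = C Sigma C' + Q``."""
    from scipy.linalg import solve_discrete_lyapunov

    C = companion_matrix(model)
    Q = np.zeros_like(C)
    Q[: model.m, : model.m] = np.diag(model.noise_sd**2)
    return solve_discrete_lyapunov(C, Q)


def benchmark_coefficients() -> np.ndarray:
    """Coefficient matrices (2, 6, 6) of the 6-node benchmark network."""
    a1 = np.zeros((6, 6))
    a2 = np.zeros((6, 6))
    # x1 <- x1, x2
    a1[0, 0], a2[0, 0] = 0.68, -0.24
    a1[0, 1], a2[0, 1] = 0.45, -0.15
    # x2 <- x2, x1
    a1[1, 1], a2[1, 1] = 0.76, -0.34
    a1[1, 0], a2[1, 0] = 0.33, -0.12
    # x3 <- x3, x1
    a1[2, 2], a2[2, 2] = 0.72, -0.36
    a1[2, 0], a2[2, 0] = 0.30, -0.09
    # x4 <- x4, x2, x5
    a1[3, 3], a2[3, 3] = 0.68, -0.22
    a1[3, 1], a2[3, 1] = 0.42, -0.19
    a1[3, 4], a2[3, 4] = 0.33, -0.14
    # x5 <- x5, x2, x4
    a1[4, 4], a2[4, 4] = 0.62, -0.29
    a1[4, 1], a2[4, 1] = 0.32, -0.12
    a1[4, 3], a2[4, 3] = 0.42, -0.18
    # x6 <- x6, x3, x5
    a1[5, 5], a2[5, 5] = 0.75, -0.26
    a1[5, 2], a2[5, 2] = 0.41, -0.22
    a1[5, 4], a2[5, 4] = 0.38, -0.15
    return np.stack([a1, a2])


def benchmark_model(
    noise_var_range: tuple[float, float] = NOISE_RANGES["low"],
    rng: np.random.Generator | int | None = None,
) -> VarModel:
    """The 6-node benchmark VAR(2) with per-node noise variances drawn
    uniformly from ``noise_var_range``.

    Passing ``lo == hi`` fixes every variance; otherwise each node's
    variance is an independent uniform draw, so each call (replicate)
    gets its own noise profile.
    """
    lo, hi = noise_var_range
    if not (0 < lo <= hi):
        raise ValueError(f"invalid noise range ({lo}, {hi}): need 0 < lo <= hi")
    rng = np.random.default_rng(rng)
    variances = rng.uniform(lo, hi, size=6)
    return VarModel(m=6, p=2, coeffs=benchmark_coefficients(),
                    noise_sd=np.sqrt(variances))


def simulate(
    model: VarModel,
    n: int,
    rng: np.random.Generator | int | None = None,
    burn_in: int = 500,
) -> TimeSeriesPanel:
    """Iterate the VAR recursion from rest and return ``n`` post-burn-in samples.

    The state starts at zero, innovations are i.i.d. Gaussian per node,
    and the first ``burn_in`` samples are discarded so the series is
    effectively drawn from the stationary distribution.  A fixed seed
    gives a bit-identical panel.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not model.is_stationary:
        warnings.warn(
            f"model is not stationary (spectral radius {model.spectral_radius:.3f})",
            RuntimeWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(rng)
    total = n + burn_in
    eps = rng.standard_normal((total, model.m)) * model.noise_sd
    x = np.zeros((total + model.p, model.m))
    for t in range(model.p, total + model.p):
        acc = eps[t - model.p]
        for l in range(model.p):
            acc = acc + model.coeffs[l] @ x[t - 1 - l]
        if not np.all(np.isfinite(acc)) or np.max(np.abs(acc)) > 1e100:
            raise FloatingPointError("explosive simulation: state diverged")
        x[t] = acc
    return TimeSeriesPanel(x[model.p + burn_in :])


def ground_truth() -> np.ndarray:
    """The 6x6 boolean cross-node adjacency of the benchmark: entry (i, j)
    is True iff node i+1 drives node j+1 (9 true edges, 21 true absences)."""
    edges = np.zeros((6, 6), dtype=bool)
    for src, dst in [(2, 1), (1, 2), (1, 3), (2, 4), (5, 4), (2, 5), (4, 5),
                     (3, 6), (5, 6)]:
        edges[src - 1, dst - 1] = True
    return edges
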