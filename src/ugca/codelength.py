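"""Description lengths of a fitted lagged regression under three MDL schemes.

All code lengths are in nats (natural-log units).  The headline scheme is
the normalized-maximum-likelihood (NML) stochastic complexity of Gaussian
regression,

    L_NML = n ln sqrt(2 pi tau) + RSS/(2 tau) + (k/2) ln(n/2)
            - ln Gamma(k/2) + (k/2) ln(R_hat / tau0) - 2 ln k,

evaluated at the maximum-likelihood noise level tau = tau0 = RSS/n, so the
first two terms collapse to (n/2) ln(2 pi RSS/n) + n/2.  Here
R_hat = beta' S beta / n bounds the parameter ball over which the Fisher
information is integrated, and S = X'X is the Gram matrix of the design.

Two baselines are provided: the crude two-part code (fit term plus
(k/2) ln n parameter cost) and the SIC/Laplace mixture code (fit term plus
half the log-determinant of the unit-noise Fisher information S/tau0).

Every logarithm is natural.  A uniform base change rescales all code
lengths by the same constant and therefore cannot flip the sign of a
code-length difference, but mixing bases within one formula could, so one
base is used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.special import gammaln

from .var_core import DegenerateFitError, LaggedRegression

__all__ = [
    "Scheme",
    "CodeLength",
    "FisherGaussian",
    "nml_codelength",
    "tp_codelength",
    "mix_codelength",
    "fisher_gaussian",
    "codelength",
]


class Scheme(str, Enum):
    """Coding scheme used for a description length (or the F-test baseline)."""

    NML = "nml"
    TP = "tp"
    MIX = "mix"
    GCA = "gca"


@dataclass(frozen=True)
class CodeLength:
    scheme: Scheme
    nats: float
    k: int
    n_eff: int


@dataclass(frozen=True)
class FisherGaussian:
    """Determinant of the Gaussian-regression Fisher information.

    For a linear-Gaussian model with coefficient vector beta (k entries)
    and noise level tau, ``|I(beta, tau)| = |S| / (2 tau^(k+2))``.
    """

    det_fisher: float
    tau: float
    k: int
    det_gram: float


#: Relative floor below which a residual sum of squares is treated as exact
#: zero: lstsq round-off leaves rss ~ 1e-30 on deterministic series.
_RSS_REL_TOL = 1e-12


def _check_fit(reg: LaggedRegression) -> None:
    if reg.k < 1:
        raise ValueError("empty model: k must be >= 1")
    scale = reg.rss + reg.n_eff * reg.r_hat  # total sum of squares of the fit
    if reg.rss <= 0.0 or reg.rss < _RSS_REL_TOL * scale:
        raise DegenerateFitError("degenerate fit: code length undefined (rss = 0)")


def nml_codelength(reg: LaggedRegression) -> CodeLength:
    """Normalized-maximum-likelihood stochastic complexity of the fit, in nats."""
    _check_fit(reg)
    if reg.r_hat <= 0.0:
        raise DegenerateFitError("degenerate fit: code length undefined (r_hat = 0)")
    n, k = reg.n_eff, reg.k
    tau = reg.tau0_hat  # MLE plug-in: first two terms become (n/2)ln(2*pi*tau) + n/2
    nats = (
        0.5 * n * np.log(2.0 * np.pi * tau)
        + 0.5 * n
        + 0.5 * k * np.log(0.5 * n)
        - gammaln(0.5 * k)
        + 0.5 * k * np.log(reg.r_hat / tau)
        - 2.0 * np.log(k)
    )
    return CodeLength(Scheme.NML, float(nats), k, n)


def tp_codelength(reg: LaggedRegression) -> CodeLength:
    """Crude two-part code length: (n/2) ln(RSS/n) + (k/2) ln n."""
    _check_fit(reg)
    n, k = reg.n_eff, reg.k
    nats = 0.5 * n * np.log(reg.rss / n) + 0.5 * k * np.log(n)
    return CodeLength(Scheme.TP, float(nats), k, n)


def mix_codelength(reg: LaggedRegression) -> CodeLength:
    """Mixture (SIC/Laplace) code length: (n/2) ln(RSS/n) + (1/2) ln|S/tau0|."""
    _check_fit(reg)
    n, k = reg.n_eff, reg.k
    sign, logdet = np.linalg.slogdet(reg.gram / reg.tau0_hat)
    if sign <= 0:
        raise DegenerateFitError("degenerate fit: Gram matrix is singular")
    nats = 0.5 * n * np.log(reg.rss / n) + 0.5 * logdet
    return CodeLength(Scheme.MIX, float(nats), k, n)


_DISPATCH = {
    Scheme.NML: nml_codelength,
    Scheme.TP: tp_codelength,
    Scheme.MIX: mix_codelength,
}


def codelength(reg: LaggedRegression, scheme: Scheme | str) -> CodeLength:
    """Dispatch to the requested coding scheme."""
    scheme = Scheme(scheme)
    if scheme not in _DISPATCH:
        raise ValueError(f"no code length defined for scheme {scheme!r}")
    return _DISPATCH[scheme](reg)


def fisher_gaussian(reg: LaggedRegression, tau: float | None = None) -> FisherGaussian:
    """Fisher-information determinant |S| / (2 tau^(k+2)) at tau = tau0_hat.

    Test utility tying the Gram matrix of the fit to the parametric
    complexity integral behind the NML formula.
    """
    if tau is None:
        tau = reg.tau0_hat
    if tau <= 0.0:
        raise DegenerateFitError("degenerate fit: tau = 0")
    det_gram = float(np.linalg.det(reg.gram))
    det_fisher = det_gram / (2.0 * tau ** (reg.k + 2))
    return FisherGaussian(det_fisher=det_fisher, tau=tau, k=reg.k, det_gram=det_gram)
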