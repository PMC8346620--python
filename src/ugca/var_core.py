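"""Lagged design matrices and per-equation autoregressive OLS fits.

Every causal decision in this package reduces to comparing two nested
linear autoregressions of a target node: the *restricted* model (target
on its own past) and the *unrestricted* model (target on its own past
plus the past of one or more candidate causes).  This module builds the
lagged design matrices and fits them equation-by-equation by ordinary
least squares, exposing every statistic the description-length schemes
need: the residual sum of squares, the Gram matrix ``S = X'X``, and the
maximum-likelihood quantities ``tau0_hat = RSS/n`` and
``r_hat = beta' S beta / n``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TimeSeriesPanel",
    "LagSpec",
    "LaggedRegression",
    "DegenerateFitError",
    "InsufficientDataError",
    "build_design",
    "fit_ols",
]


class InsufficientDataError(ValueError):
    """The series is too short for the requested lag structure."""


class DegenerateFitError(ValueError):
    """A fit whose code length is undefined (zero residual or zero signal)."""


@dataclass(frozen=True)
class TimeSeriesPanel:
    """A multivariate time series: one column per node, one row per time point.

    Parameters
    ----------
    values
        Real matrix of shape ``(n_time, m_nodes)`` with no missing entries.
    node_labels
        Unique names, one per column.  Defaults to ``x1 .. xm``.
    """

    values: np.ndarray
    node_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim == 1:
            vals = vals[:, None]
        if vals.ndim != 2 or vals.shape[0] < 1 or vals.shape[1] < 1:
            raise ValueError("panel must be a non-empty 2-D array (time x nodes)")
        if not np.all(np.isfinite(vals)):
            raise ValueError("panel contains NaN or infinite values")
        object.__setattr__(self, "values", vals)
        labels = tuple(self.node_labels) or tuple(
            f"x{i + 1}" for i in range(vals.shape[1])
        )
        if len(labels) != vals.shape[1]:
            raise ValueError("number of node labels must match number of columns")
        if len(set(labels)) != len(labels):
            raise ValueError("node labels must be unique")
        object.__setattr__(self, "node_labels", labels)

    @property
    def n_time(self) -> int:
        return self.values.shape[0]

    @property
    def m_nodes(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class LagSpec:
    """Which nodes predict the target, and with how many lags each.

    ``predictors`` is an ordered tuple that must contain ``target``;
    ``orders`` maps each predictor index to its lag order (>= 1).
    """

    target: int
    predictors: tuple[int, ...]
    orders: dict[int, int] = field(default_factory=dict)
    intercept: bool = False

    def __post_init__(self) -> None:
        preds = tuple(self.predictors)
        if self.target not in preds:
            raise ValueError("target must be among the predictors (self-lags)")
        if len(set(preds)) != len(preds):
            raise ValueError("duplicate predictor indices")
        orders = dict(self.orders)
        for p in preds:
            orders.setdefault(p, 1)
            if orders[p] < 1:
                raise ValueError("all lag orders must be >= 1")
        object.__setattr__(self, "predictors", preds)
        object.__setattr__(self, "orders", orders)

    @classmethod
    def uniform(
        cls, target: int, predictors: tuple[int, ...] | list[int], order: int,
        intercept: bool = False,
    ) -> "LagSpec":
        """All predictors at the same lag order."""
        preds = tuple(predictors)
        return cls(target, preds, {p: order for p in preds}, intercept)

    @property
    def max_order(self) -> int:
        return max(self.orders[p] for p in self.predictors)

    @property
    def k(self) -> int:
        return sum(self.orders[p] for p in self.predictors) + int(self.intercept)


@dataclass(frozen=True)
class LaggedRegression:
    """One fitted lagged regression and the MLE quantities derived from it."""

    spec: LagSpec
    n_eff: int
    k: int
    beta_hat: np.ndarray
    rss: float
    gram: np.ndarray
    tau0_hat: float
    r_hat: float


def build_design(
    panel: TimeSeriesPanel, spec: LagSpec, trim: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Build the response vector and lagged design matrix for one equation.

    Row ``t`` of the design holds, for each predictor ``p`` and lag
    ``j = 1..order(p)``, the value of node ``p`` at time ``t - j``; the
    response is the target at time ``t``.  The first ``max_order`` rows
    are trimmed, so both return values have ``n_eff = n_time - max_order``
    rows.  No intercept column is added unless ``spec.intercept`` is set
    (the benchmark generator is zero-mean).

    ``trim`` forces a larger trim than the spec's own maximum order, so
    models of different order can be compared on the same response sample
    (MDL order selection needs this).
    """
    for p in spec.predictors:
        if not 0 <= p < panel.m_nodes:
            raise ValueError(f"unknown node index {p} (panel has {panel.m_nodes})")
    pmax = spec.max_order
    if trim is not None:
        if trim < pmax:
            raise ValueError(f"trim {trim} is smaller than the max lag order {pmax}")
        pmax = trim
    n_eff = panel.n_time - pmax
    if n_eff < 1:
        raise InsufficientDataError(
            f"insufficient data: need more than {pmax} time points, got {panel.n_time}"
        )
    y = panel.values[pmax:, spec.target]
    cols = []
    for p in spec.predictors:
        for j in range(1, spec.orders[p] + 1):
            cols.append(panel.values[pmax - j : panel.n_time - j, p])
    if spec.intercept:
        cols.append(np.ones(n_eff))
    X = np.column_stack(cols)
    return y, X


def fit_ols(
    panel: TimeSeriesPanel, spec: LagSpec, trim: int | None = None
) -> LaggedRegression:
    """Fit the lagged regression by ordinary least squares (Gaussian MLE).

    Rank-deficient designs fall back to the minimum-norm solution with a
    warning instead of aborting, which keeps Monte-Carlo loops alive on
    pathological draws.
    """
    y, X = build_design(panel, spec, trim=trim)
    n_eff, k = X.shape
    if n_eff <= k:
        raise InsufficientDataError(
            f"insufficient data: {n_eff} usable rows for {k} coefficients"
        )
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < k:
        warnings.warn(
            f"rank-deficient design (rank {rank} < k={k}); using minimum-norm solution",
            RuntimeWarning,
            stacklevel=2,
        )
    resid = y - X @ beta
    rss = float(resid @ resid)
    gram = X.T @ X
    tau0_hat = rss / n_eff
    r_hat = float(beta @ gram @ beta) / n_eff
    return LaggedRegression(
        spec=spec,
        n_eff=n_eff,
        k=k,
        beta_hat=beta,
        rss=rss,
        gram=gram,
        tau0_hat=tau0_hat,
        r_hat=max(r_hat, 0.0),
    )
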