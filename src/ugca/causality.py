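"""Causal decisions from code lengths, and full-network inference.

A directed influence from Y to X is declared when describing X jointly
with Y's past is cheaper than describing X from its own past alone:

    F_{Y->X} = L_X - L_{X+Y} > 0,

where L is the code length of the fitted model under the chosen MDL
scheme.  The conventional Granger F-test is provided as a baseline: it
compares the same two nested regressions but decides by the tail
probability of the F statistic at a user-chosen confidence level.

Network inference runs the decision over every ordered node pair, either
pairwise (no conditioning) or conditional on all remaining nodes.  The
conditional mode is the default: in a connected network, pairwise
analysis picks up genuine two-step predictive flow (e.g. a chain
x -> z -> y makes x's past informative about y), which conditioning on
the intermediate nodes removes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats

from .codelength import Scheme, codelength
from .var_core import (
    DegenerateFitError,
    InsufficientDataError,
    LagSpec,
    LaggedRegression,
    TimeSeriesPanel,
    fit_ols,
)

__all__ = [
    "CausalDecision",
    "AdjacencyNetwork",
    "DEFAULT_P_MAX",
    "ugca_pair",
    "ugca_conditional",
    "gca_ftest",
    "infer_network",
]

#: Largest lag order scanned when ``order="mdl"``.
DEFAULT_P_MAX = 5


@dataclass(frozen=True)
class CausalDecision:
    """One directed-edge verdict.

    ``statistic`` is the code-length saving in nats for MDL schemes, or
    the F ratio for the F-test; ``edge`` applies the decision rule
    (saving > 0, or p < alpha).  ``note`` records degraded outcomes such
    as degenerate fits.
    """

    source: int
    target: int
    statistic: float
    edge: bool
    scheme: Scheme
    alpha: float | None = None
    p_value: float | None = None
    note: str | None = None


@dataclass(frozen=True)
class AdjacencyNetwork:
    """Binary directed network: ``edges[i, j]`` means i -> j; no self-loops."""

    edges: np.ndarray
    node_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=bool)
        if edges.ndim != 2 or edges.shape[0] != edges.shape[1]:
            raise ValueError("edges must be a square matrix")
        if np.any(np.diag(edges)):
            raise ValueError("self-loops are not allowed")
        object.__setattr__(self, "edges", edges)
        labels = tuple(self.node_labels) or tuple(
            f"x{i + 1}" for i in range(edges.shape[0])
        )
        if len(labels) != edges.shape[0]:
            raise ValueError("number of labels must match matrix size")
        object.__setattr__(self, "node_labels", labels)

    @property
    def m(self) -> int:
        return self.edges.shape[0]

    def offdiagonal(self) -> np.ndarray:
        """The m(m-1) off-diagonal entries in row-major order."""
        mask = ~np.eye(self.m, dtype=bool)
        return self.edges[mask]


Fitter = Callable[[int, tuple[int, ...]], LaggedRegression]


def _make_fitter(
    panel: TimeSeriesPanel,
    order: int | str,
    intercept: bool,
    select_scheme: Scheme,
    p_max: int = DEFAULT_P_MAX,
) -> Fitter:
    """Return a memoized (target, predictors) -> fit function.

    With an integer ``order`` every predictor gets that many lags.  With
    ``order="mdl"`` the uniform order in 1..p_max minimizing the model's
    own code length is selected, all candidates trimmed at ``p_max`` rows
    so their code lengths describe the same response sample.
    """
    # Key on the predictor *set*: rss, k, r_hat and |gram| are invariant to
    # column order, so e.g. the full conditional model is fitted once per
    # target instead of once per (source, target) pair.
    cache: dict[tuple[int, frozenset[int]], LaggedRegression] = {}

    def fit(target: int, predictors: tuple[int, ...]) -> LaggedRegression:
        key = (target, frozenset(predictors))
        if key not in cache:
            if order == "mdl":
                best: tuple[float, LaggedRegression] | None = None
                for o in range(1, p_max + 1):
                    reg = fit_ols(
                        panel,
                        LagSpec.uniform(target, predictors, o, intercept),
                        trim=p_max,
                    )
                    nats = codelength(reg, select_scheme).nats
                    if best is None or nats < best[0]:
                        best = (nats, reg)
                assert best is not None
                cache[key] = best[1]
            elif isinstance(order, int) and order >= 1:
                cache[key] = fit_ols(
                    panel, LagSpec.uniform(target, predictors, order, intercept)
                )
            else:
                raise ValueError(f"order must be a positive integer or 'mdl', got {order!r}")
        return cache[key]

    return fit


def _validate_pair(panel, source, target, conditioning):
    indices = (source, target, *conditioning)
    if len(set(indices)) != len(indices):
        raise ValueError("source, target and conditioning set must be distinct")
    for i in indices:
        if not 0 <= i < panel.m_nodes:
            raise ValueError(f"unknown node index {i}")


def _mdl_decision(
    source: int,
    target: int,
    conditioning: tuple[int, ...],
    scheme: Scheme,
    fitter: Fitter,
) -> CausalDecision:
    base = (target, *conditioning)
    try:
        restricted = fitter(target, base)
        unrestricted = fitter(target, (*base, source))
        stat = codelength(restricted, scheme).nats - codelength(unrestricted, scheme).nats
    except (DegenerateFitError, InsufficientDataError) as exc:
        warnings.warn(
            f"undecidable pair {source}->{target}: {exc}", RuntimeWarning, stacklevel=3
        )
        return CausalDecision(source, target, float("nan"), False, scheme,
                              note=f"undecidable: {exc}")
    return CausalDecision(source, target, float(stat), bool(stat > 0.0), scheme)


def _ftest_decision(
    source: int,
    target: int,
    conditioning: tuple[int, ...],
    alpha: float,
    fitter: Fitter,
) -> CausalDecision:
    base = (target, *conditioning)
    try:
        restricted = fitter(target, base)
        unrestricted = fitter(target, (*base, source))
    except (DegenerateFitError, InsufficientDataError) as exc:
        warnings.warn(
            f"undecidable pair {source}->{target}: {exc}", RuntimeWarning, stacklevel=3
        )
        return CausalDecision(source, target, float("nan"), False, Scheme.GCA,
                              alpha=alpha, note=f"undecidable: {exc}")
    q = unrestricted.k - restricted.k
    dof = unrestricted.n_eff - unrestricted.k
    if unrestricted.rss <= 0.0 or dof <= 0 or q <= 0:
        warnings.warn(
            f"undecidable pair {source}->{target}: degenerate unrestricted fit",
            RuntimeWarning,
            stacklevel=3,
        )
        return CausalDecision(source, target, float("nan"), False, Scheme.GCA,
                              alpha=alpha, note="undecidable: degenerate fit")
    f_stat = ((restricted.rss - unrestricted.rss) / q) / (unrestricted.rss / dof)
    f_stat = max(f_stat, 0.0)  # guard tiny negative from round-off
    p_value = float(stats.f.sf(f_stat, q, dof))
    return CausalDecision(source, target, float(f_stat), bool(p_value < alpha),
                          Scheme.GCA, alpha=alpha, p_value=p_value)


def ugca_conditional(
    panel: TimeSeriesPanel,
    source: int,
    target: int,
    conditioning: tuple[int, ...] = (),
    scheme: Scheme | str = Scheme.NML,
    order: int | str = 2,
    intercept: bool = False,
) -> CausalDecision:
    """MDL causal decision for source -> target given a conditioning set.

    The restricted model regresses the target on its own lags and those
    of the conditioning nodes; the unrestricted model adds the source's
    lags.  An empty conditioning set reduces to the pairwise analysis.
    Degenerate fits (zero residual) yield no edge plus a warning rather
    than an exception, so network loops never abort.
    """
    scheme = Scheme(scheme)
    if scheme is Scheme.GCA:
        raise ValueError("scheme 'gca' has no code length; use gca_ftest")
    conditioning = tuple(conditioning)
    _validate_pair(panel, source, target, conditioning)
    fitter = _make_fitter(panel, order, intercept, scheme)
    return _mdl_decision(source, target, conditioning, scheme, fitter)


def ugca_pair(
    panel: TimeSeriesPanel,
    source: int,
    target: int,
    scheme: Scheme | str = Scheme.NML,
    order: int | str = 2,
    intercept: bool = False,
) -> CausalDecision:
    """Pairwise MDL causal decision (no conditioning nodes)."""
    return ugca_conditional(panel, source, target, (), scheme, order, intercept)


def gca_ftest(
    panel: TimeSeriesPanel,
    source: int,
    target: int,
    conditioning: tuple[int, ...] = (),
    alpha: float = 0.05,
    order: int | str = 2,
    intercept: bool = False,
) -> CausalDecision:
    """Classic Granger-causality F-test for source -> target.

    F = ((RSS_r - RSS_u)/q) / (RSS_u/(n_eff - k_u)) with q added
    coefficients; the edge is declared when the p-value from the
    F(q, n_eff - k_u) distribution falls below alpha.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    conditioning = tuple(conditioning)
    _validate_pair(panel, source, target, conditioning)
    fitter = _make_fitter(panel, order, intercept, Scheme.NML)
    return _ftest_decision(source, target, conditioning, alpha, fitter)


def infer_network(
    panel: TimeSeriesPanel,
    scheme: Scheme | str = Scheme.NML,
    mode: str = "conditional",
    order: int | str = 2,
    alpha: float = 0.05,
    intercept: bool = False,
    return_decisions: bool = False,
) -> AdjacencyNetwork | tuple[AdjacencyNetwork, list[CausalDecision]]:
    """Run the per-pair decision over every ordered node pair.

    ``mode='conditional'`` (default) conditions each pair on all
    remaining nodes; ``mode='pairwise'`` conditions on nothing.
    ``scheme`` may be any MDL scheme or ``'gca'`` for the F-test baseline
    (which then uses ``alpha``).  Fits are shared across pairs, so a
    6-node conditional network costs 36 regressions, not 60.
    """
    scheme = Scheme(scheme)
    if mode not in ("pairwise", "conditional"):
        raise ValueError(f"unknown mode {mode!r}")
    m = panel.m_nodes
    if m < 2:
        raise ValueError("need at least 2 nodes to infer a network")
    select_scheme = Scheme.NML if scheme is Scheme.GCA else scheme
    fitter = _make_fitter(panel, order, intercept, select_scheme)
    edges = np.zeros((m, m), dtype=bool)
    decisions: list[CausalDecision] = []
    for target in range(m):
        for source in range(m):
            if source == target:
                continue
            others = tuple(i for i in range(m) if i not in (source, target))
            cond = others if mode == "conditional" else ()
            if scheme is Scheme.GCA:
                dec = _ftest_decision(source, target, cond, alpha, fitter)
            else:
                dec = _mdl_decision(source, target, cond, scheme, fitter)
            edges[source, target] = dec.edge
            decisions.append(dec)
    net = AdjacencyNetwork(edges, panel.node_labels)
    return (net, decisions) if return_decisions else net
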