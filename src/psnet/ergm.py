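"""Dyad-independent exponential random graph models.

With only dyad-independent terms the ERGM likelihood factorizes over the
N(N-1)/2 unordered dyads into independent Bernoulli terms with
logit(p_ij) = theta . x_ij, where x_ij are the change statistics of the
dyad.  Estimation therefore maximizes an exact logistic likelihood over
dyads (no MCMC); this module implements the change statistics, a damped
Newton MLE with Wald intervals, information criteria, per-dyad simulation
and the degree / edgewise-shared-partner / geodesic goodness-of-fit.

Terms: ``edges``; ``nodefactor(attr, ref)`` (count of endpoints at each
non-reference level); ``nodematch(attr)`` (uniform homophily: indicator
that the endpoints match); ``nodematch_diff(attr)`` (differential
homophily: one matching indicator per level).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.special import expit
from scipy.stats import norm

from psnet.errors import DataError, SpecificationError

#: |coefficient| beyond which a term is treated as separated (diverging).
_SEPARATION_BOUND = 12.0


# ---------------------------------------------------------------------------
# model specification


@dataclass(frozen=True)
class Edges:
    def __str__(self) -> str:
        return "edges"


@dataclass(frozen=True)
class NodeFactor:
    attribute: str
    reference: str

    def __str__(self) -> str:
        return f"nodefactor({self.attribute}, ref={self.reference})"


@dataclass(frozen=True)
class NodeMatchUniform:
    attribute: str

    def __str__(self) -> str:
        return f"nodematch({self.attribute})"


@dataclass(frozen=True)
class NodeMatchDifferential:
    attribute: str

    def __str__(self) -> str:
        return f"nodematch_diff({self.attribute})"


Term = Edges | NodeFactor | NodeMatchUniform | NodeMatchDifferential


@dataclass(frozen=True)
class ErgmSpec:
    """Ordered list of dyad-independent terms.

    ``levels`` may pin the level order per attribute; otherwise levels are
    read off the network (sorted, reference first for nodefactor).
    """

    terms: tuple[Term, ...]
    levels: tuple[tuple[str, tuple[str, ...]], ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.terms)) != len(self.terms):
            raise SpecificationError("duplicate ERGM terms")
        uniform = {t.attribute for t in self.terms if isinstance(t, NodeMatchUniform)}
        diff = {t.attribute for t in self.terms if isinstance(t, NodeMatchDifferential)}
        both = uniform & diff
        if both:
            raise SpecificationError(
                f"uniform and differential homophily on {sorted(both)} are mutually exclusive"
            )

    def attributes(self) -> set[str]:
        return {t.attribute for t in self.terms if not isinstance(t, Edges)}

    def level_order(self, attribute: str) -> tuple[str, ...] | None:
        for attr, lv in self.levels:
            if attr == attribute:
                return lv
        return None


def step1_spec(municipality: bool = True) -> ErgmSpec:
    """edges + municipality main effect/uniform homophily + occupation main
    effect + uniform occupation homophily."""
    terms: list[Term] = [Edges()]
    if municipality:
        terms += [NodeFactor("municipality", reference=""), NodeMatchUniform("municipality")]
    terms += [NodeFactor("occupation", reference="physician"), NodeMatchUniform("occupation")]
    return ErgmSpec(tuple(terms))


def step2_spec(municipality: bool = True) -> ErgmSpec:
    """Like step 1 but with differential occupation homophily (no uniform)."""
    terms: list[Term] = [Edges()]
    if municipality:
        terms += [NodeFactor("municipality", reference=""), NodeMatchUniform("municipality")]
    terms += [NodeFactor("occupation", reference="physician"), NodeMatchDifferential("occupation")]
    return ErgmSpec(tuple(terms))


# ---------------------------------------------------------------------------
# change statistics


def _node_attribute_array(net: nx.Graph, nodes: list, attribute: str) -> list:
    vals = []
    for v in nodes:
        if attribute not in net.nodes[v]:
            raise DataError(f"node {v!r} is missing attribute {attribute!r}")
        vals.append(net.nodes[v][attribute])
    return vals


def _resolve_levels(spec: ErgmSpec, attribute: str, observed: Sequence) -> list:
    pinned = spec.level_order(attribute)
    if pinned is not None:
        extra = set(observed) - set(pinned)
        if extra:
            raise SpecificationError(
                f"levels {sorted(extra)} of {attribute!r} not declared in spec"
            )
        return list(pinned)
    return sorted(set(observed))


def change_statistics(
    net: nx.Graph, spec: ErgmSpec
) -> tuple[np.ndarray, np.ndarray, list[str], tuple[np.ndarray, np.ndarray], list]:
    """Per-dyad design matrix for a dyad-independent spec.

    Returns (X, y, column names, (i_idx, j_idx), node order): one row per
    unordered dyad in upper-triangle order of the sorted node list; y is
    the 0/1 edge indicator.
    """
    nodes = sorted(net.nodes)
    n = len(nodes)
    iu, ju = np.triu_indices(n, k=1)
    adj = nx.to_numpy_array(net, nodelist=nodes, weight=None)
    y = adj[iu, ju]

    attr_codes: dict[str, np.ndarray] = {}
    attr_levels: dict[str, list] = {}
    for attribute in spec.attributes():
        observed = _node_attribute_array(net, nodes, attribute)
        levels = _resolve_levels(spec, attribute, observed)
        index = {lv: k for k, lv in enumerate(levels)}
        attr_codes[attribute] = np.array([index[v] for v in observed])
        attr_levels[attribute] = levels

    cols: list[np.ndarray] = []
    names: list[str] = []
    for term in spec.terms:
        if isinstance(term, Edges):
            cols.append(np.ones(len(iu)))
            names.append("edges")
        elif isinstance(term, NodeFactor):
            codes = attr_codes[term.attribute]
            levels = attr_levels[term.attribute]
            reference = term.reference if term.reference in levels else levels[0]
            ci, cj = codes[iu], codes[ju]
            for k, lv in enumerate(levels):
                if lv == reference:
                    continue
                cols.append((ci == k).astype(float) + (cj == k).astype(float))
                names.append(f"nodefactor.{term.attribute}.{lv}")
        elif isinstance(term, NodeMatchUniform):
            codes = attr_codes[term.attribute]
            cols.append((codes[iu] == codes[ju]).astype(float))
            names.append(f"nodematch.{term.attribute}")
        elif isinstance(term, NodeMatchDifferential):
            codes = attr_codes[term.attribute]
            ci, cj = codes[iu], codes[ju]
            for k, lv in enumerate(attr_levels[term.attribute]):
                cols.append(((ci == k) & (cj == k)).astype(float))
                names.append(f"nodematch.{term.attribute}.{lv}")
        else:  # pragma: no cover
            raise SpecificationError(f"unsupported term {term!r}")
    X = np.column_stack(cols) if cols else np.empty((len(iu), 0))
    return X, y, names, (iu, ju), nodes


# ---------------------------------------------------------------------------
# estimation


def _nll(theta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    eta = X @ theta
    # log(1 + e^eta) computed stably
    return float(np.sum(np.logaddexp(0.0, eta)) - y @ eta)


def _grad(theta: np.ndarray, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    p = expit(X @ theta)
    return X.T @ (p - y)


def _hess(theta: np.ndarray, X: np.ndarray) -> np.ndarray:
    p = expit(X @ theta)
    w = p * (1.0 - p)
    return (X * w[:, None]).T @ X


def _newton(
    X: np.ndarray,
    y: np.ndarray,
    gtol: float = 1e-8,
    max_iter: int = 200,
) -> tuple[np.ndarray, bool]:
    """Damped Newton-Raphson on the dyadic logistic negative log-likelihood."""
    k = X.shape[1]
    theta = np.zeros(k)
    f = _nll(theta, X, y)
    for _ in range(max_iter):
        g = _grad(theta, X, y)
        if np.max(np.abs(g)) < gtol:
            return theta, True
        H = _hess(theta, X)
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(k), g)
        except np.linalg.LinAlgError:
            step = g
        t = 1.0
        ftol = 1e-10 * max(1.0, abs(f))
        for _ in range(60):
            cand = theta - t * step
            fc = _nll(cand, X, y)
            if fc <= f + ftol:
                theta, f = cand, fc
                break
            t /= 2.0
        else:
            # function change below resolution: trust the full Newton step
            # (quadratic convergence drives the gradient down regardless)
            theta = theta - step
            f = _nll(theta, X, y)
    return theta, bool(np.max(np.abs(_grad(theta, X, y))) < gtol)


@dataclass
class ErgmFit:
    """A fitted dyad-independent ERGM.

    ``separated`` marks coefficients diverging to +/- infinity (perfect
    separation); their reported estimate is +/- inf with an infinite SE and
    a one-sided Wald interval.
    """

    spec: ErgmSpec
    coef_names: list[str]
    theta: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    loglik: float
    aic: float
    bic: float
    n_dyads: int
    converged: bool
    separated: np.ndarray
    #: raw (finite) optimizer estimate, before separated terms are set to inf
    theta_raw: np.ndarray = None
    network: nx.Graph = field(repr=False, default=None)

    def coefficients(self) -> dict[str, float]:
        return dict(zip(self.coef_names, self.theta))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "term": self.coef_names,
                "log_odds": self.theta,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "se": self.se,
                "separated": self.separated,
            }
        )


def fit_ergm(net: nx.Graph, spec: ErgmSpec, gtol: float = 1e-8) -> ErgmFit:
    """Maximum-likelihood fit via the exact dyadic likelihood.

    Valid because every supported term is dyad-independent, making the
    ERGM a product of per-dyad Bernoulli factors.  AIC = -2 loglik + 2k;
    BIC = -2 loglik + k log(n_dyads) with n_dyads = N(N-1)/2.
    """
    X, y, names, _, _ = change_statistics(net, spec)
    n_dyads, k = X.shape
    if n_dyads == 0:
        raise DataError("network has fewer than 2 nodes: no dyads to model")
    theta, converged = _newton(X, y, gtol=gtol)
    theta_raw = theta.copy()
    separated = np.abs(theta) > _SEPARATION_BOUND
    ll = -_nll(theta, X, y)  # achieved likelihood (limit value under separation)
    H = _hess(theta, X)
    with np.errstate(all="ignore"):
        try:
            cov = np.linalg.inv(H)
            var = np.diag(cov).copy()
        except np.linalg.LinAlgError:
            var = np.full(k, np.inf)
    var[var <= 0] = np.inf
    se = np.sqrt(var)
    z = norm.ppf(0.975)
    ci_low = theta - z * se
    ci_high = theta + z * se
    if separated.any():
        sign = np.sign(theta)
        theta = theta.copy()
        for j in np.where(separated)[0]:
            se[j] = np.inf
            if sign[j] < 0:
                theta[j], ci_low[j], ci_high[j] = -np.inf, -np.inf, ci_high[j]
            else:
                theta[j], ci_low[j], ci_high[j] = np.inf, ci_low[j], np.inf
        converged = True  # diverging coefficients, not an optimizer failure
    aic = -2.0 * ll + 2.0 * k
    bic = -2.0 * ll + k * math.log(n_dyads)
    return ErgmFit(
        spec=spec,
        coef_names=names,
        theta=theta,
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        loglik=ll,
        aic=aic,
        bic=bic,
        n_dyads=n_dyads,
        converged=converged,
        separated=separated,
        theta_raw=theta_raw,
        network=net,
    )


def dyad_probabilities(
    net: nx.Graph, spec: ErgmSpec, theta: Sequence[float]
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray], list]:
    """Per-dyad tie probabilities logistic(theta . x) for given coefficients."""
    X, _, names, (iu, ju), nodes = change_statistics(net, spec)
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (X.shape[1],):
        raise SpecificationError(
            f"coefficient vector of length {theta.size} does not match "
            f"{X.shape[1]} model columns {names}"
        )
    return expit(X @ theta), (iu, ju), nodes


def simulate_from_fit(
    fit: ErgmFit, n_sim: int = 100, seed: int = 0
) -> list[nx.Graph]:
    """Draw networks dyad-by-dyad from the fitted Bernoulli probabilities.

    Node attributes are copied from the observed network.  Refuses to
    simulate from an unconverged fit.
    """
    if not fit.converged:
        raise SpecificationError("refusing to simulate from an unconverged fit")
    theta = np.where(np.isfinite(fit.theta), fit.theta, np.sign(fit.theta) * 50.0)
    p, (iu, ju), nodes = dyad_probabilities(fit.network, fit.spec, theta)
    rng = np.random.default_rng(seed)
    sims = []
    for _ in range(n_sim):
        draws = rng.random(p.size) < p
        g = nx.Graph()
        g.add_nodes_from((v, dict(fit.network.nodes[v])) for v in nodes)
        g.add_edges_from(
            (nodes[i], nodes[j]) for i, j in zip(iu[draws], ju[draws])
        )
        sims.append(g)
    return sims


# ---------------------------------------------------------------------------
# goodness of fit


def degree_counts(net: nx.Graph) -> np.ndarray:
    degs = [d for _, d in net.degree()]
    out = np.zeros((max(degs) if degs else 0) + 1, dtype=int)
    for d in degs:
        out[d] += 1
    return out


def esp_counts(net: nx.Graph) -> np.ndarray:
    """Edgewise shared partners: common-neighbor count per existing edge."""
    esp = [len(set(net[u]) & set(net[v])) for u, v in net.edges]
    out = np.zeros((max(esp) if esp else 0) + 1, dtype=int)
    for e in esp:
        out[e] += 1
    return out


def geodesic_counts(net: nx.Graph) -> tuple[np.ndarray, int]:
    """Unordered-pair counts per geodesic length; second value counts
    unreachable pairs.  Sums to N(N-1)/2."""
    n = net.number_of_nodes()
    total_pairs = n * (n - 1) // 2
    counts: dict[int, int] = {}
    reachable = 0
    for _, lengths in nx.all_pairs_shortest_path_length(net):
        for d in lengths.values():
            if d > 0:
                counts[d] = counts.get(d, 0) + 1
    counts = {d: c // 2 for d, c in counts.items()}
    reachable = sum(counts.values())
    out = np.zeros((max(counts) if counts else 0) + 1, dtype=int)
    for d, c in counts.items():
        out[d] = c
    return out, total_pairs - reachable


def _pad(a: np.ndarray, length: int) -> np.ndarray:
    return np.pad(a, (0, length - len(a)))


@dataclass
class GofPanel:
    """One diagnostic distribution: observed vector plus simulation envelope."""

    name: str
    bins: list
    observed: np.ndarray
    sim_median: np.ndarray
    sim_lo: np.ndarray
    sim_hi: np.ndarray

    @property
    def fraction_inside(self) -> float:
        inside = (self.observed >= self.sim_lo) & (self.observed <= self.sim_hi)
        return float(np.mean(inside))


@dataclass
class GofReport:
    panels: dict[str, GofPanel]
    n_sim: int

    def summary(self) -> dict:
        return {name: p.fraction_inside for name, p in self.panels.items()}


def _panel(name: str, observed: np.ndarray, sims: list[np.ndarray], bins=None) -> GofPanel:
    length = max(len(observed), *(len(s) for s in sims))
    obs = _pad(observed, length)
    mat = np.vstack([_pad(s, length) for s in sims])
    return GofPanel(
        name=name,
        bins=list(bins) if bins is not None else list(range(length)),
        observed=obs,
        sim_median=np.median(mat, axis=0),
        sim_lo=np.percentile(mat, 2.5, axis=0),
        sim_hi=np.percentile(mat, 97.5, axis=0),
    )


def gof(fit: ErgmFit, observed: nx.Graph, n_sim: int = 100, seed: int = 0) -> GofReport:
    """Compare observed degree / ESP / geodesic distributions with
    ``n_sim`` simulations from the fitted model (2.5-97.5% envelopes)."""
    sims = simulate_from_fit(fit, n_sim=n_sim, seed=seed)
    obs_deg = degree_counts(observed)
    obs_esp = esp_counts(observed)
    obs_geo, obs_unreach = geodesic_counts(observed)
    sim_deg, sim_esp, sim_geo = [], [], []
    for g in sims:
        sim_deg.append(degree_counts(g))
        sim_esp.append(esp_counts(g))
        geo, unreach = geodesic_counts(g)
        sim_geo.append(np.append(geo, unreach))
    # realign geodesic vectors so the unreachable counts share one final bin
    length = max(len(obs_geo), *(len(g) - 1 for g in sim_geo))
    obs_vec = np.append(_pad(obs_geo, length), obs_unreach)
    sim_vecs = [np.append(_pad(g[:-1], length), g[-1]) for g in sim_geo]
    bins = list(range(length)) + ["unreachable"]
    panels = {
        "degree": _panel("degree", obs_deg, sim_deg),
        "esp": _panel("esp", obs_esp, sim_esp),
        "geodesic": _panel("geodesic", obs_vec, sim_vecs, bins=bins),
    }
    return GofReport(panels=panels, n_sim=n_sim)
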