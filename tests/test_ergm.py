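import math
from itertools import combinations, product

import networkx as nx
import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from psnet import ergm
from psnet.errors import DataError, SpecificationError
from psnet.ergm import (
    Edges,
    ErgmSpec,
    NodeFactor,
    NodeMatchDifferential,
    NodeMatchUniform,
)

OCC3 = {"physician": 0.4, "nurse": 0.4, "other": 0.2}


def attributed_graph(attrs, edges=()):
    """Graph from {node: {attr: value}} plus an edge list."""
    g = nx.Graph()
    for node, a in attrs.items():
        g.add_node(node, **a)
    g.add_edges_from(edges)
    return g


# ---------------------------------------------------------------------------
# independent oracle: naive per-dyad statistics and exhaustive enumeration


def naive_dyad_stats(g, spec):
    """Recompute change statistics with a naive double loop, term by term,
    written independently of the package implementation."""
    nodes = sorted(g.nodes)
    rows = []
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            row = []
            for term in spec.terms:
                if isinstance(term, Edges):
                    row.append(1.0)
                elif isinstance(term, NodeFactor):
                    levels = sorted({g.nodes[n][term.attribute] for n in nodes})
                    ref = term.reference if term.reference in levels else levels[0]
                    for lv in levels:
                        if lv == ref:
                            continue
                        row.append(
                            float(g.nodes[u][term.attribute] == lv)
                            + float(g.nodes[v][term.attribute] == lv)
                        )
                elif isinstance(term, NodeMatchUniform):
                    row.append(float(g.nodes[u][term.attribute] == g.nodes[v][term.attribute]))
                elif isinstance(term, NodeMatchDifferential):
                    levels = sorted({g.nodes[n][term.attribute] for n in nodes})
                    for lv in levels:
                        row.append(
                            float(g.nodes[u][term.attribute] == lv and g.nodes[v][term.attribute] == lv)
                        )
            rows.append(row)
    return np.array(rows)


def enumerate_graph_stats(X):
    """Sufficient-statistic vector of every graph on the dyad set: for
    dyad-independent terms the graph statistic is the sum of per-dyad
    statistics over present edges."""
    n_dyads = X.shape[0]
    configs = np.array(list(product([0, 1], repeat=n_dyads)), dtype=float)
    return configs, configs @ X  # (2^C, k)


def enumerated_logprob(theta, s_obs, S):
    logits = S @ theta
    m = logits.max()
    logZ = m + math.log(np.exp(logits - m).sum())
    return float(s_obs @ theta - logZ)


# ---------------------------------------------------------------------------


class TestChangeStatistics:
    def test_nurse_nurse_dyad(self):
        g = attributed_graph(
            {"a": {"occupation": "nurse"}, "b": {"occupation": "nurse"}},
        )
        spec = ErgmSpec((Edges(), NodeFactor("occupation", "physician"),
                         NodeMatchUniform("occupation")))
        X, y, names, _, _ = ergm.change_statistics(g, spec)
        row = dict(zip(names, X[0]))
        assert row["edges"] == 1
        assert row["nodematch.occupation"] == 1
        # only "nurse" is observed so it is also the fallback reference:
        # declare levels to pin physician as reference
        spec = ErgmSpec(
            (Edges(), NodeFactor("occupation", "physician"), NodeMatchUniform("occupation")),
            levels=(("occupation", ("physician", "nurse")),),
        )
        X, _, names, _, _ = ergm.change_statistics(g, spec)
        row = dict(zip(names, X[0]))
        assert row["nodefactor.occupation.nurse"] == 2

    def test_physician_other_dyad(self):
        g = attributed_graph(
            {"a": {"occupation": "physician"}, "b": {"occupation": "other"}},
        )
        spec = ErgmSpec(
            (Edges(), NodeFactor("occupation", "physician"), NodeMatchDifferential("occupation")),
            levels=(("occupation", ("physician", "nurse", "other")),),
        )
        X, _, names, _, _ = ergm.change_statistics(g, spec)
        row = dict(zip(names, X[0]))
        assert row["nodefactor.occupation.other"] == 1
        assert all(row[n] == 0 for n in names if n.startswith("nodematch."))

    @pytest.mark.parametrize("seed", [0, 1])
    def test_six_node_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        attrs = {
            f"n{i}": {
                "occupation": str(rng.choice(["physician", "nurse", "other"])),
                "municipality": str(rng.choice(["M1", "M2"])),
            }
            for i in range(6)
        }
        g = attributed_graph(attrs, edges=[("n0", "n1"), ("n2", "n3")])
        spec = ErgmSpec((
            Edges(),
            NodeFactor("occupation", "physician"),
            NodeMatchUniform("occupation"),
            NodeFactor("municipality", ""),
            NodeMatchUniform("municipality"),
        ))
        X, y, names, _, _ = ergm.change_statistics(g, spec)
        np.testing.assert_allclose(X, naive_dyad_stats(g, spec))
        assert y.sum() == 2

    def test_missing_attribute_named(self):
        g = attributed_graph({"a": {"occupation": "nurse"}, "b": {}})
        spec = ErgmSpec((Edges(), NodeMatchUniform("occupation")))
        with pytest.raises(DataError, match="b"):
            ergm.change_statistics(g, spec)


class TestSpecValidation:
    def test_duplicate_terms(self):
        with pytest.raises(SpecificationError):
            ErgmSpec((Edges(), Edges()))

    def test_uniform_and_differential_exclusive(self):
        with pytest.raises(SpecificationError):
            ErgmSpec((Edges(), NodeMatchUniform("occupation"),
                      NodeMatchDifferential("occupation")))


class TestFit:
    def test_edges_only_closed_form(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("c", "d")])
        fit = ergm.fit_ergm(g, ErgmSpec((Edges(),)))
        assert fit.theta[0] == pytest.approx(0.0, abs=1e-8)  # logit(3/6)
        assert fit.n_dyads == 6

    @pytest.mark.parametrize("density,expected", [(0.25, math.log(1 / 3))])
    def test_edges_only_matches_logit_density(self, density, expected):
        g = nx.gnp_random_graph(20, density, seed=8)
        fit = ergm.fit_ergm(g, ErgmSpec((Edges(),)))
        d = g.number_of_edges() / fit.n_dyads
        assert fit.theta[0] == pytest.approx(math.log(d / (1 - d)), abs=1e-7)

    def test_aic_bic_identities(self):
        g = nx.gnp_random_graph(15, 0.3, seed=1)
        for n in g.nodes:
            g.nodes[n]["occupation"] = "nurse" if n % 2 else "physician"
        spec = ErgmSpec((Edges(), NodeFactor("occupation", "physician"),
                         NodeMatchUniform("occupation")))
        fit = ergm.fit_ergm(g, spec)
        k = len(fit.theta)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * k)
        assert fit.bic == pytest.approx(-2 * fit.loglik + k * math.log(fit.n_dyads))
        assert fit.n_dyads == 15 * 14 // 2

    def test_ci_brackets_estimate(self):
        g = nx.gnp_random_graph(25, 0.2, seed=3)
        fit = ergm.fit_ergm(g, ErgmSpec((Edges(),)))
        assert fit.ci_low[0] < fit.theta[0] < fit.ci_high[0]

    def test_mean_value_principle_by_enumeration(self):
        # at the MLE, E[statistic] under the model equals the observed value
        rng = np.random.default_rng(2)
        attrs = {f"n{i}": {"occupation": str(rng.choice(["physician", "nurse"]))}
                 for i in range(5)}
        g = attributed_graph(attrs, edges=[("n0", "n1"), ("n1", "n2"), ("n3", "n4"), ("n0", "n2")])
        spec = ErgmSpec((Edges(), NodeMatchUniform("occupation")))
        fit = ergm.fit_ergm(g, spec)
        assert fit.converged and not fit.separated.any()
        X, y, _, _, _ = ergm.change_statistics(g, spec)
        configs, S = enumerate_graph_stats(X)
        logits = S @ fit.theta
        w = np.exp(logits - logits.max())
        w /= w.sum()
        expected = w @ S
        observed = y @ X
        np.testing.assert_allclose(expected, observed, atol=1e-6)

    def test_separation_flagged(self):
        # no edge ever touches an "other" node -> nodefactor(other) -> -inf
        g = attributed_graph(
            {
                "a": {"occupation": "physician"},
                "b": {"occupation": "physician"},
                "c": {"occupation": "other"},
                "d": {"occupation": "other"},
            },
            edges=[("a", "b")],
        )
        spec = ErgmSpec((Edges(), NodeFactor("occupation", "physician")))
        fit = ergm.fit_ergm(g, spec)
        j = fit.coef_names.index("nodefactor.occupation.other")
        assert fit.separated[j]
        assert fit.theta[j] == -math.inf
        assert fit.se[j] == math.inf
        assert fit.ci_low[j] == -math.inf

    def test_mle_matches_enumeration_argmax(self):
        rng = np.random.default_rng(4)
        attrs = {f"n{i}": {"occupation": str(rng.choice(["physician", "nurse", "other"]))}
                 for i in range(5)}
        g = attributed_graph(attrs, edges=[("n0", "n1"), ("n1", "n2"), ("n2", "n3"),
                                           ("n3", "n4"), ("n0", "n4")])
        spec = ErgmSpec((Edges(), NodeMatchUniform("occupation")))
        fit = ergm.fit_ergm(g, spec)
        assert not fit.separated.any()
        X, y, _, _, _ = ergm.change_statistics(g, spec)
        _, S = enumerate_graph_stats(X)
        s_obs = y @ X
        res = minimize(lambda th: -enumerated_logprob(th, s_obs, S), np.zeros(len(fit.theta)),
                       method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12})
        np.testing.assert_allclose(fit.theta, res.x, atol=1e-6)


class TestSimulate:
    def _edges_fit(self, n=12, p=0.4, seed=0):
        g = nx.gnp_random_graph(n, p, seed=seed)
        return ergm.fit_ergm(g, ErgmSpec((Edges(),))), g

    def test_all_zero_probability_gives_empty_graphs(self):
        g = nx.Graph()
        g.add_nodes_from(range(6))
        fit = ergm.fit_ergm(g, ErgmSpec((Edges(),)))  # empty graph -> separation to -inf
        sims = ergm.simulate_from_fit(fit, n_sim=5, seed=0)
        assert all(s.number_of_edges() == 0 for s in sims)

    def test_edge_count_moment(self):
        fit, g = self._edges_fit()
        sims = ergm.simulate_from_fit(fit, n_sim=200, seed=1)
        d = g.number_of_edges() / fit.n_dyads
        mean = np.mean([s.number_of_edges() for s in sims])
        var = fit.n_dyads * d * (1 - d) / 200
        assert abs(mean - d * fit.n_dyads) < 3 * math.sqrt(var) + 1e-9

    def test_same_seed_identical(self):
        fit, _ = self._edges_fit()
        a = ergm.simulate_from_fit(fit, n_sim=3, seed=7)
        b = ergm.simulate_from_fit(fit, n_sim=3, seed=7)
        assert all(set(x.edges) == set(y.edges) for x, y in zip(a, b))

    def test_unconverged_refused(self):
        fit, _ = self._edges_fit()
        fit.converged = False
        with pytest.raises(SpecificationError):
            ergm.simulate_from_fit(fit, n_sim=1, seed=0)

    def test_attributes_copied(self):
        g = nx.gnp_random_graph(8, 0.5, seed=5)
        for n in g.nodes:
            g.nodes[n]["occupation"] = "nurse"
        fit = ergm.fit_ergm(g, ErgmSpec((Edges(),)))
        sim = ergm.simulate_from_fit(fit, n_sim=1, seed=0)[0]
        assert all(sim.nodes[n]["occupation"] == "nurse" for n in sim.nodes)


class TestGof:
    def test_triangle_esp(self):
        counts = ergm.esp_counts(nx.complete_graph(3))
        assert list(counts) == [0, 3]  # every edge has exactly 1 shared partner

    def test_degree_mass_at_zero_for_empty(self):
        g = nx.Graph()
        g.add_nodes_from(range(4))
        assert list(ergm.degree_counts(g)) == [4]

    def test_geodesic_sums_to_dyads(self):
        g = nx.gnp_random_graph(15, 0.2, seed=2)
        counts, unreachable = ergm.geodesic_counts(g)
        assert counts.sum() + unreachable == 15 * 14 // 2

    def test_counts_sum_invariants(self):
        g = nx.gnp_random_graph(20, 0.3, seed=6)
        assert ergm.degree_counts(g).sum() == g.number_of_nodes()
        assert ergm.esp_counts(g).sum() == g.number_of_edges()

    def test_gof_report_structure(self):
        g = nx.gnp_random_graph(20, 0.3, seed=9)
        fit = ergm.fit_ergm(g, ErgmSpec((Edges(),)))
        report = ergm.gof(fit, g, n_sim=20, seed=3)
        assert set(report.panels) == {"degree", "esp", "geodesic"}
        geo = report.panels["geodesic"]
        assert geo.bins[-1] == "unreachable"
        for p in report.panels.values():
            assert (p.sim_lo <= p.sim_hi).all()
            assert 0 <= p.fraction_inside <= 1


class TestGenerateErgmNetwork:
    def test_edges_zero_density_half(self):
        from psnet.synthetic import generate_ergm_network

        spec = ErgmSpec((Edges(),))
        total = 0
        for seed in range(40):
            g = generate_ergm_network(10, OCC3, 2, spec, [0.0], seed=seed)
            total += g.number_of_edges()
        n, p = 40 * 45, 0.5
        lo, hi = (n * p - 2.58 * math.sqrt(n * p * (1 - p)),
                  n * p + 2.58 * math.sqrt(n * p * (1 - p)))
        assert lo <= total <= hi

    def test_minus_thirty_empty(self):
        from psnet.synthetic import generate_ergm_network

        g = generate_ergm_network(30, OCC3, 2, ErgmSpec((Edges(),)), [-30.0], seed=1)
        assert g.number_of_edges() == 0

    def test_probabilities_match_estimation_code_path(self):
        from psnet.synthetic import generate_ergm_network

        spec = ErgmSpec((Edges(), NodeMatchUniform("occupation")))
        g = generate_ergm_network(40, OCC3, 3, spec, [-1.0, 0.5], seed=2)
        p, _, _ = ergm.dyad_probabilities(g, spec, [-1.0, 0.5])
        X, _, _, _, _ = ergm.change_statistics(g, spec)
        np.testing.assert_allclose(p, expit(X @ np.array([-1.0, 0.5])))

    def test_parameter_recovery_uniform_homophily(self):
        from psnet.synthetic import generate_ergm_network

        spec = ErgmSpec((Edges(), NodeMatchUniform("occupation")))
        g = generate_ergm_network(500, OCC3, 3, spec, [-2.0, 1.0], seed=6)
        fit = ergm.fit_ergm(g, spec)
        j = fit.coef_names.index("nodematch.occupation")
        assert abs(fit.theta[j] - 1.0) < 3 * fit.se[j]

    def test_bad_coefficient_length(self):
        from psnet.synthetic import generate_ergm_network

        with pytest.raises(SpecificationError):
            generate_ergm_network(10, OCC3, 2, ErgmSpec((Edges(),)), [0.0, 1.0], seed=0)
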