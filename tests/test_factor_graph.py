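import numpy as np
import pandas as pd
import pytest

from conftest import network_from_edges
from pathact.factor_graph import (
    InferenceOptions,
    build_factor_graph,
    compute_ipl,
    exact_posteriors,
    expected_state,
    fit_parameters_em,
    infer_cohort_ipls,
    infer_posteriors,
)
from pathact.pathway_io import Entity, PathwayNetwork


def single_protein_net(name="A"):
    return PathwayNetwork(entities={name: Entity(name, "protein")})


class TestExpectedState:
    @pytest.mark.parametrize(
        "states,signs,rule,expected",
        [
            ([1], [1], "vote", 1),
            ([1, 1], [1, -1], "vote", 0),
            ([1, -1], [1, 1], "min", -1),
            ([1, -1], [1, 1], "max", 1),
            ([-1], [-1], "vote", 1),
            ([0, 0], [1, 1], "vote", 0),
            ([1, 1, -1], [1, 1, 1], "vote", 1),
        ],
    )
    def test_combination_rules(self, states, signs, rule, expected):
        assert expected_state(states, signs, rule) == expected

    def test_empty_parents_rejected(self):
        with pytest.raises(ValueError):
            expected_state([], [], "vote")

    def test_vote_antisymmetric_min_max_swap(self, rng):
        for _ in range(50):
            k = int(rng.integers(1, 5))
            states = rng.choice([-1, 0, 1], k).tolist()
            signs = rng.choice([-1, 1], k).tolist()
            neg = [-s for s in states]
            assert expected_state(neg, signs, "vote") == -expected_state(
                states, signs, "vote"
            )
            assert expected_state(neg, signs, "min") == -expected_state(
                states, signs, "max"
            )


class TestBuildFactorGraph:
    def test_minimal_chain_layout(self):
        net = single_protein_net()
        fg = build_factor_graph(net, pd.Series({"A": 1.0}), pd.Series({"A": 1.0}))
        assert len(fg.variables) == 3
        kinds = {}
        for f in fg.factors:
            kinds[f.kind] = kinds.get(f.kind, 0) + 1
        assert kinds == {"observation": 2, "regulation": 2, "prior": 1}

    def test_complex_regulation_scope(self, complex_net):
        fg = build_factor_graph(complex_net, None, None)
        reg = [f for f in fg.factors if f.scope[0] == ("CX", "activity")]
        assert len(reg) == 1
        assert set(reg[0].scope[1:]) == {("A", "activity"), ("B", "activity")}
        assert reg[0].rule == "min"
        fam = [f for f in fg.factors if f.scope[0] == ("FM", "activity")][0]
        assert fam.rule == "max"

    def test_unknown_gene_observation_warns_and_counts(self):
        net = single_protein_net()
        with pytest.warns(UserWarning, match="ignored"):
            fg = build_factor_graph(net, pd.Series({"Z": 1.0}), None)
        assert fg.n_ignored_observations == 1
        assert len(fg.variables) == 1  # A.activity only, Z absent

    def test_missing_observations_attach_no_factor(self):
        net = single_protein_net()
        fg = build_factor_graph(
            net, pd.Series({"A": np.nan}), pd.Series({"A": 1.0})
        )
        obs = [f for f in fg.factors if f.kind == "observation"]
        assert len(obs) == 1 and obs[0].scope[0] == ("A", "rna")


class TestInference:
    def test_uniform_prior_single_variable(self):
        fg = build_factor_graph(single_protein_net(), None, None)
        post = infer_posteriors(fg)
        np.testing.assert_allclose(
            post.probs[("A", "activity")], [1 / 3] * 3, atol=1e-12
        )

    def test_posteriors_normalized(self, chain3):
        fg = build_factor_graph(
            chain3, pd.Series({"A": 1.0}), pd.Series({"A": 1.0, "B": -1.0})
        )
        post = infer_posteriors(fg)
        for p in post.probs.values():
            assert abs(p.sum() - 1.0) < 1e-9

    def test_two_variable_chain_matches_enumeration(self, chain3):
        # A activated through its omics; B's marginal from BP equals the
        # enumeration of the full joint state space
        fg = build_factor_graph(
            chain3, pd.Series({"A": 1.0}), pd.Series({"A": 1.0})
        )
        bp = infer_posteriors(fg)
        ex = exact_posteriors(fg)
        for v in fg.variables:
            np.testing.assert_allclose(bp.probs[v], ex.probs[v], atol=1e-6)

    def test_oracle_refuses_large_graphs(self):
        net = network_from_edges(
            [f"P{i}" for i in range(13)], []
        )
        fg = build_factor_graph(net, None, None)
        with pytest.raises(ValueError, match="refused"):
            exact_posteriors(fg, max_vars=12)

    def test_noiseless_chain_propagates_activation(self, chain3):
        opts = InferenceOptions(epsilon=1e-6, eta=1e-6)
        fg = build_factor_graph(
            chain3, pd.Series({"A": 1.0}), pd.Series({"A": 1.0}), opts
        )
        post = infer_posteriors(fg, opts)
        ipl = compute_ipl(post)
        assert (ipl[["A", "B", "C"]] > 0).all()
        assert post.probs[("C", "activity")][2] > 0.999

    def test_sign_symmetry_on_vote_fixture(self, chain3):
        cna = pd.Series({"A": 1.0, "B": -1.0})
        rna = pd.Series({"A": 1.0, "C": 0.0})
        up = compute_ipl(infer_posteriors(build_factor_graph(chain3, cna, rna)))
        down = compute_ipl(
            infer_posteriors(build_factor_graph(chain3, -cna, -rna))
        )
        np.testing.assert_allclose(up.values, -down.values, atol=1e-9)

    def test_ipl_values(self):
        from pathact.factor_graph import PosteriorTable

        post = PosteriorTable(
            probs={
                ("X", "activity"): np.array([0.09, 0.01, 0.9]),
                ("Y", "activity"): np.array([0.4, 0.2, 0.4]),
            }
        )
        ipl = compute_ipl(post)
        assert ipl["X"] == pytest.approx(1.0, abs=1e-12)
        assert ipl["Y"] == pytest.approx(0.0, abs=1e-12)


class TestOracleEquivalence:
    """BP equals brute-force enumeration on random acyclic fixtures."""

    @pytest.mark.parametrize("seed", range(12))
    def test_random_tree_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 5))  # observed proteins: 3 vars each
        proteins = [f"P{i}" for i in range(n)]
        edges = []
        for i in range(1, n):
            j = int(rng.integers(0, i))
            rel = rng.choice(["protein-activate", "protein-repress",
                              "transcript-activate", "transcript-repress"])
            edges.append((proteins[j], proteins[i], str(rel)))
        net = network_from_edges(proteins, edges)
        vals = rng.choice([-1.0, 0.0, 1.0, np.nan], size=(2, n))
        cna = pd.Series(vals[0], index=proteins)
        rna = pd.Series(vals[1], index=proteins)
        fg = build_factor_graph(net, cna, rna)
        assert len(fg.variables) <= 12  # 4 observed proteins x 3 layers
        bp = infer_posteriors(fg)
        ex = exact_posteriors(fg)
        for v in fg.variables:
            np.testing.assert_allclose(bp.probs[v], ex.probs[v], atol=1e-6)


class TestCohortBatching:
    def test_batched_equals_per_sample(self, complex_net, rng):
        genes = ["A", "B", "C"]
        samples = [f"s{j}" for j in range(5)]
        cna = pd.DataFrame(
            rng.choice([-1.0, 0.0, 1.0, np.nan], (3, 5)), index=genes, columns=samples
        )
        rna = pd.DataFrame(
            rng.choice([-1.0, 0.0, 1.0, np.nan], (3, 5)), index=genes, columns=samples
        )
        ipls, info = infer_cohort_ipls(complex_net, cna, rna)
        assert info["converged"]
        for s in samples:
            fg = build_factor_graph(complex_net, cna[s], rna[s], sample_id=s)
            solo = compute_ipl(infer_posteriors(fg))
            np.testing.assert_allclose(
                ipls[s].sort_index().values, solo.sort_index().values, atol=1e-7
            )


@pytest.fixture(scope="module")
def sampled_graphs():
    # forward-sample the generative model (independent of the BP path)
    rng = np.random.default_rng(7)
    return _sample_em_graphs(rng)


def _sample_em_graphs(rng):
    eps, eta = 0.05, 0.05
    states = [-1, 0, 1]

    def reg(parents, signs):
        exp = int(np.sign(sum(s * x for s, x in zip(signs, parents))))
        if rng.random() < 1 - eps:
            return exp
        return int(rng.choice([s for s in states if s != exp]))

    def noisy(h):
        if rng.random() < 1 - eta:
            return h
        return int(rng.choice([s for s in states if s != h]))

    net = network_from_edges(
        ["X", "Y"], [("X", "Y", "protein-activate")]
    )
    graphs = []
    for i in range(200):
        vals = {}
        for g in ("X", "Y"):
            vals[(g, "dna")] = int(rng.choice(states))
            vals[(g, "rna")] = reg([vals[(g, "dna")]], [1])
        vals[("X", "activity")] = reg([vals[("X", "rna")]], [1])
        vals[("Y", "activity")] = reg(
            [vals[("Y", "rna")], vals[("X", "activity")]], [1, 1]
        )
        cna = pd.Series({g: float(noisy(vals[(g, "dna")])) for g in ("X", "Y")})
        rna = pd.Series({g: float(noisy(vals[(g, "rna")])) for g in ("X", "Y")})
        graphs.append(build_factor_graph(net, cna, rna, sample_id=f"s{i}"))
    return graphs


class TestEM:
    def test_parameter_recovery_and_monotone_loglik(self, sampled_graphs):
        res = fit_parameters_em(
            sampled_graphs, InferenceOptions(epsilon=0.2, eta=0.2, em_max_iter=40)
        )
        assert abs(res.epsilon - 0.05) < 0.05
        assert abs(res.eta - 0.05) < 0.05
        diffs = np.diff(res.loglik_trace)
        assert (diffs >= -1e-12).all()

    def test_restart_at_optimum_stops_quickly(self, sampled_graphs):
        first = fit_parameters_em(
            sampled_graphs, InferenceOptions(epsilon=0.2, eta=0.2, em_max_iter=40)
        )
        again = fit_parameters_em(
            sampled_graphs,
            InferenceOptions(
                epsilon=first.epsilon, eta=first.eta, em_max_iter=40
            ),
        )
        assert again.n_iter <= 2

    def test_iteration_cap_respected(self, sampled_graphs):
        res = fit_parameters_em(
            sampled_graphs, InferenceOptions(epsilon=0.4, eta=0.4, em_max_iter=3)
        )
        assert res.n_iter <= 3 and res.hit_cap

    def test_no_observations_is_error(self):
        fg = build_factor_graph(single_protein_net(), None, None)
        with pytest.raises(ValueError, match="observation"):
            fit_parameters_em([fg])


class TestOptionsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"epsilon": 0.0},
            {"eta": 1.0},
            {"bp_tol": 0.0},
            {"max_sweeps": 0},
            {"damping": 1.0},
        ],
    )
    def test_invalid_options_rejected(self, kwargs):
        with pytest.raises(ValueError):
            InferenceOptions(**kwargs)
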