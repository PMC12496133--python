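import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import fisher_exact
from sklearn.metrics import adjusted_rand_score

from pathact.pathway_io import GeneSetCollection
from pathact.profiles import (
    GroupAssignment,
    benjamini_hochberg,
    build_profile_matrix,
    cluster_patients,
    fisher_overrepresentation_p,
    overrepresentation,
    overrepresentation_cohort,
    select_display_terms,
)


class TestFisher:
    def test_hypergeometric_example(self):
        # K=10 marked in N=100, draw n=20, observe k=5
        from scipy.stats import hypergeom

        p = fisher_overrepresentation_p(5, 10, 20, 100)
        assert p == pytest.approx(float(hypergeom.sf(4, 100, 10, 20)), abs=1e-15)

    def test_zero_overlap_is_one(self):
        assert fisher_overrepresentation_p(0, 10, 20, 100) == 1.0

    def test_matches_scipy_fisher_exhaustive_small(self):
        # independent oracle: scipy's conditional exact test, alternative
        # 'greater', over every consistent table with N <= 12
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(max(0, K + n - N), min(K, n) + 1):
                        table = [[k, K - k], [n - k, N - K - (n - k)]]
                        _, expected = fisher_exact(table, alternative="greater")
                        got = fisher_overrepresentation_p(k, K, n, N)
                        assert got == pytest.approx(expected, abs=1e-10)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_overrepresentation_p(5, 300, 20, 100)


class TestBenjaminiHochberg:
    def test_step_up_by_hand(self):
        adj = benjamini_hochberg(np.array([0.01, 0.02, 0.04]))
        np.testing.assert_allclose(adj, [0.03, 0.03, 0.04], atol=1e-12)

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=50)
    )
    @settings(max_examples=60, deadline=None)
    def test_adjusted_geq_raw_and_monotone(self, raw):
        raw = np.asarray(raw)
        adj = benjamini_hochberg(raw)
        assert (adj >= raw - 1e-15).all() and (adj <= 1 + 1e-15).all()
        order = np.argsort(raw, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestOverrepresentation:
    @pytest.fixture
    def sets(self):
        return GeneSetCollection(
            sets={
                "S_hit": frozenset({"A", "B", "C"}),
                "S_miss": frozenset({"D", "E"}),
                "S_out": frozenset({"zz"}),
            },
            descriptions={},
        )

    def test_single_patient_row(self, sets):
        states = pd.Series({"A": 1.0, "B": -1.0, "C": 0.0, "D": 0.0, "E": 0.0})
        df = overrepresentation(states, sets, universe={"A", "B", "C", "D", "E"})
        assert df.loc["S_hit", "k"] == 2
        assert df.loc["S_miss", "k"] == 0 and df.loc["S_miss", "raw_p"] == 1.0
        assert df.loc["S_out", "no_overlap"] and df.loc["S_out", "raw_p"] == 1.0
        assert (df["adj_p"] >= df["raw_p"] - 1e-15).all()

    def test_cohort_matches_single(self, sets):
        states = pd.DataFrame(
            {"p1": [1.0, -1.0, 0.0, 0.0, 0.0], "p2": [0.0, 0.0, 1.0, 1.0, 1.0]},
            index=["A", "B", "C", "D", "E"],
        )
        res = overrepresentation_cohort(states, sets, {"A", "B", "C", "D", "E"})
        for p in ("p1", "p2"):
            solo = overrepresentation(states[p], sets, {"A", "B", "C", "D", "E"})
            np.testing.assert_allclose(
                res.raw_p[p].values, solo["raw_p"].reindex(res.raw_p.index).values
            )

    def test_global_null_false_positive_rate(self, rng):
        # fair-coin states, random sets: adjusted P < .05 in <= 5% + MC slack
        universe = {f"g{i}" for i in range(60)}
        sets = GeneSetCollection(
            sets={
                f"S{j}": frozenset(
                    rng.choice(sorted(universe), size=10, replace=False)
                )
                for j in range(40)
            },
            descriptions={},
        )
        n_sig = 0
        n_tot = 0
        for _ in range(25):
            states = pd.Series(
                rng.choice([0.0, 1.0], size=60), index=sorted(universe)
            )
            df = overrepresentation(states, sets, universe)
            n_sig += int((df["adj_p"] < 0.05).sum())
            n_tot += len(df)
        assert n_sig / n_tot <= 0.05 + 0.02


class TestProfileMatrix:
    def make_result(self, adj):
        from pathact.profiles import EnrichmentResult

        adj = pd.DataFrame(adj)
        return EnrichmentResult(
            raw_p=adj.copy(), adj_p=adj, k=adj * 0, K=pd.Series(dtype=int),
            n=pd.Series(dtype=int), N=1,
        )

    def test_log_transform_and_cap(self):
        prof = build_profile_matrix(
            self.make_result({"p": [0.05, 1e-12, 1.0]}), cap=10.0
        )
        assert prof.iloc[0, 0] == pytest.approx(1.3010, abs=1e-4)
        assert prof.iloc[1, 0] == 10.0
        assert prof.iloc[2, 0] == 0.0

    def test_entries_in_range(self, rng):
        adj = pd.DataFrame(rng.random((20, 5)))
        prof = build_profile_matrix(self.make_result(adj), cap=8.0)
        assert ((prof >= 0) & (prof <= 8)).all().all()


class TestClusterPatients:
    def planted_profile(self, rng, n_per_block=10, sep=5.0):
        left = rng.normal(0, 0.3, (12, n_per_block))
        right = rng.normal(0, 0.3, (12, n_per_block))
        right[:4] += sep
        X = np.hstack([left, right])
        cols = [f"p{i}" for i in range(2 * n_per_block)]
        truth = [0] * n_per_block + [1] * n_per_block
        return pd.DataFrame(X, columns=cols), truth

    def test_separated_blocks_recovered(self, rng):
        profile, truth = self.planted_profile(rng)
        ga = cluster_patients(profile, k=2)
        assert adjusted_rand_score(truth, ga.labels.values) == 1.0

    def test_k_one_single_group(self, rng):
        profile, _ = self.planted_profile(rng)
        ga = cluster_patients(profile, k=1)
        assert set(ga.labels) == {1}

    def test_column_permutation_invariance(self, rng):
        profile, _ = self.planted_profile(rng)
        ga = cluster_patients(profile, k=2)
        perm = rng.permutation(profile.shape[1])
        ga2 = cluster_patients(profile.iloc[:, perm], k=2)
        joined = pd.concat(
            [ga.labels.rename("a"), ga2.labels.rename("b")], axis=1
        )
        assert adjusted_rand_score(joined["a"], joined["b"]) == 1.0

    def test_invalid_k_rejected(self, rng):
        profile, _ = self.planted_profile(rng)
        with pytest.raises(ValueError):
            cluster_patients(profile, k=0)
        with pytest.raises(ValueError):
            cluster_patients(profile, k=profile.shape[1] + 1)

    def test_consensus_mode_recovers_blocks(self, rng):
        profile, truth = self.planted_profile(rng)
        ga = cluster_patients(profile, k=2, seed=1, n_resample=20)
        assert adjusted_rand_score(truth, ga.labels.values) == 1.0


class TestSelectDisplayTerms:
    def make(self):
        adj = pd.DataFrame(
            {
                "p1": [0.01, 0.2], "p2": [0.01, 0.2], "p3": [0.01, 0.01],
                "p4": [0.2, 0.01], "p5": [0.01, 0.9],
            },
            index=["T1", "T2"],
        )
        groups = GroupAssignment(
            labels=pd.Series({"p1": 1, "p2": 1, "p3": 1, "p4": 1, "p5": 1, }), k=2
        )
        return adj, groups

    def test_fraction_threshold(self):
        adj, groups = self.make()
        sel = select_display_terms(adj, groups, q_threshold=0.05, frac_threshold=0.8)
        assert sel[1] == ["T1"]  # significant in 4/5 patients
        assert sel[2] == []  # empty group

    def test_lowering_fraction_is_monotone(self):
        adj, groups = self.make()
        strict = select_display_terms(adj, groups, frac_threshold=0.9)
        loose = select_display_terms(adj, groups, frac_threshold=0.4)
        assert set(strict[1]) <= set(loose[1])
        assert "T2" in loose[1]
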