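import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from conftest import network_from_edges
from pathact.discovery import (
    Submodule,
    find_submodules,
    kaplan_meier_coordinates,
    key_proteins,
    logrank_test,
    neighbor_state_table,
    stratify_by_activation,
    validate_submodule,
)


@pytest.fixture
def module_net():
    # 6-entity connected region: chain of 5 proteins + complex on (P1, P2),
    # plus a separate 4-protein region
    return network_from_edges(
        [f"P{i}" for i in range(1, 10)],
        [
            ("P1", "P2", "protein-activate"),
            ("P2", "P3", "protein-activate"),
            ("P3", "P4", "protein-activate"),
            ("P4", "P5", "protein-activate"),
            ("P1", "CX", "component"),
            ("P2", "CX", "component"),
            ("P6", "P7", "protein-activate"),
            ("P7", "P8", "protein-activate"),
            ("P8", "P9", "protein-activate"),
        ],
        complexes=["CX"],
    )


def states_frame(net, rows, patients):
    df = pd.DataFrame(0.0, index=sorted(net.entities), columns=patients)
    for entity, vals in rows.items():
        df.loc[entity] = vals
    return df


class TestFindSubmodules:
    def test_six_entity_region_found(self, module_net):
        pats = ["a", "b", "c"]
        rows = {e: [1.0, 1.0, 1.0] for e in ["P1", "P2", "P3", "P4", "P5", "CX"]}
        states = states_frame(module_net, rows, pats)
        subs = find_submodules(
            module_net, states, pats, observed_genes={"P1"}, min_size=5
        )
        assert len(subs) == 1
        assert subs[0].entities == frozenset({"P1", "P2", "P3", "P4", "P5", "CX"})
        validate_submodule(subs[0], module_net, min_size=5)

    def test_small_region_excluded(self, module_net):
        pats = ["a", "b"]
        rows = {e: [1.0, 1.0] for e in ["P6", "P7", "P8", "P9"]}  # size 4 < 5
        states = states_frame(module_net, rows, pats)
        assert (
            find_submodules(module_net, states, pats, observed_genes={"P6"}) == []
        )

    def test_region_without_observed_protein_excluded(self, module_net):
        pats = ["a"]
        rows = {e: [1.0] for e in ["P1", "P2", "P3", "P4", "P5", "CX"]}
        states = states_frame(module_net, rows, pats)
        assert find_submodules(module_net, states, pats, observed_genes=set()) == []

    def test_one_zero_patient_breaks_membership(self, module_net):
        pats = ["a", "b"]
        rows = {e: [1.0, 1.0] for e in ["P1", "P2", "P3", "P4", "P5", "CX"]}
        rows["P3"] = [1.0, 0.0]  # P3 normal in patient b
        states = states_frame(module_net, rows, pats)
        subs = find_submodules(
            module_net, states, pats, observed_genes={"P1", "P4"}, min_size=2
        )
        # P3 dropped: region splits into {P1,P2,CX} (+P4,P5 fragment)
        assert all("P3" not in s.entities for s in subs)

    def test_mixed_sign_entity_allowed_unless_strict(self, module_net):
        pats = ["a", "b"]
        rows = {e: [1.0, 1.0] for e in ["P1", "P2", "P3", "P4", "P5", "CX"]}
        rows["P3"] = [1.0, -1.0]
        states = states_frame(module_net, rows, pats)
        subs = find_submodules(
            module_net, states, pats, observed_genes={"P1"}, min_size=5
        )
        assert len(subs) == 1 and "P3" in subs[0].entities
        strict = find_submodules(
            module_net, states, pats, observed_genes={"P1"},
            min_size=5, require_constant_sign=True,
        )
        assert all("P3" not in s.entities for s in strict)

    def test_empty_group_rejected(self, module_net):
        states = states_frame(module_net, {}, ["a"])
        with pytest.raises(ValueError):
            find_submodules(module_net, states, [], observed_genes={"P1"})

    def test_maximality_adding_neighbor_violates(self, module_net):
        pats = ["a", "b"]
        rows = {e: [1.0, 1.0] for e in ["P1", "P2", "P3", "P4", "P5", "CX"]}
        states = states_frame(module_net, rows, pats)
        subs = find_submodules(
            module_net, states, pats, observed_genes={"P1"}, min_size=5
        )
        sub = subs[0]
        skel = module_net.skeleton()
        boundary = {
            n for e in sub.entities for n in skel.neighbors(e)
        } - set(sub.entities)
        for n in boundary:
            col = states.loc[n, pats]
            assert (col == 0).any() or col.isna().any()


class TestKeyProteins:
    def make_sub(self, states):
        df = pd.DataFrame(states).T
        return Submodule(
            entities=frozenset(df.index),
            group=1,
            states=df,
            proteins=tuple(p for p in df.index if p.startswith("P")),
            observed_proteins=("P1",),
        )

    def test_constant_direction_is_key(self):
        sub = self.make_sub({"P1": [1, 1, 1], "P2": [-1, -1, -1], "CX": [1, 1, 1]})
        keys = key_proteins(sub)
        assert ("P1", 1) in keys and ("P2", -1) in keys
        assert all(not name.startswith("CX") for name, _ in keys)

    def test_sign_flip_not_key(self):
        sub = self.make_sub({"P1": [1, -1, 1]})
        assert key_proteins(sub) == []


class TestStratifyByActivation:
    def make_ipls(self):
        return pd.DataFrame(
            {"p1": [0.5, 0.2], "p2": [0.5, 0.0], "p3": [-0.1, 0.4]},
            index=["A", "B"],
        )

    def test_all_positive_required(self):
        labels = stratify_by_activation(self.make_ipls(), ["A", "B"])
        assert labels.to_dict() == {
            "p1": "activated", "p2": "other", "p3": "other",
        }

    def test_missing_protein_named_in_error(self):
        with pytest.raises(ValueError, match="ZZ"):
            stratify_by_activation(self.make_ipls(), ["ZZ"])

    def test_empty_protein_list_rejected(self):
        with pytest.raises(ValueError):
            stratify_by_activation(self.make_ipls(), [])

    def test_labels_partition_patients(self):
        labels = stratify_by_activation(self.make_ipls(), ["A"])
        assert set(labels.index) == {"p1", "p2", "p3"}
        assert set(labels.unique()) <= {"activated", "other"}


class TestLogrank:
    def surv(self, times, events, strata):
        return pd.DataFrame({"time": times, "event": events, "stratum": strata})

    def test_identical_arms_give_zero(self):
        s = self.surv([3, 5, 8, 3, 5, 8], [1, 1, 0, 1, 1, 0], list("aaabbb"))
        stat, p = logrank_test(s)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_six_patient_fixture(self):
        # observed-minus-expected tabulation over event times gives
        # chi-square 0.073903 (frozen from the standard formula)
        s = self.surv([2, 4, 6, 1, 3, 5], [1, 1, 0, 1, 1, 0], list("aaabbb"))
        stat, p = logrank_test(s)
        assert stat == pytest.approx(0.0739030023094689, rel=1e-9)
        assert p == pytest.approx(float(chi2.sf(stat, 1)), rel=1e-12)

    def test_all_censored_flagged(self):
        s = self.surv([1, 2, 3, 4], [0, 0, 0, 0], list("aabb"))
        with pytest.warns(UserWarning, match="no events"):
            stat, p = logrank_test(s)
        assert (stat, p) == (0.0, 1.0)

    def test_single_stratum_rejected(self):
        with pytest.raises(ValueError):
            logrank_test(self.surv([1, 2], [1, 1], ["a", "a"]))

    def test_matches_permutation_null(self, rng):
        # Monte-Carlo P from label permutation within 3 SE of the chi2 P
        times = rng.exponential(10, 14)
        events = rng.random(14) < 0.8
        strata = np.array(["a"] * 7 + ["b"] * 7)
        s = self.surv(times, events.astype(int), strata)
        stat, p = logrank_test(s)
        B = 1500
        hits = 0
        for _ in range(B):
            perm = rng.permutation(strata)
            ps = self.surv(times, events.astype(int), perm)
            stat_b, _ = logrank_test(ps)
            hits += stat_b >= stat - 1e-12
        mc = hits / B
        se = np.sqrt(mc * (1 - mc) / B)
        assert abs(mc - p) < 3 * se + 0.02


class TestNeighborStateTable:
    def test_conflicting_omics_pattern(self, module_net):
        pats = ["t1"]
        states = states_frame(module_net, {"P1": [1.0], "P2": [1.0]}, pats)
        cna = pd.DataFrame({"t1": [-1.0]}, index=["P1"])
        rna = pd.DataFrame({"t1": [1.0]}, index=["P1"])
        table = neighbor_state_table("P1", module_net, states, cna, rna, pats)
        assert table.loc[("P1", "pathway"), "t1"] == 1.0
        assert table.loc[("P1", "CNA"), "t1"] == -1.0
        assert table.loc[("P1", "RNA"), "t1"] == 1.0
        # neighbors present: P2 (regulation) and CX (complex)
        entities = set(table.index.get_level_values("entity"))
        assert {"P1", "P2", "CX"} <= entities
        # unobserved complex has no omic rows
        assert ("CX", "CNA") not in table.index

    def test_isolated_protein_single_entity(self):
        net = network_from_edges(["X"], [])
        states = pd.DataFrame({"t": [0.0]}, index=["X"])
        table = neighbor_state_table("X", net, states, None, None, ["t"])
        assert list(table.index.get_level_values("entity")) == ["X"]

    def test_unknown_protein_rejected(self, module_net):
        with pytest.raises(ValueError):
            neighbor_state_table("nope", module_net, pd.DataFrame(), None, None)


class TestKaplanMeier:
    def test_curve_coordinates_start_at_one(self):
        s = pd.DataFrame(
            {"time": [1, 2, 3, 4], "event": [1, 0, 1, 1],
             "stratum": ["a", "a", "b", "b"]}
        )
        km = kaplan_meier_coordinates(s)
        for _, grp in km.groupby("stratum"):
            assert grp.iloc[0]["survival"] == 1.0
            assert (grp["survival"].diff().dropna() <= 1e-12).all()
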