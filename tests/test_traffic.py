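"""Traffic classification, Jaccard-Tanimoto statistics, switch analysis."""

import itertools
import math

import numpy as np
import pytest

from lipidtraffic.traffic import (
    CompartmentNetwork,
    PresenceMatrix,
    TrafficError,
    call_presence,
    classify_traffic,
    jaccard,
    jaccard_p,
    switch_analysis,
)

from conftest import analytical, feat, make_sheet


def brute_force_categories(pattern: set, network: CompartmentNetwork) -> set[str]:
    """Direct transcription of the four lipid-type definitions.

    Returns the category labels a lipid with this compartment pattern
    belongs to (B excludes A; lipids in >2 but not all compartments with no
    covered edge are 'other').
    """
    cats = set()
    everything = set(network.compartments)
    if pattern == everything:
        return {"A"}
    if len(pattern) == 1:
        return {f"U@{next(iter(pattern))}"}
    if len(pattern) == 2:
        a, b = sorted(pattern, key=network.compartments.index)
        if not network.is_adjacent(a, b):
            return {f"N2@{a}|{b}"}
    for x, y in network.edges:
        if x in pattern and y in pattern:
            k = network.edge_key(x, y)
            cats.add(f"B@{k[0]}-{k[1]}")
    if not cats and len(pattern) >= 3:
        cats.add("other")
    return cats


def categories_of(classification, lipid: str) -> set[str]:
    cats = {
        label
        for label, s in classification.category_sets().items()
        if lipid in s
    }
    if lipid in classification.other_set:
        cats.add("other")
    return cats


class TestNetwork:
    def test_invariants(self):
        with pytest.raises(TrafficError, match="self-loop"):
            CompartmentNetwork(("a", "b"), (("a", "a"),))
        with pytest.raises(TrafficError, match="unknown compartment"):
            CompartmentNetwork(("a", "b"), (("a", "c"),))
        with pytest.raises(TrafficError, match="at least 2"):
            CompartmentNetwork(("a",), ())

    def test_json_roundtrip(self, path_network, tmp_path):
        p = tmp_path / "net.json"
        path_network.to_json(p)
        assert CompartmentNetwork.from_json(p) == path_network

    def test_nonadjacent_pairs(self, path_network):
        assert path_network.nonadjacent_pairs() == [("L", "B")]


class TestClassify:
    @pytest.mark.parametrize(
        "pattern, expected",
        [
            ({"L", "S", "B"}, {"A"}),
            ({"L", "B"}, {"N2@L|B"}),
            ({"L", "S"}, {"B@L-S"}),
            ({"S"}, {"U@S"}),
        ],
    )
    def test_path_network_examples(self, path_network, pattern, expected):
        presence = PresenceMatrix("F", {"x": set(pattern)})
        cls = classify_traffic(presence, path_network)
        assert categories_of(cls, "x") == expected

    def test_exactly_one_membership_category(self, path_network):
        """Every present lipid lands in exactly one of A/U/N2/B-attached/other."""
        for bits in itertools.product([0, 1], repeat=3):
            pattern = {c for c, b in zip(path_network.compartments, bits) if b}
            if not pattern:
                continue
            presence = PresenceMatrix("F", {"x": pattern})
            cls = classify_traffic(presence, path_network)
            cats = categories_of(cls, "x")
            kinds = {c.split("@")[0] for c in cats}
            assert len(kinds) == 1
            assert cls.detected() == {"x"}

    def test_agrees_with_brute_force_on_a_cycle_with_chord(self):
        net = CompartmentNetwork.from_edges(
            "abcde",
            [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"), ("e", "a"), ("a", "c")],
        )
        for bits in itertools.product([0, 1], repeat=5):
            pattern = {c for c, b in zip(net.compartments, bits) if b}
            if not pattern:
                continue
            cls = classify_traffic(PresenceMatrix("F", {"x": pattern}), net)
            assert categories_of(cls, "x") == brute_force_categories(pattern, net)

    def test_b_inclusive_flag_restores_a_on_edges(self, path_network):
        presence = PresenceMatrix("F", {"x": {"L", "S", "B"}})
        cls = classify_traffic(presence, path_network, b_excludes_a=False)
        assert "x" in cls.a_set
        assert all("x" in s for s in cls.b_sets.values())

    def test_unknown_compartment_rejected(self, path_network):
        with pytest.raises(TrafficError, match="unknown compartments"):
            classify_traffic(PresenceMatrix("F", {"x": {"Z"}}), path_network)


def _presence_sheet(counts_by_comp, n_per_group=3, phenotype="F"):
    """One feature; counts_by_comp: {comp: n_samples_with_signal}."""
    samples, row = [], []
    for comp, n_present in counts_by_comp.items():
        for i in range(n_per_group):
            samples.append(
                analytical(f"{phenotype}_{comp}_{i}", compartment=comp, phenotype=phenotype)
            )
            row.append(10.0 if i < n_present else 0.0)
    return make_sheet([feat("f1", annotation="TG(50:1)", lipid_class="TG")], samples, [row])


class TestPresence:
    def test_two_of_three_is_present(self):
        sheet = _presence_sheet({"L": 2})
        pm = call_presence(sheet, "F")
        assert pm.presence["TG(50:1)"] == {"L"}

    def test_zero_detected_is_absent(self):
        sheet = _presence_sheet({"L": 0})
        pm = call_presence(sheet, "F")
        assert pm.presence["TG(50:1)"] == set()

    def test_exact_boundary_inclusive(self):
        # 33 of 50 samples = 0.66 exactly: >= is inclusive
        sheet = _presence_sheet({"L": 33}, n_per_group=50)
        pm = call_presence(sheet, "F", min_frac=0.66)
        assert pm.presence["TG(50:1)"] == {"L"}
        sheet32 = _presence_sheet({"L": 32}, n_per_group=50)
        assert call_presence(sheet32, "F").presence["TG(50:1)"] == set()

    def test_unknown_phenotype_errors(self):
        sheet = _presence_sheet({"L": 2})
        with pytest.raises(TrafficError, match="phenotype"):
            call_presence(sheet, "nope")

    def test_monotone_in_intensity(self):
        sheet = _presence_sheet({"L": 2})
        pm_before = call_presence(sheet, "F")
        bumped = make_sheet(
            sheet.features, sheet.samples, np.maximum(sheet.intensities, 1.0)
        )
        pm_after = call_presence(bumped, "F")
        assert pm_before.presence["TG(50:1)"] <= pm_after.presence["TG(50:1)"]


class TestJaccard:
    def test_examples(self):
        assert jaccard({1, 2, 3}, {2, 3, 4}) == 0.5
        assert jaccard({1}, {1}) == 1.0
        assert jaccard({1}, {2}) == 0.0
        assert jaccard(set(), set()) == 1.0  # empty comparison convention

    def test_symmetric_bounded_and_discriminative(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            s1 = set(rng.integers(0, 30, size=rng.integers(0, 15)).tolist())
            s2 = set(rng.integers(0, 30, size=rng.integers(0, 15)).tolist())
            j = jaccard(s1, s2)
            assert j == jaccard(s2, s1)
            assert 0.0 <= j <= 1.0
            if s1 or s2:
                assert (j == 1.0) == (s1 == s2)


class TestJaccardP:
    def test_identical_sets_in_large_universe_significant(self):
        s = set(range(10))
        p = jaccard_p(s, s, set(range(1000)), n_perm=10_000, seed=0, method="mc")
        assert p <= 0.001

    def test_two_singletons_two_element_universe(self):
        # exact enumeration over the 4 equally likely outcomes: all equally
        # extreme around the null mean 0.5, so p = 1
        p = jaccard_p({"a"}, {"b"}, {"a", "b"}, method="exact")
        assert p == pytest.approx(1.0)

    def test_exact_matches_enumeration_on_tiny_universe(self):
        universe = set(range(6))
        s1, s2 = {0, 1, 2}, {2, 3}
        # brute-force enumeration over all subset pairs of the same sizes
        js = []
        for c1 in itertools.combinations(universe, len(s1)):
            for c2 in itertools.combinations(universe, len(s2)):
                js.append(jaccard(set(c1), set(c2)))
        js = np.array(js)
        mean = js.mean()
        obs = jaccard(s1, s2)
        expected = np.mean(np.abs(js - mean) >= abs(obs - mean) - 1e-12)
        assert jaccard_p(s1, s2, universe, method="exact") == pytest.approx(expected)

    def test_mc_close_to_exact(self):
        universe = set(range(100))
        s1, s2 = set(range(20)), set(range(10, 40))
        exact = jaccard_p(s1, s2, universe, method="exact")
        mc = jaccard_p(s1, s2, universe, method="mc", n_perm=20_000, seed=1)
        assert mc == pytest.approx(exact, abs=0.02)

    def test_universe_must_contain_sets(self):
        with pytest.raises(TrafficError, match="subsets"):
            jaccard_p({1, 99}, {1}, {1, 2, 3})

    def test_invariant_under_relabelling(self):
        uni = set(range(50))
        s1, s2 = set(range(8)), set(range(5, 15))
        p1 = jaccard_p(s1, s2, uni, method="exact")
        relabel = {i: f"x{i}" for i in uni}
        p2 = jaccard_p(
            {relabel[i] for i in s1},
            {relabel[i] for i in s2},
            set(relabel.values()),
            method="exact",
        )
        assert p1 == p2

    def test_conservative_p_is_valid(self):
        """Tie-inclusive permutation p satisfies P(p <= a) <= a under the null."""
        rng = np.random.default_rng(7)
        uni = list(range(150))
        pvals = []
        for _ in range(400):
            n1, n2 = rng.integers(5, 40, 2)
            s1 = set(rng.choice(uni, n1, replace=False).tolist())
            s2 = set(rng.choice(uni, n2, replace=False).tolist())
            pvals.append(
                jaccard_p(s1, s2, uni, n_perm=499, seed=int(rng.integers(2**31)), method="mc")
            )
        pvals = np.array(pvals)
        for alpha in (0.05, 0.1, 0.25, 0.5):
            # binomial slack at 400 replicates
            assert (pvals <= alpha).mean() <= alpha + 3 * math.sqrt(alpha * (1 - alpha) / 400)


class TestSwitchAnalysis:
    def _classifications(self, path_network, sets_1, sets_2):
        cls = []
        for sets in (sets_1, sets_2):
            presence = {}
            for lipid, pattern in sets.items():
                presence[lipid] = set(pattern)
            pm = PresenceMatrix("F" if sets is sets_1 else "H", presence)
            cls.append(classify_traffic(pm, path_network, "TG"))
        return cls

    def test_a_category_counts_and_j(self, path_network):
        all3 = {"L", "S", "B"}
        c1, c2 = self._classifications(
            path_network,
            {x: all3 for x in "abc"},
            {x: all3 for x in "bcd"},
        )
        comps = {c.category: c for c in switch_analysis(c1, c2, n_perm=100, seed=0)}
        a = comps["A"]
        assert a.counts == (1, 2, 1)
        assert a.jtc == 0.5

    def test_identical_classifications_give_j_one(self, path_network):
        sets = {"a": {"L", "S", "B"}, "b": {"L"}, "c": {"L", "B"}}
        c1, c2 = self._classifications(path_network, sets, dict(sets))
        for comp in switch_analysis(c1, c2, n_perm=100, seed=0):
            if not comp.empty:
                assert comp.jtc == 1.0

    def test_empty_categories_flagged(self, path_network):
        c1, c2 = self._classifications(
            path_network, {"a": {"L", "S", "B"}}, {"b": {"L", "S", "B"}}
        )
        comps = {c.category: c for c in switch_analysis(c1, c2, n_perm=100, seed=0)}
        assert comps["U@S"].empty and comps["U@S"].p_value is None
        assert not comps["A"].empty

    def test_network_mismatch_errors(self, path_network):
        other = CompartmentNetwork.from_edges(["L", "S", "B"], [("L", "S")])
        c1 = classify_traffic(PresenceMatrix("F", {"a": {"L"}}), path_network, "TG")
        c2 = classify_traffic(PresenceMatrix("H", {"a": {"L"}}), other, "TG")
        with pytest.raises(TrafficError, match="network"):
            switch_analysis(c1, c2)

    def test_deterministic_given_seed(self, path_network):
        sets1 = {x: {"L", "S", "B"} for x in "abcdef"}
        sets2 = {x: {"L", "S", "B"} for x in "defghi"}
        c1, c2 = self._classifications(path_network, sets1, sets2)
        r1 = [c.to_dict() for c in switch_analysis(c1, c2, n_perm=500, seed=42)]
        r2 = [c.to_dict() for c in switch_analysis(c1, c2, n_perm=500, seed=42)]
        assert r1 == r2
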