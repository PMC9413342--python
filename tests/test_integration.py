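"""Gene-metabolite integration: targets, combined PCIT, interaction model."""

import numpy as np
import pandas as pd
import pytest

from omicnet import (
    TargetSet,
    ValidationError,
    combined_pcit_network,
    intlim_fit,
    intlim_scan,
    overlap_pairs,
    select_gm_pairs,
    simulate_interaction_pair,
    spearman_group_difference,
    unique_targets,
    variance_filter,
)
from omicnet.matrix import FeatureMatrix
from omicnet.pcit import CorrelationNetwork, pcit_edges_reference, correlation_matrix
from omicnet.matrix import stack


def _fm(values, kind, n_ref, prefix):
    values = np.asarray(values, dtype=float)
    samples = [f"s{i}" for i in range(values.shape[1])]
    phen = pd.Series(
        ["NP"] * n_ref + ["AI-P"] * (values.shape[1] - n_ref), index=samples
    )
    return FeatureMatrix(
        pd.DataFrame(values, index=[f"{prefix}{i}" for i in range(len(values))],
                     columns=samples),
        kind,
        phen,
    )


class TestUniqueTargets:
    def test_set_algebra(self):
        a = TargetSet("AI-P", hubs={"x", "y"}, differentially_connected={"z"})
        b = TargetSet("NP", hubs={"y"}, differentially_connected={"z", "w"})
        ex_a, ex_b, shared = unique_targets(a, b)
        assert ex_a == {"x"} and ex_b == {"w"} and shared == {"y", "z"}

    def test_identical_inputs_have_empty_exclusives(self):
        a = TargetSet("A", hubs={"x"}, differentially_connected={"y"})
        b = TargetSet("B", hubs={"x"}, differentially_connected={"y"})
        ex_a, ex_b, shared = unique_targets(a, b)
        assert not ex_a and not ex_b and shared == {"x", "y"}

    def test_counting_identity_on_random_sets(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = TargetSet("A", hubs=set(rng.choice(50, 15).astype(str)))
            b = TargetSet("B", hubs=set(rng.choice(50, 15).astype(str)))
            ex_a, ex_b, shared = unique_targets(a, b)
            assert len(a.members) + len(b.members) == len(ex_a) + len(ex_b) + 2 * len(shared)

    def test_provenance_labels(self):
        t = TargetSet("A", hubs={"h", "b"}, differentially_connected={"d", "b"})
        prov = t.provenance().set_index("feature_id")["provenance"]
        assert prov["h"] == "hub" and prov["d"] == "differentially_connected"
        assert prov["b"] == "both"


class TestVarianceFilter:
    def test_zero_fraction_is_identity(self, matrix_factory):
        m = matrix_factory(np.random.default_rng(0).normal(size=(10, 8)), "gene", 4, 4)
        assert variance_filter(m, 0.0).feature_ids == m.feature_ids

    def test_five_percent_of_hundred_drops_five(self, matrix_factory):
        rng = np.random.default_rng(1)
        m = matrix_factory(rng.normal(0, 1, size=(100, 10)), "gene", 5, 5)
        assert variance_filter(m, 0.05).n_features == 95

    def test_constant_features_always_fall_in_the_dropped_set(self, matrix_factory):
        rng = np.random.default_rng(2)
        vals = rng.normal(0, 1, size=(20, 10))
        vals[7] = 3.14
        m = matrix_factory(vals, "gene", 5, 5)
        assert "f7" not in variance_filter(m, 0.05).feature_ids


class TestIntlimFit:
    def test_matches_statsmodels_ols(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        g, m, phen = simulate_interaction_pair(25, (1.0, 0.5, -0.3, 1.2), 0.7, rng)
        fit = intlim_fit(g, m, phen)
        p = (phen != "NP").astype(float)
        X = sm.add_constant(np.column_stack([g, p, g * p]))
        ref = sm.OLS(m, X).fit()
        assert fit["b1"] == pytest.approx(ref.params[0], abs=1e-10)
        assert fit["b2"] == pytest.approx(ref.params[1], abs=1e-10)
        assert fit["b3"] == pytest.approx(ref.params[2], abs=1e-10)
        assert fit["b4"] == pytest.approx(ref.params[3], abs=1e-10)
        assert fit["p_interaction"] == pytest.approx(ref.pvalues[3], abs=1e-10)

    def test_swapping_phenotype_levels_negates_b4_keeps_p(self):
        rng = np.random.default_rng(4)
        g, m, phen = simulate_interaction_pair(20, (0.0, 0.5, 0.2, 1.0), 0.5, rng)
        fwd = intlim_fit(g, m, phen, reference="NP")
        rev = intlim_fit(g, m, phen, reference="AI-P")
        assert rev["b4"] == pytest.approx(-fwd["b4"], abs=1e-10)
        assert rev["p_interaction"] == pytest.approx(fwd["p_interaction"], abs=1e-10)

    def test_singular_design_is_rejected(self):
        g = np.array([1.0] * 6 + [0, 1, 2, 0, 1, 2])  # constant within NP
        m = np.random.default_rng(5).normal(size=12)
        phen = np.array(["NP"] * 6 + ["AI-P"] * 6)
        with pytest.raises(ValidationError, match="singular"):
            intlim_fit(g, m, phen)

    def test_b4_recovery_at_moderate_n(self):
        """b4 = 1.5, noise 0.5, n = 50/group: near-unbiased with high power."""
        estimates, hits = [], 0
        for seed in range(60):
            rng = np.random.default_rng(seed)
            g, m, phen = simulate_interaction_pair(50, (1.0, 0.5, 0.0, 1.5), 0.5, rng)
            fit = intlim_fit(g, m, phen)
            estimates.append(fit["b4"])
            hits += fit["p_interaction"] <= 0.05
        assert abs(np.mean(estimates) - 1.5) < 0.1
        assert hits / 60 >= 0.8


class TestIntlimScan:
    def test_batched_scan_equals_per_pair_fit(self):
        rng = np.random.default_rng(6)
        genes = _fm(rng.normal(size=(4, 24)), "gene", 12, "g")
        metabs = _fm(rng.normal(size=(3, 24)), "metabolite", 12, "m")
        scan = intlim_scan(genes, metabs).set_index(["gene_id", "metabolite_id"])
        for gid in genes.feature_ids:
            for mid in metabs.feature_ids:
                fit = intlim_fit(
                    genes.values.loc[gid].values,
                    metabs.values.loc[mid].values,
                    genes.phenotype.values,
                )
                row = scan.loc[(gid, mid)]
                assert row["b4"] == pytest.approx(fit["b4"], abs=1e-10)
                assert row["p_interaction"] == pytest.approx(
                    fit["p_interaction"], abs=1e-10
                )

    def test_singular_gene_is_skipped_with_reason(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=(2, 24))
        vals[0, :12] = 2.0  # constant within NP
        genes = _fm(vals, "gene", 12, "g")
        metabs = _fm(rng.normal(size=(1, 24)), "metabolite", 12, "m")
        scan = intlim_scan(genes, metabs)
        skipped = scan[scan["gene_id"] == "g0"]
        assert (skipped["skip_reason"] == "singular_design").all()
        assert not skipped["significant"].any()


class TestSpearmanDifference:
    def test_same_monotone_relation_gives_zero(self):
        g = np.array([1, 2, 3, 4, 1, 2, 3, 4], dtype=float)
        m = g**3
        phen = np.array(["NP"] * 4 + ["AI-P"] * 4)
        diff, absdiff = spearman_group_difference(g, m, phen)
        assert diff == pytest.approx(0.0)

    def test_opposite_perfect_relations_give_two(self):
        g = np.array([1, 2, 3, 4, 1, 2, 3, 4], dtype=float)
        m = np.array([4, 3, 2, 1, 1, 2, 3, 4], dtype=float)  # decreasing in NP
        phen = np.array(["NP"] * 4 + ["AI-P"] * 4)
        diff, absdiff = spearman_group_difference(g, m, phen)
        assert diff == pytest.approx(2.0)  # r_AIP - r_NP = 1 - (-1)
        assert absdiff == pytest.approx(2.0)

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(8)
        g = rng.normal(size=20)
        m = g + rng.normal(0, 0.5, 20)
        phen = np.array(["NP"] * 10 + ["AI-P"] * 10)
        base = spearman_group_difference(g, m, phen)[0]
        assert spearman_group_difference(np.exp(g), m, phen)[0] == pytest.approx(base)
        assert spearman_group_difference(g, m**3, phen)[0] == pytest.approx(base)


class TestCombinedNetworkAndSelection:
    def test_exact_linear_metabolite_yields_cross_edge(self):
        rng = np.random.default_rng(9)
        gvals = rng.normal(size=(5, 20))
        genes = _fm(gvals, "gene", 10, "g")
        metabs = _fm(np.vstack([2 * gvals[0] + 1, rng.normal(size=20)]),
                     "metabolite", 10, "m")
        net = combined_pcit_network(genes, metabs, "NP")
        kinds = net.nodes
        assert set(kinds.unique()) == {"gene", "metabolite"}
        sig = net.edges[net.edges["significant"]]
        assert (("g0", "m0") in set(zip(sig["source"], sig["target"]))) or (
            ("m0", "g0") in set(zip(sig["source"], sig["target"]))
        )

    def test_independent_layers_have_no_strong_cross_edges(self):
        rng = np.random.default_rng(10)
        genes = _fm(rng.normal(size=(10, 1000)), "gene", 500, "g")
        metabs = _fm(rng.normal(size=(5, 1000)), "metabolite", 500, "m")
        net = combined_pcit_network(genes, metabs, "NP")
        strong = net.edges[net.edges["significant"] & (net.edges["r"].abs() >= 0.75)]
        assert len(strong) == 0

    def test_cross_edges_match_stacked_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        genes = _fm(rng.normal(size=(15, 14)), "gene", 7, "g")
        metabs = _fm(rng.normal(size=(5, 14)), "metabolite", 7, "m")
        net = combined_pcit_network(genes, metabs, "NP", cross_layer_only=False)
        combined = stack(genes, metabs)
        corr = correlation_matrix(combined, "NP")
        ref = pcit_edges_reference(corr.values)
        ids = list(corr.index)
        expect = {
            tuple(sorted((ids[i], ids[j])))
            for i in range(len(ids))
            for j in range(i + 1, len(ids))
            if ref[i, j]
        }
        sig = net.edges[net.edges["significant"]]
        got = {tuple(sorted(p)) for p in zip(sig["source"], sig["target"])}
        assert got == expect

    def test_selection_thresholds_and_anchoring(self):
        edges = pd.DataFrame(
            [
                ("g1", "m1", 0.8, True),
                ("g2", "m2", 0.74, True),
                ("g3", "m3", 0.9, True),
            ],
            columns=["source", "target", "r", "significant"],
        )
        nodes = pd.Series(
            {"g1": "gene", "g2": "gene", "g3": "gene",
             "m1": "metabolite", "m2": "metabolite", "m3": "metabolite"}
        )
        net = CorrelationNetwork(edges, nodes, group="AI-P", layer="combined")
        pairs = select_gm_pairs(net, {"g1", "g2"}, r_min=0.75)
        assert list(pairs["gene_id"]) == ["g1"]  # g2 below r_min, g3 unanchored
        assert (pairs["evidence"] == "pcit").all()

    def test_selection_monotone_in_r_min(self):
        rng = np.random.default_rng(12)
        edges = pd.DataFrame(
            [(f"g{i}", f"m{i}", rng.uniform(-1, 1), True) for i in range(30)],
            columns=["source", "target", "r", "significant"],
        )
        nodes = pd.Series(
            {**{f"g{i}": "gene" for i in range(30)},
             **{f"m{i}": "metabolite" for i in range(30)}}
        )
        net = CorrelationNetwork(edges, nodes, group="NP", layer="combined")
        targets = {f"g{i}" for i in range(30)}
        prev = None
        for r_min in (0.0, 0.5, 0.75, 0.9):
            got = set(map(tuple, select_gm_pairs(net, targets, r_min)[
                ["gene_id", "metabolite_id"]].values))
            if prev is not None:
                assert got <= prev
            prev = got

    def test_empty_target_set_warns(self):
        net = CorrelationNetwork(
            pd.DataFrame([("g1", "m1", 0.9, True)],
                         columns=["source", "target", "r", "significant"]),
            pd.Series({"g1": "gene", "m1": "metabolite"}),
            group="NP",
            layer="combined",
        )
        with pytest.warns(UserWarning, match="empty target"):
            assert len(select_gm_pairs(net, set())) == 0


class TestOverlap:
    def _pairs(self, keys, evidence="pcit"):
        return pd.DataFrame(
            {
                "gene_id": [k[0] for k in keys],
                "metabolite_id": [k[1] for k in keys],
                "r": 0.8,
                "group": "AI-P",
                "evidence": evidence,
            }
        )

    def _intlim(self, keys, significant=True):
        return pd.DataFrame(
            {
                "gene_id": [k[0] for k in keys],
                "metabolite_id": [k[1] for k in keys],
                "b4": 1.0,
                "p_interaction": 0.01,
                "significant": significant,
                "evidence": "intlim",
            }
        )

    def test_disjoint_lists_give_empty_overlap(self):
        out = overlap_pairs(self._pairs([("g1", "m1")]), self._intlim([("g2", "m2")]))
        assert len(out) == 0

    def test_identical_lists_all_evidence_both(self):
        keys = [("g1", "m1"), ("g2", "m2")]
        out = overlap_pairs(self._pairs(keys), self._intlim(keys))
        assert len(out) == 2
        assert (out["evidence"] == "both").all()
        assert (out["sign_call"] == "positive").all()

    def test_only_significant_intlim_rows_count(self):
        keys = [("g1", "m1")]
        out = overlap_pairs(self._pairs(keys), self._intlim(keys, significant=False))
        assert len(out) == 0

    def test_overlap_is_subset_of_both_inputs(self):
        rng = np.random.default_rng(13)
        all_keys = [(f"g{i}", f"m{j}") for i in range(6) for j in range(6)]
        a = [all_keys[i] for i in rng.choice(36, 15, replace=False)]
        b = [all_keys[i] for i in rng.choice(36, 15, replace=False)]
        out = overlap_pairs(self._pairs(a), self._intlim(b))
        got = set(zip(out["gene_id"], out["metabolite_id"]))
        assert got == set(a) & set(b)
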