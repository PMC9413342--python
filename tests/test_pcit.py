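"""PCIT network inference: correlation, partial correlation, elimination rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omicnet import (
    ValidationError,
    correlation_matrix,
    filter_network,
    partial_correlation,
    pcit_edges,
    pcit_edges_reference,
    pcit_network,
)
from _oracles import pearson_by_definition


class TestCorrelationMatrix:
    def test_diagonal_and_exact_linearity(self, matrix_factory):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 8)
        vals = np.vstack([x, 2 * x + 3, -x, rng.normal(0, 1, 8)])
        m = matrix_factory(np.hstack([vals, vals]), "gene", 8, 8)
        corr = correlation_matrix(m, "NP")
        assert np.allclose(np.diag(corr), 1.0)
        assert corr.loc["f0", "f1"] == pytest.approx(1.0)
        assert corr.loc["f0", "f2"] == pytest.approx(-1.0)
        pd.testing.assert_frame_equal(corr, corr.T)

    def test_matches_textbook_formula(self, matrix_factory):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 1, size=(10, 6))
        m = matrix_factory(np.hstack([vals, vals]), "gene", 6, 6)
        corr = correlation_matrix(m, "NP")
        for i in range(10):
            for j in range(i + 1, 10):
                expect = pearson_by_definition(vals[i], vals[j])
                assert corr.iloc[i, j] == pytest.approx(expect, abs=1e-12)

    def test_too_few_samples_and_zero_variance(self, matrix_factory):
        rng = np.random.default_rng(2)
        vals = rng.normal(0, 1, size=(4, 9))
        vals[2] = 5.0  # flat feature
        samples = [f"s{i}" for i in range(9)]
        phen = pd.Series(["NP"] * 2 + ["AI-P"] * 7, index=samples)
        from omicnet.matrix import FeatureMatrix

        m = FeatureMatrix(
            pd.DataFrame(vals, index=[f"f{i}" for i in range(4)], columns=samples),
            "gene",
            phen,
        )
        with pytest.raises(ValidationError, match="NP"):
            correlation_matrix(m, "NP")
        with pytest.warns(UserWarning, match="zero-variance"):
            corr = correlation_matrix(m, "AI-P")
        assert "f2" not in corr.index


class TestPartialCorrelation:
    def test_independence_limit_returns_direct(self):
        assert partial_correlation(0.7, 0.0, 0.0) == pytest.approx(0.7)

    def test_closed_form_half(self):
        assert partial_correlation(0.5, 0.5, 0.5) == pytest.approx(1.0 / 3.0)

    def test_explained_away_is_zero(self):
        assert partial_correlation(0.4 * 0.6, 0.4, 0.6) == pytest.approx(0.0)


class TestPCITRule:
    def test_mutually_uncorrelated_features_have_no_edges(self):
        R = np.eye(3)
        assert pcit_edges(R).sum() == 0

    def test_weak_transitive_chain_edge_is_eliminated(self):
        """x-y-z chain with r_xy = r_yz = 0.5 and r_xz = 0.25 = r_xy * r_yz:
        the partial r_xz.y is 0, the tolerance ~0.60, and 0.25 < 0.60 * 0.5,
        so the transitive edge is cut while the chain links survive."""
        R = np.array([[1.0, 0.5, 0.25], [0.5, 1.0, 0.5], [0.25, 0.5, 1.0]])
        keep = pcit_edges(R)
        assert not keep[0, 2] and not keep[2, 0]
        assert keep[0, 1] and keep[1, 2]
        ref = pcit_edges_reference(R)
        assert (keep == ref).all()

    def test_strong_transitive_edge_survives_the_tolerance(self):
        """With r_xy = r_yz = 0.9 the tolerance averages ~0.50, which can
        never exceed r_xz / r_xy = 0.9: a strong transitive edge is retained.
        The elimination rule only removes edges clearly weaker than the
        indirect path allows."""
        R = np.array([[1.0, 0.9, 0.81], [0.9, 1.0, 0.9], [0.81, 0.9, 1.0]])
        keep = pcit_edges(R)
        assert keep[0, 2]
        assert (keep == pcit_edges_reference(R)).all()

    @pytest.mark.parametrize("seed", range(12))
    def test_vectorized_equals_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 21))
        x = rng.standard_normal((n, int(rng.integers(4, 12))))
        if seed % 3 == 0 and n >= 3:
            x[1] = 2 * x[0] + 1  # exact collinearity
        R = np.corrcoef(x)
        assert (pcit_edges(R) == pcit_edges_reference(R)).all()

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        R = np.corrcoef(rng.standard_normal((12, 8)))
        perm = rng.permutation(12)
        a = pcit_edges(R)[np.ix_(perm, perm)]
        b = pcit_edges(R[np.ix_(perm, perm)])
        assert (a == b).all()

    def test_fewer_than_three_features_warns_and_keeps_nonzero(self):
        R = np.array([[1.0, 0.4], [0.4, 1.0]])
        with pytest.warns(UserWarning, match="fewer than 3"):
            keep = pcit_edges(R)
        assert keep[0, 1]

    def test_better_than_marginal_threshold_on_sparse_ggm(self):
        """On data from a sparse Gaussian graphical model with moderate
        partial correlations, PCIT's edge set has a higher mean F1 against
        the true graph than keeping the same number of top-|r| edges: the
        eliminated edges are mostly transitive fill-in."""
        n = 30

        def instance(seed):
            rng = np.random.default_rng(seed)
            P = np.eye(n)
            edges = set()
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.15:
                        P[i, j] = P[j, i] = rng.uniform(0.2, 0.4) * rng.choice([-1, 1])
                        edges.add((i, j))
            ev = np.linalg.eigvalsh(P).min()
            if ev < 0.1:
                P += np.eye(n) * (0.1 - ev)
            cov = np.linalg.inv(P)
            d = np.sqrt(np.diag(cov))
            return cov / np.outer(d, d), edges

        def f1(pred, truth):
            tp = len(pred & truth)
            if not pred or not truth:
                return 0.0
            p, r = tp / len(pred), tp / len(truth)
            return 0.0 if p + r == 0 else 2 * p * r / (p + r)

        iu, ju = np.triu_indices(n, 1)
        pcit_f1, thresh_f1 = [], []
        for seed in range(20):
            cov, truth = instance(seed)
            rng = np.random.default_rng(100 + seed)
            X = rng.multivariate_normal(np.zeros(n), cov, size=200).T
            R = np.corrcoef(X)
            keep = pcit_edges(R)
            kept = {(i, j) for i, j in zip(iu, ju) if keep[i, j]}
            order = np.argsort(-np.abs(R[iu, ju]))[: len(kept)]
            top = {(iu[o], ju[o]) for o in order}
            pcit_f1.append(f1(kept, truth))
            thresh_f1.append(f1(top, truth))
        assert np.mean(pcit_f1) > np.mean(thresh_f1)


class TestFilterNetwork:
    def _net(self, rows):
        edges = pd.DataFrame(rows, columns=["source", "target", "r", "significant"])
        nodes = pd.Series(
            "gene", index=sorted(set(edges["source"]) | set(edges["target"]))
        )
        from omicnet.pcit import CorrelationNetwork

        return CorrelationNetwork(edges, nodes, group="NP", layer="gene")

    def test_thresholds_and_de_anchoring(self):
        net = self._net(
            [
                ("a", "b", 0.995, True),   # DE-anchored, passes gene cutoff
                ("a", "c", 0.95, True),    # below gene cutoff
                ("d", "e", 0.999, True),   # no DE endpoint
                ("a", "f", 0.995, False),  # not PCIT-significant
            ]
        )
        gene = filter_network(net, {"a"}, r_min=0.99)
        assert list(zip(gene.edges["source"], gene.edges["target"])) == [("a", "b")]
        metab = filter_network(net, {"a"}, r_min=0.9)
        assert set(zip(metab.edges["source"], metab.edges["target"])) == {
            ("a", "b"),
            ("a", "c"),
        }

    def test_monotone_in_r_min(self):
        rng = np.random.default_rng(8)
        rows = [
            (f"n{i}", f"n{j}", rng.uniform(-1, 1), True)
            for i in range(10)
            for j in range(i + 1, 10)
        ]
        net = self._net(rows)
        de = {f"n{i}" for i in range(5)}
        prev = None
        for r_min in (0.0, 0.3, 0.6, 0.9):
            kept = set(
                zip(
                    filter_network(net, de, r_min).edges["source"],
                    filter_network(net, de, r_min).edges["target"],
                )
            )
            if prev is not None:
                assert kept <= prev
            prev = kept

    def test_empty_de_set_is_an_error_unless_disabled(self):
        net = self._net([("a", "b", 0.999, True)])
        with pytest.raises(ValidationError, match="de_features"):
            filter_network(net, set(), r_min=0.9)
        out = filter_network(net, None, r_min=0.9, require_de=False)
        assert out.n_edges == 1


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_pcit_oracle_equivalence_property(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 16))
    R = np.corrcoef(rng.standard_normal((n, int(rng.integers(4, 10)))))
    assert (pcit_edges(R) == pcit_edges_reference(R)).all()


def test_pcit_network_edge_table_is_consistent():
    rng = np.random.default_rng(9)
    vals = rng.standard_normal((8, 10))
    corr = pd.DataFrame(
        np.corrcoef(vals),
        index=[f"f{i}" for i in range(8)],
        columns=[f"f{i}" for i in range(8)],
    )
    net = pcit_network(corr, kinds="gene", group="NP", layer="gene")
    assert net.n_edges == 8 * 7 // 2
    sig = pcit_edges(corr.values)
    assert int(net.edges["significant"].sum()) == int(sig.sum() // 2)
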