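"""Gene-metabolite integration.

Two complementary routes identify phenotype-relevant gene-metabolite pairs:

1. *Correlation route*: a combined PCIT network over stacked gene and
   metabolite layers per group; cross-layer edges with |r| >= 0.75 anchored
   on a group-exclusive target (hub or differentially connected feature).
2. *Interaction-model route*: per candidate pair, the ordinary least squares
   fit of

       m = b1 + b2*g + b3*p + b4*(g:p) + e

   where m is log metabolite abundance, g the log2 gene expression, p the
   0/1 phenotype (0 = reference group). A two-sided t-test on the
   interaction coefficient b4 (n - 4 residual df) flags pairs whose
   gene-metabolite slope differs by phenotype. The within-group Spearman
   correlation difference (r_other - r_ref) is reported alongside.

The overlap of the two routes is the high-confidence pair list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import FeatureMatrix, ValidationError, stack
from .pcit import CorrelationNetwork, correlation_matrix, filter_network, pcit_network

__all__ = [
    "TargetSet",
    "unique_targets",
    "combined_pcit_network",
    "select_gm_pairs",
    "variance_filter",
    "intlim_fit",
    "intlim_scan",
    "spearman_group_difference",
    "overlap_pairs",
]


@dataclass
class TargetSet:
    """Hub plus differentially connected features for one phenotype group."""

    group: str
    hubs: set[str] = field(default_factory=set)
    differentially_connected: set[str] = field(default_factory=set)

    @property
    def members(self) -> set[str]:
        return self.hubs | self.differentially_connected

    def provenance(self) -> pd.DataFrame:
        rows = []
        for m in sorted(self.members):
            src = (
                "both"
                if m in self.hubs and m in self.differentially_connected
                else ("hub" if m in self.hubs else "differentially_connected")
            )
            rows.append((m, src))
        return pd.DataFrame(rows, columns=["feature_id", "provenance"])


def unique_targets(
    targets_a: TargetSet, targets_b: TargetSet
) -> tuple[set[str], set[str], set[str]]:
    """(A-exclusive, B-exclusive, shared) target features between two groups."""
    a, b = targets_a.members, targets_b.members
    return a - b, b - a, a & b


def combined_pcit_network(
    genes: FeatureMatrix,
    metabs: FeatureMatrix,
    group: str,
    cross_layer_only: bool = True,
) -> CorrelationNetwork:
    """PCIT on the stacked gene + metabolite layers for one group.

    Inputs must already be on their analysis scales (log2(CPM+1) genes,
    natural-log metabolites). Returns only gene-metabolite (cross-layer)
    edges by default.
    """
    combined = stack(genes, metabs)
    corr = correlation_matrix(combined, group)
    net = pcit_network(
        corr, kinds=combined.kind, group=group, layer="combined"
    )
    if not cross_layer_only:
        return net
    kind = net.nodes
    e = net.edges
    cross = kind.loc[e["source"].values].values != kind.loc[e["target"].values].values
    return CorrelationNetwork(
        e[cross].reset_index(drop=True), net.nodes, group=group, layer="combined"
    )


def select_gm_pairs(
    cross_edges: CorrelationNetwork,
    targets: set[str],
    r_min: float = 0.75,
) -> pd.DataFrame:
    """Cross-layer edges with |r| >= r_min anchored on a target feature.

    ``targets`` is the group's exclusive target set. Returns a table with
    columns gene_id, metabolite_id, r, group, evidence (= "pcit").
    """
    if not targets:
        warnings.warn("empty target set: no pairs selected", stacklevel=2)
        return pd.DataFrame(
            columns=["gene_id", "metabolite_id", "r", "group", "evidence"]
        )
    e = cross_edges.edges
    kind = cross_edges.nodes
    mask = (
        e["significant"]
        & (e["r"].abs() >= r_min)
        & (e["source"].isin(targets) | e["target"].isin(targets))
    )
    kept = e[mask]
    src_is_gene = kind.loc[kept["source"].values].values == "gene"
    genes = np.where(src_is_gene, kept["source"], kept["target"])
    metabs = np.where(src_is_gene, kept["target"], kept["source"])
    out = pd.DataFrame(
        {
            "gene_id": genes,
            "metabolite_id": metabs,
            "r": kept["r"].values,
            "group": cross_edges.group,
            "evidence": "pcit",
        }
    )
    return out.sort_values(["gene_id", "metabolite_id"]).reset_index(drop=True)


def variance_filter(
    matrix: FeatureMatrix, drop_fraction: float = 0.05
) -> FeatureMatrix:
    """Drop the lowest ``drop_fraction`` quantile of per-feature variance.

    With no ties, exactly floor(n * drop_fraction) features are dropped; ties
    at the cut are retained.
    """
    if not 0 <= drop_fraction < 1:
        raise ValidationError("drop_fraction must be in [0, 1)")
    if drop_fraction == 0 or matrix.n_features == 0:
        return matrix
    var = matrix.values.var(axis=1, ddof=1)
    k = int(np.floor(matrix.n_features * drop_fraction))
    if k == 0:
        return matrix
    threshold = np.sort(var.values)[k]
    keep = [f for f in matrix.feature_ids if var[f] >= threshold]
    return matrix.subset_features(keep)


def _design(g: np.ndarray, p: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(g), g, p, g * p])


def intlim_fit(
    gene: np.ndarray,
    metab: np.ndarray,
    phenotype: np.ndarray | pd.Series,
    reference: str = "NP",
) -> dict[str, float]:
    """OLS fit of m = b1 + b2*g + b3*p + b4*(g:p) + e for one pair.

    Phenotype is coded 0 for the reference level, 1 otherwise. Returns the
    four coefficients, the standard error of b4, and the two-sided p-value
    for b4 on n - 4 residual degrees of freedom. Raises on singular designs
    (e.g. a gene constant within a phenotype level).
    """
    g = np.asarray(gene, dtype=float)
    m = np.asarray(metab, dtype=float)
    p = (np.asarray(phenotype) != reference).astype(float)
    n = len(g)
    if n < 8 or min((p == 0).sum(), (p == 1).sum()) < 3:
        raise ValidationError("need >= 3 samples per phenotype level (n >= 8 total)")
    X = _design(g, p)
    XtX = X.T @ X
    if np.linalg.cond(XtX) > 1e12:
        raise ValidationError("singular design (constant gene within a level?)")
    beta = np.linalg.solve(XtX, X.T @ m)
    resid = m - X @ beta
    df = n - 4
    s2 = float(resid @ resid) / df
    cov = s2 * np.linalg.inv(XtX)
    se4 = float(np.sqrt(cov[3, 3]))
    t4 = beta[3] / se4 if se4 > 0 else np.inf * np.sign(beta[3])
    p4 = 2.0 * stats.t.sf(abs(t4), df)
    return {
        "b1": float(beta[0]),
        "b2": float(beta[1]),
        "b3": float(beta[2]),
        "b4": float(beta[3]),
        "se_b4": se4,
        "t_b4": float(t4),
        "p_interaction": float(p4),
        "df": df,
    }


def intlim_scan(
    genes: FeatureMatrix,
    metabs: FeatureMatrix,
    gene_ids: list[str] | None = None,
    metab_ids: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Interaction-model scan over the gene x metabolite candidate grid.

    For each gene the design matrix is shared across metabolites, so all
    metabolite fits for that gene are solved in one batched least-squares
    step. Singular designs are skipped with a reason column. Adds the
    within-group Spearman difference per pair and a BH column.
    """
    gene_ids = list(gene_ids if gene_ids is not None else genes.feature_ids)
    metab_ids = list(metab_ids if metab_ids is not None else metabs.feature_ids)
    samples = genes.sample_ids
    if set(samples) != set(metabs.sample_ids):
        raise ValidationError("gene and metabolite matrices must share samples")
    M = metabs.values[samples].loc[metab_ids].values  # metab x sample
    phen = genes.phenotype.loc[samples]
    p = (phen != genes.reference).astype(float).values
    ref_idx = p == 0
    oth_idx = p == 1
    n = len(samples)
    df = n - 4

    # Spearman: rank once per group
    def group_ranks(values: np.ndarray, idx: np.ndarray) -> np.ndarray:
        return np.apply_along_axis(stats.rankdata, 1, values[:, idx])

    Mr_ref = group_ranks(M, ref_idx)
    Mr_oth = group_ranks(M, oth_idx)

    rows = []
    for gid in gene_ids:
        g = genes.values.loc[gid, samples].values.astype(float)
        X = _design(g, p)
        XtX = X.T @ X
        if np.linalg.cond(XtX) > 1e12:
            for mid in metab_ids:
                rows.append((gid, mid, *[np.nan] * 8, "singular_design"))
            continue
        XtX_inv = np.linalg.inv(XtX)
        B = XtX_inv @ (X.T @ M.T)  # 4 x n_metab
        resid = M.T - X @ B
        s2 = (resid**2).sum(axis=0) / df
        se4 = np.sqrt(s2 * XtX_inv[3, 3])
        with np.errstate(divide="ignore", invalid="ignore"):
            t4 = B[3] / se4
        p4 = 2.0 * stats.t.sf(np.abs(t4), df)
        p4 = np.where(np.isfinite(p4), p4, 1.0)

        gr_ref = stats.rankdata(g[ref_idx])
        gr_oth = stats.rankdata(g[oth_idx])
        r_ref = _rowcorr(Mr_ref, gr_ref)
        r_oth = _rowcorr(Mr_oth, gr_oth)
        for j, mid in enumerate(metab_ids):
            rows.append(
                (
                    gid,
                    mid,
                    B[0, j],
                    B[1, j],
                    B[2, j],
                    B[3, j],
                    p4[j],
                    r_oth[j],
                    r_ref[j],
                    r_oth[j] - r_ref[j],
                    "",
                )
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "metabolite_id",
            "b1",
            "b2",
            "b3",
            "b4",
            "p_interaction",
            "spearman_other",
            "spearman_ref",
            "spearman_diff",
            "skip_reason",
        ],
    )
    ok = out["skip_reason"] == ""
    out["significant"] = ok & (out["p_interaction"] <= alpha)
    out["evidence"] = "intlim"
    return out


def _rowcorr(rows: np.ndarray, vec: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of ``rows`` with ``vec``."""
    rc = rows - rows.mean(axis=1, keepdims=True)
    vc = vec - vec.mean()
    denom = np.sqrt((rc**2).sum(axis=1) * (vc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (rc @ vc) / denom
    return out


def spearman_group_difference(
    gene: np.ndarray,
    metab: np.ndarray,
    phenotype: np.ndarray | pd.Series,
    reference: str = "NP",
) -> tuple[float, float]:
    """Within-group Spearman correlations; returns (r_other - r_ref, |diff|).

    The non-reference group corresponds to the pregnant (AI-P) level in the
    study design, so the signed value is r_AIP - r_NP.
    """
    phen = np.asarray(phenotype)
    out = {}
    for level, mask in ((reference, phen == reference), ("other", phen != reference)):
        g, m = np.asarray(gene)[mask], np.asarray(metab)[mask]
        if len(g) < 3:
            raise ValidationError("need >= 3 samples per level")
        if len(np.unique(g)) < 2 or len(np.unique(m)) < 2:
            raise ValidationError(f"constant vector in level {level!r}")
        out[level] = stats.spearmanr(g, m).statistic
    diff = out["other"] - out[reference]
    return float(diff), float(abs(diff))


def overlap_pairs(
    pcit_pairs: pd.DataFrame, intlim_pairs: pd.DataFrame
) -> pd.DataFrame:
    """Pairs present in both routes; evidence = "both".

    ``intlim_pairs`` is restricted to its significant rows. Per-group sign is
    annotated from the PCIT correlation (positive/negative).
    """
    if "significant" in intlim_pairs.columns:
        intlim_pairs = intlim_pairs[intlim_pairs["significant"]]
    keys = ["gene_id", "metabolite_id"]
    merged = pcit_pairs.merge(
        intlim_pairs, on=keys, how="inner", suffixes=("_pcit", "_intlim")
    )
    if merged.empty:
        cols = list(pcit_pairs.columns) + ["sign_call", "evidence"]
        return pd.DataFrame(columns=[c for c in cols if c != "evidence"] + ["evidence"])
    merged["sign_call"] = np.where(merged["r"] >= 0, "positive", "negative")
    merged["evidence"] = "both"
    return merged.reset_index(drop=True)
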