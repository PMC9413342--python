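"""Partial correlation and information theory (PCIT) network inference.

PCIT decides, for every pair of features, whether their marginal correlation
is better explained through some third feature. For each trio (x, y, z) the
three first-order partial correlations are computed and an information-
theoretic local tolerance

    eps = 1/3 * (r_xy.z / r_xy + r_xz.y / r_xz + r_yz.x / r_yz)

is formed from the partial/direct ratios. The edge (x, y) is *eliminated* if
for some conditioning feature z

    |r_xy| < |eps * r_xz|  and  |r_xy| < |eps * r_yz|

i.e. the direct association is weaker than both indirect paths allow once the
tolerance is accounted for. Edges surviving every trio are flagged
significant.

Two implementations are provided: :func:`pcit_edges` (vectorized over (x, y)
panels for each conditioning feature z, the one to use) and
:func:`pcit_edges_reference` (a readable naive triple loop kept as the
reference for validation). Both apply identical guards:

* ratio terms whose direct correlation has |r| < 1e-12 are excluded from the
  tolerance average; if all three are degenerate the trio is skipped;
* trios where a conditioning correlation has |r| = 1 (partial correlation
  undefined) are skipped;
* elimination uses strict "<"; ties retain the edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .matrix import FeatureMatrix, ValidationError

__all__ = [
    "CorrelationNetwork",
    "correlation_matrix",
    "partial_correlation",
    "pcit_edges",
    "pcit_edges_reference",
    "pcit_network",
    "filter_network",
]

_EPS_DEGENERATE = 1e-12
_ONE_GUARD = 1.0 - 1e-12


@dataclass
class CorrelationNetwork:
    """Weighted undirected edge list for one phenotype group and layer.

    ``edges`` has columns source, target, r, significant with source < target
    lexicographically (each unordered pair at most once, no self edges).
    ``nodes`` maps node ID -> feature kind for every feature the network was
    computed over (including currently edge-less ones).
    """

    edges: pd.DataFrame
    nodes: pd.Series
    group: str = ""
    layer: str = "gene"

    def __post_init__(self) -> None:
        e = self.edges
        if len(e):
            if (e["source"] == e["target"]).any():
                raise ValidationError("self-edges are not allowed")
            keys = [tuple(sorted(p)) for p in zip(e["source"], e["target"])]
            if len(set(keys)) != len(keys):
                raise ValidationError("duplicate undirected edges")
            if (e["r"].abs() > 1 + 1e-9).any():
                raise ValidationError("|r| > 1 in edge list")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def significant(self) -> "CorrelationNetwork":
        return CorrelationNetwork(
            self.edges[self.edges["significant"]].reset_index(drop=True),
            self.nodes,
            self.group,
            self.layer,
        )

    def graph(self, significant_only: bool = True):
        """As a networkx Graph (edge attribute ``r``)."""
        import networkx as nx

        e = self.edges[self.edges["significant"]] if significant_only else self.edges
        g = nx.Graph()
        g.add_nodes_from(
            self.edges["source"].tolist() + self.edges["target"].tolist()
        )
        g.add_weighted_edges_from(
            zip(e["source"], e["target"], e["r"]), weight="r"
        )
        return g

    def connected_nodes(self) -> set[str]:
        e = self.edges[self.edges["significant"]]
        return set(e["source"]) | set(e["target"])

    def write_tsv(self, path: str | Path) -> None:
        self.edges.to_csv(path, sep="\t", index=False, float_format="%.10g")

    def write_sif(self, path: str | Path, relation: str = "co") -> None:
        e = self.edges[self.edges["significant"]]
        with Path(path).open("w", encoding="utf-8") as fh:
            for s, t in zip(e["source"], e["target"]):
                fh.write(f"{s}\t{relation}\t{t}\n")


def correlation_matrix(
    matrix: FeatureMatrix, group: str, method: str = "pearson"
) -> pd.DataFrame:
    """Correlation between features across one group's samples.

    Zero-variance features are dropped with a warning. Requires >= 3 samples.
    """
    samples = matrix.samples_in(group)
    if len(samples) < 3:
        raise ValidationError(
            f"group {group!r} has {len(samples)} samples; >= 3 required"
        )
    vals = matrix.values[samples]
    sd = vals.std(axis=1, ddof=1)
    flat = list(sd.index[sd == 0])
    if flat:
        warnings.warn(
            f"dropping {len(flat)} zero-variance features in group {group!r}",
            stacklevel=2,
        )
        vals = vals.drop(index=flat)
    if method == "spearman":
        vals = vals.rank(axis=1)
    elif method != "pearson":
        raise ValidationError(f"unknown correlation method {method!r}")
    x = vals.values
    x = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt((x * x).sum(axis=1))
    corr = (x @ x.T) / np.outer(norms, norms)
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    return pd.DataFrame(corr, index=vals.index, columns=vals.index)


def partial_correlation(r_xy, r_xz, r_yz):
    """First-order partial correlation r_xy.z; broadcasts over arrays.

    Undefined when |r_xz| = 1 or |r_yz| = 1 (the caller skips such trios).
    """
    r_xy, r_xz, r_yz = np.asarray(r_xy), np.asarray(r_xz), np.asarray(r_yz)
    denom = np.sqrt((1.0 - r_xz**2) * (1.0 - r_yz**2))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (r_xy - r_xz * r_yz) / denom
    return out if out.shape else float(out)


def pcit_edges(corr: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Boolean matrix of PCIT-significant edges (vectorized implementation).

    For each conditioning feature z the elimination test is evaluated for all
    (x, y) pairs at once. Edges with r exactly 0 are never significant.
    Complexity O(n^3) time, O(n^2) memory.
    """
    R = np.asarray(corr, dtype=float)
    n = R.shape[0]
    if R.shape != (n, n):
        raise ValidationError("correlation matrix must be square")
    offdiag = ~np.eye(n, dtype=bool)
    if n < 3:
        warnings.warn("fewer than 3 features: all nonzero edges kept", stacklevel=2)
        return (R != 0) & offdiag

    keep = np.ones((n, n), dtype=bool)
    absR = np.abs(R)
    Rsq = R**2
    for z in range(n):
        rz = R[:, z]  # r_xz for all x
        rz_sq = rz**2
        valid_z = np.abs(rz) < _ONE_GUARD  # partials conditioning on x or y need |r.z|<1

        # r_xy.z
        with np.errstate(divide="ignore", invalid="ignore"):
            p_xy = (R - np.outer(rz, rz)) / np.sqrt(
                np.outer(1.0 - rz_sq, 1.0 - rz_sq)
            )
            # r_xz.y = (r_xz - r_xy r_yz) / sqrt((1-r_xy^2)(1-r_yz^2))
            p_xz = (rz[:, None] - R * rz[None, :]) / np.sqrt(
                (1.0 - Rsq) * (1.0 - rz_sq)[None, :]
            )
            # r_yz.x = (r_yz - r_xy r_xz) / sqrt((1-r_xy^2)(1-r_xz^2))
            p_yz = (rz[None, :] - R * rz[:, None]) / np.sqrt(
                (1.0 - Rsq) * (1.0 - rz_sq)[:, None]
            )
            t_xy = p_xy / R
            t_xz = p_xz / rz[:, None]
            t_yz = p_yz / rz[None, :]

        v_xy = absR >= _EPS_DEGENERATE
        v_xz = (np.abs(rz) >= _EPS_DEGENERATE)[:, None] & np.ones((1, n), dtype=bool)
        v_yz = v_xz.T
        with np.errstate(invalid="ignore"):
            num = (
                np.where(v_xy, np.nan_to_num(t_xy, nan=0.0, posinf=0.0, neginf=0.0), 0.0)
                + np.where(v_xz, np.nan_to_num(t_xz, nan=0.0, posinf=0.0, neginf=0.0), 0.0)
                + np.where(v_yz, np.nan_to_num(t_yz, nan=0.0, posinf=0.0, neginf=0.0), 0.0)
            )
            cnt = v_xy.astype(int) + v_xz.astype(int) + v_yz.astype(int)
            eps = num / cnt  # NaN where cnt == 0 -> trio skipped
            elim = (absR < np.abs(eps * rz[:, None])) & (absR < np.abs(eps * rz[None, :]))
        # trio validity: z distinct from x and y; partials defined (|r_xz|,|r_yz| < 1
        # and |r_xy| < 1 for the two partials conditioning on x or y)
        trio_ok = np.outer(valid_z, valid_z) & (absR < _ONE_GUARD)
        trio_ok[z, :] = False
        trio_ok[:, z] = False
        elim &= trio_ok & np.isfinite(eps)
        keep &= ~elim
    return keep & (R != 0) & offdiag


def pcit_edges_reference(corr: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Naive triple-loop PCIT, kept as the readable reference implementation."""
    R = np.asarray(corr, dtype=float)
    n = R.shape[0]
    offdiag = ~np.eye(n, dtype=bool)
    if n < 3:
        return (R != 0) & offdiag
    keep = np.ones((n, n), dtype=bool)
    for x in range(n):
        for y in range(x + 1, n):
            r_xy = R[x, y]
            for z in range(n):
                if z == x or z == y:
                    continue
                r_xz, r_yz = R[x, z], R[y, z]
                if (
                    abs(r_xz) >= _ONE_GUARD
                    or abs(r_yz) >= _ONE_GUARD
                    or abs(r_xy) >= _ONE_GUARD
                ):
                    continue  # a partial correlation is undefined
                p_xy = partial_correlation(r_xy, r_xz, r_yz)
                p_xz = partial_correlation(r_xz, r_xy, r_yz)
                p_yz = partial_correlation(r_yz, r_xy, r_xz)
                terms = []
                if abs(r_xy) >= _EPS_DEGENERATE:
                    terms.append(p_xy / r_xy)
                if abs(r_xz) >= _EPS_DEGENERATE:
                    terms.append(p_xz / r_xz)
                if abs(r_yz) >= _EPS_DEGENERATE:
                    terms.append(p_yz / r_yz)
                if not terms:
                    continue
                eps = sum(terms) / len(terms)
                if abs(r_xy) < abs(eps * r_xz) and abs(r_xy) < abs(eps * r_yz):
                    keep[x, y] = keep[y, x] = False
                    break
    return keep & (R != 0) & offdiag


def pcit_network(
    corr: pd.DataFrame,
    kinds: pd.Series | str = "gene",
    group: str = "",
    layer: str = "gene",
) -> CorrelationNetwork:
    """Run PCIT on a correlation matrix and package the result.

    The edge list contains every off-diagonal pair with nonzero correlation
    flagged by whether it survived PCIT elimination.
    """
    sig = pcit_edges(corr)
    ids = np.asarray(corr.index)
    iu, ju = np.triu_indices(len(ids), k=1)
    r = corr.values[iu, ju]
    nonzero = r != 0
    edges = pd.DataFrame(
        {
            "source": ids[iu[nonzero]],
            "target": ids[ju[nonzero]],
            "r": r[nonzero],
            "significant": sig[iu[nonzero], ju[nonzero]],
        }
    )
    if isinstance(kinds, str):
        nodes = pd.Series(kinds, index=corr.index, dtype=object)
    else:
        nodes = kinds.reindex(corr.index)
    return CorrelationNetwork(edges, nodes, group=group, layer=layer)


def filter_network(
    net: CorrelationNetwork,
    de_features: Iterable[str] | None,
    r_min: float,
    require_de: bool = True,
) -> CorrelationNetwork:
    """Keep PCIT-significant edges with |r| >= r_min anchored on a DE feature.

    An edge is retained if it is flagged significant, |r| >= ``r_min`` and at
    least one endpoint is in ``de_features``. Nodes with no surviving edge are
    dropped from the node table. Set ``require_de=False`` to skip the
    anchoring rule (then ``de_features`` may be None).
    """
    e = net.edges
    mask = e["significant"] & (e["r"].abs() >= r_min)
    if require_de:
        de = set(de_features or ())
        if not de:
            raise ValidationError(
                "de_features is empty; pass require_de=False to disable anchoring"
            )
        mask &= e["source"].isin(de) | e["target"].isin(de)
    kept = e[mask].reset_index(drop=True)
    node_ids = sorted(set(kept["source"]) | set(kept["target"]))
    return CorrelationNetwork(
        kept, net.nodes.reindex(node_ids), group=net.group, layer=net.layer
    )
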