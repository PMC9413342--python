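"""Network topology: degree, betweenness, hubs, the union reference network
and the differential-connectivity (DK) statistic.

Betweenness is Brandes' exact algorithm on the unweighted graph (via
networkx), unnormalized by default so values are counts of shortest-path
fractions, matching common NetworkAnalyzer output; a normalization option
divides by (N-1)(N-2)/2.

Differential connectivity compares per-node degree between the two group
networks over the union node set: DK_i = K_ref(i) - K_other(i) (reference
defaults to NP), standardized to z = (DK - mean) / sd across nodes. Nodes at
|z| >= z_crit (default 1.96, the two-sided 5% normal cutoff) are called
"gain" (more connected in the reference network) or "loss".
"""

from __future__ import annotations

import warnings
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .matrix import ValidationError
from .pcit import CorrelationNetwork

__all__ = [
    "topology_table",
    "node_degrees",
    "betweenness",
    "call_hubs",
    "union_reference_network",
    "differential_connectivity",
]


def node_degrees(net: CorrelationNetwork) -> pd.Series:
    g = net.graph()
    return pd.Series(dict(g.degree()), dtype=int).reindex(sorted(g.nodes()))


def betweenness(net: CorrelationNetwork, normalized: bool = False) -> pd.Series:
    g = net.graph()
    bc = nx.betweenness_centrality(g, normalized=normalized)
    return pd.Series(bc, dtype=float).reindex(sorted(g.nodes()))


def topology_table(net: CorrelationNetwork, normalized: bool = False) -> pd.DataFrame:
    """Per-node degree and betweenness for one group's network."""
    deg = node_degrees(net)
    bc = betweenness(net, normalized=normalized)
    return pd.DataFrame(
        {"node_id": deg.index, "degree": deg.values, "betweenness": bc.values}
    ).reset_index(drop=True)


def call_hubs(
    topo: pd.DataFrame,
    min_degree: int = 1,
    min_betweenness: float = 0.0,
    mode: str = "practical",
    top_k: int | None = None,
) -> set[str]:
    """Hub nodes by degree and betweenness thresholds.

    ``mode="paper"`` uses degree >= min_degree and betweenness >=
    min_betweenness (with the published defaults this admits every
    non-isolated node); ``mode="practical"`` (default) requires betweenness
    strictly greater than ``min_betweenness``, i.e. the node must lie on some
    shortest path. ``top_k`` optionally keeps only the k highest-degree hubs
    (ties broken by betweenness then ID, deterministic).
    """
    if mode == "paper":
        mask = (topo["degree"] >= min_degree) & (topo["betweenness"] >= min_betweenness)
    elif mode == "practical":
        mask = (topo["degree"] >= min_degree) & (topo["betweenness"] > min_betweenness)
    else:
        raise ValidationError(f"unknown hub mode {mode!r}")
    hubs = topo[mask]
    if top_k is not None:
        hubs = hubs.sort_values(
            ["degree", "betweenness", "node_id"], ascending=[False, False, True]
        ).head(top_k)
    return set(hubs["node_id"])


def union_reference_network(
    netA: CorrelationNetwork, netB: CorrelationNetwork
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Central reference (union) network annotated with membership.

    Returns (nodes, edges): nodes with columns node_id, membership; edges with
    source, target, membership; membership in {A-only, B-only, shared} where A
    is the first input. Only significant edges participate.
    """
    if netA.layer != netB.layer:
        raise ValidationError(
            f"layer mismatch: {netA.layer!r} vs {netB.layer!r}"
        )

    def edge_set(net: CorrelationNetwork) -> set[tuple[str, str]]:
        e = net.edges[net.edges["significant"]]
        return {tuple(sorted(p)) for p in zip(e["source"], e["target"])}

    ea, eb = edge_set(netA), edge_set(netB)
    na = {n for p in ea for n in p}
    nb = {n for p in eb for n in p}

    def member(x, in_a, in_b):
        return "shared" if (x in in_a and x in in_b) else ("A-only" if x in in_a else "B-only")

    nodes = pd.DataFrame(
        {
            "node_id": sorted(na | nb),
            "membership": [member(n, na, nb) for n in sorted(na | nb)],
        }
    )
    all_edges = sorted(ea | eb)
    edges = pd.DataFrame(
        {
            "source": [e[0] for e in all_edges],
            "target": [e[1] for e in all_edges],
            "membership": [member(e, ea, eb) for e in all_edges],
        }
    )
    return nodes, edges


def write_union_sif(edges: pd.DataFrame, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for s, t in zip(edges["source"], edges["target"]):
            fh.write(f"{s}\tco\t{t}\n")


def differential_connectivity(
    net_ref: CorrelationNetwork,
    net_other: CorrelationNetwork,
    z_crit: float = 1.96,
    nodes: list[str] | None = None,
) -> pd.DataFrame:
    """Per-node DK = K_ref - K_other over the union node set, z-standardized.

    ``net_ref`` is the reference-group network (NP in the study design); a
    node absent from one network contributes degree 0 there. ``nodes``
    optionally fixes the node universe (defaults to the union of connected
    nodes). Returns a table with columns node_id, K_ref, K_other, DK, z,
    significant, call; call is "gain" when z >= +z_crit (more connected in
    the reference network), "loss" when z <= -z_crit, else "none".
    """
    k_ref = node_degrees(net_ref) if net_ref.n_edges else pd.Series(dtype=int)
    k_oth = node_degrees(net_other) if net_other.n_edges else pd.Series(dtype=int)
    if nodes is None:
        nodes = sorted(set(k_ref.index) | set(k_oth.index))
    k_ref = k_ref.reindex(nodes).fillna(0).astype(int)
    k_oth = k_oth.reindex(nodes).fillna(0).astype(int)
    dk = (k_ref - k_oth).astype(float)

    mu = dk.mean()
    sigma = dk.std(ddof=0)
    if sigma == 0 or not np.isfinite(sigma):
        warnings.warn(
            "all DK values equal; z-scores undefined, no significant nodes",
            stacklevel=2,
        )
        z = pd.Series(np.nan, index=dk.index)
    else:
        z = (dk - mu) / sigma

    sig = z.abs() >= z_crit
    sig = sig.fillna(False)
    call = np.where(sig & (z >= z_crit), "gain", np.where(sig & (z <= -z_crit), "loss", "none"))
    return pd.DataFrame(
        {
            "node_id": nodes,
            "K_ref": k_ref.values,
            "K_other": k_oth.values,
            "DK": dk.values,
            "z": z.values,
            "significant": sig.values,
            "call": call,
        }
    )
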