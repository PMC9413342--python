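"""Over-representation analysis (ORA) against user-supplied annotation sets.

Hypergeometric upper-tail enrichment of a query feature set against named
annotation sets (GMT format), Holm (Bonferroni step-down) multiple-testing
correction, and a joint gene + metabolite pathway combination by Fisher's
method (chi-square with 4 df on -2(ln p_g + ln p_m); a layer missing a
pathway contributes p = 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ValidationError

__all__ = [
    "AnnotationCollection",
    "read_gmt",
    "write_gmt",
    "hypergeometric_ora",
    "bonferroni_step_down",
    "joint_pathway",
]


@dataclass
class AnnotationCollection:
    """Named feature sets plus a background universe.

    Sets are trimmed to the universe on construction; the number of trimmed
    members per set is kept in ``n_trimmed``.
    """

    sets: dict[str, set[str]]
    universe: set[str]
    n_trimmed: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.universe = set(self.universe)
        trimmed = {}
        clean = {}
        for name, members in self.sets.items():
            members = set(members)
            kept = members & self.universe
            trimmed[name] = len(members) - len(kept)
            clean[name] = kept
        self.sets = clean
        self.n_trimmed = trimmed

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> AnnotationCollection:
    """Read a GMT file (tab-separated: name, description, members...).

    If ``universe`` is omitted, the union of all set members is used.
    """
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValidationError(f"GMT line with < 3 fields: {line[:60]!r}")
        name, _desc, *members = parts
        if name in sets:
            raise ValidationError(f"duplicate set name {name!r}")
        sets[name] = {m for m in members if m}
    if universe is None:
        universe = set().union(*sets.values()) if sets else set()
    return AnnotationCollection(sets, set(universe))


def write_gmt(collection: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for name, members in collection.items():
            fh.write("\t".join([name, "na"] + sorted(members)) + "\n")


def hypergeometric_ora(
    query: Iterable[str],
    annot: AnnotationCollection,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``query`` in each set.

    p_raw = P[X >= k] for X ~ Hypergeometric(N, K, n) with N the universe
    size, K the set size, n the query size and k the overlap. Query members
    outside the universe are trimmed with a warning. Holm-adjusted p-values
    and a significance flag at ``alpha`` are included.
    """
    query = set(query)
    if not query:
        raise ValidationError("empty query set")
    outside = query - annot.universe
    if outside:
        warnings.warn(
            f"{len(outside)} query features outside the universe were trimmed",
            stacklevel=2,
        )
        query &= annot.universe
        if not query:
            raise ValidationError("query has no overlap with the universe")
    N, n = len(annot.universe), len(query)
    rows = []
    for name in sorted(annot.sets):
        members = annot.sets[name]
        K = len(members)
        k = len(query & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((name, k, K, n, N, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["set_name", "k", "K", "n", "N", "p_raw"])
    out["p_adjusted"] = bonferroni_step_down(out["p_raw"].values)
    out["significant"] = out["p_adjusted"] <= alpha
    return out.sort_values(["p_raw", "set_name"]).reset_index(drop=True)


def bonferroni_step_down(p_values: Iterable[float]) -> np.ndarray:
    """Holm step-down adjustment, mapped back to input order.

    Sort ascending; adjusted_(i) = max_{j <= i} min(1, (m - j + 1) * p_(j)).
    """
    p = np.asarray(list(p_values), dtype=float)
    if ((p <= 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in (0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    stepped = np.minimum((m - np.arange(m)) * p[order], 1.0)
    stepped = np.maximum.accumulate(stepped)
    out = np.empty(m)
    out[order] = stepped
    return out


def joint_pathway(
    gene_query: Iterable[str],
    metab_query: Iterable[str],
    gene_annot: AnnotationCollection,
    metab_annot: AnnotationCollection,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Combine per-layer enrichment p-values pathway-wise (Fisher's method).

    Pathways are matched by name across the two collections (union of
    names); a layer lacking a pathway contributes p = 1. The Fisher statistic
    -2(ln p_g + ln p_m) is referred to chi-square with 4 df.
    """
    shared = set(gene_annot.sets) | set(metab_annot.sets)
    if not (set(gene_annot.sets) & set(metab_annot.sets)):
        warnings.warn("no pathway names shared between layers", stacklevel=2)
        if not shared:
            return pd.DataFrame(
                columns=["set_name", "p_gene", "p_metab", "fisher_stat", "p_combined", "significant"]
            )
    gene_p = _layer_p(gene_query, gene_annot)
    metab_p = _layer_p(metab_query, metab_annot)
    rows = []
    for name in sorted(shared):
        pg = gene_p.get(name, 1.0)
        pm = metab_p.get(name, 1.0)
        stat = -2.0 * (np.log(pg) + np.log(pm))
        pc = float(stats.chi2.sf(stat, df=4))
        rows.append((name, pg, pm, stat, pc))
    out = pd.DataFrame(
        rows, columns=["set_name", "p_gene", "p_metab", "fisher_stat", "p_combined"]
    )
    out["significant"] = out["p_combined"] <= alpha
    return out.sort_values(["p_combined", "set_name"]).reset_index(drop=True)


def _layer_p(query: Iterable[str], annot: AnnotationCollection) -> dict[str, float]:
    query = set(query) & annot.universe
    if not query or not annot.sets:
        return {name: 1.0 for name in annot.sets}
    table = hypergeometric_ora(query, annot)
    return dict(zip(table["set_name"], table["p_raw"]))
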