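"""Two-group differential expression / abundance calls.

The network filters downstream only need a set of differentially expressed
features. The built-in caller is deliberately simple and transparent: a Welch
two-sample t-test on log2(CPM+1) for genes, or on the (already log-scale)
abundances for metabolites, with log2 fold change = difference of group means
on the log2 scale. Externally computed calls (e.g. from edgeR/DESeq2 runs, or
a published metabolite list) can be loaded instead.

Sign convention: the nonpregnant (NP) group is the reference, and
log2FC > 0 means higher expression in the reference group; ``direction`` is
"up"/"down" in the reference group. ``fc_direction="other-minus-reference"``
flips the sign.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import FeatureMatrix, ValidationError
from .qc import log2_cpm

__all__ = [
    "differential_test",
    "call_significant",
    "load_external_calls",
    "write_table",
]

LOG2E = np.log2(np.e)


def differential_test(
    matrix: FeatureMatrix,
    alpha: float = 0.05,
    lfc_min: float = 0.5,
    fc_direction: str = "reference-minus-other",
    transform: str | None = None,
) -> pd.DataFrame:
    """Welch t-test per feature between the two phenotype groups.

    ``transform`` controls the scale the test runs on: ``"log2cpm"``
    (default for gene matrices) applies log2(CPM+1) to raw counts;
    ``"log2"`` converts natural-log metabolite abundances to log2;
    ``"none"`` uses values as given. Returns a table with columns
    feature_id, log2fc, p_value, direction, significant, p_bh.
    """
    if transform is None:
        transform = "log2cpm" if (matrix.kind == "gene").all() else "log2"
    if transform == "log2cpm":
        data = log2_cpm(matrix).values
    elif transform == "log2":
        data = matrix.values * LOG2E  # natural log -> log2
    elif transform == "none":
        data = matrix.values
    else:
        raise ValidationError(f"unknown transform {transform!r}")

    ref, other = matrix.groups
    a = data[matrix.samples_in(ref)].values
    b = data[matrix.samples_in(other)].values
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValidationError("need >= 2 samples per group")

    lfc = a.mean(axis=1) - b.mean(axis=1)
    if fc_direction == "other-minus-reference":
        lfc = -lfc
    elif fc_direction != "reference-minus-other":
        raise ValidationError(f"unknown fc_direction {fc_direction!r}")

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # constant features trigger scipy's precision-loss warning; they are
        # handled explicitly below (p = 1)
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    # zero variance in both groups: no evidence either way
    degenerate = ~np.isfinite(p)
    p[degenerate] = 1.0

    table = pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            "log2fc": lfc,
            "p_value": p,
            "direction": np.where(lfc > 0, "up", "down"),
            "significant": (p <= alpha) & (np.abs(lfc) >= lfc_min),
            "p_bh": _bh(p),
        }
    )
    return table.reset_index(drop=True)


def _bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (informational column)."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def call_significant(
    table: pd.DataFrame, alpha: float = 0.05, lfc_min: float = 0.5
) -> set[str]:
    """Features with p <= alpha and |log2FC| >= lfc_min (boundaries included)."""
    mask = (table["p_value"] <= alpha) & (table["log2fc"].abs() >= lfc_min)
    return set(table.loc[mask, "feature_id"])


def load_external_calls(
    path: str | Path, known_ids: set[str] | None = None
) -> set[str]:
    """Load an externally computed differential feature list.

    Accepts either one feature ID per line, or a tab-separated table with a
    ``feature_id`` column (rows with a ``significant`` column restricted to
    true values). Unknown IDs (not in ``known_ids``) are dropped with a
    warning naming them.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8").strip()
    if not text:
        raise ValidationError(f"{path} is empty")
    lines = text.splitlines()
    if "\t" in lines[0] and "feature_id" in lines[0].split("\t"):
        table = pd.read_csv(path, sep="\t")
        if "significant" in table.columns:
            table = table[table["significant"].astype(bool)]
        ids = set(table["feature_id"].astype(str))
    else:
        ids = {ln.strip() for ln in lines if ln.strip()}
    if known_ids is not None:
        unknown = sorted(ids - set(known_ids))
        if unknown:
            warnings.warn(f"unknown feature IDs dropped: {unknown}", stacklevel=2)
        ids &= set(known_ids)
    return ids


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")
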