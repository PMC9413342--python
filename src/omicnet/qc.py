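"""Count and metabolite quality control.

Genes: CPM transform and the three sequential count filters (unexpressed /
very lowly expressed / rarely expressed). Metabolites: per-group relative
standard deviation (RSD) filtering on raw peak heights followed by natural-log
normalization.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .matrix import FeatureMatrix, FilterReport, ValidationError

__all__ = [
    "cpm",
    "log2_cpm",
    "filter_counts",
    "metabolite_qc",
    "log_normalize",
]


def cpm(counts: FeatureMatrix) -> FeatureMatrix:
    """Counts per million: count / library size x 1e6.

    Library size is the column sum of the matrix as given (compute CPM before
    any feature filtering if library sizes should reflect the full library).
    """
    vals = counts.values
    if (vals.values < 0).any():
        raise ValidationError("counts must be non-negative")
    libsize = vals.sum(axis=0)
    zero = list(libsize.index[libsize == 0])
    if zero:
        raise ValidationError(f"samples with all-zero counts: {zero}")
    out = vals / libsize * 1e6
    return FeatureMatrix(out, counts.kind, counts.phenotype, counts.reference)


def log2_cpm(counts: FeatureMatrix, pseudocount: float = 1.0) -> FeatureMatrix:
    """log2(CPM + pseudocount): the variance-stabilized gene scale used for
    correlation, differential testing and the interaction model."""
    c = cpm(counts)
    out = np.log2(c.values + pseudocount)
    return FeatureMatrix(out, counts.kind, counts.phenotype, counts.reference)


def filter_counts(
    counts: FeatureMatrix,
    min_mean_cpm: float = 1.0,
    presence_cpm: float = 1.0,
    min_presence_fraction: float = 0.5,
) -> tuple[FeatureMatrix, FilterReport]:
    """Apply the three count filters in order, pooling both groups.

    (i) unexpressed: all counts zero; (ii) very lowly expressed: mean CPM
    across samples < ``min_mean_cpm``; (iii) rarely expressed: CPM >=
    ``presence_cpm`` ("present") in fewer than ``min_presence_fraction`` of
    samples. Each removed feature is attributed to the first rule it fails;
    the retained set equals the intersection of the three rules regardless of
    order. Returns the retained raw counts and a :class:`FilterReport`.
    """
    raw = counts.values
    c = cpm(counts).values

    unexpressed = (raw == 0).all(axis=1)
    low = c.mean(axis=1) < min_mean_cpm
    present_frac = (c >= presence_cpm).mean(axis=1)
    rare = present_frac < min_presence_fraction

    rule1 = unexpressed
    rule2 = low & ~rule1
    rule3 = rare & ~rule1 & ~rule2
    keep = ~(rule1 | rule2 | rule3)

    retained_ids = list(raw.index[keep])
    report = FilterReport(
        n_input=counts.n_features,
        n_removed_by_rule={
            "unexpressed": int(rule1.sum()),
            "low_mean_cpm": int(rule2.sum()),
            "rarely_expressed": int(rule3.sum()),
        },
        n_retained=len(retained_ids),
        retained_ids=retained_ids,
    )
    if not retained_ids:
        warnings.warn("count filtering removed every feature", stacklevel=2)
    return counts.subset_features(retained_ids), report


def rsd(values: pd.DataFrame) -> pd.Series:
    """Relative standard deviation (sd/mean) per row; ddof=1."""
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    return sd / mean


def log_normalize(metab: FeatureMatrix, pseudocount: float = 0.0) -> FeatureMatrix:
    """Natural-log transform of peak heights (optional +pseudocount)."""
    vals = metab.values + pseudocount
    if (vals.values <= 0).any():
        bad = np.argwhere(vals.values <= 0)[0]
        raise ValidationError(
            f"non-positive peak height at feature {vals.index[bad[0]]!r}, "
            f"sample {vals.columns[bad[1]]!r}"
        )
    return FeatureMatrix(np.log(vals), metab.kind, metab.phenotype, metab.reference)


def metabolite_qc(
    metab: FeatureMatrix,
    rsd_max: float = 0.15,
    pseudocount: float = 0.0,
) -> tuple[FeatureMatrix, FilterReport]:
    """Per-group RSD filter on raw peak heights, then natural-log normalize.

    A metabolite is retained *for a group's analyses* if its within-group RSD
    (sd/mean of raw peak heights) is <= ``rsd_max`` in that group; the
    retained sets may differ between groups and are reported in
    ``report.group_retained_ids``. The returned matrix holds log values for
    every metabolite retained in at least one group; removal is attributed to
    rule ``rsd>{rsd_max}_both_groups``.
    """
    check = metab.values + pseudocount
    if (check.values <= 0).any():
        bad = np.argwhere(check.values <= 0)[0]
        raise ValidationError(
            f"non-positive peak height at feature {check.index[bad[0]]!r}, "
            f"sample {check.columns[bad[1]]!r}"
        )
    group_keep: dict[str, list[str]] = {}
    for g in metab.groups:
        vals = metab.group_values(g)
        r = rsd(vals)
        group_keep[g] = list(r.index[r <= rsd_max])
    union = [f for f in metab.feature_ids if any(f in group_keep[g] for g in metab.groups)]
    report = FilterReport(
        n_input=metab.n_features,
        n_removed_by_rule={f"rsd>{rsd_max}_both_groups": metab.n_features - len(union)},
        n_retained=len(union),
        retained_ids=union,
        group_retained_ids=group_keep,
    )
    logged = log_normalize(metab.subset_features(union), pseudocount=pseudocount)
    return logged, report
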