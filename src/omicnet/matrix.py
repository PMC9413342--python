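"""Feature-by-sample matrices with phenotype labels.

The central container is :class:`FeatureMatrix`: a numeric features x samples
table (raw counts for genes, peak heights or log-abundances for metabolites)
together with a per-feature kind, a two-level phenotype label per sample, and
a designated reference phenotype level (default ``"NP"``, nonpregnant).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureMatrix",
    "FilterReport",
    "read_feature_matrix",
    "read_phenotype_map",
    "ValidationError",
]

GENE = "gene"
METABOLITE = "metabolite"
_KINDS = (GENE, METABOLITE)


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _duplicates(items: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for x in items:
        if x in seen and x not in dups:
            dups.append(x)
        seen.add(x)
    return dups


@dataclass
class FeatureMatrix:
    """Numeric features x samples matrix with phenotype metadata.

    Parameters
    ----------
    values
        DataFrame indexed by feature ID, columns are sample IDs.
    kind
        Either a single kind (``"gene"`` or ``"metabolite"``) applied to all
        features, or a per-feature Series (required for combined layers).
    phenotype
        Two-level label per sample (Series indexed by sample ID, or mapping).
    reference
        The reference phenotype level. Defaults to ``"NP"``.
    """

    values: pd.DataFrame
    kind: pd.Series | str = GENE
    phenotype: pd.Series | Mapping[str, str] = field(default_factory=dict)
    reference: str = "NP"

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        self.values.index = self.values.index.astype(str)
        self.values.columns = self.values.columns.astype(str)

        dups = _duplicates(self.values.index)
        if dups:
            raise ValidationError(f"duplicate feature IDs: {dups}")
        dups = _duplicates(self.values.columns)
        if dups:
            raise ValidationError(f"duplicate sample IDs: {dups}")

        if isinstance(self.kind, str):
            if self.kind not in _KINDS:
                raise ValidationError(f"unknown feature kind {self.kind!r}")
            self.kind = pd.Series(self.kind, index=self.values.index, dtype=object)
        else:
            self.kind = pd.Series(self.kind).astype(object)
            self.kind.index = self.kind.index.astype(str)
            missing = [f for f in self.values.index if f not in self.kind.index]
            if missing:
                raise ValidationError(f"features without kind: {missing[:5]}")
            self.kind = self.kind.reindex(self.values.index)
            bad = sorted(set(self.kind) - set(_KINDS))
            if bad:
                raise ValidationError(f"unknown feature kinds: {bad}")

        if not isinstance(self.phenotype, pd.Series):
            self.phenotype = pd.Series(dict(self.phenotype), dtype=object)
        self.phenotype.index = self.phenotype.index.astype(str)
        missing = [s for s in self.values.columns if s not in self.phenotype.index]
        if missing:
            raise ValidationError(f"samples without phenotype label: {missing}")
        self.phenotype = self.phenotype.reindex(self.values.columns).astype(str)

        levels = sorted(self.phenotype.unique())
        if len(levels) != 2:
            raise ValidationError(
                f"phenotype must have exactly two levels, got {levels}"
            )
        if self.reference not in levels:
            raise ValidationError(
                f"reference level {self.reference!r} not among phenotype levels {levels}"
            )
        counts = self.phenotype.value_counts()
        small = counts[counts < 2]
        if not small.empty:
            raise ValidationError(
                f"each phenotype level needs >= 2 samples; got {counts.to_dict()}"
            )

    # -- basic accessors ---------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def groups(self) -> list[str]:
        """Phenotype levels, reference first."""
        other = [g for g in sorted(self.phenotype.unique()) if g != self.reference]
        return [self.reference] + other

    @property
    def other(self) -> str:
        """The non-reference phenotype level."""
        return self.groups[1]

    def samples_in(self, group: str) -> list[str]:
        if group not in self.groups:
            raise ValidationError(f"unknown phenotype level {group!r}")
        return list(self.phenotype.index[self.phenotype == group])

    def group_values(self, group: str) -> pd.DataFrame:
        return self.values[self.samples_in(group)]

    def subset_features(self, ids: Sequence[str]) -> "FeatureMatrix":
        ids = [str(i) for i in ids]
        unknown = [i for i in ids if i not in self.values.index]
        if unknown:
            raise ValidationError(f"unknown feature IDs: {unknown[:5]}")
        return FeatureMatrix(
            self.values.loc[ids], self.kind.loc[ids], self.phenotype, self.reference
        )

    def subset_samples(self, ids: Sequence[str]) -> "FeatureMatrix":
        ids = [str(i) for i in ids]
        return FeatureMatrix(
            self.values[ids], self.kind, self.phenotype.loc[ids], self.reference
        )

    def write(self, path: str | Path, sep: str = "\t") -> None:
        self.values.to_csv(path, sep=sep, index_label="feature_id")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        kinds = self.kind.value_counts().to_dict()
        return (
            f"FeatureMatrix({self.n_features} features {kinds}, "
            f"{self.n_samples} samples, groups={self.groups})"
        )


def stack(gene: FeatureMatrix, metab: FeatureMatrix) -> FeatureMatrix:
    """Stack a gene layer and a metabolite layer into one combined matrix.

    Samples must match exactly (order taken from the gene layer).
    """
    missing = set(gene.sample_ids) ^ set(metab.sample_ids)
    if missing:
        raise ValidationError(
            f"sample sets differ between layers; symmetric difference: {sorted(missing)}"
        )
    overlap = set(gene.feature_ids) & set(metab.feature_ids)
    if overlap:
        raise ValidationError(f"feature IDs shared across layers: {sorted(overlap)[:5]}")
    metab_aligned = metab.values[gene.sample_ids]
    values = pd.concat([gene.values, metab_aligned])
    kind = pd.concat([gene.kind, metab.kind])
    return FeatureMatrix(values, kind, gene.phenotype, gene.reference)


@dataclass
class FilterReport:
    """Accounting for a QC filter: every removal attributed to one rule."""

    n_input: int
    n_removed_by_rule: dict[str, int]
    n_retained: int
    retained_ids: list[str]
    group_retained_ids: dict[str, list[str]] | None = None

    def __post_init__(self) -> None:
        removed = sum(self.n_removed_by_rule.values())
        if self.n_input != self.n_retained + removed:
            raise ValidationError(
                f"filter accounting broken: {self.n_input} != "
                f"{self.n_retained} + {removed}"
            )

    def to_frame(self) -> pd.DataFrame:
        rows = [("input", self.n_input)]
        rows += [(f"removed:{k}", v) for k, v in self.n_removed_by_rule.items()]
        rows.append(("retained", self.n_retained))
        return pd.DataFrame(rows, columns=["rule", "n"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def describe(self) -> str:
        parts = [f"{self.n_input} features in"]
        parts += [f"{v} removed by {k}" for k, v in self.n_removed_by_rule.items()]
        parts.append(f"{self.n_retained} retained")
        return "; ".join(parts)


def _sniff_sep(path: Path) -> str:
    head = path.open("r", encoding="utf-8").readline()
    return "\t" if head.count("\t") >= head.count(",") else ","


def read_feature_matrix(
    path: str | Path,
    kind: str,
    phenotype_map: Mapping[str, str] | pd.Series,
    reference: str = "NP",
) -> FeatureMatrix:
    """Read a delimited feature-by-sample table (TSV or CSV, auto-detected).

    First column holds feature IDs, header row holds sample IDs. Every sample
    in the file must appear in ``phenotype_map``.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    dups = _duplicates(header)
    if dups:
        raise ValidationError(f"duplicate sample IDs in header: {dups}")
    table = pd.read_csv(path, sep=sep, index_col=0)
    table.index = table.index.astype(str)
    if not all(np.issubdtype(dt, np.number) for dt in table.dtypes):
        raise ValidationError(f"non-numeric values in {path}")
    pheno = pd.Series(dict(phenotype_map)) if not isinstance(
        phenotype_map, pd.Series
    ) else phenotype_map
    missing = [s for s in table.columns if str(s) not in pheno.index.astype(str)]
    if missing:
        raise ValidationError(
            f"samples in {path.name} absent from phenotype map: {missing}"
        )
    return FeatureMatrix(table, kind, pheno, reference)


def read_phenotype_map(path: str | Path) -> pd.Series:
    """Read a two-column sample -> phenotype table (TSV/CSV, header optional)."""
    path = Path(path)
    sep = _sniff_sep(path)
    first = path.open("r", encoding="utf-8").readline().rstrip("\n").split(sep)
    header = 0 if first and first[0].lower() in {"sample", "sample_id", "id"} else None
    table = pd.read_csv(path, sep=sep, header=header)
    if table.shape[1] < 2:
        raise ValidationError(f"{path}: expected two columns (sample, phenotype)")
    out = pd.Series(table.iloc[:, 1].values, index=table.iloc[:, 0].astype(str))
    dups = _duplicates(out.index)
    if dups:
        raise ValidationError(f"duplicate sample IDs in phenotype map: {dups}")
    return out.astype(str)
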