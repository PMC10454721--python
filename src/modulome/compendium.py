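"""Expression-compendium loading, quality control and reference centering.

The compendium is a log2 gene × sample matrix paired with a sample metadata
table (project, condition, reference condition, replicate group). Quality
control removes samples whose best within-replicate-group Pearson correlation
falls below a cutoff, and normalization subtracts, per project, the mean
expression of the project's reference condition, so downstream activities are
log2 fold changes against each project's control state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

METADATA_COLUMNS = [
    "sample_id",
    "project_id",
    "condition_id",
    "reference_condition_id",
    "replicate_group",
]


class CompendiumError(ValueError):
    """Raised for malformed expression matrices or metadata tables."""


@dataclass
class ExpressionCompendium:
    """A log2 gene × sample expression matrix with sample metadata.

    Attributes
    ----------
    values : pd.DataFrame
        Genes as rows (index), samples as columns, log2 units.
    metadata : pd.DataFrame
        One row per sample, indexed by ``sample_id``, with columns
        ``project_id``, ``condition_id``, ``reference_condition_id`` and
        ``replicate_group``. Row order matches the column order of `values`.
    centered : bool
        True once per-project reference-condition means have been subtracted.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    centered: bool = False
    load_warnings: list[str] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def __post_init__(self) -> None:
        # light checks only: QC may legitimately leave a project without its
        # reference samples, which center_to_reference rejects later
        if self.metadata.index.duplicated().any():
            dups = self.metadata.index[self.metadata.index.duplicated()].tolist()
            raise CompendiumError(f"duplicate sample ids in metadata: {dups}")
        if list(self.values.columns) != list(self.metadata.index):
            raise CompendiumError("sample order mismatch between values and metadata")
        if self.values.isna().any().any():
            raise CompendiumError("expression matrix contains missing values")

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionCompendium":
        return replace(
            self,
            values=self.values[sample_ids],
            metadata=self.metadata.loc[sample_ids],
        )


def validate_metadata(metadata: pd.DataFrame) -> None:
    """Check the metadata invariants: unique sample ids, resolvable references."""
    if metadata.index.duplicated().any():
        dups = metadata.index[metadata.index.duplicated()].tolist()
        raise CompendiumError(f"duplicate sample ids in metadata: {dups}")
    required = set(METADATA_COLUMNS) - {"sample_id"}
    missing = required - set(metadata.columns)
    if missing:
        raise CompendiumError(f"metadata missing columns: {sorted(missing)}")
    for project, sub in metadata.groupby("project_id"):
        conditions = set(sub["condition_id"])
        for ref in set(sub["reference_condition_id"]):
            if ref not in conditions:
                raise CompendiumError(
                    f"reference condition {ref!r} of project {project!r} "
                    "names no sample's condition in that project"
                )


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, dtype=str)
    missing = set(METADATA_COLUMNS) - set(meta.columns)
    if missing:
        raise CompendiumError(f"metadata missing columns: {sorted(missing)}")
    meta = meta.set_index("sample_id")
    validate_metadata(meta)
    return meta


def load_expression(path, metadata_path, log2: bool = False) -> ExpressionCompendium:
    """Load an expression TSV (genes × samples) plus a metadata CSV.

    Columns are restricted to samples present in the metadata, in metadata
    order. Samples listed in the metadata but absent from the TSV are an
    error; TSV columns absent from the metadata are dropped and recorded in
    ``load_warnings``.

    Parameters
    ----------
    log2 : bool
        Apply a log2 transform at load (for raw-intensity input). Synthetic
        and pre-processed matrices are already on the log2 scale.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0)
    if raw.index.duplicated().any():
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise CompendiumError(f"duplicate gene ids: {dups}")
    if pd.Index(raw.columns).duplicated().any():
        dups = pd.Index(raw.columns)[pd.Index(raw.columns).duplicated()].tolist()
        raise CompendiumError(f"duplicate sample ids: {dups}")

    non_numeric = []
    for col in raw.columns:
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = raw.index[coerced.isna() & raw[col].notna()]
        non_numeric.extend((g, col) for g in bad)
    if non_numeric:
        raise CompendiumError(f"non-numeric cells at (gene, sample): {non_numeric[:5]}")
    values = raw.astype(float)
    if values.isna().any().any():
        where = values.isna().stack()
        coords = where[where].index.tolist()[:5]
        raise CompendiumError(f"missing values at (gene, sample): {coords}")

    meta = read_metadata(metadata_path)
    absent = [s for s in meta.index if s not in values.columns]
    if absent:
        raise CompendiumError(f"metadata samples absent from expression matrix: {absent}")
    load_warnings = []
    extra = [s for s in values.columns if s not in meta.index]
    if extra:
        load_warnings.append(f"dropped samples absent from metadata: {extra}")
    values = values[list(meta.index)]
    if log2:
        if (values <= 0).any().any():
            raise CompendiumError("log2 transform requested but matrix has values <= 0")
        values = np.log2(values)
    return ExpressionCompendium(values, meta, centered=False, load_warnings=load_warnings)


def write_expression(c: ExpressionCompendium, path) -> None:
    out = c.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def write_metadata(c: ExpressionCompendium, path) -> None:
    out = c.metadata.reset_index()
    out = out.rename(columns={out.columns[0]: "sample_id"})
    out.to_csv(path, index=False)


def _group_correlations(values: pd.DataFrame, samples: list[str]) -> pd.DataFrame:
    """Pairwise Pearson correlations between sample columns (over genes)."""
    return values[samples].corr(method="pearson")


def filter_replicates(
    c: ExpressionCompendium, min_corr: float = 0.95
) -> tuple[ExpressionCompendium, list[str]]:
    """Drop samples with poor replicability.

    Within each replicate group of size >= 2, a sample is removed when its
    best Pearson correlation to any other sample of the group is below
    `min_corr`. Singleton groups are untouched. Keying on the best in-group
    correlation (rather than the mean) removes only true outliers.
    """
    if c.centered:
        raise CompendiumError("replicate QC must run on the uncentered compendium")
    removed: list[str] = []
    for group, sub in c.metadata.groupby("replicate_group"):
        samples = list(sub.index)
        if len(samples) < 2:
            continue
        corr = _group_correlations(c.values, samples)
        np.fill_diagonal(corr.values, np.nan)
        best = corr.max(axis=1)
        bad = [s for s in samples if not best[s] >= min_corr]
        if len(bad) == len(samples):
            warnings.warn(
                f"replicate group {group!r}: all samples mutually below "
                f"{min_corr}; removing the whole group",
                stacklevel=2,
            )
        removed.extend(bad)
    keep = [s for s in c.samples if s not in set(removed)]
    return c.subset_samples(keep), removed


def replicate_correlation_summary(c: ExpressionCompendium) -> dict:
    """Median/min Pearson correlation over all within-replicate-group pairs.

    Returns an empty summary (``n_pairs == 0``) when no group has >= 2
    samples.
    """
    per_group: dict[str, list[float]] = {}
    all_pairs: list[float] = []
    for group, sub in c.metadata.groupby("replicate_group"):
        samples = list(sub.index)
        if len(samples) < 2:
            continue
        corr = _group_correlations(c.values, samples).values
        iu = np.triu_indices(len(samples), k=1)
        pairs = corr[iu].tolist()
        per_group[str(group)] = pairs
        all_pairs.extend(pairs)
    if not all_pairs:
        return {"median": None, "min": None, "n_pairs": 0, "per_group": {}}
    return {
        "median": float(np.median(all_pairs)),
        "min": float(np.min(all_pairs)),
        "n_pairs": len(all_pairs),
        "per_group": per_group,
    }


def center_to_reference(c: ExpressionCompendium) -> ExpressionCompendium:
    """Subtract, per project, each gene's mean over the reference-condition samples.

    Idempotent in effect: once reference means are zero, re-centering changes
    nothing.
    """
    values = c.values.copy()
    for project, sub in c.metadata.groupby("project_id"):
        refs = set(sub["reference_condition_id"])
        if len(refs) != 1:
            raise CompendiumError(
                f"project {project!r} has multiple reference conditions: {sorted(refs)}"
            )
        ref = refs.pop()
        ref_samples = sub.index[sub["condition_id"] == ref].tolist()
        if not ref_samples:
            raise CompendiumError(
                f"project {project!r}: reference condition {ref!r} has no samples"
            )
        proj_samples = list(sub.index)
        ref_mean = values[ref_samples].mean(axis=1)
        values[proj_samples] = values[proj_samples].sub(ref_mean, axis=0)
    return replace(c, values=values, centered=True)
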