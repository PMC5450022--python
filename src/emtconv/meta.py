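"""EMT-microarray meta-analysis.

Reproduces the compendium-building procedure: biological replicates of
the same treatment are averaged and normalized to the (shared) control
mean, results are log₂-transformed, gene names are replaced by official
symbols, and datasets are merged on symbol into one genes ×
(dataset, treatment) table of log₂ changes. On the merged compendium
the module reports per-gene up-regulation fractions (how many columns
exceed a fold threshold) and stratifies columns by EMT-score strength
to test whether a gene's up-regulation is enriched in strongly induced
datasets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from math import log2
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .scoring import ExpressionChanges, SignatureSet, signature_score

logger = logging.getLogger(__name__)

LINEAR = "linear"
LOG2 = "log2"
LOG2_VS_CONTROL = "log2-vs-control"


@dataclass
class RawDataset:
    """One expression dataset: genes × samples plus sample metadata.

    ``scale`` declares how values are stored: ``linear`` (raw
    intensities), ``log2`` (log₂ intensities) or ``log2-vs-control``
    (already log₂ ratios to control — normalization is then a no-op).
    Metadata columns: sample, treatment, replicate, is_control.
    """

    dataset_id: str
    expression: pd.DataFrame
    metadata: pd.DataFrame
    scale: str = LINEAR

    def __post_init__(self) -> None:
        if self.scale not in (LINEAR, LOG2, LOG2_VS_CONTROL):
            raise ValueError(f"undeclared/unknown scale {self.scale!r}")
        required = {"sample", "treatment", "is_control"}
        if not required <= set(self.metadata.columns):
            raise ValueError(f"metadata must have columns {sorted(required)}")
        if self.scale != LOG2_VS_CONTROL and not self.metadata.is_control.any():
            raise ValueError(f"{self.dataset_id}: no control sample")
        missing = set(self.metadata["sample"]) - set(self.expression.columns)
        if missing:
            raise ValueError(f"{self.dataset_id}: metadata samples absent "
                             f"from expression: {sorted(missing)}")


def normalize_dataset(raw: RawDataset) -> pd.DataFrame:
    """Per-treatment log₂ changes vs the shared control.

    Replicates of each non-control treatment are averaged (on the linear
    scale), divided by the mean over all control samples — the same
    control mean for every treatment — and log₂-transformed. A dataset
    already declared as log₂-vs-control passes through unchanged
    (idempotence). Returns genes × treatments.
    """
    meta = raw.metadata
    expr = raw.expression

    if raw.scale == LOG2_VS_CONTROL:
        treatments = [
            t for t in meta.loc[~meta.is_control, "treatment"].unique()
        ] or list(expr.columns)
        if set(meta["sample"]) == set(expr.columns) and not meta.is_control.all():
            out = {}
            for t in meta.loc[~meta.is_control, "treatment"].unique():
                cols = meta.loc[meta.treatment == t, "sample"]
                out[t] = expr[cols].mean(axis=1)
            return pd.DataFrame(out)
        return expr.copy()

    if raw.scale == LOG2:
        expr = 2.0**expr

    ctrl_cols = meta.loc[meta.is_control, "sample"]
    ctrl_mean = expr[ctrl_cols].mean(axis=1)
    bad = ctrl_mean[ctrl_mean <= 0]
    if len(bad):
        raise ValueError(
            f"{raw.dataset_id}: non-positive control mean for gene(s) "
            f"{', '.join(map(str, bad.index[:5]))}"
        )
    out = {}
    for t in meta.loc[~meta.is_control, "treatment"].unique():
        cols = meta.loc[(meta.treatment == t) & ~meta.is_control, "sample"]
        ratio = expr[cols].mean(axis=1) / ctrl_mean
        if (ratio <= 0).any():
            g = ratio.index[ratio <= 0][0]
            raise ValueError(f"{raw.dataset_id}: non-positive ratio for gene {g}")
        out[t] = np.log2(ratio)
    return pd.DataFrame(out)


@dataclass
class MergedCompendium:
    """Genes × (dataset, treatment) log₂ changes vs control."""

    matrix: pd.DataFrame                     # columns: MultiIndex (dataset, treatment)
    emt_scores: Optional[pd.Series] = None   # per column, filled by score_columns
    species: str = "mouse"

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]


def _apply_aliases(index: pd.Index, alias_table: Optional[pd.DataFrame]) -> pd.Index:
    if alias_table is None:
        return index
    lut = dict(zip(alias_table.iloc[:, 0].str.upper(), alias_table.iloc[:, 1]))
    return pd.Index([lut.get(str(g).upper(), g) for g in index])


def merge_by_symbol(
    normalized: Mapping[str, pd.DataFrame],
    alias_table: Optional[pd.DataFrame] = None,
    species: str = "mouse",
) -> MergedCompendium:
    """Outer-merge normalized datasets on official gene symbols.

    ``normalized`` maps dataset id → genes × treatments log₂-change
    table. ``alias_table`` (columns: alias, official) rewrites symbols
    before the merge. Duplicate symbols within a dataset are collapsed
    by mean with a logged warning; genes absent from a dataset stay
    missing (NaN), never zero.
    """
    if not normalized:
        raise ValueError("no datasets to merge")
    pieces = []
    for ds_id, df in normalized.items():
        d = df.copy()
        d.index = _apply_aliases(pd.Index(d.index.astype(str)), alias_table)
        if d.index.duplicated().any():
            dups = sorted(set(d.index[d.index.duplicated()]))
            logger.warning("dataset %s: collapsing duplicate symbols by mean: %s",
                           ds_id, ", ".join(map(str, dups[:10])))
            d = d.groupby(level=0).mean()
        d.columns = pd.MultiIndex.from_product([[ds_id], d.columns],
                                               names=["dataset", "treatment"])
        pieces.append(d)
    matrix = pd.concat(pieces, axis=1, join="outer").sort_index()
    return MergedCompendium(matrix=matrix, species=species)


def score_columns(comp: MergedCompendium, signature: SignatureSet) -> pd.Series:
    """Per-column EMT score on the merged matrix (missing genes per
    column are excluded as usual)."""
    scores = {}
    for col in comp.matrix.columns:
        series = comp.matrix[col].dropna()
        changes = ExpressionChanges(series.to_dict(), sample=str(col),
                                    species=comp.species)
        scores[col] = signature_score(changes, signature).score
    s = pd.Series(scores).reindex(comp.matrix.columns)
    comp.emt_scores = s
    return s


@dataclass(frozen=True)
class FractionResult:
    percent: float
    n_up: int
    basis: int          # columns where the gene is non-missing


def upregulation_fraction(
    comp: MergedCompendium,
    gene: str,
    fold_threshold: float = 1.5,
) -> FractionResult:
    """Percent of compendium columns in which ``gene`` is up-regulated
    beyond ``fold_threshold`` (log₂FC > log₂ threshold), over the
    columns where the gene is measured (the basis count)."""
    from .scoring import normalize_symbol

    key = normalize_symbol(gene, comp.species)
    idx = pd.Index([normalize_symbol(str(g), comp.species) for g in comp.matrix.index])
    if key not in set(idx):
        raise KeyError(f"gene {gene} absent from the compendium")
    row = comp.matrix.loc[idx == key].iloc[0]
    present = row.dropna()
    if present.empty:
        raise KeyError(f"gene {gene} missing in every column")
    n_up = int((present > log2(fold_threshold)).sum())
    return FractionResult(100.0 * n_up / len(present), n_up, len(present))


def stratify_by_emt(
    comp: MergedCompendium,
    signature: SignatureSet,
    query_genes: Sequence[str] = ("Sox2", "Map1b", "Reln", "Robo1", "Tubb3", "Stat3"),
    strong_quantile: float = 0.25,
    fold_threshold: float = 1.5,
) -> pd.DataFrame:
    """Split columns into strongly vs weakly EMT-induced groups and
    compare per-gene up-regulation fractions.

    Strong = the top ``strong_quantile`` of per-column EMT scores
    (default top quartile). Returns one row per query gene with the
    up-regulation fraction in each group, the basis counts and the
    difference (strong − weak).
    """
    if comp.n_columns < 4:
        raise ValueError("need at least 4 columns to stratify")
    scores = comp.emt_scores if comp.emt_scores is not None else score_columns(comp, signature)
    cutoff = scores.quantile(1.0 - strong_quantile)
    strong_cols = scores[scores >= cutoff].index
    weak_cols = scores[scores < cutoff].index

    def _fraction(sub: pd.DataFrame, gene: str) -> tuple[float, int]:
        c = MergedCompendium(matrix=sub, species=comp.species)
        try:
            r = upregulation_fraction(c, gene, fold_threshold)
            return r.percent, r.basis
        except KeyError:
            return float("nan"), 0

    rows = []
    for g in query_genes:
        fs, ns = _fraction(comp.matrix[strong_cols], g)
        fw, nw = _fraction(comp.matrix[weak_cols], g)
        rows.append((g, fs, ns, fw, nw, fs - fw))
    return pd.DataFrame(
        rows,
        columns=["gene", "strong_pct", "strong_basis", "weak_pct", "weak_basis", "diff"],
    )
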