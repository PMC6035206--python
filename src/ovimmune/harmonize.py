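"""Cohort merging and preservation-artefact handling.

Case samples in this analysis are FFPE (formalin-fixed paraffin-embedded)
while public control cohorts are fresh-frozen (FF).  Genes known to differ
between paired FFPE/FF samples are confounded with phenotype and must be
removed before any case-vs-control comparison.  This module merges
heterogeneous cohorts on their common gene set, strips a user-supplied
FFPE-affected gene list, quantile-normalizes the merged matrix, and reports
how strongly a differential-expression ranking overlaps the artefact list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PRESERVATIONS = ("FFPE", "FF")
PHENOTYPES = ("case", "control")

METADATA_COLUMNS = ("cohort", "preservation", "phenotype")


@dataclass
class ExpressionMatrix:
    """Log2 gene x sample expression with per-sample metadata.

    Parameters
    ----------
    values
        DataFrame of log2 expression, index = gene ids, columns = sample ids.
    metadata
        DataFrame indexed by sample id with columns ``cohort``,
        ``preservation`` (FFPE/FF) and ``phenotype`` (case/control).
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if v.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if not np.isfinite(v.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")
        missing = set(v.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"metadata missing for samples: {sorted(missing)[:5]}")
        for col in METADATA_COLUMNS:
            if col not in self.metadata.columns:
                raise ValueError(f"metadata lacks required column {col!r}")
        bad = set(self.metadata["preservation"]) - set(PRESERVATIONS)
        if bad:
            raise ValueError(f"unknown preservation labels: {bad}")
        bad = set(self.metadata["phenotype"]) - set(PHENOTYPES)
        if bad:
            raise ValueError(f"unknown phenotype labels: {bad}")
        # keep metadata aligned to the sample order of the value matrix
        self.metadata = self.metadata.loc[list(v.columns)]

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def phenotype_mask(self, phenotype: str) -> np.ndarray:
        return (self.metadata["phenotype"] == phenotype).to_numpy()

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        keep = [g for g in self.genes if g in set(genes)]
        return ExpressionMatrix(self.values.loc[keep], self.metadata.copy())


def merge_cohorts(matrices: Sequence[ExpressionMatrix]) -> ExpressionMatrix:
    """Merge cohorts on the intersection of their gene sets.

    Genes are intersected (sorted order), samples concatenated.  Raises on an
    empty gene intersection or duplicated sample ids across cohorts.
    """
    if len(matrices) < 2:
        raise ValueError("need at least two cohorts to merge")
    common: set[str] = set(matrices[0].genes)
    for m in matrices[1:]:
        common &= set(m.genes)
    if not common:
        raise ValueError("gene intersection across cohorts is empty")
    all_samples: list[str] = []
    for m in matrices:
        all_samples.extend(m.samples)
    if len(all_samples) != len(set(all_samples)):
        raise ValueError("duplicate sample ids across cohorts")
    genes = sorted(common)
    values = pd.concat([m.values.loc[genes] for m in matrices], axis=1)
    metadata = pd.concat([m.metadata for m in matrices], axis=0)
    return ExpressionMatrix(values, metadata)


def remove_preservation_genes(
    matrix: ExpressionMatrix, ffpe_list: Iterable[str]
) -> tuple[ExpressionMatrix, int]:
    """Drop genes known to differ between FFPE and FF preparations.

    Returns the filtered matrix and the number of genes removed.
    """
    ffpe = set(ffpe_list)
    keep = [g for g in matrix.genes if g not in ffpe]
    removed = matrix.n_genes - len(keep)
    if not keep:
        raise ValueError("removing preservation genes would leave zero genes")
    return ExpressionMatrix(matrix.values.loc[keep], matrix.metadata.copy()), removed


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the mean quantile distribution.

    After normalization each sample's sorted values equal the across-sample
    mean of sorted values; tied observations receive the mean of the quantile
    values their ranks span.  Idempotent and rank-preserving within samples.
    """
    if matrix.n_samples < 2:
        raise ValueError("quantile normalization needs at least two samples")
    x = matrix.values.to_numpy(dtype=float)
    n = x.shape[0]
    mean_quantiles = np.sort(x, axis=0).mean(axis=1)
    from scipy.stats import rankdata

    out = np.empty_like(x)
    positions = np.arange(1, n + 1, dtype=float)
    for j in range(x.shape[1]):
        ranks = rankdata(x[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, mean_quantiles)
    values = pd.DataFrame(out, index=matrix.genes, columns=matrix.samples)
    return ExpressionMatrix(values, matrix.metadata.copy())


def preservation_overlap_fraction(
    de_genes: Sequence[str], ffpe_list: Iterable[str], top_k: int
) -> float:
    """Percent of the top-``top_k`` DE genes that are FFPE-artefact genes.

    A high value indicates the differential signal is dominated by the
    preservation artefact rather than phenotype.
    """
    if top_k <= 0:
        raise ValueError("top_k must be positive")
    if top_k > len(de_genes):
        raise ValueError("top_k exceeds the length of the DE ranking")
    prefix = set(de_genes[:top_k])
    return 100.0 * len(prefix & set(ffpe_list)) / top_k
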