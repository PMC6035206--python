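"""Transcriptomic subtype scoring and consensus assignment.

Each subtype is represented by a marker gene set; samples are scored by
ssGSEA and the scores z-scaled within each subtype across samples so that
subtypes with different set sizes are comparable.  Several independent
scorers (e.g. different subtype gene-set collections) vote their argmax
subtype per sample and the majority wins, with ties broken by the highest
mean z-score — the consensus logic that makes multi-classifier subtype
calls robust.  A PCA of the score matrix and a leave-one-out
nearest-centroid phenotype classification serve as sanity checks that the
scores separate the biology they are supposed to.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta

from .gsea import DEFAULT_SSGSEA_WEIGHT, GeneSet, ssgsea_matrix
from .harmonize import ExpressionMatrix


@dataclass
class SubtypeAssignment:
    labels: pd.Series  # sample -> consensus subtype
    votes: pd.DataFrame  # sample x subtype vote counts
    margin: pd.Series  # best minus second-best mean z-score


def score_subtypes(
    matrix: ExpressionMatrix,
    subtype_sets: Sequence[GeneSet],
    weight: float = DEFAULT_SSGSEA_WEIGHT,
) -> pd.DataFrame:
    """ssGSEA score per sample per subtype, z-scaled within each subtype."""
    raw = ssgsea_matrix(matrix, subtype_sets, weight)
    return zscale_columns(raw)


def zscale_columns(scores: pd.DataFrame) -> pd.DataFrame:
    sd = scores.std(axis=0, ddof=1).replace(0.0, 1.0)
    return (scores - scores.mean(axis=0)) / sd


def assign_consensus(scores: Sequence[pd.DataFrame]) -> SubtypeAssignment:
    """Majority vote of per-scorer argmax subtypes.

    All scorers must cover the same samples and subtype labels (order
    free).  Ties are broken by the subtype with the highest mean z-score
    across scorers; the margin is best minus second-best mean z.
    """
    if not scores:
        raise ValueError("need at least one score matrix")
    ref_samples = set(scores[0].index)
    ref_labels = set(scores[0].columns)
    for s in scores[1:]:
        if set(s.index) != ref_samples or set(s.columns) != ref_labels:
            raise ValueError("scorers disagree on samples or subtype labels")
    samples = list(scores[0].index)
    labels = sorted(ref_labels)
    aligned = [s.loc[samples, labels] for s in scores]
    mean_z = sum(aligned) / len(aligned)

    votes = pd.DataFrame(0, index=samples, columns=labels, dtype=int)
    for s in aligned:
        for sample, label in s.idxmax(axis=1).items():
            votes.loc[sample, label] += 1

    consensus = {}
    for sample in samples:
        v = votes.loc[sample]
        top = v[v == v.max()].index
        if len(top) == 1:
            consensus[sample] = top[0]
        else:
            consensus[sample] = mean_z.loc[sample, list(top)].idxmax()
    ordered = np.sort(mean_z.to_numpy(), axis=1)
    margin = pd.Series(ordered[:, -1] - ordered[:, -2], index=samples)
    return SubtypeAssignment(
        labels=pd.Series(consensus), votes=votes, margin=margin
    )


def pca_scores(scores: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Centred SVD of the score matrix.

    Returns the component coordinates (samples x components) and the
    variance-explained fractions, non-increasing and summing to 1 over all
    components.
    """
    if scores.shape[0] < 2 or scores.shape[1] < 2:
        raise ValueError("need at least two samples and two score columns")
    x = scores.to_numpy(dtype=float)
    centred = x - x.mean(axis=0)
    if np.allclose(centred, 0):
        raise ValueError("score matrix is constant")
    u, s, _ = np.linalg.svd(centred, full_matrices=False)
    coords = pd.DataFrame(
        u * s,
        index=scores.index,
        columns=[f"PC{i + 1}" for i in range(s.size)],
    )
    explained = s**2 / (s**2).sum()
    return coords, explained


def classify_phenotype_loo(
    matrix: ExpressionMatrix, return_predictions: bool = False
):
    """Leave-one-out nearest-centroid phenotype classification.

    Each held-out sample is assigned the phenotype whose training-set
    centroid (on genes z-scaled with training-set statistics only) is
    nearest in Euclidean distance.  Returns accuracy in percent and the
    two-sided 95% Clopper-Pearson interval, also in percent (plus the
    per-sample predicted labels when ``return_predictions`` is set).
    """
    pheno = matrix.metadata["phenotype"]
    if pheno.nunique() < 2:
        raise ValueError("both phenotypes must be present")
    x = matrix.values.to_numpy(dtype=float)  # genes x samples
    labels = pheno.to_numpy()
    n = x.shape[1]
    correct = 0
    predictions = []
    for held in range(n):
        train = np.ones(n, dtype=bool)
        train[held] = False
        mu = x[:, train].mean(axis=1)
        sd = x[:, train].std(axis=1, ddof=1)
        sd[sd == 0] = 1.0
        z = (x - mu[:, None]) / sd[:, None]
        best_label, best_dist = None, np.inf
        for label in np.unique(labels[train]):
            centroid = z[:, train & (labels == label)].mean(axis=1)
            dist = float(np.linalg.norm(z[:, held] - centroid))
            if dist < best_dist:
                best_label, best_dist = label, dist
        predictions.append(best_label)
        if best_label == labels[held]:
            correct += 1
    accuracy = 100.0 * correct / n
    ci = tuple(100.0 * b for b in clopper_pearson(correct, n))
    if return_predictions:
        return accuracy, ci, pd.Series(predictions, index=matrix.samples)
    return accuracy, ci


def clopper_pearson(x: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval for x successes of n."""
    if not 0 <= x <= n or n <= 0:
        raise ValueError("need 0 <= x <= n with n > 0")
    lo = 0.0 if x == 0 else float(beta.ppf(alpha / 2, x, n - x + 1))
    hi = 1.0 if x == n else float(beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lo, hi
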