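"""Genomic clustering of a gene set.

Tests whether a gene list (e.g. differentially expressed genes) sits in
non-random genomic proximity: the statistic is the median distance from
each listed gene to its nearest listed neighbour on the same chromosome,
compared against random gene sets of the same size drawn from the
annotation universe.  A rainfall series (inter-gene distances along each
chromosome) and a sliding-window hotspot detector localize where the
clustering concentrates.

Distances are start-to-start and strand-agnostic.  Genes with no
same-chromosome partner in the set are excluded rather than given an
infinite distance, keeping the median finite.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import comb

ANNOTATION_COLUMNS = ("chrom", "start", "end", "strand")
EXHAUSTIVE_LIMIT = 10_000
DEFAULT_WINDOW = 1_000_000
MIN_HOTSPOT_SUPPORT = 3


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Check a gene annotation frame (index = gene id, 0-based half-open)."""
    for col in ("chrom", "start", "end"):
        if col not in annotation.columns:
            raise ValueError(f"annotation lacks column {col!r}")
    if annotation.index.has_duplicates:
        raise ValueError("duplicate gene ids in annotation")
    if (annotation["end"] <= annotation["start"]).any():
        raise ValueError("annotation intervals must satisfy end > start")
    if (annotation["chrom"].astype(str).str.len() == 0).any():
        raise ValueError("empty chromosome name")
    return annotation


@dataclass
class ClusterTest:
    observed: float  # median NN distance, bp
    null: np.ndarray  # null statistic draws
    p: float
    n_perm: int
    seed: int | None
    clustered: bool


@dataclass
class Hotspot:
    chrom: str
    start: int
    end: int
    observed: int
    expected: float
    ratio: float
    nearest_gene: str


def nn_median_distance(gene_set, annotation: pd.DataFrame) -> float:
    """Median start-to-start distance to the nearest same-set neighbour.

    Genes alone on their chromosome (within the set) are excluded.
    """
    sub = annotation.loc[annotation.index.intersection(set(gene_set))]
    if len(sub) < 2:
        raise ValueError("need at least two annotated genes in the set")
    dists: list[np.ndarray] = []
    for _, grp in sub.groupby("chrom"):
        if len(grp) < 2:
            continue
        starts = np.sort(grp["start"].to_numpy(dtype=float))
        gaps = np.diff(starts)
        nn = np.empty(starts.size)
        nn[0] = gaps[0]
        nn[-1] = gaps[-1]
        if starts.size > 2:
            nn[1:-1] = np.minimum(gaps[:-1], gaps[1:])
        dists.append(nn)
    if not dists:
        raise ValueError("no chromosome holds two or more set genes")
    return float(np.median(np.concatenate(dists)))


def _nn_median_from_arrays(chrom_codes: np.ndarray, starts: np.ndarray) -> float:
    """Fast path used by the permutation loop (pre-encoded annotation)."""
    order = np.lexsort((starts, chrom_codes))
    c = chrom_codes[order]
    s = starts[order]
    gaps = np.diff(s).astype(float)
    same = c[:-1] == c[1:]
    gaps[~same] = np.inf
    nn = np.full(s.size, np.inf)
    nn[:-1] = gaps
    nn[1:] = np.minimum(nn[1:], gaps)
    nn = nn[np.isfinite(nn)]
    if nn.size == 0:
        # a draw whose genes all sit alone on their chromosomes is maximally
        # dispersed; score it +inf so it never looks clustered
        return float("inf")
    return float(np.median(nn))


def permutation_null(
    annotation: pd.DataFrame,
    set_size: int,
    n_perm: int = 1000,
    seed: int | None = None,
    exhaustive: str = "auto",
) -> np.ndarray:
    """Null distribution of the median NN distance for random gene sets.

    Draws ``n_perm`` sets of ``set_size`` genes uniformly without
    replacement from the annotation; when the number of possible sets is
    small (<= 10,000) the full combinatorial distribution is enumerated
    instead of sampled (``exhaustive='auto'``; force with 'always'/'never').
    """
    validate_annotation(annotation)
    n_univ = len(annotation)
    if set_size > n_univ:
        raise ValueError("set_size exceeds the annotation universe")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    chrom_codes = pd.factorize(annotation["chrom"])[0]
    starts = annotation["start"].to_numpy(dtype=np.int64)

    n_comb = comb(n_univ, set_size, exact=True)
    do_exhaustive = exhaustive == "always" or (
        exhaustive == "auto" and n_comb <= EXHAUSTIVE_LIMIT
    )
    if do_exhaustive:
        values = [
            _nn_median_from_arrays(chrom_codes[list(idx)], starts[list(idx)])
            for idx in itertools.combinations(range(n_univ), set_size)
        ]
        return np.array(values)

    rng = np.random.default_rng(seed)
    out = np.empty(n_perm)
    for b in range(n_perm):
        idx = rng.choice(n_univ, size=set_size, replace=False)
        out[b] = _nn_median_from_arrays(chrom_codes[idx], starts[idx])
    return out


def clustering_test(
    gene_set,
    annotation: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
    exhaustive: str = "auto",
) -> ClusterTest:
    """Is the set's median NN distance smaller than random sets of its size?

    One-sided empirical p with the add-one rule; p can never reach zero.
    """
    observed = nn_median_distance(gene_set, annotation)
    usable = len(annotation.index.intersection(set(gene_set)))
    null = permutation_null(
        annotation, usable, n_perm=n_perm, seed=seed, exhaustive=exhaustive
    )
    p = (1.0 + int((null <= observed).sum())) / (1.0 + null.size)
    return ClusterTest(
        observed=observed,
        null=null,
        p=p,
        n_perm=null.size,
        seed=seed,
        clustered=p < alpha,
    )


def rainfall(gene_set, annotation: pd.DataFrame) -> pd.DataFrame:
    """Inter-gene distance series along each chromosome.

    Set genes are sorted by start per chromosome; each entry records the
    distance to the previous set gene (the first gene per chromosome is
    omitted).  Runs of small distances reveal clusters.
    """
    sub = annotation.loc[annotation.index.intersection(set(gene_set))]
    if len(sub) < 2:
        raise ValueError("need at least two annotated genes in the set")
    rows = []
    for chrom, grp in sub.sort_values("start").groupby("chrom", sort=True):
        starts = grp["start"].to_numpy(dtype=np.int64)
        genes = grp.index.to_numpy()
        for i in range(1, starts.size):
            rows.append(
                {
                    "chrom": chrom,
                    "gene": genes[i],
                    "position": int(starts[i]),
                    "distance": int(starts[i] - starts[i - 1]),
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "gene", "position", "distance"])


def detect_hotspot(
    gene_set,
    annotation: pd.DataFrame,
    window: int = DEFAULT_WINDOW,
    min_support: int = MIN_HOTSPOT_SUPPORT,
) -> Hotspot | None:
    """Highest-density window of set genes relative to background density.

    Half-overlapping windows slide along every chromosome; each window's
    expected count is the set size times the share of annotation genes in
    the window.  Returns the window maximizing observed/expected among
    windows holding at least ``min_support`` set genes, or ``None`` when no
    window reaches that support.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    validate_annotation(annotation)
    genes_in_set = annotation.index.intersection(set(gene_set))
    n_univ = len(annotation)
    n_set = len(genes_in_set)
    best: Hotspot | None = None
    step = max(window // 2, 1)
    for chrom, grp in annotation.groupby("chrom"):
        starts_all = np.sort(grp["start"].to_numpy(dtype=np.int64))
        set_grp = grp.loc[grp.index.isin(genes_in_set)]
        starts_set = np.sort(set_grp["start"].to_numpy(dtype=np.int64))
        if starts_set.size < min_support:
            continue
        hi = int(starts_all.max()) + window
        for wstart in range(0, hi, step):
            wend = wstart + window
            obs = int(
                np.searchsorted(starts_set, wend) - np.searchsorted(starts_set, wstart)
            )
            if obs < min_support:
                continue
            in_window = int(
                np.searchsorted(starts_all, wend) - np.searchsorted(starts_all, wstart)
            )
            expected = n_set * in_window / n_univ
            if expected <= 0:
                continue
            ratio = obs / expected
            if best is None or ratio > best.ratio:
                mid = (wstart + wend) / 2.0
                nearest = grp.index[(grp["start"] - mid).abs().argmin()]
                best = Hotspot(
                    chrom=str(chrom),
                    start=wstart,
                    end=wend,
                    observed=obs,
                    expected=expected,
                    ratio=ratio,
                    nearest_gene=str(nearest),
                )
    return best
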