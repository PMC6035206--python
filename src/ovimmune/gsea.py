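"""Gene-set scoring and enrichment.

Three engines used downstream:

* single-sample GSEA (ssGSEA): a per-sample, rank-based enrichment score
  for a gene set, used for immune/stromal scoring and subtype scoring;
* exact hypergeometric over-representation of one gene set in another;
* brain-structure enrichment of a differential-expression signature with a
  |logFC|-weighted score and max-statistic permutation control of the
  family-wise error rate across structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, rankdata

from .diffexpr import select_de
from .harmonize import ExpressionMatrix

DEFAULT_SSGSEA_WEIGHT = 0.75


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    @classmethod
    def from_iterable(cls, name: str, genes: Iterable[str]) -> "GeneSet":
        return cls(name, frozenset(str(g) for g in genes))

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class EnrichmentResult:
    """Upper-tail hypergeometric over-representation of target in query."""

    k: int  # overlap
    K: int  # target set size in universe
    n: int  # query size
    N: int  # universe size
    p: float
    q: float | None = None


def ssgsea_score(
    profile: pd.Series, gene_set: GeneSet, weight: float = DEFAULT_SSGSEA_WEIGHT
) -> float:
    """Single-sample enrichment score of ``gene_set`` in one profile.

    Genes are ordered by decreasing expression.  Walking down that list, an
    in-set cumulative distribution weighted by rank^weight (rank N for the
    highest gene, so the score depends on ranks only, never on the raw
    values) is compared with the unweighted out-of-set cumulative
    distribution; the score is the sum of their differences over all
    positions.  Positive scores mean the set is concentrated at the top.
    """
    if profile.size < 2:
        raise ValueError("profile needs at least two genes")
    in_set = profile.index.isin(gene_set.genes)
    n_in = int(in_set.sum())
    if n_in == 0:
        raise ValueError(f"gene set {gene_set.name!r} shares no genes with the profile")
    if n_in == profile.size:
        raise ValueError(f"gene set {gene_set.name!r} covers every profile gene")
    values = profile.to_numpy(dtype=float)
    ranks = rankdata(values, method="average")  # N = top
    order = np.argsort(-ranks, kind="stable")
    in_ordered = in_set[order]
    w = ranks[order] ** weight
    w_in = np.where(in_ordered, w, 0.0)
    p_in = np.cumsum(w_in) / w_in.sum()
    p_out = np.cumsum(~in_ordered) / (profile.size - n_in)
    return float(np.sum(p_in - p_out))


def ssgsea_matrix(
    matrix: ExpressionMatrix | pd.DataFrame,
    sets: Sequence[GeneSet],
    weight: float = DEFAULT_SSGSEA_WEIGHT,
) -> pd.DataFrame:
    """ssGSEA score for every sample (rows) and gene set (columns)."""
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    out = pd.DataFrame(
        index=values.columns, columns=[s.name for s in sets], dtype=float
    )
    for sample in values.columns:
        profile = values[sample]
        for s in sets:
            out.loc[sample, s.name] = ssgsea_score(profile, s, weight)
    return out


def hypergeom_enrich(
    query: GeneSet, target: GeneSet, universe: Iterable[str]
) -> EnrichmentResult:
    """Exact upper-tail hypergeometric test P(X >= k).

    ``query`` is the observed list (e.g. DE genes), ``target`` the annotated
    set (e.g. AIRE-regulated genes); both must lie inside ``universe``.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("universe is empty")
    if not query.genes <= uni or not target.genes <= uni:
        raise ValueError("query and target must be subsets of the universe")
    N = len(uni)
    K = len(target)
    n = len(query)
    k = len(query.genes & target.genes)
    p = float(hypergeom.sf(k - 1, N, K, n))  # exact P(X >= k)
    return EnrichmentResult(k=k, K=K, n=n, N=N, p=min(p, 1.0))


def structure_enrichment(
    de_table: pd.DataFrame,
    structure_map: Mapping[str, Iterable[str]],
    de_genes: Sequence[str] | None = None,
    n_perm: int = 1000,
    fwer: float = 0.05,
    seed: int | None = None,
    all_structures: bool = False,
) -> pd.DataFrame:
    """Which structures' gene sets are enriched for the DE signature?

    The observed score of a structure is the sum of |logFC| over DE genes
    in its set.  The null records, for each of ``n_perm`` random gene sets
    of the same size drawn from the table's universe, the maximum score
    across structures; comparing every structure against that max-statistic
    null controls the family-wise error rate.  Adjusted p-values use the
    add-one rule and can never be zero.

    Returns structures with adjusted p < ``fwer`` sorted by adjusted p
    (all structures when ``all_structures`` is set), as a DataFrame with
    columns ``structure``, ``score``, ``p_adj``, ``significant``.
    """
    if not structure_map:
        raise ValueError("structure_map is empty")
    if n_perm < 100:
        import warnings

        warnings.warn(f"n_perm={n_perm} gives a coarse FWER estimate", stacklevel=2)
    universe = list(de_table.index)
    if de_genes is None:
        de_genes = select_de(de_table)
    de_set = [g for g in de_genes if g in de_table.index]
    if not de_set:
        raise ValueError("DE gene set is empty")
    abs_lfc = de_table["logFC"].abs()

    names = list(structure_map)
    memberships = [set(structure_map[s]) for s in names]
    observed = np.array(
        [float(abs_lfc[[g for g in de_set if g in m]].sum()) for m in memberships]
    )

    rng = np.random.default_rng(seed)
    uni_arr = np.array(universe)
    lfc_arr = abs_lfc.to_numpy(dtype=float)
    member_masks = np.array(
        [[g in m for g in universe] for m in memberships]
    )  # structures x genes
    weighted = member_masks * lfc_arr  # structures x genes
    max_null = np.empty(n_perm)
    for b in range(n_perm):
        idx = rng.choice(uni_arr.size, size=len(de_set), replace=False)
        max_null[b] = weighted[:, idx].sum(axis=1).max()

    p_adj = (1.0 + (max_null[None, :] >= observed[:, None]).sum(axis=1)) / (1.0 + n_perm)
    result = pd.DataFrame(
        {
            "structure": names,
            "score": observed,
            "p_adj": p_adj,
            "significant": p_adj < fwer,
        }
    ).sort_values(["p_adj", "score"], ascending=[True, False], ignore_index=True)
    if all_structures:
        return result
    return result[result["significant"]].reset_index(drop=True)
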