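"""Motif ranking, rank-product aggregation across PSSM thresholds, consensus.

Each supervised co-inertia run yields signed motif loadings toward the
resistant pole; motifs are ranked per threshold (rank 1 = most
resistance-associated) and the per-threshold ranks are combined by the rank
product RP_m = (Π_t r_{m,t})^{1/T}.  Significance comes from the
permutation null in which every list is an independent uniform random
permutation of 1..M.  When the per-motif null space of rank profiles (M^T
combinations, all equally likely under full list permutations) fits within
the requested permutation budget, the null is enumerated exhaustively in
complete sweeps — exact at small scale and still reported through the
(1 + count) / (B + 1) estimator; otherwise the null is sampled.  The final
consensus is the overlap of the two comparisons' top-k lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .ordination import SupervisedCIAResult

log = logging.getLogger("tfcia")

_ENUM_LIMIT = 300_000  # largest M**T null space enumerated exhaustively


@dataclass
class RankedMotifList:
    """Motifs ranked by association with the resistant group at one threshold."""

    comparison: tuple[str, str]
    threshold: float | None
    ranks: pd.Series  # motif -> rank in 1..M (1 = most resistant-associated)

    def __post_init__(self) -> None:
        m = len(self.ranks)
        if sorted(self.ranks) != list(range(1, m + 1)):
            raise ValidationError("ranks must be a permutation of 1..M")


def rank_motifs(
    cia: SupervisedCIAResult, by_magnitude: bool = False
) -> RankedMotifList:
    """Rank motifs by descending signed loading toward the resistant pole.

    Ties break lexicographically by motif identifier.  ``by_magnitude=True``
    ranks by |loading| instead, for direction-agnostic discovery.
    """
    loadings = cia.motif_loadings
    key = loadings.abs() if by_magnitude else loadings
    order = sorted(loadings.index, key=lambda m: (-key[m], m))
    ranks = pd.Series(
        np.arange(1, len(order) + 1), index=order, name="rank"
    ).reindex(loadings.index)
    return RankedMotifList(cia.comparison, cia.threshold, ranks)


@dataclass
class RankProductResult:
    """Geometric-mean rank aggregation with permutation significance."""

    comparison: tuple[str, str]
    table: pd.DataFrame  # index motif; columns: RP, p, pfp, rank (p/pfp NaN if B=0)
    n_lists: int
    n_permutations: int

    def top(self, k: int) -> list[str]:
        if k > len(self.table):
            raise ValidationError(f"k={k} exceeds the {len(self.table)} ranked motifs")
        return list(self.table.sort_values(["rank"]).index[:k])


def _null_counts_exact(products: np.ndarray, m: int, t: int) -> np.ndarray:
    """#{rank profiles with Π ranks ≤ Π_m} over all M^T equally-likely profiles.

    Integer rank products compare exactly, so ties need no epsilon.
    """
    null = np.sort(
        [int(np.prod(combo, dtype=np.int64)) for combo in product(range(1, m + 1), repeat=t)]
    )
    return np.searchsorted(null, products, side="right")


def rank_product(
    lists: list[RankedMotifList],
    n_permutations: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> RankProductResult:
    """Combine T ranked lists by the rank product, with permutation p-values.

    RP_m is the geometric mean of motif m's T ranks.  With B = ``n_permutations``
    rounds of independent random list permutations, p_m = (1 + #{rounds with
    null RP_m ≤ RP_m}) / (B + 1); the estimated percentage of false
    predictions is pfp_m = p_m · M / rank(p_m).  When M^T ≤ B the null is
    enumerated in complete sweeps instead of sampled.  ``n_permutations=0``
    skips significance (RP and final ranks only).
    """
    if len(lists) < 2:
        raise ValidationError("rank_product needs at least two lists")
    motifs = list(lists[0].ranks.index)
    for lst in lists[1:]:
        if set(lst.ranks.index) != set(motifs):
            raise ValidationError("all ranked lists must cover the same motif set")
    t = len(lists)
    m = len(motifs)
    ranks = np.column_stack([lst.ranks.reindex(motifs).to_numpy() for lst in lists])
    rp = np.exp(np.log(ranks).mean(axis=1))

    order = sorted(range(m), key=lambda i: (rp[i], motifs[i]))
    final_rank = np.empty(m, dtype=int)
    final_rank[order] = np.arange(1, m + 1)

    p = np.full(m, np.nan)
    pfp = np.full(m, np.nan)
    if n_permutations > 0:
        products = ranks.astype(np.int64).prod(axis=1)
        n_profiles = m**t
        if n_profiles <= min(n_permutations, _ENUM_LIMIT):
            sweeps = n_permutations // n_profiles
            b_eff = sweeps * n_profiles
            counts = sweeps * _null_counts_exact(products, m, t)
            log.info(
                "rank product null enumerated exhaustively (%d sweeps of %d profiles)",
                sweeps, n_profiles,
            )
        else:
            rng = np.random.default_rng(rng)
            b_eff = n_permutations
            counts = np.zeros(m, dtype=int)
            for _ in range(n_permutations):
                null_ranks = np.empty((m, t), dtype=np.int64)
                for j in range(t):
                    null_ranks[rng.permutation(m), j] = np.arange(1, m + 1)
                counts += null_ranks.prod(axis=1) <= products
        p = (1.0 + counts) / (b_eff + 1.0)
        p_rank = stats.rankdata(p, method="max")
        pfp = p * m / p_rank

    table = pd.DataFrame(
        {"RP": rp, "p": p, "pfp": pfp, "rank": final_rank}, index=pd.Index(motifs, name="motif")
    )
    return RankProductResult(
        comparison=lists[0].comparison,
        table=table.sort_values("rank"),
        n_lists=t,
        n_permutations=n_permutations,
    )


@dataclass
class ConsensusTFList:
    """Motifs in the top-k of both comparisons' rank-product lists."""

    motifs: list[str]  # ordered by the sum of the two final ranks
    k: int
    table: pd.DataFrame  # motif, rank/RP in each comparison, rank sum


def consensus(
    rp_a: RankProductResult, rp_b: RankProductResult, k: int = 20
) -> ConsensusTFList:
    """Overlap of the two comparisons' top-k lists, ordered by rank sum."""
    if set(rp_a.table.index) != set(rp_b.table.index):
        raise ValidationError("consensus requires a common motif universe")
    top_a, top_b = set(rp_a.top(k)), set(rp_b.top(k))
    shared = top_a & top_b
    if not shared:
        log.warning("consensus is empty: the two top-%d lists are disjoint", k)
    rows = []
    for motif in shared:
        ra = int(rp_a.table.loc[motif, "rank"])
        rb = int(rp_b.table.loc[motif, "rank"])
        rows.append(
            {
                "motif": motif,
                "rank_a": ra,
                "rank_b": rb,
                "RP_a": float(rp_a.table.loc[motif, "RP"]),
                "RP_b": float(rp_b.table.loc[motif, "RP"]),
                "rank_sum": ra + rb,
            }
        )
    cols = ["motif", "rank_a", "rank_b", "RP_a", "RP_b", "rank_sum"]
    table = pd.DataFrame(rows, columns=cols).sort_values(
        ["rank_sum", "motif"]
    ).reset_index(drop=True)
    return ConsensusTFList(motifs=list(table["motif"]), k=k, table=table)
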