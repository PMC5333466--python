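"""Duality-diagram ordinations coupling expression with motif counts.

Non-symmetric correspondence analysis (NSCA) decomposes the asymmetric
dependence of gene rows on sample or motif columns: with P the table scaled
to unit grand total, row masses r_i and column masses c_j, the transformed
table holds q_ij = p_ij / c_j − r_i (column profiles centered by the average
profile) and is decomposed by an SVD with columns weighted by sqrt(c_j).
The total inertia Σ_j c_j Σ_i q_ij² is the numerator of Goodman–Kruskal's
tau with columns as predictors, and equals the sum of eigenvalues.

Co-inertia analysis (CIA) couples two such ordinations that share gene rows,
finding paired axes maximizing squared covariance of the gene scores; the RV
coefficient summarizes the coupling on [0, 1].  For the coupling both tables
are re-expressed with uniform gene weights — uniform both in the cross
product metric and in the profile centering — because the two tables'
natural row masses differ and the coupled triplets must share one row
metric.

Between-group analysis (BGA) ordinates the table of group-mean columns with
the same NSCA transform (at most K−1 axes for K groups) and projects the
original samples supplementarily; the supervised CIA couples the BGA-reduced
expression side of one pairwise comparison with a motif table and orients
the single discriminating axis so the resistant group sits on the positive
pole.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import NumericalError, ValidationError

_RANK_RTOL = 1e-12


@dataclass
class Ordination:
    """A decomposed duality-diagram triplet (table, row weights, col weights)."""

    Q: pd.DataFrame  # transformed table, genes as rows
    row_weights: np.ndarray  # d_i, sums to 1
    col_weights: np.ndarray  # c_j (column masses)
    eigenvalues: np.ndarray  # all nonzero-rank eigenvalues, non-increasing
    row_scores: pd.DataFrame  # gene coordinates, retained axes
    col_scores: pd.DataFrame  # sample/motif coordinates, retained axes
    total_inertia: float
    centering: str  # "mass" or "uniform"

    @property
    def n_axes(self) -> int:
        return self.row_scores.shape[1]


def _as_frame(table) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        return table
    # duck-type the package containers
    for attr in ("values", "counts"):
        inner = getattr(table, attr, None)
        if isinstance(inner, pd.DataFrame):
            return inner
    return pd.DataFrame(np.asarray(table, dtype=float))


def nsca(table, n_axes: int = 5, centering: str = "mass") -> Ordination:
    """Non-symmetric correspondence analysis of a non-negative table.

    ``centering='mass'`` centers column profiles by the row masses r_i (the
    canonical transform, rows unweighted in the metric); ``'uniform'``
    re-expresses the triplet with uniform gene weights (centering by the
    unweighted mean profile, rows weighted 1/n), the form used for coupling.
    """
    df = _as_frame(table)
    x = df.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValidationError("NSCA requires a non-negative table")
    total = x.sum()
    if total <= 0:
        raise NumericalError("NSCA requires a nonzero grand total")
    col_sums = x.sum(axis=0)
    if (col_sums == 0).any():
        j = int(np.argmax(col_sums == 0))
        raise NumericalError(
            f"column {df.columns[j]!r} is all zero; its profile is undefined"
        )
    n = x.shape[0]
    p = x / total
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    profiles = p / c
    if centering == "mass":
        q = profiles - r[:, None]
        w_row = r  # natural masses, reported; the SVD metric leaves rows unweighted
        sqrt_row = np.ones(n)
        m = q * np.sqrt(c)
    elif centering == "uniform":
        q = profiles - profiles.mean(axis=0)
        w_row = np.full(n, 1.0 / n)
        sqrt_row = np.sqrt(w_row)
        m = (q * np.sqrt(c)) * sqrt_row[:, None]
    else:
        raise ValidationError(f"unknown centering {centering!r}")
    u, s, vt = np.linalg.svd(m, full_matrices=False)
    rank = int(np.sum(s > s[0] * _RANK_RTOL)) if s.size and s[0] > 0 else 0
    eigenvalues = s[:rank] ** 2
    k = min(n_axes, rank)
    u_k, s_k, v_k = u[:, :k], s[:k], vt[:k].T
    # deterministic orientation: the largest-|loading| column element positive
    for a in range(k):
        j = int(np.argmax(np.abs(v_k[:, a])))
        if v_k[j, a] < 0:
            v_k[:, a] = -v_k[:, a]
            u_k[:, a] = -u_k[:, a]
    axes = [f"axis{a + 1}" for a in range(k)]
    with np.errstate(divide="ignore", invalid="ignore"):
        row_coords = (u_k / sqrt_row[:, None]) * s_k
        col_coords = (v_k / np.sqrt(c)[:, None]) * s_k
    return Ordination(
        Q=pd.DataFrame(q, index=df.index, columns=df.columns),
        row_weights=w_row,
        col_weights=c,
        eigenvalues=eigenvalues,
        row_scores=pd.DataFrame(row_coords, index=df.index, columns=axes),
        col_scores=pd.DataFrame(col_coords, index=df.columns, columns=axes),
        total_inertia=float((s**2).sum()),
        centering=centering,
    )


def nsca_inertia_direct(table) -> float:
    """Brute-force Goodman–Kruskal inertia Σ_j c_j Σ_i (p_ij/c_j − r_i)².

    Independent of the SVD path; used to check inertia conservation.
    """
    x = _as_frame(table).to_numpy(dtype=float)
    p = x / x.sum()
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    q = p / c - r[:, None]
    return float((c * (q**2).sum(axis=0)).sum())


def _weighted_table(ord_: Ordination) -> np.ndarray:
    return ord_.Q.to_numpy() * np.sqrt(ord_.col_weights)


def _check_coupled(ord_a: Ordination, ord_b: Ordination) -> None:
    if list(ord_a.Q.index) != list(ord_b.Q.index):
        raise ValidationError("coupled ordinations must share row identifiers and order")
    if not np.allclose(ord_a.row_weights, ord_b.row_weights):
        raise ValidationError("coupled ordinations must share row weights")
    # near-zero inertia (e.g. a constant table leaving only rounding residue)
    # makes the RV normalization meaningless
    if ord_a.total_inertia <= 1e-20 or ord_b.total_inertia <= 1e-20:
        raise NumericalError("cannot couple a zero-inertia ordination")


@dataclass
class CoinertiaResult:
    """Paired-axis decomposition of the cross-covariance of two tables."""

    left_loadings: pd.DataFrame  # table-A columns x axes
    right_loadings: pd.DataFrame  # table-B columns x axes
    singular_values: np.ndarray
    total_coinertia: float
    rv: float
    row_scores_a: pd.DataFrame  # gene projections, A side
    row_scores_b: pd.DataFrame


def _cross_product(ord_a: Ordination, ord_b: Ordination) -> np.ndarray:
    a_w, b_w = _weighted_table(ord_a), _weighted_table(ord_b)
    d = ord_a.row_weights
    return a_w.T @ (d[:, None] * b_w)


def coinertia(ord_a: Ordination, ord_b: Ordination, n_axes: int = 5) -> CoinertiaResult:
    """Co-inertia decomposition of two ordinations sharing gene rows.

    Decomposes Z = A_wᵀ D B_w; total co-inertia is ‖Z‖²_F and the RV
    coefficient normalizes it by the self-co-inertias, so RV(A, A) = 1.
    """
    _check_coupled(ord_a, ord_b)
    z = _cross_product(ord_a, ord_b)
    zaa = _cross_product(ord_a, ord_a)
    zbb = _cross_product(ord_b, ord_b)
    total = float((z**2).sum())
    denom = np.sqrt(float((zaa**2).sum()) * float((zbb**2).sum()))
    if denom <= 0:
        raise NumericalError("cannot couple a zero-inertia ordination")
    rv = float(np.clip(total / denom, 0.0, 1.0))
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    rank = int(np.sum(s > s[0] * _RANK_RTOL)) if s.size and s[0] > 0 else 0
    k = min(n_axes, rank)
    u_k, s_k, v_k = u[:, :k], s[:k], vt[:k].T
    for a in range(k):
        j = int(np.argmax(np.abs(v_k[:, a])))
        if v_k[j, a] < 0:
            v_k[:, a] = -v_k[:, a]
            u_k[:, a] = -u_k[:, a]
    axes = [f"axis{a + 1}" for a in range(k)]
    a_w, b_w = _weighted_table(ord_a), _weighted_table(ord_b)
    return CoinertiaResult(
        left_loadings=pd.DataFrame(u_k * s_k, index=ord_a.Q.columns, columns=axes),
        right_loadings=pd.DataFrame(v_k * s_k, index=ord_b.Q.columns, columns=axes),
        singular_values=s[:rank],
        total_coinertia=total,
        rv=rv,
        row_scores_a=pd.DataFrame(a_w @ u_k, index=ord_a.Q.index, columns=axes),
        row_scores_b=pd.DataFrame(b_w @ v_k, index=ord_b.Q.index, columns=axes),
    )


def rv_permutation_test(
    ord_a: Ordination,
    ord_b: Ordination,
    n_permutations: int = 999,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float, np.ndarray]:
    """Monte-Carlo p-value for the RV coefficient under row permutations.

    Rows of table B are permuted jointly (the self-co-inertias are invariant
    under a permutation, so only the cross term is recomputed);
    p = (1 + #{null RV ≥ observed}) / (B + 1).
    """
    _check_coupled(ord_a, ord_b)
    rng = np.random.default_rng(rng)
    a_w, b_w = _weighted_table(ord_a), _weighted_table(ord_b)
    d = ord_a.row_weights
    if not np.allclose(d, d[0]):
        raise ValidationError("RV permutation test requires uniform row weights")
    zaa = _cross_product(ord_a, ord_a)
    zbb = _cross_product(ord_b, ord_b)
    denom = np.sqrt(float((zaa**2).sum()) * float((zbb**2).sum()))
    a_wd = d[:, None] * a_w
    observed = float(((a_wd.T @ b_w) ** 2).sum()) / denom
    null = np.empty(n_permutations)
    n = a_w.shape[0]
    for b in range(n_permutations):
        perm = rng.permutation(n)
        null[b] = float(((a_wd.T @ b_w[perm]) ** 2).sum()) / denom
    p = (1.0 + np.sum(null >= observed)) / (n_permutations + 1.0)
    return observed, float(p), null


@dataclass
class BGAResult:
    """Supervised ordination of group-mean profiles."""

    ordination: Ordination  # NSCA of the gene x group-mean table
    group_centroids: pd.DataFrame  # groups x axes
    sample_scores: pd.DataFrame  # supplementary sample projections
    between_ratio: float  # between-group / total inertia

    @property
    def n_axes(self) -> int:
        return self.ordination.n_axes


def group_mean_table(table, group_of: dict[str, str]) -> pd.DataFrame:
    df = _as_frame(table)
    missing = [s for s in df.columns if s not in group_of]
    if missing:
        raise ValidationError(f"sample {missing[0]!r} has no group label")
    groups: dict[str, list[str]] = {}
    for s in df.columns:
        groups.setdefault(group_of[s], []).append(s)
    empty = [g for g, ss in groups.items() if not ss]
    if empty:
        raise ValidationError(f"group {empty[0]!r} has zero samples")
    return pd.DataFrame({g: df[ss].mean(axis=1) for g, ss in groups.items()})


def bga(table, group_of: dict[str, str], n_axes: int | None = None) -> BGAResult:
    """Between-group analysis: NSCA of the per-group mean columns.

    Yields at most K−1 discriminating axes for K groups; the original sample
    columns are projected supplementarily onto those axes, and the ratio of
    the group-mean-table inertia to the full-table inertia summarizes how
    much structure the grouping explains.
    """
    df = _as_frame(table)
    means = group_mean_table(df, group_of)
    n_groups = means.shape[1]
    if n_groups < 2:
        raise ValidationError("BGA needs at least two groups")
    k = n_groups - 1 if n_axes is None else min(n_axes, n_groups - 1)
    ord_means = nsca(means, n_axes=k, centering="mass")
    total = nsca_inertia_direct(df)
    between = ord_means.total_inertia
    # supplementary projection: center each sample's profile by the BGA row
    # masses and read its coordinate against the row axes (u_k . q_sample)
    x = df.to_numpy(dtype=float)
    col_sums = x.sum(axis=0)
    if (col_sums == 0).any():
        j = int(np.argmax(col_sums == 0))
        raise NumericalError(f"sample column {df.columns[j]!r} is all zero")
    profiles = x / col_sums
    q_sup = profiles - ord_means.row_weights[:, None]
    # recover u_k from row scores (mass centering: row coords = u s)
    s_k = np.sqrt(ord_means.eigenvalues[: ord_means.n_axes])
    u_k = ord_means.row_scores.to_numpy() / s_k
    coords = q_sup.T @ u_k
    axes = list(ord_means.row_scores.columns)
    return BGAResult(
        ordination=ord_means,
        group_centroids=ord_means.col_scores.copy(),
        sample_scores=pd.DataFrame(coords, index=df.columns, columns=axes),
        between_ratio=float(between / total) if total > 0 else 0.0,
    )


@dataclass
class SupervisedCIAResult:
    """One oriented discriminating axis coupling expression contrast to motifs."""

    comparison: tuple[str, str]  # (parental, resistant)
    threshold: float | None
    motif_loadings: pd.Series  # signed, resistant pole positive
    group_coordinates: pd.Series  # the two group centroids on the paired axis
    singular_value: float
    rv: float


def supervised_cia(
    expr_table,
    group_of: dict[str, str],
    motif_table,
    comparison: tuple[str, str],
    threshold: float | None = None,
) -> SupervisedCIAResult:
    """BGA-constrained co-inertia for one resistant-vs-parental comparison.

    The expression side is reduced to the two groups' mean columns, both
    sides are re-expressed with uniform gene weights, and their co-inertia
    axis is oriented so the resistant centroid has a positive coordinate.
    The signed motif loadings on that axis rank motifs by association with
    the resistant state.
    """
    parental, resistant = comparison
    df = _as_frame(expr_table)
    present = {group_of.get(s) for s in df.columns}
    for g in comparison:
        if g not in present:
            raise ValidationError(f"comparison group {g!r} has no samples")
    keep = [s for s in df.columns if group_of[s] in comparison]
    means = group_mean_table(df[keep], {s: group_of[s] for s in keep})
    means = means[[parental, resistant]]
    motifs = _as_frame(motif_table)
    if list(means.index) != list(motifs.index):
        raise ValidationError("expression and motif tables must share gene rows")
    ord_a = nsca(means, n_axes=1, centering="uniform")
    ord_b = nsca(motifs, n_axes=1, centering="uniform")
    cia = coinertia(ord_a, ord_b, n_axes=1)
    u = cia.left_loadings["axis1"]
    v = cia.right_loadings["axis1"]
    if u[resistant] - u[parental] < 0:
        u, v = -u, -v
    return SupervisedCIAResult(
        comparison=comparison,
        threshold=threshold,
        motif_loadings=v.rename("loading"),
        group_coordinates=u,
        singular_value=float(cia.singular_values[0]) if cia.singular_values.size else 0.0,
        rv=cia.rv,
    )
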