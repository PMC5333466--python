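"""Moderated differential expression between resistant and parental groups.

The chain is the classic microarray one: quantile-normalize the log-scale
matrix so all sample columns share the mean empirical distribution, fit a
per-gene two-group mean difference with pooled variance, shrink the gene
variances toward a scaled-F prior estimated from all genes by moment
matching on log-variances (the empirical-Bayes moderated t), convert to
two-sided p-values on d_g + d0 degrees of freedom, control FDR with
Benjamini-Hochberg, and keep the genes significant in BOTH
resistant-vs-parental comparisons with the same direction ("consistent
overlap").

The moderated-t hyperparameter fit follows the standard moment-matching on
z_g = log s²_g:

    E[z_g]  = log s0² + ψ(d0/2) − log(d0/2) + ψ(d_g/2) − log(d_g/2) ... (prior + sampling parts)
    Var[z_g] = ψ'(d_g/2) + ψ'(d0/2)

so d0 comes from a trigamma inversion of the excess variance of z and s0²
from the corrected mean.  When the observed log-variances are under-dispersed
relative to pure sampling noise the inversion has no solution; d0 is then set
to infinity (full shrinkage to s0²) with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix
from .errors import NumericalError, ValidationError

log = logging.getLogger("tfcia")


def quantile_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto the mean empirical distribution.

    Each column's order statistics are replaced by the across-sample mean of
    the order statistics; ties within a column receive the average of their
    tied target positions, so within-column rank order is preserved.
    """
    values = expr.values.to_numpy(dtype=float)
    n_genes, n_samples = values.shape
    if n_samples < 2:
        raise ValidationError("quantile normalization needs ≥ 2 samples")
    mean_sorted = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    positions = np.arange(1, n_genes + 1, dtype=float)
    for j in range(n_samples):
        ranks = stats.rankdata(values[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, mean_sorted)
    return ExpressionMatrix(
        pd.DataFrame(out, index=expr.values.index, columns=expr.values.columns),
        dict(expr.group_of),
    )


@dataclass
class GroupFit:
    """Per-gene two-group fit: mean difference and pooled variance."""

    comparison: tuple[str, str]  # (reference/parental, test/resistant)
    genes: list[str]
    log_fc: np.ndarray  # test − reference, log scale
    s2: np.ndarray  # pooled within-group variance
    df_residual: float  # n_A + n_B − 2
    n_a: int
    n_b: int


def fit_group_model(expr: ExpressionMatrix, comparison: tuple[str, str]) -> GroupFit:
    """Per-gene mean difference (B − A) with pooled within-group variance."""
    group_a, group_b = comparison
    for g in comparison:
        if g not in set(expr.group_of.values()):
            raise ValidationError(f"group {g!r} absent from expression annotations")
    xa = expr.values[expr.samples_in(group_a)].to_numpy(dtype=float)
    xb = expr.values[expr.samples_in(group_b)].to_numpy(dtype=float)
    n_a, n_b = xa.shape[1], xb.shape[1]
    if min(n_a, n_b) < 2:
        raise ValidationError(f"both groups in {comparison} need ≥ 2 replicates")
    beta = xb.mean(axis=1) - xa.mean(axis=1)
    ss = ((xa - xa.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (xb - xb.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    df = n_a + n_b - 2
    return GroupFit(comparison, expr.gene_ids, beta, ss / df, float(df), n_a, n_b)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the reciprocal scale)."""
    if y <= 0:
        raise NumericalError("trigamma inverse undefined for non-positive values")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if -dif / x < 1e-8:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0²) of the scaled-F variance prior from log s².

    Returns ``d0 = inf`` when the log-variances are under-dispersed relative
    to the pure-sampling trigamma term (no finite prior fits).
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if positive.size == 0:
        raise NumericalError("all residual variances are zero; no prior estimable")
    if positive.size < 10:
        raise ValidationError("need ≥ 10 genes with positive variance to estimate the prior")
    z = np.log(positive)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        log.warning("log-variances under-dispersed; setting prior df d0 = inf")
        d0 = np.inf
        s0_sq = np.exp(emean)
    return float(d0), float(s0_sq)


@dataclass
class DEResult:
    """Moderated test results for one two-group comparison."""

    comparison: tuple[str, str]
    genes: list[str]
    log_fc: np.ndarray
    s2: np.ndarray
    df_residual: float
    d0: float
    s0_sq: float
    s2_post: np.ndarray  # moderated variance
    t: np.ndarray  # moderated t statistic
    p: np.ndarray
    adj_p: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.genes,
                "comparison": f"{self.comparison[0]}_vs_{self.comparison[1]}",
                "logFC": self.log_fc,
                "t": self.t,
                "P": self.p,
                "adjP": self.adj_p,
            }
        )


def ebayes_moderate(fit: GroupFit, d0: float | None = None, s0_sq: float | None = None) -> DEResult:
    """Shrink per-gene variances toward the estimated prior and test.

    ``d0``/``s0_sq`` may be supplied to bypass estimation (``d0=0`` recovers
    the ordinary pooled t; ``d0=inf`` tests against s0² alone).
    """
    if d0 is None or s0_sq is None:
        est_d0, est_s0 = estimate_prior(fit.s2, fit.df_residual)
        d0 = est_d0 if d0 is None else d0
        s0_sq = est_s0 if s0_sq is None else s0_sq
    df = fit.df_residual
    if np.isinf(d0):
        s2_post = np.full_like(fit.s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df * fit.s2) / (d0 + df)
        df_total = df + d0
    stderr = np.sqrt(s2_post * (1.0 / fit.n_a + 1.0 / fit.n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(stderr > 0, fit.log_fc / np.where(stderr > 0, stderr, 1.0), 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return DEResult(
        comparison=fit.comparison,
        genes=fit.genes,
        log_fc=fit.log_fc,
        s2=fit.s2,
        df_residual=df,
        d0=float(d0),
        s0_sq=float(s0_sq),
        s2_post=s2_post,
        t=t,
        p=p,
        adj_p=bh_adjust(p),
    )


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def moderated_comparison(
    expr: ExpressionMatrix, comparison: tuple[str, str]
) -> DEResult:
    """Convenience: fit + moderate + adjust for one comparison."""
    return ebayes_moderate(fit_group_model(expr, comparison))


@dataclass
class ConsensusGenes:
    """Genes differential in both comparisons, split by shared direction."""

    up: list[str]
    down: list[str]

    @property
    def genes(self) -> list[str]:
        return self.up + self.down


def consistent_overlap(
    de_a: DEResult,
    de_b: DEResult,
    cutoff: float = 0.01,
    require_sign_concordance: bool = True,
) -> ConsensusGenes:
    """Genes with adjusted P < cutoff in BOTH comparisons (and same sign).

    The direction requirement is the default reading of "consistent"; set
    ``require_sign_concordance=False`` for joint significance alone (such
    genes are partitioned by their direction in the first comparison).
    """
    if de_a.genes != de_b.genes:
        raise ValidationError("consistent_overlap requires identical gene universes")
    sig = (de_a.adj_p < cutoff) & (de_b.adj_p < cutoff)
    same_sign = np.sign(de_a.log_fc) == np.sign(de_b.log_fc)
    keep = sig & (same_sign if require_sign_concordance else True)
    up = [g for g, k, fc in zip(de_a.genes, keep, de_a.log_fc) if k and fc > 0]
    down = [g for g, k, fc in zip(de_a.genes, keep, de_a.log_fc) if k and fc < 0]
    return ConsensusGenes(up=up, down=down)
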