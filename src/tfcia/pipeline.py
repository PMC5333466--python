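"""End-to-end orchestration of the discovery and clinical arms.

Discovery: quantile-normalize the expression matrix, run the two
resistant-vs-parental moderated comparisons and their consistent overlap,
run unsupervised co-inertia at the strictest PSSM threshold for data
exploration, then for each comparison run the supervised (BGA-constrained)
co-inertia at every threshold, rank motifs per threshold, aggregate with
rank products, and intersect the two comparisons' top-k lists into the
final consensus.  Clinical: site positivity, contingency tests of score
class vs site type, Spearman correlations and Kaplan-Meier / log-rank
survival comparisons of the dichotomized patients.

All randomness (rank-product permutations) derives from the single run
seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clinical as clin
from . import diffexpr, io, ranking
from .containers import ClinicalTable, ExpressionMatrix, GeneMotifTable
from .errors import ValidationError
from .ordination import CoinertiaResult, SupervisedCIAResult, coinertia, nsca, supervised_cia


@dataclass
class DiscoveryResult:
    config: io.RunConfig
    normalized: ExpressionMatrix
    de: dict[str, diffexpr.DEResult]  # resistant group -> result
    overlap: diffexpr.ConsensusGenes
    unsupervised: CoinertiaResult
    unsupervised_threshold: float
    supervised: dict[tuple[str, float], SupervisedCIAResult]
    ranked_lists: dict[str, list[ranking.RankedMotifList]]
    rank_products: dict[str, ranking.RankProductResult]
    consensus: ranking.ConsensusTFList


def run_discovery(
    expr: ExpressionMatrix,
    motif_tables: list[GeneMotifTable],
    config: io.RunConfig,
) -> DiscoveryResult:
    if not motif_tables:
        raise ValidationError("no motif tables supplied")
    groups = set(expr.group_of.values())
    if config.parental_group not in groups:
        raise ValidationError(f"parental group {config.parental_group!r} has no samples")
    resistant = [g for g in config.resistant_groups if g in groups]
    if len(resistant) < 2:
        raise ValidationError("need two resistant groups for the overlap consensus")

    # align everything to the common gene set, lexicographic order
    expr, loosest = io.align_to_expression(expr, motif_tables[0])
    tables = [loosest] + [t.subset_genes(loosest.gene_ids) for t in motif_tables[1:]]

    norm = diffexpr.quantile_normalize(expr)

    de = {
        g: diffexpr.moderated_comparison(norm, (config.parental_group, g))
        for g in resistant
    }
    overlap = diffexpr.consistent_overlap(
        de[resistant[0]],
        de[resistant[1]],
        cutoff=config.adj_p_cutoff,
        require_sign_concordance=config.require_sign_concordance,
    )

    strictest = tables[-1]
    ord_expr = nsca(norm.values, n_axes=config.n_axes, centering="uniform")
    ord_motif = nsca(strictest.counts, n_axes=config.n_axes, centering="uniform")
    unsupervised = coinertia(ord_expr, ord_motif, n_axes=config.n_axes)

    supervised: dict[tuple[str, float], SupervisedCIAResult] = {}
    ranked: dict[str, list[ranking.RankedMotifList]] = {}
    for g in resistant:
        lists = []
        for table in tables:
            sup = supervised_cia(
                norm.values, norm.group_of, table.counts,
                (config.parental_group, g), table.threshold,
            )
            supervised[(g, table.threshold)] = sup
            lists.append(ranking.rank_motifs(sup))
        ranked[g] = lists

    seeds = np.random.SeedSequence(config.seed).spawn(len(resistant))
    rank_products = {
        g: ranking.rank_product(
            ranked[g], n_permutations=config.rank_product_permutations,
            rng=np.random.default_rng(s),
        )
        for g, s in zip(resistant, seeds)
    }
    cons = ranking.consensus(
        rank_products[resistant[0]], rank_products[resistant[1]], k=config.consensus_k
    )
    return DiscoveryResult(
        config=config,
        normalized=norm,
        de=de,
        overlap=overlap,
        unsupervised=unsupervised,
        unsupervised_threshold=strictest.threshold,
        supervised=supervised,
        ranked_lists=ranked,
        rank_products=rank_products,
        consensus=cons,
    )


def consensus_frame(
    result: DiscoveryResult, descriptions: dict[str, str] | None = None
) -> pd.DataFrame:
    """Consensus list with supporting DE evidence for the motif's own transcript.

    Columns mirror a published TF table: symbol, description, log
    fold-change and P-value (left missing when no matching transcript is in
    the expression matrix).
    """
    descriptions = descriptions or {}
    de_frames = {g: d.to_frame().set_index("gene") for g, d in result.de.items()}
    first_group = next(iter(de_frames))
    rows = []
    for motif in result.consensus.motifs:
        fc = pval = np.nan
        if motif in de_frames[first_group].index:
            fc = float(de_frames[first_group].loc[motif, "logFC"])
            pval = float(de_frames[first_group].loc[motif, "adjP"])
        rows.append(
            {
                "Symbol": motif,
                "Description": descriptions.get(motif, ""),
                "logFC": fc,
                "P-Value": pval,
            }
        )
    return pd.DataFrame(rows, columns=["Symbol", "Description", "logFC", "P-Value"])


def write_discovery(result: DiscoveryResult, outdir: str | Path) -> list[Path]:
    """Write DE tables, projections, rankings, rank products and consensus."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _w(df: pd.DataFrame, name: str, index_label: str | None = None) -> None:
        path = outdir / name
        io.write_table(df, path, index_label=index_label)
        written.append(path)

    for g, d in result.de.items():
        _w(d.to_frame(), f"de_{result.config.parental_group}_vs_{g}.tsv")
    _w(
        pd.DataFrame(
            {
                "gene": result.overlap.genes,
                "direction": ["up"] * len(result.overlap.up)
                + ["down"] * len(result.overlap.down),
            }
        ),
        "consistent_overlap_genes.tsv",
    )
    _w(result.unsupervised.row_scores_a, "cia_gene_scores_expression.tsv", "gene")
    _w(result.unsupervised.left_loadings, "cia_sample_projections.tsv", "sample")
    _w(result.unsupervised.right_loadings, "cia_motif_projections.tsv", "motif")
    for (g, thr), sup in result.supervised.items():
        _w(
            sup.motif_loadings.to_frame(),
            f"supervised_loadings_{g}_t{thr:.2f}.tsv",
            "motif",
        )
    for g, rp in result.rank_products.items():
        _w(rp.table, f"rank_product_{g}.tsv", "motif")
    _w(consensus_frame(result), "consensus_tf_list.tsv")
    manifest = {
        "outputs": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in written
        },
        "seed": result.config.seed,
    }
    written.append(io.write_run_metadata(outdir, result.config, manifest))
    return written


@dataclass
class ClinicalReport:
    positivity: pd.DataFrame
    site_type_table: np.ndarray  # 2x2: rows bone/soft, cols high/low
    chi2_stat: float
    chi2_p: float
    fisher_p: float
    spearman_by_baseline: dict[str, float]
    survival: dict[str, clin.SurvivalComparison]
    summaries: list[clin.PatientSummary] = field(repr=False)


def run_clinical(
    clinical: ClinicalTable,
    docetaxel_treated: bool | None = True,
    compartment: str = "bone",
) -> ClinicalReport:
    """Positivity, contingency, correlation and survival for one cohort."""
    positivity = clin.site_positivity_table(clinical, docetaxel_treated)
    sites = clinical.usable_sites()
    if docetaxel_treated is not None:
        sites = sites[sites["docetaxel_treated"].astype(bool) == docetaxel_treated]
    high = sites["ihc_score"].astype(float) >= 2
    bone = sites["site_type"] == "bone"
    table = np.array(
        [
            [int((bone & high).sum()), int((bone & ~high).sum())],
            [int((~bone & high).sum()), int((~bone & ~high).sum())],
        ]
    )
    chi_stat, chi_p = clin.chi_square(table)
    fisher_p = clin.fisher_exact(table)

    filtered = ClinicalTable(
        sites.copy()
        if docetaxel_treated is None
        else clinical.data[
            clinical.data["docetaxel_treated"].astype(bool) == docetaxel_treated
        ].copy()
    )
    summaries = clin.summarize_patients(filtered)
    attr = f"mean_{compartment}"
    with_score = [s for s in summaries if getattr(s, attr) is not None]
    rho = {}
    for b in clin.BASELINES:
        if len(with_score) >= 3:
            rho[b] = clin.spearman(
                [getattr(s, attr) for s in with_score],
                [s.durations[b] for s in with_score],
            )
        else:
            rho[b] = float("nan")
    survival = {
        b: clin.compare_survival_by_class(summaries, compartment, b)
        for b in clin.BASELINES
    }
    return ClinicalReport(
        positivity=positivity,
        site_type_table=table,
        chi2_stat=chi_stat,
        chi2_p=chi_p,
        fisher_p=fisher_p,
        spearman_by_baseline=rho,
        survival=survival,
        summaries=summaries,
    )


def write_clinical_report(report: ClinicalReport, outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    path = outdir / "site_positivity.tsv"
    io.write_table(report.positivity, path, index_label="compartment")
    written.append(path)
    tests = pd.DataFrame(
        [
            {"test": "chi_square", "statistic": report.chi2_stat, "p": report.chi2_p},
            {"test": "fisher_exact", "statistic": np.nan, "p": report.fisher_p},
        ]
        + [
            {"test": f"logrank_{b}", "statistic": s.statistic, "p": s.p_value}
            for b, s in report.survival.items()
        ]
        + [
            {"test": f"spearman_{b}", "statistic": r, "p": np.nan}
            for b, r in report.spearman_by_baseline.items()
        ]
    )
    path = outdir / "clinical_tests.tsv"
    io.write_table(tests, path)
    written.append(path)
    for b, s in report.survival.items():
        for lab, curve in s.curves.items():
            path = outdir / f"km_{b}_{lab}.tsv"
            io.write_table(curve.table, path, index_label="time")
            written.append(path)
    return written
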