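"""Synthetic data with the structure the discovery and validation arms assume.

Three generators share one :class:`SimulationConfig` and one global seed:

* threshold-nested gene x motif count tables — Poisson occurrences at the
  loosest PSSM threshold, binomially thinned at each stricter threshold, so
  counts are element-wise non-increasing with threshold by construction;
* a group-structured expression matrix in which a set of planted "active"
  motifs drives a log-scale shift in the resistant groups, proportional to
  each gene's promoter occurrence count of those motifs;
* a metastatic-cohort clinical table with per-site IHC scores drawn
  conditionally on a latent high/low TF class, and exponential survival from
  three baselines whose hazard is multiplied for TF-high patients, under
  independent exponential censoring.

Every generator returns its ground truth so recovery and calibration tests
can score the downstream pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CLINICAL_COLUMNS, ClinicalTable, ExpressionMatrix, GeneMotifTable
from .errors import ValidationError


@dataclass
class SimulationConfig:
    """Study-design parameters for all three generators.

    Defaults mirror the study design the pipeline targets: three cell-line
    groups (parental ``Ag`` plus resistant ``D8``/``D12``) with four
    replicates each, motif tables at PSSM thresholds 0.70/0.75/0.80/0.85,
    and a rapid-autopsy-style cohort of 42 patients of whom roughly half
    received docetaxel.
    """

    n_genes: int = 2000
    n_motifs: int = 100
    thresholds: tuple[float, ...] = (0.70, 0.75, 0.80, 0.85)
    groups: dict[str, int] = field(
        default_factory=lambda: {"Ag": 4, "D8": 4, "D12": 4}
    )
    parental_group: str = "Ag"
    n_active_motifs: int = 5
    active_motifs: tuple[str, ...] | None = None
    effect_size: float = 1.0  # log2 shift per active-motif occurrence
    group_effect_scale: dict[str, float] | None = None  # per-resistant-group multiplier
    noise_sd: float = 0.5  # residual SD, log2 scale
    baseline_mean: float = 8.0  # log2 baseline intensity (RMA-like scale)
    motif_rate: float = 0.02  # mean occurrences per motif per promoter, loosest threshold
    retention: float = 0.8  # per-step survival prob. of an occurrence
    expression_scale: str = "log2"  # "log2" (clip at 0) or "intensity" (2**x)
    on_degenerate: str = "regenerate"  # or "raise"
    # clinical arm
    n_patients: int = 42
    docetaxel_fraction: float = 0.55
    prob_tf_high: float = 0.4
    sites_per_patient: tuple[int, int] = (1, 6)
    bone_fraction: float = 0.65
    score_probs_low: tuple[float, ...] = (0.45, 0.40, 0.10, 0.05)
    score_probs_high: tuple[float, ...] = (0.05, 0.15, 0.45, 0.35)
    unusable_rate: float = 0.05
    baseline_hazards: tuple[float, float, float] = (0.14, 0.25, 0.33)  # per year
    hazard_ratio: float = 3.0
    censor_rate: float = 0.05  # per year, independent
    seed: int = 0

    def __post_init__(self) -> None:
        if list(self.thresholds) != sorted(self.thresholds) or len(
            set(self.thresholds)
        ) != len(self.thresholds):
            raise ValidationError("thresholds must be strictly increasing")
        if not all(0 < t <= 1 for t in self.thresholds):
            raise ValidationError("thresholds must lie in (0, 1]")
        if not 0 <= self.retention <= 1:
            raise ValidationError(f"retention must lie in [0,1], got {self.retention}")
        for name in ("n_genes", "n_motifs", "n_patients", "n_active_motifs"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if any(n < 2 for n in self.groups.values()):
            raise ValidationError("every group needs ≥ 2 replicates")
        if self.parental_group not in self.groups:
            raise ValidationError(f"parental group {self.parental_group!r} not in groups")
        if self.expression_scale not in ("log2", "intensity"):
            raise ValidationError(f"unknown expression_scale {self.expression_scale!r}")
        if self.on_degenerate not in ("regenerate", "raise"):
            raise ValidationError(f"unknown on_degenerate {self.on_degenerate!r}")
        for p in (self.score_probs_low, self.score_probs_high):
            if len(p) != 4 or abs(sum(p) - 1) > 1e-9:
                raise ValidationError("score probabilities must be 4 values summing to 1")

    @property
    def resistant_groups(self) -> tuple[str, ...]:
        return tuple(g for g in self.groups if g != self.parental_group)

    def rng_streams(self) -> dict[str, np.random.Generator]:
        """One independent, splittable stream per sub-generator."""
        children = np.random.SeedSequence(self.seed).spawn(3)
        names = ("motifs", "expression", "clinical")
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside each simulated dataset."""

    active_motifs: tuple[str, ...] = ()
    # per resistant group: gene -> sign of the planted log-fold-change
    differential: dict[str, dict[str, int]] = field(default_factory=dict)
    tf_class: dict[str, str] = field(default_factory=dict)  # patient -> high/low

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "active_motifs": list(self.active_motifs),
                    "differential": self.differential,
                    "tf_class": self.tf_class,
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n)]


def _motif_ids(n: int) -> list[str]:
    return [f"M{i:04d}" for i in range(n)]


def _is_degenerate(counts: np.ndarray) -> bool:
    # an all-zero motif column has an undefined profile downstream; an
    # all-zero gene row is normal in sparse TFBS tables and harmless
    return bool((counts.sum(axis=0) == 0).any())


def simulate_motif_tables(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[GeneMotifTable]:
    """One gene x motif count table per PSSM threshold, nested by thinning.

    The loosest table draws each cell from Poisson(``motif_rate``); each
    stricter table binomially thins the previous one with probability
    ``retention``, so tightening the threshold can only remove occurrences.
    A table with an all-zero row or column would break the profile transforms
    downstream; depending on ``on_degenerate`` such a draw is re-drawn or
    raises.
    """
    rng = rng if rng is not None else config.rng_streams()["motifs"]
    genes, motifs = _gene_ids(config.n_genes), _motif_ids(config.n_motifs)
    for _attempt in range(100):
        tables = [rng.poisson(config.motif_rate, size=(config.n_genes, config.n_motifs))]
        for _ in config.thresholds[1:]:
            tables.append(rng.binomial(tables[-1], config.retention))
        if not any(_is_degenerate(t) for t in tables):
            break
        if config.on_degenerate == "raise":
            raise ValidationError(
                "simulated motif table has an all-zero row or column "
                "(raise requested); increase motif_rate or retention"
            )
    else:
        raise ValidationError(
            "could not draw non-degenerate motif tables in 100 attempts; "
            "increase motif_rate or retention"
        )
    return [
        GeneMotifTable(pd.DataFrame(t, index=genes, columns=motifs, dtype=float), thr)
        for t, thr in zip(tables, config.thresholds)
    ]


def _resolve_active(config: SimulationConfig, motif_ids: list[str]) -> tuple[str, ...]:
    if config.active_motifs is not None:
        missing = set(config.active_motifs) - set(motif_ids)
        if missing:
            raise ValidationError(f"active motif {sorted(missing)[0]!r} not simulated")
        return tuple(config.active_motifs)
    if config.n_active_motifs > len(motif_ids):
        raise ValidationError("n_active_motifs exceeds n_motifs")
    return tuple(motif_ids[: config.n_active_motifs])


def simulate_expression(
    config: SimulationConfig,
    loosest_table: GeneMotifTable,
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Group-structured expression with motif-driven differential effects.

    Log2 value for gene g in sample s:

        baseline_mean
        + effect_size * scale(group(s)) * (sum of active-motif counts of g)
          if group(s) is resistant
        + Gaussian(0, noise_sd)

    The same planted effect applies to every resistant group by default, so
    the two resistant-vs-parental comparisons have a common, sign-concordant
    truth; ``group_effect_scale`` lets tests plant discordance.  Values are
    returned non-negative: clipped log2 values (default) or base-2
    exponentiated intensities.
    """
    rng = rng if rng is not None else config.rng_streams()["expression"]
    genes = loosest_table.gene_ids
    if len(genes) != config.n_genes:
        raise ValidationError("loosest_table gene set does not match config.n_genes")
    active = _resolve_active(config, loosest_table.motif_ids)
    active_counts = loosest_table.counts[list(active)].sum(axis=1).to_numpy()

    scale = {g: 1.0 for g in config.resistant_groups}
    if config.group_effect_scale:
        unknown = set(config.group_effect_scale) - set(scale)
        if unknown:
            raise ValidationError(f"group_effect_scale names unknown group {sorted(unknown)[0]!r}")
        scale.update(config.group_effect_scale)

    samples, group_of, cols = [], {}, []
    for group, n_rep in config.groups.items():
        for i in range(1, n_rep + 1):
            name = f"{group}_{i}"
            samples.append(name)
            group_of[name] = group
            shift = (
                config.effect_size * scale[group] * active_counts
                if group != config.parental_group
                else np.zeros(config.n_genes)
            )
            cols.append(config.baseline_mean + shift)
    log2 = np.column_stack(cols) + rng.normal(
        0.0, config.noise_sd, size=(config.n_genes, len(samples))
    )
    values = np.clip(log2, 0.0, None) if config.expression_scale == "log2" else 2.0 ** log2
    expr = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), group_of
    )

    differential: dict[str, dict[str, int]] = {}
    for group in config.resistant_groups:
        eff = config.effect_size * scale[group] * active_counts
        differential[group] = {
            g: int(np.sign(e)) for g, e in zip(genes, eff) if e != 0
        }
    truth = SyntheticTruth(active_motifs=active, differential=differential)
    return expr, truth


def simulate_clinical_cohort(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[ClinicalTable, SyntheticTruth]:
    """A metastatic cohort with a latent TF class driving scores and hazard.

    Each patient carries a latent high/low TF class; usable sites draw IHC
    scores from the class-conditional distribution over {0,1,2,3}; the three
    survival durations are exponential with the per-baseline hazard
    multiplied by ``hazard_ratio`` for TF-high patients, censored by an
    independent exponential clock.
    """
    rng = rng if rng is not None else config.rng_streams()["clinical"]
    rows = []
    tf_class: dict[str, str] = {}
    lo, hi = config.sites_per_patient
    for p in range(config.n_patients):
        pid = f"p{p:03d}"
        high = rng.random() < config.prob_tf_high
        tf_class[pid] = "high" if high else "low"
        treated = bool(rng.random() < config.docetaxel_fraction)
        hr = config.hazard_ratio if high else 1.0
        surv = {}
        for name, lam in zip(
            ("diagnosis", "crpc", "bone_met"), config.baseline_hazards
        ):
            t_event = rng.exponential(1.0 / (lam * hr))
            t_cens = (
                rng.exponential(1.0 / config.censor_rate)
                if config.censor_rate > 0
                else np.inf
            )
            surv[f"time_from_{name}"] = min(t_event, t_cens)
            surv[f"event_from_{name}"] = bool(t_event <= t_cens)
        probs = config.score_probs_high if high else config.score_probs_low
        n_sites = int(rng.integers(lo, hi + 1))
        for s in range(n_sites):
            usable = rng.random() >= config.unusable_rate
            rows.append(
                {
                    "patient_id": pid,
                    "site_id": f"{pid}_s{s}",
                    "site_type": "bone" if rng.random() < config.bone_fraction else "soft",
                    "ihc_score": int(rng.choice(4, p=probs)) if usable else np.nan,
                    "usable": usable,
                    "docetaxel_treated": treated,
                    **surv,
                }
            )
    table = ClinicalTable(pd.DataFrame(rows, columns=CLINICAL_COLUMNS))
    return table, SyntheticTruth(tf_class=tf_class)


def simulate_all(
    config: SimulationConfig,
) -> tuple[list[GeneMotifTable], ExpressionMatrix, ClinicalTable, SyntheticTruth]:
    """Run all three generators off one seed; truths merged into one record."""
    streams = config.rng_streams()
    tables = simulate_motif_tables(config, streams["motifs"])
    expr, truth_e = simulate_expression(config, tables[0], streams["expression"])
    clin, truth_c = simulate_clinical_cohort(config, streams["clinical"])
    truth = SyntheticTruth(
        active_motifs=truth_e.active_motifs,
        differential=truth_e.differential,
        tf_class=truth_c.tf_class,
    )
    return tables, expr, clin, truth
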