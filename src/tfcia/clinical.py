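"""Clinical validation statistics for IHC-scored metastatic cohorts.

Sites carry a semi-quantitative nuclear staining score 0-3 (0 no staining,
1 faint, 2 moderate, 3 strong in >10% of epithelial cells); a site is
"high"/positive at 2-3 and "low"/negative at 0-1.  Patients are summarized
by the mean score over their usable sites per compartment (bone, soft
tissue, both) and dichotomized at the scale midpoint (mean ≥ 1.5 → high).
Association with site type uses chi-square and Fisher exact tests on 2x2
tables, continuous association uses Spearman mid-rank correlation, and the
survival arm uses Kaplan-Meier product-limit curves with log-rank tests
from each of the three clinical baselines.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import floor

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .containers import ClinicalTable
from .errors import ValidationError

BASELINES = ("diagnosis", "crpc", "bone_met")


def dichotomize_site(score: int) -> str:
    """Site-level call: scores 0/1 are 'low', 2/3 are 'high'."""
    if score not in (0, 1, 2, 3):
        raise ValidationError(f"IHC score {score!r} outside {{0,1,2,3}}")
    return "high" if score >= 2 else "low"


@dataclass
class PatientSummary:
    """Per-patient compartment means and dichotomized classes."""

    patient_id: str
    mean_bone: float | None
    mean_soft: float | None
    mean_all: float | None
    class_bone: str | None
    class_soft: str | None
    class_all: str | None
    n_usable_sites: int
    docetaxel_treated: bool
    durations: dict[str, float]
    events: dict[str, bool]


def _mean_and_class(scores: pd.Series, cutoff: float) -> tuple[float | None, str | None]:
    if len(scores) == 0:
        return None, None
    mean = float(scores.mean())
    return mean, ("high" if mean >= cutoff else "low")


def summarize_patient(
    sites: pd.DataFrame, class_cutoff: float = 1.5
) -> PatientSummary:
    """Average the usable sites of one patient per compartment and classify.

    The class cutoff is the midpoint of the 0-3 scale (mean ≥ 1.5 → high),
    midpoint inclusive; configurable.
    """
    usable = sites[sites["usable"].astype(bool)]
    if len(usable) == 0:
        raise ValidationError(
            f"patient {sites['patient_id'].iloc[0]!r} has no usable sites"
        )
    scores = usable["ihc_score"].astype(float)
    bone = scores[usable["site_type"] == "bone"]
    soft = scores[usable["site_type"] == "soft"]
    mean_bone, class_bone = _mean_and_class(bone, class_cutoff)
    mean_soft, class_soft = _mean_and_class(soft, class_cutoff)
    mean_all, class_all = _mean_and_class(scores, class_cutoff)
    first = sites.iloc[0]
    return PatientSummary(
        patient_id=str(first["patient_id"]),
        mean_bone=mean_bone,
        mean_soft=mean_soft,
        mean_all=mean_all,
        class_bone=class_bone,
        class_soft=class_soft,
        class_all=class_all,
        n_usable_sites=int(len(usable)),
        docetaxel_treated=bool(first["docetaxel_treated"]),
        durations={b: float(first[f"time_from_{b}"]) for b in BASELINES},
        events={b: bool(first[f"event_from_{b}"]) for b in BASELINES},
    )


def summarize_patients(
    clinical: ClinicalTable, class_cutoff: float = 1.5
) -> list[PatientSummary]:
    out = []
    for _, sites in clinical.data.groupby("patient_id", sort=True):
        if not sites["usable"].astype(bool).any():
            continue  # flagged upstream; nothing to summarize
        out.append(summarize_patient(sites, class_cutoff))
    return out


def _round_half_away(x: float) -> int:
    return int(floor(x + 0.5)) if x >= 0 else -int(floor(-x + 0.5))


def site_positivity_table(
    clinical: ClinicalTable, docetaxel_treated: bool | None = True
) -> pd.DataFrame:
    """High/low site counts and percentages overall and per compartment.

    Percentages are rounded to the nearest integer, half away from zero.
    Unusable sites are excluded (they carry no score).
    """
    sites = clinical.usable_sites()
    if docetaxel_treated is not None:
        sites = sites[sites["docetaxel_treated"].astype(bool) == docetaxel_treated]
    if len(sites) == 0:
        raise ValidationError("no usable sites after filtering")
    rows = []
    selections = {
        "overall": sites,
        "bone": sites[sites["site_type"] == "bone"],
        "soft": sites[sites["site_type"] == "soft"],
    }
    for name, sel in selections.items():
        n = len(sel)
        pos = int((sel["ihc_score"].astype(float) >= 2).sum())
        neg = n - pos
        rows.append(
            {
                "compartment": name,
                "n_sites": n,
                "n_positive": pos,
                "n_negative": neg,
                "pct_positive": _round_half_away(100.0 * pos / n) if n else 0,
                "pct_negative": _round_half_away(100.0 * neg / n) if n else 0,
            }
        )
    return pd.DataFrame(rows).set_index("compartment")


def fisher_exact(table: np.ndarray | list) -> float:
    """Two-sided Fisher exact p: hypergeometric mass of tables ≤ observed."""
    t = np.asarray(table)
    if t.shape != (2, 2) or (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if t.shape != (2, 2) or (t < 0).any() or (t != np.round(t)).any():
            raise ValidationError("Fisher test needs a 2x2 table of non-negative integers")
        t = t.astype(int)
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def chi_square(table: np.ndarray | list, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, 1 df, continuity correction off by default."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValidationError("chi-square needs a 2x2 table of non-negative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValidationError("chi-square is undefined with a zero margin")
    stat, p, _, _ = stats.chi2_contingency(t, correction=correction)
    return float(stat), float(p)


def spearman(x, y) -> float:
    """Spearman rank correlation (Pearson on mid-ranks, average ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("spearman needs two equal-length vectors of length ≥ 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("spearman is undefined for a zero-variance vector")
    return float(stats.spearmanr(x, y).statistic)


@dataclass
class SurvivalCurve:
    """Kaplan-Meier product-limit estimate for one group."""

    group: str
    table: pd.DataFrame  # index time; columns: at_risk, events, censored, survival
    median: float | None  # None when the curve never crosses 0.5

    @property
    def times(self) -> np.ndarray:
        return self.table.index.to_numpy()

    @property
    def survival(self) -> np.ndarray:
        return self.table["survival"].to_numpy()


def km_estimate(durations, events, group: str = "all") -> SurvivalCurve:
    """Product-limit estimator; at equal times events precede censorings."""
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=bool)
    if durations.size == 0:
        raise ValidationError(f"group {group!r} has zero subjects")
    if (durations < 0).any():
        raise ValidationError("durations must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    ev = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"].reindex(ev.index)
    table = pd.DataFrame(
        {
            "at_risk": ev["at_risk"].astype(int),
            "events": ev["observed"].astype(int),
            "censored": ev["censored"].astype(int),
            "survival": surv,
        }
    )
    table.index.name = "time"
    median = kmf.median_survival_time_
    return SurvivalCurve(
        group=group,
        table=table,
        median=None if np.isinf(median) else float(median),
    )


def logrank(durations, events, groups) -> tuple[float, float]:
    """Log-rank test across groups: statistic and p-value."""
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValidationError("log-rank needs at least two groups")
    if (counts == 0).any():
        raise ValidationError("log-rank group with zero subjects")
    res = multivariate_logrank_test(durations, groups, events)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class SurvivalComparison:
    baseline: str
    curves: dict[str, SurvivalCurve]
    statistic: float
    p_value: float
    medians: dict[str, float | None]


def compare_survival_by_class(
    summaries: list[PatientSummary],
    compartment: str = "bone",
    baseline: str = "crpc",
) -> SurvivalComparison:
    """KM + log-rank comparison of high vs low patients from one baseline."""
    if baseline not in BASELINES:
        raise ValidationError(f"unknown baseline {baseline!r}")
    attr = f"class_{compartment}"
    usable = [s for s in summaries if getattr(s, attr) is not None]
    durations = np.array([s.durations[baseline] for s in usable])
    events = np.array([s.events[baseline] for s in usable])
    classes = np.array([getattr(s, attr) for s in usable])
    stat, p = logrank(durations, events, classes)
    curves = {
        lab: km_estimate(durations[classes == lab], events[classes == lab], lab)
        for lab in np.unique(classes)
    }
    return SurvivalComparison(
        baseline=baseline,
        curves=curves,
        statistic=stat,
        p_value=p,
        medians={lab: c.median for lab, c in curves.items()},
    )
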