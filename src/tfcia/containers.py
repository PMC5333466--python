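"""In-memory containers for the three tables the pipeline couples.

All containers are thin, validated wrappers around :class:`pandas.DataFrame`:
an expression matrix (genes x samples, non-negative, with a sample->group map),
a gene x motif binding-site count table at one PSSM match threshold, and a
per-site clinical table of immunohistochemistry scores with per-patient
survival durations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

CLINICAL_COLUMNS = [
    "patient_id",
    "site_id",
    "site_type",
    "ihc_score",
    "usable",
    "docetaxel_treated",
    "time_from_diagnosis",
    "event_from_diagnosis",
    "time_from_crpc",
    "event_from_crpc",
    "time_from_bone_met",
    "event_from_bone_met",
]

SITE_TYPES = ("bone", "soft")


def _check_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dup = idx[idx.duplicated()][0]
        raise ValidationError(f"duplicate {what} identifier: {dup!r}")


@dataclass
class ExpressionMatrix:
    """Non-negative gene x sample intensities with group labels per sample."""

    values: pd.DataFrame  # genes as rows, samples as columns
    group_of: dict[str, str]

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        arr = self.values.to_numpy()
        if np.isnan(arr).any():
            r, c = np.argwhere(np.isnan(arr))[0]
            raise ValidationError(
                f"missing value at gene {self.values.index[r]!r}, "
                f"sample {self.values.columns[c]!r}"
            )
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative expression value at gene {self.values.index[r]!r}, "
                f"sample {self.values.columns[c]!r}"
            )
        missing = [s for s in self.values.columns if s not in self.group_of]
        if missing:
            raise ValidationError(f"sample {missing[0]!r} has no group annotation")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def groups(self) -> list[str]:
        """Group labels in order of first appearance over samples."""
        seen: dict[str, None] = {}
        for s in self.values.columns:
            seen.setdefault(self.group_of[s], None)
        return list(seen)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.group_of[s] == group]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], dict(self.group_of))

    def subset_groups(self, groups) -> "ExpressionMatrix":
        keep = [s for s in self.values.columns if self.group_of[s] in set(groups)]
        if not keep:
            raise ValidationError(f"no samples in groups {list(groups)!r}")
        return ExpressionMatrix(
            self.values[keep], {s: self.group_of[s] for s in keep}
        )


@dataclass
class GeneMotifTable:
    """Non-negative gene x motif occurrence counts at one PSSM threshold."""

    counts: pd.DataFrame  # genes as rows, motifs as columns
    threshold: float

    def __post_init__(self) -> None:
        _check_unique(self.counts.index, "gene")
        _check_unique(self.counts.columns, "motif")
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative motif count at gene {self.counts.index[r]!r}, "
                f"motif {self.counts.columns[c]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def motif_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset_genes(self, genes) -> "GeneMotifTable":
        return GeneMotifTable(self.counts.loc[list(genes)], self.threshold)


@dataclass
class ClinicalTable:
    """Per-metastatic-site IHC scores plus per-patient survival columns.

    One row per site.  ``ihc_score`` is an integer in {0,1,2,3} for usable
    cores; unusable cores carry ``usable == False`` and a missing score (they
    are flagged, never silently dropped).  The three duration/event pairs are
    measured from prostate-cancer diagnosis, from castration resistance
    (CRPC), and from first bone metastasis.
    """

    data: pd.DataFrame = field()

    def __post_init__(self) -> None:
        missing = [c for c in CLINICAL_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"clinical table missing column {missing[0]!r}")
        usable = self.data["usable"].astype(bool)
        scores = self.data.loc[usable, "ihc_score"]
        bad = scores[~scores.isin([0, 1, 2, 3])]
        if len(bad):
            raise ValidationError(
                f"IHC score {bad.iloc[0]!r} at site {self.data.loc[bad.index[0], 'site_id']!r} "
                "outside {0,1,2,3}"
            )
        bad_type = self.data.loc[~self.data["site_type"].isin(SITE_TYPES)]
        if len(bad_type):
            raise ValidationError(
                f"site_type {bad_type['site_type'].iloc[0]!r} not in {SITE_TYPES}"
            )
        for col in ("time_from_diagnosis", "time_from_crpc", "time_from_bone_met"):
            if (self.data[col] < 0).any():
                raise ValidationError(f"negative duration in column {col!r}")

    @property
    def patients(self) -> list:
        return list(pd.unique(self.data["patient_id"]))

    def usable_sites(self) -> pd.DataFrame:
        return self.data[self.data["usable"].astype(bool)]
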