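"""Core in-memory containers for case-control OTU-table analysis.

The pipeline operates on three tabular objects — an integer OTU count
matrix (samples x OTUs), a taxonomy lookup (OTU id -> rank-prefixed
lineage), and per-sample cohort metadata (case/control group, cohort,
SLEDAI disease-activity score, clinical indices) — plus an optional
rooted phylogeny over OTU ids for UniFrac distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

RANKS = ("domain", "phylum", "class", "order", "family", "genus")

RANK_PREFIXES = {
    "d": "domain",
    "k": "domain",  # Greengenes kingdom prefix
    "p": "phylum",
    "c": "class",
    "o": "order",
    "f": "family",
    "g": "genus",
}

GROUPS = ("case", "control")
COHORTS = ("derivation", "validation", "cross_regional")
ACTIVITY_LEVELS = ("mild", "moderate", "severe")

CLINICAL_INDICES = ("age", "bmi", "wbc", "rbc", "hb", "plt", "lyn", "glb")


class FormatError(ValueError):
    """Malformed input file or value."""


class ValidationError(ValueError):
    """Structurally valid input violating a domain invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what} id(s): {dups}")


@dataclass
class OtuTable:
    """Integer read-count matrix, samples as rows, OTUs as columns.

    ``counts`` is a pandas DataFrame indexed by sample id with OTU-id
    columns.  Counts must be non-negative and every sample must have a
    positive library size.  ``relative`` marks a table already holding
    relative abundances (permitted for stages that accept them; the
    integer-only richness estimators refuse such tables).
    """

    counts: pd.DataFrame
    relative: bool = False

    def __post_init__(self) -> None:
        _check_unique(list(self.counts.index), "sample")
        _check_unique(list(self.counts.columns), "OTU")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("OTU table body must be numeric")
        if np.isnan(values).any():
            raise FormatError("OTU table contains missing values")
        if (values < 0).any():
            raise FormatError("OTU table contains negative counts")
        if not self.relative:
            if not np.allclose(values, np.round(values)):
                raise FormatError(
                    "OTU table contains non-integer counts; pass relative=True "
                    "for pre-normalized relative-abundance input"
                )
            self.counts = self.counts.astype(np.int64)
        totals = self.counts.sum(axis=1)
        empty = totals.index[totals == 0].tolist()
        if empty:
            raise ValidationError(f"sample(s) with zero total count: {empty}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances (rows sum to 1)."""
        return self.counts.div(self.counts.sum(axis=1), axis=0)

    def subset_samples(self, sample_ids: Iterable[str]) -> "OtuTable":
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self.counts.index]
        if missing:
            raise KeyError(f"unknown sample id(s): {missing}")
        return OtuTable(self.counts.loc[ids].copy(), relative=self.relative)

    def subset_otus(self, otu_ids: Iterable[str], strict: bool = True) -> "OtuTable":
        """Restrict to the given OTUs; with ``strict=False`` missing OTUs
        are filled as zero columns (cross-cohort prediction contract)."""
        ids = list(otu_ids)
        missing = [o for o in ids if o not in self.counts.columns]
        if missing and strict:
            raise KeyError(f"unknown OTU id(s): {missing}")
        sub = self.counts.reindex(columns=ids, fill_value=0).copy()
        table = object.__new__(OtuTable)
        table.counts = sub
        table.relative = self.relative
        return table


@dataclass
class TaxonomyMap:
    """OTU id -> six-rank lineage (domain..genus).

    Ranks missing from an input lineage are filled with the deepest
    named ancestor suffixed ``_unclassified`` (e.g. an OTU classified to
    family Micrococcaceae gets genus ``Micrococcaceae_unclassified``).
    """

    lineages: pd.DataFrame  # index OTU id, columns RANKS

    def __post_init__(self) -> None:
        missing = [r for r in RANKS if r not in self.lineages.columns]
        if missing:
            raise FormatError(f"taxonomy missing rank column(s): {missing}")
        self.lineages = self.lineages[list(RANKS)]
        _check_unique(list(self.lineages.index), "taxonomy OTU")

    def lineage(self, otu_id: str) -> dict[str, str]:
        if otu_id not in self.lineages.index:
            raise KeyError(f"OTU id not in taxonomy: {otu_id!r}")
        return self.lineages.loc[otu_id].to_dict()

    def name_at_rank(self, otu_id: str, rank: str) -> str:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
        return self.lineage(otu_id)[rank]

    def require(self, otu_ids: Iterable[str]) -> None:
        missing = [o for o in otu_ids if o not in self.lineages.index]
        if missing:
            raise KeyError(f"OTU id(s) missing from taxonomy: {missing}")


def derive_activity(sledai: float | None) -> str | None:
    """SLEDAI strata: mild <= 6, moderate 7-11, severe >= 12."""
    if sledai is None or (isinstance(sledai, float) and np.isnan(sledai)):
        return None
    if sledai < 0:
        raise ValidationError(f"negative SLEDAI score: {sledai}")
    if sledai <= 6:
        return "mild"
    if sledai <= 11:
        return "moderate"
    return "severe"


@dataclass
class CohortMetadata:
    """Per-sample study metadata.

    ``frame`` is indexed by sample id with columns ``group`` (case /
    control), ``cohort`` (derivation / validation / cross_regional),
    optional ``sledai`` (non-negative, cases only in practice), derived
    ``activity`` (mild / moderate / severe), ``gender`` ('F'/'M') and
    real-valued clinical indices.  Missing clinical values are allowed
    and propagate as NaN (pairwise-complete analysis downstream).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(list(self.frame.index), "metadata sample")
        if "group" not in self.frame.columns:
            raise FormatError("metadata must contain a 'group' column")
        bad = set(self.frame["group"].dropna()) - set(GROUPS)
        if bad:
            raise FormatError(
                f"unknown group value(s) {sorted(bad)}; allowed: {list(GROUPS)}"
            )
        if self.frame["group"].isna().any():
            missing = self.frame.index[self.frame["group"].isna()].tolist()
            raise ValidationError(f"group undefined for sample(s): {missing}")
        if "cohort" in self.frame.columns:
            bad = set(self.frame["cohort"].dropna()) - set(COHORTS)
            if bad:
                raise FormatError(
                    f"unknown cohort value(s) {sorted(bad)}; allowed: {list(COHORTS)}"
                )
        if "gender" in self.frame.columns:
            bad = set(self.frame["gender"].dropna()) - {"F", "M"}
            if bad:
                raise FormatError(f"unknown gender value(s) {sorted(bad)}; allowed: F, M")
        if "sledai" in self.frame.columns:
            sled = pd.to_numeric(self.frame["sledai"], errors="coerce")
            if (sled.dropna() < 0).any():
                raise ValidationError("negative SLEDAI score in metadata")
            self.frame = self.frame.copy()
            self.frame["sledai"] = sled
            self.frame["activity"] = [derive_activity(v) for v in sled]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def group_labels(self, sample_ids: Sequence[str] | None = None) -> pd.Series:
        labels = self.frame["group"]
        if sample_ids is not None:
            missing = [s for s in sample_ids if s not in labels.index]
            if missing:
                raise ValidationError(
                    f"sample(s) in table but absent from metadata: {missing}"
                )
            labels = labels.loc[list(sample_ids)]
        return labels

    def samples_in(self, cohort: str | None = None, group: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self.frame.index)
        if cohort is not None:
            if "cohort" not in self.frame.columns:
                raise ValidationError("metadata has no cohort column")
            mask &= self.frame["cohort"] == cohort
        if group is not None:
            mask &= self.frame["group"] == group
        return list(self.frame.index[mask])

    def subset(self, sample_ids: Iterable[str]) -> "CohortMetadata":
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self.frame.index]
        if missing:
            raise ValidationError(f"sample(s) absent from metadata: {missing}")
        return CohortMetadata(self.frame.loc[ids].copy())


@dataclass
class GroundTruth:
    """Bookkeeping of planted effects in a simulated cohort."""

    marker_otus: dict[str, float] = field(default_factory=dict)  # id -> planted fold
    activity_otus: dict[str, int] = field(default_factory=dict)  # id -> +1/-1 trend
    clinical_links: list[tuple[str, str, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "marker_otus": self.marker_otus,
            "activity_otus": self.activity_otus,
            "clinical_links": [list(t) for t in self.clinical_links],
        }
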