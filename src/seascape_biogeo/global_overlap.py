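"""Overlap between the regional ASV set and external "global" region sets.

Quantifies how many of the study's ASVs are shared with each user-supplied
region/database set (by identifier or by exact full-length sequence match),
overall and within each biogeographic category, plus the fraction of study
ASVs found in no region at all, and fits the linear relationship between a
region's richness and its percent overlap with the study set.

Matching across denoising pipelines is exact string equality only; primer-
region harmonization and fuzzy/OTU-level matching are deliberately out of
scope, and cross-dataset overlaps should be read with that caveat.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from Bio import SeqIO

from .table_io import TableValidationError

MATCH_MODES = ("id", "exact-sequence")

_VALID_NT = set("ACGTU")


@dataclass
class RegionSet:
    """One external region/database ASV set."""

    region: str
    database: str
    ids: frozenset = frozenset()
    sequences: frozenset = frozenset()

    def __post_init__(self) -> None:
        self.ids = frozenset(self.ids)
        seqs = {s.upper() for s in self.sequences}
        bad = [s for s in seqs if not set(s) <= _VALID_NT]
        if bad:
            raise TableValidationError(
                f"region {self.region!r}: sequences contain non-ACGTU characters")
        self.sequences = frozenset(seqs)

    @property
    def richness(self) -> int:
        return len(self.sequences) if self.sequences else len(self.ids)

    def keys(self, mode: str) -> frozenset:
        if mode == "id":
            if not self.ids:
                raise TableValidationError(
                    f"region {self.region!r} has no identifiers for id-mode matching")
            return self.ids
        if not self.sequences:
            raise TableValidationError(
                f"region {self.region!r} has no sequences for sequence-mode matching")
        return self.sequences


def region_set_from_fasta(region: str, database: str, path: str | Path) -> RegionSet:
    """Load a region set from FASTA (ids = record ids, sequences uppercased,
    deduplicated)."""
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    return RegionSet(region, database, frozenset(ids), frozenset(seqs))


def region_set_from_ids(region: str, database: str, path: str | Path) -> RegionSet:
    """Load a region set from a one-ID-per-line text file."""
    with open(path) as fh:
        ids = [line.strip() for line in fh if line.strip()]
    return RegionSet(region, database, frozenset(ids))


def match_sets(study_keys: set, regions: list, mode: str = "exact-sequence",
               study_categories: dict | None = None) -> pd.DataFrame:
    """Overlap of the study ASV set against each region set.

    ``study_keys``: the study's ASV identifiers (mode "id") or uppercase
    sequences (mode "exact-sequence"); ``study_categories`` optionally maps
    each study key to its biogeographic category, enabling per-category
    percentages (denominator = that category's study size). The last row of
    bookkeeping — the percentage of study ASVs found in no region at all —
    is returned via :func:`found_nowhere`.
    """
    if mode not in MATCH_MODES:
        raise TableValidationError(f"mode must be one of {MATCH_MODES}")
    study = {str(s).upper() for s in study_keys} if mode == "exact-sequence" \
        else set(study_keys)
    if not study:
        raise TableValidationError("empty study set")
    cats: dict[str, set] = {}
    if study_categories:
        for key, cat in study_categories.items():
            k = str(key).upper() if mode == "exact-sequence" else key
            cats.setdefault(cat, set()).add(k)
    rows = []
    for rs in regions:
        keys = rs.keys(mode)
        shared = study & keys
        row = {
            "region": rs.region, "database": rs.database,
            "richness": rs.richness, "shared": len(shared),
            "percent_study_found": 100.0 * len(shared) / len(study),
        }
        for cat, members in sorted(cats.items()):
            denom = len(members)
            row[f"shared_{cat}"] = len(members & keys)
            row[f"percent_{cat}"] = 100.0 * len(members & keys) / denom if denom else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def found_nowhere(study_keys: set, regions: list, mode: str = "exact-sequence") -> float:
    """Percentage of study ASVs absent from the union of all region sets."""
    study = {str(s).upper() for s in study_keys} if mode == "exact-sequence" \
        else set(study_keys)
    union: set = set()
    for rs in regions:
        union |= rs.keys(mode)
    return 100.0 * len(study - union) / len(study)


def fit_richness_overlap(records: pd.DataFrame,
                         percent_column: str = "percent_study_found") -> dict:
    """OLS of percent overlap on region richness.

    Returns slope, intercept, r-squared and coefficient p-values (statsmodels
    OLS). Requires >= 3 records and non-constant richness.
    """
    if len(records) < 3:
        raise TableValidationError("need at least 3 overlap records for a fit")
    x = records["richness"].to_numpy(float)
    y = records[percent_column].to_numpy(float)
    if np.ptp(x) == 0:
        raise TableValidationError("zero-variance richness: fit undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return {
        "slope": float(model.params[1]),
        "intercept": float(model.params[0]),
        "r_squared": float(model.rsquared),
        "p_slope": float(model.pvalues[1]),
        "n": int(len(records)),
    }


def fit_by_category(records: pd.DataFrame, categories: list) -> pd.DataFrame:
    """Per-category richness-vs-overlap fits (plus the overall fit)."""
    rows = [{"category": "all", **fit_richness_overlap(records)}]
    for cat in categories:
        col = f"percent_{cat}"
        if col in records.columns:
            rows.append({"category": cat, **fit_richness_overlap(records, col)})
    return pd.DataFrame(rows)
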