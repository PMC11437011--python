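"""Endemic / generalist / cosmopolitan classification across the ensemble.

A taxon's habitat-presence set in one ensemble member is the set of habitats
containing at least one sample with at least one read of that taxon. Across
members: a taxon present in the SAME single habitat in every (non-empty)
member is endemic; one present in all habitats in every (non-empty) member is
cosmopolitan; everything else is generalist. Members where the taxon is
entirely absent after rarefaction are skipped by default (the taxon is
unobserved there, so that member carries no presence evidence); a strict mode
treats such members as breaking both endemism and cosmopolitanism.

Ubiquity — occurrence in every sample of every member — is reported as a flag
(ubiquitous taxa are necessarily cosmopolitan), not as a fourth category.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rarefaction_ensemble import RarefactionEnsemble
from .table_io import TableValidationError

CATEGORIES = ("endemic", "generalist", "cosmopolitan")


def habitat_presence(member: np.ndarray, sample_ids: np.ndarray,
                     assignment: pd.Series) -> dict:
    """Per-ASV habitat presence in one member.

    Returns ``{habitat: boolean vector over ASVs}``; habitat h is in an ASV's
    presence set iff the ASV has >= 1 read in >= 1 sample labeled h.
    """
    missing = [s for s in sample_ids if s not in assignment.index]
    if missing:
        raise TableValidationError(f"samples missing from habitat assignment: {missing}")
    labels = assignment.loc[list(sample_ids)].to_numpy()
    out = {}
    for h in pd.unique(labels):
        cols = np.flatnonzero(labels == h)
        out[h] = (member[:, cols] > 0).any(axis=1)
    return out


@dataclass
class PresenceSummary:
    """Streaming summary of per-member presence sets for every ASV."""

    habitats: tuple
    n_members: int
    #: number of non-empty members per ASV
    n_observed: np.ndarray
    #: min/max habitat-set size over non-empty members
    min_count: np.ndarray
    max_count: np.ndarray
    #: True when every non-empty member has the identical presence set
    constant_set: np.ndarray
    #: True when every non-empty member's set contains all habitats
    always_all: np.ndarray
    #: presence in every sample of every member
    ubiquitous: np.ndarray
    #: mean relative abundance across all samples and members
    mean_overall_abundance: np.ndarray


def summarize_presence(ensemble: RarefactionEnsemble,
                       assignment: pd.Series) -> PresenceSummary:
    """Scan every member once, accumulating the presence statistics that the
    category rule needs."""
    labels = assignment.loc[list(ensemble.sample_ids)].to_numpy()
    habitats = tuple(pd.unique(labels))
    k = len(habitats)
    cols = [np.flatnonzero(labels == h) for h in habitats]
    n_asv = ensemble.n_asvs

    n_observed = np.zeros(n_asv, dtype=np.int64)
    min_count = np.full(n_asv, k + 1, dtype=np.int64)
    max_count = np.zeros(n_asv, dtype=np.int64)
    constant_set = np.ones(n_asv, dtype=bool)
    first_set = np.full((n_asv, k), -1, dtype=np.int8)  # -1 until first observation
    ubiquitous = np.ones(n_asv, dtype=bool)
    abundance = np.zeros(n_asv)

    for cnt in ensemble.members:
        pres = cnt > 0
        sets = np.column_stack([pres[:, c].any(axis=1) for c in cols])
        sizes = sets.sum(axis=1)
        observed = sizes > 0
        n_observed += observed
        np.minimum(min_count, np.where(observed, sizes, k + 1), out=min_count)
        np.maximum(max_count, sizes, out=max_count)
        seen_before = first_set[:, 0] >= 0
        newly = observed & ~seen_before
        first_set[newly] = sets[newly]
        cmp_rows = observed & seen_before
        if cmp_rows.any():
            same = (first_set[cmp_rows] == sets[cmp_rows]).all(axis=1)
            constant_set[np.flatnonzero(cmp_rows)[~same]] = False
        ubiquitous &= pres.all(axis=1)
        abundance += cnt.sum(axis=1, dtype=np.float64)

    always_all = (min_count == k) & (n_observed == len(ensemble.members))
    # for skip semantics: all non-empty members have all habitats
    always_all_skip = np.where(n_observed > 0, min_count == k, False)
    mean_ab = abundance / (len(ensemble.members) * ensemble.n_samples * ensemble.depth)
    return PresenceSummary(
        habitats=habitats,
        n_members=len(ensemble.members),
        n_observed=n_observed,
        min_count=np.where(n_observed > 0, min_count, 0),
        max_count=max_count,
        constant_set=constant_set,
        always_all=always_all_skip,
        ubiquitous=ubiquitous,
        mean_overall_abundance=mean_ab,
    )


def classify_biogeography(presence_sets: list, k: int,
                          strict_endemic: bool = True,
                          absent_member_policy: str = "skip") -> str:
    """Category of one taxon from its per-member presence sets.

    ``presence_sets`` is a list of sets (one per member). Endemic: the same
    single habitat in every counted member (with ``strict_endemic=False``,
    any single habitat per member suffices); cosmopolitan: all ``k`` habitats
    in every counted member; generalist otherwise. Empty sets are skipped
    (default) or break both extremes (policy "strict").
    """
    if absent_member_policy not in ("skip", "strict"):
        raise TableValidationError(f"unknown absent-member policy {absent_member_policy!r}")
    nonempty = [s for s in presence_sets if s]
    if not nonempty:
        raise TableValidationError("taxon absent from all members; filter it first")
    had_empty = len(nonempty) < len(presence_sets)
    if absent_member_policy == "strict" and had_empty:
        return "generalist"
    if all(len(s) == k for s in nonempty):
        return "cosmopolitan"
    if all(len(s) == 1 for s in nonempty):
        if not strict_endemic or all(s == nonempty[0] for s in nonempty):
            return "endemic"
    return "generalist"


def classify_ensemble(ensemble: RarefactionEnsemble, assignment: pd.Series,
                      strict_endemic: bool = True,
                      absent_member_policy: str = "skip") -> pd.DataFrame:
    """Classify every ASV of the ensemble (vectorized presence scan).

    Returns a DataFrame with asv_id, category, ubiquitous flag, presence-set
    summaries and mean overall relative abundance. ASVs absent from every
    member are rejected — the singleton screen should have removed them.
    """
    summ = summarize_presence(ensemble, assignment)
    k = len(summ.habitats)
    absent = summ.n_observed == 0
    if absent.any():
        raise TableValidationError(
            f"{int(absent.sum())} ASV(s) absent from all members; "
            "run the singleton screen first")
    observed_all = summ.n_observed == summ.n_members

    cosmopolitan = summ.always_all
    endemic_base = (summ.max_count == 1)
    if strict_endemic:
        endemic_base &= summ.constant_set
    if absent_member_policy == "strict":
        cosmopolitan &= observed_all
        endemic_base &= observed_all
    category = np.where(cosmopolitan, "cosmopolitan",
                        np.where(endemic_base, "endemic", "generalist"))
    # ubiquitous implies presence of all habitats in all members
    assert not np.any(summ.ubiquitous & (category != "cosmopolitan"))
    return pd.DataFrame({
        "asv_id": ensemble.asv_ids,
        "category": category,
        "ubiquitous": summ.ubiquitous,
        "min_habitat_count": summ.min_count,
        "max_habitat_count": summ.max_count,
        "constant_presence_set": summ.constant_set,
        "members_observed": summ.n_observed,
        "mean_overall_abundance": summ.mean_overall_abundance,
    })


def check_ubiquity(ensemble: RarefactionEnsemble) -> np.ndarray:
    """True per ASV iff it has >= 1 read in every retained sample of every
    member."""
    flag = np.ones(ensemble.n_asvs, dtype=bool)
    for cnt in ensemble.members:
        flag &= (cnt > 0).all(axis=1)
    return flag


def summarize_categories(records: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages per biogeographic category."""
    if len(records) == 0:
        return pd.DataFrame(columns=["category", "count", "percent"])
    counts = records["category"].value_counts()
    total = int(counts.sum())
    rows = [(cat, int(counts.get(cat, 0)), 100.0 * counts.get(cat, 0) / total)
            for cat in CATEGORIES]
    return pd.DataFrame(rows, columns=["category", "count", "percent"])
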