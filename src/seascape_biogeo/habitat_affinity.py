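"""Bootstrap null model for pelagic habitat affinity.

For one taxon in one equal-depth ensemble member, its per-sample relative
abundances (count / rarefaction depth) are averaged within each habitat to
give the actual habitat means (mu_PSUW, mu_ENPCW, mu_PEW, ...). The null
model resamples the taxon's per-sample relative abundances across all N
samples with replacement, B times, keeping the habitat labels fixed, and
recomputes the habitat means on each surrogate dataset. The p-value per
habitat is

    p = (# surrogate habitat means strictly > actual habitat mean) / B,

i.e. the probability under random placement that the habitat would look at
least as enriched as observed. Ensemble-level significance is the mean
p-value per habitat across contributing members; a taxon has affinity for
habitat h when that mean p is below alpha. Because the sample-weighted habitat
means always average to the overall mean, at most two of three habitat means
can strictly exceed the overall mean — so affinity for all three habitats is
impossible, and the per-taxon affinity count is 0, 1 or 2.

Degenerate cases are handled explicitly: a taxon whose proportions are
identical in every sample would tie every surrogate mean and score p = 0
under the strict inequality, so a constant-taxon guard reports p = 1; a taxon
with zero reads in a member is, by default, skipped for that member (policy
"skip"), with policies "p1" (score p = 1) and "error" available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rarefaction_ensemble import RarefactionEnsemble
from .table_io import TableValidationError, rng_for

ABSENT_POLICIES = ("skip", "p1", "error")


@dataclass
class NullSettings:
    """Settings of the bootstrap null (surrogate count B, significance level
    alpha, absent-member policy, base seed)."""

    surrogate_count: int = 1000
    alpha: float = 0.05
    absent_policy: str = "skip"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.surrogate_count < 1:
            raise TableValidationError("surrogate count must be >= 1")
        if not 0 < self.alpha < 1:
            raise TableValidationError("alpha must be in (0, 1)")
        if self.absent_policy not in ABSENT_POLICIES:
            raise TableValidationError(
                f"absent-member policy must be one of {ABSENT_POLICIES}")


def relative_abundance(member: np.ndarray, depth: int) -> np.ndarray:
    """Per-(asv, sample) proportions of one equal-depth member.

    The denominator is the rarefaction depth; on the full pre-filter taxon
    set each sample's proportions sum to 1.
    """
    if depth <= 0:
        raise TableValidationError("zero-depth sample: proportions undefined")
    return member / float(depth)


def habitat_means(proportions: np.ndarray, labels: np.ndarray,
                  habitats: tuple) -> tuple[np.ndarray, float]:
    """Unweighted per-habitat means of one taxon's per-sample proportions,
    plus the overall mean across all samples.

    A habitat with zero samples gets a NaN mean (flagged undefined).
    """
    mu = np.empty(len(habitats))
    for j, h in enumerate(habitats):
        sel = labels == h
        mu[j] = proportions[sel].mean() if sel.any() else np.nan
    return mu, float(proportions.mean())


def null_affinity_p(proportions: np.ndarray, labels: np.ndarray, habitats: tuple,
                    settings: NullSettings, rng: np.random.Generator) -> np.ndarray:
    """Bootstrap p-value per habitat for one taxon in one member.

    ``proportions``: the taxon's per-sample relative abundances (length N).
    Surrogates resample these N values with replacement, labels fixed.
    Constant taxa (zero variance, including all-zero) get p = 1 everywhere.
    """
    n = proportions.size
    if np.all(proportions == proportions[0]):
        return np.ones(len(habitats))
    B = settings.surrogate_count
    idx = rng.integers(0, n, size=(B, n))
    vals = proportions[idx]
    p = np.empty(len(habitats))
    for j, h in enumerate(habitats):
        sel = labels == h
        if not sel.any():
            p[j] = np.nan
            continue
        actual = proportions[sel].mean()
        sur = vals[:, sel].mean(axis=1)
        p[j] = np.count_nonzero(sur > actual) / B
    return p


def _above_overall_tol(mu: np.ndarray, overall) -> np.ndarray:
    """Strictly-above comparison with a relative tolerance absorbing float
    rounding of the sample means (the weighted-mean identity is exact in real
    arithmetic)."""
    overall = np.asarray(overall)
    tol = 1e-9 * np.maximum(np.abs(overall), 1e-30)
    return mu > overall + tol


def _check_max_two_above_overall(mu: np.ndarray, overall: float) -> None:
    finite = np.isfinite(mu)
    if np.count_nonzero(_above_overall_tol(mu[finite], overall)) >= 3:
        raise AssertionError(
            "three habitat means strictly above the overall mean; the "
            "weighted-mean identity is violated")


@dataclass
class AffinityResult:
    """Ensemble-aggregated affinity results.

    ``table`` has one row per ASV with mean habitat relative abundances
    (mu_<habitat>), the overall mean, mean p-values (p_<habitat>), the
    affinity set and count, and the number of skipped (absent) members.
    """

    table: pd.DataFrame
    habitats: tuple
    settings: NullSettings


def affinity_ensemble(ensemble: RarefactionEnsemble, assignment: pd.Series,
                      settings: NullSettings | None = None) -> AffinityResult:
    """Run the null model for every ASV across every ensemble member and
    aggregate.

    Surrogate draws for (taxon t, member m) are seeded from
    ``(settings.seed, "affinity", m, t)``, so per-taxon results do not depend
    on iteration order. Members where a taxon has zero reads are handled by
    the absent-member policy (default "skip": excluded from its mean p-value
    and counted in ``members_skipped``).
    """
    settings = settings or NullSettings()
    labels = assignment.loc[list(ensemble.sample_ids)].to_numpy()
    habitats = tuple(pd.unique(labels))
    k = len(habitats)
    n_asv, n_m = ensemble.n_asvs, ensemble.n_members

    mu_sum = np.zeros((n_asv, k))
    overall_sum = np.zeros(n_asv)
    p_sum = np.zeros((n_asv, k))
    p_members = np.zeros(n_asv, dtype=np.int64)
    skipped = np.zeros(n_asv, dtype=np.int64)

    hab_sel = [labels == h for h in habitats]
    for m, cnt in enumerate(ensemble.members):
        props = relative_abundance(cnt, ensemble.depth)
        # habitat means for all taxa at once (vectorized over taxa)
        mu_m = np.column_stack([props[:, s].mean(axis=1) for s in hab_sel])
        overall_m = props.mean(axis=1)
        # exact identity check: at most two habitat means above the overall
        above = _above_overall_tol(mu_m, overall_m[:, None]).sum(axis=1)
        if np.any(above >= k) and k >= 3:
            raise AssertionError("a taxon has every habitat mean strictly above "
                                 "its overall mean")
        mu_sum += mu_m
        overall_sum += overall_m
        present = cnt.any(axis=1)
        absent_idx = np.flatnonzero(~present)
        if absent_idx.size and settings.absent_policy == "error":
            raise TableValidationError(
                f"taxon {ensemble.asv_ids[absent_idx[0]]!r} absent from member {m}")
        for t in range(n_asv):
            if not present[t]:
                if settings.absent_policy == "p1":
                    p_sum[t] += 1.0
                    p_members[t] += 1
                else:
                    skipped[t] += 1
                continue
            rng = rng_for(settings.seed, "affinity", m, t)
            p = null_affinity_p(props[t], labels, habitats, settings, rng)
            p_sum[t] += np.nan_to_num(p, nan=0.0)
            p_members[t] += 1

    if np.any(p_members == 0):
        bad = ensemble.asv_ids[p_members == 0]
        raise TableValidationError(
            f"taxa absent from all members: {list(bad[:5])}"
            f"{'...' if bad.size > 5 else ''}")

    mu_bar = mu_sum / n_m
    overall_bar = overall_sum / n_m
    p_bar = p_sum / p_members[:, None]
    affinity = p_bar < settings.alpha
    counts = affinity.sum(axis=1)
    if np.any(counts > 2) and k >= 3:
        raise AssertionError("a taxon was flagged with affinity for all habitats")

    table = pd.DataFrame({"asv_id": ensemble.asv_ids})
    for j, h in enumerate(habitats):
        table[f"mu_{h}"] = mu_bar[:, j]
    table["mu_overall"] = overall_bar
    for j, h in enumerate(habitats):
        table[f"p_{h}"] = p_bar[:, j]
    table["affinity_set"] = [",".join(str(habitats[j]) for j in np.flatnonzero(row))
                             for row in affinity]
    table["affinity_count"] = counts
    table["members_skipped"] = skipped
    return AffinityResult(table=table, habitats=habitats, settings=settings)


def aggregate_affinity(member_pvalues: np.ndarray, settings: NullSettings,
                       habitats: tuple) -> dict:
    """Aggregate one taxon's per-member p-values (rows = members, columns =
    habitats; NaN rows = absent members under policy "skip").

    Returns the mean p per habitat, the affinity set and the affinity count.
    """
    member_pvalues = np.asarray(member_pvalues, float)
    absent = np.all(np.isnan(member_pvalues), axis=1)
    if absent.all():
        raise TableValidationError("taxon absent from all members")
    contributing = member_pvalues[~absent]
    p_bar = contributing.mean(axis=0)
    aff = {h for j, h in enumerate(habitats) if p_bar[j] < settings.alpha}
    if len(aff) > 2 and len(habitats) >= 3:
        raise AssertionError("affinity for all habitats is impossible")
    return {"p_bar": p_bar, "affinity_set": aff, "affinity_count": len(aff),
            "members_skipped": int(absent.sum())}


def exact_null_p(proportions: np.ndarray, labels: np.ndarray,
                 habitats: tuple) -> np.ndarray:
    """Exact p-values by exhaustive enumeration of all N^N with-replacement
    resamples. Exponential cost; intended for N <= 6 oracle checks."""
    n = proportions.size
    if n > 8:
        raise TableValidationError("exhaustive enumeration is limited to N <= 8")
    grids = np.meshgrid(*([np.arange(n)] * n), indexing="ij")
    idx = np.stack([g.ravel() for g in grids], axis=1)  # (n^n, n)
    vals = proportions[idx]
    p = np.empty(len(habitats))
    for j, h in enumerate(habitats):
        sel = labels == h
        actual = proportions[sel].mean()
        sur = vals[:, sel].mean(axis=1)
        p[j] = np.count_nonzero(sur > actual) / sur.size
    return p
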