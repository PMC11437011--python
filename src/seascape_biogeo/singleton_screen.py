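"""Singleton detection/removal and the read-count mixture diagnostic.

A singleton is an ASV observed in at most one sample; such taxa are removed
before biogeographic classification and affinity testing because a taxon seen
once carries no habitat signal and is plausibly a sequencing artifact. Since
all occurrence statistics in this pipeline are ensemble statistics, singleton
status is evaluated on the rarefaction ensemble: under the default "max" rule
an ASV is a singleton when its sample occurrence is <= 1 in every member;
under the "mean" rule when its mean occurrence across members is <= 1.

The Gaussian-mixture/BIC diagnostic asks whether the distribution of log10
mean reads per ASV is better described by two modes (a low-read
singleton-like mode plus the main community) than by one; it justifies the
filter but never changes the filter set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .rarefaction_ensemble import RarefactionEnsemble
from .table_io import TableValidationError, logger, rng_for

SINGLETON_RULES = ("max", "mean")


@dataclass
class SingletonReport:
    """Per-ASV singleton flags plus the occurrence statistic they were based
    on, and mean-read summaries of the two groups."""

    table: pd.DataFrame  # asv_id, occurrence_stat, singleton, zero_occurrence
    rule: str
    ensemble_fingerprint: str
    mean_reads_singletons: float
    mean_reads_others: float

    @property
    def flags(self) -> np.ndarray:
        return self.table["singleton"].to_numpy(bool)


def detect_singletons(ensemble: RarefactionEnsemble, rule: str = "max") -> SingletonReport:
    """Flag singleton ASVs on the rarefied ensemble.

    rule "max": occurrence <= 1 in every member (strictest reading of "found
    at most in only one sample"); rule "mean": mean occurrence <= 1.
    All-zero ASVs are singletons under both rules and get a zero-occurrence
    note.
    """
    if rule not in SINGLETON_RULES:
        raise TableValidationError(
            f"unknown singleton rule {rule!r}; choose from {SINGLETON_RULES}")
    n_m = ensemble.n_members
    occ = np.empty((n_m, ensemble.n_asvs))
    reads = np.empty((n_m, ensemble.n_asvs))
    for m, cnt in enumerate(ensemble.members):
        occ[m] = (cnt > 0).sum(axis=1)
        reads[m] = cnt.sum(axis=1)
    if rule == "max":
        stat = occ.max(axis=0)
    else:
        stat = occ.mean(axis=0)
    flags = stat <= 1.0
    mean_reads = reads.mean(axis=0)
    zero = occ.max(axis=0) == 0
    if zero.any():
        logger.info("%d ASV(s) have zero occurrence in every member", int(zero.sum()))
    table = pd.DataFrame({
        "asv_id": ensemble.asv_ids,
        "occurrence_stat": stat,
        "mean_reads": mean_reads,
        "singleton": flags,
        "zero_occurrence": zero,
    })
    return SingletonReport(
        table=table,
        rule=rule,
        ensemble_fingerprint=ensemble.fingerprint,
        mean_reads_singletons=float(mean_reads[flags].mean()) if flags.any() else float("nan"),
        mean_reads_others=float(mean_reads[~flags].mean()) if (~flags).any() else float("nan"),
    )


def drop_singletons(ensemble: RarefactionEnsemble,
                    report: SingletonReport) -> RarefactionEnsemble:
    """Remove flagged ASVs from every member.

    The relative-abundance denominator downstream remains the rarefaction
    depth, so retained taxa keep the proportions they had before filtering.
    """
    if report.ensemble_fingerprint != ensemble.fingerprint:
        raise TableValidationError(
            "singleton report was derived from a different ensemble "
            f"({report.ensemble_fingerprint!r} != {ensemble.fingerprint!r})")
    flags = report.flags
    if flags.all():
        raise TableValidationError("all ASVs flagged as singletons: empty analysis set")
    return ensemble.select_asvs(~flags)


# ---------------------------------------------------------------------------
# Univariate Gaussian mixture via EM, for the BIC diagnostic
# ---------------------------------------------------------------------------

@dataclass
class GmmFit:
    """One fitted univariate Gaussian mixture on log10 mean reads."""

    k: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    log_likelihood: float
    bic: float
    n: int
    loglik_trajectories: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if not np.isclose(self.weights.sum(), 1.0, atol=1e-8):
            raise TableValidationError("mixture weights must sum to 1")
        if np.any(self.sds <= 0) or not np.isfinite(self.bic):
            raise TableValidationError("degenerate mixture fit")


def _em_once(x: np.ndarray, k: int, rng: np.random.Generator,
             tol: float, max_iter: int, min_sd: float):
    """One EM run from a random start; returns (logL, params, trajectory) or
    None when a component's sd collapses."""
    n = x.size
    means = rng.choice(x, size=k, replace=False)
    sds = np.full(k, x.std() if x.std() > 0 else 1.0)
    weights = np.full(k, 1.0 / k)
    traj: list[float] = []
    prev = -np.inf
    xc = x[:, None]
    log_2pi = float(np.log(2.0 * np.pi))
    for _ in range(max_iter):
        # E step (inline normal log-pdf; this loop dominates the diagnostic)
        z = (xc - means[None, :]) / sds[None, :]
        log_comp = (np.log(weights) - np.log(sds) - 0.5 * log_2pi)[None, :] \
            - 0.5 * z * z
        log_norm = logsumexp(log_comp, axis=1)
        ll = float(log_norm.sum())
        traj.append(ll)
        resp = np.exp(log_comp - log_norm[:, None])
        # M step
        nk = resp.sum(axis=0)
        if np.any(nk <= 0):
            return None
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        sds = np.sqrt(var)
        if np.any(sds < min_sd):
            return None
        if ll - prev < tol and np.isfinite(prev):
            break
        prev = ll
    return ll, (weights, means, sds), traj


def fit_gmm_bic(log_reads: np.ndarray, k_range=range(1, 10), n_restarts: int = 20,
                tol: float = 1e-8, max_iter: int = 500, min_sd: float = 1e-6,
                seed: int = 0) -> list[GmmFit]:
    """Fit univariate Gaussian mixtures for each k and score them with BIC.

    BIC = k_params * ln(n) - 2 * logL with k_params = 3k - 1 (k means, k sds,
    k-1 free weights); lower is better. Each k gets ``n_restarts`` seeded EM
    restarts; a restart whose component sd collapses below ``min_sd`` is
    discarded, and an error is raised only when every restart for some k
    degenerates.
    """
    x = np.asarray(log_reads, float)
    x = x[np.isfinite(x)]
    kmax = max(k_range)
    if x.size < 2 * kmax:
        raise TableValidationError(
            f"need at least {2 * kmax} observations for k up to {kmax}, got {x.size}")
    fits: list[GmmFit] = []
    for k in k_range:
        best = None
        trajectories = []
        for r in range(n_restarts):
            rng = rng_for(seed, "gmm", k, r)
            res = _em_once(x, k, rng, tol, max_iter, min_sd)
            if res is None:
                continue
            ll, params, traj = res
            trajectories.append(traj)
            if best is None or ll > best[0]:
                best = (ll, params)
        if best is None:
            raise TableValidationError(
                f"all {n_restarts} EM restarts degenerated for k={k}")
        ll, (weights, means, sds) = best
        k_params = 3 * k - 1
        bic = k_params * np.log(x.size) - 2.0 * ll
        order = np.argsort(means)
        fits.append(GmmFit(k=k, weights=weights[order], means=means[order],
                           sds=sds[order], log_likelihood=ll, bic=float(bic),
                           n=x.size, loglik_trajectories=trajectories))
    return fits


def bic_table(fits: list[GmmFit]) -> pd.DataFrame:
    """BIC per k plus the improvement (BIC drop) at each k-1 -> k increment."""
    df = pd.DataFrame({"k": [f.k for f in fits], "bic": [f.bic for f in fits],
                       "log_likelihood": [f.log_likelihood for f in fits]})
    df["bic_improvement"] = -df["bic"].diff()
    return df


def best_bic_increment(fits: list[GmmFit]) -> int:
    """The k at which the largest BIC improvement (drop) occurs, i.e. the
    right endpoint of the best (k-1 -> k) increment."""
    df = bic_table(fits)
    idx = df["bic_improvement"].idxmax()
    return int(df.loc[idx, "k"])
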