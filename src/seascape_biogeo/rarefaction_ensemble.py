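"""Repeated rarefaction of ASV count tables.

Rarefaction subsamples each sample's reads without replacement (a multivariate
hypergeometric draw) to a common depth, removing library-size effects. A
single rarefaction discards rare reads at random, so the pipeline builds an
ensemble of independent rarefactions of the same table and computes all
downstream occurrence/abundance statistics as means (with 5%/95% percentile
bands) across members.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .table_io import CountMatrix, StationMap, derive_seed, logger, rng_for


class InsufficientDepthError(ValueError):
    """A sample's library size is below the requested rarefaction depth."""


def rarefy_sample(counts: np.ndarray, depth: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Subsample one sample's read counts to ``depth`` reads without
    replacement (multivariate hypergeometric)."""
    counts = np.asarray(counts)
    total = int(counts.sum())
    if total < depth:
        raise InsufficientDepthError(
            f"sample has {total} reads, below rarefaction depth {depth}")
    return rng.multivariate_hypergeometric(counts, depth)


@dataclass
class RarefactionEnsemble:
    """An ordered collection of equal-depth rarefied count tables.

    Every member shares the parent table's ASV ordering and the retained
    sample ordering; samples whose library size was below ``depth`` were
    dropped once, identically across members.
    """

    depth: int
    asv_ids: np.ndarray
    sample_ids: np.ndarray
    members: list
    dropped_sample_ids: np.ndarray
    member_seeds: list
    fingerprint: str = ""

    def __post_init__(self) -> None:
        if not self.fingerprint:
            self.fingerprint = (f"d{self.depth}-m{len(self.members)}-"
                                f"a{len(self.asv_ids)}-s{len(self.sample_ids)}")

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def n_asvs(self) -> int:
        return int(self.asv_ids.size)

    @property
    def n_samples(self) -> int:
        return int(self.sample_ids.size)

    def validate(self) -> None:
        """Check the equal-depth invariant on every member."""
        for m, cnt in enumerate(self.members):
            sums = cnt.sum(axis=0)
            if not np.all(sums == self.depth):
                bad = self.sample_ids[sums != self.depth]
                raise AssertionError(
                    f"member {m}: samples {list(bad)} do not sum to depth {self.depth}")

    def select_asvs(self, keep_mask: np.ndarray) -> "RarefactionEnsemble":
        """New ensemble restricted to the ASVs where ``keep_mask`` is True.

        Column sums no longer equal the depth; the rarefaction depth remains
        the relative-abundance denominator downstream.
        """
        keep_mask = np.asarray(keep_mask, bool)
        return RarefactionEnsemble(
            depth=self.depth,
            asv_ids=self.asv_ids[keep_mask],
            sample_ids=self.sample_ids,
            members=[m[keep_mask] for m in self.members],
            dropped_sample_ids=self.dropped_sample_ids,
            member_seeds=self.member_seeds,
            fingerprint=self.fingerprint + f"-f{int(keep_mask.sum())}",
        )


def build_ensemble(matrix: CountMatrix, depth: int, n_members: int,
                   base_seed: int, dtype=np.int32) -> RarefactionEnsemble:
    """Rarefy ``matrix`` to ``depth`` reads per sample, ``n_members`` times.

    Samples below depth are dropped once, uniformly across members, with a
    logged warning; member ``i`` uses the seed derived from
    ``(base_seed, "rarefy", i)``.
    """
    lib = matrix.library_sizes()
    keep = lib >= depth
    if not keep.any():
        raise InsufficientDepthError(
            f"no sample reaches rarefaction depth {depth} "
            f"(max library size {int(lib.max()) if lib.size else 0})")
    dropped = matrix.sample_ids[~keep]
    if dropped.size:
        logger.warning("dropping %d sample(s) below depth %d: %s",
                       dropped.size, depth, list(dropped))
    cols = np.flatnonzero(keep)
    base = matrix.counts[:, cols]
    members, seeds = [], []
    for i in range(n_members):
        seed = derive_seed(base_seed, "rarefy", i)
        rng = np.random.Generator(np.random.PCG64(seed))
        out = np.empty(base.shape, dtype=dtype)
        for j in range(base.shape[1]):
            out[:, j] = rarefy_sample(base[:, j], depth, rng)
        members.append(out)
        seeds.append(seed)
    return RarefactionEnsemble(
        depth=depth,
        asv_ids=matrix.asv_ids.copy(),
        sample_ids=matrix.sample_ids[keep].copy(),
        members=members,
        dropped_sample_ids=dropped.copy(),
        member_seeds=seeds,
    )


def _nearest_rank_percentiles(values: np.ndarray, qs=(5.0, 95.0)) -> list:
    """Nearest-rank percentiles along axis 0 (members)."""
    n = values.shape[0]
    srt = np.sort(values, axis=0)
    out = []
    for q in qs:
        rank = max(int(np.ceil(q / 100.0 * n)), 1) - 1
        out.append(srt[rank])
    return out


def summarize_occurrence(ensemble: RarefactionEnsemble,
                         station_map: StationMap | None = None) -> pd.DataFrame:
    """Per-ASV ensemble occurrence/abundance summary.

    For each ASV: the mean over members of total reads, of the number of
    samples with >= 1 read, and (given a station map) of the number of
    stations with >= 1 read, with 5th/95th nearest-rank percentiles across
    members, and ranks by descending mean.
    """
    n_m = ensemble.n_members
    reads = np.empty((n_m, ensemble.n_asvs))
    occ_samples = np.empty((n_m, ensemble.n_asvs))
    occ_stations = None
    if station_map is not None:
        stations = station_map.stations_for(ensemble.sample_ids)
        uniq_stations = pd.unique(stations)
        st_cols = [np.flatnonzero(stations == st) for st in uniq_stations]
        occ_stations = np.empty((n_m, ensemble.n_asvs))
    for m, cnt in enumerate(ensemble.members):
        pres = cnt > 0
        reads[m] = cnt.sum(axis=1)
        occ_samples[m] = pres.sum(axis=1)
        if occ_stations is not None:
            occ_stations[m] = np.sum(
                [pres[:, c].any(axis=1) for c in st_cols], axis=0)

    out = pd.DataFrame({"asv_id": ensemble.asv_ids})
    for name, arr in (("reads", reads), ("occ_samples", occ_samples),
                      ("occ_stations", occ_stations)):
        if arr is None:
            continue
        mean = arr.mean(axis=0)
        p5, p95 = _nearest_rank_percentiles(arr)
        if np.any((p5 > mean) | (p95 < mean)):
            logger.warning("%s: percentile band does not bracket the mean for "
                           "%d ASV(s) (skewed small ensemble)", name,
                           int(np.sum((p5 > mean) | (p95 < mean))))
        out[f"mean_{name}"] = mean
        out[f"p5_{name}"] = p5
        out[f"p95_{name}"] = p95
    # ranks by descending mean; ties broken by first occurrence for a
    # reproducible permutation
    out["abundance_rank"] = _descending_rank(out["mean_reads"].to_numpy())
    out["occurrence_rank"] = _descending_rank(out["mean_occ_samples"].to_numpy())
    return out


def _descending_rank(values: np.ndarray) -> np.ndarray:
    order = np.argsort(-values, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(1, order.size + 1)
    return ranks
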