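"""Pelagic-habitat classification with a self-organizing map (SOM).

Samples are embedded in a three-feature space — temperature (degC), salinity
(PSU) and dissolved inorganic nitrogen (uM, log10-transformed by default) —
each feature z-scored. A classical online SOM summarizes the cloud with a 2-D
grid of prototype (codebook) vectors, the codebook is clustered
hierarchically (Ward linkage) into k seascapes, and each sample inherits the
cluster of its best-matching node. For k = 3 the clusters can be named after
the three Southern California Current surface water masses by simple centroid
rules: the freshest cluster is the subarctic water (PSUW); of the remaining
two, the warmer is the central water (ENPCW) and the nitrogen-richer is the
equatorial water (PEW).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .table_io import EnvTable, TableValidationError, logger, rng_for

DIN_EPS = 1e-3  # uM offset inside log10(din + eps); keeps zero DIN finite

WATER_MASS_NAMES = ("PSUW", "ENPCW", "PEW")


@dataclass
class Standardization:
    """Per-feature z-score constants plus the DIN transform flag, stored so
    new samples can be projected into the training feature space."""

    means: np.ndarray
    sds: np.ndarray
    log_din: bool

    def apply(self, env: EnvTable) -> np.ndarray:
        feats = env.features()
        if self.log_din:
            feats = feats.copy()
            feats[:, 2] = np.log10(feats[:, 2] + DIN_EPS)
        return (feats - self.means) / self.sds


def standardize_env(env: EnvTable, log_din: bool = True,
                    ) -> tuple[np.ndarray, Standardization]:
    """Z-score (T, S, DIN) features (sample sd, ddof=1; DIN on log10 by
    default). Two samples at 10 and 20 degC standardize to -1/sqrt(2) and
    +1/sqrt(2)."""
    feats = env.features()
    if log_din:
        feats = feats.copy()
        feats[:, 2] = np.log10(feats[:, 2] + DIN_EPS)
    means = feats.mean(axis=0)
    sds = feats.std(axis=0, ddof=1)
    zero = sds <= 0
    if zero.any():
        names = np.asarray(["temperature", "salinity", "din"])[zero]
        raise TableValidationError(
            f"zero-variance feature(s) {list(names)}: degenerate environmental "
            "input, habitat classification is not meaningful")
    const = Standardization(means, sds, log_din)
    return (feats - means) / sds, const


@dataclass
class SomModel:
    """A trained SOM: grid shape, codebook in standardized feature space,
    training parameters, and the feature standardization constants."""

    grid: tuple[int, int]
    codebook: np.ndarray  # (rows*cols, n_features)
    standardization: Standardization
    n_steps: int
    learning_rate: float
    radius: float

    @property
    def n_nodes(self) -> int:
        return self.grid[0] * self.grid[1]

    def node_positions(self) -> np.ndarray:
        r, c = self.grid
        rr, cc = np.meshgrid(np.arange(r), np.arange(c), indexing="ij")
        return np.column_stack([rr.ravel(), cc.ravel()]).astype(float)

    def bmu(self, features: np.ndarray) -> np.ndarray:
        """Best-matching unit index per row of ``features`` (ties -> lowest
        node index, the argmin convention)."""
        d2 = ((features[:, None, :] - self.codebook[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)

    def quantization_error(self, features: np.ndarray) -> float:
        d2 = ((features[:, None, :] - self.codebook[None, :, :]) ** 2).sum(axis=2)
        return float(np.sqrt(d2.min(axis=1)).mean())


def train_som(features: np.ndarray, grid: tuple[int, int] = (10, 10),
              n_steps: int | None = None, learning_rate: float = 0.5,
              radius: float | None = None, seed: int = 0,
              standardization: Standardization | None = None) -> SomModel:
    """Train a classical online SOM on standardized features.

    The codebook is initialized from randomly chosen data rows; at each step
    one random sample is presented, its best-matching unit found by Euclidean
    distance, and all nodes are pulled toward it with a Gaussian neighborhood
    whose radius and learning rate decay exponentially (both reach ~1/e of
    roughly their final fraction at the last step; the radius decays to 1
    node). Deterministic given the seed.
    """
    features = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(features)):
        raise TableValidationError("non-finite feature passed to SOM training")
    rows, cols = int(grid[0]), int(grid[1])
    if rows < 2 or cols < 2:
        raise TableValidationError("SOM grid must be at least 2x2")
    n = features.shape[0]
    if n < 1:
        raise TableValidationError("no samples to train on")
    if n_steps is None:
        n_steps = 100 * n
    if radius is None:
        radius = float(np.hypot(rows - 1, cols - 1)) / 2.0

    rng = rng_for(seed, "som")
    codebook = features[rng.integers(0, n, rows * cols)].copy()
    pos = np.column_stack([np.repeat(np.arange(rows), cols),
                           np.tile(np.arange(cols), rows)]).astype(float)
    # pairwise squared grid distances between nodes
    grid_d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)

    # exponential decay: radius from radius0 to 1 node, lr from lr0 to 1% of lr0
    t = np.arange(n_steps)
    radius_t = radius * (1.0 / max(radius, 1.0)) ** (t / max(n_steps - 1, 1))
    lr_t = learning_rate * 0.01 ** (t / max(n_steps - 1, 1))
    order = rng.integers(0, n, n_steps)

    for step in range(n_steps):
        x = features[order[step]]
        d2 = ((codebook - x) ** 2).sum(axis=1)
        bmu = int(d2.argmin())
        sigma2 = 2.0 * radius_t[step] ** 2
        h = np.exp(-grid_d2[bmu] / sigma2)
        codebook += (lr_t[step] * h)[:, None] * (x - codebook)

    if standardization is None:
        standardization = Standardization(np.zeros(features.shape[1]),
                                          np.ones(features.shape[1]), False)
    return SomModel((rows, cols), codebook, standardization,
                    n_steps, learning_rate, radius)


def cluster_codebook(model: SomModel, k: int = 3) -> np.ndarray:
    """Agglomerative (Ward linkage, Euclidean) clustering of the codebook,
    cut at ``k`` clusters. Returns a label in 1..k per SOM node."""
    if k > model.n_nodes:
        raise TableValidationError(
            f"k={k} exceeds the number of SOM nodes ({model.n_nodes})")
    if k == model.n_nodes:
        return np.arange(1, k + 1)
    Z = linkage(model.codebook, method="ward", metric="euclidean")
    return fcluster(Z, t=k, criterion="maxclust")


def assign_samples(model: SomModel, node_labels: np.ndarray,
                   env: EnvTable) -> pd.DataFrame:
    """Label each sample by its best-matching node's cluster.

    Returns a DataFrame (sample_id, habitat, bmu_row, bmu_col); BMU ties are
    broken by the lowest node index.
    """
    node_labels = np.asarray(node_labels)
    if node_labels.size != model.n_nodes:
        raise TableValidationError("one label per SOM node is required")
    feats = model.standardization.apply(env)
    bmus = model.bmu(feats)
    rows = bmus // model.grid[1]
    cols = bmus % model.grid[1]
    return pd.DataFrame({
        "sample_id": env.sample_ids,
        "habitat": node_labels[bmus].astype(int),
        "bmu_row": rows,
        "bmu_col": cols,
    })


def assignment_series(assignment: pd.DataFrame) -> pd.Series:
    """sample_id -> habitat label Series (named labels when present)."""
    col = "habitat_name" if "habitat_name" in assignment.columns else "habitat"
    return pd.Series(assignment[col].to_numpy(),
                     index=assignment["sample_id"].to_numpy(), name="habitat")


def name_habitats(assignment: pd.DataFrame, env: EnvTable) -> pd.DataFrame:
    """Attach water-mass names to a k=3 assignment by centroid rules.

    Lowest-salinity cluster -> PSUW; of the remaining two, the warmer ->
    ENPCW and the DIN-richer -> PEW. If the two rules point at the same
    remaining cluster (or centroids tie), names are withheld with a warning
    and the numeric labels stand.
    """
    out = assignment.copy()
    labels = np.unique(out["habitat"])
    if labels.size != 3:
        logger.info("habitat naming skipped: %d clusters (need 3)", labels.size)
        return out
    env_df = env.data.set_index("sample_id")
    cent = {}
    for lab in labels:
        sids = out.loc[out["habitat"] == lab, "sample_id"]
        sub = env_df.loc[sids]
        cent[lab] = (sub["temperature_c"].mean(), sub["salinity_psu"].mean(),
                     sub["din_umol"].mean())
    sal = {lab: c[1] for lab, c in cent.items()}
    vals = sorted(sal.values())
    if vals[0] == vals[1]:
        logger.warning("habitat naming withheld: salinity centroids tie")
        return out
    psuw = min(sal, key=sal.get)
    rest = [lab for lab in labels if lab != psuw]
    a, b = rest
    warmer = a if cent[a][0] > cent[b][0] else b if cent[b][0] > cent[a][0] else None
    richer = a if cent[a][2] > cent[b][2] else b if cent[b][2] > cent[a][2] else None
    if warmer is None or richer is None or warmer == richer:
        logger.warning("habitat naming withheld: temperature and DIN rules "
                       "conflict for clusters %s and %s", a, b)
        return out
    names = {psuw: "PSUW", warmer: "ENPCW", richer: "PEW"}
    out["habitat_name"] = out["habitat"].map(names)
    return out
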