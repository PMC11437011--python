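"""Core tabular types and I/O for the seascape biogeography pipeline.

Holds the central count-matrix container, environmental metadata, the pipeline
configuration, deterministic seed derivation, and the readers/writers for every
plain-text artifact the pipeline consumes or produces.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("seascape_biogeo")

ENV_COLUMNS = ("sample_id", "temperature_c", "salinity_psu", "din_umol")


def setup_logging(level: str = "INFO", logfile: str | Path | None = None) -> None:
    """Configure the package logger with a plain-text format (optional file)."""
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    logger.setLevel(level.upper())
    logger.handlers.clear()
    for h in handlers:
        h.setFormatter(fmt)
        logger.addHandler(h)


# ---------------------------------------------------------------------------
# Seed derivation
# ---------------------------------------------------------------------------

def derive_seed(base_seed: int, stage: str, *indices: int) -> np.random.SeedSequence:
    """Derive a reproducible :class:`numpy.random.SeedSequence` for one stage.

    The derivation is a pure function of ``(base_seed, stage, *indices)``:
    the stage name is hashed with CRC-32 so every pipeline stage draws from an
    independent stream regardless of execution order.
    """
    return np.random.SeedSequence([int(base_seed) & 0x7FFFFFFF,
                                   zlib.crc32(stage.encode("utf-8")),
                                   *(int(i) for i in indices)])


def rng_for(base_seed: int, stage: str, *indices: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(derive_seed(base_seed, stage, *indices)))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

class TableValidationError(ValueError):
    """Raised when a tabular input violates its contract."""


@dataclass
class CountMatrix:
    """ASV-by-sample table of non-negative integer read counts.

    ``counts`` has shape ``(len(asv_ids), len(sample_ids))``.
    """

    asv_ids: np.ndarray
    sample_ids: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.asv_ids = np.asarray(self.asv_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        counts = np.asarray(self.counts)
        if counts.shape != (self.asv_ids.size, self.sample_ids.size):
            raise TableValidationError(
                f"counts shape {counts.shape} does not match "
                f"{self.asv_ids.size} ASVs x {self.sample_ids.size} samples")
        if counts.dtype.kind == "f":
            if not np.all(np.isfinite(counts)) or np.any(counts != np.floor(counts)):
                bad = np.argwhere((counts != np.floor(counts)) | ~np.isfinite(counts))
                r, c = bad[0]
                raise TableValidationError(
                    f"non-integer count {counts[r, c]!r} at ASV "
                    f"{self.asv_ids[r]!r}, sample {self.sample_ids[c]!r}")
            counts = counts.astype(np.int64)
        elif counts.dtype.kind not in "iu":
            raise TableValidationError(f"counts must be integral, got dtype {counts.dtype}")
        if np.any(counts < 0):
            r, c = np.argwhere(counts < 0)[0]
            raise TableValidationError(
                f"negative count {counts[r, c]} at ASV {self.asv_ids[r]!r}, "
                f"sample {self.sample_ids[c]!r}")
        for name, ids in (("asv_ids", self.asv_ids), ("sample_ids", self.sample_ids)):
            if len(set(ids)) != len(ids):
                seen: set = set()
                dups = sorted({str(x) for x in ids if x in seen or seen.add(x)})
                raise TableValidationError(f"duplicate identifiers in {name}: {dups}")
        self.counts = np.ascontiguousarray(counts)

    @property
    def n_asvs(self) -> int:
        return int(self.asv_ids.size)

    @property
    def n_samples(self) -> int:
        return int(self.sample_ids.size)

    def library_sizes(self) -> np.ndarray:
        """Per-sample column sums (total reads per sample)."""
        return self.counts.sum(axis=0)

    def check_no_empty_samples(self) -> None:
        empty = self.library_sizes() == 0
        if empty.any():
            raise TableValidationError(
                f"samples with zero reads: {list(self.sample_ids[empty])}")

    def sample_index(self) -> dict:
        return {s: i for i, s in enumerate(self.sample_ids)}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.asv_ids, name="asv_id"),
                            columns=list(self.sample_ids))


@dataclass
class EnvTable:
    """Per-sample environmental metadata: temperature (degC), salinity (PSU),
    dissolved inorganic nitrogen (NO3 + NH3, uM)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in ENV_COLUMNS if c not in df.columns]
        if missing:
            raise TableValidationError(f"environmental table missing columns: {missing}")
        df = df.loc[:, list(ENV_COLUMNS)].copy()
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise TableValidationError(f"duplicate sample_id in environmental table: {dups}")
        for col in ENV_COLUMNS[1:]:
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any():
                bad = df.loc[vals.isna(), "sample_id"].tolist()
                raise TableValidationError(f"non-numeric {col} for samples {bad}")
            df[col] = vals.astype(float)
        if not np.isfinite(df[["temperature_c", "salinity_psu"]].to_numpy()).all():
            raise TableValidationError("temperature/salinity must be finite")
        if (df["din_umol"] < 0).any():
            bad = df.loc[df["din_umol"] < 0, "sample_id"].tolist()
            raise TableValidationError(f"negative DIN concentration for samples {bad}")
        self.data = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> np.ndarray:
        return self.data["sample_id"].to_numpy(dtype=object)

    def features(self) -> np.ndarray:
        """(n_samples, 3) array of (temperature, salinity, DIN)."""
        return self.data[["temperature_c", "salinity_psu", "din_umol"]].to_numpy(float)

    def subset(self, sample_ids: Sequence) -> "EnvTable":
        keep = self.data["sample_id"].isin(list(sample_ids))
        return EnvTable(self.data.loc[keep].reset_index(drop=True))


@dataclass
class StationMap:
    """Total mapping sample_id -> station_id used for station-occurrence summaries."""

    mapping: dict

    def stations_for(self, sample_ids: Sequence) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.mapping]
        if missing:
            raise TableValidationError(f"samples missing from station map: {missing}")
        return np.asarray([self.mapping[s] for s in sample_ids], dtype=object)


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters; every stage's randomness flows from
    ``base_seed`` through :func:`derive_seed`."""

    rarefaction_depth: int = 10_000
    ensemble_size: int = 1000
    surrogate_count: int = 1000
    alpha: float = 0.05
    som_grid: tuple[int, int] = (10, 10)
    clustering_k: int = 3
    base_seed: int = 0
    singleton_rule: str = "max"
    log_din: bool = True
    counts_path: str | None = None
    env_path: str | None = None
    station_path: str | None = None
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.rarefaction_depth <= 0:
            raise TableValidationError("rarefaction depth must be > 0")
        if self.ensemble_size < 1:
            raise TableValidationError("ensemble size must be >= 1")
        if self.surrogate_count < 1:
            raise TableValidationError("surrogate count must be >= 1")
        if not 0 < self.alpha < 1:
            raise TableValidationError("alpha must be in (0, 1)")
        if self.clustering_k < 2:
            raise TableValidationError("clustering k must be >= 2")
        self.som_grid = (int(self.som_grid[0]), int(self.som_grid[1]))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - valid
        if unknown:
            raise TableValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["som_grid"] = list(self.som_grid)
        return d


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_count_matrix(path: str | Path, format: str = "tsv",
                      allow_empty_samples: bool = False) -> CountMatrix:
    """Read an ASV-by-sample count table.

    ``format="tsv"``: dense table, ASVs as rows (first column ``asv_id``),
    samples as columns. ``format="triplets"``: sparse three-column TSV
    (asv_id, sample_id, count); absent pairs are zero.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.index.name is None and df.columns.size == 0:
            raise TableValidationError(f"{path}: malformed header")
        if df.index.duplicated().any():
            raise TableValidationError(
                f"{path}: duplicate ASV ids {df.index[df.index.duplicated()].tolist()}")
        if pd.Index(df.columns).duplicated().any():
            raise TableValidationError(f"{path}: duplicate sample columns")
        arr = df.to_numpy()
        cm = CountMatrix(df.index.to_numpy(object), np.asarray(df.columns, object), arr)
    elif format == "triplets":
        df = pd.read_csv(path, sep="\t", header=0)
        if df.shape[1] != 3:
            raise TableValidationError(
                f"{path}: triplet format needs 3 columns (asv_id, sample_id, count)")
        df.columns = ["asv_id", "sample_id", "count"]
        if df.duplicated(["asv_id", "sample_id"]).any():
            raise TableValidationError(f"{path}: duplicate (asv_id, sample_id) triplets")
        wide = (df.pivot(index="asv_id", columns="sample_id", values="count")
                  .fillna(0))
        cm = CountMatrix(wide.index.to_numpy(object),
                         np.asarray(wide.columns, object), wide.to_numpy())
    else:
        raise TableValidationError(f"unknown count-matrix format {format!r}")
    if not allow_empty_samples:
        cm.check_no_empty_samples()
    return cm


def write_count_matrix(cm: CountMatrix, path: str | Path) -> None:
    """Write a count matrix in canonical dense TSV form."""
    cm.to_dataframe().to_csv(path, sep="\t")


def read_env_table(path: str | Path) -> EnvTable:
    """Read per-sample environmental metadata from CSV
    (columns sample_id, temperature_c, salinity_psu, din_umol)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return EnvTable(pd.read_csv(path))


def write_env_table(env: EnvTable, path: str | Path) -> None:
    env.data.to_csv(path, index=False)


def read_station_map(path: str | Path) -> StationMap:
    """Read a two-column CSV (sample_id, station_id)."""
    df = pd.read_csv(path)
    if not {"sample_id", "station_id"} <= set(df.columns):
        raise TableValidationError(f"{path}: need columns sample_id, station_id")
    if df["sample_id"].duplicated().any():
        raise TableValidationError(f"{path}: duplicate sample_id")
    return StationMap(dict(zip(df["sample_id"], df["station_id"])))


# ---------------------------------------------------------------------------
# Result writers
# ---------------------------------------------------------------------------

RESULT_COLUMN_ORDER: dict[str, list[str]] = {}


def write_results_tables(records: Mapping[str, pd.DataFrame], out_dir: str | Path,
                         config: PipelineConfig | None = None) -> list[Path]:
    """Write one TSV per record family plus a run manifest.

    Column order within each family is deterministic (sorted insertion order of
    the DataFrame); rerunning with an identical config + seed yields
    byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for family, df in records.items():
        p = out / f"{family}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.10g")
        written.append(p)
    manifest = {
        "families": sorted(records.keys()),
        "config": config.to_dict() if config is not None else None,
    }
    mp = out / "run_manifest.json"
    with open(mp, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(mp)
    return written
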