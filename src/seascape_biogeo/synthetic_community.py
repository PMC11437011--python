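"""Synthetic marine-microbiome communities with planted biogeographic structure.

Emulates a regional amplicon survey in which near-surface samples fall into
three pelagic habitats (water masses) with distinct temperature / salinity /
dissolved-nitrogen envelopes, and taxa are planted as endemic (one habitat),
generalist (two habitats), or cosmopolitan (all habitats), with or without an
extra within-habitat enrichment, on top of a large randomly distributed rare
fraction. Ground truth is returned alongside the data so every downstream
stage can be tested for parameter recovery.

Default environmental envelopes follow the three surface water masses of the
Southern California Current region: a fresh/cool/nutrient-poor subarctic water
(PSUW), a warm/salty/nutrient-poor central water (ENPCW), and a
cool/salty/nutrient-rich equatorial water (PEW). DIN is modeled lognormal:
concentrations are positive and right-skewed, and the nutrient-rich /
nutrient-poor contrast is a contrast of log-means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .table_io import CountMatrix, EnvTable, TableValidationError, rng_for

HABITATS = ("PSUW", "ENPCW", "PEW")

#: taxon classes, in generation order
TAXON_CLASSES = (
    "endemic", "endemic_affinity",
    "generalist", "generalist_affinity",
    "cosmopolitan", "cosmopolitan_affinity",
    "random_rare",
)

#: the biogeographic category each planted class should recover to
CLASS_TO_CATEGORY = {
    "endemic": "endemic",
    "endemic_affinity": "endemic",
    "generalist": "generalist",
    "generalist_affinity": "generalist",
    "cosmopolitan": "cosmopolitan",
    "cosmopolitan_affinity": "cosmopolitan",
    "random_rare": None,  # unstructured; no planted category
}


@dataclass
class HabitatEnv:
    """Environmental envelope of one habitat: means and sds of temperature
    (degC), salinity (PSU) and log10 DIN (log10 uM)."""

    t_mean: float
    t_sd: float
    s_mean: float
    s_sd: float
    log_din_mean: float
    log_din_sd: float


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic survey.

    The defaults are the package's standard study conditions: 3 habitats x 150
    samples, ~5,000 taxa of which half are randomly distributed rare taxa,
    heavy-tailed (lognormal) baseline abundances, variable lognormal library
    sizes, and a spurious-singleton error mode that plants low-read taxa seen
    in a single sample each.
    """

    n_samples_per_habitat: dict = field(default_factory=lambda: {
        "PSUW": 150, "ENPCW": 150, "PEW": 150})
    habitat_env: dict = field(default_factory=lambda: {
        # fresh / cool / nutrient-poor
        "PSUW": HabitatEnv(12.0, 1.0, 32.8, 0.12, np.log10(0.3), 0.25),
        # warm / salty / nutrient-poor
        "ENPCW": HabitatEnv(19.0, 1.0, 33.6, 0.12, np.log10(0.2), 0.25),
        # cool / salty / nutrient-rich
        "PEW": HabitatEnv(13.0, 1.0, 33.5, 0.12, np.log10(4.0), 0.25),
    })
    n_taxa: dict = field(default_factory=lambda: {
        "endemic": 500, "endemic_affinity": 500,
        "generalist": 500, "generalist_affinity": 250,
        "cosmopolitan": 500, "cosmopolitan_affinity": 250,
        "random_rare": 2500,
    })
    # lognormal baseline abundance of structured taxa (natural-log scale)
    abundance_mu: float = 0.0
    abundance_sigma: float = 1.5
    # latent weight of each random-rare taxon, relative to the structured
    # median weight exp(abundance_mu); tiny and equal in every habitat
    rare_support: float = 0.005
    enrichment_factor: float = 10.0
    # lognormal library sizes (natural-log scale)
    library_mu: float = float(np.log(30_000.0))
    library_sigma: float = 0.35
    # expected number of spurious singleton taxa, as a fraction of real taxa
    singleton_error_rate: float = 0.0
    # minimum pairwise habitat separation (in pooled sds) before warning
    separation_margin: float = 2.0
    strict_separation: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_taxa.values()):
            raise TableValidationError("taxon counts must be >= 0")
        if any(n < 0 for n in self.n_samples_per_habitat.values()):
            raise TableValidationError("sample counts must be >= 0")
        for h, env in self.habitat_env.items():
            if min(env.t_sd, env.s_sd, env.log_din_sd) < 0:
                raise TableValidationError(f"negative sd in habitat {h}")
        if self.abundance_sigma <= 0 or self.library_sigma <= 0:
            raise TableValidationError("lognormal sigmas must be > 0")
        if self.singleton_error_rate < 0:
            raise TableValidationError("singleton error rate must be >= 0")
        self._check_separation()

    @property
    def habitats(self) -> tuple:
        return tuple(self.n_samples_per_habitat)

    def _check_separation(self) -> None:
        """Warn (or fail in strict mode) when two habitats' environmental
        envelopes are closer than ``separation_margin`` pooled sds in every
        feature simultaneously."""
        habs = list(self.habitat_env)
        for i, a in enumerate(habs):
            for b in habs[i + 1:]:
                ea, eb = self.habitat_env[a], self.habitat_env[b]
                seps = []
                for ma, mb, sa, sb in (
                        (ea.t_mean, eb.t_mean, ea.t_sd, eb.t_sd),
                        (ea.s_mean, eb.s_mean, ea.s_sd, eb.s_sd),
                        (ea.log_din_mean, eb.log_din_mean, ea.log_din_sd, eb.log_din_sd)):
                    pooled = max(np.hypot(sa, sb) / np.sqrt(2), 1e-12)
                    seps.append(abs(ma - mb) / pooled)
                if max(seps) < self.separation_margin:
                    msg = (f"habitats {a} and {b} are separated by < "
                           f"{self.separation_margin} pooled sds in every feature")
                    if self.strict_separation:
                        raise TableValidationError(msg)
                    warnings.warn(msg, stacklevel=3)


@dataclass
class SyntheticTruth:
    """Ground truth for one synthetic community.

    ``profiles`` holds the latent per-habitat relative-abundance weights
    (rows = taxa, columns = habitats, unnormalized); ``classes`` the planted
    class name per taxon; ``affinity_habitats`` the set of habitats whose
    profile entry was multiplied by the enrichment factor.
    """

    asv_ids: np.ndarray
    classes: np.ndarray
    affinity_habitats: list
    profiles: np.ndarray
    habitats: tuple

    def __post_init__(self) -> None:
        if np.any(self.profiles < 0):
            raise TableValidationError("latent profiles must be non-negative")
        if any(len(a) > 2 for a in self.affinity_habitats):
            raise TableValidationError("planted affinity sets must have size <= 2")
        endemic = np.isin(self.classes, ["endemic", "endemic_affinity"])
        if endemic.any() and np.any((self.profiles[endemic] > 0).sum(axis=1) != 1):
            raise TableValidationError("endemic profiles must have exactly one habitat")

    def category(self) -> np.ndarray:
        """Planted biogeographic category per taxon (None for random-rare)."""
        return np.asarray([CLASS_TO_CATEGORY[c] for c in self.classes], dtype=object)


def generate_env(spec: SyntheticSpec) -> tuple[EnvTable, pd.Series]:
    """Draw per-sample (T, S, DIN) from each habitat's envelope.

    Temperature and salinity are normal; DIN is lognormal (normal on log10,
    exponentiated). Returns the environmental table and the true habitat label
    per sample (a Series indexed by sample_id) for recovery tests.
    """
    rng = rng_for(spec.seed, "env")
    rows, labels = [], []
    for h in spec.habitats:
        env = spec.habitat_env[h]
        n = spec.n_samples_per_habitat[h]
        t = rng.normal(env.t_mean, env.t_sd, n)
        s = rng.normal(env.s_mean, env.s_sd, n)
        din = 10.0 ** rng.normal(env.log_din_mean, env.log_din_sd, n)
        for j in range(n):
            rows.append((f"{h}_s{j:04d}", t[j], s[j], din[j]))
            labels.append(h)
    df = pd.DataFrame(rows, columns=["sample_id", "temperature_c",
                                     "salinity_psu", "din_umol"])
    truth = pd.Series(labels, index=df["sample_id"].to_numpy(), name="habitat")
    return EnvTable(df), truth


def _habitat_support(cls: str, habitats: tuple, rng: np.random.Generator) -> np.ndarray:
    """Boolean support vector over habitats for one taxon of a given class."""
    k = len(habitats)
    sup = np.zeros(k, dtype=bool)
    if cls.startswith("endemic"):
        sup[rng.integers(k)] = True
    elif cls.startswith("generalist"):
        sup[rng.choice(k, size=2, replace=False)] = True
    else:  # cosmopolitan / random_rare
        sup[:] = True
    return sup


def generate_latent_profiles(spec: SyntheticSpec) -> SyntheticTruth:
    """Plant per-taxon latent habitat profiles.

    Each structured taxon draws a lognormal baseline weight, supported on one
    (endemic), two (generalist) or all (cosmopolitan) habitats; "affinity"
    variants additionally multiply exactly one supported habitat entry by the
    enrichment factor. Random-rare taxa get equal tiny support everywhere.
    """
    rng = rng_for(spec.seed, "profiles")
    habitats = spec.habitats
    k = len(habitats)
    ids, classes, aff_sets, profiles = [], [], [], []
    for cls in TAXON_CLASSES:
        n = spec.n_taxa.get(cls, 0)
        for i in range(n):
            if cls == "random_rare":
                w = spec.rare_support * np.exp(spec.abundance_mu)
                prof = np.full(k, w)
                aff: tuple = ()
            else:
                base = float(rng.lognormal(spec.abundance_mu, spec.abundance_sigma))
                sup = _habitat_support(cls, habitats, rng)
                prof = np.where(sup, base, 0.0)
                if cls.endswith("_affinity"):
                    j = int(rng.choice(np.flatnonzero(sup)))
                    prof[j] *= spec.enrichment_factor
                    aff = (habitats[j],)
                else:
                    aff = ()
            ids.append(f"{cls}_{i:05d}")
            classes.append(cls)
            aff_sets.append(aff)
            profiles.append(prof)
    return SyntheticTruth(np.asarray(ids, dtype=object),
                          np.asarray(classes, dtype=object),
                          aff_sets,
                          np.asarray(profiles, dtype=float),
                          habitats)


def sample_reads(truth: SyntheticTruth, assignment: pd.Series, spec: SyntheticSpec,
                 ) -> tuple[CountMatrix, np.ndarray]:
    """Draw the read-count table.

    Each sample's library size is lognormal (rounded); its reads are a single
    multinomial draw from its habitat's normalized latent profile. When the
    singleton error mode is on, spurious taxa with 1-10 reads in one random
    sample each are injected; their reads are carved out of the sample's
    library so column sums still equal the drawn library sizes exactly.
    """
    if tuple(truth.habitats) != tuple(spec.habitats):
        raise TableValidationError("truth and spec disagree on habitat labels")
    sample_ids = assignment.index.to_numpy(object)
    hab_index = {h: j for j, h in enumerate(truth.habitats)}
    unknown = set(assignment.unique()) - set(hab_index)
    if unknown:
        raise TableValidationError(f"assignment contains unknown habitats {unknown}")
    n_real, n_samp = truth.profiles.shape[0], sample_ids.size

    rng = rng_for(spec.seed, "reads")
    lib = np.round(rng.lognormal(spec.library_mu, spec.library_sigma, n_samp)).astype(np.int64)

    n_spurious = int(round(spec.singleton_error_rate * n_real))
    spur_counts = np.zeros((n_spurious, n_samp), dtype=np.int64)
    if n_spurious:
        spur_sample = rng.integers(0, n_samp, n_spurious)
        spur_reads = rng.integers(1, 11, n_spurious)
        for t in range(n_spurious):
            j = spur_sample[t]
            # carve out of the library so the column sum is preserved
            take = min(spur_reads[t], lib[j])
            spur_counts[t, j] = take

    counts = np.zeros((n_real, n_samp), dtype=np.int64)
    col_probs = {}
    for h, j in hab_index.items():
        prof = truth.profiles[:, j]
        tot = prof.sum()
        col_probs[h] = prof / tot if tot > 0 else None
    for j, sid in enumerate(sample_ids):
        p = col_probs[assignment.iloc[j]]
        size = int(lib[j] - spur_counts[:, j].sum())
        if p is None or size <= 0:
            continue  # habitat with no supported taxa, or fully spurious column
        counts[:, j] = rng.multinomial(size, p)

    if n_spurious:
        all_counts = np.vstack([counts, spur_counts])
        all_ids = np.concatenate([truth.asv_ids,
                                  np.asarray([f"spurious_{t:05d}" for t in range(n_spurious)],
                                             dtype=object)])
    else:
        all_counts, all_ids = counts, truth.asv_ids
    cm = CountMatrix(all_ids, sample_ids, all_counts)
    return cm, lib


def generate_community(spec: SyntheticSpec,
                       ) -> tuple[CountMatrix, EnvTable, pd.Series, SyntheticTruth, np.ndarray]:
    """Convenience end-to-end generation: env + truth + counts."""
    env, assignment = generate_env(spec)
    truth = generate_latent_profiles(spec)
    counts, lib = sample_reads(truth, assignment, spec)
    return counts, env, assignment, truth, lib
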