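"""End-to-end orchestration: counts + environment -> biogeography + affinity.

Glue over the stage modules; every stage draws its randomness from the one
base seed in the config through the documented seed derivation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import biogeography_classifier as biogeo
from . import habitat_affinity as affinity
from . import rarefaction_ensemble as rarefy
from . import seascape_som as som
from . import singleton_screen as screen
from .table_io import CountMatrix, EnvTable, PipelineConfig, StationMap, logger


@dataclass
class PipelineResult:
    assignment: pd.DataFrame
    occurrence: pd.DataFrame
    singleton_report: screen.SingletonReport
    biogeography: pd.DataFrame
    category_summary: pd.DataFrame
    affinity: affinity.AffinityResult
    n_asvs_analyzed: int


def classify_habitats(env: EnvTable, config: PipelineConfig) -> pd.DataFrame:
    """SOM + Ward habitat classification of the environmental table."""
    feats, const = som.standardize_env(env, log_din=config.log_din)
    model = som.train_som(feats, grid=config.som_grid, seed=config.base_seed,
                          standardization=const)
    node_labels = som.cluster_codebook(model, k=config.clustering_k)
    assignment = som.assign_samples(model, node_labels, env)
    if config.clustering_k == 3:
        assignment = som.name_habitats(assignment, env)
    return assignment


def run_pipeline(counts: CountMatrix, env: EnvTable, config: PipelineConfig,
                 station_map: StationMap | None = None,
                 run_affinity: bool = True) -> PipelineResult:
    """Full analysis: habitats, rarefaction ensemble, singleton screen,
    biogeographic classification, habitat affinity."""
    env_samples = set(env.sample_ids)
    missing_env = [s for s in counts.sample_ids if s not in env_samples]
    if missing_env:
        logger.warning("excluding %d sample(s) without environmental data: %s",
                       len(missing_env), missing_env[:5])
        keep = np.asarray([s in env_samples for s in counts.sample_ids])
        counts = CountMatrix(counts.asv_ids, counts.sample_ids[keep],
                             counts.counts[:, keep])

    assignment = classify_habitats(env, config)
    assign_series = som.assignment_series(assignment)

    ensemble = rarefy.build_ensemble(counts, config.rarefaction_depth,
                                     config.ensemble_size, config.base_seed)
    occurrence = rarefy.summarize_occurrence(ensemble, station_map)
    report = screen.detect_singletons(ensemble, rule=config.singleton_rule)
    filtered = screen.drop_singletons(ensemble, report)
    logger.info("singleton screen: %d of %d ASVs removed",
                int(report.flags.sum()), ensemble.n_asvs)

    records = biogeo.classify_ensemble(filtered, assign_series)
    summary = biogeo.summarize_categories(records)

    aff = None
    if run_affinity:
        settings = affinity.NullSettings(surrogate_count=config.surrogate_count,
                                         alpha=config.alpha, seed=config.base_seed)
        aff = affinity.affinity_ensemble(filtered, assign_series, settings)

    return PipelineResult(
        assignment=assignment,
        occurrence=occurrence,
        singleton_report=report,
        biogeography=records,
        category_summary=summary,
        affinity=aff,
        n_asvs_analyzed=filtered.n_asvs,
    )
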