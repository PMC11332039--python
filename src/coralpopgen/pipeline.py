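"""End-to-end orchestration: simulate -> filter -> prune -> clones ->
structure -> FST/GIDs -> RDA -> selection scan -> enrichment.

Each stage logs its input/output shapes and a content checksum so runs
are auditable; the global seed drives every stochastic stage.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import (
    clonality,
    divergence,
    enrichment,
    gea,
    geo_env,
    selection,
    structure,
    synthetic_data,
    variants,
)

logger = logging.getLogger("coralpopgen")

__all__ = ["PipelineResult", "run_all"]


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha1(np.ascontiguousarray(arr).tobytes()).hexdigest()[:12]


def _log_stage(name: str, gm: variants.GenotypeMatrix) -> None:
    logger.info(
        "%s: %d samples x %d sites [sha1:%s]",
        name, gm.n_samples, gm.n_sites, _checksum(gm.dosages),
    )


@dataclass
class PipelineResult:
    config: synthetic_data.SimulationConfig
    genotypes: variants.GenotypeMatrix
    filtered: variants.GenotypeMatrix
    unlinked: variants.GenotypeMatrix
    metadata: pd.DataFrame
    environment: pd.DataFrame
    truth: synthetic_data.TruthTable
    clones: clonality.ClonalPartition
    best_k: int
    cross_entropy: dict[int, float]
    ancestry: structure.AncestryResult
    group_fst: pd.DataFrame
    window_track: divergence.WindowFstTrack
    gids: divergence.GidSet
    outliers: pd.DataFrame
    scan: selection.FModelResult
    calls: selection.SelectionCall
    report: enrichment.EnrichmentReport
    mantel_geo: geo_env.MantelResult | None = None
    mantel_env: geo_env.MantelResult | None = None
    extras: dict = field(default_factory=dict)


def run_all(
    config: synthetic_data.SimulationConfig,
    filter_spec: variants.FilterSpec = variants.FilterSpec(),
    k_range=range(1, 6),
    mcmc: selection.McmcSettings | None = None,
    fdr_target: float = 0.05,
    gid_quantile: float = 0.01,
    run_mantel: bool = True,
    n_perm: int = 999,
) -> PipelineResult:
    """Run the whole inference chain on one simulated dataset.

    The selection scan runs on the filtered ("linked") site set with
    islands as populations within the highest-level lineages; the RDA
    and enrichment use the LD-pruned ("unlinked") set, matching the
    denominators of the reported percentages.
    """
    seed = config.seed
    gm, metadata, environment, truth = synthetic_data.simulate_dataset(config)
    _log_stage("simulated", gm)

    filtered = variants.apply_site_filters(gm, filter_spec)
    _log_stage("filtered", filtered)
    unlinked = variants.ld_prune(filtered, filter_spec)
    _log_stage("unlinked", unlinked)

    detector = clonality.CloneDetector().fit(unlinked)
    clones = detector.partition_
    keep = detector.representatives_
    logger.info("clones: %d MLLs over %d samples", clones.n_mll, unlinked.n_samples)
    unlinked_1r = unlinked.take_samples(keep)
    filtered_1r = filtered.take_samples(keep)
    meta_1r = metadata[metadata["sample_id"].isin(keep)].reset_index(drop=True)

    best_k, curve = structure.choose_K(unlinked_1r, K_range=k_range, seed=seed)
    ancestry = structure.estimate_ancestry(unlinked_1r, best_k, seed=seed, n_init=5)
    logger.info("ancestry: best K=%d", best_k)

    lineages = meta_1r.set_index("sample_id")["lineage"]
    group_fst = divergence.pairwise_group_fst(unlinked_1r, lineages)
    track = divergence.window_fst(filtered_1r, lineages)
    gids = divergence.call_gids(track, quantile=gid_quantile)
    logger.info("windows: %d, GIDs: %d", len(track.windows), len(gids.gid_windows))

    env_scores = gea.env_pc_scores(environment)
    predictors = gea.sample_env_predictors(env_scores, meta_1r)
    scanner = gea.RdaOutlierScanner().fit(unlinked_1r, predictors)
    outliers = scanner.table_
    logger.info(
        "RDA: %d axes, lambda=%.2f, %d outliers",
        scanner.n_axes_retained_, scanner.inflation_, int(outliers["is_outlier"].sum()),
    )

    # divergent selection: population units are lineage x island (the
    # population-within-group hierarchy collapsed to one level); locus
    # effects then capture excess differentiation across those units,
    # including among-lineage divergence
    mcmc = mcmc or selection.McmcSettings(seed=seed)
    pop_units = lineages + "_" + meta_1r.set_index("sample_id")["island"]
    scan = selection.scan_genome(unlinked_1r, pop_units, mcmc, two_pass=False)
    calls = selection.call_selection(scan, fdr_target)
    logger.info("selection: %.1f%% flagged", 100 * calls.fraction_flagged)

    report = enrichment.build_report(outliers, gids, calls.flagged)

    mantel_geo = mantel_env = None
    if run_mantel:
        islands = meta_1r.set_index("sample_id")["island"]
        fst_island = divergence.pairwise_group_fst(unlinked_1r, islands)
        gen = geo_env.linearize_fst(fst_island)
        coords = geo_env.island_coordinates(meta_1r)
        geo = geo_env.great_circle_km(coords.loc[gen.labels])
        island_of = meta_1r.drop_duplicates("site").set_index("site")["island"]
        env_d = geo_env.env_pca_distance(environment, island_of=island_of)
        env_d = env_d.reindex(gen.labels)
        mantel_geo = geo_env.mantel(gen, geo, n_perm=n_perm, seed=seed)
        mantel_env = geo_env.mantel(gen, env_d, n_perm=n_perm, seed=seed + 1)
        logger.info(
            "Mantel: geography r=%.3f p=%.4f; environment r=%.3f p=%.4f",
            mantel_geo.r, mantel_geo.p, mantel_env.r, mantel_env.p,
        )

    return PipelineResult(
        config=config, genotypes=gm, filtered=filtered, unlinked=unlinked,
        metadata=metadata, environment=environment, truth=truth, clones=clones,
        best_k=best_k, cross_entropy=curve, ancestry=ancestry,
        group_fst=group_fst, window_track=track, gids=gids, outliers=outliers,
        scan=scan, calls=calls, report=report,
        mantel_geo=mantel_geo, mantel_env=mantel_env,
    )
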