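"""End-to-end orchestration: scan -> conserve -> cluster -> access -> co-localize.

The in-memory driver (:func:`run_pipeline`) is what tests and the
reproduction script use; the file-based CLI in :mod:`comotif.cli` wraps the
same stage functions with on-disk artifacts and JSON manifests.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from comotif.accessibility import annotate_accessibility
from comotif.colocalization import ColocResult, run_colocalization
from comotif.conservation import annotate_conservation, conservation_percentiles
from comotif.intervals import IntervalSet
from comotif.motifs import (
    MotifCluster,
    cluster_pwms,
    composition_assignment,
    composition_clusters,
)
from comotif.scan import ScoreModel, encode_sequence, mask_exons, merge_cluster_sites, scan_sequence
from comotif.simulate import SimData


@dataclass
class RunConfig:
    """All pipeline thresholds; defaults are the published operating point."""

    scan_p: float = 1e-4  # PWM match p-value threshold
    pseudocount: float = 1e-3
    granularity: int = 1000  # score-distribution bins per column
    conservation_offset: int = 10  # nt offset for cross-species matches
    top_conserved_fraction: float = 0.2  # site set for network-level evaluation
    floor_percentile: float = 0.6  # analysis floor for pair finding
    access_top_fraction: float = 0.05  # genome-wide accessibility quantile
    access_flank: int = 50
    similarity_cut: float = 0.8  # PWM cluster cut
    n_rand: int = 10000
    fdr: float = 0.05
    min_weighted: float = 10.0
    max_pair_distance: int = 1000
    pair_window: int = 100
    tss_window: int = 2000
    seed: int = 0


@dataclass
class PipelineResult:
    raw_sites: pd.DataFrame  # per-motif sites with bls + percentile
    sites: pd.DataFrame  # cluster-merged sites with accessibility flags
    clusters: list[MotifCluster]
    comp_clusters: list
    comp_of_label: dict  # cluster site label -> composition cluster id
    label_of_motif: dict  # motif_id -> cluster site label
    stages: list[str]
    coloc: ColocResult | None = None


def predict_sites(sim: SimData, cfg: RunConfig, exon_mask: IntervalSet | None = None) -> pd.DataFrame:
    """Scan all motifs over the genome and attach conservation percentiles."""
    bg = sim.background
    codes = {c: encode_sequence(s) for c, s in sim.genome.items()}
    parts = []
    for pwm in sim.pwms:
        model = ScoreModel(pwm, bg, cfg.pseudocount, cfg.granularity)
        per_chrom = [
            scan_sequence(model, codes[c], c, cfg.scan_p) for c in sorted(codes)
        ]
        sites = pd.concat(per_chrom, ignore_index=True)
        if exon_mask:
            sites = mask_exons(sites, exon_mask)
        sites = annotate_conservation(
            sites, sim.blocks, pwm, sim.tree, model,
            offset=cfg.conservation_offset, p_threshold=cfg.scan_p,
        )
        parts.append(sites)
    raw = pd.concat(parts, ignore_index=True)
    return conservation_percentiles(raw)


def cluster_and_merge(raw_sites: pd.DataFrame, sim: SimData, cfg: RunConfig):
    """Cluster similar PWMs, merge their sites, and build shuffling strata."""
    clusters = cluster_pwms(sim.pwms, cut=cfg.similarity_cut)
    merged = merge_cluster_sites(raw_sites, clusters)
    comp = composition_clusters(clusters, background=sim.background)
    assign = composition_assignment(comp)
    comp_of_label = {c.name: assign[c.cluster_id] for c in clusters}
    label_of_motif = {mid: c.name for c in clusters for mid in c.members}
    return clusters, merged, comp, comp_of_label, label_of_motif


def run_pipeline(
    sim: SimData,
    cfg: RunConfig | None = None,
    exon_mask: IntervalSet | None = None,
    colocalize: bool = True,
) -> PipelineResult:
    """Full run on one simulated (or loaded) study."""
    cfg = cfg or RunConfig()
    raw = predict_sites(sim, cfg, exon_mask)
    clusters, merged, comp, comp_of_label, label_of_motif = cluster_and_merge(raw, sim, cfg)
    merged = annotate_accessibility(
        merged, sim.tracks, flank=cfg.access_flank, top_fraction=cfg.access_top_fraction
    )
    stages = [t.stage for t in sim.tracks]
    result = PipelineResult(
        raw_sites=raw,
        sites=merged,
        clusters=clusters,
        comp_clusters=comp,
        comp_of_label=comp_of_label,
        label_of_motif=label_of_motif,
        stages=stages,
    )
    if colocalize:
        result.coloc = run_colocalization(
            merged,
            comp_of_label,
            stages,
            n_rand=cfg.n_rand,
            master_seed=cfg.seed,
            floor_percentile=cfg.floor_percentile,
            fdr_cut=cfg.fdr,
            min_weighted=cfg.min_weighted,
            max_dist=cfg.max_pair_distance,
        )
    return result
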