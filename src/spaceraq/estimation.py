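"""Parameter recovery: run the whole analysis on simulated data in memory and
compare pipeline estimates with the realized simulated values.

Estimates are absolute-count weighted so they sit on the same scale as the
per-event truth: with constant read depth, cluster sizes are proportional to
the number of acquisition events behind each unique spacer.
"""
from __future__ import annotations

from types import SimpleNamespace

from .clustering import ClusterConfig, SpacerPool, cluster_pool
from .config import default_loci
from .mapping import AlignConfig, hierarchical_map
from .motifs import detect_sam, extract_flanks
from .overlap_null import NullModelConfig, observed_overlap, run_null
from .read_processing import ExtractionConfig, extract_all
from .synthetic_data import (AcquisitionParams, ReadErrorModel,
                             emit_amplicon_reads, generate_genome,
                             simulate_acquisition)
from .target_stats import MRNA_TARGETING, INTERGENIC, classify_mrna

__all__ = ["run_synthetic_pipeline", "estimate_parameters"]


def run_synthetic_pipeline(params: AcquisitionParams, seed: int,
                           loci=None, n_replicates: int = 3,
                           depth_per_event: int = 3,
                           error_model: ReadErrorModel | None = None,
                           phage_length: int = 47_000,
                           host_length: int = 120_000,
                           orf_density: float = 0.9):
    """Simulate, emit reads, extract, cluster and map; returns all artifacts.

    The error model defaults to error-free reads (recovery properties are
    about the analysis chain; noise robustness is exercised separately).
    """
    loci = loci or default_loci()
    error_model = error_model or ReadErrorModel(substitution_rate=0.0,
                                                insertion_rate=0.0,
                                                deletion_rate=0.0,
                                                quality_mean=38.0, quality_sd=1.0)
    phage = generate_genome(phage_length, 0.32, orf_density, seed=seed,
                            genome_id="sim_phage", topology="linear")
    host = generate_genome(host_length, 0.32, orf_density, seed=seed + 1,
                           genome_id="sim_host", topology="circular")
    truth = simulate_acquisition(phage, host, loci, params, seed=seed + 2,
                                 n_replicates=n_replicates)
    reads = emit_amplicon_reads(truth, loci, depth_per_event, error_model,
                                seed=seed + 3)
    ex_cfg = ExtractionConfig()
    cl_cfg = ClusterConfig()
    pools: dict[str, SpacerPool] = {}
    for locus in loci:
        observations = []
        for (locus_id, rep), rr in sorted(reads.items()):
            if locus_id != locus.locus_id:
                continue
            obs, _ = extract_all(rr, locus, ex_cfg, replicate_id=rep)
            observations.extend(obs)
        pools[locus.locus_id] = cluster_pool(observations, cl_cfg, view="unique",
                                             locus_id=locus.locus_id)
    hits = {}
    for locus in loci:
        hits[locus.locus_id], _ = hierarchical_map(pools[locus.locus_id],
                                                   phage, host, AlignConfig())
    return dict(phage=phage, host=host, truth=truth, reads=reads,
                pools=pools, hits=hits, loci=loci)


def _wmean(pairs) -> tuple[float, int]:
    """Weighted mean of (flag, weight) pairs -> (fraction, total weight)."""
    num = sum(w for f, w in pairs if f)
    den = sum(w for _, w in pairs)
    return (num / den if den else float("nan")), den


def estimate_parameters(params: AcquisitionParams, seed: int,
                        overlap: bool = False, n_iterations: int = 300,
                        **pipeline_kwargs) -> dict:
    """Estimated vs realized acquisition parameters for one simulation.

    Keys: ``est_*``/``true_*`` for the SAM-adjacency rate (donor locus, phage
    targets), the self-targeting fraction, and the mRNA-targeting fraction of
    ORF-contained phage hits; ``n_*`` gives the effective count behind each
    estimate.  With ``overlap=True`` the inter-locus sharing statistics are
    added.
    """
    art = run_synthetic_pipeline(params, seed, **pipeline_kwargs)
    phage, host, truth = art["phage"], art["host"], art["truth"]
    loci = art["loci"]
    donor = loci[0]
    donor_hits = art["hits"][donor.locus_id]
    genomes = {"phage": phage, "self": host}

    # --- SAM-adjacency rate (phage targets, donor locus) ---
    tr = [(e.sam_flag, 1) for e in truth.for_locus(donor.locus_id)
          if e.target_class == "phage"]
    true_sam, n_true_sam = _wmean(tr)
    est_pairs = []
    for h in donor_hits:
        if h.target_class != "phage":
            continue
        flag = detect_sam(extract_flanks(h, phage), donor)
        if flag is not None:
            est_pairs.append((flag, h.absolute_count))
    est_sam, n_est_sam = _wmean(est_pairs)

    # --- self-targeting fraction (all loci pooled, absolute weights) ---
    true_self, n_true_self = _wmean([(e.target_class == "self", 1)
                                     for e in truth.events])
    est_pairs = [(h.target_class == "self", h.absolute_count)
                 for hs in art["hits"].values() for h in hs]
    est_self, n_est_self = _wmean(est_pairs)

    # --- mRNA-targeting fraction of ORF-contained phage targets (donor) ---
    def truth_label(e):
        g = genomes[e.target_class]
        h = SimpleNamespace(start=e.start, end=e.end, strand=e.strand)
        return classify_mrna(h, g.features)

    tl = [truth_label(e) for e in truth.for_locus(donor.locus_id)
          if e.target_class == "phage"]
    true_mrna, n_true_mrna = _wmean([(l == MRNA_TARGETING, 1)
                                     for l in tl if l != INTERGENIC])
    est_pairs = []
    for h in donor_hits:
        if h.target_class != "phage":
            continue
        lab = classify_mrna(h, phage.features)
        if lab != INTERGENIC:
            est_pairs.append((lab == MRNA_TARGETING, h.absolute_count))
    est_mrna, n_est_mrna = _wmean(est_pairs)

    result = dict(
        true_sam_rate=true_sam, est_sam_rate=est_sam, n_sam=n_est_sam,
        true_self_fraction=true_self, est_self_fraction=est_self, n_self=n_est_self,
        true_mrna_fraction=true_mrna, est_mrna_fraction=est_mrna, n_mrna=n_est_mrna,
    )

    if overlap and len(loci) >= 2:
        query_id, ref_id = loci[-1].locus_id, loci[0].locus_id
        qpool = _phage_subpool(art["pools"][query_id], art["hits"][query_id])
        rpool = _phage_subpool(art["pools"][ref_id], art["hits"][ref_id])
        nm = NullModelConfig(n_iterations=n_iterations, sample_size=max(len(qpool), 1),
                             sampling_mode="random", seed=seed + 10)
        obs = observed_overlap(qpool, rpool, nm)
        res = run_null(phage, rpool, nm, observed=obs)
        result.update(observed_overlap=obs, null_mu=res.mu, null_sigma=res.sigma,
                      p_normal=res.p_normal, p_empirical=res.p_empirical,
                      n_query=len(qpool), n_reference=len(rpool))
    return result


def _phage_subpool(pool: SpacerPool, hits) -> SpacerPool:
    phage_reps = {h.spacer for h in hits if h.target_class == "phage"}
    clusters = [c for c in pool.clusters if c.representative in phage_reps]
    return SpacerPool(clusters=clusters, locus_id=pool.locus_id, view="unique")
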