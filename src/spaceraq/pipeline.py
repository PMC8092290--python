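"""End-to-end orchestration: extract -> cluster -> map -> motif -> stats -> overlap.

Each stage writes a plain TSV/JSON file stamped with the tool version and
config hash, and the run returns a :class:`PipelineReport` whose numbers are
all traceable to those files.  A failure confined to one locus or replicate
is collected and reported without aborting the remaining work.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .clustering import cluster_pool, SpacerPool
from .config import RunConfig, default_loci
from .io_formats import FormatError, read_fasta, read_fastq, read_features, write_fasta, write_gff3, write_fastq
from .mapping import hierarchical_map
from .motifs import build_pfm, extract_flanks, motif_offset_histogram, sam_rate
from .overlap_null import NullModelConfig, observed_overlap, run_null
from .read_processing import extract_all
from .synthetic_data import (AcquisitionParams, ReadErrorModel, emit_amplicon_reads,
                             generate_genome, simulate_acquisition)
from .target_stats import bin_distribution, mrna_proportions

__all__ = ["PipelineReport", "run_pipeline", "run_simulation_study", "simulate_to_dir"]


@dataclass
class PipelineReport:
    seed: int
    config_hash: str
    version: str
    extraction: dict = field(default_factory=dict)
    clustering: dict = field(default_factory=dict)
    mapping: dict = field(default_factory=dict)
    sam: dict = field(default_factory=dict)
    mrna: dict = field(default_factory=dict)
    overlap: dict = field(default_factory=dict)
    errors: list = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _stamp(path: Path, cfg_hash: str) -> None:
    body = path.read_text()
    path.write_text(f"# spaceraq {__version__} config={cfg_hash}\n" + body)


def _write_tsv(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    df.to_csv(path, sep="\t", index=False)
    _stamp(path, cfg_hash)


def _load_genome(gi, default_id: str):
    records = read_fasta(gi.fasta, topology=gi.topology)
    if len(records) != 1:
        raise FormatError(f"{gi.fasta}: expected exactly one sequence")
    genome = records[0]
    if gi.features:
        genome.features = read_features(gi.features, gi.feature_dialect)
    return genome


def run_pipeline(config: RunConfig | str | Path, out_dir: str | Path) -> PipelineReport:
    """Run the full analysis described by a config; returns the report."""
    cfg = config if isinstance(config, RunConfig) else RunConfig.from_yaml(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = cfg.config_hash()
    report = PipelineReport(seed=cfg.seed, config_hash=cfg_hash, version=__version__)

    # fail fast on missing inputs
    for gi in (cfg.phage, cfg.host):
        for p in (gi.fasta, gi.features):
            if p and not Path(p).exists():
                raise FileNotFoundError(p)
    for lr in cfg.loci:
        for p in lr.reads.values():
            if not Path(p).exists():
                raise FileNotFoundError(p)

    phage = _load_genome(cfg.phage, "phage")
    host = _load_genome(cfg.host, "host")
    features_by_genome = {phage.id: phage.features, host.id: host.features}

    pools: dict[str, SpacerPool] = {}
    hits_by_locus: dict[str, list] = {}
    phage_pools: dict[str, SpacerPool] = {}
    locus_models = {}

    for lr in cfg.loci:
        locus = lr.locus
        locus_models[locus.locus_id] = locus
        ex_cfg = dataclasses.replace(cfg.extraction, read_orientation=lr.read_orientation)
        observations = []
        ex_summary = {}
        for rep, fastq in sorted(lr.reads.items()):
            try:
                obs, summ = extract_all(read_fastq(fastq), locus, ex_cfg,
                                        replicate_id=rep)
                observations.extend(obs)
                ex_summary[rep] = summ.as_dict()
            except FormatError as exc:
                report.errors.append(f"extract {locus.locus_id}/{rep}: {exc}")
        report.extraction[locus.locus_id] = ex_summary

        pool = cluster_pool(observations, cfg.clustering, view="unique",
                            locus_id=locus.locus_id)
        pools[locus.locus_id] = pool
        report.clustering[locus.locus_id] = {
            "n_observations": len(observations),
            "n_clusters": len(pool),
        }
        cl_df = pd.DataFrame(
            [(c.representative, c.size, ";".join(s for s, _ in c.members))
             for c in pool.clusters],
            columns=["representative", "size", "members"])
        _write_tsv(cl_df, out / f"clusters_{locus.locus_id}.tsv", cfg_hash)

        hits, summary = hierarchical_map(pool, phage, host, cfg.alignment)
        hits_by_locus[locus.locus_id] = hits
        report.mapping[locus.locus_id] = {
            "n_input": summary.n_input, "n_phage": summary.n_phage,
            "n_self": summary.n_self, "n_discarded": summary.n_discarded,
            "discard_fraction": summary.discard_fraction,
        }
        hit_df = pd.DataFrame(
            [dict(spacer=h.spacer, genome=h.genome_id, start=h.start, end=h.end,
                  strand=h.strand, score=h.score, mismatches=h.mismatches,
                  target_class=h.target_class, unique_count=h.unique_count,
                  absolute_count=h.absolute_count) for h in hits])
        _write_tsv(hit_df, out / f"hits_{locus.locus_id}.tsv", cfg_hash)

        # guide-oriented motif analysis over phage-targeting hits
        phage_hits = [h for h in hits if h.target_class == "phage"]
        contexts = [extract_flanks(h, phage) for h in phage_hits]
        if contexts:
            rate, k, n = sam_rate(contexts, locus)
            side = locus.sam_side
            try:
                pfm = build_pfm(contexts, side)
                (out / f"pfm_{locus.locus_id}_{side}.tsv").write_text(
                    f"# spaceraq {__version__} config={cfg_hash}\n" + pfm.to_text() + "\n")
                consensus = pfm.consensus()
            except Exception as exc:  # zero usable flanks
                report.errors.append(f"pfm {locus.locus_id}: {exc}")
                consensus = ""
            hist = motif_offset_histogram(contexts, side=side)
            report.sam[locus.locus_id] = {
                "rate": rate, "k": k, "n": n, "flank_consensus": consensus,
                "offset_histogram": {str(o): c for o, c in sorted(hist.items())},
            }
        # phage-targeting unique pool for overlap analysis
        cls = [c for c, h in zip(pool.clusters, _match_hits(pool, hits))
               if h is not None and h.target_class == "phage"]
        phage_pools[locus.locus_id] = SpacerPool(clusters=cls,
                                                 locus_id=locus.locus_id,
                                                 view="unique")

    all_hits = [h for hs in hits_by_locus.values() for h in hs]
    mrna_df = pd.concat(
        [mrna_proportions(all_hits, features_by_genome, grouping="pooled"),
         mrna_proportions(all_hits, features_by_genome, grouping="per_replicate")],
        ignore_index=True)
    _write_tsv(mrna_df, out / "mrna_bias.tsv", cfg_hash)
    report.mrna = {
        f"{r.locus_id}|{r.target_class}|{r.view}|{r.replicate}":
            {"n": int(r.n), "k": int(r.k), "proportion": None if pd.isna(r.proportion)
             else float(r.proportion),
             "p_value": None if pd.isna(r.p_value) else float(r.p_value)}
        for r in mrna_df.itertuples()
    }

    for genome in (phage, host):
        for locus_id, hits in hits_by_locus.items():
            bc = bin_distribution(hits, genome, cfg.binning, motif=cfg.null_model.sam_motif)
            _write_tsv(bc.table, out / f"bins_{locus_id}_{genome.id}.tsv", cfg_hash)

    qid = cfg.overlap_query_locus or cfg.loci[-1].locus.locus_id
    rid = cfg.overlap_reference_locus or cfg.loci[0].locus.locus_id
    if qid != rid and len(phage_pools.get(qid, [])) and len(phage_pools.get(rid, [])):
        query, reference = phage_pools[qid], phage_pools[rid]
        nm = dataclasses.replace(cfg.null_model, sample_size=len(query),
                                 seed=cfg.seed)
        obs = observed_overlap(query, reference, nm)
        report.overlap = {"query_locus": qid, "reference_locus": rid,
                          "query_pool_size": len(query),
                          "reference_pool_size": len(reference),
                          "observed_fraction": obs}
        for mode in ("random", "pam_adjacent"):
            res = run_null(phage, reference,
                           dataclasses.replace(nm, sampling_mode=mode), observed=obs)
            report.overlap[mode] = {
                "mu": res.mu, "sigma": res.sigma,
                "p_normal": res.p_normal, "p_empirical": res.p_empirical,
            }
    report.to_json(out / "report.json")
    return report


def _match_hits(pool: SpacerPool, hits):
    by_spacer = {h.spacer: h for h in hits}
    return [by_spacer.get(c.representative) for c in pool.clusters]


# --- simulation front door -------------------------------------------------

def simulate_to_dir(out_dir: str | Path, seed: int = 1,
                    params: AcquisitionParams | None = None,
                    error_model: ReadErrorModel | None = None,
                    loci=None, n_replicates: int = 3, depth_per_event: int = 5,
                    phage_length: int = 47_000, host_length: int = 300_000,
                    orf_density: float = 0.9, gc_fraction: float = 0.32,
                    ) -> RunConfig:
    """Generate a synthetic data set on disk and return a ready RunConfig.

    Default genome sizes keep phage realism (47 kb) while the host is scaled
    down (300 kb) so a full run stays fast.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = params or AcquisitionParams()
    error_model = error_model or ReadErrorModel()
    loci = loci or default_loci()
    phage = generate_genome(phage_length, gc_fraction, orf_density, seed=seed,
                            genome_id="sim_phage", topology="linear")
    host = generate_genome(host_length, gc_fraction, orf_density, seed=seed + 1,
                           genome_id="sim_host", topology="circular")
    truth = simulate_acquisition(phage, host, loci, params, seed=seed + 2,
                                 n_replicates=n_replicates)
    reads = emit_amplicon_reads(truth, loci, depth_per_event, error_model,
                                seed=seed + 3)
    write_fasta([phage], out / "phage.fasta")
    write_fasta([host], out / "host.fasta")
    write_gff3(phage, out / "phage.gff3")
    write_gff3(host, out / "host.gff3")
    truth.write_tsv(out / "truth.tsv")
    from .config import GenomeInput, LocusRun
    locus_runs = []
    for locus in loci:
        rep_files = {}
        for (locus_id, rep), rr in sorted(reads.items()):
            if locus_id != locus.locus_id:
                continue
            path = out / f"reads_{locus_id}_{rep}.fastq"
            write_fastq(rr, path)
            rep_files[rep] = str(path)
        locus_runs.append(LocusRun(locus=locus, reads=rep_files))
    cfg = RunConfig(
        phage=GenomeInput(fasta=str(out / "phage.fasta"),
                          features=str(out / "phage.gff3"), topology="linear"),
        host=GenomeInput(fasta=str(out / "host.fasta"),
                         features=str(out / "host.gff3"), topology="circular"),
        loci=locus_runs, seed=seed)
    cfg.to_yaml(out / "run_config.yaml")
    return cfg


def run_simulation_study(seed: int = 1,
                         pi_grid=(0.0, 0.63, 1.0),
                         rho_grid=(0.0, 1.0),
                         n_events: int = 300,
                         phage_length: int = 47_000,
                         host_length: int = 120_000,
                         n_iterations: int = 300) -> pd.DataFrame:
    """Parameter-recovery sweep: estimated vs true acquisition parameters.

    For each grid point the full pipeline (reads -> spacers -> pools -> hits)
    is run in memory and the estimate compared with the realized simulated
    value; for the sharing sweep the overlap-null p-value is reported.
    """
    from .estimation import estimate_parameters  # local import: thin helper
    rows = []
    for i, pi in enumerate(pi_grid):
        params = AcquisitionParams(n_events=n_events, pam_preference=pi,
                                   self_fraction=0.1, shared_pool_fraction=0.0)
        est = estimate_parameters(params, seed=seed + i)
        rows.append(dict(sweep="pam_preference", true_value=pi, **est))
    for j, rho in enumerate(rho_grid):
        params = AcquisitionParams(n_events=n_events, pam_preference=0.63,
                                   self_fraction=0.0, shared_pool_fraction=rho)
        est = estimate_parameters(params, seed=seed + 100 + j,
                                  overlap=True, n_iterations=n_iterations,
                                  phage_length=phage_length,
                                  host_length=host_length)
        rows.append(dict(sweep="shared_pool_fraction", true_value=rho, **est))
    return pd.DataFrame(rows)
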