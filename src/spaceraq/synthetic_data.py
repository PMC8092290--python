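"""Synthetic genomes, acquisition events and amplicon reads with ground truth.

The generator emulates a population-level spacer-acquisition experiment on a
two-locus CRISPR system: protospacers are sampled from a phage (or, with a
small probability, the host) genome with a tunable preference for
SAM-adjacent placements, a strand/mRNA-targeting bias, positional hotspots,
and a shared prespacer pool that lets the second locus reuse protospacers
already sampled by the first (in-trans adaptation).  Each event is then
turned into CRISPR-array amplicon reads (repeat - new spacer - repeat - old
array context) carrying Ion-Torrent-like substitution and indel errors, so
every downstream pipeline stage can be validated against known truth.
"""
from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._dna import iupac_to_regex, random_dna, revcomp, revcomp_iupac
from .io_formats import GenomeRecord, OrfFeature, ParameterError, ReadRecord
from .loci import LocusModel

__all__ = [
    "AcquisitionParams",
    "ReadErrorModel",
    "TruthEvent",
    "GroundTruth",
    "generate_genome",
    "sam_placement_starts",
    "is_sam_adjacent",
    "simulate_acquisition",
    "emit_amplicon_reads",
]

SPACER_LEN_RANGE = (27, 32)


@dataclass
class AcquisitionParams:
    """Tunable parameters of the simulated acquisition process.

    pam_preference
        Probability an event's protospacer is drawn from SAM-adjacent
        placements (the remainder are position-sampled freely and may still be
        SAM-adjacent by chance; the recorded flag is always the realized one).
    strand_bias
        For free (non-SAM-planted) events falling fully inside an ORF, the
        probability the crRNA-matching strand opposes the ORF strand, i.e.
        that the spacer is mRNA-targeting.  Outside ORFs strands are uniform.
    self_fraction
        Probability an event targets the host genome instead of the phage.
    hotspot_mixture / uniform_weight
        Truncated Gaussians in genome-fraction space, mixed with a uniform
        component, giving the positional acquisition density.
    shared_pool_fraction
        Probability an event at a non-donor locus reuses a protospacer
        already sampled by the first (donor) locus.
    """

    n_events: int = 300
    pam_preference: float = 0.63
    sam_motif: str = "NNNNNTAAA"
    spacer_length_dist: dict[int, float] = field(
        default_factory=lambda: {27: 0.02, 28: 0.05, 29: 0.13, 30: 0.60, 31: 0.15, 32: 0.05}
    )
    strand_bias: float = 0.5
    self_fraction: float = 0.05
    hotspot_mixture: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(0.8, 0.5, 0.05)]
    )
    uniform_weight: float = 0.5
    shared_pool_fraction: float = 0.58

    def __post_init__(self) -> None:
        if self.n_events < 0:
            raise ParameterError("n_events must be >= 0")
        for name in ("pam_preference", "strand_bias", "self_fraction",
                     "shared_pool_fraction", "uniform_weight"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} outside [0, 1]")
        lo, hi = SPACER_LEN_RANGE
        if not self.spacer_length_dist:
            raise ParameterError("spacer_length_dist is empty")
        for length, p in self.spacer_length_dist.items():
            if not lo <= length <= hi:
                raise ParameterError(f"spacer length {length} outside [{lo}, {hi}]")
            if p < 0:
                raise ParameterError("spacer length probabilities must be >= 0")
        total = sum(self.spacer_length_dist.values())
        if total <= 0:
            raise ParameterError("spacer_length_dist has zero total mass")
        self.spacer_length_dist = {k: v / total for k, v in self.spacer_length_dist.items()}
        w = self.uniform_weight + sum(wt for _, wt, _ in self.hotspot_mixture)
        if w <= 0:
            raise ParameterError("hotspot mixture has zero total weight")
        self.uniform_weight /= w
        self.hotspot_mixture = [(c, wt / w, sd) for c, wt, sd in self.hotspot_mixture]


@dataclass
class ReadErrorModel:
    """Ion-Torrent-like read errors: substitution plus indel-dominant noise,
    with indel rates inflated inside homopolymer runs."""

    substitution_rate: float = 0.005
    insertion_rate: float = 0.003
    deletion_rate: float = 0.005
    homopolymer_indel_multiplier: float = 4.0
    quality_mean: float = 28.0
    quality_sd: float = 5.0

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "insertion_rate", "deletion_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 0.2:
                raise ParameterError(f"{name}={v} outside [0, 0.2]")
        if not 10.0 <= self.quality_mean <= 41.0:
            raise ParameterError("quality_mean outside [10, 41]")
        if self.homopolymer_indel_multiplier < 0 or self.quality_sd < 0:
            raise ParameterError("multiplier and quality_sd must be >= 0")

    @property
    def error_free(self) -> bool:
        return (self.substitution_rate == 0 and self.insertion_rate == 0
                and self.deletion_rate == 0)


@dataclass
class TruthEvent:
    event_id: str
    locus_id: str
    genome_id: str
    start: int
    end: int
    strand: str
    sam_flag: bool
    spacer: str            # crRNA orientation
    replicate: str
    copies: int = 1
    target_class: str = "phage"


@dataclass
class GroundTruth:
    events: list[TruthEvent]

    def for_locus(self, locus_id: str) -> list[TruthEvent]:
        return [e for e in self.events if e.locus_id == locus_id]

    def spacer_multiset(self, locus_id: str | None = None):
        from collections import Counter
        evs = self.events if locus_id is None else self.for_locus(locus_id)
        return Counter(e.spacer for e in evs)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.events])

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


# --- genome generation ----------------------------------------------------

def generate_genome(length: int, gc_fraction: float = 0.32, orf_density: float = 0.9,
                    seed: int = 0, genome_id: str = "synthetic_genome",
                    topology: str = "linear") -> GenomeRecord:
    """Generate a random genome with non-overlapping ORFs on both strands.

    ORF lengths are uniform on [600, 1200) nt and intergenic gaps are sized so
    the expected coding span is ``orf_density`` of the genome.
    """
    if length < 1000:
        raise ParameterError("genome length must be >= 1000")
    if orf_density > 0.95:
        raise ParameterError("orf_density > 0.95 leaves no room for intergenic gaps")
    if not 0.0 <= orf_density <= 0.95:
        raise ParameterError("orf_density outside [0, 0.95]")
    rng = np.random.default_rng(seed)
    seq = random_dna(rng, length, gc_fraction)
    features: list[OrfFeature] = []
    if orf_density > 0:
        mean_gene = 900.0
        mean_gap = mean_gene * (1.0 - orf_density) / orf_density
        pos = int(rng.uniform(0, mean_gap + 1))
        i = 1
        while True:
            gene_len = int(rng.integers(600, 1200))
            if pos + gene_len > length:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            features.append(OrfFeature(id=f"orf_{i:04d}", start=pos,
                                       end=pos + gene_len, strand=strand))
            i += 1
            pos += gene_len + int(rng.uniform(0, 2 * mean_gap))
    return GenomeRecord(id=genome_id, sequence=seq, topology=topology,
                        features=features)


# --- SAM placement machinery ----------------------------------------------

def sam_placement_starts(sequence: str, motif: str = "NNNNNTAAA") -> dict[str, np.ndarray]:
    """Positions where the guide-oriented downstream-SAM convention can anchor
    a protospacer.

    Returns, per strand, the genomic coordinate that abuts the motif:

    ``+``: array of protospacer *end* coordinates ``e`` such that
    ``sequence[e : e+len(motif)]`` matches the motif (read forward).
    ``-``: array of protospacer *start* coordinates ``s`` such that
    ``sequence[s-len(motif) : s]`` matches the reverse-complement motif.

    The upstream-SAM convention (leader-to-array loci) uses the same genomic
    placements with the strands swapped.
    """
    fwd = re.compile("(?=" + iupac_to_regex(motif) + ")")
    rev = re.compile("(?=" + iupac_to_regex(revcomp_iupac(motif)) + ")")
    m = len(motif)
    plus = np.array([mt.start() for mt in fwd.finditer(sequence)], dtype=np.int64)
    minus = np.array([mt.start() + m for mt in rev.finditer(sequence)], dtype=np.int64)
    return {"+": plus, "-": minus}


def is_sam_adjacent(sequence: str, start: int, end: int, strand: str,
                    sam_side: str, motif: str = "NNNNNTAAA") -> bool:
    """Realized SAM adjacency of a genomic protospacer under a locus's
    convention (``sam_side`` from :class:`~spaceraq.loci.LocusModel`).

    Out-of-bounds (truncated) flanks count as not adjacent.
    """
    # The upstream convention sees the identical genomic placement with the
    # crRNA on the opposite strand.
    eff_strand = strand if sam_side == "downstream" else ("-" if strand == "+" else "+")
    m = len(motif)
    if eff_strand == "+":
        if end + m > len(sequence):
            return False
        window = sequence[end:end + m]
        return re.fullmatch(iupac_to_regex(motif), window) is not None
    if start - m < 0:
        return False
    window = sequence[start - m:start]
    return re.fullmatch(iupac_to_regex(revcomp_iupac(motif)), window) is not None


# --- acquisition simulation ------------------------------------------------

class _PositionSampler:
    """Mixture of a uniform component and truncated Gaussians over genome
    fractions; also provides relative density weights at given positions."""

    def __init__(self, params: AcquisitionParams, genome_len: int):
        self.glen = genome_len
        self.uniform_w = params.uniform_weight
        self.components = params.hotspot_mixture

    def density(self, positions: np.ndarray) -> np.ndarray:
        frac = positions / self.glen
        d = np.full(frac.shape, self.uniform_w, dtype=float)
        for center, weight, width in self.components:
            if width <= 0:
                continue
            # truncation to [0,1] renormalizes near linear-genome edges
            mass = norm.cdf(1.0, center, width) - norm.cdf(0.0, center, width)
            d += weight * norm.pdf(frac, center, width) / max(mass, 1e-12)
        return d

    def sample_start(self, rng: np.random.Generator, spacer_len: int) -> int:
        hi = self.glen - spacer_len
        while True:
            r = rng.random()
            acc = self.uniform_w
            if r < acc:
                return int(rng.integers(0, hi + 1))
            for center, weight, width in self.components:
                acc += weight
                if r < acc:
                    for _ in range(1000):
                        frac = rng.normal(center, width)
                        if 0.0 <= frac <= 1.0:
                            start = int(frac * self.glen)
                            if start <= hi:
                                return start
                    break  # pathological width: fall through and redraw
            # redraw mixture component


def _containing_feature(features: list[OrfFeature], start: int, end: int) -> OrfFeature | None:
    for f in features:
        if f.contains(start, end):
            return f
    return None


def _anchor_collision(spacer: str, repeat: str, anchor_len: int = 4,
                      min_spacer_len: int = SPACER_LEN_RANGE[0]) -> bool:
    """True when the repeat's anchor prefix occurs inside the array region at
    an offset that the first-valid extraction rule would pick before the true
    spacer end (which would truncate the recovered spacer)."""
    region = spacer + repeat
    anchor = repeat[:anchor_len]
    return any(region[off:off + anchor_len] == anchor
               for off in range(min_spacer_len, len(spacer)))


def simulate_acquisition(phage: GenomeRecord, host: GenomeRecord,
                         loci: list[LocusModel], params: AcquisitionParams,
                         seed: int, n_replicates: int = 1) -> GroundTruth:
    """Simulate acquisition events for each locus and return the ground truth.

    The first locus in ``loci`` acts as the donor pool for in-trans sharing:
    with probability ``shared_pool_fraction`` an event at any later locus
    copies a protospacer (genome, interval and strand) already sampled by the
    donor, so its spacer sequence is identical.  Spacers are recorded in crRNA
    orientation (the sequence of the crRNA-matching genome strand).
    """
    rng = np.random.default_rng(seed)
    genomes = {"phage": phage, "self": host}
    lengths = np.array(sorted(params.spacer_length_dist))
    length_p = np.array([params.spacer_length_dist[int(l)] for l in lengths])
    samplers = {k: _PositionSampler(params, len(g)) for k, g in genomes.items()}
    placements = {k: sam_placement_starts(g.sequence, params.sam_motif)
                  for k, g in genomes.items()}
    if params.pam_preference > 0:
        for k, g in genomes.items():
            if all(p.size == 0 for p in placements[k].values()):
                if params.pam_preference == 1.0 or k == "phage":
                    raise ParameterError(
                        f"pam_preference={params.pam_preference} but the {k} genome "
                        f"contains no {params.sam_motif} placement"
                    )

    replicates = [f"r{i+1}" for i in range(n_replicates)]
    events: list[TruthEvent] = []
    donor_events: list[TruthEvent] = []
    plc_cache: dict[tuple, tuple | None] = {}

    for locus_idx, locus in enumerate(loci):
        for j in range(params.n_events):
            replicate = replicates[int(rng.integers(0, n_replicates))]
            eid = f"{locus.locus_id}_ev{j:05d}"
            if locus_idx > 0 and donor_events and rng.random() < params.shared_pool_fraction:
                donor = donor_events[int(rng.integers(0, len(donor_events)))]
                g = genomes[donor.target_class]
                # A reused prespacer keeps the donor's protospacer identity
                # (interval, strand, spacer string) and its SAM-adjacency flag:
                # adjacency is a property of how the prespacer was sampled.
                ev = TruthEvent(
                    event_id=eid, locus_id=locus.locus_id, genome_id=donor.genome_id,
                    start=donor.start, end=donor.end, strand=donor.strand,
                    sam_flag=donor.sam_flag,
                    spacer=donor.spacer, replicate=replicate,
                    target_class=donor.target_class,
                )
                events.append(ev)
                continue
            ev = _sample_fresh_event(rng, eid, locus, params, genomes, samplers,
                                     placements, lengths, length_p, replicate,
                                     plc_cache)
            events.append(ev)
            if locus_idx == 0:
                donor_events.append(ev)
    return GroundTruth(events=events)


def _sample_fresh_event(rng, eid, locus, params, genomes, samplers, placements,
                        lengths, length_p, replicate, plc_cache) -> TruthEvent:
    target = "self" if rng.random() < params.self_fraction else "phage"
    genome = genomes[target]
    seq = genome.sequence
    sampler = samplers[target]
    for _ in range(10_000):
        L = int(rng.choice(lengths, p=length_p))
        planted = rng.random() < params.pam_preference
        if planted:
            key = (target, locus.sam_side, L)
            if key not in plc_cache:
                plc_cache[key] = _placement_table(seq, placements[target],
                                                  sampler, locus.sam_side, L)
            got = _sample_sam_placement(rng, plc_cache[key])
            if got is None:
                raise ParameterError(
                    f"no usable {params.sam_motif} placement on the {target} genome "
                    f"for locus {locus.locus_id}"
                )
            start, end, strand = got
        else:
            start = sampler.sample_start(rng, L)
            end = start + L
            feat = _containing_feature(genome.features, start, end)
            if feat is not None:
                mrna = rng.random() < params.strand_bias
                strand = ("-" if feat.strand == "+" else "+") if mrna else feat.strand
            else:
                strand = "+" if rng.random() < 0.5 else "-"
        spacer = seq[start:end] if strand == "+" else revcomp(seq[start:end])
        if "N" in spacer:
            continue
        if _anchor_collision(spacer, locus.repeat):
            continue  # would defeat first-valid anchor extraction; resample
        return TruthEvent(
            event_id=eid, locus_id=locus.locus_id, genome_id=genome.id,
            start=start, end=end, strand=strand,
            sam_flag=is_sam_adjacent(seq, start, end, strand, locus.sam_side,
                                     params.sam_motif),
            spacer=spacer, replicate=replicate, target_class=target,
        )
    raise ParameterError("could not sample a valid protospacer in 10000 tries")


def _placement_table(seq, genome_placements, sampler, sam_side, L):
    # Downstream convention: '+' entries are protospacer ends, '-' entries are
    # starts.  The upstream convention swaps strands over the same placements.
    starts_all, ends_all, strands_all, weights = [], [], [], []
    for strand_key, anchored in genome_placements.items():
        if anchored.size == 0:
            continue
        if strand_key == "+":
            ends = anchored
            starts = ends - L
            strand = "+" if sam_side == "downstream" else "-"
        else:
            starts = anchored
            ends = starts + L
            strand = "-" if sam_side == "downstream" else "+"
        ok = (starts >= 0) & (ends <= len(seq))
        starts_all.append(starts[ok])
        ends_all.append(ends[ok])
        strands_all.extend([strand] * int(ok.sum()))
        weights.append(sampler.density(starts[ok]))
    if not strands_all:
        return None
    starts = np.concatenate(starts_all)
    ends = np.concatenate(ends_all)
    w = np.concatenate(weights)
    return starts, ends, np.array(strands_all), w / w.sum()


def _sample_sam_placement(rng, table):
    if table is None:
        return None
    starts, ends, strands, w = table
    idx = int(rng.choice(len(starts), p=w))
    return int(starts[idx]), int(ends[idx]), str(strands[idx])


# --- read emission ---------------------------------------------------------

def emit_amplicon_reads(truth: GroundTruth, loci: list[LocusModel],
                        depth_per_event: int, error_model: ReadErrorModel,
                        seed: int,
                        orientation: dict[str, str] | None = None,
                        ) -> dict[tuple[str, str], list[ReadRecord]]:
    """Emit amplicon reads for every truth event, grouped by (locus, replicate).

    Each amplicon covers the variable end of the array: full repeat, the new
    spacer, the following full repeat and ~20 nt of pre-existing array
    context.  Reads are emitted already primer-trimmed.  ``orientation`` maps
    locus_id to ``as_crRNA`` (default) or ``reverse_complement_of_crRNA``.
    """
    if depth_per_event < 1:
        raise ParameterError("depth_per_event must be >= 1")
    rng = np.random.default_rng(seed)
    orientation = orientation or {}
    locus_by_id = {l.locus_id: l for l in loci}
    out: dict[tuple[str, str], list[ReadRecord]] = {}
    for ev in truth.events:
        locus = locus_by_id[ev.locus_id]
        pad_src = (locus.preexisting_spacers[0] if locus.preexisting_spacers
                   else locus.leader * 4)
        template = locus.repeat + ev.spacer + locus.repeat + pad_src[:20]
        if orientation.get(ev.locus_id, "as_crRNA") == "reverse_complement_of_crRNA":
            template = revcomp(template)
        key = (ev.locus_id, ev.replicate)
        bucket = out.setdefault(key, [])
        for c in range(depth_per_event * ev.copies):
            seq = template if error_model.error_free else _corrupt(rng, template, error_model)
            quals = np.clip(
                np.rint(rng.normal(error_model.quality_mean, error_model.quality_sd,
                                   size=len(seq))),
                2, 41).astype(int).tolist()
            bucket.append(ReadRecord(id=f"{ev.event_id}|{ev.replicate}|c{c}",
                                     sequence=seq, qualities=quals))
    return out


_OTHER = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}


def _corrupt(rng: np.random.Generator, template: str, em: ReadErrorModel) -> str:
    out: list[str] = []
    prev = ""
    for base in template:
        hp = em.homopolymer_indel_multiplier if base == prev else 1.0
        if rng.random() < min(em.deletion_rate * hp, 1.0):
            prev = base
            continue
        if rng.random() < em.substitution_rate and base in _OTHER:
            base_out = _OTHER[base][int(rng.integers(0, 3))]
        else:
            base_out = base
        out.append(base_out)
        if rng.random() < min(em.insertion_rate * hp, 1.0):
            out.append("ACGT"[int(rng.integers(0, 4))])
        prev = base
    return "".join(out) if out else "A"
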