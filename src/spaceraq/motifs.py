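"""Guide-oriented flank extraction, SAM detection, PFMs and motif counting.

Flanks are always reported on the crRNA-matching (nontarget) strand, read
5'->3', so the acquisition motif of a DNA protospacer looks identical no
matter which strand the spacer came from.  The canonical SAM of this system
is 5'-NNNNNTAAA-3' downstream of the protospacer in guide orientation for
array-to-leader (II-C-style) loci; leader-to-array (VI-B-style) loci see the
same genomic motif upstream as its reverse complement, 5'-TTTANNNNN-3'.
"""
from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass

import numpy as np

from ._dna import iupac_to_regex, revcomp, revcomp_iupac
from .io_formats import GenomeRecord, OrfFeature, ParameterError
from .loci import LocusModel
from .mapping import ProtospacerHit

__all__ = [
    "FlankContext",
    "PositionFrequencyMatrix",
    "MotifCountResult",
    "extract_flanks",
    "detect_sam",
    "build_pfm",
    "count_motif",
    "sam_rate",
    "motif_offset_histogram",
    "CANONICAL_SAM",
]

CANONICAL_SAM = "NNNNNTAAA"
#: 0-based window of the TAAA core within a 15-nt downstream flank
SAM_CORE_SLICE = slice(5, 9)


@dataclass
class FlankContext:
    hit: ProtospacerHit
    upstream: str
    downstream: str
    upstream_truncated: bool
    downstream_truncated: bool


def extract_flanks(hit: ProtospacerHit, genome: GenomeRecord,
                   flank_len: int = 15) -> FlankContext:
    """Flanks of a hit on its crRNA-matching strand, 5'->3'.

    On linear genomes a flank running past a physical end is truncated (and
    flagged); on circular genomes it wraps around the origin.
    """
    seq = genome.sequence
    G = len(seq)
    if not (0 <= hit.start < hit.end <= G):
        raise ParameterError(f"hit [{hit.start},{hit.end}) outside genome {genome.id}")

    def fetch(lo: int, hi: int) -> tuple[str, bool]:
        if genome.topology == "circular":
            return "".join(seq[i % G] for i in range(lo, hi)), False
        clo, chi = max(lo, 0), min(hi, G)
        return seq[clo:chi], (clo != lo or chi != hi)

    left, left_trunc = fetch(hit.start - flank_len, hit.start)
    right, right_trunc = fetch(hit.end, hit.end + flank_len)
    if hit.strand == "+":
        return FlankContext(hit, left, right, left_trunc, right_trunc)
    return FlankContext(hit, revcomp(right), revcomp(left),
                        right_trunc, left_trunc)


def detect_sam(ctx: FlankContext, locus: LocusModel,
               motif: str = CANONICAL_SAM) -> bool | None:
    """Canonical SAM present next to this protospacer, per the locus's side?

    Array-to-leader loci: the motif reads forward at the start of the
    downstream flank (TAAA at flank positions 6-9, 1-based).  Leader-to-array
    loci: the reverse-complement motif ends at the protospacer-proximal end
    of the upstream flank (TTTA at positions 7-10 of a 15-nt flank).  Returns
    None (indeterminate) when the relevant flank is truncated.
    """
    m = len(motif)
    if locus.sam_side == "downstream":
        if ctx.downstream_truncated or len(ctx.downstream) < m:
            return None
        window = ctx.downstream[:m]
        return re.fullmatch(iupac_to_regex(motif), window) is not None
    if ctx.upstream_truncated or len(ctx.upstream) < m:
        return None
    window = ctx.upstream[-m:]
    return re.fullmatch(iupac_to_regex(revcomp_iupac(motif)), window) is not None


def sam_rate(contexts, locus: LocusModel, motif: str = CANONICAL_SAM,
             ) -> tuple[float, int, int]:
    """(rate, k, n) of SAM-positive contexts, excluding indeterminate ones."""
    flags = [detect_sam(c, locus, motif) for c in contexts]
    usable = [f for f in flags if f is not None]
    n = len(usable)
    k = sum(usable)
    return (k / n if n else float("nan")), k, n


@dataclass
class PositionFrequencyMatrix:
    counts: np.ndarray          # shape (4, flank_len), rows A, C, G, T
    n_sequences: int
    side: str

    ALPHABET = "ACGT"

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.counts.sum(axis=0, keepdims=True)

    @property
    def information_content(self) -> np.ndarray:
        """Per-column information content in bits: 2 - Shannon entropy."""
        f = self.frequencies
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = np.where(f > 0, -f * np.log2(f), 0.0).sum(axis=0)
        return 2.0 - ent

    def consensus(self) -> str:
        return "".join(self.ALPHABET[i] for i in self.counts.argmax(axis=0))

    def to_text(self) -> str:
        lines = ["pos\tA\tC\tG\tT\tIC_bits"]
        ic = self.information_content
        for j in range(self.counts.shape[1]):
            col = "\t".join(str(int(c)) for c in self.counts[:, j])
            lines.append(f"{j + 1}\t{col}\t{ic[j]:.3f}")
        return "\n".join(lines)


def build_pfm(contexts, side: str) -> PositionFrequencyMatrix:
    """Position-frequency matrix over the untruncated flanks of one side."""
    if side not in ("upstream", "downstream"):
        raise ParameterError(f"side must be upstream/downstream, got {side!r}")
    seqs = []
    for c in contexts:
        truncated = c.upstream_truncated if side == "upstream" else c.downstream_truncated
        s = c.upstream if side == "upstream" else c.downstream
        if not truncated and s and "N" not in s:
            seqs.append(s)
    if not seqs:
        raise ParameterError("no usable (untruncated) flank contexts")
    width = len(seqs[0])
    counts = np.zeros((4, width), dtype=np.int64)
    lut = {b: i for i, b in enumerate(PositionFrequencyMatrix.ALPHABET)}
    for s in seqs:
        for j, b in enumerate(s):
            counts[lut[b], j] += 1
    return PositionFrequencyMatrix(counts=counts, n_sequences=len(seqs), side=side)


def motif_offset_histogram(contexts, core: str = "TAAA",
                           side: str = "downstream") -> Counter:
    """Histogram of 0-based offsets at which the motif core occurs within the
    given flank (resolves 'extended or shortened N region' variants)."""
    hist: Counter = Counter()
    pat = re.compile("(?=" + iupac_to_regex(core) + ")")
    for c in contexts:
        truncated = c.upstream_truncated if side == "upstream" else c.downstream_truncated
        if truncated:
            continue
        s = c.upstream if side == "upstream" else c.downstream
        for m in pat.finditer(s):
            hist[m.start()] += 1
    return hist


@dataclass
class MotifCountResult:
    motif: str
    scope: str
    count_total: int
    count_coding_strand: int
    count_template_strand: int

    @property
    def proportions(self) -> tuple[float, float]:
        if self.count_total == 0:
            return (float("nan"), float("nan"))
        return (self.count_coding_strand / self.count_total,
                self.count_template_strand / self.count_total)


def _count_overlapping(pattern: re.Pattern, text: str) -> int:
    return sum(1 for _ in pattern.finditer(text))


def count_motif(genome: GenomeRecord, motif: str, scope: str = "whole_genome",
                features: list[OrfFeature] | None = None) -> MotifCountResult:
    """Count motif occurrences on both strands, whole-genome or CDS-only.

    Whole-genome scope labels the forward strand as 'coding' by reporting
    convention.  CDS scope counts occurrences fully inside each feature and
    labels them by the feature's own orientation (an occurrence on the
    feature's strand is on the coding strand).  Overlapping occurrences are
    all counted; features are counted independently, so motifs inside
    overlapping CDS regions contribute once per feature.
    """
    fwd = re.compile("(?=" + iupac_to_regex(motif) + ")")
    rev = re.compile("(?=" + iupac_to_regex(revcomp_iupac(motif)) + ")")
    seq = genome.sequence
    if scope == "whole_genome":
        coding = _count_overlapping(fwd, seq)
        template = _count_overlapping(rev, seq)
    elif scope == "cds_only":
        feats = features if features is not None else genome.features
        coding = template = 0
        for f in feats:
            sub = seq[f.start:f.end]
            n_fwd = _count_overlapping(fwd, sub)
            n_rev = _count_overlapping(rev, sub)
            if f.strand == "+":
                coding += n_fwd
                template += n_rev
            else:
                coding += n_rev
                template += n_fwd
    else:
        raise ParameterError(f"unknown scope {scope!r}")
    return MotifCountResult(motif=motif, scope=scope,
                            count_total=coding + template,
                            count_coding_strand=coding,
                            count_template_strand=template)
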