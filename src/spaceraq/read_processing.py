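"""Quality trimming and repeat-anchored spacer extraction.

Trimming follows Trimmomatic-style rules (TRAILING, then a 5'->3' sliding
window, then a minimum-length filter).  Extraction finds an intact
full-length repeat in the read, then looks for the first ``repeat_anchor_len``
bases of the next repeat 27-32 nt downstream; the intervening bases are the
new spacer.  Spacers are always emitted in crRNA orientation: when a locus is
sequenced from the strand opposite its crRNA, the read is reverse-
complemented before the search.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from ._dna import revcomp
from .io_formats import ParameterError, ReadRecord
from .loci import LocusModel

__all__ = [
    "ExtractionConfig",
    "SpacerObservation",
    "ExtractionSummary",
    "trim_read",
    "extract_spacer",
    "extract_all",
]


@dataclass
class ExtractionConfig:
    window_size: int = 3
    window_mean_quality: float = 21.0
    trailing_quality: int = 23
    min_read_length: int = 100
    min_spacer_len: int = 27
    max_spacer_len: int = 32
    repeat_anchor_len: int = 4
    max_repeat_mismatches: int = 0
    read_orientation: str = "as_crRNA"

    def __post_init__(self) -> None:
        if not 0 < self.min_spacer_len <= self.max_spacer_len:
            raise ParameterError("need 0 < min_spacer_len <= max_spacer_len")
        if self.repeat_anchor_len < 1:
            raise ParameterError("repeat_anchor_len must be >= 1")
        if self.window_size < 1:
            raise ParameterError("window_size must be >= 1")
        if self.read_orientation not in ("as_crRNA", "reverse_complement_of_crRNA"):
            raise ParameterError(f"unknown read_orientation {self.read_orientation!r}")


@dataclass
class SpacerObservation:
    sequence: str
    locus_id: str
    replicate_id: str
    source_read_id: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise ParameterError(f"spacer contains non-ACGT characters {sorted(bad)}")


@dataclass
class ExtractionSummary:
    n_input: int = 0
    n_trimmed_out: int = 0
    n_no_spacer: int = 0
    n_extracted: int = 0

    def as_dict(self) -> dict:
        return dict(vars(self))


def trim_read(read: ReadRecord, cfg: ExtractionConfig) -> ReadRecord | None:
    """Apply TRAILING then SLIDINGWINDOW then MINLEN; None means dropped.

    TRAILING removes 3' bases while their quality is below
    ``trailing_quality``.  The sliding window then scans full windows of
    ``window_size`` from the 5' end and cuts the read at the start of the
    first window whose mean quality falls below ``window_mean_quality``.
    """
    q = read.qualities
    end = len(q)
    while end > 0 and q[end - 1] < cfg.trailing_quality:
        end -= 1
    cut = end
    w = cfg.window_size
    for i in range(0, end - w + 1):
        if sum(q[i:i + w]) / w < cfg.window_mean_quality:
            cut = i
            break
    if cut < cfg.min_read_length:
        return None
    if cut == len(q):
        return read
    return ReadRecord(id=read.id, sequence=read.sequence[:cut], qualities=q[:cut])


def _find_hamming(haystack: str, needle: str, max_mm: int, start: int = 0) -> int:
    """First position of ``needle`` in ``haystack`` with <= max_mm mismatches."""
    if max_mm == 0:
        return haystack.find(needle, start)
    n = len(needle)
    for i in range(start, len(haystack) - n + 1):
        mm = 0
        for a, b in zip(haystack[i:i + n], needle):
            if a != b:
                mm += 1
                if mm > max_mm:
                    break
        if mm <= max_mm:
            return i
    return -1


def extract_spacer(read: ReadRecord, locus: LocusModel,
                   cfg: ExtractionConfig, replicate_id: str = "r1",
                   ) -> SpacerObservation | None:
    """Extract at most one spacer from a trimmed read; None if no valid hit.

    The first full-length repeat occurrence anchors the search; anchor
    offsets are tried in ascending order so the leader-proximal (shortest
    valid) spacer wins deterministically.
    """
    seq = read.sequence
    if cfg.read_orientation == "reverse_complement_of_crRNA":
        seq = revcomp(seq)
    rep = locus.repeat
    p = _find_hamming(seq, rep, cfg.max_repeat_mismatches)
    if p < 0:
        return None
    sp_start = p + len(rep)
    anchor = rep[:cfg.repeat_anchor_len]
    for L in range(cfg.min_spacer_len, cfg.max_spacer_len + 1):
        a = sp_start + L
        if a + cfg.repeat_anchor_len > len(seq):
            break
        window = seq[a:a + cfg.repeat_anchor_len]
        mm = sum(x != y for x, y in zip(window, anchor))
        if mm <= cfg.max_repeat_mismatches:
            spacer = seq[sp_start:a]
            if set(spacer) - set("ACGT"):
                return None
            return SpacerObservation(sequence=spacer, locus_id=locus.locus_id,
                                     replicate_id=replicate_id,
                                     source_read_id=read.id)
    return None


def extract_all(reads: Iterable[ReadRecord], locus: LocusModel,
                cfg: ExtractionConfig, replicate_id: str = "r1",
                ) -> tuple[list[SpacerObservation], ExtractionSummary]:
    """Trim then extract every read; returns observations plus counts."""
    summary = ExtractionSummary()
    observations: list[SpacerObservation] = []
    for read in reads:
        summary.n_input += 1
        trimmed = trim_read(read, cfg)
        if trimmed is None:
            summary.n_trimmed_out += 1
            continue
        obs = extract_spacer(trimmed, locus, cfg, replicate_id=replicate_id)
        if obs is None:
            summary.n_no_spacer += 1
        else:
            summary.n_extracted += 1
            observations.append(obs)
    return observations, summary
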