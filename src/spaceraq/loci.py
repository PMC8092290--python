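"""CRISPR locus description.

A locus is defined by its repeat, leader, and the direction its array is
transcribed.  The transcription direction alone fixes two downstream
contracts: the orientation of the crRNA relative to the stored spacer DNA,
and on which side of a protospacer the shared acquisition motif (SAM) is
read in guide orientation.

For the dual-locus system this package models, the DNA-targeting II-C array
is transcribed from within the array toward the variable (leader) end
(``array_to_leader``), so its guide-oriented SAM lies downstream of the
protospacer (5'-NNNNNTAAA-3').  The RNA-targeting VI-B array is transcribed
conventionally, leader first (``leader_to_array``); the same genomic motif is
then read upstream on the opposite strand as 5'-TTTANNNNN-3'.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import ParameterError

__all__ = ["LocusModel"]

_DIRECTIONS = ("leader_to_array", "array_to_leader")


@dataclass
class LocusModel:
    locus_id: str
    repeat: str
    leader: str
    transcription_direction: str
    preexisting_spacers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.repeat = self.repeat.upper()
        self.leader = self.leader.upper()
        if len(self.repeat) < 20:
            raise ParameterError(
                f"locus {self.locus_id}: repeat shorter than 20 nt "
                "(must exceed extraction anchor requirements)"
            )
        if self.transcription_direction not in _DIRECTIONS:
            raise ParameterError(
                f"locus {self.locus_id}: transcription_direction must be one of "
                f"{_DIRECTIONS}, got {self.transcription_direction!r}"
            )

    @property
    def sam_side(self) -> str:
        """Which guide-oriented flank carries the SAM: ``downstream`` for
        array-to-leader transcription (II-C style), ``upstream`` otherwise."""
        if self.transcription_direction == "array_to_leader":
            return "downstream"
        return "upstream"
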