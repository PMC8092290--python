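"""Small shared DNA helpers: complementation, encoding, IUPAC handling."""
from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: IUPAC nucleotide codes -> set of concrete bases they stand for.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def revcomp_iupac(motif: str) -> str:
    """Reverse complement of an IUPAC motif string."""
    return motif.translate(_IUPAC_COMPLEMENT)[::-1]


def iupac_to_regex(motif: str) -> str:
    """Translate an IUPAC motif into a plain regex character-class pattern.

    An N in the target sequence matches nothing (conservative choice: ambiguous
    genome positions never count as motif occurrences).
    """
    parts = []
    for sym in motif.upper():
        try:
            bases = IUPAC[sym]
        except KeyError:
            raise ValueError(f"unknown IUPAC symbol {sym!r} in motif {motif!r}") from None
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return "".join(parts)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array of ASCII codes (vector comparisons)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def random_dna(rng: np.random.Generator, length: int, gc_fraction: float = 0.5) -> str:
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    bases = rng.choice(np.array(list("ACGT")), size=length, p=[at, gc, gc, at])
    return "".join(bases)
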