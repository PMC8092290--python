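"""Run configuration: one YAML document describing a full pipeline run.

Every stage's tunables live in one validated object so a run is reproducible
from its config plus a seed; outputs are stamped with the config hash.
"""
from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .clustering import ClusterConfig
from .io_formats import ParameterError
from .loci import LocusModel
from .mapping import AlignConfig
from .overlap_null import NullModelConfig
from .read_processing import ExtractionConfig
from .target_stats import BinningConfig

__all__ = ["GenomeInput", "LocusRun", "RunConfig", "default_loci"]


def default_loci() -> list[LocusModel]:
    """The simulated dual-locus system: a DNA-targeting locus transcribed
    array-to-leader (II-C style) and an RNA-targeting locus transcribed
    leader-to-array (VI-B style), with distinct 36-nt repeats."""
    return [
        LocusModel(
            locus_id="II-C",
            repeat="GTTGTAGTTCCCTTTATAACGGGTTTAGAAATTTCA",
            leader="ATTTAAATTGAAATAAGTTATTTTAACTTG",
            transcription_direction="array_to_leader",
            preexisting_spacers=["TACCAGTTGATTGGATAACAACCTGAATCA"],
        ),
        LocusModel(
            locus_id="VI-B",
            repeat="GTTGGAACTAACTTAAGACCTGTTAAAGGTTTTGAG",
            leader="TTAAATAACTTAAATTGAAGTTTTAAGCAA",
            transcription_direction="leader_to_array",
            preexisting_spacers=["CAATCTGAGAAATTGCCAAGTTAGTTCAAT"],
        ),
    ]


@dataclass
class GenomeInput:
    fasta: str
    features: str | None = None
    feature_dialect: str = "gff3"
    topology: str = "linear"


@dataclass
class LocusRun:
    locus: LocusModel
    read_orientation: str = "as_crRNA"
    reads: dict[str, str] = field(default_factory=dict)   # replicate -> FASTQ path


@dataclass
class RunConfig:
    phage: GenomeInput
    host: GenomeInput
    loci: list[LocusRun]
    seed: int = 1
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    clustering: ClusterConfig = field(default_factory=ClusterConfig)
    alignment: AlignConfig = field(default_factory=AlignConfig)
    null_model: NullModelConfig = field(default_factory=NullModelConfig)
    binning: BinningConfig = field(default_factory=BinningConfig)
    overlap_query_locus: str | None = None      # defaults to the last locus
    overlap_reference_locus: str | None = None  # defaults to the first locus

    def __post_init__(self) -> None:
        if not self.loci:
            raise ParameterError("config needs at least one locus")
        for lr in self.loci:
            if not lr.reads:
                raise ParameterError(
                    f"locus {lr.locus.locus_id}: zero replicates configured")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        def sub(klass, key):
            return klass(**data[key]) if key in data and data[key] else klass()

        loci = []
        for entry in data.get("loci", []):
            entry = dict(entry)
            lr_kwargs = {k: entry.pop(k) for k in ("read_orientation", "reads")
                         if k in entry}
            locus_fields = entry.pop("locus", None) or entry  # nested or flat
            loci.append(LocusRun(locus=LocusModel(**locus_fields), **lr_kwargs))
        return cls(
            phage=GenomeInput(**data["phage"]),
            host=GenomeInput(**data["host"]),
            loci=loci,
            seed=int(data.get("seed", 1)),
            extraction=sub(ExtractionConfig, "extraction"),
            clustering=sub(ClusterConfig, "clustering"),
            alignment=sub(AlignConfig, "alignment"),
            null_model=sub(NullModelConfig, "null_model"),
            binning=sub(BinningConfig, "binning"),
            overlap_query_locus=data.get("overlap_query_locus"),
            overlap_reference_locus=data.get("overlap_reference_locus"),
        )
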