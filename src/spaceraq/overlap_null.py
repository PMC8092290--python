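"""Monte-Carlo nulls for inter-locus spacer-pool sharing.

The question: is the fraction of one locus's unique phage-targeting spacers
that also occur in the other locus's pool higher than expected if each locus
sampled protospacers independently?  Two nulls are simulated by drawing
pools of genome subsequences — either uniformly at random or restricted to
SAM-adjacent placements — and measuring the fraction of each simulated pool
matching the reference pool at 90% identity.  A normal distribution is
fitted to the simulated fractions (maximum likelihood: sample mean and
population SD) and the observed overlap is scored by its upper-tail
probability; the rank-based empirical p-value is co-reported because the
normal fit is an approximation.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from ._dna import revcomp
from .clustering import ClusterConfig, SpacerPool, bulk_best_identity, cross_pool_fraction
from .io_formats import GenomeRecord, ParameterError
from .synthetic_data import sam_placement_starts

__all__ = [
    "NullModelConfig",
    "OverlapNullResult",
    "sample_null_pool",
    "run_null",
    "observed_overlap",
]


@dataclass
class NullModelConfig:
    n_iterations: int = 1000
    sample_size: int = 430
    simulated_spacer_length: int = 30
    sam_motif: str = "NNNNNTAAA"
    sampling_mode: str = "random"       # or "pam_adjacent"
    cross_pool_identity: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ParameterError("n_iterations must be >= 1")
        if self.sample_size < 1:
            raise ParameterError("sample_size must be >= 1")
        if self.sampling_mode not in ("random", "pam_adjacent"):
            raise ParameterError(f"unknown sampling_mode {self.sampling_mode!r}")


@dataclass
class OverlapNullResult:
    mode: str
    fractions: np.ndarray
    mu: float                   # fitted normal mean
    sigma: float                # fitted normal SD (maximum likelihood, divisor n)
    observed: float | None = None
    p_normal: float | None = None
    p_empirical: float | None = None
    degenerate_fit: bool = False


def _pam_placements(genome: GenomeRecord, cfg: NullModelConfig) -> list[tuple[int, int, str]]:
    """All genomic placements whose downstream guide-strand flank matches the
    SAM (either strand), for the configured simulated spacer length."""
    L = cfg.simulated_spacer_length
    starts = sam_placement_starts(genome.sequence, cfg.sam_motif)
    out: list[tuple[int, int, str]] = []
    for e in starts["+"]:
        if e - L >= 0:
            out.append((int(e) - L, int(e), "+"))
    for s in starts["-"]:
        if s + L <= len(genome):
            out.append((int(s), int(s) + L, "-"))
    return out


def sample_null_pool(genome: GenomeRecord, cfg: NullModelConfig,
                     rng: np.random.Generator,
                     placements: list[tuple[int, int, str]] | None = None,
                     ) -> list[str]:
    """Draw ``sample_size`` simulated spacers from the genome, with replacement.

    ``random`` mode: uniform start position and strand.  ``pam_adjacent``
    mode: uniform choice among all SAM-adjacent placements on either strand
    (downstream guide-strand flank matching the motif).
    """
    L = cfg.simulated_spacer_length
    seq = genome.sequence
    if cfg.sampling_mode == "random":
        starts = rng.integers(0, len(seq) - L + 1, size=cfg.sample_size)
        strands = rng.integers(0, 2, size=cfg.sample_size)
        return [seq[s:s + L] if st == 0 else revcomp(seq[s:s + L])
                for s, st in zip(starts, strands)]
    if placements is None:
        placements = _pam_placements(genome, cfg)
    if not placements:
        raise ParameterError(
            f"pam_adjacent sampling: no {cfg.sam_motif} placement of length {L} "
            f"on genome {genome.id}")
    idx = rng.integers(0, len(placements), size=cfg.sample_size)
    out = []
    for i in idx:
        s, e, st = placements[int(i)]
        out.append(seq[s:e] if st == "+" else revcomp(seq[s:e]))
    return out


def run_null(genome: GenomeRecord, reference_pool: SpacerPool,
             cfg: NullModelConfig, observed: float | None = None,
             ) -> OverlapNullResult:
    """Simulate the overlap null and (optionally) score an observed fraction.

    Per iteration, a simulated pool is drawn and the fraction matching the
    reference pool at ``cross_pool_identity`` recorded.  p_normal is the
    upper-tail probability of the fitted normal at the observed value;
    p_empirical = (1 + #{fractions >= observed}) / (1 + n_iterations).
    """
    if len(reference_pool) == 0:
        raise ParameterError("reference pool is empty")
    rng = np.random.default_rng(cfg.seed)
    refs = reference_pool.representatives
    placements = (_pam_placements(genome, cfg)
                  if cfg.sampling_mode == "pam_adjacent" else None)
    fractions = np.empty(cfg.n_iterations)
    for it in range(cfg.n_iterations):
        pool = sample_null_pool(genome, cfg, rng, placements)
        matched = bulk_best_identity(pool, refs, cfg.cross_pool_identity)
        fractions[it] = matched.mean()
    mu = float(fractions.mean())
    sigma = float(fractions.std(ddof=0))
    result = OverlapNullResult(mode=cfg.sampling_mode, fractions=fractions,
                               mu=mu, sigma=sigma)
    if observed is not None:
        result.observed = float(observed)
        if sigma == 0.0:
            result.degenerate_fit = observed != mu
            if result.degenerate_fit:
                warnings.warn("degenerate normal fit (sigma = 0); p is 0 or 1")
            result.p_normal = 0.0 if observed > mu else 1.0
        else:
            result.p_normal = float(norm.sf(observed, loc=mu, scale=sigma))
        result.p_empirical = float(
            (1 + int((fractions >= observed - 1e-12).sum())) / (1 + cfg.n_iterations))
    return result


def observed_overlap(query_pool: SpacerPool, reference_pool: SpacerPool,
                     cfg: NullModelConfig | ClusterConfig) -> float:
    """Observed sharing: fraction of query representatives matching the
    reference pool at the cross-pool identity threshold."""
    ccfg = (cfg if isinstance(cfg, ClusterConfig)
            else ClusterConfig(cross_pool_identity=cfg.cross_pool_identity))
    frac, _ = cross_pool_fraction(query_pool, reference_pool, ccfg)
    return frac
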