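"""mRNA-targeting classification, binomial bias tests, and binned target maps.

A spacer can silence a transcript only when (i) its crRNA is complementary
to the coding strand — i.e. the crRNA-matching protospacer strand is the
opposite of the ORF strand — and (ii) the protospacer lies fully within the
ORF.  Hits outside or straddling ORFs are excluded rather than counted.

The bias statistic compares the mRNA-targeting proportion of each pool
(locus x target genome x unique/absolute view) to a Binomial(n, 1/2) null
that assumes equal odds of either strand, with the null distribution sized
to the pool, exactly as one would for pool-size-matched expectation bands.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import binom

from .io_formats import GenomeRecord, OrfFeature, ParameterError
from .mapping import ProtospacerHit

__all__ = [
    "classify_mrna",
    "BinomialTestResult",
    "binomial_bias_test",
    "mrna_proportions",
    "BinningConfig",
    "BinCounts",
    "bin_distribution",
]

MRNA_TARGETING = "mRNA_targeting"
NON_MRNA = "non_mRNA"
INTERGENIC = "intergenic_excluded"


def classify_mrna(hit: ProtospacerHit, features: list[OrfFeature]) -> str:
    """One of mRNA_targeting / non_mRNA / intergenic_excluded.

    ORF-boundary-straddling hits are excluded.  If overlapping ORFs on both
    strands fully contain the hit, transcript complementarity to any one of
    them counts as mRNA targeting.
    """
    containing = [f for f in features if f.contains(hit.start, hit.end)]
    if not containing:
        return INTERGENIC
    if any(f.strand != hit.strand for f in containing):
        return MRNA_TARGETING
    return NON_MRNA


@dataclass
class BinomialTestResult:
    n: int
    k: int
    direction: str            # 'above' or 'below' the p=0.5 expectation
    p_value: float
    ci_low: float             # 95% expected interval of k/n under the null
    ci_high: float

    @property
    def proportion(self) -> float:
        return self.k / self.n


def _log_binom_pmf(n: int, k: np.ndarray) -> np.ndarray:
    lg = math.lgamma(n + 1)
    return (lg - np.vectorize(math.lgamma)(k + 1)
            - np.vectorize(math.lgamma)(n - k + 1) - n * math.log(2.0))


def binomial_bias_test(k: int, n: int, direction: str) -> BinomialTestResult:
    """One-tailed exact binomial test against p = 1/2.

    p = P(X >= k) for direction 'above', P(X <= k) for 'below', with
    X ~ Binomial(n, 1/2), evaluated by exact log-space summation of the pmf.
    The 95% expected interval is [q(0.025), q(0.975)] / n from the exact
    binomial quantiles.
    """
    if n < 1:
        raise ParameterError("binomial test needs n >= 1")
    if not 0 <= k <= n:
        raise ParameterError(f"k={k} outside [0, {n}]")
    if direction not in ("above", "below"):
        raise ParameterError(f"direction must be above/below, got {direction!r}")
    ks = np.arange(k, n + 1) if direction == "above" else np.arange(0, k + 1)
    p = float(np.exp(logsumexp(_log_binom_pmf(n, ks))))
    p = min(p, 1.0)
    lo = binom.ppf(0.025, n, 0.5) / n
    hi = binom.ppf(0.975, n, 0.5) / n
    return BinomialTestResult(n=n, k=k, direction=direction, p_value=p,
                              ci_low=float(lo), ci_high=float(hi))


def mrna_proportions(hits: list[ProtospacerHit], features_by_genome: dict[str, list[OrfFeature]],
                     views: tuple[str, ...] = ("unique", "absolute"),
                     grouping: str = "pooled",
                     direction: str = "auto") -> pd.DataFrame:
    """Per-pool mRNA-targeting proportions with pool-size-matched binomial tests.

    Pools are formed by locus x target class (and replicate when
    ``grouping='per_replicate'``).  ``direction='auto'`` tests above the null
    when the observed proportion exceeds 1/2 and below otherwise; the chosen
    direction is recorded in the output.  Empty pools yield NA rows.
    """
    if grouping not in ("pooled", "per_replicate"):
        raise ParameterError(f"unknown grouping {grouping!r}")
    rows = []
    pools: dict[tuple, list[ProtospacerHit]] = {}
    for h in hits:
        if grouping == "pooled":
            pools.setdefault((h.locus_id, h.target_class, "pooled"), []).append(h)
        else:
            reps = h.per_replicate or {"r1": 1}
            for rep in reps:
                pools.setdefault((h.locus_id, h.target_class, rep), []).append(h)
    for (locus, target, rep), pool_hits in sorted(pools.items()):
        feats = features_by_genome.get(pool_hits[0].genome_id, [])
        labels = [classify_mrna(h, feats) for h in pool_hits]
        for view in views:
            def weight(h: ProtospacerHit) -> int:
                if view == "unique":
                    return 1 if grouping == "pooled" else int(h.per_replicate.get(rep, 0) > 0)
                return h.absolute_count if grouping == "pooled" else h.per_replicate.get(rep, 0)
            n = sum(weight(h) for h, lab in zip(pool_hits, labels) if lab != INTERGENIC)
            k = sum(weight(h) for h, lab in zip(pool_hits, labels) if lab == MRNA_TARGETING)
            if n == 0:
                rows.append(dict(locus_id=locus, target_class=target, replicate=rep,
                                 view=view, n=0, k=0, proportion=float("nan"),
                                 direction="NA", p_value=float("nan"),
                                 ci_low=float("nan"), ci_high=float("nan")))
                continue
            d = direction if direction != "auto" else ("above" if k / n > 0.5 else "below")
            res = binomial_bias_test(k, n, d)
            rows.append(dict(locus_id=locus, target_class=target, replicate=rep,
                             view=view, n=n, k=k, proportion=res.proportion,
                             direction=d, p_value=res.p_value,
                             ci_low=res.ci_low, ci_high=res.ci_high))
    return pd.DataFrame(rows)


@dataclass
class BinningConfig:
    bin_fraction: float = 0.03
    smoothing_window: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.bin_fraction <= 1:
            raise ParameterError("bin_fraction outside (0, 1]")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ParameterError("smoothing_window must be odd and >= 1")

    def n_bins(self) -> int:
        return math.ceil(1.0 / self.bin_fraction)


@dataclass
class BinCounts:
    genome_id: str
    n_bins: int
    table: pd.DataFrame        # columns: bin, replicate, strand, count, proportion
    smoothed: pd.DataFrame     # columns: bin, strand, mean_proportion, smoothed
    motif_track: np.ndarray | None


def bin_distribution(hits: list[ProtospacerHit], genome: GenomeRecord,
                     cfg: BinningConfig | None = None, motif: str | None = None,
                     view: str = "unique") -> BinCounts:
    """Per-strand, per-replicate binned protospacer distribution.

    Bin index is floor(midpoint / (bin_fraction * genome length)); the last
    bin absorbs the remainder.  Proportions are normalized per replicate over
    all (bin, strand) cells.  The smoothed curve is a centered moving average
    of the across-replicate mean proportion.  ``motif`` adds a per-bin motif
    occurrence track (both strands) normalized to the genome total.
    """
    cfg = cfg or BinningConfig()
    G = len(genome)
    nb = cfg.n_bins()
    width = cfg.bin_fraction * G
    recs = []
    for h in hits:
        if h.genome_id != genome.id:
            continue
        mid = (h.start + h.end) / 2.0
        b = min(int(mid // width), nb - 1)
        reps = h.per_replicate or {"r1": (1 if view == "unique" else h.absolute_count)}
        for rep, cnt in reps.items():
            w = (1 if view == "unique" else cnt) if h.per_replicate else cnt
            recs.append((b, rep, h.strand, w))
    cols = ["bin", "replicate", "strand", "count"]
    df = pd.DataFrame(recs, columns=cols)
    replicates = sorted(df["replicate"].unique()) if len(df) else []
    full = pd.MultiIndex.from_product(
        [range(nb), replicates or ["r1"], ["+", "-"]], names=["bin", "replicate", "strand"])
    counts = (df.groupby(["bin", "replicate", "strand"])["count"].sum()
              .reindex(full, fill_value=0).reset_index())
    totals = counts.groupby("replicate")["count"].transform("sum").to_numpy(float)
    cnt = counts["count"].to_numpy(float)
    counts["proportion"] = np.divide(cnt, totals, out=np.zeros_like(cnt),
                                     where=totals > 0)
    mean_prop = (counts.groupby(["bin", "strand"])["proportion"].mean()
                 .reset_index().rename(columns={"proportion": "mean_proportion"}))
    mean_prop["smoothed"] = (
        mean_prop.groupby("strand")["mean_proportion"]
        .transform(lambda s: s.rolling(cfg.smoothing_window, center=True,
                                       min_periods=1).mean()))
    track = None
    if motif is not None:
        track = np.zeros(nb)
        total = 0
        import re as _re
        from ._dna import iupac_to_regex, revcomp_iupac
        pats = [_re.compile("(?=" + iupac_to_regex(m) + ")")
                for m in (motif, revcomp_iupac(motif))]
        for pat in pats:
            for mt in pat.finditer(genome.sequence):
                mid = mt.start() + len(motif) / 2.0
                track[min(int(mid // width), nb - 1)] += 1
                total += 1
        if total:
            track /= total
    return BinCounts(genome_id=genome.id, n_bins=nb, table=counts,
                     smoothed=mean_prop, motif_track=track)
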