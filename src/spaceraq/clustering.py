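"""Greedy identity clustering of spacers and cross-pool sharing fractions.

Sequence identity is the CD-HIT-EST-style effective definition for
near-equal-length fragments: the best ungapped alignment over all relative
offsets, with the match count divided by the length of the shorter sequence.
Clustering is greedy over a deterministic content-based ordering
(count desc, length desc, lexicographic), so results are independent of
input order; membership additionally requires at least one shared word of
``word_size`` exact bases (the CD-HIT word filter).

Spacers are compared in the orientation they were extracted in (canonical
crRNA orientation); reverse complements are deliberately not considered, so
sense and antisense acquisition events stay distinct.
"""
from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._dna import encode
from .io_formats import ParameterError
from .read_processing import SpacerObservation

__all__ = [
    "ClusterConfig",
    "Cluster",
    "SpacerPool",
    "sequence_identity",
    "cluster_pool",
    "cross_pool_fraction",
    "bulk_best_identity",
]


@dataclass
class ClusterConfig:
    within_pool_identity: float = 0.8
    cross_pool_identity: float = 0.9
    word_size: int = 5

    def __post_init__(self) -> None:
        for name in ("within_pool_identity", "cross_pool_identity"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ParameterError(f"{name}={v} outside (0, 1]")
        if self.word_size < 3:
            raise ParameterError("word_size must be >= 3")


@dataclass
class Cluster:
    representative: str
    members: list[tuple[str, int]]                 # (sequence, observation count)
    per_replicate: Counter = field(default_factory=Counter)

    @property
    def size(self) -> int:
        """Total observation count (absolute size)."""
        return sum(c for _, c in self.members)


@dataclass
class SpacerPool:
    clusters: list[Cluster]
    locus_id: str
    view: str = "unique"

    @property
    def representatives(self) -> list[str]:
        return [c.representative for c in self.clusters]

    def counts(self) -> list[int]:
        """Per-cluster counts under this pool's view."""
        if self.view == "unique":
            return [1] * len(self.clusters)
        return [c.size for c in self.clusters]

    def as_view(self, view: str) -> "SpacerPool":
        if view not in ("unique", "absolute"):
            raise ParameterError(f"unknown pool view {view!r}")
        return SpacerPool(clusters=self.clusters, locus_id=self.locus_id, view=view)

    def __len__(self) -> int:
        return len(self.clusters)


def sequence_identity(a: str, b: str, min_identity: float = 0.0) -> float:
    """Best-offset ungapped identity: matches / len(shorter sequence).

    ``min_identity`` is an optional pruning hint: offsets whose overlap is too
    short to reach it are skipped (the returned value is exact whenever it is
    >= min_identity, and otherwise an underestimate).
    """
    if not a or not b:
        raise ParameterError("sequence_identity requires non-empty sequences")
    la, lb = len(a), len(b)
    lmin = min(la, lb)
    need = int(math.ceil(min_identity * lmin - 1e-9))
    ea, eb = encode(a), encode(b)
    best = 0
    # offset k: position of a's start relative to b's start
    for k in range(-(la - 1), lb):
        qs, rs = max(0, -k), max(0, k)
        ov = min(la - qs, lb - rs)
        if ov < max(1, need):
            continue
        m = int((ea[qs:qs + ov] == eb[rs:rs + ov]).sum())
        if m > best:
            best = m
    return best / lmin


def _words(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def _canonical_order(items: Sequence[tuple[str, int]]) -> list[tuple[str, int]]:
    return sorted(items, key=lambda t: (-t[1], -len(t[0]), t[0]))


def cluster_pool(observations: Iterable[SpacerObservation], cfg: ClusterConfig,
                 view: str = "unique", locus_id: str | None = None) -> SpacerPool:
    """Greedily cluster spacer observations into a pool.

    Identical sequences are first aggregated with counts; the distinct
    sequences are then processed in canonical order, each joining the first
    existing representative at identity >= ``within_pool_identity`` that
    shares a word, or founding a new cluster.
    """
    observations = list(observations)
    if locus_id is None:
        locus_id = observations[0].locus_id if observations else "pool"
    counts: Counter = Counter()
    rep_counts: dict[str, Counter] = defaultdict(Counter)
    for obs in observations:
        counts[obs.sequence] += 1
        rep_counts[obs.sequence][obs.replicate_id] += 1
    clusters: list[Cluster] = []
    words_by_cluster: list[set[str]] = []
    for seq, n in _canonical_order(list(counts.items())):
        w = _words(seq, cfg.word_size)
        joined = False
        for cl, cw in zip(clusters, words_by_cluster):
            if not (w & cw):
                continue
            if sequence_identity(seq, cl.representative,
                                 cfg.within_pool_identity) >= cfg.within_pool_identity - 1e-12:
                cl.members.append((seq, n))
                cl.per_replicate.update(rep_counts[seq])
                joined = True
                break
        if not joined:
            clusters.append(Cluster(representative=seq, members=[(seq, n)],
                                    per_replicate=Counter(rep_counts[seq])))
            words_by_cluster.append(w)
    return SpacerPool(clusters=clusters, locus_id=locus_id, view=view)


def bulk_best_identity(queries: Sequence[str], references: Sequence[str],
                       threshold: float) -> np.ndarray:
    """Boolean vector: does each query reach ``threshold`` identity against
    any reference?  Vectorized over length groups; equivalent to calling
    :func:`sequence_identity` pairwise."""
    if len(references) == 0:
        return np.zeros(len(queries), dtype=bool)
    matched = np.zeros(len(queries), dtype=bool)
    q_groups: dict[int, list[int]] = defaultdict(list)
    for i, q in enumerate(queries):
        q_groups[len(q)].append(i)
    r_groups: dict[int, list[str]] = defaultdict(list)
    for r in references:
        r_groups[len(r)].append(r)
    r_mats = {lr: np.vstack([encode(r) for r in rs]) for lr, rs in r_groups.items()}
    for lq, idxs in q_groups.items():
        qmat = np.vstack([encode(queries[i]) for i in idxs])
        hit = np.zeros(len(idxs), dtype=bool)
        for lr, rmat in r_mats.items():
            lmin = min(lq, lr)
            need = int(math.ceil(threshold * lmin - 1e-9))
            for k in range(-(lq - 1), lr):
                qs, rs = max(0, -k), max(0, k)
                ov = min(lq - qs, lr - rs)
                if ov < max(1, need):
                    continue
                eq = qmat[:, None, qs:qs + ov] == rmat[None, :, rs:rs + ov]
                m = eq.sum(axis=2)            # (nq, nr) match counts
                hit |= (m >= need).any(axis=1)
            if hit.all():
                break
        matched[np.array(idxs)] = hit
    return matched


def cross_pool_fraction(query: SpacerPool, reference: SpacerPool,
                        cfg: ClusterConfig) -> tuple[float, list[bool]]:
    """Fraction of query representatives with a reference representative at
    identity >= ``cross_pool_identity``; also returns the per-query matches."""
    if len(query) == 0:
        raise ParameterError("cross_pool_fraction: empty query pool")
    matched = bulk_best_identity(query.representatives, reference.representatives,
                                 cfg.cross_pool_identity)
    return float(matched.mean()), matched.tolist()
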