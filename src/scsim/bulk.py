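"""Bulk-sample composition by mixing pure per-prototype read pools.

For each prototype genome a pool of paired-end reads is generated once per
run; each bulk sample then draws read pairs *without replacement* from
these shared pools in proportions given by its realized genotype
distribution G_ij.  Pools are depleted globally, so no read pair is ever
duplicated within or across the bulk samples of a run.

Counts are apportioned by the largest-remainder (Hamilton) method with
ties broken toward the lowest prototype index: they are non-negative, sum
exactly to the requested total, and each count is within 1 of the ideal
quota total * g_k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import PoolExhaustedError, RangeError
from .formats import write_fastq_pair
from .reads import ReadBatch

__all__ = ["ReadPool", "allocate_counts", "draw_without_replacement",
           "compose_bulk_sample"]


def allocate_counts(g_sample, total: int) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` draws across prototypes.

    Returns integer counts >= 0 summing exactly to ``total``; remainder
    ties go to the lowest index.
    """
    if total < 0:
        raise RangeError(f"total must be >= 0, got {total}")
    g = np.asarray(g_sample, dtype=float)
    quota = g * total
    counts = np.floor(quota).astype(np.int64)
    short = int(total - counts.sum())
    if short > 0:
        remainders = quota - counts
        # stable sort descending by remainder; ties keep index order
        order = np.argsort(-remainders, kind="stable")
        counts[order[:short]] += 1
    return counts


@dataclass
class ReadPool:
    """A depleting pool of read pairs simulated from one prototype genome."""

    prototype: int
    batch: ReadBatch
    _names: list[str] = field(init=False, repr=False)
    _remaining: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self._names = self.batch.names()
        self._remaining = np.arange(len(self.batch), dtype=np.int64)

    @property
    def remaining(self) -> int:
        return int(self._remaining.size)

    def draw(self, count: int, rng: np.random.Generator) -> np.ndarray:
        """Remove and return ``count`` uniformly chosen pair indices."""
        if count < 0:
            raise RangeError(f"count must be >= 0, got {count}")
        if count > self._remaining.size:
            raise PoolExhaustedError(self.prototype, count, self._remaining.size)
        if count == 0:
            return np.empty(0, dtype=np.int64)
        pick = rng.choice(self._remaining.size, size=count, replace=False)
        drawn = self._remaining[pick]
        mask = np.ones(self._remaining.size, dtype=bool)
        mask[pick] = False
        self._remaining = self._remaining[mask]
        return drawn


def draw_without_replacement(pool: ReadPool, count: int,
                             rng: np.random.Generator) -> np.ndarray:
    """Functional wrapper over :meth:`ReadPool.draw` (mutates the pool)."""
    return pool.draw(count, rng)


def compose_bulk_sample(pools: list[ReadPool], g_sample, total_pairs: int,
                        rng: np.random.Generator,
                        path_r1: str, path_r2: str) -> dict[int, int]:
    """Write one bulk sample's FASTQ pair by mixing the prototype pools.

    Draws ``allocate_counts(g_sample, total_pairs)`` read pairs from each
    pool, shuffles the combined order, and writes exactly ``total_pairs``
    records to each mate file.  Returns the per-prototype pair counts.
    """
    counts = allocate_counts(g_sample, total_pairs)
    if len(counts) != len(pools):
        raise RangeError("g_sample length must match number of pools")
    # fail fast before touching any pool
    for pool, c in zip(pools, counts):
        if c > pool.remaining:
            raise PoolExhaustedError(pool.prototype, int(c), pool.remaining)

    names: list[str] = []
    seq1_parts, seq2_parts, quals = [], [], []
    for pool, c in zip(pools, counts):
        idx = pool.draw(int(c), rng)
        names.extend(pool._names[i] for i in idx)
        seq1_parts.append(pool.batch.seq1[idx])
        seq2_parts.append(pool.batch.seq2[idx])
        quals.extend([pool.batch.quality_char * pool.batch.read_length] * len(idx))

    seq1 = np.concatenate(seq1_parts) if seq1_parts else np.empty((0, 0), np.uint8)
    seq2 = np.concatenate(seq2_parts) if seq2_parts else np.empty((0, 0), np.uint8)
    order = rng.permutation(len(names))

    rl = seq1.shape[1] if len(names) else 0
    s1 = seq1[order].reshape(len(names), -1).view(f"S{max(rl,1)}")[:, 0] if len(names) else []
    s2 = seq2[order].reshape(len(names), -1).view(f"S{max(rl,1)}")[:, 0] if len(names) else []
    write_fastq_pair(
        path_r1, path_r2,
        (names[i] for i in order),
        (b.decode("ascii") for b in s1),
        (quals[i] for i in order),
        (b.decode("ascii") for b in s2),
        (quals[i] for i in order),
    )
    return {pool.prototype: int(c) for pool, c in zip(pools, counts)}
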