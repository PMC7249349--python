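"""Internal paired-end short-read engine.

Simulates Illumina-like paired-end reads from a diploid genome (two
haplotype edit lists over a reference region) at a target mean coverage:

* number of pairs = round(coverage * L / (2 * read_length));
* per pair: source haplotype by fair coin, fragment length ~
  Normal(fragment_mean, fragment_sd) rounded and clipped to
  [2*read_length, L], fragment start uniform over valid starts;
* read 1 is the fragment prefix on the forward strand, read 2 the reverse
  complement of the fragment suffix;
* every emitted base is independently substituted with probability
  ``error_rate`` to a uniformly chosen different base (N bases pass
  through untouched); qualities are a constant Phred score.

Read names encode full provenance, colon-separated::

    <sample>:<source>:<hap>:<fragstart>:<fragend>:<serial>

where ``source`` identifies the genome of origin (``p<k>`` for prototype
k) — this is what lets bulk-mixture composition be audited exactly — and
fragment coordinates are 0-based half-open, so the error-free read bases
can be re-extracted from the source haplotype.

All heavy lifting is vectorized over numpy byte arrays; a million pairs
simulate in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import ReadParams
from .errors import RangeError

__all__ = [
    "ReadBatch",
    "pair_count_for_coverage",
    "materialize_haplotype",
    "simulate_read_pairs",
    "parse_read_name",
    "reverse_complement",
]

# base codes: A=0 C=1 G=2 T=3 N=4
_CODE_OF = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_OF[_b] = _i
_ASCII_OF = np.frombuffer(b"ACGTN", dtype=np.uint8)
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def pair_count_for_coverage(region_length: int, coverage: float,
                            read_length: int) -> int:
    """Pairs needed for a mean coverage: round(c*L / (2*read_length))."""
    if region_length <= 0 or coverage < 0 or read_length <= 0:
        raise RangeError("region_length and read_length must be positive, coverage >= 0")
    return int(round(coverage * region_length / (2.0 * read_length)))


def materialize_haplotype(reference: str, edits) -> np.ndarray:
    """Apply an edit list to the reference; returns base codes (uint8)."""
    codes = _CODE_OF[np.frombuffer(reference.encode("ascii"), dtype=np.uint8)].copy()
    for pos, alt in edits:
        codes[pos] = _CODE_OF[ord(alt)]
    return codes


def reverse_complement(seq: str) -> str:
    codes = _CODE_OF[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    return bytes(_ASCII_OF[_COMP[codes]][::-1]).decode("ascii")


@dataclass
class ReadBatch:
    """A batch of simulated read pairs with provenance arrays.

    ``seq1``/``seq2`` are (n, read_length) ASCII byte matrices; names are
    built lazily by :meth:`names` from the provenance columns.
    """

    name_prefix: str           # "<sample>:<source>"
    seq1: np.ndarray
    seq2: np.ndarray
    hap: np.ndarray            # 0/1 per pair
    frag_start: np.ndarray
    frag_end: np.ndarray
    quality_char: str

    def __len__(self) -> int:
        return self.seq1.shape[0]

    @property
    def read_length(self) -> int:
        return self.seq1.shape[1]

    def names(self, serial_offset: int = 0) -> list[str]:
        p = self.name_prefix
        return [
            f"{p}:{h}:{s}:{e}:{serial_offset + i}"
            for i, (h, s, e) in enumerate(zip(self.hap, self.frag_start, self.frag_end))
        ]

    def seq_strings(self, mate: int):
        mat = self.seq1 if mate == 1 else self.seq2
        view = mat.reshape(len(self), -1).view(f"S{self.read_length}")[:, 0]
        return [b.decode("ascii") for b in view]

    def qual_strings(self):
        q = self.quality_char * self.read_length
        return [q] * len(self)


def _inject_errors(mat: np.ndarray, error_rate: float, rng: np.random.Generator):
    if error_rate <= 0:
        return
    codes = _CODE_OF[mat]
    mask = (rng.random(mat.shape) < error_rate) & (codes < 4)
    n_err = int(mask.sum())
    if n_err == 0:
        return
    shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
    codes[mask] = (codes[mask] + shift) % 4
    mat[mask] = _ASCII_OF[codes[mask]]


def simulate_read_pairs(hap_a: np.ndarray, hap_b: np.ndarray,
                        params: ReadParams, n_pairs: int,
                        rng: np.random.Generator,
                        name_prefix: str) -> ReadBatch:
    """Simulate ``n_pairs`` paired-end reads from a diploid genome.

    ``hap_a``/``hap_b`` are base-code arrays from
    :func:`materialize_haplotype` (equal length L).  Fragment coordinates
    in read names are 0-based half-open over the region.
    """
    if n_pairs < 0:
        raise RangeError(f"n_pairs must be >= 0, got {n_pairs}")
    L = hap_a.shape[0]
    rl = params.read_length
    if params.fragment_mean > L:
        raise RangeError(f"fragment_mean {params.fragment_mean} exceeds region length {L}")

    frag_len = np.rint(rng.normal(params.fragment_mean, params.fragment_sd,
                                  size=n_pairs)).astype(np.int64)
    np.clip(frag_len, 2 * rl, L, out=frag_len)
    start = rng.integers(0, L - frag_len + 1)
    end = start + frag_len
    hap = rng.integers(0, 2, size=n_pairs).astype(np.int8)

    offsets = np.arange(rl, dtype=np.int64)
    idx1 = start[:, None] + offsets
    idx2 = (end - rl)[:, None] + offsets
    seq1_codes = np.empty((n_pairs, rl), dtype=np.uint8)
    seq2_codes = np.empty((n_pairs, rl), dtype=np.uint8)
    for h, source in ((0, hap_a), (1, hap_b)):
        rows = hap == h
        seq1_codes[rows] = source[idx1[rows]]
        seq2_codes[rows] = source[idx2[rows]]
    # read 2 reports the reverse complement of the fragment's far end
    seq2_codes = _COMP[seq2_codes][:, ::-1]

    seq1 = _ASCII_OF[seq1_codes]
    seq2 = _ASCII_OF[seq2_codes]
    _inject_errors(seq1, params.error_rate, rng)
    _inject_errors(seq2, params.error_rate, rng)

    return ReadBatch(
        name_prefix=name_prefix,
        seq1=np.ascontiguousarray(seq1),
        seq2=np.ascontiguousarray(seq2),
        hap=hap,
        frag_start=start,
        frag_end=end,
        quality_char=chr(33 + params.base_quality),
    )


def parse_read_name(name: str) -> dict:
    """Decode the provenance fields of a simulated read name."""
    fields = name.rsplit(":", 4)
    if len(fields) != 5:
        raise ValueError(f"not a scsim read name: {name!r}")
    head, hap, start, end, serial = fields
    sample, _, source = head.rpartition(":")
    return {
        "sample": sample,
        "source": source,
        "hap": int(hap),
        "frag_start": int(start),
        "frag_end": int(end),
        "serial": int(serial),
    }
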