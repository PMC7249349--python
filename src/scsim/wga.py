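"""Whole-genome-amplification error model for single-cell samples.

A single cell carries exactly one of the K prototype genotypes, selected
by a categorical draw from its realized sample distribution G_ij (for the
small gamma values used in practice G_ij sits near a simplex vertex, so
cells of a sample almost always share a genotype).  Amplifying the cell's
genome before sequencing introduces two error classes:

* **Allelic dropout (ADO)** — at each heterozygous site, with probability
  ``ado_rate`` one allele fails to amplify; the surviving allele is chosen
  by a fair coin and the site becomes homozygous for it.  Homozygous sites
  are never altered.
* **False positives (FP)** — spurious heterozygous mutations at
  non-variant positions; the number of FP sites is Binomial(L, fp_rate)
  over the whole region length L, positions uniform without replacement,
  alt allele drawn from the substitution-matrix row of the reference base.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import BASES, SnvModelParams, default_subst_matrix
from .errors import RangeError
from .prototypes import PrototypeGenome

__all__ = ["CellGenome", "select_cell_genotype", "apply_wga"]


@dataclass(frozen=True)
class CellGenome:
    """A single cell's diploid genome after WGA errors."""

    source_prototype: int
    haplotype_a: tuple[tuple[int, str], ...]
    haplotype_b: tuple[tuple[int, str], ...]
    ado_events: tuple[tuple[int, str], ...]   # (position, dropped allele 'ref'/'alt')
    fp_events: tuple[tuple[int, str], ...]    # (position, alt base)

    @property
    def variant_positions(self) -> set[int]:
        return {p for p, _ in self.haplotype_a} | {p for p, _ in self.haplotype_b}


def select_cell_genotype(g_sample, rng: np.random.Generator) -> int:
    """Pick the cell's prototype index: one categorical draw from G_ij."""
    g = np.asarray(g_sample, dtype=float)
    return int(rng.choice(g.size, p=g / g.sum()))


def apply_wga(prototype: PrototypeGenome, ado_rate: float, fp_rate: float,
              reference: str, rng: np.random.Generator,
              subst: SnvModelParams | None = None) -> CellGenome:
    """Apply ADO and FP errors to a prototype genome, yielding a cell genome.

    ``reference`` is the region sequence (its length L sets the FP count
    distribution Binomial(L, fp_rate) and supplies reference bases for FP
    alt-allele draws).  FP positions never collide with prototype variant
    positions and FP sites are heterozygous on a randomly chosen haplotype.
    """
    if not 0.0 <= ado_rate <= 1.0:
        raise RangeError(f"ado_rate must be in [0,1], got {ado_rate}")
    if not 0.0 <= fp_rate <= 1.0:
        raise RangeError(f"fp_rate must be in [0,1], got {fp_rate}")
    subst_matrix = (subst.subst_matrix if subst is not None
                    else default_subst_matrix())

    hap_a = dict(prototype.haplotype_a)
    hap_b = dict(prototype.haplotype_b)

    # --- allelic dropout over heterozygous sites
    ado_events = []
    for pos in sorted(prototype.het_positions):
        if rng.random() >= ado_rate:
            continue
        # choose which haplotype's allele survives; site becomes hom for it
        alt_hap, other = (hap_a, hap_b) if pos in hap_a else (hap_b, hap_a)
        if rng.random() < 0.5:
            # alt-carrying haplotype survives -> hom alt
            other[pos] = alt_hap[pos]
            ado_events.append((pos, "ref"))
        else:
            # ref haplotype survives -> hom ref
            del alt_hap[pos]
            ado_events.append((pos, "alt"))

    # --- WGA false positives over non-variant positions
    region_length = len(reference)
    n_fp = int(rng.binomial(region_length, fp_rate))
    fp_events = []
    if n_fp > 0:
        forbidden = prototype.variant_positions
        chosen: set[int] = set()
        while len(chosen) < n_fp:
            cand = rng.integers(0, region_length, size=n_fp - len(chosen))
            for pos in cand:
                pos = int(pos)
                if pos in forbidden or pos in chosen or reference[pos] == "N":
                    continue
                chosen.add(pos)
        for pos in sorted(chosen):
            row = subst_matrix[BASES.index(reference[pos])]
            alt = BASES[int(rng.choice(4, p=row))]
            target = hap_a if rng.random() < 0.5 else hap_b
            target[pos] = alt
            fp_events.append((pos, alt))

    return CellGenome(
        source_prototype=prototype.index,
        haplotype_a=tuple(sorted(hap_a.items())),
        haplotype_b=tuple(sorted(hap_b.items())),
        ado_events=tuple(ado_events),
        fp_events=tuple(fp_events),
    )
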