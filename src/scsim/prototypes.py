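"""Construction of the K mutated diploid synthetic prototype genomes.

From a single haploid reference region the forge places ``n_snv`` equally
spaced potential SNV locations, assigns each a sharing tier — one-third of
sites present in all K prototypes, one-third in half of them, one-third in
a uniformly-drawn proportion of them — then draws zygosity (het/hom) and a
substitution allele per site from a row-stochastic base-substitution
matrix, and finally materializes per-prototype haplotype edit lists.

Prototype genomes play the role of clonal genotypes in the cancer analogy:
every simulated cell or bulk mixture is built from these K genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .design import BASES, SnvModelParams
from .errors import ConfigurationError, RangeError
from .rng import rng_for

__all__ = [
    "SnvSite",
    "PrototypeGenome",
    "place_snv_sites",
    "assign_substitutions",
    "build_prototype_genomes",
    "tier_counts",
]

TIER_ALL = "all"
TIER_HALF = "half"
TIER_UNIFORM = "uniform"

ZYG_ABSENT, ZYG_HET, ZYG_HOM = 0, 1, 2


@dataclass(frozen=True)
class SnvSite:
    """One potential SNV location within the simulated region (0-based)."""

    position: int
    tier: str
    presence: np.ndarray          # bool, length K
    zygosity: np.ndarray | None = None   # int8, length K: 0 absent, 1 het, 2 hom
    ref_base: str | None = None
    alt_base: str | None = None


@dataclass(frozen=True)
class PrototypeGenome:
    """Diploid genome stored as two haplotype edit lists over the reference."""

    index: int
    haplotype_a: tuple[tuple[int, str], ...]   # (position, alt_base)
    haplotype_b: tuple[tuple[int, str], ...]

    @property
    def het_positions(self) -> set[int]:
        a = {p for p, _ in self.haplotype_a}
        b = {p for p, _ in self.haplotype_b}
        return a ^ b

    @property
    def hom_positions(self) -> set[int]:
        a = {p for p, _ in self.haplotype_a}
        b = {p for p, _ in self.haplotype_b}
        return a & b

    @property
    def variant_positions(self) -> set[int]:
        return {p for p, _ in self.haplotype_a} | {p for p, _ in self.haplotype_b}


def tier_counts(n_snv: int) -> tuple[int, int, int]:
    """Deterministic split of n sites into (all, half, uniform) tiers.

    Exactly n/3 each when 3 divides n; otherwise ceil-first so the counts
    always sum to n.
    """
    c_all = -(-n_snv // 3)
    c_half = -(-(n_snv - c_all) // 2)
    return c_all, c_half, n_snv - c_all - c_half


def place_snv_sites(region_length: int, n_snv: int, K: int,
                    margin_fraction: float = 0.1, seed: int = 0) -> list[SnvSite]:
    """Place equally spaced SNV sites and assign sharing tiers and presence.

    Sites are confined to the central ``1 - 2*margin_fraction`` of the
    region: the first site sits at ``floor(margin*L)`` and consecutive
    sites are ``floor((1-2*margin)*L / (n-1))`` bp apart (for the
    documented defaults L=1e6, n=100 this gives the 8080 bp spacing).
    Tier labels are assigned to sites in position order by the
    :func:`tier_counts` split, then shuffled deterministically.  Presence:
    'all' sites in every prototype; 'half' sites in a random subset of
    ceil(K/2) prototypes; 'uniform' sites in max(1, round(p*K)) random
    prototypes with p ~ U(0,1).
    """
    if n_snv < 1:
        raise RangeError("n_snv must be >= 1")
    if K < 1:
        raise RangeError("K must be >= 1")
    rng = rng_for(seed, "place_snv_sites")

    if n_snv == 1:
        positions = np.array([region_length // 2])
    else:
        usable = (1.0 - 2.0 * margin_fraction) * region_length
        spacing = int(usable // (n_snv - 1))
        if spacing < 1:
            raise ConfigurationError(
                f"region of {region_length} bp too small to space {n_snv} sites "
                f"with margin {margin_fraction}"
            )
        first = int(margin_fraction * region_length)
        positions = first + spacing * np.arange(n_snv)

    c_all, c_half, c_unif = tier_counts(n_snv)
    tiers = np.array([TIER_ALL] * c_all + [TIER_HALF] * c_half
                     + [TIER_UNIFORM] * c_unif, dtype=object)
    rng.shuffle(tiers)

    half_count = -(-K // 2)    # ceil(K/2)
    sites = []
    for pos, tier in zip(positions, tiers):
        presence = np.zeros(K, dtype=bool)
        if tier == TIER_ALL:
            presence[:] = True
        elif tier == TIER_HALF:
            presence[rng.choice(K, size=half_count, replace=False)] = True
        else:
            m = max(1, int(round(float(rng.uniform()) * K)))
            presence[rng.choice(K, size=m, replace=False)] = True
        sites.append(SnvSite(position=int(pos), tier=str(tier), presence=presence))
    return sites


def assign_substitutions(sites: list[SnvSite], reference: str,
                         params: SnvModelParams, seed: int = 0) -> list[SnvSite]:
    """Fill in zygosity and substitution alleles for placed sites.

    The alt allele is drawn once per site from the substitution-matrix row
    of its reference base and shared by every prototype carrying the site;
    zygosity is drawn independently per present (site, prototype) pair:
    heterozygous with probability ``p_het``, else homozygous.  Sites whose
    reference base is N are moved deterministically rightward to the
    nearest non-N base.
    """
    m = np.asarray(params.subst_matrix, dtype=float)
    if np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-9):
        raise ConfigurationError("substitution matrix rows must sum to 1 within 1e-9")
    rng = rng_for(seed, "assign_substitutions")
    taken = {s.position for s in sites}
    out = []
    for site in sites:
        pos = site.position
        while reference[pos] == "N" or (pos != site.position and pos in taken):
            pos += 1
            if pos >= len(reference):
                raise ConfigurationError(
                    f"no non-N reference base at or right of {site.position}"
                )
        if pos != site.position:
            taken.discard(site.position)
            taken.add(pos)
        ref_base = reference[pos]
        row = m[BASES.index(ref_base)]
        alt_base = BASES[int(rng.choice(4, p=row))]
        zyg = np.zeros(len(site.presence), dtype=np.int8)
        present = np.flatnonzero(site.presence)
        het = rng.random(len(present)) < params.p_het
        zyg[present] = np.where(het, ZYG_HET, ZYG_HOM)
        out.append(replace(site, position=pos, zygosity=zyg,
                           ref_base=ref_base, alt_base=alt_base))
    return out


def build_prototype_genomes(reference: str, sites: list[SnvSite],
                            seed: int = 0) -> list[PrototypeGenome]:
    """Materialize K diploid prototype genomes as haplotype edit lists.

    Homozygous sites edit both haplotypes; heterozygous sites edit exactly
    one, chosen by a fair coin per (site, prototype).
    """
    if not sites:
        return []
    K = len(sites[0].presence)
    rng = rng_for(seed, "build_prototype_genomes")
    edits_a: list[list[tuple[int, str]]] = [[] for _ in range(K)]
    edits_b: list[list[tuple[int, str]]] = [[] for _ in range(K)]
    for site in sorted(sites, key=lambda s: s.position):
        if site.zygosity is None or site.alt_base is None:
            raise ConfigurationError("sites must be fully assigned before building genomes")
        for k in range(K):
            z = int(site.zygosity[k])
            if z == ZYG_ABSENT:
                continue
            edit = (site.position, site.alt_base)
            if z == ZYG_HOM:
                edits_a[k].append(edit)
                edits_b[k].append(edit)
            else:
                if rng.random() < 0.5:
                    edits_a[k].append(edit)
                else:
                    edits_b[k].append(edit)
    return [PrototypeGenome(index=k, haplotype_a=tuple(edits_a[k]),
                            haplotype_b=tuple(edits_b[k]))
            for k in range(K)]
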