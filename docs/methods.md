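# Methods

## Overview

`scsim` simulates next-generation sequencing reads for a grouped sampling
design in which samples are nested inside biological units (patients,
replicates) drawn from a population — the setting of cancer studies that
collect bulk biopsies and single cells from several patients.  The
simulator produces, from one haploid reference sequence and a YAML design:

1. **K mutated diploid prototype genomes** — the clonal genotypes;
2. a **realized genotype distribution** for every unit and sample via a
   truncated hierarchical Dirichlet model;
3. **single-cell FASTQ** reads from one genotype per cell after a
   whole-genome-amplification (WGA) error model;
4. **bulk FASTQ** reads mixed without replacement from pure per-prototype
   read pools in the realized proportions;
5. **truth VCF/TSV files** and a JSON manifest, so variant callers can be
   benchmarked against a gold standard (the `eval` subcommand computes
   recall, precision, F1 and Ti/Tv, with standard hard post-filters).

## Prototype genomes

`n_snv` potential SNV locations are placed equally spaced in the central
`1 − 2·margin_fraction` of the region: the first site at
`floor(margin·L)`, subsequent sites `floor((1 − 2·margin)·L/(n − 1))` bp
apart.  With the defaults (margin 0.1) a 1 Mbp region and 100 sites give a
spacing of exactly 8080 bp.  A single site degenerates to the region
midpoint.  The margin keeps fragments that overlap a site fully inside the
region at typical fragment lengths.

Sharing tiers: one third of sites are present in all K prototypes, one
third in `ceil(K/2)` of them (chosen uniformly per site), and one third in
`max(1, round(p·K))` prototypes with `p ~ U(0,1)` — the `max(1, ·)` floor
avoids orphan sites carried by nobody.  For `n` not divisible by 3 the
split is `(ceil(n/3), ceil(rest/2), rest)`, assigned in position order and
then shuffled, so the counts are deterministic and exact whenever `3 | n`.

Zygosity and substitution type: each present (site, prototype) pair is
heterozygous with probability `p_het` (default 0.5), else homozygous.  The
alt allele is drawn once per site from the row of a 4×4 zero-diagonal
row-stochastic substitution matrix indexed by the reference base, and
shared by all prototypes carrying the site (a location has one variant
type).  The default matrix puts 0.58 on the transition partner of each
base and 0.21 on each transversion, giving an expected
transition/transversion ratio of 0.58/0.42 ≈ 1.38 — inside the 1.2–1.6
band expected for human SNV sets.  Both `p_het` and the matrix are
user-configurable.  Sites falling on an N reference base are moved
deterministically rightward to the nearest usable base.

Heterozygous edits land on one haplotype chosen by a fair coin per (site,
prototype); homozygous edits on both.  Only substitutions are modelled —
no indels, structural variants or context-dependent signatures — so
haplotype length always equals the region length.

## Hierarchical Dirichlet sampling

    G''   ~ Dirichlet(alpha)            population distribution over genotypes
    G'_i  ~ Dirichlet(beta_i · G'')     biological unit i
    G_ij  ~ Dirichlet(gamma_ij · G'_i)  sample j of unit i

`beta_i` and `gamma_ij` control how tightly each level concentrates around
its parent: at 0.1 draws sit near a simplex vertex (a sample dominated by
one genotype, the expected situation for a single cell), at large values
they converge to the parent vector.  By iterated expectations
`E[G_ij] = alpha / Σalpha` at every level.  `G''` is drawn once per run.
With K → ∞ and genotypes drawn i.i.d. from a base measure this truncated
model approaches a hierarchical Dirichlet process mixture; with the fixed,
small K typical of sequencing studies the truncated form is used directly.

**Numerics.**  Child concentrations `beta_i · G''_k` routinely reach
1e-13, where gamma variates underflow to an all-zero vector.  Draws
therefore use log-gamma variates (`scipy.stats.loggamma`) normalized by
log-sum-exp — distributionally identical to normalized gamma variates but
stable at arbitrarily small shapes.  Concentrations are floored at 1e-12
before drawing; simplex entries below 1e-12 are clamped and the vector
renormalized.  Every stage derives its own child seed from a
blake2b hash of (master seed, stage, unit id, sample id), so adding a
sample to a design leaves all other draws unchanged.

## Single cells and the WGA error model

A cell's genotype is one categorical draw from its `G_ij` — a cell has a
single genome, not a mixture.  Amplification errors:

* **Allelic dropout (ADO)** — per heterozygous site, with probability
  `ado_rate` (default 0.20) one allele is lost; the surviving allele is a
  fair coin, and the site becomes homozygous for it.  Homozygous sites are
  untouched.  The per-het-site reading makes 20% an interpretable dropout
  probability.
* **False positives (FP)** — the FP count is `Binomial(L, fp_rate)`
  (default rate 3.2e-5, i.e. 32 expected on 1 Mbp), positions uniform
  without replacement over non-variant, non-N positions, each a
  heterozygous substitution (amplification errors affect one allele) with
  alt drawn from the substitution matrix row of the reference base.

Dropout is applied to the genome *before* read simulation, so read data
are consistent with the post-ADO genotype.  Per-cell truth VCFs flag FP
rows with `INFO/WGAFP` and ADO-altered genotypes with `FORMAT/ADO`.
Amplification-bias coverage unevenness, doublets and chimeric reads are
not modelled.

## Read engine

Paired-end reads are simulated internally (uniform fragment model):
`round(coverage·L / (2·read_length))` pairs per genome, haplotype by fair
coin (each haplotype receives ≈ coverage/2), fragment length
`Normal(fragment_mean, fragment_sd)` rounded then clipped to
`[2·read_length, L]` (clipping, not rejection — the tail mass moved to the
bounds is negligible at the default mean 500 / sd 50), start uniform over
valid positions.  Read 1 is the fragment prefix; read 2 the reverse
complement of the fragment suffix.  Each emitted base is substituted with
probability `error_rate` (default 1e-3) to a uniformly chosen different
base; qualities are a constant Phred 30 — plausible rather than
empirically calibrated, which is sufficient for caller benchmarking but
not for quality-model research.  Defaults (read length 100, fragment
500±50) are typical Illumina values.  Read names encode provenance
(`sample:source:haplotype:fragstart:fragend:serial`), so error-free bases
can be reproduced exactly from the name and mixtures audited read by read.

## Bulk mixing

One read pool per prototype is generated from that prototype's diploid
genome, sized to the exact summed demand of all bulk samples.  Each bulk
sample's `n_bulk_reads` (counted as records across both mate files; reads
are drawn as whole pairs) is apportioned across prototypes by
largest-remainder (Hamilton) rounding of `total · G_ij` with ties to the
lowest index — counts are non-negative, sum exactly to the total, and
each sits within 1 of its ideal quota.  Pairs are then drawn uniformly
*without replacement* from the shared pools, which deplete globally
across samples, so no read is duplicated anywhere in a run.  Feasibility
is validated before any FASTQ is written.

## Evaluation module

Calls match truth at the site level (1-based position + alt allele;
genotypes are not compared), truth and calls pooled across samples into
unique site sets.  `recall = TP/n_truth`, `precision = TP/n_called`,
`F1 = 2PR/(P+R)` (0 when degenerate; an empty call set warns and reports
precision 0).  Post-filters, all strict inequalities: mapping quality > 1,
base quality > 30, alt-supporting reads > 5, and strand bias — by default
a call fails when it has ≥ 4 alt reads all on one strand; a Fisher exact
test on the ref/alt × strand table (p < 0.001) is selectable.  A filter
whose annotation a record lacks is skipped for that record and counted.
Ti/Tv counts A↔G and C↔T as transitions; a set with no transversions
reports infinity.  An all-off-by-one call set triggers a coordinate-system
warning but is never silently shifted.

## Synthetic reference generator

`make_fixture_reference` draws i.i.d. bases at a target GC fraction
(default 0.41, human-like).  It reproduces none of the long-range
structure of real genomes — no repeats, no GC waves, no N gaps — so tests
passing on it demonstrate the simulator's sampling arithmetic and
bookkeeping, not robustness to alignability or mappability artifacts.
End-to-end caller benchmarks on real references (alignment, BCFtools /
Monovar calling) are downstream of this package and out of its scope.

## Reproducibility and problem sizes

All randomness flows from the design seed through named child seeds
recorded in the manifest; reruns are byte-identical (FASTQ gzip members
are written with a zero mtime).  The test suite exercises the full-scale
protocol quantities where they are cheap (8080 bp spacing on 1 Mbp, WGA
rates on a 1 Mbp genome, a 1,000,000-record bulk sample) and scales the
end-to-end pipeline run down to a 30 kb region at 2× coverage, which
covers every code path at a few seconds' cost.
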