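# scsim

Joint simulation of **correlated single-cell and bulk DNA sequencing
reads**, with truth files for benchmarking variant callers.

Studies that sequence both bulk biopsies and single cells from several
individuals need simulated data whose samples are *correlated the way real
grouped samples are* — cells and biopsies from the same patient share
clonal genotypes.  `scsim` generates exactly this structure.  From one
haploid reference FASTA and a YAML experiment design it produces paired
FASTQ files for every sample, gold-standard truth VCFs, and a JSON
manifest, all bitwise-reproducible from a single seed.

## Model

K mutated diploid *prototype genomes* (clonal genotypes) are derived from
the reference: n equally spaced SNV positions, one third shared by all K
prototypes, one third by half of them, one third by a uniformly drawn
proportion; zygosity and substitution alleles come from a configurable
base-substitution matrix (default transition mass 0.58, Ti/Tv ≈ 1.38).

Genotype proportions follow a truncated hierarchical Dirichlet model over
the grouping population → biological unit → sample:

    G″   ~ Dirichlet(α)
    G′ᵢ  ~ Dirichlet(βᵢ G″)          i = 1…N units
    Gᵢⱼ  ~ Dirichlet(γᵢⱼ G′ᵢ)        j = 1…Nᵢ samples of unit i

Small βᵢ, γᵢⱼ concentrate a level near a single genotype; large values
pin it to its parent.  Each **single cell** takes one genotype drawn from
its Gᵢⱼ and passes through a whole-genome-amplification error model —
allelic dropout at heterozygous sites (default rate 0.20) and spurious
heterozygous false positives (default 3.2×10⁻⁵ per base, 32 expected per
Mbp) — before paired-end reads are simulated.  Each **bulk sample** is
composed by drawing reads *without replacement* from pure per-prototype
read pools in proportions Gᵢⱼ (largest-remainder apportionment, exact to
the read).  The `eval` subcommand scores a caller's VCF against the truth
(recall, precision, F1, Ti/Tv) with standard post-filters (MQ > 1,
BQ > 30, alt reads > 5, strand bias).

See `docs/methods.md` for the full model description and numerics.

## Worked example

```bash
# a self-contained random reference (use a real FASTA for real work)
scsim fixture-ref --length 50000 --seed 11 --out ref.fa
scsim simulate --config design.yaml --reference ref.fa --outdir out --quiet
```

with `design.yaml` describing two units — one with a bulk + a single-cell
sample, one with two single cells (`alpha: [0.1, 0.3, 0.6]`, all β = γ =
0.1, coverage 4, 10,000 bulk reads; see the schema in
`src/scsim/design.py`).  The command prints:

```json
{
  "samples": {
    "u1_sc": 2000,
    "u2_sc1": 2000,
    "u2_sc2": 2000,
    "u1_bulk": 10000
  },
  "outdir": "out"
}
```

Each single cell got 2,000 reads (coverage 4 × 50 kb / 100 bp reads =
1,000 pairs) and the bulk sample exactly the 10,000 requested.  `out/`
holds `<sample>_R1/R2.fastq.gz`, per-cell truth VCFs (WGA false positives
flagged `WGAFP`, dropout-altered genotypes flagged `ADO`),
`prototypes_truth.vcf`/`.tsv`, a per-bulk-sample composition table and
`manifest.json` with the realized hierarchy draw and all child seeds.  In
this run `out/u1_bulk_composition.tsv` shows the realized G₁,bulk sat on a
vertex — all 5,000 pairs from prototype p2:

```
prototype  pairs  reads
p0         0      0
p1         0      0
p2         5000   10000
```

Scoring a call set against truth, here a caller that found 88 of 90 true
SNVs among 156 calls:

```python
>>> from scsim import score_calls
>>> truth = [(i*100+1, "G") for i in range(90)]
>>> calls = truth[:88] + [(10**6+i, "A") for i in range(68)]
>>> score_calls(calls, truth).to_dict()
{'n_truth': 90, 'n_called': 156, 'tp': 88, 'fp': 68, 'fn': 2,
 'recall': 0.9778, 'precision': 0.5641, 'f1': 0.7154, 'titv': None}
```

i.e. recall 97.8%, precision 56.4%, F1 0.715.

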