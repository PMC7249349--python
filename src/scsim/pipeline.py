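"""End-to-end simulation workflow.

Reference + experiment design in; per-sample paired FASTQ, truth VCF/TSV
and a JSON run manifest out.  Stage order: forge prototype genomes, draw
the genotype hierarchy, per single-cell sample select a genotype / apply
WGA / simulate reads, generate per-prototype read pools sized to the
exact bulk demand, compose each bulk sample by without-replacement
mixing, then write truth files and the manifest.  All randomness derives
from the design seed through per-stage child seeds, so a rerun with the
same inputs and seed is byte-identical (FASTQ gzip headers carry no
timestamps).
"""

from __future__ import annotations

import json
import logging
import os
import time
from pathlib import Path

import numpy as np

from . import __version__
from .bulk import ReadPool, allocate_counts, compose_bulk_sample
from .design import ExperimentDesign, SampleType, serialize_design
from .errors import ConfigurationError, PoolExhaustedError, ScsimError
from .formats import (TruthRecord, read_reference, write_fasta,
                      write_fastq_pair, write_truth_tsv, write_truth_vcf)
from .hierarchy import hierarchy_child_seeds, sample_hierarchy
from .prototypes import (ZYG_HET, ZYG_HOM, PrototypeGenome, SnvSite,
                         assign_substitutions, build_prototype_genomes,
                         place_snv_sites)
from .reads import materialize_haplotype, pair_count_for_coverage, simulate_read_pairs
from .rng import child_seed, rng_for
from .wga import CellGenome, apply_wga, select_cell_genotype

log = logging.getLogger(__name__)

__all__ = ["run_simulation", "make_fixture_reference",
           "prototype_truth_records", "cell_truth_records"]


def make_fixture_reference(length: int, gc_fraction: float = 0.41,
                           seed: int = 0, path: str | None = None,
                           name: str = "synthetic_ref") -> tuple[str, str]:
    """Generate a random i.i.d. reference sequence with a target GC fraction.

    Intended for tests and self-contained demonstrations; real analyses
    should pass a genuine reference FASTA.  Returns ``(name, sequence)``
    and writes a FASTA when ``path`` is given.
    """
    if length < 1:
        raise ConfigurationError("length must be >= 1")
    rng = rng_for(seed, "fixture_reference")
    gc = gc_fraction / 2.0
    at = (1.0 - gc_fraction) / 2.0
    seq = "".join(np.array(list("ACGT"))[
        rng.choice(4, size=length, p=[at, gc, gc, at])])
    if path is not None:
        write_fasta(path, name, seq)
    return name, seq


def prototype_truth_records(sites: list[SnvSite]) -> list[TruthRecord]:
    """VCF truth rows for the prototype genomes (one GT column per prototype)."""
    gt_of = {0: "0/0", ZYG_HET: "0/1", ZYG_HOM: "1/1"}
    records = []
    for s in sorted(sites, key=lambda x: x.position):
        if not s.presence.any():
            continue
        records.append(TruthRecord(
            position=s.position, ref=s.ref_base, alt=s.alt_base,
            genotypes=tuple(gt_of[int(z)] for z in s.zygosity),
            info={"TIER": s.tier},
        ))
    return records


def cell_truth_records(cell: CellGenome, sites: list[SnvSite],
                       reference: str) -> list[TruthRecord]:
    """VCF truth rows for one cell: prototype sites post-ADO plus WGA FPs."""
    hap_a = dict(cell.haplotype_a)
    hap_b = dict(cell.haplotype_b)
    ado_pos = {p for p, _ in cell.ado_events}
    fp = dict(cell.fp_events)
    records = []
    for s in sorted(sites, key=lambda x: x.position):
        if not s.presence[cell.source_prototype]:
            continue
        in_a, in_b = s.position in hap_a, s.position in hap_b
        gt = "1/1" if (in_a and in_b) else ("0/1" if (in_a or in_b) else "0/0")
        records.append(TruthRecord(
            position=s.position, ref=s.ref_base, alt=s.alt_base,
            genotypes=(gt,), ado=(1,) if s.position in ado_pos else (0,),
        ))
    for pos, alt in sorted(fp.items()):
        records.append(TruthRecord(
            position=pos, ref=reference[pos], alt=alt,
            genotypes=("0/1",), wga_fp=True, ado=(0,),
        ))
    records.sort(key=lambda r: r.position)
    return records


def _bulk_demand(design: ExperimentDesign, hierarchy) -> np.ndarray:
    """Exact per-prototype pair demand summed over all bulk samples."""
    demand = np.zeros(design.K, dtype=np.int64)
    for unit, s in design.samples:
        if s.type is SampleType.BULK:
            pairs = s.n_bulk_reads // 2
            demand += allocate_counts(hierarchy.g_sample[(unit.id, s.id)], pairs)
    return demand


def run_simulation(design: ExperimentDesign, reference_path: str | os.PathLike,
                   outdir: str | os.PathLike,
                   seed_override: int | None = None) -> dict:
    """Run the full workflow; returns the run manifest (also written as JSON).

    Bulk sample sizes (``n_bulk_reads``) count read records across both
    mate files, drawn as whole pairs.  On any stage failure the partial
    outputs written so far are removed and the error re-raised with the
    stage named.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master = design.seed if seed_override is None else seed_override
    created: list[Path] = []
    stage = "setup"

    def out(pathname: str) -> str:
        p = outdir / pathname
        created.append(p)
        return str(p)

    try:
        stage = "reference"
        t0 = time.perf_counter()
        contig, full_seq = read_reference(reference_path)
        end = design.region_start + design.region_length
        if end > len(full_seq):
            raise ConfigurationError(
                f"region [{design.region_start}, {end}) exceeds reference "
                f"length {len(full_seq)}")
        region = full_seq[design.region_start:end]
        region_contig = (contig if design.region_start == 0
                         and design.region_length == len(full_seq)
                         else f"{contig}_{design.region_start}_{end}")

        stage = "prototypes"
        sites = place_snv_sites(design.region_length, design.n_snv, design.K,
                                design.margin_fraction,
                                seed=child_seed(master, "sites"))
        sites = assign_substitutions(sites, region, design.subst,
                                     seed=child_seed(master, "substitutions"))
        prototypes = build_prototype_genomes(region, sites,
                                             seed=child_seed(master, "genomes"))
        proto_haps = [(materialize_haplotype(region, p.haplotype_a),
                       materialize_haplotype(region, p.haplotype_b))
                      for p in prototypes]
        log.info("forged %d prototypes, %d SNV sites (%.2fs)",
                 design.K, len(sites), time.perf_counter() - t0)

        stage = "hierarchy"
        hierarchy = sample_hierarchy(design, master)

        manifest_samples = {}
        cell_genomes: dict[str, CellGenome] = {}

        stage = "single-cell samples"
        for unit, s in design.samples:
            if s.type is not SampleType.SINGLE_CELL:
                continue
            g = hierarchy.g_sample[(unit.id, s.id)]
            rng = rng_for(master, "cell", unit.id, s.id)
            k = select_cell_genotype(g, rng)
            cell = apply_wga(prototypes[k], design.wga.ado_rate,
                             design.wga.fp_rate, region, rng, design.subst)
            cell_genomes[s.id] = cell
            hap_a = materialize_haplotype(region, cell.haplotype_a)
            hap_b = materialize_haplotype(region, cell.haplotype_b)
            n_pairs = pair_count_for_coverage(design.region_length, s.coverage,
                                              design.reads.read_length)
            batch = simulate_read_pairs(
                hap_a, hap_b, design.reads, n_pairs,
                rng_for(master, "reads", unit.id, s.id),
                name_prefix=f"{s.id}:p{k}")
            r1, r2 = out(f"{s.id}_R1.fastq.gz"), out(f"{s.id}_R2.fastq.gz")
            write_fastq_pair(r1, r2, batch.names(), batch.seq_strings(1),
                             batch.qual_strings(), batch.seq_strings(2),
                             batch.qual_strings())
            truth_path = out(f"{s.id}_truth.vcf")
            write_truth_vcf(truth_path, region_contig, design.region_length,
                            [s.id], cell_truth_records(cell, sites, region))
            manifest_samples[s.id] = {
                "unit": unit.id, "type": "single_cell",
                "prototype": k, "n_pairs": n_pairs, "n_reads": 2 * n_pairs,
                "ado_events": len(cell.ado_events),
                "fp_events": len(cell.fp_events),
                "fastq": [r1, r2], "truth_vcf": truth_path,
            }
            log.info("single cell %s: prototype %d, %d pairs, %d ADO, %d FP",
                     s.id, k, n_pairs, len(cell.ado_events), len(cell.fp_events))

        stage = "bulk pools"
        demand = _bulk_demand(design, hierarchy)
        pools = []
        for k in range(design.K):
            # sized to the exact demand: allocations are deterministic given G_ij
            n_pool = int(demand[k])
            batch = simulate_read_pairs(
                proto_haps[k][0], proto_haps[k][1], design.reads, n_pool,
                rng_for(master, "pool", k), name_prefix=f"pool:p{k}")
            pools.append(ReadPool(prototype=k, batch=batch))
            log.info("pool p%d: %d pairs", k, n_pool)

        stage = "bulk samples"
        for unit, s in design.samples:
            if s.type is not SampleType.BULK:
                continue
            g = hierarchy.g_sample[(unit.id, s.id)]
            pairs = s.n_bulk_reads // 2
            r1, r2 = out(f"{s.id}_R1.fastq.gz"), out(f"{s.id}_R2.fastq.gz")
            composition = compose_bulk_sample(
                pools, g, pairs, rng_for(master, "bulk", unit.id, s.id), r1, r2)
            comp_path = out(f"{s.id}_composition.tsv")
            with open(comp_path, "w") as fh:
                fh.write("prototype\tpairs\treads\n")
                for k, c in sorted(composition.items()):
                    fh.write(f"p{k}\t{c}\t{2 * c}\n")
            manifest_samples[s.id] = {
                "unit": unit.id, "type": "bulk",
                "n_pairs": pairs, "n_reads": 2 * pairs,
                "composition_pairs": {f"p{k}": int(c)
                                      for k, c in sorted(composition.items())},
                "fastq": [r1, r2], "truth_vcf": None,
                "composition_tsv": comp_path,
            }
            log.info("bulk %s: %d pairs, composition %s", s.id, pairs, composition)

        stage = "truth output"
        proto_vcf = out("prototypes_truth.vcf")
        write_truth_vcf(proto_vcf, region_contig, design.region_length,
                        [f"p{k}" for k in range(design.K)],
                        prototype_truth_records(sites))
        proto_tsv = out("prototypes_truth.tsv")
        write_truth_tsv(proto_tsv, sites, design.K)

        stage = "manifest"
        manifest = {
            "scsim_version": __version__,
            "master_seed": master,
            "design": serialize_design(design),
            "region": {"contig": region_contig, "start": design.region_start,
                       "length": design.region_length},
            "child_seeds": {
                "sites": child_seed(master, "sites"),
                "substitutions": child_seed(master, "substitutions"),
                "genomes": child_seed(master, "genomes"),
                **hierarchy_child_seeds(design, master),
            },
            "hierarchy": hierarchy.to_jsonable(),
            "samples": manifest_samples,
            "prototype_truth": {"vcf": proto_vcf, "tsv": proto_tsv},
        }
        manifest_path = out("manifest.json")
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2)
        return manifest
    except ScsimError:
        for p in created:
            p.unlink(missing_ok=True)
        log.error("simulation aborted during stage %r; partial outputs removed", stage)
        raise
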