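"""Standard-format I/O: FASTA in; FASTQ, VCF 4.2 and TSV truth tables out.

Coordinates are 0-based half-open everywhere inside the package; the single
place 1-based coordinates appear is the POS column written to (and read
from) VCF.
"""

from __future__ import annotations

import gzip
import io
import logging
import os
from dataclasses import dataclass, field

import pysam

from .errors import FormatError, ScsimError

log = logging.getLogger(__name__)

__all__ = [
    "read_reference",
    "write_fasta",
    "write_fastq_pair",
    "read_fastq_names",
    "count_fastq_records",
    "TruthRecord",
    "write_truth_vcf",
    "read_truth_vcf",
    "write_truth_tsv",
]

_IUPAC = set("ACGTNRYSWKMBDHV")
_AMBIGUOUS = set("RYSWKMBDHV")


def read_reference(fasta_path: str | os.PathLike) -> tuple[str, str]:
    """Read the first record of a FASTA file.

    Returns ``(contig_name, sequence)`` with the sequence uppercased and
    restricted to the alphabet {A,C,G,T,N}: IUPAC ambiguity codes are
    converted to N with a warning, anything else raises
    :class:`FormatError`.  If the file holds more than one record, the
    first is used and a warning is logged.
    """
    records = []
    with pysam.FastxFile(str(fasta_path)) as fh:
        for i, rec in enumerate(fh):
            if i == 0:
                records.append((rec.name, rec.sequence))
            else:
                log.warning(
                    "reference %s has multiple records; using first (%s)",
                    fasta_path, records[0][0],
                )
                break
    if not records:
        raise FormatError(f"no FASTA records found in {fasta_path}")
    name, seq = records[0]
    seq = seq.upper()
    bad = set(seq) - _IUPAC
    if bad:
        raise FormatError(
            f"reference {fasta_path} contains non-IUPAC characters: {sorted(bad)}"
        )
    if set(seq) & _AMBIGUOUS:
        log.warning("reference contains IUPAC ambiguity codes; converting to N")
        seq = "".join(c if c in "ACGTN" else "N" for c in seq)
    return name, seq


def write_fasta(path: str | os.PathLike, name: str, sequence: str,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(sequence), width):
            fh.write(sequence[i:i + width] + "\n")


def _open_fastq_out(path: str) -> io.BufferedWriter:
    raw = open(path, "wb")
    if str(path).endswith(".gz"):
        # mtime pinned to 0 so identical seeds give byte-identical files
        return gzip.GzipFile(filename="", mode="wb", fileobj=raw,
                             mtime=0, compresslevel=1)  # type: ignore[return-value]
    return raw


def write_fastq_pair(path_r1: str, path_r2: str, names, seqs1, quals1,
                     seqs2, quals2) -> int:
    """Write a paired FASTQ file pair (gzipped when paths end in .gz).

    ``names`` are the pair names without the /1 and /2 mate suffixes.
    Returns the number of pairs written.
    """
    n = 0
    with _open_fastq_out(path_r1) as f1, _open_fastq_out(path_r2) as f2:
        for name, s1, q1, s2, q2 in zip(names, seqs1, quals1, seqs2, quals2):
            if len(s1) != len(q1) or len(s2) != len(q2):
                raise ScsimError("sequence/quality length mismatch")
            f1.write(f"@{name}/1\n{s1}\n+\n{q1}\n".encode())
            f2.write(f"@{name}/2\n{s2}\n+\n{q2}\n".encode())
            n += 1
    return n


def read_fastq_names(path: str) -> list[str]:
    """Read names (mate suffix stripped) from a FASTQ file."""
    names = []
    with pysam.FastxFile(path) as fh:
        for rec in fh:
            name = rec.name
            names.append(name[:-2] if name.endswith(("/1", "/2")) else name)
    return names


def count_fastq_records(path: str) -> int:
    with pysam.FastxFile(path) as fh:
        return sum(1 for _ in fh)


@dataclass(frozen=True)
class TruthRecord:
    """One truth variant row (0-based position; VCF output is 1-based)."""

    position: int                 # 0-based within the emitted contig
    ref: str
    alt: str
    genotypes: tuple[str, ...]    # e.g. ("0/1", "0/0", "1/1"), one per column
    wga_fp: bool = False          # site introduced by the WGA FP process
    ado: tuple[int, ...] = ()     # per-column ADO flag (1 = genotype altered)
    info: dict = field(default_factory=dict)


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=scsim
##contig=<ID={contig},length={length}>
##INFO=<ID=WGAFP,Number=0,Type=Flag,Description="Spurious heterozygous site introduced by whole-genome amplification">
##INFO=<ID=TIER,Number=1,Type=String,Description="Sharing tier of the SNV (all/half/uniform)">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=ADO,Number=1,Type=Integer,Description="1 if allelic dropout altered this genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""


def write_truth_vcf(path: str | os.PathLike, contig: str, contig_length: int,
                    sample_names: list[str], records: list[TruthRecord]) -> None:
    """Emit a truth call set as VCF 4.2.

    Records must be strictly sorted by position (an :class:`ScsimError` is
    raised otherwise — truth emission is expected to sort upstream).  The
    FORMAT column carries GT always and ADO when any record has ADO flags.
    """
    positions = [r.position for r in records]
    if any(b <= a for a, b in zip(positions, positions[1:])):
        raise ScsimError("truth records must be sorted by strictly increasing position")
    with_ado = any(r.ado for r in records)
    fmt = "GT:ADO" if with_ado else "GT"
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(contig=contig, length=contig_length,
                                    samples="\t".join(sample_names)))
        for r in records:
            if len(r.genotypes) != len(sample_names):
                raise ScsimError("genotype column count mismatch")
            info_items = []
            if r.wga_fp:
                info_items.append("WGAFP")
            for k, v in r.info.items():
                info_items.append(f"{k}={v}")
            info = ";".join(info_items) if info_items else "."
            if with_ado:
                ado = r.ado if r.ado else (0,) * len(sample_names)
                cols = [f"{gt}:{a}" for gt, a in zip(r.genotypes, ado)]
            else:
                cols = list(r.genotypes)
            fh.write(
                f"{contig}\t{r.position + 1}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t"
                f"{info}\t{fmt}\t" + "\t".join(cols) + "\n"
            )


def read_truth_vcf(path: str | os.PathLike) -> list[TruthRecord]:
    """Read a truth VCF back into :class:`TruthRecord` objects (0-based)."""
    out = []
    with pysam.VariantFile(str(path)) as vf:
        sample_names = list(vf.header.samples)
        for rec in vf:
            gts = []
            ados = []
            for s in sample_names:
                sm = rec.samples[s]
                gt = sm.get("GT")
                gts.append("/".join("." if a is None else str(a) for a in gt))
                a = sm.get("ADO")
                ados.append(int(a) if a is not None else 0)
            info = {k: v for k, v in rec.info.items() if k not in ("WGAFP",)}
            out.append(TruthRecord(
                position=rec.pos - 1,
                ref=rec.ref,
                alt=rec.alts[0] if rec.alts else ".",
                genotypes=tuple(gts),
                wga_fp=bool(rec.info.get("WGAFP", False)),
                ado=tuple(ados) if any(ados) else (),
                info=info,
            ))
    return out


def write_truth_tsv(path: str | os.PathLike, sites, K: int) -> None:
    """Flat TSV truth table: position, tier, ref, alt, per-prototype zygosity."""
    zyg_name = {0: "absent", 1: "het", 2: "hom"}
    with open(path, "w") as fh:
        cols = ["position", "tier", "ref", "alt"] + [f"proto{k}" for k in range(K)]
        fh.write("\t".join(cols) + "\n")
        for s in sites:
            row = [str(s.position), s.tier, s.ref_base, s.alt_base]
            row += [zyg_name[int(z)] for z in s.zygosity]
            fh.write("\t".join(row) + "\n")
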