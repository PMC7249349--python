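"""Truth-aware scoring of variant call sets.

Compares a caller's SNV calls against the simulator's truth set at the
site level (match on 1-based position + alt allele, genotype ignored) and
reports recall, precision, F1 and the transition/transversion ratio.
Standard hard post-filters can be applied first: minimum read mapping
quality (> 1), minimum base quality (> 30), minimum number of
alt-supporting reads (> 5), and a strand-bias filter (by default a call
fails when it has at least ``strand_min`` alt reads all on one strand; a
Fisher exact test on the ref/alt strand table is selectable instead).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pysam
from scipy import stats

from .errors import FormatError, RangeError

log = logging.getLogger(__name__)

__all__ = [
    "CallRecord",
    "FilterThresholds",
    "ScoreReport",
    "score_calls",
    "apply_post_filters",
    "titv_ratio",
    "load_calls_vcf",
    "load_truth_sites",
]

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass(frozen=True)
class CallRecord:
    """One SNV call with the annotations the post-filters consume."""

    position: int                 # 1-based
    ref: str
    alt: str
    mq: float | None = None       # mapping quality of supporting reads
    bq: float | None = None       # base-quality summary at the site
    alt_reads: int | None = None  # alt-supporting read count
    alt_fwd: int | None = None    # alt reads on the forward strand
    alt_rev: int | None = None
    ref_fwd: int | None = None
    ref_rev: int | None = None

    def __post_init__(self):
        if self.position < 1:
            raise RangeError("CallRecord position is 1-based and must be >= 1")
        if self.alt == self.ref:
            raise RangeError("alt allele must differ from ref")


@dataclass(frozen=True)
class FilterThresholds:
    """Hard post-filter thresholds (all comparisons are strict)."""

    min_mq: float = 1.0
    min_bq: float = 30.0
    min_alt_reads: int = 5
    strand_min: int = 4            # one-sided rule arms at this many alt reads
    strand_mode: str = "one_sided"  # or "fisher"
    fisher_p: float = 0.001


@dataclass(frozen=True)
class ScoreReport:
    n_truth: int
    n_called: int
    tp: int
    fp: int
    fn: int
    recall: float
    precision: float
    f1: float
    titv: float | None = None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("n_truth", "n_called", "tp", "fp", "fn",
                 "recall", "precision", "f1", "titv")}


def _f1(precision: float, recall: float) -> float:
    return 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)


def score_calls(called, truth) -> ScoreReport:
    """Site-level scoring of a call set against a truth set.

    ``called`` is an iterable of :class:`CallRecord` (or (position, alt)
    pairs); ``truth`` an iterable of (position, alt) pairs, both 1-based.
    Duplicate sites are collapsed.  An empty call set scores precision 0
    with a warning rather than dividing by zero.
    """
    def as_key(x):
        if isinstance(x, CallRecord):
            return (x.position, x.alt)
        return (int(x[0]), str(x[1]))

    call_keys = {as_key(c) for c in called}
    truth_keys = {as_key(t) for t in truth}

    if truth_keys and call_keys:
        call_pos = {p for p, _ in call_keys}
        truth_pos = {p for p, _ in truth_keys}
        if not call_pos & truth_pos and {p - 1 for p in call_pos} & truth_pos:
            log.warning(
                "no call position matches truth but all would match shifted by "
                "one; possible 0-based/1-based coordinate mismatch (not corrected)"
            )

    tp = len(call_keys & truth_keys)
    fp = len(call_keys - truth_keys)
    fn = len(truth_keys - call_keys)
    if not call_keys:
        log.warning("empty call set: precision reported as 0")
    recall = tp / len(truth_keys) if truth_keys else 0.0
    precision = tp / len(call_keys) if call_keys else 0.0
    return ScoreReport(
        n_truth=len(truth_keys), n_called=len(call_keys),
        tp=tp, fp=fp, fn=fn,
        recall=recall, precision=precision, f1=_f1(precision, recall),
    )


def _strand_biased(c: CallRecord, t: FilterThresholds) -> bool | None:
    if t.strand_mode == "fisher":
        if None in (c.ref_fwd, c.ref_rev, c.alt_fwd, c.alt_rev):
            return None
        _, p = stats.fisher_exact([[c.ref_fwd, c.ref_rev], [c.alt_fwd, c.alt_rev]])
        return p < t.fisher_p
    if c.alt_fwd is None or c.alt_rev is None:
        return None
    n_alt = c.alt_fwd + c.alt_rev
    return n_alt >= t.strand_min and (c.alt_fwd == 0 or c.alt_rev == 0)


def apply_post_filters(calls, thresholds: FilterThresholds | None = None
                       ) -> tuple[list[CallRecord], int]:
    """Apply the hard post-filters; a call survives iff every filter passes.

    A filter whose annotation is missing on a record is skipped for that
    record (counted; the count of such skips is returned alongside the
    surviving calls).
    """
    t = thresholds or FilterThresholds()
    kept: list[CallRecord] = []
    n_skipped = 0
    for c in calls:
        ok = True
        for value, cut in ((c.mq, t.min_mq), (c.bq, t.min_bq),
                           (c.alt_reads, t.min_alt_reads)):
            if value is None:
                n_skipped += 1
            elif not value > cut:
                ok = False
                break
        if ok:
            biased = _strand_biased(c, t)
            if biased is None:
                n_skipped += 1
            elif biased:
                ok = False
        if ok:
            kept.append(c)
    if n_skipped:
        log.warning("%d filter evaluations skipped for missing annotations", n_skipped)
    return kept, n_skipped


def titv_ratio(snvs) -> float:
    """Transition/transversion ratio over (ref, alt) pairs.

    Transitions are A<->G and C<->T.  Returns ``math.inf`` when there are
    transitions but no transversions; raises on empty input.
    """
    ti = tv = 0
    for item in snvs:
        ref, alt = (item.ref, item.alt) if isinstance(item, CallRecord) else item
        if ref == alt:
            raise RangeError(f"not an SNV: ref == alt == {ref}")
        if (ref, alt) in _TRANSITIONS:
            ti += 1
        else:
            tv += 1
    if ti + tv == 0:
        raise RangeError("Ti/Tv undefined on an empty SNV set")
    return math.inf if tv == 0 else ti / tv


def load_calls_vcf(path: str) -> list[CallRecord]:
    """Load SNV calls from a VCF, extracting filter annotations best-effort.

    Mapping quality from INFO/MQ; base quality from INFO/BQ or the record
    QUAL; strand counts from INFO/DP4 (ref-fwd, ref-rev, alt-fwd, alt-rev,
    the bcftools convention) or FORMAT ADF/ADR summed over samples.
    Multi-allelic records contribute one call per alt; non-SNV alleles
    are skipped.
    """
    out: list[CallRecord] = []
    with pysam.VariantFile(path) as vf:
        declared = set(vf.header.info)
        for rec in vf:
            if rec.ref is None or len(rec.ref) != 1:
                continue
            info = rec.info
            mq = info.get("MQ") if "MQ" in declared else None
            bq = (info.get("BQ") if "BQ" in declared else None) or rec.qual
            dp4 = info.get("DP4") if "DP4" in declared else None
            ref_fwd = ref_rev = alt_fwd = alt_rev = alt_reads = None
            if dp4 is not None and len(dp4) == 4:
                ref_fwd, ref_rev, alt_fwd, alt_rev = (int(x) for x in dp4)
                alt_reads = alt_fwd + alt_rev
            for alt in rec.alts or ():
                if len(alt) != 1 or alt == rec.ref or alt not in "ACGT":
                    continue
                out.append(CallRecord(
                    position=rec.pos, ref=rec.ref, alt=alt,
                    mq=float(mq) if mq is not None else None,
                    bq=float(bq) if bq is not None else None,
                    alt_reads=alt_reads, alt_fwd=alt_fwd, alt_rev=alt_rev,
                    ref_fwd=ref_fwd, ref_rev=ref_rev,
                ))
    return out


def load_truth_sites(path: str, include_wga_fp: bool = True) -> set[tuple[int, str]]:
    """Truth (position, alt) pairs (1-based) from a simulator truth VCF."""
    sites: set[tuple[int, str]] = set()
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            if not include_wga_fp and rec.info.get("WGAFP", False):
                continue
            for alt in rec.alts or ():
                sites.add((rec.pos, alt))
    if not sites:
        log.warning("truth file %s contains no sites", path)
    return sites


def evaluate_files(calls_path: str, truth_paths: list[str],
                   thresholds: FilterThresholds | None = None,
                   filtered: bool = False) -> ScoreReport:
    """Score a call VCF against one or more truth VCFs (sites pooled)."""
    calls = load_calls_vcf(calls_path)
    truth: set[tuple[int, str]] = set()
    for p in truth_paths:
        truth |= load_truth_sites(p)
    if not truth:
        raise FormatError("no truth sites loaded")
    if filtered:
        calls, _ = apply_post_filters(calls, thresholds)
    report = score_calls(calls, truth)
    try:
        titv = titv_ratio(calls)
    except RangeError:
        titv = None
    return ScoreReport(**{**report.to_dict(), "titv": titv})
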