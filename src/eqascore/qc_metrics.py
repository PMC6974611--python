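"""Per-submission quality metrics and cohort benchmarking.

FASTQ-level: mean base quality, fraction of bases >= Q20 / Q30.
Alignment-level (from a SAM-like tab-delimited summary — binary BAM
decoding is an adapter concern): on/off-target fractions, error rate on
target, coverage at configurable depth thresholds, insert-size statistics,
depth uniformity. VCF-level: Ti/Tv, SNP/indel counts, Het:Hom ratios, mean
call quality. Undefined ratios (zero denominator) are reported as ``None``,
never as exceptions.
"""

from __future__ import annotations

import gzip
import re
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import rankdata

from .regions import RegionSet
from .variant_model import (
    CLASS_SNP,
    HET_CLASSES,
    HOM_CLASSES,
    NormalizedVariant,
)

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

FLAG_PAIRED = 0x1
FLAG_PROPER_PAIR = 0x2
FLAG_UNMAPPED = 0x4


@dataclass
class FastqMetrics:
    mean_base_quality: Optional[float]
    frac_q20: Optional[float]
    frac_q30: Optional[float]
    n_reads: int = 0
    n_bases: int = 0
    warnings: List[str] = field(default_factory=list)


@dataclass
class AlignmentMetrics:
    frac_on_target: Optional[float]
    frac_off_target: Optional[float]
    error_rate_on_target: Optional[float]
    coverage_ge: Dict[int, float]
    insert_mean: Optional[float]
    insert_sd: Optional[float]
    uniformity: Optional[float]
    n_reads: int = 0
    n_mapped: int = 0


@dataclass
class VcfMetrics:
    titv: Optional[float]
    snp_count: int
    indel_count: int
    het_hom_snp: Optional[float]
    het_hom_indel: Optional[float]
    mean_call_quality: Optional[float]
    call_quality_quartiles: Optional[Tuple[float, float, float]] = None


@dataclass
class QCReport:
    fastq: Optional[FastqMetrics] = None
    alignment: Optional[AlignmentMetrics] = None
    vcf: Optional[VcfMetrics] = None


def _open_maybe_gz(path: str | Path):
    p = str(path)
    if p.endswith(".gz"):
        return gzip.open(p, "rt")
    return open(p)


def iter_fastq(path: str | Path) -> Iterator[Tuple[str, str, str]]:
    """Yield (name, sequence, quality) from a FASTQ file (plain or gzip)."""
    with _open_maybe_gz(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            fh.readline()  # '+'
            qual = fh.readline().rstrip("\n")
            yield header.rstrip("\n").lstrip("@"), seq, qual


def fastq_metrics(
    reads: Iterable[Tuple[str, str, str]] | str | Path,
    phred64_probe_reads: int = 10_000,
) -> FastqMetrics:
    """Mean Phred base quality and fractions of bases >= Q20 / Q30.

    Phred+33 is assumed; if no quality byte below 59 is seen in the first
    ``phred64_probe_reads`` reads a Phred+64 warning is attached (no
    auto-conversion).
    """
    if isinstance(reads, (str, Path)):
        reads = iter_fastq(reads)
    total = 0
    qsum = 0
    q20 = q30 = 0
    n_reads = 0
    min_byte = 255
    warnings: List[str] = []
    for name, seq, qual in reads:
        if len(seq) != len(qual):
            warnings.append(f"read {name!r}: sequence/quality length mismatch")
            continue
        n_reads += 1
        for ch in qual.encode("ascii", errors="replace"):
            q = ch - 33
            qsum += q
            total += 1
            if q >= 20:
                q20 += 1
            if q >= 30:
                q30 += 1
            if n_reads <= phred64_probe_reads and ch < min_byte:
                min_byte = ch
    if n_reads and min_byte >= 59:
        warnings.append(
            "no quality byte below 59 observed; input may be Phred+64 encoded"
        )
    if total == 0:
        return FastqMetrics(None, None, None, n_reads, 0, warnings)
    return FastqMetrics(qsum / total, q20 / total, q30 / total,
                        n_reads, total, warnings)


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


@dataclass(frozen=True)
class AlignedRead:
    """One record of the SAM-like alignment summary."""

    chrom: str
    pos: int  # 1-based leftmost mapped base
    mapq: int
    cigar: str
    tlen: int
    nm: int  # edit-distance / mismatch count
    flags: int

    @property
    def mapped(self) -> bool:
        return not self.flags & FLAG_UNMAPPED

    def ref_blocks(self) -> List[Tuple[int, int]]:
        """0-based half-open reference spans consumed by this alignment."""
        blocks = []
        cur = self.pos - 1
        for n_s, op in _CIGAR_RE.findall(self.cigar):
            n = int(n_s)
            if op in "M=X":
                blocks.append((cur, cur + n))
                cur += n
            elif op in "DN":
                cur += n
        return blocks

    @property
    def aligned_bases(self) -> int:
        return sum(e - s for s, e in self.ref_blocks())


def read_alignment_summary(path: str | Path) -> List[AlignedRead]:
    """Parse the tab-delimited summary: chrom pos mapq cigar tlen NM flags."""
    reads = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            c = line.rstrip("\n").split("\t")
            reads.append(AlignedRead(c[0], int(c[1]), int(c[2]), c[3],
                                     int(c[4]), int(c[5]), int(c[6])))
    return reads


def _roi_depth(reads: Sequence[AlignedRead], roi: RegionSet) -> Dict[Tuple[str, int, int], np.ndarray]:
    depth = {
        (chrom, s, e): np.zeros(e - s, dtype=np.int64) for chrom, s, e in roi
    }
    by_chrom: Dict[str, List[Tuple[int, int, np.ndarray]]] = {}
    for (chrom, s, e), arr in depth.items():
        by_chrom.setdefault(chrom, []).append((s, e, arr))
    for read in reads:
        if not read.mapped:
            continue
        ivs = by_chrom.get(read.chrom)
        if not ivs:
            continue
        for bs, be in read.ref_blocks():
            for s, e, arr in ivs:
                lo, hi = max(bs, s), min(be, e)
                if lo < hi:
                    arr[lo - s : hi - s] += 1
    return depth


def alignment_metrics(
    reads: Sequence[AlignedRead] | str | Path,
    roi: RegionSet,
    thresholds: Sequence[int] = (20, 30, 500),
) -> AlignmentMetrics:
    """Coverage, on/off-target and insert-size metrics over the declared ROI.

    On-target = the read's reference span overlaps the ROI. Error rate on
    target uses the supplied per-read mismatch counts (NM) over aligned
    bases of on-target reads. Uniformity = fraction of ROI bases with depth
    within a factor of two of the median ROI depth. Insert statistics use
    proper pairs with positive template length only (one entry per pair).
    """
    if isinstance(reads, (str, Path)):
        reads = read_alignment_summary(reads)
    mapped = [r for r in reads if r.mapped]
    on_target = [
        r for r in mapped
        if any(roi.overlaps_interval(r.chrom, s, e) for s, e in r.ref_blocks())
    ]
    frac_on = len(on_target) / len(mapped) if mapped else None
    frac_off = 1 - frac_on if frac_on is not None else None

    aligned = sum(r.aligned_bases for r in on_target)
    err = sum(r.nm for r in on_target) / aligned if aligned else None

    depth = _roi_depth(mapped, roi)
    all_depth = (
        np.concatenate(list(depth.values())) if depth else np.array([], dtype=np.int64)
    )
    coverage_ge: Dict[int, float] = {}
    uniformity = None
    if all_depth.size:
        for t in thresholds:
            coverage_ge[int(t)] = float((all_depth >= t).mean())
        med = float(np.median(all_depth))
        uniformity = float(
            ((all_depth >= med / 2) & (all_depth <= 2 * med)).mean()
        )
    else:
        coverage_ge = {int(t): 0.0 for t in thresholds}

    inserts = [
        r.tlen for r in mapped
        if r.flags & FLAG_PAIRED and r.flags & FLAG_PROPER_PAIR and r.tlen > 0
    ]
    imean = statistics.fmean(inserts) if inserts else None
    isd = statistics.stdev(inserts) if len(inserts) > 1 else None
    return AlignmentMetrics(
        frac_on_target=frac_on,
        frac_off_target=frac_off,
        error_rate_on_target=err,
        coverage_ge=coverage_ge,
        insert_mean=imean,
        insert_sd=isd,
        uniformity=uniformity,
        n_reads=len(reads),
        n_mapped=len(mapped),
    )


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den else None


def vcf_metrics(variants: Sequence[NormalizedVariant]) -> VcfMetrics:
    """Ti/Tv, SNP/indel counts, Het:Hom ratios and call-quality summary."""
    snps = [v for v in variants if v.var_class == CLASS_SNP]
    indels = [v for v in variants if v.var_class in ("insertion", "deletion")]
    ti = sum(1 for v in snps if (v.ref.upper(), v.alt.upper()) in TRANSITIONS)
    tv = len(snps) - ti

    def het_hom(vs):
        het = sum(1 for v in vs if v.genotype in HET_CLASSES)
        hom = sum(1 for v in vs if v.genotype in HOM_CLASSES)
        return _ratio(het, hom)

    quals = [v.qual for v in variants if v.qual is not None]
    quartiles = None
    mean_q = None
    if quals:
        mean_q = statistics.fmean(quals)
        q = np.percentile(quals, [25, 50, 75])
        quartiles = (float(q[0]), float(q[1]), float(q[2]))
    return VcfMetrics(
        titv=_ratio(ti, tv),
        snp_count=len(snps),
        indel_count=len(indels),
        het_hom_snp=het_hom(snps),
        het_hom_indel=het_hom(indels),
        mean_call_quality=mean_q,
        call_quality_quartiles=quartiles,
    )


@dataclass
class CohortSummary:
    n: int
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float


def cohort_benchmark(
    values: Dict[str, float],
    strata: Optional[Dict[str, str]] = None,
) -> Tuple[Dict[str, float], CohortSummary, Dict[str, CohortSummary]]:
    """Rank each lab's metric within the cohort (and within its stratum).

    Percentile uses mean ranks for ties: ``100 * (rank - 0.5) / n``, so a
    singleton cohort and an all-tied cohort both sit at 50.
    """
    if not values:
        raise ValueError("need at least one submission")
    labs = sorted(values)
    arr = np.array([values[k] for k in labs], dtype=float)
    ranks = rankdata(arr, method="average")
    pct = {lab: float(100 * (r - 0.5) / len(labs)) for lab, r in zip(labs, ranks)}

    def summarize(a: np.ndarray) -> CohortSummary:
        q = np.percentile(a, [25, 50, 75])
        return CohortSummary(len(a), float(a.min()), float(q[0]), float(q[1]),
                             float(q[2]), float(a.max()))

    by_stratum: Dict[str, CohortSummary] = {}
    if strata:
        groups: Dict[str, List[float]] = {}
        for lab in labs:
            groups.setdefault(strata.get(lab, "unreported"), []).append(values[lab])
        by_stratum = {k: summarize(np.array(v)) for k, v in sorted(groups.items())}
    return pct, summarize(arr), by_stratum
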