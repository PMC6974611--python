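"""Reading, validation and writing of the formats the EQA workflow touches.

VCF 4.1/4.2 and BED are parsed with a deliberately tolerant line-level
parser: the submission-validation contract requires per-line diagnostics on
arbitrary (possibly broken) input, which index-based library readers do not
provide. BED is 0-based half-open; VCF POS is 1-based; everything internal
is 0-based half-open and converted at this boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from .regions import RegionSet
from .variant_model import (
    ALLELE_RE,
    ContextProvider,
    NormalizedVariant,
    RawCall,
    canonical_chrom,
    normalize_record,
)

SUPPORTED_VCF_VERSIONS = ("VCFv4.1", "VCFv4.2")

SCHEME_GERMLINE = "germline"
SCHEME_SOMATIC = "somatic"

VCF_COLUMNS = ("#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO")


@dataclass(frozen=True)
class Diagnostic:
    severity: str  # "error" | "warning"
    message: str
    line: Optional[int] = None

    def __str__(self) -> str:
        loc = f" (line {self.line})" if self.line is not None else ""
        return f"{self.severity}: {self.message}{loc}"


def _errors(diags: Sequence[Diagnostic]) -> List[Diagnostic]:
    return [d for d in diags if d.severity == "error"]


@dataclass
class Submission:
    """One laboratory's dataset: identity, scheme, variants and declared ROI."""

    participant_id: str
    scheme: str
    reference_build: str
    variants: List[NormalizedVariant]
    roi: RegionSet
    metadata: Dict[str, str] = field(default_factory=dict)
    dropped_records: int = 0
    rejected: List[str] = field(default_factory=list)


def validate_vcf(path: str | Path) -> List[Diagnostic]:
    """Validate a VCF file, returning diagnostics instead of raising.

    Checks: readable file, ``##fileformat`` declaring 4.1 or 4.2, header
    line shape, column counts, numeric POS, allele alphabet, sort order
    (warning) and duplicate records (warning). Empty list ⟺ acceptable.
    """
    diags: List[Diagnostic] = []
    try:
        with open(path, "rb") as fh:
            raw = fh.read()
    except OSError as exc:
        return [Diagnostic("error", f"unreadable file: {exc}")]
    text = raw.decode("utf-8", errors="replace")
    lines = text.splitlines()
    if not lines:
        return [Diagnostic("error", "empty file")]

    first = lines[0]
    m = re.match(r"^##fileformat=(\S+)\s*$", first)
    if not m:
        diags.append(Diagnostic("error", "missing ##fileformat line", 1))
    elif m.group(1) not in SUPPORTED_VCF_VERSIONS:
        diags.append(
            Diagnostic("error", f"unsupported VCF version {m.group(1)!r} "
                                "(must be 4.1 or 4.2)", 1)
        )

    header_seen = False
    n_fixed = 8
    prev: Optional[Tuple[str, int]] = None
    seen_records = set()
    order_warned = False
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if line.startswith("##"):
            if header_seen:
                diags.append(Diagnostic("error", "meta line after records", lineno))
            continue
        if line.startswith("#"):
            if header_seen:
                diags.append(Diagnostic("error", "duplicate header line", lineno))
                continue
            header_seen = True
            cols = line.split("\t")
            if tuple(cols[:8]) != VCF_COLUMNS:
                diags.append(Diagnostic("error", "malformed header line", lineno))
            elif len(cols) > 8 and cols[8] != "FORMAT":
                diags.append(Diagnostic("error", "9th header column must be FORMAT", lineno))
            n_fixed = len(cols)
            continue
        # data line
        if not header_seen:
            diags.append(Diagnostic("error", "data line before #CHROM header", lineno))
            header_seen = True  # report once
        cols = line.split("\t")
        if len(cols) < 8:
            diags.append(Diagnostic("error", f"expected >=8 columns, got {len(cols)}", lineno))
            continue
        chrom, pos_s, _id, ref, alt = cols[0], cols[1], cols[2], cols[3], cols[4]
        if not pos_s.isdigit():
            diags.append(Diagnostic("error", f"non-numeric POS {pos_s!r}", lineno))
            continue
        if not ALLELE_RE.match(ref):
            diags.append(Diagnostic("error", f"invalid REF allele {ref!r}", lineno))
        for a in alt.split(","):
            if not ALLELE_RE.match(a) and not re.match(r"^<[^<>]+>$|^\*$|\[|\]", a):
                diags.append(Diagnostic("error", f"invalid ALT allele {a!r}", lineno))
        pos = int(pos_s)
        key = (chrom, pos, ref, alt)
        if key in seen_records:
            diags.append(Diagnostic("warning", f"duplicate record {chrom}:{pos} {ref}>{alt}", lineno))
        seen_records.add(key)
        if prev is not None and prev[0] == chrom and pos < prev[1] and not order_warned:
            diags.append(Diagnostic("warning", "records not sorted by position", lineno))
            order_warned = True
        prev = (chrom, pos)
    if not header_seen:
        diags.append(Diagnostic("error", "missing #CHROM header line"))
    return diags


def validate_bed(path: str | Path) -> List[Diagnostic]:
    """Validate a BED file (3+ tab-separated columns, start < end)."""
    diags: List[Diagnostic] = []
    try:
        with open(path, "rb") as fh:
            text = fh.read().decode("utf-8", errors="replace")
    except OSError as exc:
        return [Diagnostic("error", f"unreadable file: {exc}")]
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split("\t")
        if len(cols) < 3:
            diags.append(Diagnostic("error", f"expected >=3 columns, got {len(cols)}", lineno))
            continue
        if not cols[1].lstrip("-").isdigit() or not cols[2].lstrip("-").isdigit():
            diags.append(Diagnostic("error", "non-numeric interval bounds", lineno))
            continue
        s, e = int(cols[1]), int(cols[2])
        if s < 0 or s >= e:
            diags.append(Diagnostic("error", f"invalid interval [{s}, {e})", lineno))
    return diags


def read_bed(path: str | Path, chrom_dialect: str = "bare") -> RegionSet:
    triples = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.rstrip("\n").split("\t")
            triples.append((canonical_chrom(cols[0], chrom_dialect),
                            int(cols[1]), int(cols[2])))
    return RegionSet(triples)


def write_bed(regions: RegionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e in regions:
            fh.write(f"{chrom}\t{s}\t{e}\n")


_GT_SPLIT = re.compile(r"[/|]")


def _parse_gt(fmt: str, sample: str) -> Optional[Tuple[Optional[int], ...]]:
    keys = fmt.split(":")
    vals = sample.split(":")
    if "GT" not in keys:
        return None
    gt = vals[keys.index("GT")] if keys.index("GT") < len(vals) else "."
    alleles = []
    for tok in _GT_SPLIT.split(gt):
        alleles.append(None if tok in (".", "") else int(tok))
    return tuple(alleles)


def _parse_af(info: str, fmt: Optional[str], sample: Optional[str]) -> Optional[float]:
    if fmt and sample:
        keys, vals = fmt.split(":"), sample.split(":")
        if "AF" in keys and keys.index("AF") < len(vals):
            try:
                return float(vals[keys.index("AF")].split(",")[0])
            except ValueError:
                pass
    for entry in info.split(";"):
        if entry.startswith("AF="):
            try:
                return float(entry[3:].split(",")[0])
            except ValueError:
                return None
    return None


def iter_vcf_records(path: str | Path, chrom_dialect: str = "bare"):
    """Yield :class:`RawCall` objects from an uncompressed VCF."""
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            chrom = canonical_chrom(cols[0], chrom_dialect)
            qual = None
            if cols[5] not in (".", ""):
                try:
                    qual = float(cols[5])
                except ValueError:
                    qual = None
            fmt = cols[8] if len(cols) > 9 else None
            sample = cols[9] if len(cols) > 9 else None
            gt = _parse_gt(fmt, sample) if fmt and sample else None
            yield RawCall(
                chrom=chrom,
                pos=int(cols[1]),
                ref=cols[3].upper(),
                alts=tuple(cols[4].split(",")),
                gt=gt,
                qual=qual,
                filter=cols[6],
                allele_fraction=_parse_af(cols[7], fmt, sample),
            )


class IngestError(RuntimeError):
    """Fatal ingest diagnostics."""

    def __init__(self, diagnostics: Sequence[Diagnostic]):
        self.diagnostics = list(diagnostics)
        super().__init__("; ".join(str(d) for d in self.diagnostics))


def read_submission(
    vcf_path: str | Path,
    bed_path: str | Path,
    scheme: str,
    build: str = "GRCh37",
    pass_only: bool = True,
    participant_id: Optional[str] = None,
    contexts: Optional[ContextProvider] = None,
    chrom_dialect: str = "bare",
    metadata: Optional[Dict[str, str]] = None,
) -> Submission:
    """Read, filter and normalize one lab's VCF+BED into a :class:`Submission`.

    With ``pass_only`` (the paper's rule), only FILTER values of ``PASS`` or
    ``.`` are kept. Records are normalized via :mod:`eqascore.variant_model`;
    ``contexts`` supplies per-chromosome reference context for left
    alignment (without it, indels stay as submitted). Identical normalized
    duplicates are dropped with a note.
    """
    vdiags = _errors(validate_vcf(vcf_path))
    bdiags = _errors(validate_bed(bed_path))
    if vdiags or bdiags:
        raise IngestError(vdiags + bdiags)
    roi = read_bed(bed_path, chrom_dialect)
    variants: List[NormalizedVariant] = []
    rejected: List[str] = []
    dropped = 0
    for rec in iter_vcf_records(vcf_path, chrom_dialect):
        if pass_only and rec.filter not in ("PASS", ".", None, ""):
            dropped += 1
            continue
        ctx = None
        if contexts is not None:
            try:
                ctx = contexts(rec.chrom)
            except KeyError:
                rejected.append(f"{rec.chrom}:{rec.pos} unknown chromosome")
                dropped += 1
                continue
        try:
            result = normalize_record(rec, ctx)
        except Exception as exc:  # noqa: BLE001 — normalization faults become rejects
            rejected.append(f"{rec.chrom}:{rec.pos} {exc}")
            dropped += 1
            continue
        rejected.extend(result.rejected)
        variants.extend(result.variants)
    seen = set()
    unique = []
    for v in sorted(variants):
        k = (v.chrom, v.pos, v.ref, v.alt, v.genotype)
        if k in seen:
            rejected.append(f"{v.chrom}:{v.pos} duplicate normalized record {v.ref}>{v.alt}")
            continue
        seen.add(k)
        unique.append(v)
    return Submission(
        participant_id=participant_id or Path(vcf_path).stem,
        scheme=scheme,
        reference_build=build,
        variants=unique,
        roi=roi,
        metadata=dict(metadata or {}),
        dropped_records=dropped,
        rejected=rejected,
    )


def restrict_roi(roi: RegionSet, targets: RegionSet, mode: str) -> RegionSet:
    """Narrow an ROI by an include (intersection) or exclude (subtraction) list."""
    if mode == "include":
        return roi.intersection(targets)
    if mode == "exclude":
        return roi.subtract(targets)
    raise ValueError(f"unknown ROI restriction mode {mode!r}")


def _gt_field(genotype: Optional[str]) -> str:
    return {
        "het": "0/1",
        "hom-alt": "1/1",
        "het-other": "1/2",
        "hemi": "1",
        None: "./.",
        "unknown": "./.",
    }.get(genotype, "./.")


def write_truth_vcf(truth, vcf_path: str | Path, bed_path: str | Path | None = None) -> None:
    """Write a truth set as VCF 4.2 plus a companion assessable-region BED.

    INFO carries per-variant support: ``NLABS`` (covering), ``NAGREE``
    (agreeing) and ``AGREEFRAC``.
    """
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=eqascore-{truth.provenance}\n")
        fh.write('##INFO=<ID=NLABS,Number=1,Type=Integer,Description="Covering laboratories">\n')
        fh.write('##INFO=<ID=NAGREE,Number=1,Type=Integer,Description="Agreeing laboratories">\n')
        fh.write('##INFO=<ID=AGREEFRAC,Number=1,Type=Float,Description="Agreement fraction">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTRUTH\n")
        for v in sorted(truth.variants):
            cov, agr = truth.support.get(v.call_key(True), (0, 0))
            info_parts = []
            if cov:
                info_parts = [f"NLABS={cov}", f"NAGREE={agr}",
                              f"AGREEFRAC={agr / cov:.6g}"]
            info = ";".join(info_parts) or "."
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\t"
                f"GT\t{_gt_field(v.genotype)}\n"
            )
    if bed_path is not None and truth.assessable is not None:
        write_bed(truth.assessable, bed_path)


def read_truth_vcf(
    vcf_path: str | Path,
    bed_path: str | Path | None = None,
    contexts: Optional[ContextProvider] = None,
    chrom_dialect: str = "bare",
):
    """Read a truth set written by :func:`write_truth_vcf` (or any plain VCF).

    Returns an :class:`eqascore.consensus_engine.TruthSet`; support counts
    are recovered from ``NLABS``/``NAGREE`` INFO fields when present.
    """
    from .consensus_engine import TruthSet  # deferred: avoids import cycle

    variants: List[NormalizedVariant] = []
    support = {}
    with open(vcf_path) as fh:
        info_by_key: Dict[tuple, Tuple[int, int]] = {}
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            info = dict(
                kv.split("=", 1) for kv in cols[7].split(";") if "=" in kv
            )
            if "NLABS" in info and "NAGREE" in info:
                info_by_key[(canonical_chrom(cols[0], chrom_dialect), int(cols[1]),
                             cols[3].upper(), cols[4].upper())] = (
                    int(info["NLABS"]), int(info["NAGREE"]))
    for rec in iter_vcf_records(vcf_path, chrom_dialect):
        ctx = contexts(rec.chrom) if contexts is not None else None
        result = normalize_record(rec, ctx)
        for v in result.variants:
            variants.append(v)
            raw_key = (rec.chrom, rec.pos, rec.ref, rec.alts[0].upper())
            if raw_key in info_by_key:
                support[v.call_key(True)] = info_by_key[raw_key]
    assessable = read_bed(bed_path, chrom_dialect) if bed_path else None
    return TruthSet(variants=sorted(variants), assessable=assessable,
                    provenance="eqa", support=support)


def write_submission_vcf(path: str | Path, rows: List[str], somatic: bool = False) -> None:
    """Write pre-formatted VCF data rows under a minimal valid 4.2 header."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=eqascore-simulator\n")
        if somatic:
            fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele fraction">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE\n")
        for row in rows:
            fh.write(row + "\n")


def write_fasta(seqs: Dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> Dict[str, str]:
    seqs: Dict[str, str] = {}
    name = None
    chunks: List[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs
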