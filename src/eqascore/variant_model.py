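"""Variant representation and normalization.

Pure functions over domain types: multi-allelic decomposition, MNP→SNP
splitting, minimal representation, and reference-guided left alignment.
No file I/O happens here; raw records arrive via :mod:`eqascore.formats_io`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Callable, List, Optional, Sequence, Tuple

ALLELE_RE = re.compile(r"^[ACGTNacgtn]+$")

# genotype classes (unordered allele multisets, phasing ignored)
GT_HET = "het"              # ref + alt
GT_HOM_ALT = "hom-alt"      # alt + alt
GT_HET_OTHER = "het-other"  # alt + a different non-ref allele
GT_HEMI = "hemi"            # single alt allele (haploid)
GT_UNKNOWN = "unknown"      # GT absent or uncalled
GT_ABSENT = "absent"        # genotype does not carry this alt at all

HET_CLASSES = frozenset({GT_HET, GT_HET_OTHER})
HOM_CLASSES = frozenset({GT_HOM_ALT})

CLASS_SNP = "snp"
CLASS_INS = "insertion"
CLASS_DEL = "deletion"
CLASS_COMPLEX = "complex"


class NormalizationError(ValueError):
    """A record cannot be normalized (symbolic allele, null variant, ...)."""


class InsufficientContextError(NormalizationError):
    """The reference window is too small to prove the leftmost placement."""


class ReferenceMismatchError(NormalizationError):
    """REF allele disagrees with the supplied reference sequence."""


def classify_alleles(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return CLASS_SNP
    if len(ref) < len(alt) and alt.startswith(ref):
        return CLASS_INS
    if len(alt) < len(ref) and ref.startswith(alt):
        return CLASS_DEL
    return CLASS_COMPLEX


@dataclass(frozen=True, order=True)
class NormalizedVariant:
    """A single-alt, minimally represented, left-aligned variant call.

    ``pos`` is the 1-based position of the first REF base. ``genotype`` is a
    genotype class string (see module constants), not a raw GT field.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    var_class: str = field(compare=False, default="")
    genotype: Optional[str] = field(compare=False, default=None)
    allele_fraction: Optional[float] = field(compare=False, default=None)
    qual: Optional[float] = field(compare=False, default=None)

    def __post_init__(self):
        if not self.ref or not self.alt:
            raise NormalizationError("empty allele")
        if not ALLELE_RE.match(self.ref) or not ALLELE_RE.match(self.alt):
            raise NormalizationError(f"non-sequence allele {self.ref}>{self.alt}")
        if not self.var_class:
            object.__setattr__(self, "var_class", classify_alleles(self.ref, self.alt))

    @property
    def start0(self) -> int:
        """0-based start of the REF span."""
        return self.pos - 1

    @property
    def end0(self) -> int:
        """0-based exclusive end of the REF span."""
        return self.pos - 1 + len(self.ref)

    @property
    def indel_len(self) -> int:
        return abs(len(self.ref) - len(self.alt))

    @property
    def has_n(self) -> bool:
        return "N" in self.ref.upper() or "N" in self.alt.upper()

    def site_key(self) -> Tuple[str, int, str]:
        return (self.chrom, self.pos, self.ref)

    def call_key(self, with_genotype: bool) -> Tuple:
        if with_genotype:
            return (self.chrom, self.pos, self.ref, self.alt, self.genotype)
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class ReferenceContext:
    """A window of reference sequence backing left alignment.

    ``window_start`` is the 1-based coordinate of ``sequence[0]``.
    """

    chrom: str
    window_start: int
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty reference context")

    @property
    def window_end(self) -> int:  # 1-based exclusive
        return self.window_start + len(self.sequence)

    def base(self, pos: int) -> str:
        """Reference base at 1-based ``pos``."""
        if not (self.window_start <= pos < self.window_end):
            raise InsufficientContextError(
                f"position {pos} outside context window "
                f"[{self.window_start}, {self.window_end})"
            )
        return self.sequence[pos - self.window_start].upper()

    def slice(self, pos: int, length: int) -> str:
        if pos < self.window_start or pos + length > self.window_end:
            raise InsufficientContextError(
                f"span {pos}+{length} outside context window"
            )
        off = pos - self.window_start
        return self.sequence[off : off + length].upper()

    @classmethod
    def from_sequence(cls, chrom: str, sequence: str) -> "ReferenceContext":
        """Whole-chromosome context (window starts at position 1)."""
        return cls(chrom, 1, sequence)


@dataclass(frozen=True)
class RawCall:
    """One parsed VCF data line, before normalization."""

    chrom: str
    pos: int
    ref: str
    alts: Tuple[str, ...]
    gt: Optional[Tuple[Optional[int], ...]] = None  # allele indices; None item = '.'
    qual: Optional[float] = None
    filter: Optional[str] = None
    allele_fraction: Optional[float] = None


def _is_symbolic(alt: str) -> bool:
    return not ALLELE_RE.match(alt)


def genotype_class_for_alt(
    gt: Optional[Sequence[Optional[int]]], alt_index: int
) -> str:
    """Recode a GT allele-index vector as a class for one ALT (1-based index)."""
    if gt is None:
        return GT_UNKNOWN
    known = [a for a in gt if a is not None]
    if not known:
        return GT_UNKNOWN
    count = sum(1 for a in known if a == alt_index)
    if count == 0:
        return GT_ABSENT
    if len(known) == 1:
        return GT_HEMI
    if count >= 2:
        return GT_HOM_ALT
    if any(a not in (0, alt_index) for a in known):
        return GT_HET_OTHER
    return GT_HET


def decompose_multiallelic(record: RawCall) -> List[RawCall]:
    """Split a raw record into one single-alt record per ALT allele.

    Genotypes are recoded per output via :func:`genotype_class_for_alt`
    downstream; here the GT vector is carried through unchanged together
    with the originating alt index (encoded by output order).
    """
    if not record.alts:
        raise NormalizationError("record has no ALT allele")
    for alt in record.alts:
        if _is_symbolic(alt):
            raise NormalizationError(f"non-sequence ALT {alt!r}")
    return [replace(record, alts=(alt,)) for alt in record.alts]


def split_mnp(v: NormalizedVariant) -> List[NormalizedVariant]:
    """Decompose a same-length substitution into its component SNPs."""
    if len(v.ref) != len(v.alt):
        raise NormalizationError("not an MNP: ref and alt lengths differ")
    out = []
    for i, (r, a) in enumerate(zip(v.ref.upper(), v.alt.upper())):
        if r != a:
            out.append(replace(v, pos=v.pos + i, ref=r, alt=a, var_class=CLASS_SNP))
    return out


def minimal_representation(
    chrom: str, pos: int, ref: str, alt: str
) -> Tuple[str, int, str, str]:
    """Trim shared suffix then shared prefix, keeping >=1 base per allele."""
    ref, alt = ref.upper(), alt.upper()
    if ref == alt:
        raise NormalizationError("null variant: ref == alt")
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return chrom, pos, ref, alt


def left_align(v: NormalizedVariant, ctx: ReferenceContext) -> NormalizedVariant:
    """Shift an indel to its unique leftmost minimal representation.

    SNPs and length-preserving substitutions are returned unchanged.
    Idempotent. Raises :class:`InsufficientContextError` when the window
    cannot prove the leftmost placement.
    """
    if len(v.ref) == len(v.alt):
        return v
    if v.chrom != ctx.chrom:
        raise NormalizationError(f"context chromosome {ctx.chrom!r} != {v.chrom!r}")
    pos, ref, alt = v.pos, v.ref.upper(), v.alt.upper()
    if ctx.slice(pos, len(ref)) != ref:
        raise ReferenceMismatchError(
            f"{v.chrom}:{pos} REF {ref} does not match reference"
        )
    while True:
        if ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                prev = ctx.base(pos - 1)
                pos -= 1
                ref, alt = prev + ref, prev + alt
            continue
        break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return replace(v, pos=pos, ref=ref, alt=alt,
                   var_class=classify_alleles(ref, alt))


@dataclass
class NormalizationResult:
    variants: List[NormalizedVariant]
    rejected: List[str]  # human-readable diagnostics for skipped alleles


def normalize_record(
    record: RawCall,
    ctx: Optional[ReferenceContext] = None,
    drop_absent: bool = True,
) -> NormalizationResult:
    """Full normalization pipeline for one raw record.

    decompose → minimal representation → MNP split → left alignment, with
    output sorted by ``(chrom, pos, ref, alt)``. Symbolic ALTs in a
    multi-allelic record are skipped and reported in ``rejected``; a record
    whose every ALT is symbolic yields no variants. ALTs absent from the
    genotype (e.g. the unused allele of a 1/1 multi-allelic) are dropped
    when ``drop_absent``.
    """
    out: List[NormalizedVariant] = []
    rejected: List[str] = []
    if not record.alts:
        raise NormalizationError("record has no ALT allele")
    for alt_index, alt in enumerate(record.alts, start=1):
        if _is_symbolic(alt):
            rejected.append(
                f"{record.chrom}:{record.pos} non-sequence ALT {alt!r}"
            )
            continue
        gclass = genotype_class_for_alt(record.gt, alt_index)
        if drop_absent and gclass == GT_ABSENT:
            continue
        try:
            chrom, pos, ref, nalt = minimal_representation(
                record.chrom, record.pos, record.ref, alt
            )
        except NormalizationError as exc:
            rejected.append(f"{record.chrom}:{record.pos} {exc}")
            continue
        v = NormalizedVariant(
            chrom, pos, ref, nalt,
            genotype=gclass if record.gt is not None else None,
            allele_fraction=record.allele_fraction,
            qual=record.qual,
        )
        pieces = split_mnp(v) if len(v.ref) == len(v.alt) and len(v.ref) > 1 else [v]
        for piece in pieces:
            if ctx is not None and len(piece.ref) != len(piece.alt):
                piece = left_align(piece, ctx)
            out.append(piece)
    # dedupe identical normalized calls from one record
    seen = set()
    unique = []
    for v in sorted(out):
        k = (v.chrom, v.pos, v.ref, v.alt, v.genotype)
        if k not in seen:
            seen.add(k)
            unique.append(v)
    return NormalizationResult(unique, rejected)


def apply_edit(sequence: str, window_start: int, v: NormalizedVariant) -> str:
    """Apply a variant's edit to a reference window (1-based ``window_start``).

    Used for haplotype-identity checks; raises if the REF does not match.
    """
    off = v.pos - window_start
    if off < 0 or off + len(v.ref) > len(sequence):
        raise ValueError("variant outside window")
    if sequence[off : off + len(v.ref)].upper() != v.ref.upper():
        raise ReferenceMismatchError("REF mismatch in window")
    return sequence[:off] + v.alt + sequence[off + len(v.ref):]


def canonical_chrom(name: str, dialect: str = "bare") -> str:
    """Canonicalize chromosome naming across submissions.

    ``bare`` strips any ``chr`` prefix (default); ``chr`` enforces one.
    """
    base = name[3:] if name.lower().startswith("chr") else name
    if dialect == "chr":
        return "chr" + base
    if dialect == "bare":
        return base
    raise ValueError(f"unknown chromosome dialect {dialect!r}")


ContextProvider = Callable[[str], ReferenceContext]


def contexts_from_sequences(seqs: dict) -> ContextProvider:
    """Context provider backed by an in-memory {chrom: sequence} mapping."""
    def provider(chrom: str) -> ReferenceContext:
        return ReferenceContext.from_sequence(chrom, seqs[chrom])
    return provider
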