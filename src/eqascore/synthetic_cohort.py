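"""Synthetic cohort generator.

Builds a reproducible reference genome with engineered repeat tracts, an
exon annotation, a planted ground-truth variant set, and a cohort of lab
submissions with controllable false-negative / false-positive rates and
representation quirks (MNP merging, right-shifted indels, decoy
multi-allelic records). Everything is driven by explicit seeds: the same
seed yields byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np

from .formats_io import (
    SCHEME_GERMLINE,
    SCHEME_SOMATIC,
    Submission,
    read_submission,
    write_bed,
    write_fasta,
    write_submission_vcf,
)
from .regions import RegionSet
from .variant_model import (
    GT_HET,
    GT_HOM_ALT,
    NormalizedVariant,
    ReferenceContext,
    contexts_from_sequences,
    left_align,
    minimal_representation,
)

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class QuirkRates:
    mnp_merge: float = 0.0      # chance two adjacent SNPs are merged into one MNP
    right_shift: float = 0.0    # chance an indel is emitted right-shifted
    multiallelic: float = 0.0   # chance a record carries a decoy extra ALT

    def __post_init__(self):
        for name in ("mnp_merge", "right_shift", "multiallelic"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class LabProfile:
    roi_fraction: float = 1.0
    fn_rate: float = 0.0
    fp_rate: float = 0.0  # expected spurious calls per kb of ROI
    genotype_error_rate: float = 0.0
    quirks: QuirkRates = QuirkRates()
    seed: int = 0
    # deterministic-drop mode: exact call keys (chrom,pos,ref,alt) to omit,
    # overriding fn_rate, so threshold tests are exact rather than stochastic
    drop_keys: Optional[FrozenSet[Tuple[str, int, str, str]]] = None
    n_spurious: Optional[int] = None  # exact FP count, overriding fp_rate

    def __post_init__(self):
        for name in ("roi_fraction", "fn_rate", "genotype_error_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.fp_rate < 0:
            raise ValueError("fp_rate must be >= 0")


@dataclass
class SimulatedTruth:
    reference: Dict[str, str]
    exons: RegionSet
    variants: List[NormalizedVariant] = field(default_factory=list)
    scheme: str = SCHEME_GERMLINE

    def context(self, chrom: str) -> ReferenceContext:
        return ReferenceContext.from_sequence(chrom, self.reference[chrom])


def generate_reference(
    seed: int,
    n_chrom: int = 1,
    length_per_chrom: int = 100_000,
    exon_density: float = 0.2,
    repeat_rate: float = 0.02,
) -> SimulatedTruth:
    """Reproducible reference with homopolymer / dinucleotide repeat tracts.

    ``exon_density`` is the expected fraction of each chromosome covered by
    exons (length ~U[100,200], exponential intergenic gaps).
    """
    if length_per_chrom < 1000:
        raise ValueError("length_per_chrom must be >= 1 kb")
    if not 0 <= exon_density < 1:
        raise ValueError("exon_density must be in [0, 1)")
    rng = np.random.default_rng(seed)
    reference: Dict[str, str] = {}
    triples = []
    for ci in range(n_chrom):
        chrom = str(ci + 1)
        parts: List[str] = []
        n = 0
        while n < length_per_chrom:
            if rng.random() < repeat_rate:
                if rng.random() < 0.5:  # homopolymer
                    tract = str(rng.choice(BASES)) * int(rng.integers(5, 13))
                else:  # dinucleotide repeat
                    unit = "".join(rng.choice(BASES, size=2))
                    tract = unit * int(rng.integers(3, 9))
                parts.append(tract)
                n += len(tract)
            else:
                parts.append(str(rng.choice(BASES)))
                n += 1
        reference[chrom] = "".join(parts)[:length_per_chrom]
        if exon_density > 0:
            mean_exon = 150.0
            mean_gap = mean_exon * (1 - exon_density) / exon_density
            pos = 50 + int(rng.exponential(mean_gap / 2))
            while pos < length_per_chrom - 300:
                elen = int(rng.integers(100, 201))
                triples.append((chrom, pos, min(pos + elen, length_per_chrom - 50)))
                pos += elen + max(20, int(rng.exponential(mean_gap)))
    return SimulatedTruth(reference=reference, exons=RegionSet(triples))


def _sample_indel_length(rng, lo: int, hi: int, median: int = 3) -> int:
    # geometric with p tuned so the median lands near the requested value
    p = 1 - 0.5 ** (1.0 / max(median, 1))
    while True:
        length = int(rng.geometric(p))
        if lo <= length <= hi:
            return length


def plant_truth_variants(
    scaffold: SimulatedTruth,
    n_snp: int,
    n_indel: int,
    scheme: str = SCHEME_GERMLINE,
    seed: int = 0,
    indel_len_range: Tuple[int, int] = (1, 35),
    het_fraction: float = 0.7,
) -> SimulatedTruth:
    """Plant SNPs and indels inside exons, stored pre-normalized.

    No two variants share a normalized start; indel spans (plus a guard
    band covering their repeat tract) never overlap another variant.
    """
    rng = np.random.default_rng(seed)
    exon_positions: List[Tuple[str, int]] = []
    for chrom, s, e in scaffold.exons:
        exon_positions.extend((chrom, p) for p in range(s, e))
    if not exon_positions:
        raise ValueError("scaffold has no exons to plant variants in")
    rng.shuffle(exon_positions)
    blocked: Dict[str, set] = {c: set() for c in scaffold.reference}
    variants: List[NormalizedVariant] = []
    guard = 45  # wider than any engineered repeat tract

    def block(chrom: str, lo: int, hi: int) -> bool:
        span = set(range(lo, hi))
        if span & blocked[chrom]:
            return False
        blocked[chrom].update(span)
        return True

    def germline_gt() -> str:
        return GT_HET if rng.random() < het_fraction else GT_HOM_ALT

    def attrs() -> dict:
        if scheme == SCHEME_GERMLINE:
            return {"genotype": germline_gt()}
        return {"genotype": None,
                "allele_fraction": float(np.round(rng.uniform(0.05, 1.0), 3))}

    # indels first: they need a clear window for their repeat tract
    planted_indels = 0
    for chrom, pos0 in exon_positions:
        if planted_indels >= n_indel:
            break
        seq = scaffold.reference[chrom]
        length = _sample_indel_length(rng, *indel_len_range)
        if pos0 + 1 + length >= len(seq) or pos0 < guard:
            continue
        anchor = seq[pos0]
        if rng.random() < 0.5:  # insertion
            ins = "".join(rng.choice(BASES, size=length))
            raw = NormalizedVariant(chrom, pos0 + 1, anchor, anchor + ins, **attrs())
        else:  # deletion
            raw = NormalizedVariant(chrom, pos0 + 1, seq[pos0 : pos0 + 1 + length],
                                    anchor, **attrs())
        v = left_align(raw, scaffold.context(chrom))
        # the canonical (left-aligned) start must stay exonic, or no ROI
        # built from exons would ever cover the consensus site
        if not scaffold.exons.contains_point(chrom, v.start0):
            continue
        if not block(chrom, v.start0 - guard, max(v.end0, raw.end0) + guard):
            continue
        variants.append(v)
        planted_indels += 1

    # SNPs block only their own base, so adjacent SNPs (MNP fodder) can occur
    planted_snps = 0
    for chrom, pos0 in exon_positions:
        if planted_snps >= n_snp:
            break
        seq = scaffold.reference[chrom]
        ref = seq[pos0]
        if ref not in "ACGT":
            continue
        alt = str(rng.choice(BASES[BASES != ref]))
        if not block(chrom, pos0, pos0 + 1):
            continue
        variants.append(NormalizedVariant(chrom, pos0 + 1, ref, alt, **attrs()))
        planted_snps += 1
    if planted_snps < n_snp or planted_indels < n_indel:
        raise RuntimeError(
            f"exonic space exhausted: placed {planted_snps}/{n_snp} SNPs, "
            f"{planted_indels}/{n_indel} indels"
        )
    variants.sort()
    return SimulatedTruth(reference=scaffold.reference, exons=scaffold.exons,
                          variants=variants, scheme=scheme)


def equivalent_indel_placements(
    seq: str, v: NormalizedVariant, max_shift: int = 64
) -> List[NormalizedVariant]:
    """All VCF-anchored placements of an indel producing the same haplotype.

    Brute-force window enumeration; used by the simulator to emit
    right-shifted (non-canonical) representations.
    """
    if len(v.ref) == len(v.alt):
        return [v]
    length = abs(len(v.ref) - len(v.alt))
    w0 = max(0, v.start0 - max_shift)
    w1 = min(len(seq), v.end0 + max_shift + length)
    window = seq[w0:w1]
    off = v.start0 - w0
    target = window[:off] + v.alt + window[off + len(v.ref):]
    out = []
    is_del = len(v.ref) > len(v.alt)
    for a in range(w0, w1 - length - 1):
        anchor = seq[a]
        if is_del:
            ref, alt = seq[a : a + 1 + length], anchor
        else:
            ins = target[a - w0 + 1 : a - w0 + 1 + length]
            if len(ins) < length:
                continue
            ref, alt = anchor, anchor + ins
        cand_hap = window[: a - w0] + alt + window[a - w0 + len(ref):]
        if cand_hap == target:
            out.append(replace(v, pos=a + 1, ref=ref, alt=alt))
    return out


def right_shift(seq: str, v: NormalizedVariant, max_shift: int = 64) -> NormalizedVariant:
    """Rightmost haplotype-equivalent placement (identity when unique)."""
    placements = equivalent_indel_placements(seq, v, max_shift)
    return max(placements, key=lambda p: p.pos) if placements else v


_GT_TO_FIELD = {GT_HET: "0/1", GT_HOM_ALT: "1/1", None: "0/1", "unknown": "./."}


def _vcf_rows(
    records: List[dict], scheme: str
) -> List[str]:
    rows = []
    for rec in sorted(records, key=lambda r: (r["chrom"], r["pos"], r["ref"], r["alt"])):
        info = "."
        if scheme == SCHEME_SOMATIC and rec.get("af") is not None:
            info = f"AF={rec['af']:.3f}"
        gt = _GT_TO_FIELD.get(rec.get("genotype"), "0/1")
        rows.append(
            f"{rec['chrom']}\t{rec['pos']}\t.\t{rec['ref']}\t{rec['alt']}\t"
            f"{rec.get('qual', 100)}\t{rec.get('filter', 'PASS')}\t{info}\tGT\t{gt}"
        )
    return rows


def simulate_submission(
    truth: SimulatedTruth,
    profile: LabProfile,
    scheme: str,
    vcf_path: str | Path,
    bed_path: str | Path,
) -> dict:
    """Write one lab's VCF + BED; returns a manifest entry.

    ROI = a random subset of exons (``roi_fraction`` by count) expanded by
    2 bp. Kept calls = truth within ROI minus drops (Bernoulli ``fn_rate``
    or the deterministic ``drop_keys`` list); spurious SNPs are added
    uniformly over ROI away from truth sites; representation quirks are
    applied last so normalization is genuinely exercised.
    """
    rng = np.random.default_rng(profile.seed)
    exons = list(truth.exons)
    if profile.roi_fraction >= 1.0:
        chosen = exons
    else:
        k = max(1, int(round(profile.roi_fraction * len(exons))))
        pick = rng.choice(len(exons), size=k, replace=False)
        chosen = [exons[i] for i in sorted(pick)]
    roi = RegionSet(chosen).expand(2)

    kept: List[NormalizedVariant] = []
    for v in truth.variants:
        if not roi.contains_point(v.chrom, v.start0):
            continue
        if profile.drop_keys is not None:
            if (v.chrom, v.pos, v.ref, v.alt) in profile.drop_keys:
                continue
        elif profile.fn_rate > 0 and rng.random() < profile.fn_rate:
            continue
        if (scheme == SCHEME_GERMLINE and profile.genotype_error_rate > 0
                and rng.random() < profile.genotype_error_rate):
            flipped = GT_HOM_ALT if v.genotype == GT_HET else GT_HET
            v = replace(v, genotype=flipped)
        kept.append(v)

    # spurious calls, uniform over ROI excluding truth sites and flanks
    truth_blocked = set()
    for v in truth.variants:
        truth_blocked.update((v.chrom, p) for p in range(v.start0 - 2, v.end0 + 2))
    roi_points = [(c, p) for c, s, e in roi for p in range(s, e)]
    if profile.n_spurious is not None:
        n_fp = profile.n_spurious
    else:
        n_fp = int(rng.poisson(profile.fp_rate * roi.total_bases() / 1000.0))
    spurious: List[NormalizedVariant] = []
    used = set()
    guard_iter = 0
    while len(spurious) < n_fp and guard_iter < 50 * n_fp + 100:
        guard_iter += 1
        chrom, p = roi_points[int(rng.integers(len(roi_points)))]
        if (chrom, p) in truth_blocked or (chrom, p) in used:
            continue
        ref = truth.reference[chrom][p]
        if ref not in "ACGT":
            continue
        alt = str(rng.choice(BASES[BASES != ref]))
        gt = GT_HET if scheme == SCHEME_GERMLINE else None
        af = float(np.round(rng.uniform(0.05, 0.5), 3)) if scheme == SCHEME_SOMATIC else None
        spurious.append(NormalizedVariant(chrom, p + 1, ref, alt,
                                          genotype=gt, allele_fraction=af))
        used.add((chrom, p))

    records: List[dict] = []

    def to_record(v: NormalizedVariant) -> dict:
        return {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                "genotype": v.genotype, "af": v.allele_fraction}

    calls = sorted(kept + spurious)
    i = 0
    while i < len(calls):
        v = calls[i]
        seq = truth.reference[v.chrom]
        # MNP-merge quirk: adjacent SNPs with the same genotype class
        if (v.var_class == "snp" and i + 1 < len(calls)
                and calls[i + 1].chrom == v.chrom
                and calls[i + 1].pos == v.pos + 1
                and calls[i + 1].var_class == "snp"
                and calls[i + 1].genotype == v.genotype
                and rng.random() < profile.quirks.mnp_merge):
            nxt = calls[i + 1]
            records.append({"chrom": v.chrom, "pos": v.pos,
                            "ref": v.ref + nxt.ref, "alt": v.alt + nxt.alt,
                            "genotype": v.genotype, "af": v.allele_fraction})
            i += 2
            continue
        if v.var_class in ("insertion", "deletion") and rng.random() < profile.quirks.right_shift:
            v = right_shift(seq, v)
        rec = to_record(v)
        if rng.random() < profile.quirks.multiallelic:
            # decoy extra ALT never referenced by GT; decomposition drops it
            decoy_ref = rec["ref"][0]
            decoy = str(rng.choice(BASES[BASES != decoy_ref]))
            if decoy != rec["alt"]:
                rec = dict(rec, alt=f"{rec['alt']},{decoy}")
        records.append(rec)
        i += 1

    write_submission_vcf(vcf_path, _vcf_rows(records, scheme),
                         somatic=(scheme == SCHEME_SOMATIC))
    write_bed(roi, bed_path)
    return {
        "vcf": str(vcf_path),
        "bed": str(bed_path),
        "seed": profile.seed,
        "roi_fraction": profile.roi_fraction,
        "fn_rate": profile.fn_rate,
        "fp_rate": profile.fp_rate,
        "genotype_error_rate": profile.genotype_error_rate,
        "quirks": {"mnp_merge": profile.quirks.mnp_merge,
                   "right_shift": profile.quirks.right_shift,
                   "multiallelic": profile.quirks.multiallelic},
        "n_records": len(records),
    }


def simulate_cohort(
    truth: SimulatedTruth,
    n_labs: int,
    out_dir: str | Path,
    seed: int = 0,
    profiles: Optional[Sequence[LabProfile]] = None,
    base_profile: LabProfile = LabProfile(),
) -> dict:
    """Write a full cohort (reference, exons, truth, per-lab VCF+BED, manifest)."""
    if n_labs < 1:
        raise ValueError("n_labs must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if profiles is None:
        profiles = [replace(base_profile, seed=seed * 1_000_003 + i)
                    for i in range(n_labs)]
    if len(profiles) != n_labs:
        raise ValueError("profiles length must equal n_labs")
    write_fasta(truth.reference, out / "reference.fasta")
    write_bed(truth.exons, out / "exons.bed")
    labs = {}
    for i, profile in enumerate(profiles):
        lab_id = f"lab{i + 1:02d}"
        entry = simulate_submission(
            truth, profile, truth.scheme,
            out / f"{lab_id}.vcf", out / f"{lab_id}.bed",
        )
        labs[lab_id] = entry
    manifest = {
        "seed": seed,
        "scheme": truth.scheme,
        "n_labs": n_labs,
        "reference": str(out / "reference.fasta"),
        "exons": str(out / "exons.bed"),
        "labs": labs,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def load_cohort(truth: SimulatedTruth, manifest: dict) -> List[Submission]:
    """Read a simulated cohort back through the real ingest path."""
    contexts = contexts_from_sequences(truth.reference)
    subs = []
    for lab_id in sorted(manifest["labs"]):
        entry = manifest["labs"][lab_id]
        subs.append(read_submission(
            entry["vcf"], entry["bed"], scheme=manifest["scheme"],
            participant_id=lab_id, contexts=contexts,
        ))
    return subs
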