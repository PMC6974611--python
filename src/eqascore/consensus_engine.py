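"""Participant-consensus truth sets and assessable-region policies.

A variant enters the consensus iff (a) its position lies in the ROI of at
least ``min_participants`` labs and (b) at least ``agreement_fraction`` of
those labs made the identical normalized call. Fractions are compared with
exact rational arithmetic so 6/8 >= 75% holds exactly.

Four assessable-region policies are supported:

``germline_exon2bp``
    all protein-coding exons extended by ``exon_extension_bp``;
``germline_consensus_exon2bp``
    only exons containing at least one consensus variant, extended;
``somatic_exact``
    the exact REF spans of the truth variants, no extension;
``somatic_proximity``
    per submission, the declared ROI minus anything further than
    ``somatic_proximity_bp`` from the nearest reported variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .formats_io import SCHEME_GERMLINE, Submission
from .regions import RegionSet
from .variant_model import NormalizedVariant

POLICY_GERMLINE_EXON = "germline_exon2bp"
POLICY_GERMLINE_CONSENSUS_EXON = "germline_consensus_exon2bp"
POLICY_SOMATIC_EXACT = "somatic_exact"
POLICY_SOMATIC_PROXIMITY = "somatic_proximity"

ASSESSABLE_POLICIES = (
    POLICY_GERMLINE_EXON,
    POLICY_GERMLINE_CONSENSUS_EXON,
    POLICY_SOMATIC_EXACT,
    POLICY_SOMATIC_PROXIMITY,
)


def _as_fraction(x) -> Fraction:
    if isinstance(x, Fraction):
        return x
    if isinstance(x, float):
        return Fraction(str(x))  # decimal-exact, not binary-exact
    return Fraction(x)


@dataclass(frozen=True)
class ConsensusParameters:
    min_participants: int = 7
    agreement_fraction: Fraction = Fraction(3, 4)
    exon_extension_bp: int = 2
    somatic_proximity_bp: int = 1000
    indel_max_len: int = 50

    def __post_init__(self):
        object.__setattr__(self, "agreement_fraction",
                           _as_fraction(self.agreement_fraction))
        if self.min_participants < 1:
            raise ValueError("min_participants must be >= 1")
        if not (0 < self.agreement_fraction <= 1):
            raise ValueError("agreement_fraction must be in (0, 1]")
        for name in ("exon_extension_bp", "somatic_proximity_bp", "indel_max_len"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SiteTally:
    """Vote bookkeeping at one normalized variant start site."""

    chrom: str
    pos: int  # 1-based
    covering_labs: int = 0
    call_counts: Dict[Tuple, int] = field(default_factory=dict)
    calling_labs: int = 0

    @property
    def noncalling_labs(self) -> int:
        return self.covering_labs - self.calling_labs


@dataclass
class TruthSet:
    variants: List[NormalizedVariant]
    assessable: Optional[RegionSet] = None
    provenance: str = "consensus"  # eqa | consensus | merged
    # per-variant (covering_labs, agreeing_labs), keyed by full call key
    support: Dict[Tuple, Tuple[int, int]] = field(default_factory=dict)
    excluded_weak_sites: List[Tuple[str, int]] = field(default_factory=list)

    def variant_keys(self, with_genotype: bool) -> set:
        return {v.call_key(with_genotype) for v in self.variants}


def _call_key(v: NormalizedVariant, scheme: str) -> Tuple:
    return v.call_key(with_genotype=(scheme == SCHEME_GERMLINE))


def tally_sites(submissions: Sequence[Submission], scheme: str) -> Dict[Tuple[str, int], SiteTally]:
    """Tally every site where any lab calls a variant.

    Covering = the lab's ROI contains the site point; a covering lab with no
    call there is a non-caller. Calls from labs whose ROI does not cover the
    site are ignored (they cannot vote at a site they did not target).
    """
    builds = {s.reference_build for s in submissions}
    if len(builds) > 1:
        raise ValueError(f"mixed reference builds in cohort: {sorted(builds)}")
    sites: Dict[Tuple[str, int], SiteTally] = {}
    per_site_calls: Dict[Tuple[str, int], Dict[str, List[NormalizedVariant]]] = {}
    for sub in submissions:
        for v in sub.variants:
            site = (v.chrom, v.pos)
            per_site_calls.setdefault(site, {}).setdefault(
                sub.participant_id, []
            ).append(v)
    for site, by_lab in per_site_calls.items():
        chrom, pos = site
        tally = SiteTally(chrom, pos)
        for sub in submissions:
            covers = sub.roi.contains_point(chrom, pos - 1)
            if covers:
                tally.covering_labs += 1
            calls = by_lab.get(sub.participant_id, [])
            if not covers or not calls:
                continue
            tally.calling_labs += 1
            for v in calls:  # a lab with two alts contributes both calls
                key = _call_key(v, scheme)
                tally.call_counts[key] = tally.call_counts.get(key, 0) + 1
        sites[site] = tally
    return sites


def tally_site(
    site: Tuple[str, int], submissions: Sequence[Submission], scheme: str
) -> SiteTally:
    """Tally a single ``(chrom, 1-based pos)`` site."""
    chrom, pos = site
    tally = SiteTally(chrom, pos)
    for sub in submissions:
        if not sub.roi.contains_point(chrom, pos - 1):
            continue
        tally.covering_labs += 1
        calls = [v for v in sub.variants if (v.chrom, v.pos) == site]
        if calls:
            tally.calling_labs += 1
            for v in calls:
                key = _call_key(v, scheme)
                tally.call_counts[key] = tally.call_counts.get(key, 0) + 1
    return tally


def meets_consensus(count: int, covering: int, params: ConsensusParameters) -> bool:
    """Exact threshold test: covering >= min labs and count/covering >= fraction."""
    if covering < params.min_participants:
        return False
    frac = params.agreement_fraction
    return count * frac.denominator >= frac.numerator * covering


def build_consensus(
    submissions: Sequence[Submission],
    params: ConsensusParameters,
    scheme: str,
) -> TruthSet:
    """Derive the participant-consensus truth set (assessable regions unset)."""
    if not submissions:
        raise ValueError("need at least one submission")
    sites = tally_sites(submissions, scheme)
    variant_by_key: Dict[Tuple, NormalizedVariant] = {}
    for sub in submissions:
        for v in sub.variants:
            variant_by_key.setdefault(_call_key(v, scheme), v)
    chosen: List[NormalizedVariant] = []
    support: Dict[Tuple, Tuple[int, int]] = {}
    for site in sorted(sites):
        tally = sites[site]
        for key, count in sorted(tally.call_counts.items(), key=lambda kv: repr(kv[0])):
            if meets_consensus(count, tally.covering_labs, params):
                proto = variant_by_key[key]
                v = NormalizedVariant(
                    proto.chrom, proto.pos, proto.ref, proto.alt,
                    genotype=proto.genotype if scheme == SCHEME_GERMLINE else None,
                )
                chosen.append(v)
                support[v.call_key(True)] = (tally.covering_labs, count)
    chosen.sort()
    return TruthSet(variants=chosen, assessable=None, provenance="consensus",
                    support=support)


def build_assessable(
    policy: str,
    params: ConsensusParameters,
    exons: Optional[RegionSet] = None,
    truth_variants: Optional[Iterable[NormalizedVariant]] = None,
    roi: Optional[RegionSet] = None,
    reported_variants: Optional[Iterable[NormalizedVariant]] = None,
) -> RegionSet:
    """Construct assessable regions under one of the four scheme policies."""
    if policy == POLICY_GERMLINE_EXON:
        if exons is None:
            raise ValueError("germline policies require an exon annotation")
        return exons.expand(params.exon_extension_bp)
    if policy == POLICY_GERMLINE_CONSENSUS_EXON:
        if exons is None:
            raise ValueError("germline policies require an exon annotation")
        if truth_variants is None:
            raise ValueError("policy requires consensus variants")
        starts = [(v.chrom, v.start0) for v in truth_variants]
        keep = [
            (chrom, s, e)
            for chrom, s, e in exons
            if any(c == chrom and s <= p < e for c, p in starts)
        ]
        return RegionSet(keep).expand(params.exon_extension_bp)
    if policy == POLICY_SOMATIC_EXACT:
        if truth_variants is None:
            raise ValueError("policy requires truth variants")
        return RegionSet((v.chrom, v.start0, v.end0) for v in truth_variants)
    if policy == POLICY_SOMATIC_PROXIMITY:
        if roi is None or reported_variants is None:
            raise ValueError("policy requires the submitted ROI and reported variants")
        near = RegionSet(
            (v.chrom,
             max(0, v.start0 - params.somatic_proximity_bp),
             v.end0 + params.somatic_proximity_bp)
            for v in reported_variants
        )
        return roi.intersection(near)
    raise ValueError(f"unknown assessable policy {policy!r}")


def merge_truth(
    eqa: TruthSet,
    consensus: TruthSet,
    params: ConsensusParameters,
    scheme: str = SCHEME_GERMLINE,
) -> TruthSet:
    """2016-mode merge: EQA truth with strong-consensus override.

    At sites defined by both sources the EQA call stands unless the
    consensus call differs and is strong (covering >= min labs, agreement
    >= fraction), in which case the consensus replaces it. Sites unique to
    one source are kept from that source, except weak-consensus-only sites,
    which are excluded and flagged.
    """
    with_gt = scheme == SCHEME_GERMLINE

    def strong(v: NormalizedVariant) -> bool:
        cov, agr = consensus.support.get(v.call_key(True), (0, 0))
        return meets_consensus(agr, cov, params)

    def by_site(ts: TruthSet) -> Dict[Tuple[str, int], List[NormalizedVariant]]:
        out: Dict[Tuple[str, int], List[NormalizedVariant]] = {}
        for v in ts.variants:
            out.setdefault((v.chrom, v.pos), []).append(v)
        return out

    eqa_sites = by_site(eqa)
    cons_sites = by_site(consensus)
    merged: List[NormalizedVariant] = []
    support: Dict[Tuple, Tuple[int, int]] = {}
    excluded: List[Tuple[str, int]] = []
    for site in sorted(set(eqa_sites) | set(cons_sites)):
        e_calls = eqa_sites.get(site, [])
        c_calls = cons_sites.get(site, [])
        if e_calls and c_calls:
            same = {v.call_key(with_gt) for v in e_calls} == {
                v.call_key(with_gt) for v in c_calls
            }
            if not same and all(strong(v) for v in c_calls):
                take = c_calls
            else:
                take = e_calls
        elif e_calls:
            take = e_calls
        else:  # consensus-only site: keep only if strong
            take = [v for v in c_calls if strong(v)]
            if not take:
                excluded.append(site)
                continue
        for v in take:
            merged.append(v)
            if v.call_key(True) in consensus.support:
                support[v.call_key(True)] = consensus.support[v.call_key(True)]
    merged.sort()
    assessable = eqa.assessable
    if assessable is not None and consensus.assessable is not None:
        assessable = assessable.union(consensus.assessable)
    elif consensus.assessable is not None:
        assessable = consensus.assessable
    return TruthSet(variants=merged, assessable=assessable, provenance="merged",
                    support=support, excluded_weak_sites=excluded)
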