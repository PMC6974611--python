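"""Concordance scoring of a submission against a truth set.

Every eligible call inside the comparison region (assessable ∩ declared
ROI) falls in one of four categories: agree (TP), disagree (FP and FN by
default), extra (FP) or missing (FN). Germline matching requires the called
genotype class to match; somatic matching requires only the alternate
allele.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .consensus_engine import ConsensusParameters, TruthSet
from .formats_io import Submission
from .regions import RegionSet
from .variant_model import NormalizedVariant

MODE_GENOTYPE = "genotype"
MODE_ALT_ALLELE = "alt_allele"

CAT_AGREE = "agree"
CAT_DISAGREE = "disagree"
CAT_EXTRA = "extra"
CAT_MISSING = "missing"

DISAGREE_BOTH = "both"      # a disagreement counts as FP and FN
DISAGREE_FN_ONLY = "fn-only"


@dataclass(frozen=True)
class Scores:
    sensitivity: float
    precision: float
    f_score: float


def compute_scores(tp: int, fp: int, fn: int) -> Scores:
    """sensitivity = TP/(TP+FN), precision = TP/(TP+FP), F = harmonic mean.

    Any 0/0 is defined as 0.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    sens = tp / (tp + fn) if tp + fn else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    f = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    return Scores(sens, prec, f)


def efficiency(total_bases_sequenced: float, declared_variants: int) -> Optional[float]:
    """Raw bases generated per declared variant; None when undefined (0 variants)."""
    if total_bases_sequenced < 0 or declared_variants < 0:
        raise ValueError("inputs must be non-negative")
    if declared_variants == 0:
        return None
    return total_bases_sequenced / declared_variants


@dataclass
class ConcordanceResult:
    classifications: List[Tuple[NormalizedVariant, str]]
    tp: int
    fp: int
    fn: int
    sensitivity: float
    precision: float
    f_score: float
    comparison_region: RegionSet
    matching_mode: str
    not_assessed: List[NormalizedVariant] = field(default_factory=list)

    def category_count(self, category: str) -> int:
        return sum(1 for _, c in self.classifications if c == category)


def comparison_region(truth: TruthSet, sub: Submission) -> RegionSet:
    """Intersection of the truth's assessable regions and the declared ROI."""
    if truth.assessable is None:
        raise ValueError("truth set has no assessable regions")
    return truth.assessable.intersection(sub.roi)


def _eligible(v: NormalizedVariant, max_indel: int) -> bool:
    return v.indel_len < max_indel


def _in_region(v: NormalizedVariant, region: RegionSet) -> bool:
    return region.contains_point(v.chrom, v.start0)


def classify(
    sub: Submission,
    truth: TruthSet,
    mode: str,
    params: ConsensusParameters = ConsensusParameters(),
    disagree_mode: str = DISAGREE_BOTH,
    region: Optional[RegionSet] = None,
) -> ConcordanceResult:
    """Classify every call and populate counts and scores.

    Same-site means identical (chrom, normalized start, REF); a submitted
    call there with a different alt or genotype class is a disagreement.
    Calls failing the <``indel_max_len`` eligibility filter are excluded
    from all categories and listed under ``not_assessed``.
    """
    if mode not in (MODE_GENOTYPE, MODE_ALT_ALLELE):
        raise ValueError(f"unknown matching mode {mode!r}")
    if region is None:
        region = comparison_region(truth, sub)
    with_gt = mode == MODE_GENOTYPE

    not_assessed = [v for v in sub.variants if not _eligible(v, params.indel_max_len)]
    truth_in = [
        v for v in truth.variants
        if _eligible(v, params.indel_max_len) and _in_region(v, region)
    ]
    sub_in = [
        v for v in sub.variants
        if _eligible(v, params.indel_max_len) and _in_region(v, region)
    ]

    truth_by_site: Dict[Tuple[str, int, str], List[NormalizedVariant]] = {}
    for v in truth_in:
        truth_by_site.setdefault(v.site_key(), []).append(v)
    sub_by_site: Dict[Tuple[str, int, str], List[NormalizedVariant]] = {}
    for v in sub_in:
        sub_by_site.setdefault(v.site_key(), []).append(v)

    classifications: List[Tuple[NormalizedVariant, str]] = []
    n_agree = n_disagree = n_missing = n_extra = 0

    for site in sorted(set(truth_by_site) | set(sub_by_site)):
        t_calls = list(truth_by_site.get(site, []))
        s_calls = list(sub_by_site.get(site, []))
        # exact matches under the mode key
        for t in list(t_calls):
            match = next(
                (s for s in s_calls if s.call_key(with_gt) == t.call_key(with_gt)),
                None,
            )
            if match is not None:
                t_calls.remove(t)
                s_calls.remove(match)
                classifications.append((match, CAT_AGREE))
                n_agree += 1
        # leftover pairs at the same site: disagreements
        n_pairs = min(len(t_calls), len(s_calls))
        for i in range(n_pairs):
            classifications.append((s_calls[i], CAT_DISAGREE))
            n_disagree += 1
        for t in t_calls[n_pairs:]:
            classifications.append((t, CAT_MISSING))
            n_missing += 1
        for s in s_calls[n_pairs:]:
            classifications.append((s, CAT_EXTRA))
            n_extra += 1

    tp = n_agree
    fn = n_missing + n_disagree
    fp = n_extra + (n_disagree if disagree_mode == DISAGREE_BOTH else 0)
    scores = compute_scores(tp, fp, fn)
    return ConcordanceResult(
        classifications=classifications,
        tp=tp, fp=fp, fn=fn,
        sensitivity=scores.sensitivity,
        precision=scores.precision,
        f_score=scores.f_score,
        comparison_region=region,
        matching_mode=mode,
        not_assessed=not_assessed,
    )


def round_percent(fraction: float, digits: int = 1) -> float:
    """Express a fraction as a percentage rounded half-up to ``digits``."""
    scale = 10 ** digits
    return math.floor(fraction * 100 * scale + 0.5) / scale
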