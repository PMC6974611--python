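"""Unit and property tests for variant normalization.

The left-alignment checks use an independent brute-force oracle: enumerate
every anchored placement of the same-length edit inside the window, keep
those whose edited haplotype string equals the input's, and take the
leftmost.
"""

import random

import pytest

from eqascore.variant_model import (
    GT_ABSENT,
    GT_HET,
    GT_HET_OTHER,
    GT_HOM_ALT,
    GT_UNKNOWN,
    InsufficientContextError,
    NormalizationError,
    NormalizedVariant,
    RawCall,
    ReferenceContext,
    apply_edit,
    decompose_multiallelic,
    genotype_class_for_alt,
    left_align,
    minimal_representation,
    normalize_record,
    split_mnp,
)


# ---------------------------------------------------------------- oracle

def oracle_leftmost(seq: str, v: NormalizedVariant) -> NormalizedVariant:
    """Brute-force leftmost equivalent placement (1-based seq start = 1)."""
    length = abs(len(v.ref) - len(v.alt))
    if length == 0:
        return v
    start0 = v.pos - 1
    target = seq[:start0] + v.alt + seq[start0 + len(v.ref):]
    is_del = len(v.ref) > len(v.alt)
    for a in range(0, len(seq)):
        if is_del:
            if a + 1 + length > len(seq):
                break
            ref, alt = seq[a : a + 1 + length], seq[a]
        else:
            ins = target[a + 1 : a + 1 + length]
            if len(ins) < length:
                break
            ref, alt = seq[a], seq[a] + ins
        cand = seq[:a] + alt + seq[a + len(ref):]
        if cand == target:
            return NormalizedVariant(v.chrom, a + 1, ref, alt)
    raise AssertionError("no equivalent placement found")


# ---------------------------------------------------------------- decompose

class TestDecompose:
    def test_biallelic_split_order(self):
        rec = RawCall("1", 100, "A", ("G", "T"), gt=(1, 2))
        out = decompose_multiallelic(rec)
        assert [r.alts for r in out] == [("G",), ("T",)]
        assert genotype_class_for_alt(rec.gt, 1) == GT_HET_OTHER
        assert genotype_class_for_alt(rec.gt, 2) == GT_HET_OTHER

    def test_single_alt_identity(self):
        rec = RawCall("1", 100, "A", ("G",), gt=(0, 1))
        assert decompose_multiallelic(rec) == [rec]

    def test_symbolic_alt_rejected(self):
        with pytest.raises(NormalizationError, match="non-sequence ALT"):
            decompose_multiallelic(RawCall("1", 100, "A", ("<DEL>",)))

    @pytest.mark.parametrize("gt,alt_index,expected", [
        ((0, 1), 1, GT_HET),
        ((1, 1), 1, GT_HOM_ALT),
        ((1, 2), 2, GT_HET_OTHER),
        ((1,), 1, "hemi"),
        ((0, 0), 1, GT_ABSENT),
        ((None, None), 1, GT_UNKNOWN),
        (None, 1, GT_UNKNOWN),
    ])
    def test_genotype_recoding(self, gt, alt_index, expected):
        assert genotype_class_for_alt(gt, alt_index) == expected


# ---------------------------------------------------------------- split_mnp

def brute_force_mnp(pos, ref, alt):
    return [(pos + i, r, a) for i, (r, a) in enumerate(zip(ref, alt)) if r != a]


class TestSplitMnp:
    def test_two_mismatches(self):
        out = split_mnp(NormalizedVariant("1", 100, "AG", "CT", genotype=GT_HET))
        assert [(v.pos, v.ref, v.alt) for v in out] == brute_force_mnp(100, "AG", "CT")
        assert all(v.genotype == GT_HET for v in out)

    def test_matching_first_base_emits_nothing_there(self):
        out = split_mnp(NormalizedVariant("1", 100, "AC", "AT"))
        assert [(v.pos, v.ref, v.alt) for v in out] == [(101, "C", "T")]

    def test_length_one_is_snp(self):
        out = split_mnp(NormalizedVariant("1", 100, "A", "C"))
        assert [(v.pos, v.ref, v.alt) for v in out] == [(100, "A", "C")]

    def test_length_mismatch_rejected(self):
        with pytest.raises(NormalizationError, match="not an MNP"):
            split_mnp(NormalizedVariant("1", 100, "AC", "A"))

    def test_conservation_random(self):
        rng = random.Random(7)
        for _ in range(200):
            n = rng.randint(1, 12)
            ref = "".join(rng.choice("ACGT") for _ in range(n))
            alt = "".join(rng.choice("ACGT") for _ in range(n))
            if ref == alt:
                continue
            out = split_mnp(NormalizedVariant("1", 50, ref, alt))
            assert len(out) == sum(r != a for r, a in zip(ref, alt))


# ------------------------------------------------------ minimal representation

class TestMinimalRepresentation:
    def test_suffix_then_prefix(self):
        assert minimal_representation("1", 100, "CTCC", "CCC") == ("1", 100, "CT", "C")

    def test_null_variant_rejected(self):
        with pytest.raises(NormalizationError, match="null variant"):
            minimal_representation("1", 100, "A", "A")

    def test_already_minimal_unchanged(self):
        assert minimal_representation("1", 100, "G", "T") == ("1", 100, "G", "T")

    def test_prefix_trim_advances_pos(self):
        assert minimal_representation("1", 100, "AAC", "AAT") == ("1", 102, "C", "T")

    def test_haplotype_preserved_random(self):
        # oracle: the trimmed edit applies to a window with identical result
        rng = random.Random(3)
        for _ in range(300):
            seq = "".join(rng.choice("ACGT") for _ in range(30))
            pos = rng.randint(5, 15)
            ref = seq[pos - 1 : pos - 1 + rng.randint(1, 6)]
            alt = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 6)))
            if ref == alt:
                continue
            _, npos, nref, nalt = minimal_representation("1", pos, ref, alt)
            before = seq[: pos - 1] + alt + seq[pos - 1 + len(ref):]
            after = seq[: npos - 1] + nalt + seq[npos - 1 + len(nref):]
            assert before == after


# ---------------------------------------------------------------- left_align

class TestLeftAlign:
    def test_deletion_in_dinucleotide_repeat(self):
        ctx = ReferenceContext("1", 1, "GCATATATG")
        out = left_align(NormalizedVariant("1", 4, "TAT", "T"), ctx)
        assert (out.pos, out.ref, out.alt) == (2, "CAT", "C")
        assert out == oracle_leftmost(ctx.sequence, NormalizedVariant("1", 4, "TAT", "T"))

    def test_insertion_in_homopolymer(self):
        ctx = ReferenceContext("1", 1, "AAACCC")
        out = left_align(NormalizedVariant("1", 5, "C", "CC"), ctx)
        assert (out.pos, out.ref, out.alt) == (3, "A", "AC")

    def test_snp_unchanged(self):
        ctx = ReferenceContext("1", 1, "ACGTACGT")
        v = NormalizedVariant("1", 4, "T", "G")
        assert left_align(v, ctx) == v

    def test_idempotent(self):
        ctx = ReferenceContext("1", 1, "GCATATATG")
        once = left_align(NormalizedVariant("1", 4, "TAT", "T"), ctx)
        assert left_align(once, ctx) == once

    def test_insufficient_context(self):
        # window starts inside the repeat: leftmost placement unprovable
        ctx = ReferenceContext("1", 4, "TATATG")
        with pytest.raises(InsufficientContextError):
            left_align(NormalizedVariant("1", 6, "TAT", "T"), ctx)

    def test_matches_oracle_on_random_repeat_windows(self):
        rng = random.Random(42)
        for _ in range(500):
            unit = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 3)))
            seq = (
                "".join(rng.choice("ACGT") for _ in range(10))
                + unit * rng.randint(3, 8)
                + "".join(rng.choice("ACGT") for _ in range(10))
            )
            pos = rng.randint(12, len(seq) - 8)
            if rng.random() < 0.5:
                length = rng.randint(1, 4)
                if pos + length >= len(seq):
                    continue
                v = NormalizedVariant("1", pos, seq[pos - 1 : pos - 1 + 1 + length],
                                      seq[pos - 1])
            else:
                ins = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 4)))
                v = NormalizedVariant("1", pos, seq[pos - 1], seq[pos - 1] + ins)
            ctx = ReferenceContext("1", 1, seq)
            got = left_align(v, ctx)
            want = oracle_leftmost(seq, v)
            assert (got.pos, got.ref, got.alt) == (want.pos, want.ref, want.alt)
            # haplotype preservation by direct string surgery
            assert apply_edit(seq, 1, got) == apply_edit(seq, 1, v)


# ------------------------------------------------------------ normalize_record

class TestNormalizeRecord:
    CTX = ReferenceContext.from_sequence("1", "ACGT" * 60)

    def test_mnp_and_multiallelic(self):
        rec = RawCall("1", 100, "AG", ("CT", "AT"), gt=(1, 2))
        # minimal representation turns alt2 AG>AT into G>T at 101 first
        out = normalize_record(rec)
        keys = [(v.pos, v.ref, v.alt) for v in out.variants]
        assert (100, "A", "C") in keys and (101, "G", "T") in keys
        assert not out.rejected

    def test_symbolic_alt_partial_rejection(self):
        rec = RawCall("1", 8, "A", ("G", "<DUP>"), gt=(1, 2))
        out = normalize_record(rec, self.CTX)
        assert [(v.pos, v.ref, v.alt) for v in out.variants] == [(8, "A", "G")]
        assert len(out.rejected) == 1 and "non-sequence ALT" in out.rejected[0]

    def test_absent_alt_dropped(self):
        rec = RawCall("1", 8, "A", ("G", "T"), gt=(1, 1))
        out = normalize_record(rec, self.CTX)
        assert [(v.alt, v.genotype) for v in out.variants] == [("G", GT_HOM_ALT)]

    def test_idempotence(self):
        seq = "GGGCATCATCATGGG"
        ctx = ReferenceContext.from_sequence("1", seq)
        rec = RawCall("1", 6, "TCAT", ("T",), gt=(0, 1))
        first = normalize_record(rec, ctx).variants
        again = []
        for v in first:
            r2 = RawCall("1", v.pos, v.ref, (v.alt,), gt=(0, 1))
            again.extend(normalize_record(r2, ctx).variants)
        assert [(v.pos, v.ref, v.alt) for v in again] == \
               [(v.pos, v.ref, v.alt) for v in first]

    def test_output_sorted(self):
        rec = RawCall("1", 20, "ACG", ("TGA",), gt=(0, 1))
        out = normalize_record(rec).variants
        assert out == sorted(out)
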