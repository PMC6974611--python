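"""Generator determinism, planted-truth shape, quirk round-trips, recovery."""

import json

import numpy as np
import pytest

from eqascore.consensus_engine import ConsensusParameters, build_consensus
from eqascore.formats_io import read_fasta, validate_bed, validate_vcf
from eqascore.synthetic_cohort import (
    LabProfile,
    QuirkRates,
    equivalent_indel_placements,
    generate_reference,
    load_cohort,
    plant_truth_variants,
    right_shift,
    simulate_cohort,
    simulate_submission,
)
from eqascore.variant_model import ReferenceContext, left_align


class TestGenerateReference:
    def test_same_seed_identical(self):
        a = generate_reference(3, length_per_chrom=5000)
        b = generate_reference(3, length_per_chrom=5000)
        assert a.reference == b.reference
        assert a.exons == b.exons

    def test_zero_exon_density(self):
        t = generate_reference(3, length_per_chrom=5000, exon_density=0.0)
        assert len(t.exons) == 0

    def test_exon_fraction_near_requested(self):
        t = generate_reference(1, length_per_chrom=200_000, exon_density=0.2)
        frac = t.exons.total_bases() / 200_000
        assert 0.12 < frac < 0.28  # generous: gaps are exponential draws

    def test_contains_repeat_tracts(self):
        seq = generate_reference(1, length_per_chrom=20_000).reference["1"]
        assert any(b * 5 in seq for b in "ACGT")

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            generate_reference(1, length_per_chrom=500)


class TestPlantTruthVariants:
    def test_exact_counts_unique_starts(self, small_truth):
        snps = [v for v in small_truth.variants if v.var_class == "snp"]
        indels = [v for v in small_truth.variants if v.var_class != "snp"]
        assert len(snps) == 60 and len(indels) == 8
        starts = [(v.chrom, v.pos) for v in small_truth.variants]
        assert len(starts) == len(set(starts))

    def test_variants_lie_on_reference(self, small_truth):
        for v in small_truth.variants:
            seq = small_truth.reference[v.chrom]
            assert seq[v.start0 : v.end0] == v.ref

    def test_variants_already_left_aligned(self, small_truth):
        for v in small_truth.variants:
            ctx = small_truth.context(v.chrom)
            assert left_align(v, ctx) == v

    def test_indel_median_near_three(self):
        scaffold = generate_reference(2, length_per_chrom=400_000, exon_density=0.3)
        truth = plant_truth_variants(scaffold, 0, 500, seed=4)
        lengths = [v.indel_len for v in truth.variants]
        assert len(lengths) == 500
        assert 2 <= np.median(lengths) <= 4
        assert max(lengths) <= 35

    def test_somatic_scheme_has_allele_fractions(self):
        scaffold = generate_reference(5, length_per_chrom=20_000)
        truth = plant_truth_variants(scaffold, 30, 5, scheme="somatic", seed=6)
        assert all(v.allele_fraction is not None for v in truth.variants)
        assert all(0 < v.allele_fraction <= 1 for v in truth.variants)

    def test_space_exhaustion_raises(self):
        scaffold = generate_reference(7, length_per_chrom=2000, exon_density=0.1)
        with pytest.raises(RuntimeError, match="space exhausted"):
            plant_truth_variants(scaffold, 5000, 0, seed=1)


class TestRightShift:
    def test_round_trip_through_left_align(self, small_truth):
        for v in small_truth.variants:
            if v.var_class not in ("insertion", "deletion"):
                continue
            seq = small_truth.reference[v.chrom]
            shifted = right_shift(seq, v)
            back = left_align(shifted, small_truth.context(v.chrom))
            assert (back.pos, back.ref, back.alt) == (v.pos, v.ref, v.alt)

    def test_placements_contain_input(self):
        seq = "GGCACACACAGG"
        ctx = ReferenceContext("1", 1, seq)
        from eqascore.variant_model import NormalizedVariant
        v = left_align(NormalizedVariant("1", 3, "CAC", "C"), ctx)
        placements = equivalent_indel_placements(seq, v)
        assert v in placements
        assert len(placements) >= 4  # CA-repeat admits several placements


class TestSimulateSubmission:
    def test_error_free_lab_recovers_truth_exactly(self, small_truth, tmp_path):
        profile = LabProfile(seed=1)
        simulate_submission(small_truth, profile, "germline",
                            tmp_path / "s.vcf", tmp_path / "s.bed")
        from eqascore.formats_io import read_submission
        from eqascore.variant_model import contexts_from_sequences
        sub = read_submission(tmp_path / "s.vcf", tmp_path / "s.bed", "germline",
                              contexts=contexts_from_sequences(small_truth.reference))
        assert {v.call_key(True) for v in sub.variants} == \
               {v.call_key(True) for v in small_truth.variants}

    def test_quirky_lab_normalizes_back_to_truth(self, small_truth, quirky_profile, tmp_path):
        simulate_submission(small_truth, quirky_profile, "germline",
                            tmp_path / "s.vcf", tmp_path / "s.bed")
        from eqascore.formats_io import read_submission
        from eqascore.variant_model import contexts_from_sequences
        sub = read_submission(tmp_path / "s.vcf", tmp_path / "s.bed", "germline",
                              contexts=contexts_from_sequences(small_truth.reference))
        assert {v.call_key(True) for v in sub.variants} == \
               {v.call_key(True) for v in small_truth.variants}

    def test_fn_rate_binomial_drop(self, small_truth, tmp_path):
        n_runs, fn_rate = 12, 0.2
        n_truth = len(small_truth.variants)
        drops = []
        for i in range(n_runs):
            profile = LabProfile(fn_rate=fn_rate, seed=100 + i)
            entry = simulate_submission(small_truth, profile, "germline",
                                        tmp_path / f"{i}.vcf", tmp_path / f"{i}.bed")
            drops.append(n_truth - entry["n_records"])
        mean_drop = np.mean(drops)
        sd = np.sqrt(n_truth * fn_rate * (1 - fn_rate))
        assert abs(mean_drop - n_truth * fn_rate) < 3 * sd / np.sqrt(n_runs) + 1

    def test_deterministic_drop_keys(self, small_truth, tmp_path):
        victim = small_truth.variants[0]
        profile = LabProfile(
            drop_keys=frozenset({(victim.chrom, victim.pos, victim.ref, victim.alt)}),
            seed=3)
        simulate_submission(small_truth, profile, "germline",
                            tmp_path / "s.vcf", tmp_path / "s.bed")
        from eqascore.formats_io import read_submission
        sub = read_submission(tmp_path / "s.vcf", tmp_path / "s.bed", "germline")
        keys = {(v.chrom, v.pos, v.ref, v.alt) for v in sub.variants}
        assert (victim.chrom, victim.pos, victim.ref, victim.alt) not in keys
        assert len(sub.variants) == len(small_truth.variants) - 1

    def test_spurious_calls_off_truth_sites(self, small_truth, tmp_path):
        profile = LabProfile(n_spurious=15, seed=8)
        simulate_submission(small_truth, profile, "germline",
                            tmp_path / "s.vcf", tmp_path / "s.bed")
        from eqascore.formats_io import read_submission
        sub = read_submission(tmp_path / "s.vcf", tmp_path / "s.bed", "germline")
        truth_sites = {(v.chrom, v.pos) for v in small_truth.variants}
        extra = [v for v in sub.variants if (v.chrom, v.pos) not in truth_sites]
        assert len(extra) == 15

    def test_generated_files_validate(self, small_truth, quirky_profile, tmp_path):
        simulate_submission(small_truth, quirky_profile, "germline",
                            tmp_path / "s.vcf", tmp_path / "s.bed")
        assert [d for d in validate_vcf(tmp_path / "s.vcf") if d.severity == "error"] == []
        assert validate_bed(tmp_path / "s.bed") == []


class TestSimulateCohort:
    def test_manifest_determinism(self, small_truth, tmp_path):
        m1 = simulate_cohort(small_truth, 4, tmp_path / "a", seed=9)
        m2 = simulate_cohort(small_truth, 4, tmp_path / "b", seed=9)
        strip = lambda m: {k: {kk: vv for kk, vv in lab.items() if kk not in ("vcf", "bed")}
                           for k, lab in m["labs"].items()}
        assert strip(m1) == strip(m2)
        for lab in m1["labs"]:
            assert (tmp_path / "a" / f"{lab}.vcf").read_text() == \
                   (tmp_path / "b" / f"{lab}.vcf").read_text()

    def test_single_lab_cohort(self, small_truth, tmp_path):
        m = simulate_cohort(small_truth, 1, tmp_path / "c", seed=2)
        assert len(m["labs"]) == 1
        subs = load_cohort(small_truth, m)
        assert len(subs) == 1 and subs[0].variants

    def test_reference_fasta_written_and_reloadable(self, small_truth, tmp_path):
        simulate_cohort(small_truth, 1, tmp_path / "d", seed=2)
        assert read_fasta(tmp_path / "d" / "reference.fasta") == small_truth.reference

    def test_covering_counts_match_bed_recount(self, small_truth, tmp_path):
        from eqascore.consensus_engine import tally_site
        from eqascore.formats_io import read_bed
        profiles = [LabProfile(roi_fraction=0.5, seed=i) for i in range(6)]
        m = simulate_cohort(small_truth, 6, tmp_path / "e", seed=1, profiles=profiles)
        subs = load_cohort(small_truth, m)
        beds = {lab: read_bed(m["labs"][lab]["bed"]) for lab in m["labs"]}
        for v in small_truth.variants[:20]:
            expected = sum(bool(b.contains_point(v.chrom, v.start0))
                           for b in beds.values())
            t = tally_site((v.chrom, v.pos), subs, "germline")
            assert t.covering_labs == expected

    def test_heterogeneous_cohort_consensus_recovery(self, small_truth, cohort):
        truth = build_consensus(cohort, ConsensusParameters(), "germline")
        assert {v.call_key(True) for v in truth.variants} == \
               {v.call_key(True) for v in small_truth.variants}
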