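import pytest

from eqascore.consensus_engine import ConsensusParameters
from eqascore.synthetic_cohort import (
    LabProfile,
    QuirkRates,
    generate_reference,
    plant_truth_variants,
    simulate_cohort,
    load_cohort,
)


@pytest.fixture(scope="session")
def small_truth():
    """20 kb genome, 60 SNPs + 8 indels, germline genotypes."""
    scaffold = generate_reference(11, length_per_chrom=20_000, exon_density=0.25)
    return plant_truth_variants(scaffold, 60, 8, seed=12)


@pytest.fixture(scope="session")
def quirky_profile():
    return LabProfile(quirks=QuirkRates(mnp_merge=0.5, right_shift=0.7,
                                        multiallelic=0.2))


@pytest.fixture()
def cohort_dir(tmp_path, small_truth, quirky_profile):
    manifest = simulate_cohort(small_truth, 8, tmp_path / "cohort", seed=5,
                               base_profile=quirky_profile)
    return tmp_path / "cohort", manifest


@pytest.fixture()
def cohort(small_truth, cohort_dir):
    _, manifest = cohort_dir
    return load_cohort(small_truth, manifest)


@pytest.fixture(scope="session")
def default_params():
    return ConsensusParameters()
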