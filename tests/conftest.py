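import pytest

from mecfs_omics import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_spec():
    """Study-sized cohort at moderate noise; small protein/metabolite layers
    to keep the suite fast."""
    return CohortSpec(
        seed=7,
        n_proteins=400,
        n_dap_up=5,
        n_dap_down=4,
        n_metabolites=60,
        wells_per_subject_per_scheme=4,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)
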