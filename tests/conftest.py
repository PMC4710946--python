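import pytest

from fcstrength.cohort import CohortSpec, anatomy_masks, generate_cohort
from fcstrength.connectivity import compute_fcs
from fcstrength.preprocess import clean_subject, group_gm_mask


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale cohort with the default graded coupling."""
    return CohortSpec(
        grid_dims=(14, 14, 10),
        n_per_group={"AD": 4, "MCI": 10, "NC": 6},
        n_converters=6,
        n_timepoints=120,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_gm(small_cohort):
    return group_gm_mask(small_cohort.gm_probability_maps)


@pytest.fixture(scope="session")
def small_fcs_maps(small_spec, small_cohort, small_gm):
    """Preprocessed FCS maps for every subject of the small cohort."""
    comp = anatomy_masks(small_spec)
    conf = {"global": small_gm.include, "wm": comp["wm"], "csf": comp["csf"]}
    return [
        compute_fcs(clean_subject(b, m, conf), small_gm)
        for _, b, m in small_cohort
    ]
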