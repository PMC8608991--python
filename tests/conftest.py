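import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dbsconn import phantom, structconn, vta
from dbsconn.electrode import build_lead

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def spec():
    return phantom.PhantomSpec(seed=123)


@pytest.fixture(scope="session")
def head(spec):
    tissue, nuclei, parc = phantom.make_head_phantom(spec)
    return {"tissue": tissue, "nuclei": nuclei, "parc": parc}


@pytest.fixture(scope="session")
def tract_truth(spec):
    return phantom.make_tractogram(spec, 2000)


@pytest.fixture(scope="session")
def cohort_truth(spec, tract_truth):
    tract, truth = tract_truth
    return phantom.make_cohort(spec, tract, truth)


def patient_vtas(cohort, tissue, sigma=0.33, threshold=0.2):
    """Unioned bilateral analytic VTA per patient (shared test helper)."""
    lead = build_lead("medtronic3389")
    out = {}
    for pid in cohort.patient_ids:
        masks = []
        for hemi in ("right", "left"):
            f = vta.efield_analytic(
                cohort.stim_for(pid, hemi),
                cohort.placement_for(pid, hemi),
                lead,
                sigma,
                tissue,
            )
            masks.append(vta.binarize_vta(f, threshold))
        union = structconn.union_vta_mask(masks)
        out[pid] = vta.VTAMask(
            union, threshold, union.count_nonzero() * union.voxel_volume
        )
    return out


@pytest.fixture(scope="session")
def vtas(cohort_truth, head):
    cohort, _ = cohort_truth
    return patient_vtas(cohort, head["tissue"])


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
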