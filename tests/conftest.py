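"""Shared fixtures: phantoms and pipeline runs reused across test modules."""

import numpy as np
import pytest

from cvrpipe import mapping, synthetic


@pytest.fixture(scope="session")
def protocol():
    return synthetic.ProtocolSpec()


@pytest.fixture(scope="session")
def volume_schedule(protocol):
    """Ideal per-volume petCO2 excursion for the default protocol at TR 2 s."""
    return synthetic.schedule_per_volume(protocol, 2.0)


@pytest.fixture(scope="session")
def recovery_run(protocol, volume_schedule):
    """Full-size noisy phantom pushed through the default pipeline.

    The expensive shared fixture: a 40x48x40 phantom with 2:1 GM:WM truth
    CVR, scattered negative foci, 1% noise and a 6 s delay, mapped with the
    default smoothing/high-pass/GLM/threshold chain.
    """
    phantom = synthetic.default_bold_phantom(seed=5)
    series, truth = synthetic.generate_bold_phantom(phantom, volume_schedule, 2.0)
    petco2 = protocol.baseline_petco2 + volume_schedule
    peto2 = np.full_like(petco2, protocol.peto2_clamp)
    result = mapping.compute_cvr_run(series, petco2, peto2)
    return {"phantom": phantom, "truth": truth, "result": result, "series": series}


@pytest.fixture(scope="session")
def noiseless_small_run(volume_schedule):
    """Small noiseless, delay-free phantom fit without smoothing.

    Exact round-trip conditions: the GLM must reproduce the true CVR map to
    numerical precision and the significance mask must equal the nonzero-CVR
    support.
    """
    phantom = synthetic.default_bold_phantom(
        shape=(16, 20, 16), noise_sd=0.0, delay_s=0.0, n_negative_foci=1, seed=11
    )
    series, truth = synthetic.generate_bold_phantom(phantom, volume_schedule, 2.0)
    design = mapping.make_design(volume_schedule)
    glm = mapping.fit_glm(series, design)
    cvr = mapping.cvr_from_glm(glm)
    z = mapping.zstat_map(glm)
    return {"phantom": phantom, "truth": truth, "glm": glm, "cvr": cvr, "z": z}


@pytest.fixture(scope="session")
def eroded_sphere():
    """60 mm sphere brain eroded by 1.5 mm: the analytic PBVC oracle case."""
    phantom = synthetic.default_structural_phantom(brain_radius_mm=60.0, wm_radius_mm=45.0)
    vol1, vol2, truth = synthetic.generate_structural_pair(
        phantom, synthetic.AtrophySpec(boundary_shift=1.5)
    )
    return {"phantom": phantom, "vol1": vol1, "vol2": vol2, "truth": truth}
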