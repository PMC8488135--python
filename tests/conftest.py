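import numpy as np
import pytest

from lvfusion.geometry import CardiacFrame
from lvfusion.phantom import PhantomSpec, make_phantom
from lvfusion.regional import assign_aha_segments
from lvfusion.template import fit_surface


@pytest.fixture(scope="session")
def axis_frame():
    """Cardiac frame at the origin with e_long = +z, e_rv = +x."""
    return CardiacFrame(
        np.zeros(3), np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0]),
        np.array([0.0, 1.0, 0.0]),
    )


@pytest.fixture(scope="session")
def phantom():
    """One default noiseless phantom subject (fixed seed)."""
    return make_phantom(PhantomSpec(seed=123))


@pytest.fixture(scope="session")
def fitted_ed(phantom):
    """CMR ED endo/epi fitted to the default template, with label maps."""
    frame = phantom.frame
    endo = fit_surface(
        phantom.cmr["ED"].endo.vertices, frame,
        apex_extent=phantom.apex_extent, surface_tag="endo", phase="ED",
    )
    epi = fit_surface(
        phantom.cmr["ED"].epi.vertices, frame,
        apex_extent=None, surface_tag="epi", phase="ED",
    )
    return {
        "endo": endo,
        "epi": epi,
        "labels_endo": assign_aha_segments(endo),
        "labels_epi": assign_aha_segments(epi),
    }


def random_rigid(rng, max_rot_deg=180.0, max_trans=50.0):
    from lvfusion.geometry import RigidTransform, rotation_about_axis

    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    return RigidTransform(
        rotation_about_axis(axis, rng.uniform(-max_rot_deg, max_rot_deg)),
        rng.uniform(-max_trans, max_trans, size=3),
    )
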