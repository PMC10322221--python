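import numpy as np
import pytest

import retinavasc as rv


@pytest.fixture(scope="session")
def composite_phantom():
    """One mid-cohort fundus scene reused by the slower end-to-end tests."""
    return rv.generate(
        rv.PhantomSpec(
            kind="composite_fundus", size=640, width=13.0, n_vessels=8,
            radius=170.0, disc_diameter=96.0, noise_sd=4.0, seed=3,
        )
    )


@pytest.fixture(scope="session")
def composite_bundle(composite_phantom):
    ph = composite_phantom
    return rv.analyze_arrays(
        ph.image, ph.vessel_mask, ph.av_mask, roi=ph.roi, image_id="composite"
    )


def bar_graph(width=11, length=200, angle=0.0, size=400):
    """Convenience: bar phantom plus its pruned centerline graph."""
    ph = rv.generate(
        rv.PhantomSpec(kind="bar", size=size, width=width, length=length, angle_deg=angle)
    )
    skel, graph = rv.build_graph(ph.vessel_mask)
    return ph, skel, graph
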