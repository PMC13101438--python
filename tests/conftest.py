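import math

import pytest

from myelinmorph.morphometry import FiberRecord, measure_instances
from myelinmorph.popstats import summarize
from myelinmorph.qc import screen
from myelinmorph.segmentation import separate_instances
from myelinmorph.synthetic import (
    FiberTruth,
    RenderParams,
    generate_dataset,
    render_sample,
    uf_reference_preset,
)

CANONICAL_SEED = 0
N_IMAGES = 20


def make_record(fiber_id=1, diameter=1.0, thickness=0.25, eccentricity=0.3,
                g=None):
    """FiberRecord with self-consistent diameters for ad-hoc fixtures."""
    outer = diameter + 2 * thickness
    g = diameter / outer if g is None else g
    return FiberRecord(
        fiber_id=fiber_id,
        axon_area_um2=math.pi * (diameter / 2) ** 2,
        axon_diameter_um=diameter,
        outer_diameter_um=outer,
        myelin_thickness_um=thickness,
        g_ratio=g,
        eccentricity=eccentricity,
        centroid_row=10.0,
        centroid_col=10.0,
        touches_border=False,
    )


def render_single_fiber(inner_diameter, g_ratio, axis_ratio=1.0,
                        orientation=0.0, size=200, noiseless=True):
    """One centered fiber on a small frame; noiseless by default."""
    thickness = inner_diameter * (1 - g_ratio) / (2 * g_ratio)
    truth = FiberTruth(
        fiber_id=1, center=(size / 2 + 0.3, size / 2 - 0.2),
        inner_diameter=inner_diameter, myelin_thickness=thickness,
        g_ratio=inner_diameter / (inner_diameter + 2 * thickness),
        axis_ratio=axis_ratio, orientation=orientation)
    render = RenderParams(
        image_height=size, image_width=size,
        psf_sigma=0.0 if noiseless else 1.0,
        noise_sd=0.0 if noiseless else 8.0,
        artifact_rate=0.0 if noiseless else 3.0)
    return render_sample([truth], render, seed=7), truth


@pytest.fixture(scope="session")
def uf_run():
    """One canonical 20-image reference run, processed on truth masks.

    Shared across population-recovery and correlation tests; regenerating
    it per test would dominate the suite runtime.
    """
    pop, render = uf_reference_preset()
    samples = generate_dataset(pop, render, N_IMAGES, seed=CANONICAL_SEED)
    records = []
    for s in samples:
        imap = separate_instances(s.semantic_truth)
        records.extend(measure_instances(imap))
    result = screen(records)
    summary = summarize(result.kept, N_IMAGES * render.image_area_mm2)
    return {
        "samples": samples,
        "records": records,
        "screen": result,
        "summary": summary,
        "render": render,
        "pop": pop,
    }
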