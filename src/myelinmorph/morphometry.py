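"""Per-fiber morphometrics from instance maps.

All diameters are *area-equivalent*: the diameter of the circle whose area
equals the region's pixel area.  The inner diameter uses axon pixels only;
the outer diameter uses the union of axon and myelin pixels of the same
instance.  Myelin thickness and g-ratio follow from those two diameters,
so ``g == inner/outer`` and ``thickness == (outer − inner)/2`` hold exactly
for every record.  Outputs are physical (µm, µm²); pixel counts never
appear in records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage import measure

from myelinmorph.segmentation import AXON, MYELIN, InstanceMap

#: CSV column order for FiberRecord tables.
RECORD_FIELDS = (
    "fiber_id", "axon_area_um2", "axon_diameter_um", "outer_diameter_um",
    "myelin_thickness_um", "g_ratio", "eccentricity",
    "centroid_row", "centroid_col", "touches_border",
)


@dataclass(frozen=True)
class FiberRecord:
    """Measured morphometrics of one segmented fiber."""

    fiber_id: int
    axon_area_um2: float
    axon_diameter_um: float
    outer_diameter_um: float
    myelin_thickness_um: float
    g_ratio: float
    eccentricity: float
    centroid_row: float
    centroid_col: float
    touches_border: bool


def equivalent_diameter(pixel_count: int, pixel_size: float) -> float:
    """Diameter (µm) of the circle with the same area as ``pixel_count`` pixels."""
    if pixel_count < 1:
        raise ValueError("region has no pixels")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    return 2.0 * math.sqrt(pixel_count * pixel_size**2 / math.pi)


def _region_eccentricity(mask: np.ndarray) -> float:
    """Eccentricity of the best-fit ellipse (normalized second central moments)."""
    props = measure.regionprops(mask.astype(np.uint8))
    if not props:
        return float("nan")
    return float(props[0].eccentricity)


def measure_fiber(axon_mask: np.ndarray, myelin_mask: np.ndarray,
                  pixel_size: float, fiber_id: int = 1,
                  eccentricity_on: str = "axon") -> FiberRecord:
    """Morphometrics for one fiber given its axon and myelin pixel sets.

    A fiber with axon but no myelin pixels yields ``g == 1`` (equal inner
    and outer diameters); the quality screen removes such records.
    ``eccentricity_on`` selects the pixel set for the ellipse fit:
    ``"axon"`` (default, the better-conditioned lumen) or ``"fiber"``
    (axon plus myelin).
    """
    axon_mask = np.asarray(axon_mask, dtype=bool)
    myelin_mask = np.asarray(myelin_mask, dtype=bool)
    n_axon = int(axon_mask.sum())
    if n_axon == 0:
        raise ValueError("instance has no axon pixels")
    if eccentricity_on not in ("axon", "fiber"):
        raise ValueError("eccentricity_on must be 'axon' or 'fiber'")

    n_outer = n_axon + int(myelin_mask.sum())
    inner = equivalent_diameter(n_axon, pixel_size)
    outer = equivalent_diameter(n_outer, pixel_size)
    ecc_mask = axon_mask if eccentricity_on == "axon" else (axon_mask | myelin_mask)

    rows, cols = np.nonzero(axon_mask | myelin_mask)
    h, w = axon_mask.shape
    touches = bool(rows.min() == 0 or cols.min() == 0
                   or rows.max() == h - 1 or cols.max() == w - 1)
    arows, acols = np.nonzero(axon_mask)
    return FiberRecord(
        fiber_id=fiber_id,
        axon_area_um2=n_axon * pixel_size**2,
        axon_diameter_um=inner,
        outer_diameter_um=outer,
        myelin_thickness_um=(outer - inner) / 2.0,
        g_ratio=inner / outer,
        eccentricity=_region_eccentricity(ecc_mask),
        centroid_row=float(arows.mean()),
        centroid_col=float(acols.mean()),
        touches_border=touches,
    )


def measure_instances(imap: InstanceMap,
                      eccentricity_on: str = "axon") -> list[FiberRecord]:
    """Measure every instance of an instance map.

    Instances without axon pixels are skipped (they cannot occur in maps
    produced by :func:`~myelinmorph.segmentation.separate_instances`).
    Records are ordered by instance label.
    """
    records = []
    labels = imap.labels
    for k in imap.instance_ids:
        sel = labels == k
        axon = sel & (imap.roles == AXON)
        if not axon.any():
            continue
        myelin = sel & (imap.roles == MYELIN)
        records.append(measure_fiber(axon, myelin, imap.pixel_size,
                                     fiber_id=int(k),
                                     eccentricity_on=eccentricity_on))
    return records


def fiber_density(n_fibers: int, image_shape: tuple[int, int],
                  pixel_size: float, n_images: int = 1) -> float:
    """Fibers per mm² for ``n_fibers`` over ``n_images`` frames of ``image_shape``."""
    h, w = image_shape
    if h <= 0 or w <= 0 or pixel_size <= 0 or n_images <= 0:
        raise ValueError("image area must be positive")
    area_mm2 = n_images * h * w * pixel_size**2 * 1e-6
    return n_fibers / area_mm2
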