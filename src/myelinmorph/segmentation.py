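"""Semantic masks, per-fiber instance separation and overlap metrics.

The semantic convention follows the myelin-first annotation style used for
CARS fiber images: the myelin ring is the segmented structure and the axon
class is the filled interior ("hole") of each ring.  Masks carry exactly
three classes; on disk they use the 0/127/255 8-bit PNG encoding
(background/myelin/axon) so externally produced model predictions can be
dropped into the pipeline unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology, segmentation as sk_seg

BACKGROUND, MYELIN, AXON = 0, 1, 2

#: 8-connectivity structuring element for axon components (thin diagonal
#: lumens stay connected).
_S8 = np.ones((3, 3), dtype=bool)


@dataclass
class SemanticMask:
    """Three-class pixel labeling (background/myelin/axon) of one image."""

    labels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D array")
        extra = set(np.unique(self.labels)) - {BACKGROUND, MYELIN, AXON}
        if extra:
            raise ValueError(f"labels contain non-class values {sorted(extra)}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def myelin(self) -> np.ndarray:
        return self.labels == MYELIN

    @property
    def axon(self) -> np.ndarray:
        return self.labels == AXON


@dataclass
class InstanceMap:
    """Per-fiber integer labeling plus per-pixel axon/myelin role.

    ``labels`` is 0 for background and ``k`` for fiber ``k``; ``roles``
    holds the semantic class of each labeled pixel.  ``n_orphan_myelin``
    counts discarded myelin components that touched no axon.
    """

    labels: np.ndarray
    roles: np.ndarray
    pixel_size: float
    n_orphan_myelin: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.roles = np.asarray(self.roles)
        if self.labels.shape != self.roles.shape:
            raise ValueError("labels and roles must share a shape")
        if self.labels.min() < 0:
            raise ValueError("instance labels must be non-negative")

    @property
    def instance_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def to_semantic(self) -> SemanticMask:
        """Collapse instances back to the three-class mask."""
        out = np.zeros_like(self.roles, dtype=np.uint8)
        labeled = self.labels > 0
        out[labeled & (self.roles == MYELIN)] = MYELIN
        out[labeled & (self.roles == AXON)] = AXON
        return SemanticMask(labels=out, pixel_size=self.pixel_size)


def baseline_segment(image: np.ndarray, pixel_size: float,
                     threshold: float | None = None,
                     opening_radius_um: float = 0.17,
                     min_myelin_area_um2: float = 0.15) -> SemanticMask:
    """Classical threshold-based myelin/axon segmentation.

    A deterministic surrogate for learned segmentation: myelin = bright
    pixels above an Otsu (or fixed) threshold, cleaned by morphological
    opening and closing with a structuring radius given in µm; the axon
    class is the filled interior of each myelin component.  Bright
    components enclosing no interior hole (two-photon artifact spots) and
    specks below ``min_myelin_area_um2`` are suppressed.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    img = image.astype(float)
    if threshold is None:
        if np.ptp(img) == 0:          # blank frame: nothing to segment
            return SemanticMask(np.zeros(image.shape, np.uint8), pixel_size)
        # tri-modal scenes (background / lumen / bright sheath): the upper
        # multi-Otsu threshold isolates myelin; plain Otsu would split at
        # the dominant background-lumen boundary instead
        try:
            threshold = filters.threshold_multiotsu(img, classes=3)[-1]
        except ValueError:
            threshold = filters.threshold_otsu(img)
    bright = img > threshold

    radius_px = max(1, round(opening_radius_um / pixel_size))
    selem = morphology.disk(radius_px)
    bright = ndimage.binary_opening(bright, structure=selem)
    bright = ndimage.binary_closing(bright, structure=selem)

    min_area_px = min_myelin_area_um2 / pixel_size**2
    out = np.zeros(image.shape, dtype=np.uint8)
    comp, n = ndimage.label(bright, structure=_S8)
    for k in range(1, n + 1):
        ring = comp == k
        if ring.sum() < min_area_px:
            continue
        filled = ndimage.binary_fill_holes(ring)
        hole = filled & ~ring
        if not hole.any():            # no lumen: artifact, not a fiber
            continue
        out[ring] = MYELIN
        out[hole] = AXON
    return SemanticMask(labels=out, pixel_size=pixel_size)


def separate_instances(mask: SemanticMask) -> InstanceMap:
    """Split a semantic mask into per-fiber instances.

    Axon instances are 8-connected components of the axon class; every
    myelin pixel is assigned to the nearest axon component by watershed on
    the Euclidean distance to axon, restricted to fiber pixels.  With
    touching fibers the shared wall is split along the distance ridge (tie
    pixels go to the smaller label).  Myelin components reachable from no
    axon are discarded and counted in ``n_orphan_myelin``.
    """
    axon = mask.axon
    myelin = mask.myelin
    markers, n_axons = ndimage.label(axon, structure=_S8)
    fiber = axon | myelin

    if n_axons == 0:
        labels = np.zeros(mask.labels.shape, dtype=np.uint16)
        _, n_orphans = ndimage.label(myelin, structure=_S8)
        return InstanceMap(labels=labels, roles=mask.labels.copy(),
                           pixel_size=mask.pixel_size,
                           n_orphan_myelin=int(n_orphans))

    dist = ndimage.distance_transform_edt(~axon)
    labels = sk_seg.watershed(dist, markers=markers, mask=fiber)

    # myelin not flooded by any axon marker (disconnected from every lumen)
    orphan = myelin & (labels == 0)
    _, n_orphans = ndimage.label(orphan, structure=_S8)

    roles = mask.labels.copy()
    roles[orphan] = BACKGROUND
    out = labels.astype(np.uint16 if n_axons < 2**16 else np.uint32)
    out[orphan] = 0
    return InstanceMap(labels=out, roles=roles, pixel_size=mask.pixel_size,
                       n_orphan_myelin=int(n_orphans))


def _class_sets(predicted, truth, cls) -> tuple[np.ndarray, np.ndarray]:
    a = predicted.labels if isinstance(predicted, SemanticMask) else np.asarray(predicted)
    b = truth.labels if isinstance(truth, SemanticMask) else np.asarray(truth)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a == cls, b == cls


def dice(predicted, truth, cls: int = AXON) -> float:
    """Sørensen–Dice overlap 2|A∩B|/(|A|+|B|) for one class; both-empty → 1."""
    a, b = _class_sets(predicted, truth, cls)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * (a & b).sum() / denom


def iou(predicted, truth, cls: int = AXON) -> float:
    """Jaccard overlap |A∩B|/|A∪B| for one class; both-empty → 1."""
    a, b = _class_sets(predicted, truth, cls)
    union = (a | b).sum()
    if union == 0:
        return 1.0
    return (a & b).sum() / union
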