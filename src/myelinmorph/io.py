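"""File formats for images, masks, truth tables and fiber records.

Semantic masks use the 0/127/255 8-bit PNG encoding
(background/myelin/axon) compatible with AxonDeepSeg-style outputs;
instance maps are 16-bit PNGs with 0 = background and k = fiber k.  Truth
tables and fiber records travel as headered CSV.
"""

from __future__ import annotations

import math
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from myelinmorph.morphometry import RECORD_FIELDS, FiberRecord
from myelinmorph.segmentation import AXON, BACKGROUND, MYELIN, InstanceMap, SemanticMask
from myelinmorph.synthetic import FiberTruth

#: On-disk gray values for the three semantic classes.
ENCODING = {BACKGROUND: 0, MYELIN: 127, AXON: 255}
DECODING = {v: k for k, v in ENCODING.items()}

TRUTH_COLUMNS = ("fiber_id", "center_row", "center_col", "inner_diameter_um",
                 "myelin_thickness_um", "g_ratio", "axis_ratio",
                 "orientation_rad")


def write_image(path, image: np.ndarray) -> None:
    """8-bit grayscale PNG or TIFF, chosen by extension."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        tifffile.imwrite(path, np.asarray(image, dtype=np.uint8))
    else:
        iio.imwrite(path, np.asarray(image, dtype=np.uint8))


def read_image(path) -> np.ndarray:
    img = iio.imread(path)
    if img.ndim == 3:                 # tolerate gray saved as RGB
        img = img[..., 0]
    return img.astype(np.uint8)


def write_semantic_mask(path, mask: SemanticMask) -> None:
    out = np.zeros(mask.labels.shape, dtype=np.uint8)
    for cls, gray in ENCODING.items():
        out[mask.labels == cls] = gray
    iio.imwrite(Path(path), out)


def read_semantic_mask(path, pixel_size: float) -> SemanticMask:
    raw = read_image(path)
    labels = np.zeros(raw.shape, dtype=np.uint8)
    unknown = set(np.unique(raw)) - set(ENCODING.values())
    if unknown:
        raise ValueError(
            f"mask {path} contains gray values {sorted(unknown)}; expected "
            f"{sorted(ENCODING.values())} (background/myelin/axon)")
    for gray, cls in DECODING.items():
        labels[raw == gray] = cls
    return SemanticMask(labels=labels, pixel_size=pixel_size)


def write_instance_map(path, imap: InstanceMap) -> None:
    if imap.labels.max() >= 2**16:
        raise ValueError("instance labels exceed 16-bit PNG range")
    iio.imwrite(Path(path), imap.labels.astype(np.uint16))


def read_instance_map(path, semantic: SemanticMask) -> InstanceMap:
    """Instance labels from PNG; per-pixel roles come from the paired
    semantic mask."""
    labels = iio.imread(Path(path)).astype(np.uint16)
    if labels.shape != semantic.labels.shape:
        raise ValueError("instance map and semantic mask shapes differ")
    return InstanceMap(labels=labels, roles=semantic.labels.copy(),
                       pixel_size=semantic.pixel_size)


def truths_to_csv(path, truths: list[FiberTruth]) -> None:
    rows = [{
        "fiber_id": t.fiber_id,
        "center_row": t.center[0],
        "center_col": t.center[1],
        "inner_diameter_um": t.inner_diameter,
        "myelin_thickness_um": t.myelin_thickness,
        "g_ratio": t.g_ratio,
        "axis_ratio": t.axis_ratio,
        "orientation_rad": t.orientation,
    } for t in truths]
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(
        path, index=False, float_format="%.17g")


def truths_from_csv(path) -> list[FiberTruth]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        FiberTruth(
            fiber_id=int(r.fiber_id),
            center=(float(r.center_row), float(r.center_col)),
            inner_diameter=float(r.inner_diameter_um),
            myelin_thickness=float(r.myelin_thickness_um),
            g_ratio=float(r.g_ratio),
            axis_ratio=float(r.axis_ratio),
            orientation=float(r.orientation_rad),
        )
        for r in df.itertuples()
    ]


def records_to_csv(path, records: list[FiberRecord]) -> None:
    pd.DataFrame(
        [{f: getattr(r, f) for f in RECORD_FIELDS} for r in records],
        columns=RECORD_FIELDS,
    ).to_csv(path, index=False, float_format="%.17g")


def records_from_csv(path) -> list[FiberRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        FiberRecord(**{f: (bool(getattr(r, f)) if f == "touches_border"
                           else (int(getattr(r, f)) if f == "fiber_id"
                                 else float(getattr(r, f))))
                       for f in RECORD_FIELDS})
        for r in df.itertuples()
    ]


def write_flat_config(path, mapping: dict) -> None:
    """Flat ``key = value`` text file for presets and simple configs."""
    with open(path, "w") as fh:
        for k, v in mapping.items():
            fh.write(f"{k} = {v}\n")


def read_flat_config(path) -> dict[str, str]:
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            k, _, v = line.partition("=")
            out[k.strip()] = v.strip()
    return out
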