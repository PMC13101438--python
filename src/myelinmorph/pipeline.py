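"""End-to-end orchestration: generate → instances → morphometry → QC → stats.

A run is fully reproducible from its config and seed.  Stage outputs are
files in the run directory (so externally produced semantic masks can be
substituted at the instance-separation stage), and a JSON manifest records
versions, seeds and per-stage fiber counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

import myelinmorph
from myelinmorph import io as mio
from myelinmorph.morphometry import measure_instances
from myelinmorph.popstats import BinScheme, summarize
from myelinmorph.qc import QCPolicy, screen
from myelinmorph.segmentation import baseline_segment, separate_instances
from myelinmorph.synthetic import PRESETS, generate_dataset

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, path, cause: Exception):
        super().__init__(f"stage '{stage}' failed on {path}: {cause}")
        self.stage = stage
        self.path = path


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    preset: str = "uf-reference"
    n_images: int = 20
    seed: int = 0
    out_dir: str = "run"
    segmentation: str = "truth"          # "truth" or "baseline"
    eccentricity_on: str = "axon"
    qc: QCPolicy = field(default_factory=QCPolicy)
    bin_edges: tuple[float, ...] = field(
        default_factory=lambda: BinScheme().edges)
    save_images: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        qc = QCPolicy(**raw.pop("qc", {}))
        edges = tuple(raw.pop("bin_edges", BinScheme().edges))
        return cls(qc=qc, bin_edges=edges, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bin_edges"] = list(self.bin_edges)
        return d


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order; returns the manifest (also written
    to ``<out_dir>/manifest.json``)."""
    if config.preset not in PRESETS:
        raise ValueError(f"unknown preset '{config.preset}'; "
                         f"choose from {sorted(PRESETS)}")
    if config.segmentation not in ("truth", "baseline"):
        raise ValueError("segmentation must be 'truth' or 'baseline'")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pop, render = PRESETS[config.preset](seed=config.seed)
    scheme = BinScheme(edges=tuple(config.bin_edges))

    logger.info("generating %d image(s), preset=%s seed=%d",
                config.n_images, config.preset, config.seed)
    try:
        samples = generate_dataset(pop, render, config.n_images, config.seed)
    except Exception as e:                              # pragma: no cover
        raise StageError("generate", config.preset, e) from e

    records = []
    n_generated = n_segmented = 0
    for i, sample in enumerate(samples):
        tag = f"img{i:03d}"
        n_generated += len(sample.truths)
        if config.save_images:
            mio.write_image(out / f"{tag}.png", sample.image)
            mio.write_semantic_mask(out / f"{tag}_mask.png", sample.semantic_truth)
            mio.write_instance_map(out / f"{tag}_inst.png", sample.instance_truth)
            mio.truths_to_csv(out / f"{tag}_truth.csv", sample.truths)
        try:
            if config.segmentation == "truth":
                mask = sample.semantic_truth
            else:
                mask = baseline_segment(sample.image, render.pixel_size)
            imap = separate_instances(mask)
        except Exception as e:
            raise StageError("instances", f"{tag}", e) from e
        try:
            recs = measure_instances(imap, eccentricity_on=config.eccentricity_on)
        except Exception as e:
            raise StageError("morphometry", f"{tag}", e) from e
        # make fiber ids unique across images
        offset = len(records)
        recs = [dataclasses.replace(r, fiber_id=r.fiber_id + offset)
                for r in recs]
        n_segmented += len(recs)
        records.extend(recs)

    mio.records_to_csv(out / "records.csv", records)

    result = screen(records, config.qc)
    mio.records_to_csv(out / "kept.csv", result.kept)
    removed_rows = [
        {"fiber_id": r.fiber_id, "reasons": "|".join(reasons)}
        for r, reasons in result.removed
    ]
    import pandas as pd
    pd.DataFrame(removed_rows, columns=["fiber_id", "reasons"]).to_csv(
        out / "removed.csv", index=False)

    total_area = config.n_images * render.image_area_mm2
    summary = summarize(result.kept, total_area, scheme) if config.n_images \
        else None
    if summary is not None:
        summary.per_bin.to_csv(out / "bins.csv", index=False)
        overall = {
            "n_kept": summary.n,
            "mean_diameter_um": summary.mean_diameter,
            "sd_diameter_um": summary.sd_diameter,
            "mean_thickness_um": summary.mean_thickness,
            "sd_thickness_um": summary.sd_thickness,
            "mean_g_ratio": summary.mean_g,
            "sd_g_ratio": summary.sd_g,
            "density_per_mm2": summary.density_per_mm2,
            "r2_thickness_vs_diameter": summary.r2_thickness_vs_diameter,
            "r2_g_vs_diameter": summary.r2_g_vs_diameter,
        }
        pd.DataFrame([overall]).to_csv(out / "summary.csv", index=False)
        summary.correlations.to_csv(out / "correlations.csv")
        summary.correlation_p.to_csv(out / "correlation_p.csv")
    else:
        overall = {}

    manifest = {
        "package_version": myelinmorph.__version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
        "config": config.to_dict(),
        "counts": {
            "images": config.n_images,
            "fibers_generated": n_generated,
            "fibers_segmented": n_segmented,
            "fibers_kept": len(result.kept),
            "fibers_removed": len(result.removed),
        },
        "total_area_mm2": total_area,
        "summary": overall,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("run complete: %s", manifest["counts"])
    return manifest
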