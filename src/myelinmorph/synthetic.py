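"""Seeded generator of CARS-like images of myelinated fiber cross-sections.

CARS microscopy of white matter shows myelin as bright annular rings (the
CH2-rich lipid sheath), axon lumens and background as dark, plus occasional
bright spots from concurrent two-photon emission.  The generator emulates
those features in 2-D with exact per-fiber ground truth, so that instance
separation, morphometry, quality control and population statistics can all
be verified against known geometry.

Fiber populations are described by an area-equivalent inner (axon) diameter
``d`` drawn from a lognormal law, and a g-ratio (inner/outer diameter) that
rises linearly with ``d`` plus Gaussian noise.  Myelin thickness follows
from the identity ``g = d / (d + 2 m)``.  Fibers are elliptical with an
area-preserving axis ratio, so the analytic area-equivalent diameters are
exactly the circle-equivalent diameters a downstream measurement should
recover.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, stats

from myelinmorph.segmentation import AXON, BACKGROUND, MYELIN, InstanceMap, SemanticMask

logger = logging.getLogger(__name__)

#: g-ratio draws are clipped into this open interval so that every generated
#: truth passes the (0, 1) quality screen by construction.
G_CLIP = (0.05, 0.95)

#: Guard margin (px) kept between outer envelopes of neighbouring fibers and
#: between fibers and the image border.
GUARD_PX = 1.0

#: Refuse placement when the summed bounding-circle area of the requested
#: fibers exceeds this fraction of the image; random sequential packing
#: cannot realistically exceed it.
MAX_PACKING_FRACTION = 0.5


class PackingError(RuntimeError):
    """Requested fiber density is geometrically impossible to place."""


@dataclass(frozen=True)
class PopulationParams:
    """Statistical description of a fiber population.

    Diameters are in µm; ``target_density`` is in fibers per mm².  The
    g-ratio model is ``g = clip(g_intercept + g_slope * d + eps)`` with
    ``eps ~ Normal(0, g_noise_sd)`` and clipping to the open interval
    ``G_CLIP``.
    """

    mean_diameter: float
    sd_diameter: float
    min_diameter: float
    g_intercept: float
    g_slope: float
    g_noise_sd: float
    axis_ratio_range: tuple[float, float]
    target_density: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_diameter <= 0:
            raise ValueError("mean_diameter must be positive")
        if self.sd_diameter < 0:
            raise ValueError("sd_diameter must be non-negative")
        if self.min_diameter < 0:
            raise ValueError("min_diameter must be non-negative")
        if not 0 < self.g_intercept < 1:
            raise ValueError("g_intercept must lie in (0, 1)")
        if self.target_density <= 0:
            raise ValueError("target_density must be positive")
        lo, hi = self.axis_ratio_range
        if not 1.0 <= lo <= hi:
            raise ValueError("axis_ratio_range must satisfy 1 <= lo <= hi")


@dataclass(frozen=True)
class RenderParams:
    """Imaging model: geometry of the frame and the intensity/noise model.

    Defaults correspond to 8-bit 500×1000 px acquisition at 0.166 µm/px.
    Artifacts are bright disks added to the image only, never to the truth
    masks (they model acquisition artifacts, not fibers).
    """

    pixel_size: float = 0.166          # µm per pixel
    image_height: int = 500
    image_width: int = 1000
    bit_depth: int = 8
    myelin_intensity: float = 200.0
    axon_intensity: float = 25.0
    background_intensity: float = 50.0
    psf_sigma: float = 1.0             # px, Gaussian blur emulating the PSF
    noise_sd: float = 8.0              # additive Gaussian, intensity units
    artifact_rate: float = 3.0         # expected bright spots per image
    artifact_intensity: float = 255.0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        for name in ("myelin_intensity", "axon_intensity",
                     "background_intensity", "artifact_intensity"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"{name} must lie in [0, 255]")
        if self.myelin_intensity <= self.background_intensity:
            raise ValueError("myelin must be brighter than background")
        if self.psf_sigma < 0 or self.noise_sd < 0 or self.artifact_rate < 0:
            raise ValueError("psf_sigma, noise_sd, artifact_rate must be >= 0")

    @property
    def image_area_mm2(self) -> float:
        return self.image_height * self.image_width * self.pixel_size**2 * 1e-6


@dataclass(frozen=True)
class FiberTruth:
    """Ground-truth geometry of one simulated fiber.

    ``inner_diameter`` is the area-equivalent diameter of the axon lumen and
    ``myelin_thickness`` the equivalent-circle sheath half-width, so that
    ``g_ratio == inner / (inner + 2*thickness)`` exactly.  ``center`` is in
    (row, col) pixel coordinates; ``(nan, nan)`` for not-yet-placed fibers.
    """

    fiber_id: int
    center: tuple[float, float]
    inner_diameter: float      # µm
    myelin_thickness: float    # µm
    g_ratio: float
    axis_ratio: float
    orientation: float         # radians

    def __post_init__(self) -> None:
        expected = self.inner_diameter / (self.inner_diameter + 2 * self.myelin_thickness)
        if abs(self.g_ratio - expected) > 1e-9:
            raise ValueError("g_ratio inconsistent with diameter and thickness")

    @property
    def outer_diameter(self) -> float:
        return self.inner_diameter + 2 * self.myelin_thickness

    @property
    def eccentricity(self) -> float:
        # area-preserving ellipse: minor/major = 1/axis_ratio
        return math.sqrt(1.0 - 1.0 / self.axis_ratio**2)


@dataclass
class SyntheticSample:
    """One rendered image together with its exact truth."""

    image: np.ndarray
    semantic_truth: SemanticMask
    instance_truth: InstanceMap
    truths: list[FiberTruth]
    render: RenderParams

    def __post_init__(self) -> None:
        ids = {t.fiber_id for t in self.truths}
        labels = set(np.unique(self.instance_truth.labels)) - {0}
        if ids != labels:
            raise ValueError("truth table and instance map disagree on fiber ids")


# ---------------------------------------------------------------------------
# diameter law


def lognormal_moment_params(mean: float, sd: float) -> tuple[float, float]:
    """Closed-form lognormal parameters (µ, σ) matching untruncated moments.

    ``σ² = ln(1 + (sd/mean)²)``, ``µ = ln(mean) − σ²/2``.
    """
    if mean <= 0 or sd < 0:
        raise ValueError("need mean > 0 and sd >= 0")
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def truncated_lognormal_params(mean: float, sd: float,
                               lower: float) -> tuple[float, float]:
    """Lognormal parameters such that the left-truncated law has the given moments.

    The target mean/SD describe the population *after* discarding values
    below ``lower`` (this is how observed, detection-floored diameter
    statistics are reported).  Reduces to the closed form when ``lower`` is
    zero or carries negligible mass.
    """
    if lower <= 0:
        return lognormal_moment_params(mean, sd)
    if lower >= mean:
        raise ValueError(
            f"truncation floor {lower} is not below the requested mean {mean}")

    def trunc_moments(p: np.ndarray) -> tuple[float, float]:
        mu, sig = p
        a = (math.log(lower) - mu) / sig
        tail = stats.norm.sf(a)
        m1 = math.exp(mu + sig**2 / 2) * stats.norm.sf(a - sig) / tail
        m2 = math.exp(2 * mu + 2 * sig**2) * stats.norm.sf(a - 2 * sig) / tail
        return m1, math.sqrt(max(m2 - m1**2, 0.0))

    x0 = np.asarray(lognormal_moment_params(mean, sd))
    # negligible truncated mass: closed form is already the answer
    a0 = (math.log(lower) - x0[0]) / max(x0[1], 1e-12)
    if stats.norm.cdf(a0) < 1e-12:
        return float(x0[0]), float(x0[1])

    def resid(p):
        m, s = trunc_moments(p)
        return [m - mean, s - sd]

    sol, _info, ier, msg = optimize.fsolve(resid, x0, full_output=True)
    if ier != 1 or abs(resid(sol)[0]) > 1e-8 * mean:
        raise ValueError(f"unsatisfiable truncation ({msg})")
    return float(sol[0]), float(sol[1])


def sample_population(params: PopulationParams, area_mm2: float) -> list[FiberTruth]:
    """Draw fiber truths for a field of view of ``area_mm2`` mm².

    The number of fibers is ``round(target_density * area)``.  Inner
    diameters follow a lognormal law whose truncated-at-``min_diameter``
    moments equal ``(mean_diameter, sd_diameter)``; truncation is exact via
    inverse-CDF sampling.  Returned fibers are unplaced (``center`` is NaN).
    """
    if area_mm2 <= 0:
        raise ValueError("area must be positive")
    count = round(params.target_density * area_mm2)
    if count == 0:
        return []
    rng = np.random.default_rng(params.seed)

    if params.sd_diameter == 0:
        if params.mean_diameter < params.min_diameter:
            raise ValueError("mean_diameter below truncation floor")
        d = np.full(count, params.mean_diameter)
    else:
        mu, sig = truncated_lognormal_params(
            params.mean_diameter, params.sd_diameter, params.min_diameter)
        lo = 0.0
        if params.min_diameter > 0:
            lo = stats.norm.cdf((math.log(params.min_diameter) - mu) / sig)
        u = rng.uniform(lo, 1.0, count)
        d = np.exp(mu + sig * stats.norm.ppf(u))

    eps = rng.normal(0.0, params.g_noise_sd, count) if params.g_noise_sd > 0 \
        else np.zeros(count)
    g = np.clip(params.g_intercept + params.g_slope * d + eps, *G_CLIP)
    m = d * (1.0 - g) / (2.0 * g)
    q = rng.uniform(*params.axis_ratio_range, count)
    theta = rng.uniform(0.0, math.pi, count)

    return [
        FiberTruth(
            fiber_id=i + 1,
            center=(math.nan, math.nan),
            inner_diameter=float(d[i]),
            myelin_thickness=float(m[i]),
            g_ratio=float(d[i] / (d[i] + 2 * m[i])),
            axis_ratio=float(q[i]),
            orientation=float(theta[i]),
        )
        for i in range(count)
    ]


# ---------------------------------------------------------------------------
# placement and rendering


def _outer_semi_major_px(t: FiberTruth, pixel_size: float) -> float:
    return (t.outer_diameter / 2.0) * math.sqrt(t.axis_ratio) / pixel_size


def place_fibers(truths: list[FiberTruth], render: RenderParams, seed: int,
                 max_tries: int = 200) -> list[FiberTruth]:
    """Assign non-overlapping centers by rejection sampling.

    Outer envelopes (bounding circles of the outer ellipses, plus a 1-px
    guard) are kept pairwise disjoint and fully inside the frame.  Fibers
    that cannot be placed within ``max_tries`` attempts are dropped; the
    drop count is the difference in list lengths and is logged.
    """
    H, W = render.image_height, render.image_width
    radii = [_outer_semi_major_px(t, render.pixel_size) + GUARD_PX for t in truths]
    for t, r in zip(truths, radii):
        if 2 * r > min(H, W):
            raise PackingError(
                f"fiber {t.fiber_id} (outer envelope {2*r:.0f} px) does not fit")
    if sum(math.pi * r**2 for r in radii) > MAX_PACKING_FRACTION * H * W:
        raise PackingError("requested density exceeds the packing bound")

    rng = np.random.default_rng(seed)
    placed: list[FiberTruth] = []
    placed_r: list[float] = []
    dropped = 0
    # place large fibers first: random sequential packing succeeds far more
    # often, and order is restored afterwards
    order = sorted(range(len(truths)), key=lambda i: -radii[i])
    placed_by_index: dict[int, FiberTruth] = {}
    for i in order:
        t, r = truths[i], radii[i]
        ok = False
        for _ in range(max_tries):
            row = rng.uniform(r, H - 1 - r)
            col = rng.uniform(r, W - 1 - r)
            if all((row - p.center[0]) ** 2 + (col - p.center[1]) ** 2
                   > (r + pr) ** 2
                   for p, pr in zip(placed, placed_r)):
                ok = True
                break
        if not ok:
            dropped += 1
            continue
        pt = dataclasses.replace(t, center=(float(row), float(col)))
        placed.append(pt)
        placed_r.append(r)
        placed_by_index[i] = pt
    if dropped:
        logger.warning("place_fibers dropped %d of %d fibers", dropped, len(truths))
    return [placed_by_index[i] for i in sorted(placed_by_index)]


def _rasterize_fiber(t: FiberTruth, shape: tuple[int, int],
                     pixel_size: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boolean axon and myelin masks for one fiber on its bounding box.

    A pixel belongs to a region iff its center lies inside the analytic
    ellipse boundary.  Returns (rows slice array, axon mask, myelin mask)
    packed as (index arrays) for in-place assignment.
    """
    H, W = shape
    r0, c0 = t.center
    sq = math.sqrt(t.axis_ratio)
    r_in = (t.inner_diameter / 2.0) / pixel_size
    r_out = (t.outer_diameter / 2.0) / pixel_size
    a_in, b_in = r_in * sq, r_in / sq
    a_out, b_out = r_out * sq, r_out / sq

    pad = int(math.ceil(a_out)) + 1
    rlo, rhi = max(0, int(r0) - pad), min(H, int(r0) + pad + 1)
    clo, chi = max(0, int(c0) - pad), min(W, int(c0) + pad + 1)
    rows = np.arange(rlo, rhi)[:, None] - r0
    cols = np.arange(clo, chi)[None, :] - c0
    ct, st = math.cos(t.orientation), math.sin(t.orientation)
    u = cols * ct + rows * st
    v = -cols * st + rows * ct
    inner = (u / a_in) ** 2 + (v / b_in) ** 2 <= 1.0
    outer = (u / a_out) ** 2 + (v / b_out) ** 2 <= 1.0
    return (slice(rlo, rhi), slice(clo, chi)), inner, outer & ~inner


def render_sample(truths: list[FiberTruth], render: RenderParams,
                  seed: int) -> SyntheticSample:
    """Render placed fibers into an 8-bit image plus exact truth masks.

    Truth masks are rasterized from the unblurred geometry; the image gets
    a Gaussian PSF blur, additive Gaussian noise and Poisson-count bright
    artifact disks (image only, never the masks).
    """
    H, W = render.image_height, render.image_width
    for t in truths:
        if not (math.isfinite(t.center[0]) and math.isfinite(t.center[1])):
            raise ValueError(f"fiber {t.fiber_id} has no placement")

    inst = np.zeros((H, W), dtype=np.uint16)
    roles = np.zeros((H, W), dtype=np.uint8)
    for t in truths:
        window, axon, myelin = _rasterize_fiber(t, (H, W), render.pixel_size)
        inst_w = inst[window]
        roles_w = roles[window]
        inst_w[axon | myelin] = t.fiber_id
        roles_w[myelin] = MYELIN
        roles_w[axon] = AXON

    img = np.full((H, W), render.background_intensity, dtype=float)
    img[roles == MYELIN] = render.myelin_intensity
    img[roles == AXON] = render.axon_intensity
    if render.psf_sigma > 0:
        img = ndimage.gaussian_filter(img, render.psf_sigma)

    rng = np.random.default_rng(seed)
    if render.artifact_rate > 0:
        for _ in range(rng.poisson(render.artifact_rate)):
            ar = rng.uniform(1.5, 4.0)
            arow = rng.uniform(0, H - 1)
            acol = rng.uniform(0, W - 1)
            rows = np.arange(max(0, int(arow - ar) - 1), min(H, int(arow + ar) + 2))
            cols = np.arange(max(0, int(acol - ar) - 1), min(W, int(acol + ar) + 2))
            rr, cc = np.meshgrid(rows, cols, indexing="ij")
            spot = (rr - arow) ** 2 + (cc - acol) ** 2 <= ar**2
            img[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1][spot] = \
                render.artifact_intensity
    if render.noise_sd > 0:
        img = img + rng.normal(0.0, render.noise_sd, img.shape)
    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    semantic = SemanticMask(labels=roles.copy(), pixel_size=render.pixel_size)
    instance = InstanceMap(labels=inst, roles=roles, pixel_size=render.pixel_size)
    return SyntheticSample(image=image, semantic_truth=semantic,
                           instance_truth=instance, truths=list(truths),
                           render=render)


def generate_dataset(pop: PopulationParams, render: RenderParams,
                     n_images: int, seed: int) -> list[SyntheticSample]:
    """Generate ``n_images`` independent seeded samples at the target density."""
    samples = []
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n_images):
        s1, s2, s3 = child.generate_state(3)
        pop_i = dataclasses.replace(pop, seed=int(s1 % 2**31))
        truths = sample_population(pop_i, render.image_area_mm2)
        placed = place_fibers(truths, render, int(s2 % 2**31))
        samples.append(render_sample(placed, render, int(s3 % 2**31)))
    return samples


# ---------------------------------------------------------------------------
# presets


def uf_reference_preset(seed: int = 0) -> tuple[PopulationParams, RenderParams]:
    """Population and imaging parameters emulating deep-white-matter
    (uncinate-fasciculus-like) myelinated fibers.

    Frozen constants: diameters average 0.93 µm (SD 0.54) above a 0.37 µm
    detection floor at 844.36 fibers/mm²; the linear g–diameter law
    (intercept 0.3591, slope 0.1193 /µm, noise SD 0.0684) was calibrated
    once so the population mean g-ratio is 0.47 with an R² of ~0.47 for
    g against diameter and an SD of g of ~0.094, and matching mean myelin
    thickness of ~0.5 µm.  Imaging: 500×1000 px at 0.166 µm/px, 8-bit.
    """
    pop = PopulationParams(
        mean_diameter=0.93,
        sd_diameter=0.54,
        min_diameter=0.37,
        g_intercept=0.3591,
        g_slope=0.1193,
        g_noise_sd=0.0684,
        axis_ratio_range=(1.0, 1.7),
        target_density=844.36,
        seed=seed,
    )
    return pop, RenderParams()


def oblique_stress_preset(seed: int = 0) -> tuple[PopulationParams, RenderParams]:
    """Stress preset with strongly elongated (obliquely cut) fibers.

    Axis ratios up to 3.5 give eccentricities past the 0.9 screening
    threshold, exercising the quality-control path that the reference
    preset deliberately avoids.
    """
    pop, render = uf_reference_preset(seed)
    pop = dataclasses.replace(pop, axis_ratio_range=(1.8, 3.5))
    return pop, render


PRESETS = {
    "uf-reference": uf_reference_preset,
    "oblique-stress": oblique_stress_preset,
}
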