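# Methods

## The measurement model

A myelinated fiber imaged in cross-section is modeled as two concentric
ellipses: the axon lumen and the surrounding myelin sheath.  All reported
diameters are area-equivalent — d = 2·√(A/π) for region area A — so the
defining identities

    g = d_inner / d_outer,      m = (d_outer − d_inner) / 2

hold exactly for every record, with d_inner measured on axon pixels only
and d_outer on the union of axon and myelin pixels of one instance.
Eccentricity is the best-fit-ellipse value √(1 − (b/a)²) from normalized
second central moments.  It is computed on the **axon** region by default:
the lumen is the better-conditioned ellipse because the sheath's outline
is what segmentation errors corrupt first.  A switch
(`eccentricity_on="fiber"`) computes it on axon+myelin instead; which
region the established convention uses is genuinely ambiguous, so both are
exposed and the default is documented rather than asserted.

Border-touching fibers are measured and flagged (`touches_border`) but
retained; density counts all kept fibers over the full imaged area.

## Synthetic fiber populations

The generator's purpose is an *exact oracle*: every downstream stage can
be checked against analytic ground truth.  Its defaults (the
`uf-reference` preset) describe a deep white-matter population:

| parameter | value | meaning |
|---|---|---|
| mean_diameter | 0.93 µm | mean inner diameter of the observed population |
| sd_diameter | 0.54 µm | SD of inner diameter |
| min_diameter | 0.37 µm | detection floor (smallest observable fiber) |
| g_intercept / g_slope | 0.3591 / 0.1193 µm⁻¹ | linear g–d law |
| g_noise_sd | 0.0684 | per-fiber g scatter |
| axis_ratio_range | 1.0–1.7 | elliptical elongation (ecc ≤ 0.81) |
| target_density | 844.36 mm⁻² | fibers per area |
| pixel_size | 0.166 µm | 500×1000 px, 8-bit frames |

**Diameter law.** Inner diameters follow a lognormal distribution
(right-skewed, positive support — the standard shape for axon calibers)
truncated below the detection floor.  The lognormal parameters are solved
numerically so that the *truncated* distribution has the requested
mean/SD, because the quoted statistics describe the observed (already
floored) population; naive untruncated moment matching would bias the
realized mean up by ~0.05 µm at these parameters.  With no floor the
closed form σ² = ln(1+(sd/mean)²), µ = ln(mean)−σ²/2 applies, and the
solver reduces to it.  Sampling uses the inverse CDF on a uniform draw
restricted to the kept tail, so truncation is exact and deterministic
given the seed.  A floor at or above the requested mean is rejected as
unsatisfiable.

**g–d law.** g = clip(intercept + slope·d + ε), ε ~ N(0, σ), clipped to
(0.05, 0.95) so every generated truth passes the quality screen by
construction.  g rising with d is the expected physiology (thicker axons
are relatively less myelinated).  The three constants were calibrated
once, by Monte Carlo at n = 2×10⁶, against the three population targets —
mean g = 0.47, SD(g) ≈ 0.094, R²(g~d) ≈ 0.47 — and then frozen.  The
mean-g and R² conditions leave one degree of freedom; it is fixed by
matching SD(g).  The implied mean myelin thickness of the population is
≈0.50 µm.  Myelin thickness per fiber follows from the g identity,
m = d(1−g)/(2g), so truths are self-consistent to 1e-9 by construction.

**Placement.** Centers are drawn by rejection sampling so that bounding
circles of the outer ellipses (semi-major axis plus a 1-px guard) are
pairwise disjoint and fully inside the frame.  Real fibers can abut;
disjoint truth is chosen deliberately so instance evaluation has an
unambiguous oracle.  Large fibers are placed first (restoring input order
afterwards), which makes random sequential packing reliable at the
reference density; a fiber unplaced after 200 tries is dropped with a
logged warning, and a requested configuration whose summed envelope area
exceeds half the frame is rejected up front as geometrically infeasible.

**Rendering.** A pixel belongs to a region iff its center lies inside the
analytic ellipse; truth masks are rasterized from the unblurred geometry.
Ellipse axes are scaled as (r√q, r/√q) for axis ratio q, preserving area,
so the analytic area-equivalent diameter of each region equals the
generating diameter exactly.  The image is the three-level intensity map
(background 50, lumen 25, myelin 200 of 255) blurred by a Gaussian PSF
(σ = 1 px), plus additive Gaussian noise (SD 8) and a Poisson number
(mean 3/frame) of bright disks emulating concurrent two-photon artifact
spots.  Artifacts corrupt the image only, never the truth masks — they
are acquisition artifacts, not fibers.

**What the generator does not emulate.** Physically realistic CARS image
formation (coherent/nonlinear PSF, speckle), touching or overlapping
fibers, unmyelinated axons (invisible at the CH2 band), orientation
anisotropy of a real tract, intensity inhomogeneity across the field, and
3-D structure.  Passing tests therefore demonstrate the correctness of the
measurement chain on well-posed annular geometry, not segmentation
robustness on real tissue.  The paper-reported fiber statistics used for
the preset also do not constrain orientation or eccentricity
distributions; uniform orientation and axis ratios in [1.0, 1.7] are a
documented choice, and an `oblique-stress` preset (axis ratios 1.8–3.5)
exercises the eccentricity screen that the reference preset deliberately
avoids.

## Segmentation and instance separation

Semantic masks hold exactly three classes; on disk they use the 0/127/255
gray encoding so externally produced model predictions can enter the
pipeline at any stage.  The bundled `baseline_segment` is a classical
surrogate, not a learned model: myelin = pixels above the upper
three-class multi-Otsu threshold (plain Otsu splits at the dominant
background/lumen boundary on these tri-modal scenes), cleaned by binary
opening/closing with a structuring radius given in µm (default 0.17 µm
≈ 1 px); the axon class is the filled interior of each myelin component
(myelin-first, hole-fill convention); bright components with no interior
hole — artifact spots — and specks below 0.15 µm² are suppressed.

Instances: axon components are 8-connected (thin diagonal lumens stay
whole).  Myelin pixels are assigned to the nearest axon component by
watershed on the Euclidean distance-to-axon transform restricted to
fiber pixels — verified against a brute-force nearest-component oracle on
shared-wall fixtures (ridge pixels at near-exact ties may fall either
way).  Myelin components that no axon can reach are discarded and counted
(`n_orphan_myelin`).  Dice and IoU use the standard set definitions with
the both-empty case defined as 1.0 (a stated convention, tested).

## Quality control

Records are kept iff 0 < g < 1 **and** d ≥ 0.335 µm **and** ecc ≤ 0.9,
with literal boundary semantics: d = 0.335 is kept (only *below* is
removed), ecc = 0.9 is kept (only *exceeding* is removed), and g exactly
1 — zero measured myelin — is removed.  The 0.335 µm floor is taken
verbatim even though 2 px × 0.166 µm = 0.332 µm; the printed threshold
wins.  Removed records carry every violated rule; non-finite metrics
remove a record with reason `invalid`.  Screening is order-preserving,
partitions its input, and is idempotent.

## Population statistics

Diameter bins are half-open [lo, hi) on edges
(0.335, 0.5, 0.75, 1.0, 1.25, 1.5, 1.75) with a final open-ended 1.75+
bin — seven bins consistent with 0.25 µm increments; the first bin's upper
edge is read as 0.5 (the alternative reading, a sliver bin 0.335–0.35,
is inconsistent with the stated increments), and the scheme is fully
overridable.  SDs are sample (n−1) throughout.  Correlations are Pearson
r with two-sided p; R² comes from ordinary least squares of
thickness~diameter and g~diameter.  With fewer than two records (or a
constant regressor) these are reported as NaN markers, never raised.
Region comparison is purely descriptive per-bin mean±SD side by side;
empty bins stay NaN, not zero.  Density is computed post-QC (whether a
published density is pre- or post-screen is typically unstated; post-QC
is the conservative, reproducible choice).

## Pulse optics

Gaussian pulse model throughout, with the time-bandwidth product
TBP = 0.441 (2·ln2/π) by default; 0.315 selects sech².  Conversions:

* Raman shift: Δω̃ = 10⁷·(1/λ_pump − 1/λ_Stokes) cm⁻¹; 805/1045 nm gives
  2852.98 cm⁻¹, within 0.3% of the 2845 cm⁻¹ CH2 design target.
* Transform limit: Δν = c·Δλ/λ², τ = TBP/Δν.  9.0 nm at 805 nm → 105.9 fs;
  7.3 nm at 1045 nm → 220.3 fs.
* GDD of a dispersive element from its fiber-style dispersion parameter:
  |φ₂| = D·λ²·L/(2πc).  103 ps/nm/km over 19.6 cm at 805 nm → 6.94×10³
  fs².  The magnitude is returned; the rod's chirp sign (negative in the
  ω-convention) does not enter the stretch law.
* Chirped duration: τ_out = τ·√(1 + (4·ln2·φ₂/τ²)²), ≥ τ with equality
  iff φ₂ = 0.

**Known discrepancy.** With the stated rod (19.6 cm, 103 ps/nm/km) and
bandwidth, the standard Gaussian chirp law stretches the 105.9 fs pump by
×1.99 (to ≈210 fs), not the ×2.44 (250 fs) quoted for this setup;
similarly the quoted Stokes figures (1.03× at 233 fs) imply a ≈226 fs
transform limit versus 220 fs from TBP 0.441.  Possible causes include a
different duration convention or additional dispersive elements in the
beam path.  The standard law is implemented as stated and the TBP is
configurable; the ×2.44 figure is not treated as a target.

The delay-scan model is I(τ) ∝ ∫ I_p(t)²·I_s(t−τ) dt (two pump photons,
one Stokes), evaluated in closed form for Gaussian envelopes — the scan is
Gaussian with FWHM² = τ_p²/2 + τ_s² — and verified against brute-force
trapezoid integration.  Spectral FWHM of a measured spectrum subtracts a
linear baseline fitted to the flanks outside the analysis window
(2800–3100 cm⁻¹ by default), normalizes the peak, and interpolates the
half-maximum crossings linearly; a windowed signal with no crossing on
both sides is an error, not a guess.

## Problem sizes and numerical choices

The reference analysis uses 20 frames of 500×1000 px (0.2756 mm² total,
~12 fibers/frame, ~240 fibers) — enough that the recovered means sit well
within three standard errors of the generating values while a full run
stays around ten seconds.  Determinism: every stochastic step takes a
seed; per-image seeds are spawned from the run seed via
`numpy.random.SeedSequence`, so runs are bit-reproducible and images are
independent.  Sub-resolution caveat: a 0.4 µm lumen covers ~4.5 px, so a
single fiber's measured g carries unbiased quantization error up to
±0.08 depending on subpixel position; population averages are unaffected
(the 20-image run recovers mean g to <0.01), but per-fiber values near
the detection floor should be treated as quantization-limited.  A small
fraction of floor-adjacent fibers rasterize below the 0.335 µm QC
threshold or to degenerate (collinear-pixel) lumens and are screened out,
which is why ~1% of truth fibers are removed and the realized density
runs ~2% above nominal rounding effects.

## Limitations

No learned segmentation is included (the analysis accepts external mask
predictions instead); no 3-D volumes; no axonal-pathology metrics; no
estimate of total (myelinated + unmyelinated) axon density, which this
contrast mechanism cannot see; the optics module computes design-point
quantities, not hyperspectral sweeps or hardware control.
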