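"""Spectral-focusing CARS pulse optics.

Design and validation computations for a two-beam (pump/Stokes) CARS
microscope that chirps femtosecond pulses through a glass rod so that the
instantaneous frequency difference of the stretched pulses selects one
Raman band (spectral focusing):

* Raman-shift targeting from the pump and Stokes wavelengths,
* transform-limited and chirped Gaussian pulse durations,
* group-delay dispersion of a dispersive element from its fiber-optics
  dispersion parameter D (ps/nm/km),
* FWHM of a measured Raman/CARS spectrum with linear baseline correction,
* the delay-scan cross-correlation model I(τ) ∝ ∫ I_p(t)² I_s(t−τ) dt.

All durations are intensity FWHM in fs.  The Gaussian time-bandwidth
product 0.441 is the default; 0.315 selects a sech² pulse model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

C_NM_PER_FS = 299.792458        # speed of light, nm/fs
C_M_PER_S = 2.99792458e8

TBP_GAUSSIAN = 0.441
TBP_SECH2 = 0.315


@dataclass(frozen=True)
class LaserPulse:
    """One excitation beam: center wavelength, bandwidth, optional duration.

    When ``duration_fwhm_fs`` is omitted the pulse is assumed
    transform-limited for its bandwidth.
    """

    center_wavelength_nm: float
    spectral_fwhm_nm: float
    duration_fwhm_fs: float | None = None
    tbp: float = TBP_GAUSSIAN

    def __post_init__(self) -> None:
        if self.center_wavelength_nm <= 0 or self.spectral_fwhm_nm <= 0:
            raise ValueError("wavelength and bandwidth must be positive")
        tl = self.transform_limited_fs
        if self.duration_fwhm_fs is not None and self.duration_fwhm_fs < tl * (1 - 1e-9):
            raise ValueError(
                f"duration {self.duration_fwhm_fs} fs below the transform "
                f"limit {tl:.1f} fs for this bandwidth")

    @property
    def transform_limited_fs(self) -> float:
        return transform_limited_duration(self.spectral_fwhm_nm,
                                          self.center_wavelength_nm, self.tbp)

    @property
    def duration_fs(self) -> float:
        return self.duration_fwhm_fs if self.duration_fwhm_fs is not None \
            else self.transform_limited_fs


@dataclass(frozen=True)
class DispersiveElement:
    """A dispersive optic characterized by length and fiber-style D.

    ``dispersion_ps_nm_km`` may be a single value or a mapping
    ``{wavelength_nm: D}`` when the element is used at several wavelengths.
    """

    length_cm: float
    dispersion_ps_nm_km: float | dict[float, float]

    def __post_init__(self) -> None:
        if self.length_cm < 0:
            raise ValueError("length must be non-negative")

    def dispersion_at(self, wavelength_nm: float) -> float:
        d = self.dispersion_ps_nm_km
        if isinstance(d, dict):
            try:
                return d[wavelength_nm]
            except KeyError:
                raise KeyError(
                    f"no dispersion value tabulated at {wavelength_nm} nm")
        return d


@dataclass
class Spectrum:
    """Two-column spectrum: wavenumber (cm⁻¹, strictly ascending) vs intensity."""

    wavenumber: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.wavenumber = np.asarray(self.wavenumber, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavenumber.shape != self.intensity.shape or self.wavenumber.ndim != 1:
            raise ValueError("wavenumber and intensity must be equal-length 1-D")
        if not np.all(np.diff(self.wavenumber) > 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")

    @classmethod
    def from_file(cls, path) -> "Spectrum":
        data = np.loadtxt(path, delimiter=None if _is_whitespace(path) else ",")
        return cls(wavenumber=data[:, 0], intensity=data[:, 1])


def _is_whitespace(path) -> bool:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                return "," not in line
    return True


def raman_shift(pump_nm: float, stokes_nm: float) -> float:
    """Raman shift (cm⁻¹) probed by a pump/Stokes pair: 10⁷·(1/λp − 1/λs)."""
    if pump_nm <= 0:
        raise ValueError("pump wavelength must be positive")
    if stokes_nm < pump_nm:
        raise ValueError("Stokes wavelength must be >= pump wavelength")
    return 1e7 * (1.0 / pump_nm - 1.0 / stokes_nm)


def transform_limited_duration(spectral_fwhm_nm: float, center_nm: float,
                               tbp: float = TBP_GAUSSIAN) -> float:
    """Shortest intensity-FWHM duration (fs) for a given bandwidth.

    Δν = c·Δλ/λ²; τ = TBP/Δν with the Gaussian time-bandwidth product by
    default.
    """
    if spectral_fwhm_nm <= 0 or center_nm <= 0 or tbp <= 0:
        raise ValueError("inputs must be positive")
    dnu_per_fs = C_NM_PER_FS * spectral_fwhm_nm / center_nm**2   # 1/fs
    return tbp / dnu_per_fs


def group_delay_dispersion(element: DispersiveElement,
                           wavelength_nm: float) -> float:
    """|φ₂| (fs²) of an element with dispersion D (ps/nm/km) at a wavelength.

    |φ₂| = D·λ²·L/(2πc).  The magnitude is returned; material chirp sign is
    tracked separately by the caller (here the rod applies a negative
    chirp in the ω-convention; only the magnitude enters the Gaussian
    stretch law).
    """
    d_si = element.dispersion_at(wavelength_nm) * 1e-6     # s/m² from ps/nm/km
    lam = wavelength_nm * 1e-9
    length = element.length_cm * 1e-2
    phi2_s2 = abs(d_si) * lam**2 * length / (2 * math.pi * C_M_PER_S)
    return phi2_s2 * 1e30                                   # fs²


def chirped_duration(tl_duration_fs: float,
                     gdd_fs2: float) -> tuple[float, float]:
    """Gaussian chirp law: stretched duration and stretch factor.

    τ_out = τ·sqrt(1 + (4·ln2·φ₂/τ²)²); factor = τ_out/τ ≥ 1 with equality
    iff φ₂ = 0.
    """
    if tl_duration_fs <= 0:
        raise ValueError("transform-limited duration must be positive")
    x = 4.0 * math.log(2.0) * abs(gdd_fs2) / tl_duration_fs**2
    stretched = tl_duration_fs * math.sqrt(1.0 + x * x)
    return stretched, stretched / tl_duration_fs


def spectral_fwhm(spectrum: Spectrum,
                  window: tuple[float, float] = (2800.0, 3100.0)) -> float:
    """FWHM (cm⁻¹) of the peak inside ``window`` after baseline correction.

    A linear baseline is fit to the flanking points outside the window and
    subtracted; the peak is normalized to 1 and the half-maximum crossings
    are located by linear interpolation.  Raises when the signal has no
    half-maximum crossing on both sides inside the window.
    """
    lo, hi = window
    x, y = spectrum.wavenumber, spectrum.intensity.astype(float)
    if lo < x[0] or hi > x[-1]:
        raise ValueError("window extends beyond the spectral axis")
    flank = (x < lo) | (x > hi)
    if flank.sum() >= 2:
        coef = np.polyfit(x[flank], y[flank], 1)
        y = y - np.polyval(coef, x)
    inside = (x >= lo) & (x <= hi)
    xi, yi = x[inside], y[inside]
    if len(xi) < 3:
        raise ValueError("window contains too few samples")
    peak = yi.max()
    if peak <= 0:
        raise ValueError("no positive peak inside the window")
    yi = yi / peak
    ip = int(np.argmax(yi))

    def interp(i: int) -> float:
        x0, x1_, y0, y1_ = xi[i], xi[i + 1], yi[i], yi[i + 1]
        return x0 + (0.5 - y0) * (x1_ - x0) / (y1_ - y0)

    left = right = None
    for i in range(ip - 1, -1, -1):          # walk left from the peak
        if yi[i] < 0.5 <= yi[i + 1]:
            left = interp(i)
            break
    for i in range(ip, len(xi) - 1):         # walk right from the peak
        if yi[i] >= 0.5 > yi[i + 1]:
            right = interp(i)
            break
    if left is None or right is None:
        raise ValueError("no half-maximum crossing inside the window")
    return right - left


def cross_correlation_scan(pump: LaserPulse, stokes: LaserPulse,
                           delays_fs) -> np.ndarray:
    """CARS delay-scan model: I(τ) ∝ ∫ I_p(t)²·I_s(t−τ) dt, peak-normalized.

    Two pump photons and one Stokes photon drive the anti-Stokes signal,
    so the pump intensity enters squared.  For Gaussian intensity
    envelopes the scan is Gaussian with FWHM² = τ_p²/2 + τ_s².
    """
    delays = np.asarray(delays_fs, dtype=float)
    if delays.size == 0:
        raise ValueError("empty delay grid")
    tp, ts = pump.duration_fs, stokes.duration_fs
    # I_p² is Gaussian with FWHM τ_p/√2; convolution widths add in quadrature
    w2 = tp**2 / 2.0 + ts**2
    return np.exp(-4.0 * math.log(2.0) * delays**2 / w2)
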