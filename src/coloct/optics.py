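"""Source, probe and tissue optical parameters.

The probe modelled here is a forward-looking endoscopic OCT catheter: a
swept near-infrared laser (central wavelength 1060 nm, 400 kHz sweep rate)
delivered through a GRIN lens onto a MEMS mirror that fans the beam across a
~20 deg sector at 550 B-scans/s.  Axial resolution for a Gaussian-spectrum
source is delta_z = (2 ln2 / pi) * lambda0^2 / delta_lambda; the nominal
6 um resolution at 1060 nm corresponds to ~82.6 nm FWHM bandwidth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import numpy as np

TWO_LN2_OVER_PI = 2.0 * np.log(2.0) / np.pi

#: default group refractive index assumed for soft tissue
TISSUE_INDEX = 1.38


@dataclass(frozen=True)
class OpticalProperties:
    """Single-scatter optical description of one tissue class.

    scattering_coeff : per-mm attenuation (mu_s) along the geometric path;
        OCT intensity in a homogeneous slab decays as exp(-2 mu_s z).
    backscatter_frac : relative backscattered power per unit length
        (dimensionless; only ratios between classes matter).
    refractive_index : group index converting geometric to optical path.
    """

    scattering_coeff: float
    backscatter_frac: float
    refractive_index: float = TISSUE_INDEX

    def __post_init__(self):
        if self.scattering_coeff < 0:
            raise ValueError("scattering_coeff must be >= 0")
        if self.backscatter_frac < 0:
            raise ValueError("backscatter_frac must be >= 0")
        if self.refractive_index < 1:
            raise ValueError("refractive_index must be >= 1")


@dataclass(frozen=True)
class ProbeIntrinsics:
    """Swept-source and scan-geometry parameters of the probe.

    Wavelengths in nm, angles in degrees, distances in mm unless noted.
    ``sweep_span_factor`` sets the total swept range as a multiple of the
    Gaussian FWHM bandwidth; ``sweep_mode`` is 'linear_wavelength' (realistic
    swept laser, non-uniform in k, exercising resampling) or 'linear_k'.
    """

    center_wavelength: float = 1060.0        # lambda0, nm
    bandwidth_fwhm: float = 82.6             # delta-lambda, nm (Gaussian FWHM)
    sweep_rate: float = 400.0                # kHz
    bscan_rate: float = 550.0                # Hz
    fov_angle: float = 20.0                  # full sector angle, deg
    mounting_angle: float = 0.0              # in-plane rotation of the fan, deg
    working_distance: float = 1.0            # apex to nominal tissue surface, mm
    ascans_per_bscan: int = 128
    samples_per_ascan: int = 2048
    axial_resolution: float = 6.0            # um (air)
    lateral_resolution: float = 30.0         # um
    sweep_span_factor: float = 2.5
    sweep_mode: str = "linear_wavelength"

    def __post_init__(self):
        for name in ("center_wavelength", "bandwidth_fwhm", "sweep_rate",
                     "bscan_rate", "working_distance", "axial_resolution",
                     "lateral_resolution", "sweep_span_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0 < self.fov_angle < 90):
            raise ValueError("fov_angle must lie in (0, 90) degrees")
        if abs(self.mounting_angle) >= 45:
            raise ValueError("|mounting_angle| must be < 45 degrees")
        if self.ascans_per_bscan < 1 or self.samples_per_ascan < 4:
            raise ValueError("sample/A-scan counts too small")
        if self.sweep_mode not in ("linear_wavelength", "linear_k"):
            raise ValueError("sweep_mode must be 'linear_wavelength' or 'linear_k'")

    # ---- derived spectral quantities (k in rad/mm) ----

    @property
    def k0(self) -> float:
        return 2.0 * np.pi / (self.center_wavelength * 1e-6)

    @property
    def k_fwhm(self) -> float:
        """FWHM of the Gaussian source spectrum in k (rad/mm)."""
        lam0_mm = self.center_wavelength * 1e-6
        return 2.0 * np.pi * (self.bandwidth_fwhm * 1e-6) / lam0_mm ** 2

    def sweep_wavelengths(self) -> np.ndarray:
        """Instantaneous wavelengths over one sweep (nm), long to short so
        that k is strictly increasing."""
        half = 0.5 * self.sweep_span_factor * self.bandwidth_fwhm
        lam = np.linspace(self.center_wavelength + half,
                          self.center_wavelength - half,
                          self.samples_per_ascan)
        return lam

    def sweep_k(self) -> np.ndarray:
        """k samples over one sweep (rad/mm), strictly increasing."""
        if self.sweep_mode == "linear_k":
            lam = self.sweep_wavelengths()
            kmin = 2.0 * np.pi / (lam[0] * 1e-6)
            kmax = 2.0 * np.pi / (lam[-1] * 1e-6)
            return np.linspace(kmin, kmax, self.samples_per_ascan)
        return 2.0 * np.pi / (self.sweep_wavelengths() * 1e-6)

    def spectral_envelope(self, k: np.ndarray) -> np.ndarray:
        """Gaussian source amplitude envelope at wavenumbers ``k``."""
        return np.exp(-4.0 * np.log(2.0) * ((k - self.k0) / self.k_fwhm) ** 2)

    @property
    def coherence_length_mm(self) -> float:
        """Axial PSF FWHM in air (mm): (2 ln2/pi) lambda0^2 / dlambda."""
        lam0_mm = self.center_wavelength * 1e-6
        return TWO_LN2_OVER_PI * lam0_mm ** 2 / (self.bandwidth_fwhm * 1e-6)

    def axial_pitch_mm(self, refractive_index: float = 1.0) -> float:
        """Depth-pixel pitch pi/(N dk) of the reconstructed A-scan, divided
        by the assumed group index (geometric mm per pixel)."""
        k = self.sweep_k()
        dk = (k[-1] - k[0]) / (len(k) - 1)
        return np.pi / (len(k) * dk) / refractive_index

    def depth_range_mm(self, refractive_index: float = 1.0) -> float:
        """Unambiguous imaging range from the zero-delay (apex), geometric mm."""
        return self.axial_pitch_mm(refractive_index) * (self.samples_per_ascan // 2)

    def bscan_angles(self) -> np.ndarray:
        """Nominal sector angles of the A-scan columns (deg), symmetric
        about 0; mounting rotation is applied at simulation / projection
        time, not stored in the column angles."""
        return np.linspace(-self.fov_angle / 2.0, self.fov_angle / 2.0,
                           self.ascans_per_bscan)

    def with_(self, **kw) -> "ProbeIntrinsics":
        return replace(self, **kw)


def scan_intrinsics(**overrides) -> ProbeIntrinsics:
    """Desk-scale intrinsics for multi-lane scan simulation: shorter sweep
    span (coarser axial pitch, longer range per sample count), fewer samples
    and A-scans than the full-fidelity defaults.  Spectral truncation at
    1.25x FWHM costs a little axial resolution, which mosaicking and feature
    work tolerate."""
    base = dict(samples_per_ascan=768, ascans_per_bscan=48,
                sweep_span_factor=1.25, working_distance=0.3)
    base.update(overrides)
    return ProbeIntrinsics(**base)
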