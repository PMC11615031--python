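"""Fringe-to-image reconstruction: k-resampling, inverse FFT, averaging,
interlacing, and B-scan assembly in the sector (MEMS-apex) frame.

A swept-source A-scan is the magnitude of the inverse discrete Fourier
transform of the (DC-subtracted, apodized) spectral fringe, taken over the
positive-depth half of the transform.  Because a fringe component
cos(2 k z) beats at rate 2z in k, a uniform k grid with sample spacing dk
maps transform bin m to optical depth z = pi * m / (N dk); sweeps that are
linear in wavelength must therefore be resampled onto a uniform k grid
first, or the depth-dependent chirp smears the point-spread function.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from scipy.interpolate import CubicSpline

from .acquisition import FringeRecord, ScanDataset
from .optics import ProbeIntrinsics

#: relative tolerance for accepting a k grid as uniform
_UNIFORM_RTOL = 1e-6


@dataclass
class AScan:
    """Single depth profile: linear (amplitude) intensities and pixel pitch.

    ``axial_pitch`` is micrometres of *geometric* depth per pixel, i.e.
    pi/(N dk) divided by the assumed group refractive index.
    """

    intensity: np.ndarray
    axial_pitch: float  # um / pixel
    refractive_index: float = 1.0

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(self.intensity < 0):
            raise ValueError("linear intensities must be >= 0")
        if self.axial_pitch <= 0:
            raise ValueError("axial_pitch must be > 0")

    @property
    def n_pixels(self) -> int:
        return len(self.intensity)

    def log_view(self, eps_frac: float = 1e-6) -> np.ndarray:
        """20 log10(amplitude + eps) dB view, eps relative to the max."""
        eps = eps_frac * (self.intensity.max() or 1.0)
        return 20.0 * np.log10(self.intensity + eps)


@dataclass
class BScanSector:
    """Ordered A-scans across the sector: columns[depth, angle]."""

    columns: np.ndarray          # (n_depth, n_angles) linear amplitude
    angles: np.ndarray           # deg, strictly increasing, symmetric about 0
    axial_pitch: float           # um / pixel (geometric)
    apex: tuple = (0.0, 0.0)     # stage (x, y) mm
    lane: int = 0
    step: int = 0

    def __post_init__(self):
        self.columns = np.asarray(self.columns, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.columns.ndim != 2 or self.columns.shape[1] != len(self.angles):
            raise ValueError("column count must match angle count")
        if len(self.angles) > 1 and np.any(np.diff(self.angles) <= 0):
            raise ValueError("angles must be strictly increasing")
        if len(self.angles) > 1 and \
                abs(self.angles[0] + self.angles[-1]) > 1e-6 * np.ptp(self.angles):
            raise ValueError("angles must be symmetric about 0")

    @property
    def n_depth(self) -> int:
        return self.columns.shape[0]

    @property
    def angular_pitch(self) -> float:
        return float(self.angles[1] - self.angles[0]) if len(self.angles) > 1 else 0.0

    def log_view(self, eps_frac: float = 1e-6) -> np.ndarray:
        eps = eps_frac * (self.columns.max() or 1.0)
        return 20.0 * np.log10(self.columns + eps)


# ---------------------------------------------------------------------------

def resample_to_uniform_k(fringe: FringeRecord,
                          calibration=None) -> FringeRecord:
    """Cubic-spline interpolation of the fringe onto a uniform k grid of the
    same length spanning the recorded sweep.

    ``calibration`` optionally overrides the per-sample wavenumbers (a
    k-sampling map measured for the sweep); defaults to the fringe's own
    ``k_values``.
    """
    k = fringe.k_values if calibration is None else np.asarray(calibration, float)
    if len(k) != len(fringe.samples):
        raise ValueError("calibration must cover the sweep (length mismatch)")
    dk = np.diff(k)
    if not (np.all(dk > 0) or np.all(dk < 0)):
        raise ValueError("k-sampling map must be strictly monotonic")
    if dk[0] < 0:
        k, samples = k[::-1], fringe.samples[::-1]
    else:
        samples = fringe.samples
    k_uniform = np.linspace(k[0], k[-1], len(k))
    out = CubicSpline(k, samples)(k_uniform)
    return FringeRecord(out, k_uniform, angle=fringe.angle,
                        meta=dict(fringe.meta))


def fringe_to_ascan(fringe: FringeRecord, window: str = "hann",
                    refractive_index: float = 1.0,
                    pad_factor: int = 1) -> AScan:
    """Inverse-FFT reconstruction of one depth profile.

    The fringe must already be uniform in k.  The per-fringe mean (DC) is
    subtracted, the chosen apodization ('hann' or 'none') applied, and the
    magnitude of the positive-depth half of the inverse DFT returned.
    ``pad_factor`` zero-pads the windowed fringe to sample the envelope more
    finely (pitch divides accordingly; resolution is unchanged).
    """
    if not fringe.uniform_k:
        raise ValueError("fringe is not uniformly sampled in k; "
                         "apply resample_to_uniform_k first")
    n = len(fringe.samples)
    if window == "hann":
        w = np.hanning(n)
    elif window in ("none", None):
        w = np.ones(n)
    else:
        raise ValueError(f"unknown window {window!r}")
    x = (fringe.samples - fringe.samples.mean()) * w
    n_pad = n * int(pad_factor)
    spec = np.fft.ifft(x, n=n_pad)
    half = np.abs(spec[: n_pad // 2])
    dk = abs(fringe.k_values[1] - fringe.k_values[0])
    pitch_mm = np.pi / (n_pad * dk) / refractive_index
    return AScan(half, axial_pitch=pitch_mm * 1e3,
                 refractive_index=refractive_index)


def average_bscans(frames) -> BScanSector:
    """Per-pixel mean of linear intensities over repeated co-located frames
    (noise reduction); metadata of the first frame is retained."""
    frames = list(frames)
    if not frames:
        raise ValueError("no frames to average")
    first = frames[0]
    for f in frames[1:]:
        if f.columns.shape != first.columns.shape or \
                not np.allclose(f.angles, first.angles) or \
                not np.allclose(f.apex, first.apex) or \
                f.axial_pitch != first.axial_pitch:
            raise ValueError("frames must share geometry and pose")
    mean = np.mean([f.columns for f in frames], axis=0)
    return BScanSector(mean, first.angles.copy(), first.axial_pitch,
                       apex=first.apex, lane=first.lane, step=first.step)


def interlace_bscans(a: BScanSector, b: BScanSector,
                     pitch_rtol: float = 0.01) -> BScanSector:
    """Merge two B-scans whose angular grids are offset by half an angular
    step, doubling lateral sampling (the 'interlacing' enhancement).

    ``b``'s angles must sit half a pitch above ``a``'s within ``pitch_rtol``
    of the pitch.
    """
    if a.columns.shape != b.columns.shape:
        raise ValueError("interlaced frames must have equal shapes")
    p = a.angular_pitch
    off = b.angles - a.angles
    if np.any(np.abs(off - p / 2.0) > pitch_rtol * p):
        raise ValueError("second frame must be offset by half the angular "
                         "pitch of the first")
    cols = np.empty((a.n_depth, 2 * a.columns.shape[1]))
    cols[:, 0::2] = a.columns
    cols[:, 1::2] = b.columns
    angles = np.empty(2 * len(a.angles))
    angles[0::2] = a.angles
    angles[1::2] = b.angles
    # recentre so the merged sector stays symmetric about 0
    angles = angles - (angles[0] + angles[-1]) / 2.0
    return BScanSector(cols, angles, a.axial_pitch, apex=a.apex,
                       lane=a.lane, step=a.step)


def assemble_bscan(ascans, angles, apex=(0.0, 0.0), lane: int = 0,
                   step: int = 0) -> BScanSector:
    """Stack ordered A-scans into a sector container."""
    ascans = list(ascans)
    angles = np.asarray(angles, dtype=float)
    if len(ascans) != len(angles):
        raise ValueError("A-scan and angle counts must match")
    if len(ascans) == 0:
        raise ValueError("no A-scans")
    pitches = {a.axial_pitch for a in ascans}
    if len(pitches) != 1:
        raise ValueError("A-scans must share an axial pitch")
    cols = np.column_stack([a.intensity for a in ascans])
    return BScanSector(cols, angles, ascans[0].axial_pitch, apex=apex,
                       lane=lane, step=step)


def envelope_fwhm_um(ascan: AScan) -> float:
    """FWHM of the strongest peak of an A-scan envelope, micrometres,
    with linear interpolation at the half-maximum crossings."""
    env = ascan.intensity
    pk = int(np.argmax(env))
    half = env[pk] / 2.0
    left = pk
    while left > 0 and env[left - 1] > half:
        left -= 1
    right = pk
    while right < len(env) - 1 and env[right + 1] > half:
        right += 1
    if left == 0 or right == len(env) - 1:
        raise ValueError("peak not fully resolved within the A-scan")
    fl = left - (half - env[left]) / (env[left - 1] - env[left])
    fr = right + (half - env[right]) / (env[right + 1] - env[right])
    return float((fr - fl) * ascan.axial_pitch)


# ---------------------------------------------------------------------------

@dataclass
class ProcessedScan:
    """Reconstructed sector B-scans of a whole acquisition, keyed by
    (lane, step), plus the plan and true intrinsics carried through."""

    bscans: dict
    plan: object
    intrinsics_true: ProbeIntrinsics
    stage_positions: np.ndarray
    origin_mm: tuple
    truth: object = None

    def bscan(self, lane: int, step: int) -> BScanSector:
        return self.bscans[(lane, step)]


def process_dataset(dataset: ScanDataset, window: str = "hann") -> ProcessedScan:
    """Run resample + inverse FFT on every fringe of a dataset and assemble
    per-(lane, step) sector B-scans.

    Resampling cost is shared: the cubic interpolation matrix depends only
    on the common k grid, so all fringes are resampled in one vectorized
    pass.
    """
    n_idx = 1.0
    if dataset.truth is not None:
        n_idx = next(iter(dataset.truth.properties.values())).refractive_index
    k = dataset.k_values
    dk = np.diff(k)
    uniform = np.all(np.abs(dk - dk[0]) <= _UNIFORM_RTOL * abs(dk[0]))
    nl, ns, na, nk = dataset.fringes.shape
    flat = dataset.fringes.reshape(-1, nk)
    if not uniform:
        k_u = np.linspace(k[0], k[-1], nk)
        flat = CubicSpline(k, flat, axis=1)(k_u)
        k_use = k_u
    else:
        k_use = k
    out = {}
    for lane in range(nl):
        for step in range(ns):
            cols = []
            for c in range(na):
                rec = FringeRecord(flat[(lane * ns + step) * na + c], k_use)
                cols.append(fringe_to_ascan(rec, window=window,
                                            refractive_index=n_idx))
            out[(lane, step)] = assemble_bscan(
                cols, dataset.angles,
                apex=tuple(dataset.stage_positions[lane, step]),
                lane=lane, step=step)
    return ProcessedScan(bscans=out, plan=dataset.plan,
                         intrinsics_true=dataset.intrinsics_true,
                         stage_positions=dataset.stage_positions,
                         origin_mm=dataset.origin_mm, truth=dataset.truth)
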