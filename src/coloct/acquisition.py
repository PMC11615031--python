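"""Swept-source fringe synthesis and lane-based scan simulation.

The interference fringe recorded during one sweep is modelled single-scatter:

    f(k) = S(k) * Re[ sum_i A_i exp(i 2 k z_i) ] + noise

with S(k) the Gaussian source amplitude envelope, z_i the optical path from
the probe apex to scatterer i, and A_i the complex scatterer amplitude

    |A_i| prop. sqrt(backscatter_frac * ds) * exp(-integral mu_s ds)

so that reconstructed *intensity* decays as exp(-2 mu_s z), the Beer–Lambert
single-scatter model the attenuation-coefficient estimator later inverts.

Two scatterer models are provided:

* speckle=True (default): distributed scatterers at fixed path steps whose
  complex phasors come from a position-hashed field (see ``_noise``), giving
  fully developed speckle that is *shared between beams* crossing the same
  tissue — the property that makes cross-lane self-calibration possible.
* speckle=False: specular reflectors at layer interfaces only, amplitude
  set by the backscatter of the layer below; a deterministic model for
  closed-form tests.

Scan geometry: the MEMS mirror fans the beam across ``fov_angle`` inside the
slice plane (the y–z plane at the stage x position); ``mounting_angle``
rotates the whole fan in that plane.  The stage steps the probe along x
(``step_size``, nominally 0.1 mm) and jumps between parallel lanes along y.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from ._noise import cell_phasor
from .optics import ProbeIntrinsics
from .phantom import TissuePhantom, BACKGROUND

#: detector noise level (fringe SNR, dB) calibrated so that a default polyp
#: phantom images to roughly 1 mm depth
CALIBRATED_SNR_DB = 25.0


@dataclass
class FringeRecord:
    """Raw interference samples of one A-scan.

    k_values are rad/mm, strictly monotonic (possibly non-uniform when the
    sweep is linear in wavelength); ``angle`` is the nominal sector angle of
    this A-scan in degrees; ``meta`` carries (lane, step) provenance.
    """

    samples: np.ndarray
    k_values: np.ndarray
    angle: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        self.k_values = np.asarray(self.k_values, dtype=float)
        if self.samples.shape != self.k_values.shape:
            raise ValueError("samples and k_values must have equal length")
        dk = np.diff(self.k_values)
        if not (np.all(dk > 0) or np.all(dk < 0)):
            raise ValueError("k_values must be strictly monotonic")

    @property
    def uniform_k(self) -> bool:
        dk = np.diff(self.k_values)
        return bool(np.all(np.abs(dk - dk[0]) <= 1e-9 * np.abs(dk[0])))


@dataclass(frozen=True)
class ScanPlan:
    """Lane-based stage motion: ``n_lanes`` parallel lanes ``lane_spacing``
    apart, each with ``steps_per_lane`` stops every ``step_size`` mm
    (nominally 0.1 mm) along ``travel_axis``."""

    n_lanes: int = 2
    steps_per_lane: int = 20
    step_size: float = 0.1
    lane_spacing: float = 0.3
    travel_axis: str = "x"
    seed: int = 0

    def __post_init__(self):
        if self.n_lanes < 1 or self.steps_per_lane < 1:
            raise ValueError("n_lanes and steps_per_lane must be >= 1")
        if self.step_size <= 0 or self.lane_spacing <= 0:
            raise ValueError("step_size and lane_spacing must be > 0")
        if self.travel_axis != "x":
            raise ValueError("travel axis must be 'x' (lanes along y)")

    @property
    def total_bscans(self) -> int:
        return self.n_lanes * self.steps_per_lane

    @property
    def lane_travel_span(self) -> float:
        """Distance covered by one lane, mm: (steps - 1) * step."""
        return (self.steps_per_lane - 1) * self.step_size


@dataclass
class ScanDataset:
    """All fringes of one acquisition, grouped per (lane, step) B-scan.

    ``fringes`` has shape (n_lanes, steps_per_lane, ascans_per_bscan,
    samples_per_ascan); ``k_values`` is shared across all A-scans.
    ``stage_positions`` holds the (x, y) stage position of every B-scan,
    shape (n_lanes, steps_per_lane, 2).  ``truth`` references the phantom.
    """

    fringes: np.ndarray
    k_values: np.ndarray
    angles: np.ndarray
    plan: ScanPlan
    intrinsics_true: ProbeIntrinsics
    stage_positions: np.ndarray
    truth: TissuePhantom = None
    origin_mm: tuple = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self):
        expected = (self.plan.n_lanes, self.plan.steps_per_lane)
        if self.fringes.shape[:2] != expected:
            raise ValueError("one B-scan group per (lane, step) required")
        rel = self.stage_positions - np.asarray(self.origin_mm)
        lanes = np.arange(self.plan.n_lanes) * self.plan.lane_spacing
        steps = np.arange(self.plan.steps_per_lane) * self.plan.step_size
        if not (np.allclose(rel[..., 1], lanes[:, None]) and
                np.allclose(rel[..., 0], steps[None, :])):
            raise ValueError("stage_positions inconsistent with plan")

    def fringe(self, lane: int, step: int, column: int) -> FringeRecord:
        return FringeRecord(self.fringes[lane, step, column], self.k_values,
                            angle=float(self.angles[column]),
                            meta={"lane": lane, "step": step})


# ---------------------------------------------------------------------------
# fringe synthesis primitives

def fringe_from_scatterers(z_opt_mm, amplitudes, intrinsics: ProbeIntrinsics,
                           k_values=None, noise_rms: float = 0.0,
                           rng=None) -> FringeRecord:
    """Synthesize a fringe from explicit scatterers at optical depths
    ``z_opt_mm`` with (possibly complex) ``amplitudes``; the reference
    model for all reconstruction oracles."""
    k = intrinsics.sweep_k() if k_values is None else np.asarray(k_values, float)
    z = np.atleast_1d(np.asarray(z_opt_mm, dtype=float))
    a = np.atleast_1d(np.asarray(amplitudes))
    env = intrinsics.spectral_envelope(k)
    phase = np.exp(2j * np.outer(k, z))
    samples = env * np.real(phase @ a.astype(complex))
    if noise_rms > 0:
        rng = np.random.default_rng(rng)
        samples = samples + rng.normal(0.0, noise_rms, samples.shape)
    return FringeRecord(samples, k)


def point_reflector_fringe(depth_mm: float, intrinsics: ProbeIntrinsics,
                           refractive_index: float = 1.0,
                           amplitude: float = 1.0) -> FringeRecord:
    """Noiseless fringe of a single perfect reflector at geometric depth
    ``depth_mm`` in a medium of the given index."""
    return fringe_from_scatterers([depth_mm * refractive_index], [amplitude],
                                  intrinsics)


# ---------------------------------------------------------------------------
# phantom interrogation

def _ray_samples(phantom: TissuePhantom, origin, direction, intrinsics,
                 density: float):
    """March a ray through the phantom.

    Returns (z_opt, sigma, classes): optical path from the apex, one-way
    amplitude factor sqrt(backscatter*ds)*exp(-int mu_s ds) and tissue class
    per sample.  Step = coherence_length / density (geometric; the index-
    matched medium makes optical path proportional).
    """
    ds = intrinsics.coherence_length_mm / density
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    n_med = next(iter(phantom.properties.values())).refractive_index
    max_path = intrinsics.depth_range_mm(n_med) * 1.05
    t = (np.arange(int(max_path / ds)) + 0.5) * ds
    pts = origin[None, :] + t[:, None] * direction[None, :]
    cls = phantom.classify(pts)
    mu = np.zeros(t.shape)
    bsc = np.zeros(t.shape)
    n_idx = np.full(t.shape, n_med)
    for cid, prop in phantom.properties.items():
        sel = cls == cid
        mu[sel] = prop.scattering_coeff
        bsc[sel] = prop.backscatter_frac
        n_idx[sel] = prop.refractive_index
    atten = np.exp(-(np.cumsum(mu * ds) - 0.5 * mu * ds))   # one-way, to sample
    z_opt = np.cumsum(n_idx * ds) - 0.5 * n_idx * ds
    sigma = np.sqrt(bsc * ds) * atten
    return pts, atten, z_opt, sigma, cls


def simulate_fringe(phantom: TissuePhantom, beam_origin, beam_angle_deg: float,
                    intrinsics: ProbeIntrinsics, seed: int = 0,
                    speckle: bool = True, noise_snr_db: float = None,
                    scatterer_density: float = 10.0,
                    scan_plane_axis: str = "y") -> FringeRecord:
    """Simulate the interference fringe of one A-scan.

    The beam starts at ``beam_origin`` (mm, in phantom coordinates, the MEMS
    apex) and travels at ``beam_angle_deg`` from the +z (depth) axis inside
    the plane spanned by ``scan_plane_axis`` and z.  ``noise_snr_db`` sets
    additive detector noise relative to the RMS of the noiseless fringe
    (None = noiseless).  The speckle phasor field is keyed to the phantom
    seed (tissue-intrinsic); ``seed`` drives detector noise only.
    """
    th = np.deg2rad(beam_angle_deg)
    lateral = np.array([0.0, 1.0, 0.0]) if scan_plane_axis == "y" \
        else np.array([1.0, 0.0, 0.0])
    direction = np.sin(th) * lateral + np.cos(th) * np.array([0.0, 0.0, 1.0])
    o = np.asarray(beam_origin, dtype=float)
    end = o + direction * intrinsics.depth_range_mm()
    lo, hi = np.minimum(o, end), np.maximum(o, end)
    if np.any(hi < 0) or np.any(lo > phantom.extent_mm):
        raise ValueError("beam does not intersect the phantom volume")

    pts, atten, z_opt, sigma, cls = _ray_samples(phantom, o, direction,
                                                 intrinsics, scatterer_density)
    tissue = cls != BACKGROUND
    if speckle:
        sigma = sigma * np.sqrt(phantom.backscatter_modulation(pts))
        cell = intrinsics.coherence_length_mm / scatterer_density
        idx = np.floor(pts / cell).astype(np.int64)
        phasors = cell_phasor(idx[:, 0], idx[:, 1], idx[:, 2],
                              phantom.seed, stream=3)
        amps = (sigma * tissue) * phasors
        z_sel, a_sel = z_opt[tissue], amps[tissue]
    else:
        # specular interfaces: one reflector wherever the class changes,
        # amplitude sqrt(backscatter of the layer entered) x one-way loss
        change = np.flatnonzero(np.diff(cls.astype(int)) != 0) + 1
        change = change[cls[change] != BACKGROUND]
        z_sel = z_opt[change]
        a_sel = np.array([
            np.sqrt(phantom.properties[int(cls[j])].backscatter_frac) * atten[j]
            for j in change])

    k = intrinsics.sweep_k()
    env = intrinsics.spectral_envelope(k)
    if len(z_sel):
        # Re(sum A e^{i 2 k z}) = cos(2kz) @ Re(A) - sin(2kz) @ Im(A)
        phase = 2.0 * np.outer(k, z_sel)
        a_c = np.asarray(a_sel, dtype=complex)
        samples = env * (np.cos(phase) @ a_c.real - np.sin(phase) @ a_c.imag)
    else:
        samples = np.zeros_like(k)
    if noise_snr_db is not None:
        rng = np.random.default_rng(seed)
        ref = np.sqrt(np.mean(samples ** 2)) or 1.0
        samples = samples + rng.normal(
            0.0, ref * 10 ** (-noise_snr_db / 20.0), samples.shape)
    return FringeRecord(samples, k, angle=float(beam_angle_deg))


def simulate_scan(phantom: TissuePhantom, plan: ScanPlan,
                  intrinsics: ProbeIntrinsics, seed: int = 0,
                  speckle: bool = True, noise_snr_db: float = None,
                  scatterer_density: float = 10.0,
                  origin_mm=None) -> ScanDataset:
    """Acquire one B-scan per (lane, step) over the scan plan.

    The footprint is centred on the phantom unless ``origin_mm`` (stage
    position of lane 0 / step 0) is given; the apex sits ``working_distance``
    above the mean tissue surface.  Raises if any B-scan's sector footprint
    leaves the phantom laterally, naming the offending lane/step.
    """
    if origin_mm is None:
        ox = (phantom.extent_mm[0] - plan.lane_travel_span) / 2.0
        oy = (phantom.extent_mm[1] - (plan.n_lanes - 1) * plan.lane_spacing) / 2.0
        origin_mm = (float(ox), float(oy))
    intr = intrinsics
    angles = intr.bscan_angles()
    apex_z = phantom.mean_surface_mm - intr.working_distance
    n_med = next(iter(phantom.properties.values())).refractive_index
    half_w = intr.depth_range_mm(n_med) * np.sin(
        np.deg2rad(intr.fov_angle / 2.0 + abs(intr.mounting_angle)))

    fringes = np.empty((plan.n_lanes, plan.steps_per_lane,
                        intr.ascans_per_bscan, intr.samples_per_ascan))
    positions = np.empty((plan.n_lanes, plan.steps_per_lane, 2))
    for lane in range(plan.n_lanes):
        for step in range(plan.steps_per_lane):
            x = origin_mm[0] + step * plan.step_size
            y = origin_mm[1] + lane * plan.lane_spacing
            positions[lane, step] = (x, y)
            if not (0 <= x <= phantom.extent_mm[0]) or \
               y - half_w < 0 or y + half_w > phantom.extent_mm[1]:
                raise ValueError(
                    f"scan footprint exceeds phantom at lane {lane}, step {step}")
            apex = np.array([x, y, apex_z])
            for c, ang in enumerate(angles):
                rec = simulate_fringe(
                    phantom, apex, ang + intr.mounting_angle, intr,
                    seed=int(np.random.SeedSequence(
                        [seed, lane, step, c]).generate_state(1)[0] % (2**31)),
                    speckle=speckle, noise_snr_db=noise_snr_db,
                    scatterer_density=scatterer_density)
                fringes[lane, step, c] = rec.samples
    return ScanDataset(fringes=fringes, k_values=intr.sweep_k(),
                       angles=angles, plan=plan, intrinsics_true=intr,
                       stage_positions=positions, truth=phantom,
                       origin_mm=tuple(origin_mm), seed=int(seed))
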