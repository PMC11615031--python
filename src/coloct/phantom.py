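"""Digital colorectal-wall phantoms.

A phantom is a layered 3-D optical-property volume emulating the ex vivo
specimens the probe was evaluated on: epithelium over the thin, strongly
backscattering lamina propria / muscularis mucosae (LP/MM) band, over
submucosa containing low-signal blood-vessel lumens.  Polyp variants thicken
the mucosa, optionally efface the LP/MM band, raise epithelial backscatter
and roughen the surface — the three qualitative OCT reading criteria
(effacement, hyperreflectivity, surface irregularity) therefore exist in the
phantom as ground-truth flags that downstream feature extraction must
recover.

Geometry convention: x is the stage travel axis, y the lane axis, z depth
(z = 0 at the top of the volume, increasing into tissue).  Layer interfaces
are stored as continuous per-(x, y) depth maps; the voxel label grid is a
quantized view of the same geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from ._noise import fractal_noise, value_noise
from .optics import OpticalProperties, TISSUE_INDEX

# tissue class IDs
BACKGROUND = 0
EPITHELIUM = 1
LPMM = 2          # lamina propria / muscularis mucosae
SUBMUCOSA = 3
VESSEL = 4

CLASS_NAMES = {BACKGROUND: "background", EPITHELIUM: "epithelium",
               LPMM: "lamina_propria_muscularis_mucosae",
               SUBMUCOSA: "submucosa", VESSEL: "vessel_lumen"}

# Default optics.  No measured coefficients exist for this configuration;
# these are placeholders calibrated so a polyp phantom images to ~1 mm depth,
# with the LP/MM band carrying 6x backscatter so it reads as a clearly bright
# layer even under a hyperreflective epithelium.  Background is treated as
# index-matched coupling fluid (probe designed for fluid-filled-organ use),
# so geometric depth = optical/1.38 everywhere.
DEFAULT_PROPERTIES = {
    BACKGROUND: OpticalProperties(0.0, 0.0, TISSUE_INDEX),
    EPITHELIUM: OpticalProperties(1.5, 1.0, TISSUE_INDEX),
    LPMM: OpticalProperties(4.0, 6.0, TISSUE_INDEX),
    SUBMUCOSA: OpticalProperties(2.0, 1.0, TISSUE_INDEX),
    VESSEL: OpticalProperties(0.3, 0.05, TISSUE_INDEX),
}

#: depth margin of background medium above the mean tissue surface (mm)
SURFACE_MARGIN = 0.15


@dataclass(frozen=True)
class Vessel:
    """Axis-aligned ellipsoidal vessel lumen in the submucosa."""
    center: tuple  # (x, y, z) mm
    radii: tuple   # (rx, ry, rz) mm

    def contains(self, pts: np.ndarray) -> np.ndarray:
        d = (pts - np.asarray(self.center)) / np.asarray(self.radii)
        return np.einsum("ij,ij->i", d, d) <= 1.0


@dataclass
class TissuePhantom:
    """Labeled optical-property volume with continuous ground truth.

    ``boundaries`` has shape (4, nx, ny): depth (mm) of the tissue surface,
    epithelium bottom, LP/MM bottom and submucosa bottom at each lateral
    node (node pitch = voxel_size, node 0 at 0.5*voxel_size).  Where the
    LP/MM band is absent (effaced lesion) rows 1 and 2 coincide.
    """

    extent_mm: np.ndarray                  # (3,) physical size, mm
    voxel_size: float                      # mm, isotropic
    boundaries: np.ndarray                 # (4, nx, ny) mm
    properties: dict                       # class id -> OpticalProperties
    vessels: list                          # list[Vessel]
    lesion_flags: dict                     # effaced / hyperreflective / irregular_surface
    seed: int
    heterogeneity: float = 0.6             # fractional backscatter modulation
    heterogeneity_scale: float = 0.08      # mm, outer octave of tissue texture
    void_contrast: float = 0.85            # backscatter drop inside micro-voids
    void_scale: float = 0.05               # mm, size of crypt/gland-like voids
    void_threshold: float = -0.45          # noise quantile carving the voids
    _label_grid: np.ndarray = field(default=None, repr=False)  # lazy cache

    def __post_init__(self):
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")
        db = np.diff(self.boundaries, axis=0)
        if np.any(db < -1e-12):
            raise ValueError("layer boundaries must be non-decreasing with layer order")

    # ---- continuous ground truth ----

    def boundary_depths(self, x_mm, y_mm) -> np.ndarray:
        """Bilinear interpolation of the 4 interface depths at lateral
        positions (x, y); returns shape (4, n)."""
        x = np.atleast_1d(np.asarray(x_mm, dtype=float))
        y = np.atleast_1d(np.asarray(y_mm, dtype=float))
        nx, ny = self.boundaries.shape[1:]
        fx = np.clip(x / self.voxel_size - 0.5, 0, nx - 1 - 1e-9)
        fy = np.clip(y / self.voxel_size - 0.5, 0, ny - 1 - 1e-9)
        ix, iy = fx.astype(int), fy.astype(int)
        wx, wy = fx - ix, fy - iy
        b = self.boundaries
        out = (b[:, ix, iy] * (1 - wx) * (1 - wy)
               + b[:, ix + 1, iy] * wx * (1 - wy)
               + b[:, ix, iy + 1] * (1 - wx) * wy
               + b[:, ix + 1, iy + 1] * wx * wy)
        return out

    def classify(self, pts: np.ndarray) -> np.ndarray:
        """Tissue class at continuous points (n, 3) mm."""
        pts = np.asarray(pts, dtype=float)
        out = np.full(pts.shape[0], BACKGROUND, dtype=np.uint16)
        inside = np.all((pts >= 0) & (pts < self.extent_mm), axis=1)
        if not np.any(inside):
            return out
        b = self.boundary_depths(pts[inside, 0], pts[inside, 1])
        z = pts[inside, 2]
        cls = np.full(z.shape, BACKGROUND, dtype=np.uint16)
        cls[(z >= b[0]) & (z < b[1])] = EPITHELIUM
        cls[(z >= b[1]) & (z < b[2])] = LPMM
        cls[(z >= b[2]) & (z < b[3])] = SUBMUCOSA
        sub = cls == SUBMUCOSA
        if self.vessels and np.any(sub):
            sub_pts = pts[inside][sub]
            vessel_hit = np.zeros(sub_pts.shape[0], dtype=bool)
            for v in self.vessels:
                vessel_hit |= v.contains(sub_pts)
            cls_sub = cls[sub]
            cls_sub[vessel_hit] = VESSEL
            cls[sub] = cls_sub
        out[inside] = cls
        return out

    def backscatter_modulation(self, pts: np.ndarray) -> np.ndarray:
        """Multiplicative tissue-texture factor (>= 0, mean ~1-ish) applied
        to backscatter_frac; deterministic in position under the phantom
        seed (the same beam-independent texture is seen by every lane).

        Two components: smooth multi-scale heterogeneity, and dark
        crypt/gland-like micro-voids (thresholded value noise) whose sharp
        edges carry the fine-scale alignment information that overlap
        self-calibration relies on."""
        pts = np.asarray(pts)
        if self.heterogeneity == 0 and self.void_contrast == 0:
            return np.ones(pts.shape[0])
        m = np.ones(pts.shape[0])
        if self.heterogeneity:
            m += self.heterogeneity * fractal_noise(
                pts, self.heterogeneity_scale, self.seed, octaves=3, stream=11)
        if self.void_contrast:
            voids = value_noise(pts, self.void_scale, self.seed,
                                stream=13) < self.void_threshold
            m = np.where(voids, m * (1.0 - self.void_contrast), m)
        return np.clip(m, 0.0, None)

    # ---- voxel view ----

    @property
    def label_grid(self) -> np.ndarray:
        """Voxelized tissue-class grid (nx, ny, nz), rasterized lazily from
        the continuous ground truth (consistent within one voxel)."""
        if self._label_grid is None:
            self._label_grid = self._rasterize()
        return self._label_grid

    def _rasterize(self) -> np.ndarray:
        n = np.maximum(1, np.round(self.extent_mm / self.voxel_size)).astype(int)
        ys = (np.arange(n[1]) + 0.5) * self.voxel_size
        zs = (np.arange(n[2]) + 0.5) * self.voxel_size
        grid = np.empty(tuple(n), dtype=np.uint16)
        Y, Z = np.meshgrid(ys, zs, indexing="ij")
        for i in range(n[0]):  # slab-wise to bound memory
            x = (i + 0.5) * self.voxel_size
            pts = np.column_stack([np.full(Y.size, x), Y.ravel(), Z.ravel()])
            grid[i] = self.classify(pts).reshape(n[1], n[2])
        return grid

    @property
    def mean_surface_mm(self) -> float:
        return float(np.mean(self.boundaries[0]))


def _surface_undulation(nx, ny, voxel, amp_mm, seed, stream):
    """Gentle long-wavelength surface height field (mm), zero mean."""
    xs = (np.arange(nx) + 0.5) * voxel
    ys = (np.arange(ny) + 0.5) * voxel
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), np.zeros(X.size)])
    span = max(nx, ny) * voxel
    h = value_noise(pts, span / 1.5, seed, stream=stream).reshape(nx, ny)
    h -= h.mean()
    peak = np.max(np.abs(h)) or 1.0
    return h / peak * amp_mm


def _rough_height(nx, ny, voxel, rms_mm, seed, stream):
    """Band-limited random roughness with the given RMS amplitude (mm).

    A seeded single-wavelength 2-D sinusoid (0.3 mm) rather than value
    noise: its local RMS is laterally uniform, so any imaged patch of an
    "irregular" lesion carries the nominal roughness instead of a lucky
    smooth spot.  The wave direction stays within 30 degrees of the lane
    axis so cross-sections (which sample along y) always see it."""
    rng = np.random.default_rng((int(seed) << 8) ^ stream)
    xs = (np.arange(nx) + 0.5) * voxel
    ys = (np.arange(ny) + 0.5) * voxel
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    alpha = rng.uniform(-np.pi / 6, np.pi / 6)  # from the y axis
    phase = rng.uniform(0, 2 * np.pi)
    k = 2 * np.pi / 0.3
    h = np.sin(k * (np.sin(alpha) * X + np.cos(alpha) * Y) + phase)
    h -= h.mean()
    rms = np.sqrt(np.mean(h ** 2)) or 1.0
    return h / rms * rms_mm


def _make_vessels(rng, count, ztop_mm, zbot_mm, extent):
    """Seeded ellipsoidal lumens confined to [ztop, zbot] in depth."""
    vessels = []
    for _ in range(int(count)):
        radii = rng.uniform(0.05, 0.15, size=3)
        lo = ztop_mm + radii[2] + 0.05
        hi = min(zbot_mm - radii[2], extent[2] - radii[2]) - 0.02
        if hi <= lo:
            continue
        cz = rng.uniform(lo, hi)
        cx = rng.uniform(0.3, extent[0] - 0.3)
        cy = rng.uniform(0.3, extent[1] - 0.3)
        vessels.append(Vessel(center=(cx, cy, cz), radii=tuple(radii)))
    return vessels


def make_normal_wall_phantom(extent_mm=(4.0, 2.0, 2.3),
                             layer_thicknesses=(0.3, 0.1, 1.6),
                             vessel_count=3, voxel_size=0.01, seed=0,
                             undulation_mm=0.02, heterogeneity=0.6,
                             void_contrast=0.85, properties=None) -> TissuePhantom:
    """Normal colorectal wall: epithelium / LP/MM / submucosa with vessels.

    ``layer_thicknesses`` = (epithelium, LP/MM, submucosa) in mm.  The
    surface sits SURFACE_MARGIN below the top of the volume, gently
    undulating; ellipsoidal vessel lumens are placed in the submucosa.
    """
    extent = np.asarray(extent_mm, dtype=float)
    t_epi, t_lpmm, t_sub = (float(t) for t in layer_thicknesses)
    if min(t_epi, t_lpmm, t_sub) <= 0:
        raise ValueError("layer thicknesses must be > 0")
    total = SURFACE_MARGIN + t_epi + t_lpmm + t_sub
    if total > extent[2]:
        raise ValueError(
            f"phantom depth extent {extent[2]} mm smaller than margin+layers "
            f"({total:.2f} mm)")

    nx = max(2, int(round(extent[0] / voxel_size)))
    ny = max(2, int(round(extent[1] / voxel_size)))
    surf = SURFACE_MARGIN + _surface_undulation(nx, ny, voxel_size,
                                                undulation_mm, seed, stream=1)
    boundaries = np.stack([surf,
                           surf + t_epi,
                           surf + t_epi + t_lpmm,
                           surf + t_epi + t_lpmm + t_sub])
    boundaries = np.minimum(boundaries, extent[2])

    rng = np.random.default_rng(seed)
    ztop = SURFACE_MARGIN + t_epi + t_lpmm
    vessels = _make_vessels(rng, vessel_count, ztop, ztop + t_sub, extent)

    return TissuePhantom(
        extent_mm=extent, voxel_size=voxel_size, boundaries=boundaries,
        properties=dict(properties or DEFAULT_PROPERTIES), vessels=vessels,
        lesion_flags={"effaced": False, "hyperreflective": False,
                      "irregular_surface": False},
        seed=int(seed), heterogeneity=heterogeneity,
        void_contrast=void_contrast)


def make_polyp_phantom(extent_mm=(4.0, 2.0, 2.5),
                       mucosal_thickness=1.0, effaced=True,
                       epithelial_backscatter_gain=1.0,
                       surface_roughness_amp=0.0,
                       submucosa_thickness=1.2,
                       lpmm_thickness=0.1,
                       vessel_count=2, voxel_size=0.01, seed=0,
                       undulation_mm=0.02, heterogeneity=0.6,
                       void_contrast=0.85, properties=None) -> TissuePhantom:
    """Polyp variant: thickened mucosa, with optional effacement of the
    LP/MM band, epithelial hyperreflectivity and surface roughness.

    ``mucosal_thickness`` covers epithelium + LP/MM (the mucosa); when
    ``effaced`` the band is merged into the mucosa and no LP/MM voxels
    remain.  ``surface_roughness_amp`` is the RMS (mm) of band-limited
    random surface height added on top of the gentle undulation.
    ``lesion_flags`` record the constructed ground truth.
    """
    if mucosal_thickness <= 0:
        raise ValueError("mucosal_thickness must be > 0")
    if epithelial_backscatter_gain < 1:
        raise ValueError("epithelial_backscatter_gain must be >= 1")
    if surface_roughness_amp >= mucosal_thickness:
        raise ValueError("surface roughness amplitude must be smaller than "
                         "the mucosal thickness")
    extent = np.asarray(extent_mm, dtype=float)
    t_lpmm = 0.0 if effaced else float(lpmm_thickness)
    t_epi = mucosal_thickness - t_lpmm
    if t_epi <= 0:
        raise ValueError("mucosal_thickness must exceed the LP/MM thickness")
    total = SURFACE_MARGIN + mucosal_thickness + submucosa_thickness
    if total > extent[2]:
        raise ValueError(
            f"phantom depth extent {extent[2]} mm smaller than margin+layers "
            f"({total:.2f} mm)")

    nx = max(2, int(round(extent[0] / voxel_size)))
    ny = max(2, int(round(extent[1] / voxel_size)))
    surf = SURFACE_MARGIN + _surface_undulation(nx, ny, voxel_size,
                                                undulation_mm, seed, stream=1)
    if surface_roughness_amp > 0:
        surf = surf + _rough_height(nx, ny, voxel_size, surface_roughness_amp,
                                    seed, stream=2)
        surf = np.clip(surf, 0.01, None)
    boundaries = np.stack([surf,
                           surf + t_epi,
                           surf + t_epi + t_lpmm,
                           surf + t_epi + t_lpmm + submucosa_thickness])
    boundaries = np.minimum(boundaries, extent[2])

    props = dict(properties or DEFAULT_PROPERTIES)
    epi = props[EPITHELIUM]
    props[EPITHELIUM] = OpticalProperties(
        epi.scattering_coeff,
        epi.backscatter_frac * float(epithelial_backscatter_gain),
        epi.refractive_index)

    rng = np.random.default_rng(seed)
    ztop = SURFACE_MARGIN + mucosal_thickness
    vessels = _make_vessels(rng, vessel_count, ztop,
                            ztop + submucosa_thickness, extent)

    return TissuePhantom(
        extent_mm=extent, voxel_size=voxel_size, boundaries=boundaries,
        properties=props, vessels=vessels,
        lesion_flags={"effaced": bool(effaced),
                      "hyperreflective": epithelial_backscatter_gain > 1,
                      "irregular_surface": surface_roughness_amp > 0},
        seed=int(seed), heterogeneity=heterogeneity,
        void_contrast=void_contrast)
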