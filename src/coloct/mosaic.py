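"""Scan conversion, multi-lane compositing, intrinsics self-calibration and
contrast enhancement.

Sector B-scans live in a cylindrical frame centred on the MEMS mirror
(apex); mosaicking projects them into Cartesian slice planes using the
probe intrinsics (field of view, mounting angle, pitches) and the stage
displacements, then composites overlapping lanes by the *nearest-slice*
rule: each pixel takes the value of the B-scan whose apex is laterally
closest (no averaging, which would make the overlap's noise statistics
visibly differ from the rest of the image).

Because field of view and mounting angle vary between sessions, they are
re-estimated from the data by maximizing the normalized cross-correlation
of log intensities over the overlap regions of adjacent lanes — the
iterative tuning step of the reconstruction procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import warnings

import numpy as np
from scipy.ndimage import binary_erosion, gaussian_filter, map_coordinates

from .optics import ProbeIntrinsics
from .reconstruct import BScanSector, ProcessedScan, process_dataset

_DB_EPS_FRAC = 1e-6


@dataclass
class CartesianImage:
    """Scan-converted image: pixels[z, y] with the apex at (y=0, z=0),
    +z into tissue.  Invalid (out-of-sector) pixels are NaN and flagged
    false in ``valid_mask``.  ``origin`` is the (y, z) mm position of pixel
    [0, 0] relative to the apex."""

    pixels: np.ndarray
    pixel_size: float            # mm
    origin: tuple                # (y0, z0) mm
    valid_mask: np.ndarray = None

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.valid_mask is None:
            self.valid_mask = ~np.isnan(self.pixels)
        self.pixels[~self.valid_mask] = np.nan

    @property
    def z_coords(self) -> np.ndarray:
        return self.origin[1] + np.arange(self.pixels.shape[0]) * self.pixel_size

    @property
    def y_coords(self) -> np.ndarray:
        return self.origin[0] + np.arange(self.pixels.shape[1]) * self.pixel_size

    def log_view(self, eps_frac: float = _DB_EPS_FRAC) -> np.ndarray:
        valid = self.pixels[self.valid_mask]
        peak = np.nanmax(valid) if valid.size else 1.0
        eps = eps_frac * (peak or 1.0)
        out = np.full_like(self.pixels, np.nan)
        out[self.valid_mask] = 20.0 * np.log10(self.pixels[self.valid_mask] + eps)
        return out


@dataclass
class MosaicSlice:
    """Stitched cross-section at one travel position with per-pixel lane
    provenance (-1 where no lane contributes)."""

    image: CartesianImage
    provenance: np.ndarray
    x_position: float
    contributing_bscans: list = field(default_factory=list)
    normalization: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.provenance.shape != self.image.pixels.shape:
            raise ValueError("provenance must match image shape")
        if np.any((self.provenance >= 0) != self.image.valid_mask):
            raise ValueError("provenance must be defined exactly on valid pixels")


# ---------------------------------------------------------------------------

def scan_convert(bscan: BScanSector, intrinsics: ProbeIntrinsics,
                 pixel_size: float, y_range=None, z_range=None,
                 min_radius=None) -> CartesianImage:
    """Project a sector B-scan onto a Cartesian grid around its apex.

    Columns are interpreted through the *assumed* intrinsics: column c sits
    at angle linspace(-fov/2, fov/2)[c] + mounting_angle, and A-scan pixel m
    at radius m * axial_pitch from the apex (the zero-delay).  Bilinear
    interpolation in (r, theta); pixels outside |theta| <= fov/2 (about the
    mounting rotation) or with r < ``min_radius`` (default 0.1 mm, masking
    the zero-delay/DC artifact region near the apex) are invalid.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    pitch_mm = bscan.axial_pitch * 1e-3
    r_max = (bscan.n_depth - 1) * pitch_mm
    r_min = 0.1 if min_radius is None else min_radius
    half = np.deg2rad(intrinsics.fov_angle / 2.0)
    m = np.deg2rad(intrinsics.mounting_angle)
    edge = max(abs(np.sin(m + half)), abs(np.sin(m - half)))
    if y_range is None:
        w = r_max * edge + pixel_size
        y_range = (-w, w)
    if z_range is None:
        z_range = (max(r_min * np.cos(half + abs(m)) - pixel_size, 0.0), r_max)
    y = np.arange(y_range[0], y_range[1] + pixel_size / 2, pixel_size)
    z = np.arange(z_range[0], z_range[1] + pixel_size / 2, pixel_size)
    Y, Z = np.meshgrid(y, z)
    r = np.hypot(Y, Z)
    theta = np.degrees(np.arctan2(Y, Z)) - intrinsics.mounting_angle
    valid = (np.abs(theta) <= intrinsics.fov_angle / 2.0) & \
            (r >= r_min) & (r <= r_max)

    ncols = len(bscan.angles)
    if ncols > 1:
        ang_pitch = (intrinsics.fov_angle) / (ncols - 1)
        col = (theta + intrinsics.fov_angle / 2.0) / ang_pitch
    else:
        # degenerate single-column fan: the vertical line under the apex
        col = np.zeros_like(theta)
        valid &= np.abs(Y) <= pixel_size / 2.0
    row = r / pitch_mm
    out = map_coordinates(bscan.columns, [row.ravel(), col.ravel()],
                          order=1, mode="constant", cval=np.nan).reshape(r.shape)
    out[~valid] = np.nan
    return CartesianImage(out, pixel_size, origin=(float(y[0]), float(z[0])),
                          valid_mask=valid & ~np.isnan(out))


def build_slice(scan, x_index: int, intrinsics: ProbeIntrinsics,
                pixel_size: float, averaging: bool = False) -> MosaicSlice:
    """Composite all lanes' B-scans at one travel step into a slice.

    Each lane's sector is scan-converted, shifted to its lane's lateral
    stage offset, and composited by the nearest-slice rule: each pixel takes
    the value from the B-scan whose apex y is closest (ties break to the
    lower lane index).  ``averaging=True`` switches to plain averaging of
    overlapping lanes, kept only for comparison.
    """
    if isinstance(scan, ProcessedScan):
        processed = scan
    else:
        processed = process_dataset(scan)
    plan = processed.plan
    lanes = []
    for lane in range(plan.n_lanes):
        if (lane, x_index) in processed.bscans:
            lanes.append(lane)
        else:
            warnings.warn(f"lane {lane} has no B-scan at step {x_index}; skipped")
    if not lanes:
        raise ValueError(f"no lane has a B-scan at step {x_index}")

    apex_y = {ln: processed.stage_positions[ln, x_index, 1] for ln in lanes}
    conv = {ln: scan_convert(processed.bscans[(ln, x_index)], intrinsics,
                             pixel_size) for ln in lanes}
    z0 = min(c.origin[1] for c in conv.values())
    z1 = max(c.z_coords[-1] for c in conv.values())
    y0 = min(apex_y[ln] + conv[ln].origin[0] for ln in lanes)
    y1 = max(apex_y[ln] + conv[ln].y_coords[-1] for ln in lanes)
    yg = np.arange(y0, y1 + pixel_size / 2, pixel_size)
    zg = np.arange(z0, z1 + pixel_size / 2, pixel_size)
    shape = (len(zg), len(yg))

    stack = np.full((len(lanes),) + shape, np.nan)
    dist = np.full((len(lanes),) + shape, np.inf)
    for i, ln in enumerate(lanes):
        c = conv[ln]
        rows = (zg - c.origin[1]) / pixel_size
        cols = (yg - (apex_y[ln] + c.origin[0])) / pixel_size
        R, C = np.meshgrid(rows, cols, indexing="ij")
        img = map_coordinates(c.pixels, [R.ravel(), C.ravel()], order=1,
                              mode="constant", cval=np.nan).reshape(shape)
        stack[i] = img
        ok = ~np.isnan(img)
        dyy = np.abs(yg[None, :] - apex_y[ln]) * np.ones((len(zg), 1))
        dist[i][ok] = dyy[ok]

    if averaging:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            pixels = np.nanmean(stack, axis=0)
        chosen = np.argmin(dist, axis=0)
    else:
        chosen = np.argmin(dist, axis=0)  # first minimum -> lower lane index
        pixels = np.take_along_axis(stack, chosen[None], axis=0)[0]
    any_valid = np.isfinite(dist).any(axis=0)
    provenance = np.where(any_valid, np.asarray(lanes)[chosen], -1)
    pixels[~any_valid] = np.nan
    image = CartesianImage(pixels, pixel_size, origin=(float(yg[0]), float(zg[0])),
                           valid_mask=any_valid & ~np.isnan(pixels))
    provenance[~image.valid_mask] = -1
    x_pos = float(processed.stage_positions[lanes[0], x_index, 0])
    return MosaicSlice(image=image, provenance=provenance, x_position=x_pos,
                       contributing_bscans=[(ln, x_index) for ln in lanes])


# ---------------------------------------------------------------------------
# intrinsics self-calibration

def _bandpass_db(pixels: np.ndarray, mask: np.ndarray, smooth_px: float,
                 highpass_px: float):
    """Log view band-passed for overlap matching.

    Speckle is uncorrelated between lanes that cross a region at different
    fan angles, while the macroscopic backscatter texture of the tissue is
    shared; a small blur (``smooth_px``) averages speckle grains down and a
    broad mask-aware high-pass (``highpass_px``, larger than the texture
    scale) removes the depth-decay profile that would correlate even when
    badly misaligned.  Filters renormalize by the blurred mask so invalid
    pixels never bleed in.
    """
    eps = _DB_EPS_FRAC * (np.nanmax(pixels[mask]) if mask.any() else 1.0)
    db = np.full(pixels.shape, np.nan)
    db[mask] = 20 * np.log10(pixels[mask] + (eps or 1.0))
    weight = mask.astype(float)
    if smooth_px > 0:
        sm = gaussian_filter(np.where(mask, db, 0.0), smooth_px)
        wt = gaussian_filter(weight, smooth_px)
        with np.errstate(invalid="ignore"):
            db = np.where(mask, sm / wt, np.nan)
    low_in = np.where(mask, db, 0.0)
    sm = gaussian_filter(low_in, highpass_px)
    wt = gaussian_filter(weight, highpass_px)
    with np.errstate(invalid="ignore"):
        low = sm / wt
    out = db - low
    out[~mask] = np.nan
    return out


def _overlap_ncc(processed: ProcessedScan, intrinsics: ProbeIntrinsics,
                 pixel_size: float, x_indices, min_pixels: int = 64,
                 smooth_sigma_px: float = 3.0, highpass_sigma_px: float = 25.0,
                 edge_margin_px: int = 4) -> float:
    """Mean normalized cross-correlation of band-passed log intensities over
    the overlap of adjacent lanes across the sampled slices.

    Pixels within ``edge_margin_px`` of either sector boundary are excluded:
    filter residues along the mask edge otherwise correlate with the assumed
    geometry itself and bias the optimum.
    """
    plan = processed.plan
    scores = []
    for xi in x_indices:
        conv = {}
        for ln in range(plan.n_lanes):
            if (ln, xi) in processed.bscans:
                conv[ln] = scan_convert(processed.bscans[(ln, xi)],
                                        intrinsics, pixel_size)
        for ln in sorted(conv)[:-1]:
            if ln + 1 not in conv:
                continue
            a, b = conv[ln], conv[ln + 1]
            ya = processed.stage_positions[ln, xi, 1]
            yb = processed.stage_positions[ln + 1, xi, 1]
            # sample b on a's grid, shifted by the lane offset
            rows = (a.z_coords - b.origin[1]) / pixel_size
            cols = (a.y_coords + ya - yb - b.origin[0]) / pixel_size
            R, C = np.meshgrid(rows, cols, indexing="ij")
            bb = map_coordinates(b.pixels, [R.ravel(), C.ravel()], order=1,
                                 mode="constant", cval=np.nan).reshape(a.pixels.shape)
            ma, mb = a.valid_mask, ~np.isnan(bb)
            both = ma & mb
            if edge_margin_px:
                both = (binary_erosion(ma, iterations=edge_margin_px)
                        & binary_erosion(mb, iterations=edge_margin_px))
            if both.sum() < min_pixels:
                continue
            la = _bandpass_db(a.pixels, ma, smooth_sigma_px,
                              highpass_sigma_px)[both]
            lb = _bandpass_db(bb, mb, smooth_sigma_px,
                              highpass_sigma_px)[both]
            la = la - la.mean()
            lb = lb - lb.mean()
            denom = np.sqrt((la ** 2).sum() * (lb ** 2).sum())
            if denom > 0:
                scores.append(float((la * lb).sum() / denom))
    if not scores:
        raise ValueError("no genuine lane overlap at these parameters; "
                         "cannot evaluate overlap quality")
    return float(np.mean(scores))


def _golden_section(f, lo, hi, tol, trace):
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    trace += [(c, fc), (d, fd)]
    while (b - a) > tol:
        if fc > fd:  # maximize
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
            trace.append((c, fc))
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
            trace.append((d, fd))
    return (a + b) / 2.0


def tune_intrinsics(scan, init: ProbeIntrinsics, free_params=("fov_angle",),
                    bounds=None, pixel_size: float = 0.004,
                    grid_step: float = 0.5, refine_tol: float = 0.02,
                    n_passes: int = 2, slice_stride: int = 10,
                    max_slices: int = 15):
    """Recover inexact reconstruction parameters from overlap quality.

    Coordinate-wise, derivative-free maximization of the mean overlap NCC:
    a coarse grid (``grid_step`` degrees) over each free parameter's bounds
    followed by golden-section refinement, repeated for ``n_passes`` passes.
    Deterministic given the dataset.  Returns (refined intrinsics, trace)
    where trace is a list of (param_name, value, objective) evaluations.

    ``bounds`` maps parameter name to (lo, hi); default is init +/- 4 deg.
    Slices every ``slice_stride`` steps (capped at ``max_slices``) keep the
    objective desk-scale.
    """
    allowed = {"fov_angle", "mounting_angle"}
    if not set(free_params) <= allowed:
        raise ValueError(f"free_params must be a subset of {allowed}")
    processed = scan if isinstance(scan, ProcessedScan) else process_dataset(scan)
    if processed.plan.n_lanes < 2:
        raise ValueError("tuning requires at least two lanes with overlap")
    nsteps = processed.plan.steps_per_lane
    x_indices = list(range(0, nsteps, slice_stride))[:max_slices]
    bounds = dict(bounds or {})
    for p in free_params:
        bounds.setdefault(p, (getattr(init, p) - 4.0, getattr(init, p) + 4.0))

    current = {p: float(getattr(init, p)) for p in free_params}
    trace = []

    def objective(**over):
        intr = replace(init, **{**current, **over})
        return _overlap_ncc(processed, intr, pixel_size, x_indices)

    # fail early (with diagnostic) if there is no overlap at the init
    objective()

    for _ in range(n_passes):
        for p in free_params:
            lo, hi = bounds[p]
            grid = np.arange(lo, hi + grid_step / 2, grid_step)
            vals = [objective(**{p: g}) for g in grid]
            trace += [(p, float(g), float(v)) for g, v in zip(grid, vals)]
            best = int(np.argmax(vals))
            glo = grid[max(best - 1, 0)]
            ghi = grid[min(best + 1, len(grid) - 1)]
            local = []
            opt = _golden_section(lambda v: objective(**{p: v}), glo, ghi,
                                  refine_tol, local)
            trace += [(p, float(v), float(s)) for v, s in local]
            current[p] = float(opt)
    refined = replace(init, **current)
    return refined, trace


# ---------------------------------------------------------------------------

def enhance_contrast(slices, percentile_window=(1.0, 99.0), gamma: float = 0.7):
    """'Equal normalization' + gamma correction across all slices of a
    sample: percentiles of the pooled valid pixels define one linear window
    applied to every slice, followed by x**gamma.  Accepts a single slice or
    a list; returns the same shape of input.  Masked pixels are untouched.
    """
    low, high = percentile_window
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    if not (0 <= low < high <= 100):
        raise ValueError("percentile window must satisfy 0 <= low < high <= 100")
    single = isinstance(slices, MosaicSlice)
    group = [slices] if single else list(slices)
    pooled = np.concatenate([
        s.image.pixels[s.image.valid_mask].ravel() for s in group])
    if pooled.size == 0:
        raise ValueError("no valid pixels to normalize")
    p_lo, p_hi = np.percentile(pooled, [low, high])
    out = []
    for s in group:
        img = s.image
        pix = img.pixels.copy()
        if p_hi == p_lo:
            warnings.warn("constant image: all valid pixels map to 0")
            pix[img.valid_mask] = 0.0
        else:
            x = (pix[img.valid_mask] - p_lo) / (p_hi - p_lo)
            pix[img.valid_mask] = np.clip(x, 0.0, 1.0) ** gamma
        new_img = CartesianImage(pix, img.pixel_size, img.origin,
                                 valid_mask=img.valid_mask.copy())
        out.append(MosaicSlice(
            image=new_img, provenance=s.provenance.copy(),
            x_position=s.x_position,
            contributing_bscans=list(s.contributing_bscans),
            normalization={"p_low": float(p_lo), "p_high": float(p_hi),
                           "gamma": float(gamma),
                           "percentile_window": (float(low), float(high))}))
    return out[0] if single else out
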