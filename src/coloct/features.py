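"""Quantitative operationalization of the qualitative OCT reading criteria
for colorectal lesions.

The reading criteria — epithelial hyperreflectivity, effacement (loss of the
layered wall structure, i.e. absence of the bright lamina propria /
muscularis mucosae band), and surface irregularity of at least half of a
lesion's images — are defined only verbally in clinical practice.  Here
each becomes an explicit, threshold-configurable operator on reconstructed
images, plus two quantitative extras: imaging depth and the single-scatter
attenuation coefficient (intensity ~ exp(-2 mu z)).

All operators work on the dB (20 log10 amplitude) view of a Cartesian image
whose columns are lateral positions and rows are depths.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import warnings

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .mosaic import CartesianImage


class SurfaceUndefinedError(ValueError):
    """Raised when too few columns show a detectable tissue surface."""


@dataclass
class FeatureConfig:
    """Thresholds of the feature operators (config-exposed; the source
    criteria are verbal, so every number here is an explicit choice)."""

    surface_snr_db: float = 6.0        # surface = first crossing of floor + this
    surface_clear_px: int = 20         # background pixels required above it
    surface_jump_mm: float = 0.1       # adjacent-column depth jump splitting runs
    band_contrast_db: float = 3.0      # LP/MM local max must exceed window median by this
    seg_lateral_smooth_px: float = 8.0  # extra lateral smoothing for layering
    band_fraction_threshold: float = 0.3   # effacement when band fraction < this
    hyper_threshold_db: float = 3.0    # epithelium - submucosa mean dB
    roughness_threshold_mm: float = 0.030  # RMS residual about quadratic fit
    depth_snr_db: float = 3.0          # imaging depth = last crossing of floor + this
    axial_smooth_px: float = 2.0
    lateral_smooth_px: float = 2.0
    band_search_mm: tuple = (0.05, 0.8)    # window below surface for the band
    split_search_mm: tuple = (0.3, 1.2)    # change-point window for the split
    default_mucosa_mm: float = 0.4     # epi/sub split fallback (band + fit absent)
    sub_band_mm: float = 0.35          # submucosal reference thickness below split
    attenuation_compensation: bool = False


@dataclass
class LayerSegmentation:
    """Per-column layering: surface depth, optional LP/MM band, and
    epithelium / submucosa pixel masks with per-column confidence."""

    surface_depth: np.ndarray      # mm (z coordinate), NaN where absent
    lpmm_band: np.ndarray          # (2, ncols) mm top/bottom, NaN where absent
    epithelium_mask: np.ndarray
    submucosa_mask: np.ndarray
    quality: np.ndarray            # per-column in [0, 1]

    def __post_init__(self):
        if np.any(self.epithelium_mask & self.submucosa_mask):
            raise ValueError("layer masks must be disjoint")
        ok = ~np.isnan(self.lpmm_band[0])
        if np.any(self.lpmm_band[0, ok] <= self.surface_depth[ok]):
            raise ValueError("LP/MM band must lie below the surface")

    @property
    def band_fraction(self) -> float:
        cols = ~np.isnan(self.surface_depth)
        if not cols.any():
            return 0.0
        return float(np.mean(~np.isnan(self.lpmm_band[0][cols])))


@dataclass
class FeatureReport:
    """Quantitative lesion features for one sample."""

    hyperreflectivity_ratio: float
    hyperreflective: bool
    effacement: bool
    irregular_fraction: float
    irregular: bool
    imaging_depth: float           # mm
    attenuation: dict              # region -> (mu per mm, R^2)
    n_images: int
    band_fraction: float = float("nan")
    config: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.irregular_fraction <= 1.0):
            raise ValueError("irregular_fraction must lie in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# helpers

def _db_image(image: CartesianImage, cfg: FeatureConfig) -> np.ndarray:
    db = image.log_view()
    if cfg.lateral_smooth_px > 0:
        filled = np.where(np.isnan(db), np.nanmin(db), db)
        db = np.where(np.isnan(db), np.nan,
                      gaussian_filter1d(filled, cfg.lateral_smooth_px, axis=1))
    if cfg.axial_smooth_px > 0:
        filled = np.where(np.isnan(db), np.nanmin(db), db)
        db = np.where(np.isnan(db), np.nan,
                      gaussian_filter1d(filled, cfg.axial_smooth_px, axis=0))
    return db


def noise_floor_db(db: np.ndarray) -> float:
    """Noise floor = mean + 2 SD of the deepest 10% of (valid) pixels."""
    nrows = db.shape[0]
    deep = db[int(np.ceil(nrows * 0.9)):]
    deep = deep[~np.isnan(deep)]
    if deep.size == 0:
        deep = db[~np.isnan(db)]
    return float(deep.mean() + 2.0 * deep.std())


# ---------------------------------------------------------------------------
# operators

def detect_surface(image: CartesianImage, cfg: FeatureConfig = None,
                   min_fraction: float = 0.5) -> np.ndarray:
    """Per-column tissue-surface depth (mm): first depth at which the
    axially smoothed dB intensity exceeds the noise floor + 6 dB.

    A crossing only counts as the air/fluid-tissue boundary if the column
    shows some below-threshold background above it — sector-clipped columns
    (common near the edges of a forward-looking cone, whose apex sits close
    to the surface) are marked absent rather than mislocated.  If more than
    ``1 - min_fraction`` of the columns are absent, SurfaceUndefinedError is
    raised.
    """
    cfg = cfg or FeatureConfig()
    db = _db_image(image, cfg)
    thr = noise_floor_db(db) + cfg.surface_snr_db
    z = image.z_coords
    ncols = db.shape[1]
    out = np.full(ncols, np.nan)
    for c in range(ncols):
        valid = np.flatnonzero(~np.isnan(db[:, c]))
        if valid.size < 4:
            continue
        colv = db[valid, c]
        idx = np.flatnonzero(colv > thr)
        # a clear run of background above the crossing distinguishes the
        # true boundary from the sector edge clipping through tissue; the
        # signal below it must be sustained and strong (the air/fluid-tissue
        # jump is tens of dB, unlike grazing cuts through attenuated tissue)
        if idx.size and idx[0] >= cfg.surface_clear_px:
            j = idx[0]
            after = colv[j:j + 10]
            above = colv[max(j - cfg.surface_clear_px, 0):j]
            if np.median(after) > thr + cfg.surface_snr_db and \
                    np.median(above) < thr:
                out[c] = z[valid[j]]
    # single-column outliers (speckle dropouts) -> median of neighbours
    ok = np.flatnonzero(~np.isnan(out))
    if ok.size >= 5:
        from scipy.signal import medfilt
        sm = medfilt(out[ok], kernel_size=5)
        spike = np.abs(out[ok] - sm) > 5 * image.pixel_size
        out[ok[spike]] = sm[spike]
    # grazing cuts along the sector edge mimic a surface but join the true
    # surface with a depth jump; keep only the dominant smooth runs
    ok = np.flatnonzero(~np.isnan(out))
    if ok.size >= 5:
        jump = np.abs(np.diff(out[ok])) > cfg.surface_jump_mm + \
            image.pixel_size * np.diff(ok)
        run_id = np.concatenate([[0], np.cumsum(jump)])
        lengths = np.bincount(run_id)
        keep_runs = np.flatnonzero(lengths >= max(5, lengths.max() // 2))
        drop = ~np.isin(run_id, keep_runs)
        out[ok[drop]] = np.nan
    if np.isnan(out).mean() > 1.0 - min_fraction:
        raise SurfaceUndefinedError(
            "surface undefined: too few columns cross the noise floor + "
            "{:.0f} dB".format(cfg.surface_snr_db))
    return out


def segment_layers(image: CartesianImage, surface: np.ndarray,
                   cfg: FeatureConfig = None) -> LayerSegmentation:
    """Find the bright LP/MM band below the surface and split the image
    into epithelium and submucosa masks.

    Per column the band is a local maximum of the smoothed dB profile in
    the search window that stands at least ``band_contrast_db`` above the
    window median; its extent is where the profile stays above median +
    half the contrast.  Columns without a band are split at
    ``default_mucosa_mm`` below the surface with quality <= 0.5.
    """
    cfg = cfg or FeatureConfig()
    db = _db_image(image, cfg)
    # the LP/MM band is laterally continuous while speckle/texture are not:
    # extra lateral smoothing before the per-column search
    db_s = db
    if cfg.seg_lateral_smooth_px > 0:
        filled = np.where(np.isnan(db), np.nanmin(db), db)
        db_s = np.where(np.isnan(db), np.nan,
                        gaussian_filter1d(filled, cfg.seg_lateral_smooth_px,
                                          axis=1))
    z = image.z_coords
    pitch = image.pixel_size
    nrows, ncols = db.shape
    floor = noise_floor_db(db)

    # --- global band depth from the surface-flattened mean profile.
    # A true layer sits at a consistent depth below the surface in every
    # column, so it survives averaging that washes speckle and texture out.
    n_flat = int(max(cfg.band_search_mm[1], cfg.split_search_mm[1] + 0.2)
                 / pitch) + 2
    acc = np.full((ncols, n_flat), np.nan)
    for c in range(ncols):
        if np.isnan(surface[c]):
            continue
        r0 = int(round((surface[c] - z[0]) / pitch))
        seg_col = db[r0:r0 + n_flat, c]
        acc[c, :len(seg_col)] = seg_col
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_prof = np.nanmean(acc, axis=0)
    zb = np.arange(n_flat) * pitch
    search = (zb >= cfg.band_search_mm[0]) & (zb <= cfg.band_search_mm[1]) \
        & ~np.isnan(mean_prof)
    band_depth = np.nan
    comp_prof = mean_prof
    if search.sum() >= 5:
        # remove the bulk attenuation decay, then ask for a peak that
        # stands above the *submucosal* level just below it — this contrast
        # (LP/MM vs submucosa backscatter) is unaffected by how bright the
        # epithelium above happens to be
        slope = np.polyfit(zb[search], mean_prof[search], 1)[0]
        # quadratic baseline absorbs the attenuation decay including its
        # curvature (surface overshoot, deep rolloff); the narrow band does
        # not fit a quadratic.  Refit with the candidate region excluded so
        # the peak does not drag its own baseline up.
        quad = np.polyfit(zb[search], mean_prof[search], 2)
        comp_prof = mean_prof - np.polyval(quad, zb)
        j = int(np.nanargmax(np.where(search, comp_prof, -np.inf)))
        excl = search & (np.abs(zb - zb[j]) > 0.1)
        if excl.sum() >= 8:
            quad2 = np.polyfit(zb[excl], mean_prof[excl], 2)
            comp_prof = mean_prof - np.polyval(quad2, zb)
            # stricter than the per-column confirmation: the averaged
            # profile has little noise, so a genuine band clears this easily
            if comp_prof[j] >= cfg.band_contrast_db + 1.0:
                # a true layer is depth-consistent: most columns must place
                # their own brightest point near the candidate depth, which
                # scattered texture blobs do not
                peaks = []
                for c in np.flatnonzero(~np.isnan(surface)):
                    r0 = int(round((surface[c] - z[0]) / pitch))
                    cc = db_s[r0:r0 + n_flat, c] - slope * zb[:max(
                        0, min(n_flat, db_s.shape[0] - r0))]
                    cc = cc[(zb[:len(cc)] >= cfg.band_search_mm[0])
                            & (zb[:len(cc)] <= cfg.band_search_mm[1])]
                    if len(cc) >= 5 and not np.all(np.isnan(cc)):
                        off = np.flatnonzero(
                            (zb >= cfg.band_search_mm[0]))[0]
                        peaks.append(zb[off + int(np.nanargmax(cc))])
                if peaks and np.mean(
                        np.abs(np.asarray(peaks) - zb[j]) <= 0.08) >= 0.6:
                    band_depth = zb[j]

    # --- without a band, place the mucosa/submucosa split at the best
    # change-point of a two-segment linear fit of the mean depth profile:
    # the deeper layer differs in attenuation slope and (for a brighter
    # mucosa) in level, both of which the broken-stick fit picks up.
    split_depth = cfg.default_mucosa_mm
    if np.isnan(band_depth):
        lo, hi = cfg.split_search_mm
        usable = ~np.isnan(mean_prof) & (zb >= 0.05) \
            & (zb <= hi + 0.2) & (mean_prof > floor + cfg.depth_snr_db)
        if usable.any():
            # keep the split above the fade-out so a submucosal region
            # with measurable signal always remains below it
            hi = min(hi, np.max(zb[usable]) - 0.25)
        knots = zb[(zb >= lo) & (zb <= hi)][::2]
        best = (np.inf, None)
        for knot in knots:
            a_seg = usable & (zb < knot)
            b_seg = usable & (zb >= knot + 0.03)
            if a_seg.sum() < 6 or b_seg.sum() < 6:
                continue
            sse = 0.0
            for seg in (a_seg, b_seg):
                coef = np.polyfit(zb[seg], mean_prof[seg], 1)
                sse += np.sum((mean_prof[seg] - np.polyval(coef, zb[seg])) ** 2)
            if sse < best[0]:
                best = (sse, knot)
        if best[1] is not None:
            split_depth = float(np.clip(best[1], 0.15, cfg.split_search_mm[1]))

    band = np.full((2, ncols), np.nan)
    quality = np.zeros(ncols)
    epi = np.zeros_like(db, dtype=bool)
    sub = np.zeros_like(db, dtype=bool)
    for c in range(ncols):
        s = surface[c]
        if np.isnan(s):
            continue
        split = s + split_depth
        q = 0.3
        if not np.isnan(band_depth):
            # confirm the band locally around the global depth, against the
            # column's own (decay-compensated) submucosal level below it
            comp_col = db_s[:, c] - slope * (z - s)
            zlo = s + band_depth - 0.08
            zhi = s + band_depth + 0.08
            win = np.flatnonzero((z >= max(zlo, s + 0.02)) & (z <= zhi)
                                 & ~np.isnan(comp_col))
            ref = np.flatnonzero((z > s + band_depth + 0.08)
                                 & (z <= s + band_depth + 0.25)
                                 & ~np.isnan(comp_col))
            if win.size >= 3 and ref.size >= 3:
                prof = comp_col[win]
                med = np.median(comp_col[ref])
                jj = int(np.argmax(prof))
                if prof[jj] >= med + cfg.band_contrast_db / 2.0:
                    half_thr = (prof[jj] + med) / 2.0
                    top = jj
                    while top > 0 and prof[top - 1] >= half_thr:
                        top -= 1
                    bot = jj
                    while bot < win.size - 1 and prof[bot + 1] >= half_thr:
                        bot += 1
                    band[0, c] = z[win[top]]
                    band[1, c] = z[win[bot]]
                    q = min(1.0, (prof[jj] - med)
                            / (2.0 * cfg.band_contrast_db) + 0.5)
        quality[c] = q
        if not np.isnan(band[0, c]):
            epi[:, c] = (z >= s) & (z < band[0, c])
            sub_top = band[1, c]
        else:
            epi[:, c] = (z >= s) & (z < split)
            sub_top = split
        # submucosal reference: the band just below the boundary, cut off at
        # the signal fade-out — deeper pixels sit on the noise floor and
        # would drag the regional mean toward it
        deep = np.flatnonzero(db_s[:, c] > floor + cfg.depth_snr_db)
        z_deep = z[deep[-1]] if deep.size else z[-1]
        if z_deep - 0.05 > sub_top + 3 * pitch:
            z_deep -= 0.05  # back off from the fade-out edge
        sub[:, c] = (z > sub_top) & (z <= min(z_deep,
                                              sub_top + cfg.sub_band_mm))
    valid = ~np.isnan(db)
    epi &= valid
    sub &= valid
    return LayerSegmentation(surface_depth=np.asarray(surface, float),
                             lpmm_band=band, epithelium_mask=epi,
                             submucosa_mask=sub, quality=quality)


def _flat_median_profile(db, zz, pitch, max_mm=1.6):
    """Surface-flattened column-MEDIAN dB profile.

    The lateral median at each depth-below-surface bin is robust against
    the minority of columns crossing a crypt void or vessel, which would
    otherwise swing pooled regional means by decibels."""
    n = int(max_mm / pitch)
    zb = (np.arange(n) + 0.5) * pitch
    prof = np.full(n, np.nan)
    finite = ~np.isnan(db) & np.isfinite(zz)
    bins = np.full(zz.shape, -1, dtype=int)
    bins[finite] = np.floor(zz[finite] / pitch).astype(int)
    ok = finite & (bins >= 0) & (bins < n)
    b = bins[ok]
    v = db[ok]
    order = np.argsort(b, kind="stable")
    b, v = b[order], v[order]
    edges = np.searchsorted(b, np.arange(n + 1))
    for i in range(n):
        seg_v = v[edges[i]:edges[i + 1]]
        if seg_v.size >= 5:
            prof[i] = np.median(seg_v)
    return zb, prof


def _band_excess_loss(db, z, seg, epi_slope, pitch):
    """Excess one-way transmission loss (dB, >= 0) through the LP/MM band.

    The band's *internal* decay is observable; aligning columns by each
    column's own band top (rather than by the surface) keeps the estimate
    sharp even when surface jitter smears surface-flattened profiles."""
    if not np.any(np.isfinite(seg.lpmm_band[0])):
        return 0.0
    thick = np.nanmedian(seg.lpmm_band[1] - seg.lpmm_band[0])
    if not np.isfinite(thick) or thick < 4 * pitch:
        return 0.0
    rel, val = [], []
    for c in np.flatnonzero(np.isfinite(seg.lpmm_band[0])):
        top, bot = seg.lpmm_band[0, c], seg.lpmm_band[1, c]
        sel = np.flatnonzero((z >= top + pitch) & (z <= bot - pitch)
                             & ~np.isnan(db[:, c]))
        rel.extend(z[sel] - top)
        val.extend(db[sel, c])
    if len(rel) < 30:
        return 0.0
    slope_band = np.polyfit(rel, val, 1)[0]
    excess = (epi_slope - slope_band) * thick  # both slopes negative
    return float(np.clip(excess, 0.0, 8.0))


def _region_fit(db, zz, mask):
    """Pooled linear fit of dB against depth-below-surface within a region;
    returns (slope dB/mm, intercept dB at depth 0, n)."""
    sel = mask & ~np.isnan(db) & (zz > 0)
    if sel.sum() < 20:
        return None
    slope, intercept = np.polyfit(zz[sel], db[sel], 1)
    return float(slope), float(intercept), int(sel.sum())


def hyperreflectivity(image: CartesianImage, seg: LayerSegmentation,
                      cfg: FeatureConfig = None):
    """Mean dB over the epithelium minus mean dB over the submucosa.

    With ``attenuation_compensation`` the dB image is detrended by the
    pooled single-scatter attenuation estimate before comparing, removing
    the depth-induced offset between the (shallow) epithelium and (deep)
    submucosa.  Returns (ratio_db, flag).
    """
    cfg = cfg or FeatureConfig()
    if not seg.epithelium_mask.any() or not seg.submucosa_mask.any():
        raise ValueError("hyperreflectivity undefined: empty layer mask")
    db = _db_image(image, cfg)
    zz = image.z_coords[:, None] - seg.surface_depth[None, :]
    if cfg.attenuation_compensation:
        # backscatter-level comparison: fit each region's own decay line,
        # read the epithelium at the surface and the submucosa at its top
        # boundary, and undo the transmission loss through the mucosa with
        # the epithelium's own slope.  In the single-scatter model
        # dB = level - k*z this is exactly the backscatter step, whatever
        # the attenuation coefficients are.
        if not seg.submucosa_mask.any():
            raise ValueError("hyperreflectivity undefined: region too small")
        d = float(np.nanmedian(zz[seg.submucosa_mask.cumsum(axis=0).cumsum(
            axis=0) == 1]))
        pitch = image.pixel_size
        zb, prof = _flat_median_profile(db, zz, pitch)
        # epithelium line fitted on the flattened median profile, skipping
        # the surface overshoot
        epi_top = np.nanmedian(zz[seg.epithelium_mask.cumsum(axis=0).cumsum(
            axis=0) == 1]) if seg.epithelium_mask.any() else 0.0
        epi_end = d - 0.03
        if np.any(np.isfinite(seg.lpmm_band[0])):
            # stop above the band: its brightness is not epithelium
            epi_end = float(np.nanmedian(seg.lpmm_band[0]
                                         - seg.surface_depth)) - 0.03
        epi_rng = (zb >= max(0.06, epi_top)) & (zb <= epi_end) \
            & ~np.isnan(prof)
        if epi_rng.sum() < 8:
            raise ValueError("hyperreflectivity undefined: region too small")
        s_e, a_e = np.polyfit(zb[epi_rng], prof[epi_rng], 1)
        # submucosal level at its top: median-profile level in the
        # reference band, shifted by the epithelium's slope over the small
        # distance to the boundary (the sub region is too thin for its own)
        sub_rng = (zb > d + 0.02) & (zb <= d + cfg.sub_band_mm) \
            & ~np.isnan(prof)
        if sub_rng.sum() < 5:
            raise ValueError("hyperreflectivity undefined: region too small")
        sub_mean = float(np.mean(prof[sub_rng]))
        sub_at_top = sub_mean - s_e * (float(np.mean(zb[sub_rng])) - d)
        ratio = float(a_e - sub_at_top + s_e * d)
        # The bright LP/MM band attenuates more strongly than the mucosa
        # above it; its *internal* decay is observable and yields the extra
        # transmission loss the mucosa-slope correction misses.
        ratio -= _band_excess_loss(db, image.z_coords, seg, s_e, pitch)
    else:
        ratio = float(np.nanmean(db[seg.epithelium_mask])
                      - np.nanmean(db[seg.submucosa_mask]))
    return ratio, ratio > cfg.hyper_threshold_db


def effacement(seg: LayerSegmentation, cfg: FeatureConfig = None) -> bool:
    """Effaced when the LP/MM band is found in fewer than
    ``band_fraction_threshold`` of the surfaced columns (strict <)."""
    cfg = cfg or FeatureConfig()
    return seg.band_fraction < cfg.band_fraction_threshold


def surface_irregularity(surfaces, pixel_free: bool = True,
                         cfg: FeatureConfig = None):
    """Share of a lesion's images with a non-smooth surface.

    ``surfaces`` is a list of per-column surface-depth profiles (mm, NaN
    allowed).  An image is smooth when the RMS residual of its surface
    about a 2nd-order polynomial fit is below ``roughness_threshold_mm``.
    Flag is true when at least 50% of the images are non-smooth.
    Returns (fraction, flag).
    """
    cfg = cfg or FeatureConfig()
    rough = []
    for s in surfaces:
        s = np.asarray(s, float)
        ok = ~np.isnan(s)
        if ok.sum() < 4:
            continue
        x = np.flatnonzero(ok).astype(float)
        coef = np.polyfit(x, s[ok], 2)
        resid = s[ok] - np.polyval(coef, x)
        rough.append(np.sqrt(np.mean(resid ** 2)) >= cfg.roughness_threshold_mm)
    if not rough:
        raise SurfaceUndefinedError("all surfaces undefined")
    fraction = float(np.mean(rough))
    return fraction, fraction >= 0.5


def imaging_depth(image: CartesianImage, surface: np.ndarray = None,
                  cfg: FeatureConfig = None) -> float:
    """Median over columns of (deepest depth with smoothed intensity above
    noise floor + 3 dB) minus the surface depth, mm."""
    cfg = cfg or FeatureConfig()
    if surface is None:
        surface = detect_surface(image, cfg)
    ok = ~np.isnan(surface)
    if ok.mean() < 0.5:
        raise SurfaceUndefinedError("surface defined for <50% of columns")
    db = _db_image(image, cfg)
    thr = noise_floor_db(db) + cfg.depth_snr_db
    z = image.z_coords
    depths = []
    for c in np.flatnonzero(ok):
        idx = np.flatnonzero(db[:, c] > thr)
        if idx.size:
            depths.append(z[idx[-1]] - surface[c])
    if not depths:
        raise SurfaceUndefinedError("no column exceeds the noise floor")
    return float(np.median(depths))


def attenuation_coefficient(profile, axial_pitch_mm: float,
                            fit_window_mm) -> tuple:
    """Single-scatter attenuation from a linear-amplitude depth profile.

    Fits ln(intensity) = ln(amplitude^2) against depth over
    ``fit_window_mm`` = (lo, hi) relative to the profile start and returns
    (mu, r_squared) with mu = -slope/2 per mm.  ``profile`` may be one
    A-scan or an average of many (averaging first tames speckle).
    """
    profile = np.asarray(profile, dtype=float)
    lo, hi = fit_window_mm
    i0 = int(np.ceil(lo / axial_pitch_mm))
    i1 = int(np.floor(hi / axial_pitch_mm))
    if i1 - i0 + 1 < 5:
        raise ValueError("fit window shorter than 5 axial pixels")
    z = np.arange(i0, i1 + 1) * axial_pitch_mm
    seg = profile[i0:i1 + 1]
    if np.any(seg <= 0):
        seg = np.clip(seg, seg[seg > 0].min() * 1e-6, None)
    y = 2.0 * np.log(seg)  # ln(intensity), intensity = amplitude^2
    slope, intercept = np.polyfit(z, y, 1)
    pred = slope * z + intercept
    ss_res = np.sum((y - pred) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(-slope / 2.0), float(r2)


# ---------------------------------------------------------------------------

def analyze_sample(images, cfg: FeatureConfig = None,
                   attenuation_window_mm=(0.1, 0.6)) -> FeatureReport:
    """Full feature report for one lesion from its reconstructed images.

    Surface irregularity is judged across all images; layering,
    hyperreflectivity, effacement, imaging depth and attenuation are taken
    from the middle image (features vary little along a lesion at the
    phantom's scale, and the middle slice avoids edge effects).
    """
    cfg = cfg or FeatureConfig()
    images = list(images)
    if not images:
        raise ValueError("no images")
    # A forward-looking cone only sees the surface in a wedge under each
    # apex; crop every image to its surfaced column range so the per-column
    # operators work where the surface is actually defined.
    cropped, surfaces = [], []
    for im in images:
        try:
            s = detect_surface(im, cfg, min_fraction=0.02)
        except SurfaceUndefinedError:
            surfaces.append(np.full(im.pixels.shape[1], np.nan))
            cropped.append(im)
            continue
        cols = np.flatnonzero(~np.isnan(s))
        lo, hi = cols[0], cols[-1] + 1
        im2 = CartesianImage(im.pixels[:, lo:hi].copy(), im.pixel_size,
                             (im.origin[0] + lo * im.pixel_size, im.origin[1]),
                             valid_mask=im.valid_mask[:, lo:hi].copy())
        cropped.append(im2)
        surfaces.append(s[lo:hi])
    images = cropped
    frac, irregular = surface_irregularity(surfaces, cfg=cfg)

    # per-image measurements, aggregated by median for stability
    ratios, fracs, depths = [], [], []
    for image, surface in zip(images, surfaces):
        if np.all(np.isnan(surface)):
            continue
        try:
            seg_i = segment_layers(image, surface, cfg)
            ratios.append(hyperreflectivity(image, seg_i, cfg)[0])
            fracs.append(seg_i.band_fraction)
            depths.append(imaging_depth(image, surface, cfg))
        except (ValueError, SurfaceUndefinedError):
            continue
    if not ratios:
        raise SurfaceUndefinedError("no analyzable image in the sample")
    ratio = float(np.median(ratios))
    hyper = ratio > cfg.hyper_threshold_db
    band_frac = float(np.median(fracs))
    effaced = band_frac < cfg.band_fraction_threshold
    depth = float(np.median(depths))
    mid = len(images) // 2
    image, surface = images[mid], surfaces[mid]
    seg = segment_layers(image, surface, cfg)

    db = _db_image(image, cfg)
    z = image.z_coords
    # median linear-intensity profile below the surface, columns aligned
    pitch = image.pixel_size
    max_rows = int(0.9 / pitch)
    cols = np.flatnonzero(~np.isnan(surface))
    prof = np.full((len(cols), max_rows), np.nan)
    for i, c in enumerate(cols):
        r0 = int(round((surface[c] - z[0]) / pitch))
        seg_col = image.pixels[r0:r0 + max_rows, c]
        prof[i, :len(seg_col)] = seg_col
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_prof = np.nanmean(prof ** 2, axis=0)
    mean_prof = np.sqrt(np.where(np.isnan(mean_prof), 0.0, mean_prof))
    attn = {}
    try:
        mu, r2 = attenuation_coefficient(mean_prof, pitch, attenuation_window_mm)
        attn["bulk"] = {"mu_per_mm": mu, "r_squared": r2}
    except ValueError:
        pass
    return FeatureReport(
        hyperreflectivity_ratio=ratio, hyperreflective=hyper,
        effacement=effaced, irregular_fraction=frac, irregular=irregular,
        imaging_depth=depth, attenuation=attn, n_images=len(images),
        band_fraction=band_frac, config=asdict(cfg))
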