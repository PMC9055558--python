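"""Matching model observers: PM, LPM, and LFM.

All three observers share one matching core: a candidate surface geometry
predicts one eye's (filtered) image from the other eye's through the
plane-induced projection, and the candidate minimizing the prediction
error — plus the negative log prior, constant here under the uniform
prior — is the estimate.

* PM (planar matching) searches global plane parameters (slant s,
  intercept distance zeta) over the whole analysis rectangle.  It is the
  approximate ideal observer for planar surfaces in uncorrelated noise.
* LPM (local planar matching) applies the same search to square patches,
  parametrized locally by (slant s_i, patch distance z_i), then pools the
  per-patch estimates: a global slant/intercept from the distance map
  (regression of z_i on lateral position), a second slant estimate from
  the slant map (mean), combined by reliability weighting.
* LFM (local frontoparallel matching) is LPM with the local slant clamped
  to zero — a pure horizontal-shift (location-disparity) search,
  equivalent to standard cross-correlation.

All searches here are over tilt-0 planes, for which the eye-to-eye map
leaves the vertical image coordinate unchanged (the map is 1-D projective
in x).  The implementation exploits this: predicted rows align with source
rows exactly, and only column coordinates are resampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Sequence

import numpy as np

from .geometry import (
    DEG,
    DegenerateGeometryError,
    Direction,
    PlaneParams,
    ViewingGeometry,
    Window,
    map_between_eyes,
    spline_coeffs,
    sample_image,
)
from .prefilter import FilterSpec, apply_prefilter
from .stimulus import StereoStimulus

ObserverKind = Literal["PM", "LPM", "LFM"]


@dataclass(frozen=True)
class ObserverConfig:
    """Configuration shared by the three matching observers.

    Grid bounds follow the experiment's uniform prior: slant within ±70
    degrees and intercept distance within 100 ± 1 cm.  Local searches use
    a wider distance range because the depth of a slanted plane at the
    window edge can be several cm away from the intercept distance.
    """

    kind: ObserverKind = "PM"
    patch_width: float = 0.5  # degrees
    patch_stride: float | None = None  # default: patch_width / 2
    slant_bounds: tuple[float, float] = (-70.0, 70.0)
    slant_step: float = 0.25  # global PM search, degrees
    local_slant_step: float = 1.0  # LPM per-patch search, degrees
    distance_bounds: tuple[float, float] = (99.0, 101.0)  # zeta, cm
    distance_step: float = 0.02  # cm
    local_distance_bounds: tuple[float, float] = (93.0, 107.0)  # z_i, cm
    error_metric: Literal["sse", "ncorr"] = "sse"
    direction: Direction = Direction.R2L
    interp_order: int = 5
    coarse_slant_step: float = 2.5
    coarse_distance_step: float = 0.25
    min_valid_fraction: float = 0.5
    fixed_slant: float | None = None  # depth task: clamp PM slant search

    @property
    def stride(self) -> float:
        return self.patch_stride if self.patch_stride is not None else self.patch_width / 2.0

    def with_kind(self, kind: ObserverKind) -> "ObserverConfig":
        return replace(self, kind=kind)


@dataclass
class LocalEstimateMap:
    """Per-patch estimates over the analysis window (right-eye patches)."""

    x: np.ndarray  # patch-center x, degrees
    y: np.ndarray  # patch-center y, degrees
    slant: np.ndarray  # s_i hat, degrees
    distance: np.ndarray  # z_i hat, cm
    match_error: np.ndarray

    def __len__(self) -> int:
        return len(self.x)


@dataclass
class PooledEstimate:
    """Pooled global estimate from a local map."""

    slant_from_distances: float  # s_z hat
    intercept_from_distances: float  # zeta_z hat
    slant_from_slants: float  # s_s hat
    reliability_distances: float  # r_z
    reliability_slants: float  # r_s
    slant: float  # reliability-weighted combination

    @property
    def center_distance(self) -> float:
        """Estimated distance of the surface at the window center
        (lateral position 0): the pooled intercept."""
        return self.intercept_from_distances


@dataclass
class PMEstimate:
    slant: float
    intercept_distance: float
    error: float
    error_surface: "ErrorSurface | None" = None


@dataclass
class ErrorSurface:
    """Coarse-level matching-error table from the PM search."""

    slants: np.ndarray
    distances: np.ndarray
    errors: np.ndarray  # shape (len(slants), len(distances))


# ---------------------------------------------------------------------------
# matching-error core


def matching_error(
    img: np.ndarray,
    pred: np.ndarray,
    valid: np.ndarray | None = None,
    metric: Literal["sse", "ncorr"] = "sse",
) -> float:
    """Prediction error between an observed and a predicted filtered image.

    ``sse`` returns the sum of squared differences over valid pixels;
    ``ncorr`` returns ``1 - r`` (normalized correlation), so smaller is
    better for both metrics.
    """
    if img.shape != pred.shape:
        raise ValueError("image shapes must match")
    if valid is None:
        a, b = np.ravel(img), np.ravel(pred)
    else:
        if not np.any(valid):
            raise ValueError("no valid pixels")
        a, b = img[valid], pred[valid]
    if metric == "sse":
        return float(np.sum((a - b) ** 2))
    if metric == "ncorr":
        sa = a - a.mean()
        sb = b - b.mean()
        denom = np.sqrt(np.sum(sa**2) * np.sum(sb**2))
        if denom == 0:
            raise ValueError("zero-variance input to normalized correlation")
        return float(1.0 - np.sum(sa * sb) / denom)
    raise ValueError(f"unknown metric {metric!r}")


# ---------------------------------------------------------------------------
# fast separable sampling along columns (tilt-0 maps keep rows fixed)


def _bspline5(x: np.ndarray) -> np.ndarray:
    """Quintic B-spline kernel (support |x| < 3)."""
    x = np.abs(x)
    r = np.zeros_like(x)
    m = x < 1
    xm = x[m]
    r[m] = (3 - xm) ** 5 - 6 * (2 - xm) ** 5 + 15 * (1 - xm) ** 5
    m = (x >= 1) & (x < 2)
    xm = x[m]
    r[m] = (3 - xm) ** 5 - 6 * (2 - xm) ** 5
    m = (x >= 2) & (x < 3)
    r[m] = (3 - x[m]) ** 5
    return r / 120.0


def _sample_rows_cols(
    coeffs1d: np.ndarray, introws: np.ndarray, cols: np.ndarray
) -> np.ndarray:
    """Sample an image at integer rows and fractional columns with the
    quintic spline, using coefficients prefiltered along columns only.

    ``cols`` has shape (k, n) (candidates x positions); all taps must lie
    inside the coefficient array (callers guarantee a 3-pixel margin).
    Returns shape (k, nrow, n).  Agrees with :func:`geometry.sample_image`
    to interpolation precision (asserted in tests).
    """
    base = np.floor(cols).astype(np.intp)
    frac = cols - base
    offs = np.arange(-2, 4)
    idx = base[..., None] + offs  # (k, n, 6)
    w = _bspline5(frac[..., None] - offs)  # (k, n, 6)
    G = coeffs1d[introws][:, idx]  # (nrow, k, n, 6)
    return np.einsum("rknt,knt->krn", G, w, optimize=True)


# ---------------------------------------------------------------------------
# matching context: everything fixed per (stimulus, filter) pair


class MatchingContext:
    """Prefiltered images and raster bookkeeping for one stimulus.

    The source eye supplies gray levels (the right eye for the default
    R->L prediction direction); the destination eye's measured image is
    compared against predictions on its own raster.
    """

    def __init__(
        self,
        stim: StereoStimulus,
        cfg: ObserverConfig,
        fs: FilterSpec,
        vg: ViewingGeometry,
    ):
        self.cfg = cfg
        self.vg = vg
        self.fs = fs
        L_f, R_f, sigma_f = apply_prefilter(stim, fs, vg)
        self.sigma_f = sigma_f
        if cfg.direction is Direction.R2L:
            self.src_img, self.src_window = R_f, stim.right_window
            self.dst_img, self.dst_window = L_f, stim.left_window
        else:
            self.src_img, self.src_window = L_f, stim.left_window
            self.dst_img, self.dst_window = R_f, stim.right_window
        self.src_coeffs = spline_coeffs(self.src_img, cfg.interp_order)
        # column-only coefficients for the separable tilt-0 fast path
        from scipy import ndimage as _ndi

        self.src_coeffs1d = (
            _ndi.spline_filter1d(
                self.src_img, order=5, axis=1, mode="constant", output=np.float64
            )
            if cfg.interp_order == 5
            else None
        )
        self.src_yaxis, self.src_xaxis = self.src_window.axes(vg)
        self.dst_yaxis, self.dst_xaxis = self.dst_window.axes(vg)
        # eye positions for the dst -> src pixel map
        self.e_map_src = vg.eye_x(cfg.direction.destination)  # dst eye
        self.e_map_dst = vg.eye_x(cfg.direction.source)  # src eye
        self.analysis_window = stim.window
        ayax, axax = stim.window.axes(vg)
        ppd = vg.pixels_per_degree
        self.src_acol0 = (axax[0] - self.src_xaxis[0]) * ppd
        self.src_acol1 = (axax[-1] - self.src_xaxis[0]) * ppd
        self.src_arow0 = (ayax[0] - self.src_yaxis[0]) * ppd
        self.src_arow1 = (ayax[-1] - self.src_yaxis[0]) * ppd

    # -- raster helpers ----------------------------------------------------

    def dst_col_of(self, x_deg: np.ndarray) -> np.ndarray:
        return (np.asarray(x_deg) - self.dst_xaxis[0]) * self.vg.pixels_per_degree

    def dst_row_of(self, y_deg: np.ndarray) -> np.ndarray:
        return (np.asarray(y_deg) - self.dst_yaxis[0]) * self.vg.pixels_per_degree

    def src_col_of(self, x_deg: np.ndarray) -> np.ndarray:
        return (np.asarray(x_deg) - self.src_xaxis[0]) * self.vg.pixels_per_degree

    def map_cols_to_src(
        self, dst_x_deg: np.ndarray, slants: np.ndarray, zetas: np.ndarray
    ) -> np.ndarray:
        """Map destination-raster x positions through tilt-0 candidate
        planes into source-raster fractional column indices.

        Vectorized over candidates: returns shape ``(n_cand, n_x)``.
        ``dst_x_deg`` may be shared across candidates (1-D) or given per
        candidate (2-D, one row each).
        """
        vg = self.vg
        D = vg.image_plane_distance
        e_s = self.e_map_src
        e_d = self.e_map_dst
        dst_x_deg = np.asarray(dst_x_deg, dtype=float)
        tx = np.tan(dst_x_deg * DEG)
        if tx.ndim == 1:
            tx = tx[None, :]
        ts = np.tan(np.asarray(slants, dtype=float) * DEG)[:, None]
        zt = np.asarray(zetas, dtype=float)[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (zt + ts * e_s) / (D - ts * (D * tx - e_s))
            X = e_s + t * (D * tx - e_s)
            Xs = e_d + (X - e_d) / t
        x_deg = np.arctan2(Xs, D) / DEG
        col = (x_deg - self.src_xaxis[0]) * vg.pixels_per_degree
        col[~np.isfinite(col) | (t <= 0)] = -1e9  # force invalid
        return col


def prepare_context(
    stim: StereoStimulus,
    cfg: ObserverConfig,
    fs: FilterSpec,
    vg: ViewingGeometry,
) -> MatchingContext:
    return MatchingContext(stim, cfg, fs, vg)


# ---------------------------------------------------------------------------
# candidate evaluation


def _eval_global_batch(
    ctx: MatchingContext,
    slants: np.ndarray,
    zetas: np.ndarray,
) -> np.ndarray:
    """Mean per-pixel matching error of global plane candidates.

    The comparison raster is an analysis-rectangle-sized region of the
    destination image, centered on the window center; for each candidate
    only the columns whose pre-image lies inside the source raster are
    compared (renormalized by valid-pixel count).
    """
    cfg, vg = ctx.cfg, ctx.vg
    win = ctx.analysis_window
    ny_src, nx_src = ctx.src_img.shape
    # comparison block: same pixel size as the source window, centered
    yax, xax = win.axes(vg)
    row0 = int(round(ctx.dst_row_of(yax[0])))
    col0 = int(round(ctx.dst_col_of(xax[0])))
    ny, nx = len(yax), len(xax)
    if row0 < 0 or col0 < 0 or row0 + ny > ctx.dst_img.shape[0] or col0 + nx > ctx.dst_img.shape[1]:
        raise ValueError("destination image does not cover the analysis window")
    dst_block = ctx.dst_img[row0 : row0 + ny, col0 : col0 + nx]
    dst_x = ctx.dst_xaxis[col0 : col0 + nx]
    dst_y = ctx.dst_yaxis[row0 : row0 + ny]
    # tilt-0 map leaves y unchanged: source rows are fixed per pixel-row
    srows = (dst_y - ctx.src_yaxis[0]) * vg.pixels_per_degree
    mg = (cfg.interp_order + 1) // 2  # spline half-support: avoid edge error
    rlo = max(ctx.src_arow0, mg)
    rhi = min(ctx.src_arow1, ny_src - 1 - mg)
    rok = (srows >= rlo - 1e-9) & (srows <= rhi + 1e-9)
    dst_block, srows = dst_block[rok], srows[rok]
    ny = int(rok.sum())

    m = len(slants)
    errors = np.full(m, np.inf)
    order = cfg.interp_order
    chunk = max(1, 400_000 // max(1, ny * nx))
    for a in range(0, m, chunk):
        b = min(m, a + chunk)
        k = b - a
        clo = max(ctx.src_acol0, mg)
        chi = min(ctx.src_acol1, nx_src - 1 - mg)
        cols = ctx.map_cols_to_src(dst_x, slants[a:b], zetas[a:b])  # (k, nx)
        vmask = (cols >= clo) & (cols <= chi)
        nval = vmask.sum(axis=1)
        colsc = np.clip(cols, float(clo), float(chi))
        introws = np.rint(srows).astype(np.intp)
        if ctx.src_coeffs1d is not None and np.max(np.abs(srows - introws)) < 1e-6:
            pred = _sample_rows_cols(ctx.src_coeffs1d, introws, colsc)
        else:
            rowc = np.broadcast_to(srows[None, :, None], (k, ny, nx)).ravel()
            colc = np.broadcast_to(colsc[:, None, :], (k, ny, nx)).ravel()
            pred = sample_image(ctx.src_coeffs, rowc, colc, order).reshape(k, ny, nx)
        if cfg.error_metric == "sse":
            sq = (dst_block[None, :, :] - pred) ** 2
            sums = np.einsum("kij,kj->k", sq, vmask.astype(float))
            with np.errstate(invalid="ignore", divide="ignore"):
                e = sums / (ny * nval)
            e[nval < cfg.min_valid_fraction * nx] = np.inf
            errors[a:b] = e
        else:
            for i in range(k):
                vm = vmask[i]
                if vm.sum() < cfg.min_valid_fraction * nx:
                    continue
                errors[a + i] = matching_error(
                    dst_block[:, vm], pred[i][:, vm], metric="ncorr"
                )
    return errors


def _eval_local_batch(
    ctx: MatchingContext,
    patch_center: tuple[float, float],
    slants: np.ndarray,
    distances: np.ndarray,
) -> np.ndarray:
    """Mean per-pixel matching error of local (s_i, z_i) candidates for a
    single source-eye patch.

    Each candidate's comparison block in the destination image tracks the
    predicted projection of the patch center (snapped to the raster);
    destination pixels whose pre-image falls outside the source patch are
    excluded, with renormalization by valid count.
    """
    cfg, vg = ctx.cfg, ctx.vg
    xc, yc = patch_center
    wpx = max(2, int(round(cfg.patch_width * vg.pixels_per_degree)))
    step = 1.0 / vg.pixels_per_degree
    # source-patch pixel bounds (columns of the source raster)
    pcol0 = int(round(ctx.src_col_of(xc - (wpx - 1) / 2.0 * step)))
    prow0 = int(
        round((yc - (wpx - 1) / 2.0 * step - ctx.src_yaxis[0]) * vg.pixels_per_degree)
    )
    pcol1 = pcol0 + wpx - 1
    # convert (s_i, z_i) -> (s_i, zeta_i) via the patch-center ray
    slants = np.asarray(slants, dtype=float)
    distances = np.asarray(distances, dtype=float)
    D = vg.image_plane_distance
    e_src = vg.eye_x(cfg.direction.source)
    x_lat = e_src + (D * np.tan(xc * DEG) - e_src) * (distances / D)
    zetas = distances - x_lat * np.tan(slants * DEG)
    ok = zetas > 0
    errors = np.full(len(slants), np.inf)
    if not np.any(ok):
        return errors

    # predicted dst position of the patch center, snapped to the dst raster
    e_map_s, e_map_d = ctx.e_map_dst, ctx.e_map_src  # src -> dst this time
    tx_c = np.tan(xc * DEG)
    ts = np.tan(slants * DEG)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (zetas + ts * e_map_s) / (D - ts * (D * tx_c - e_map_s))
        Xc = e_map_s + t * (D * tx_c - e_map_s)
        Xs = e_map_d + (Xc - e_map_d) / t
    xc_dst = np.arctan2(Xs, D) / DEG
    ok &= np.isfinite(xc_dst) & (t > 0)

    ny_dst, nx_dst = ctx.dst_img.shape
    ccenter = np.round(ctx.dst_col_of(xc_dst)).astype(int)
    c0 = ccenter - (wpx - 1) // 2
    r0 = int(round(ctx.dst_row_of(yc - (wpx - 1) / 2.0 * step)))
    ok &= (c0 >= 0) & (c0 + wpx <= nx_dst) & (r0 >= 0) & (r0 + wpx <= ny_dst)
    idx = np.flatnonzero(ok)
    if len(idx) == 0:
        return errors

    # tilt-0 map leaves y unchanged: source rows fixed per pixel-row
    dst_y = ctx.dst_yaxis[r0 : r0 + wpx]
    srows = (dst_y - ctx.src_yaxis[0]) * vg.pixels_per_degree
    rok = (srows >= prow0 - 0.5) & (srows <= prow0 + wpx - 1 + 0.5)
    srows = srows[rok]
    nrow = int(rok.sum())
    if nrow == 0:
        return errors

    k = len(idx)
    dst_x = ctx.dst_xaxis[c0[idx, None] + np.arange(wpx)[None, :]]  # (k, wpx)
    mg = (cfg.interp_order + 1) // 2
    nx_src = ctx.src_img.shape[1]
    cols = ctx.map_cols_to_src(dst_x, slants[idx], zetas[idx])  # (k, wpx)
    lo = max(pcol0, mg)
    hi = min(pcol1, nx_src - 1 - mg)
    vmask = (cols >= lo) & (cols <= hi)
    nval = vmask.sum(axis=1)
    colsc = np.clip(cols, float(lo), float(hi))
    introws = np.rint(srows).astype(np.intp)
    if ctx.src_coeffs1d is not None and np.max(np.abs(srows - introws)) < 1e-6:
        pred = _sample_rows_cols(ctx.src_coeffs1d, introws, colsc)
    else:
        rowc = np.broadcast_to(srows[None, :, None], (k, nrow, wpx)).ravel()
        colc = np.broadcast_to(colsc[:, None, :], (k, nrow, wpx)).ravel()
        pred = sample_image(ctx.src_coeffs, rowc, colc, cfg.interp_order).reshape(
            k, nrow, wpx
        )
    # gather each candidate's tracked destination block
    from numpy.lib.stride_tricks import sliding_window_view

    strips = sliding_window_view(ctx.dst_img[r0 : r0 + wpx, :][rok], wpx, axis=1)
    data = strips[:, c0[idx], :].transpose(1, 0, 2)  # (k, nrow, wpx)
    min_valid = cfg.min_valid_fraction * wpx
    if cfg.error_metric == "sse":
        sq = (data - pred).astype(np.float64) ** 2
        sums = np.einsum("kij,kj->k", sq, vmask.astype(float))
        with np.errstate(invalid="ignore", divide="ignore"):
            e = sums / (nrow * nval)
        e[nval < min_valid] = np.inf
        errors[idx] = e
    else:
        for j, i in enumerate(idx):
            vm = vmask[j]
            if vm.sum() < min_valid:
                continue
            errors[i] = matching_error(data[j][:, vm], pred[j][:, vm], metric="ncorr")
    return errors


# ---------------------------------------------------------------------------
# grid search (exhaustive and coarse-to-fine)


def _lattice(lo: float, hi: float, step: float, anchor: float) -> np.ndarray:
    """Grid of points with spacing ``step`` on the lattice through
    ``anchor``, clipped to [lo, hi]."""
    k0 = int(np.ceil((lo - anchor) / step - 1e-9))
    k1 = int(np.floor((hi - anchor) / step + 1e-9))
    return anchor + step * np.arange(k0, k1 + 1)


def _argmin_first(err: np.ndarray) -> int:
    return int(np.argmin(err))  # first occurrence on ties (deterministic)


def grid_search_2d(
    eval_batch: Callable[[np.ndarray, np.ndarray], np.ndarray],
    s_grid: np.ndarray,
    z_grid: np.ndarray,
):
    """Exhaustive search over the product grid; returns (s, z, err, surface)."""
    ss, zz = np.meshgrid(s_grid, z_grid, indexing="ij")
    err = eval_batch(ss.ravel(), zz.ravel())
    i = _argmin_first(err)
    surface = ErrorSurface(s_grid, z_grid, err.reshape(ss.shape))
    return float(ss.ravel()[i]), float(zz.ravel()[i]), float(err[i]), surface


def coarse_to_fine_2d(
    eval_batch: Callable[[np.ndarray, np.ndarray], np.ndarray],
    s_bounds: tuple[float, float],
    z_bounds: tuple[float, float],
    s_coarse: float,
    z_coarse: float,
    s_final: float,
    z_final: float,
    refine_factor: float = 4.0,
    keep_surface: bool = False,
):
    """Coarse-to-fine minimization over a (slant, distance) rectangle.

    The coarse pass scans the full product grid; each refinement pass
    shrinks the step by ``refine_factor`` (floored at the final step) and
    scans a neighborhood of ±(previous step) around the incumbent.  Grids
    stay on the final-step lattice anchored at the lower bounds, so an
    on-lattice global minimum is recovered exactly.  Validated against
    exhaustive search in the test suite.
    """
    s_lo, s_hi = s_bounds
    z_lo, z_hi = z_bounds
    s_step = max(s_coarse, s_final)
    z_step = max(z_coarse, z_final)
    # snap steps to multiples of the final steps so lattices nest
    s_step = s_final * max(1, round(s_step / s_final))
    z_step = z_final * max(1, round(z_step / z_final))
    s_grid = _lattice(s_lo, s_hi, s_step, s_lo)
    z_grid = _lattice(z_lo, z_hi, z_step, z_lo)
    best_s, best_z, best_e, surface = grid_search_2d(eval_batch, s_grid, z_grid)
    if not keep_surface:
        surface = None
    while s_step > s_final * (1 + 1e-9) or z_step > z_final * (1 + 1e-9):
        prev_s, prev_z = s_step, z_step
        s_step = s_final * max(1, round(max(s_step / refine_factor, s_final) / s_final))
        z_step = z_final * max(1, round(max(z_step / refine_factor, z_final) / z_final))
        s_grid = _lattice(
            max(s_lo, best_s - prev_s), min(s_hi, best_s + prev_s), s_step, s_lo
        )
        z_grid = _lattice(
            max(z_lo, best_z - prev_z), min(z_hi, best_z + prev_z), z_step, z_lo
        )
        s, z, e, _ = grid_search_2d(eval_batch, s_grid, z_grid)
        if e < best_e:
            best_s, best_z, best_e = s, z, e
    return best_s, best_z, best_e, surface


# ---------------------------------------------------------------------------
# observers


def pm_estimate(
    stim: StereoStimulus,
    cfg: ObserverConfig,
    fs: FilterSpec,
    vg: ViewingGeometry,
    search: Literal["coarse_to_fine", "exhaustive"] = "coarse_to_fine",
    keep_surface: bool = False,
    ctx: MatchingContext | None = None,
) -> PMEstimate:
    """Planar-matching estimate of (slant, intercept distance).

    Minimizes the matching error over the (s, zeta) grid under the uniform
    prior (whose contribution is constant and therefore dropped).  In the
    depth-task mode (``cfg.fixed_slant``) the slant dimension is clamped
    and only the distance is searched.
    """
    ctx = ctx or prepare_context(stim, cfg, fs, vg)

    def eval_batch(s, z):
        return _eval_global_batch(ctx, np.atleast_1d(s), np.atleast_1d(z))

    if cfg.fixed_slant is not None:
        s_bounds = (cfg.fixed_slant, cfg.fixed_slant)
        s_coarse = s_final = 1.0  # single-point dimension
    else:
        s_bounds = cfg.slant_bounds
        s_coarse, s_final = cfg.coarse_slant_step, cfg.slant_step

    if search == "exhaustive":
        s_grid = (
            np.array([cfg.fixed_slant])
            if cfg.fixed_slant is not None
            else _lattice(*s_bounds, cfg.slant_step, s_bounds[0])
        )
        z_grid = _lattice(*cfg.distance_bounds, cfg.distance_step, cfg.distance_bounds[0])
        s, z, e, surface = grid_search_2d(eval_batch, s_grid, z_grid)
        if not keep_surface:
            surface = None
    else:
        s, z, e, surface = coarse_to_fine_2d(
            eval_batch,
            s_bounds,
            cfg.distance_bounds,
            s_coarse,
            cfg.coarse_distance_step,
            s_final,
            cfg.distance_step,
            keep_surface=keep_surface,
        )
    if not np.isfinite(e):
        raise DegenerateGeometryError("no valid candidate in the PM search")
    return PMEstimate(slant=s, intercept_distance=z, error=e, error_surface=surface)


def patch_centers(cfg: ObserverConfig, window: Window) -> tuple[np.ndarray, np.ndarray]:
    """Centers of square patches fully inside the analysis window, on the
    configured stride grid."""
    w = cfg.patch_width
    if w >= min(window.width, window.height):
        raise ValueError("patch_width must be smaller than the analysis window")
    # as many stride steps as fit with the patch fully inside, the whole
    # set centered in the window
    nx = int(np.floor((window.width - w) / cfg.stride + 1e-9)) + 1
    ny = int(np.floor((window.height - w) / cfg.stride + 1e-9)) + 1
    cx = window.center[0] + cfg.stride * (np.arange(nx) - (nx - 1) / 2.0)
    cy = window.center[1] + cfg.stride * (np.arange(ny) - (ny - 1) / 2.0)
    return cx, cy


def local_matching(
    stim: StereoStimulus,
    cfg: ObserverConfig,
    fs: FilterSpec,
    vg: ViewingGeometry,
    ctx: MatchingContext | None = None,
) -> LocalEstimateMap:
    """Per-patch (s_i, z_i) estimates (LPM) or z_i-only estimates (LFM).

    For LFM the slant dimension is clamped to zero, which reduces the
    search to a horizontal-shift (location-disparity) search.
    """
    if cfg.kind not in ("LPM", "LFM"):
        raise ValueError("local_matching requires an LPM or LFM config")
    ctx = ctx or prepare_context(stim, cfg, fs, vg)
    cx, cy = patch_centers(cfg, stim.window)
    xs, ys, ss, zs, es = [], [], [], [], []
    lfm = cfg.kind == "LFM"
    for yc in cy:
        for xc in cx:
            def eval_batch(s, z, _c=(float(xc), float(yc))):
                return _eval_local_batch(ctx, _c, np.atleast_1d(s), np.atleast_1d(z))

            if lfm:
                s_bounds, s_coarse, s_final = (0.0, 0.0), 1.0, 1.0
            else:
                s_bounds = cfg.slant_bounds
                s_coarse, s_final = 10.0, cfg.local_slant_step
            s, z, e, _ = coarse_to_fine_2d(
                eval_batch,
                s_bounds,
                cfg.local_distance_bounds,
                s_coarse,
                0.5,
                s_final,
                cfg.distance_step,
            )
            if not np.isfinite(e):
                continue
            xs.append(xc)
            ys.append(yc)
            ss.append(s)
            zs.append(z)
            es.append(e)
    if not xs:
        raise DegenerateGeometryError("no patch produced a valid local estimate")
    return LocalEstimateMap(
        x=np.array(xs), y=np.array(ys), slant=np.array(ss),
        distance=np.array(zs), match_error=np.array(es),
    )


def lateral_position(
    x_deg: np.ndarray, distance: np.ndarray, vg: ViewingGeometry, eye: str = "R"
) -> np.ndarray:
    """Lateral (X, cm) position of the surface point at depth ``distance``
    on the eye's ray through image position ``x_deg``."""
    D = vg.image_plane_distance
    e = vg.eye_x(eye)
    return e + (D * np.tan(np.asarray(x_deg) * DEG) - e) * (
        np.asarray(distance) / D
    )


def pool_distances(
    est: LocalEstimateMap, vg: ViewingGeometry, eye: str = "R"
) -> tuple[float, float]:
    """Global (slant, intercept) from the local distance map.

    Minimizes ``sum_i (z_i - (zeta + x_i tan s))^2`` in closed form:
    ordinary least squares of the distances on the lateral positions, with
    slant = atan(slope) and intercept distance = intercept.  Equivalent to
    a dense 2-D grid minimization of the same objective (asserted in the
    test suite).
    """
    if len(est) < 2:
        raise ValueError("need at least two patches to pool distances")
    x_lat = lateral_position(est.x, est.distance, vg, eye)
    if np.ptp(x_lat) < 1e-12:
        raise np.linalg.LinAlgError("all patch lateral positions coincide")
    A = np.column_stack([x_lat, np.ones_like(x_lat)])
    (slope, intercept), *_ = np.linalg.lstsq(A, est.distance, rcond=None)
    return float(np.arctan(slope) / DEG), float(intercept)


def pool_slants(est: LocalEstimateMap) -> float:
    """Global slant from the local slant map: the least-squares pool
    ``argmin_s sum_i (s_i - s)^2`` is the arithmetic mean."""
    if len(est) < 1:
        raise ValueError("empty estimate map")
    return float(np.mean(est.slant))


def combine_slant_estimates(
    s_z: float, s_s: float, r_z: float, r_s: float
) -> float:
    """Reliability-weighted combination of the two slant estimates."""
    if r_z < 0 or r_s < 0:
        raise ValueError("reliabilities must be non-negative")
    if r_z + r_s == 0:
        raise ValueError("at least one reliability must be positive")
    return (r_z * s_z + r_s * s_s) / (r_z + r_s)


def pooled_estimate(
    est: LocalEstimateMap,
    vg: ViewingGeometry,
    reliabilities: tuple[float, float] | None = None,
    eye: str = "R",
) -> PooledEstimate:
    """Pool a local map into a single global estimate.

    ``reliabilities = (r_z, r_s)`` should come from a calibration run
    (dispersion of pooled estimates over repeated stimuli).  Without one,
    within-map dispersions provide a fallback: the sampling variance of
    the regression slope (propagated through atan) for r_z, and of the
    mean local slant for r_s.  For an LFM map (all local slants zero by
    construction) the slant cue carries no information and r_s = 0.
    """
    s_z, zeta_z = pool_distances(est, vg, eye)
    s_s = pool_slants(est)
    if reliabilities is not None:
        r_z, r_s = reliabilities
    elif np.ptp(est.slant) < 1e-12:  # LFM: degenerate slant map
        r_z, r_s = 1.0, 0.0
    else:
        n = len(est)
        x_lat = lateral_position(est.x, est.distance, vg, eye)
        resid = est.distance - (zeta_z + x_lat * np.tan(s_z * DEG))
        sxx = np.sum((x_lat - x_lat.mean()) ** 2)
        var_slope = np.sum(resid**2) / max(n - 2, 1) / sxx
        slope = np.tan(s_z * DEG)
        var_s_z = var_slope / (1 + slope**2) ** 2 / DEG**2  # deg^2
        var_s_s = np.var(est.slant, ddof=1) / n
        r_z = 1.0 / max(var_s_z, 1e-12)
        r_s = 1.0 / max(var_s_s, 1e-12)
    s_hat = combine_slant_estimates(s_z, s_s, r_z, r_s)
    return PooledEstimate(
        slant_from_distances=s_z,
        intercept_from_distances=zeta_z,
        slant_from_slants=s_s,
        reliability_distances=r_z,
        reliability_slants=r_s,
        slant=s_hat,
    )


def estimate_surface(
    stim: StereoStimulus,
    cfg: ObserverConfig,
    fs: FilterSpec,
    vg: ViewingGeometry,
    reliabilities: tuple[float, float] | None = None,
):
    """Run the configured observer on a stimulus.

    Returns a :class:`PMEstimate` for PM, else a :class:`PooledEstimate`.
    """
    if cfg.kind == "PM":
        return pm_estimate(stim, cfg, fs, vg)
    est = local_matching(stim, cfg, fs, vg)
    return pooled_estimate(est, vg, reliabilities, eye=cfg.direction.source)


@dataclass
class ReliabilityCalibration:
    test_slants: np.ndarray
    bias_distances: np.ndarray  # mean(s_z hat) - s per test slant
    bias_slants: np.ndarray
    r_z: float
    r_s: float


def calibrate_reliability(
    simulate: Callable[[float, int], tuple[float, float]],
    reference_slant: float,
    test_slants: Sequence[float],
    n_sims: int,
    seed: int,
    reliability_cap: float = 1e6,
) -> ReliabilityCalibration:
    """Measure the reliabilities of the two pooled slant cues by
    simulation around a reference slant.

    ``simulate(test_slant, seed)`` must return one draw of the pooled
    ``(s_z hat, s_s hat)`` pair for a fresh stimulus.  Per test slant the
    bias of each cue is computed and subtracted; the reliability is the
    reciprocal variance of the bias-corrected estimates pooled across test
    slants.  Zero dispersion is capped at ``reliability_cap``.
    """
    test_slants = np.asarray(list(test_slants), dtype=float)
    ss = np.random.SeedSequence(seed)
    subseeds = ss.generate_state(len(test_slants) * n_sims).reshape(
        len(test_slants), n_sims
    )
    est_z = np.empty((len(test_slants), n_sims))
    est_s = np.empty((len(test_slants), n_sims))
    for i, s in enumerate(test_slants):
        for j in range(n_sims):
            est_z[i, j], est_s[i, j] = simulate(float(s), int(subseeds[i, j] % (2**31)))
    bias_z = est_z.mean(axis=1) - test_slants
    bias_s = est_s.mean(axis=1) - test_slants
    resid_z = est_z - est_z.mean(axis=1, keepdims=True)
    resid_s = est_s - est_s.mean(axis=1, keepdims=True)
    var_z = float(np.var(resid_z, ddof=len(test_slants)))
    var_s = float(np.var(resid_s, ddof=len(test_slants)))
    r_z = min(1.0 / var_z, reliability_cap) if var_z > 0 else reliability_cap
    r_s = min(1.0 / var_s, reliability_cap) if var_s > 0 else reliability_cap
    return ReliabilityCalibration(
        test_slants=test_slants,
        bias_distances=bias_z,
        bias_slants=bias_s,
        r_z=r_z,
        r_s=r_s,
    )
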