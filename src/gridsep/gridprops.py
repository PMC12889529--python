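"""Grid score and grid scale from 2D rate maps.

Standard spatial-autocorrelogram analysis: the rate map's 2D
autocorrelation (Pearson correlation at each lag over the overlapping
defined bins) shows a hexagonal ring of six peaks for a grid cell.  Grid
scale is the mean distance from the central peak to its six nearest
surrounding peaks; grid score is the mean correlation of an annulus
around those peaks with itself rotated by 60 and 120 degrees minus the
mean at 30, 90 and 150 degrees — positive for six-fold symmetry, negative
for four-fold, near zero for isotropic maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["GridProps", "spatial_autocorr", "find_peaks", "grid_scale", "grid_score", "grid_properties"]


@dataclass
class GridProps:
    grid_score: float
    grid_scale: float
    peak_coords: np.ndarray | None
    autocorr: np.ndarray


def spatial_autocorr(map2d: np.ndarray, min_overlap: int = 20) -> np.ndarray:
    """Pearson autocorrelogram of a rate map at every 2D lag.

    For an n x n map the result is (2n-1) x (2n-1); entry (dx, dy) is the
    correlation between the map and its copy shifted by (dx, dy), over
    bins defined (finite) in both.  Lags with fewer than ``min_overlap``
    overlapping bins (default 20 — correlations over a handful of corner
    bins are meaningless), or zero variance in the overlap, are NaN.  The
    centre is 1 and the map is symmetric under 180-degree rotation.
    """
    m = np.asarray(map2d, dtype=float)
    if m.ndim != 2:
        raise ValueError("expected a 2D map")
    n0, n1 = m.shape
    out = np.full((2 * n0 - 1, 2 * n1 - 1), np.nan)
    for dx in range(-(n0 - 1), n0):
        for dy in range(0, n1):
            if dy == 0 and dx < 0:
                continue  # filled by symmetry
            a = m[max(dx, 0): n0 + min(dx, 0), max(dy, 0): n1 + min(dy, 0)]
            b = m[max(-dx, 0): n0 - max(dx, 0), max(-dy, 0): n1 - max(dy, 0)]
            valid = np.isfinite(a) & np.isfinite(b)
            r = np.nan
            if valid.sum() >= min_overlap:
                av = a[valid]
                bv = b[valid]
                sa = av.std()
                sb = bv.std()
                if sa > 0 and sb > 0:
                    r = float(np.mean((av - av.mean()) * (bv - bv.mean())) / (sa * sb))
            out[n0 - 1 + dx, n1 - 1 + dy] = r
            out[n0 - 1 - dx, n1 - 1 - dy] = r
    return out


def _smooth_nan(a: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian smoothing that ignores NaNs (normalised convolution)."""
    mask = np.isfinite(a)
    filled = np.where(mask, a, 0.0)
    num = ndimage.gaussian_filter(filled, sigma)
    den = ndimage.gaussian_filter(mask.astype(float), sigma)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 1e-12, num / den, np.nan)
    out[~mask] = np.nan
    return out


def find_peaks(autocorr: np.ndarray, smooth_sigma: float = 1.0, n_peaks: int = 6):
    """Locations (in lag bins, relative to centre) of the six autocorr
    peaks closest to the centre, central peak excluded.

    The autocorrelogram is lightly smoothed (sigma = 1 bin), local maxima
    are taken over 8-neighbourhoods, the contiguous region around lag zero
    with correlation >= 0.5 is masked out, and the ``n_peaks`` maxima
    nearest the centre are returned (ties broken by distance, then angle).
    Returns None if fewer than ``n_peaks`` peaks exist.
    """
    ac = _smooth_nan(autocorr, smooth_sigma)
    c0 = (autocorr.shape[0] - 1) // 2
    c1 = (autocorr.shape[1] - 1) // 2

    filled = np.where(np.isfinite(ac), ac, -np.inf)
    local_max = (
        (ndimage.maximum_filter(filled, size=3) == filled)
        & np.isfinite(ac)
        & (ac > 0)  # a firing-field peak is positively correlated
    )

    # mask the central peak's own region: contiguous bins of the RAW
    # autocorrelogram >= 0.5 around lag zero (the raw centre is exactly 1;
    # smoothing can pull it below any fixed threshold)
    high = np.where(np.isfinite(autocorr), autocorr, -np.inf) >= 0.5
    labels, _ = ndimage.label(high)
    central = labels[c0, c1]
    if central != 0:
        local_max[labels == central] = False
    local_max[c0, c1] = False

    px, py = np.nonzero(local_max)
    if len(px) < n_peaks:
        return None
    dx = px - c0
    dy = py - c1
    dist = np.hypot(dx, dy)
    ang = np.mod(np.arctan2(dy, dx), 2 * np.pi)
    order = np.lexsort((ang, dist))
    sel = order[:n_peaks]
    return np.column_stack([dx[sel], dy[sel]]).astype(float)


def grid_scale(autocorr: np.ndarray, bin_size: float = 5.0) -> float:
    """Mean distance (cm) from the six nearest autocorr peaks to the
    centre; NaN when six peaks cannot be found."""
    peaks = find_peaks(autocorr)
    if peaks is None:
        return np.nan
    return float(np.mean(np.hypot(peaks[:, 0], peaks[:, 1])) * bin_size)


def _rotate_sample(autocorr: np.ndarray, coords: np.ndarray, angle_deg: float) -> np.ndarray:
    """Bilinear sample of the autocorrelogram at ``coords`` rotated about
    the centre; NaN outside the domain."""
    c0 = (autocorr.shape[0] - 1) / 2.0
    c1 = (autocorr.shape[1] - 1) / 2.0
    th = np.deg2rad(angle_deg)
    rel = coords - [c0, c1]
    rot = rel @ np.array([[np.cos(th), np.sin(th)], [-np.sin(th), np.cos(th)]]).T
    pts = rot + [c0, c1]
    filled = np.where(np.isfinite(autocorr), autocorr, np.nan)
    vals = ndimage.map_coordinates(
        np.nan_to_num(filled, nan=0.0), pts.T, order=1, mode="constant", cval=np.nan
    )
    # kill samples whose bilinear support touches a NaN or falls outside
    bad = ndimage.map_coordinates(
        (~np.isfinite(filled)).astype(float), pts.T, order=1, mode="constant", cval=1.0
    )
    vals = np.where(bad > 1e-9, np.nan, vals)
    return vals


def grid_score(
    autocorr: np.ndarray, scale_bins: float | None = None, min_bins: int = 10
) -> float:
    """Six-fold minus non-six-fold rotational correlation of the annulus.

    The annulus spans 0.5-1.5 times the grid scale (in lag bins; computed
    from the six peaks when not given).  Correlations between the annulus
    and its rotated copies are Pearson over pairwise-valid samples.  NaN
    when the annulus holds fewer than ``min_bins`` valid bins.
    """
    if scale_bins is None:
        peaks = find_peaks(autocorr)
        if peaks is None:
            return np.nan
        scale_bins = float(np.mean(np.hypot(peaks[:, 0], peaks[:, 1])))
    c0 = (autocorr.shape[0] - 1) // 2
    c1 = (autocorr.shape[1] - 1) // 2
    ii, jj = np.indices(autocorr.shape)
    rr = np.hypot(ii - c0, jj - c1)
    ring = (rr >= 0.5 * scale_bins) & (rr <= 1.5 * scale_bins) & np.isfinite(autocorr)
    if ring.sum() < min_bins:
        return np.nan
    coords = np.column_stack(np.nonzero(ring)).astype(float)
    base = autocorr[ring]

    def corr_at(angle):
        rot = _rotate_sample(autocorr, coords, angle)
        valid = np.isfinite(rot) & np.isfinite(base)
        if valid.sum() < min_bins:
            return np.nan
        a = base[valid]
        b = rot[valid]
        if a.std() == 0 or b.std() == 0:
            return np.nan
        return float(np.corrcoef(a, b)[0, 1])

    hex_corr = np.nanmean([corr_at(60.0), corr_at(120.0)])
    off_corr = np.nanmean([corr_at(30.0), corr_at(90.0), corr_at(150.0)])
    return float(hex_corr - off_corr)


def grid_properties(map2d: np.ndarray, bin_size: float = 5.0) -> GridProps:
    """Autocorrelogram, grid score and grid scale of one rate map."""
    ac = spatial_autocorr(map2d)
    peaks = find_peaks(ac)
    if peaks is None:
        return GridProps(grid_score=np.nan, grid_scale=np.nan, peak_coords=None, autocorr=ac)
    scale_bins = float(np.mean(np.hypot(peaks[:, 0], peaks[:, 1])))
    return GridProps(
        grid_score=grid_score(ac, scale_bins=scale_bins),
        grid_scale=scale_bins * bin_size,
        peak_coords=peaks * bin_size,
        autocorr=ac,
    )
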