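"""Non-separability statistics: cosine-similarity map, SDCS, null test.

For each velocity bin (i, j) the position map restricted to that bin is
compared with the velocity-marginalised position map by cosine similarity,

    c(i, j) = <r(., ., vx_i, vy_j), E_v[r]> / (||r(., ., vx_i, vy_j)|| ||E_v[r]||),

giving a 5x5 matrix of scores.  A separable tuning curve (velocity a pure
gain on one spatial map) has identical position maps up to scale in every
velocity bin, hence constant c; the standard deviation of the cosine
similarities (SDCS) is therefore zero under separability and grows with
field shifts, appearances or disappearances across velocity bins.

Because estimation noise alone inflates SDCS, a cell's score is compared
with the SDCS distribution obtained from matched null sessions — spikes
regenerated from the cell's zero-velocity position map along the same
trajectory (see :func:`gridsep.simulate.make_null_session`), analysed with
the same GP settings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .binning import TuningCurve4D, marginal_position_tuning

__all__ = [
    "NonSepReport",
    "cosine_map",
    "sdcs",
    "null_comparison",
    "property_regression",
]


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    valid = np.isfinite(a) & np.isfinite(b)
    if not np.any(valid):
        return np.nan
    a = a[valid]
    b = b[valid]
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        return np.nan
    return float(a @ b / (na * nb))


def cosine_map(source, marginal: np.ndarray | None = None) -> np.ndarray:
    """5x5 (n_vel x n_vel) cosine similarities c(i, j).

    ``source`` is either a :class:`TuningCurve4D` (binned rates, NaN at
    unvisited bins — each inner product is restricted to position bins
    defined in both the slice and the marginal) or a plain 4D array such
    as a GP ``mean4d`` (all bins defined).  The marginal map is the
    occupancy-weighted one for a tuning curve and the plain velocity-mean
    for an array, unless supplied explicitly.
    """
    if isinstance(source, TuningCurve4D):
        rate4d = source.rate
        if marginal is None:
            marginal = marginal_position_tuning(source)
    else:
        rate4d = np.asarray(source, dtype=float)
        if rate4d.ndim != 4:
            raise ValueError("expected a 4D rate array")
        if marginal is None:
            with np.errstate(invalid="ignore"):
                marginal = np.nanmean(rate4d, axis=(2, 3))
    n_i, n_j = rate4d.shape[2], rate4d.shape[3]
    out = np.full((n_i, n_j), np.nan)
    for i in range(n_i):
        for j in range(n_j):
            out[i, j] = _cosine(rate4d[:, :, i, j].ravel(), marginal.ravel())
    return out


def sdcs(cmap: np.ndarray) -> float:
    """Standard deviation of the defined cosine similarities (population).

    Zero for exactly separable tuning; NaN (undefined) with fewer than two
    defined entries.
    """
    vals = np.asarray(cmap, dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        return np.nan
    return float(np.std(vals))


def null_comparison(value: float, null_values, q: float = 95.0):
    """Empirical quantile of ``value`` in the null SDCS distribution.

    Returns ``(quantile, flagged)`` where ``quantile`` is the fraction of
    null values strictly below ``value`` and ``flagged`` is True when
    ``value`` exceeds the null ``q``-th percentile — the cell's
    non-separability cannot be explained by estimation noise on a
    velocity-invariant map.
    """
    null_values = np.asarray(list(null_values), dtype=float)
    null_values = null_values[np.isfinite(null_values)]
    if null_values.size == 0:
        raise ValueError("empty null distribution")
    quantile = float(np.mean(null_values < value))
    flagged = bool(value > np.percentile(null_values, q))
    return quantile, flagged


def property_regression(prop, delta_fve):
    """OLS line relating a per-cell property to delta-FVE.

    Returns ``(slope, pearson_r, p_value)`` from ``scipy.stats.linregress``
    (two-sided p for a nonzero slope).  Requires >= 3 cells and a
    non-constant property.
    """
    prop = np.asarray(prop, dtype=float)
    delta_fve = np.asarray(delta_fve, dtype=float)
    if prop.size != delta_fve.size or prop.size < 3:
        raise ValueError("need >= 3 paired finite values")
    if not (np.all(np.isfinite(prop)) and np.all(np.isfinite(delta_fve))):
        raise ValueError("values must be finite")
    if np.ptp(prop) == 0:
        raise ValueError("constant predictor; regression undefined")
    res = stats.linregress(prop, delta_fve)
    return float(res.slope), float(res.rvalue), float(res.pvalue)


@dataclass
class NonSepReport:
    """Per-cell non-separability summary.

    ``source`` records whether the cosine map came from the binned curve
    or the GP estimate.  ``sdcs`` scores the fold-averaged GP estimate;
    ``sdcs_single`` scores a single fit on all high-occupancy bins and is
    the value compared against ``null_sdcs``, because the null replicates
    are scored with that same single-fit procedure.
    """

    cell_id: int
    cosine_map: np.ndarray
    sdcs: float
    delta_fve: float = np.nan
    sdcs_single: float = np.nan
    null_sdcs: np.ndarray | None = None
    null_quantile: float = np.nan
    flagged: bool = False
    source: str = "gp_estimate"

    def summary(self) -> str:
        lines = [f"Non-separability report — cell {self.cell_id} ({self.source})"]
        lines.append("=" * 52)
        lines.append(f"SDCS:            {self.sdcs:.4f}")
        lines.append(f"delta-FVE:       {self.delta_fve:.4f}")
        if self.null_sdcs is not None and len(self.null_sdcs):
            lines.append(
                f"null SDCS:       median {np.median(self.null_sdcs):.4f}, "
                f"95th pct {np.percentile(self.null_sdcs, 95):.4f} "
                f"(n={len(self.null_sdcs)})"
            )
            lines.append(f"null quantile:   {self.null_quantile:.3f}")
            lines.append(f"non-separable:   {'yes' if self.flagged else 'no'}")
        return "\n".join(lines)
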