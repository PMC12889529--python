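"""From session to 4D binned tuning curve.

Velocity is the finite difference of the Gaussian-smoothed trajectory;
samples with |vx| or |vy| above an artifact cutoff (50 cm/s) are dropped,
and the remainder are histogrammed into 5-cm position x 10-cm/s velocity
bins over (+/-75 cm)^2 x (+/-25 cm/s)^2 — 30 x 30 x 5 x 5 = 22,500 bins.
Each bin's rate is total spikes over total occupancy seconds; bins never
visited carry NaN (unvisited is not the same as silent), and bins with at
least ``occupancy_threshold`` visits form the "high-occupancy" mask used
for model training.

Bin-edge conventions: position edges at -75, -70, ..., +75 cm; velocity
edges at -25, -15, -5, +5, +15, +25 cm/s, so the middle velocity bin is
centred at zero.  Bins are half-open [lo, hi) with the final bin closed.
Samples with 25 < |v| <= 50 cm/s survive the artifact filter but fall
outside the velocity range and contribute to nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .session import Session

__all__ = [
    "BinningSpec",
    "Occupancy4D",
    "TuningCurve4D",
    "compute_velocity",
    "filter_speed",
    "bin_4d",
    "bin_position_2d",
    "marginal_position_tuning",
    "slice_by_velocity",
]


@dataclass
class BinningSpec:
    """Bin geometry and occupancy threshold for the 4D tuning curve."""

    pos_bin: float = 5.0
    pos_range: float = 75.0
    vel_bin: float = 10.0
    vel_range: float = 25.0
    speed_cutoff: float = 50.0
    occupancy_threshold: int = 10
    smooth_window: float = 0.050  # trajectory smoothing sigma, seconds

    @property
    def n_pos(self) -> int:
        return int(round(2 * self.pos_range / self.pos_bin))

    @property
    def n_vel(self) -> int:
        return int(round(2 * self.vel_range / self.vel_bin))

    @property
    def pos_edges(self) -> np.ndarray:
        return np.linspace(-self.pos_range, self.pos_range, self.n_pos + 1)

    @property
    def vel_edges(self) -> np.ndarray:
        return np.linspace(-self.vel_range, self.vel_range, self.n_vel + 1)

    @property
    def pos_centers(self) -> np.ndarray:
        e = self.pos_edges
        return 0.5 * (e[:-1] + e[1:])

    @property
    def vel_centers(self) -> np.ndarray:
        e = self.vel_edges
        return 0.5 * (e[:-1] + e[1:])

    @property
    def shape(self) -> tuple:
        return (self.n_pos, self.n_pos, self.n_vel, self.n_vel)

    @property
    def n_bins(self) -> int:
        return int(np.prod(self.shape))


@dataclass
class Occupancy4D:
    """Time (seconds) and sample counts per 4D bin."""

    seconds: np.ndarray
    visits: np.ndarray


@dataclass
class TuningCurve4D:
    """Binned mean firing rate over (x, y, vx, vy) with occupancy.

    ``rate`` is NaN wherever ``visits == 0``.  ``spike_counts`` keeps the
    raw per-bin spike totals so that occupancy-weighted marginals are exact
    (total spikes over total time, not an average of averages).
    """

    rate: np.ndarray
    occupancy: Occupancy4D
    mask_high: np.ndarray
    spec: BinningSpec
    spike_counts: np.ndarray = field(default=None)  # type: ignore[assignment]
    cell_id: int = 0

    @property
    def bin_centers(self) -> tuple:
        c = self.spec
        return (c.pos_centers, c.pos_centers, c.vel_centers, c.vel_centers)

    def bin_center_coords(self, flat_idx: np.ndarray) -> np.ndarray:
        """(n, 4) array of bin-centre coordinates for flat bin indices."""
        ii = np.unravel_index(flat_idx, self.spec.shape)
        cx, cy, cvx, cvy = self.bin_centers
        return np.column_stack([cx[ii[0]], cy[ii[1]], cvx[ii[2]], cvy[ii[3]]])

    @property
    def data_density(self) -> float:
        """Fraction of the 22,500 bins visited at least once."""
        return float(np.mean(self.occupancy.visits > 0))

    # ------------------------------------------------------------------ I/O

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("rate", data=self.rate)
            f.create_dataset("seconds", data=self.occupancy.seconds)
            f.create_dataset("visits", data=self.occupancy.visits)
            f.create_dataset("mask_high", data=self.mask_high)
            f.create_dataset("spike_counts", data=self.spike_counts)
            f.create_dataset("pos_edges", data=self.spec.pos_edges)
            f.create_dataset("vel_edges", data=self.spec.vel_edges)
            f.attrs["occupancy_threshold"] = self.spec.occupancy_threshold
            f.attrs["speed_cutoff"] = self.spec.speed_cutoff
            f.attrs["cell_id"] = self.cell_id

    @classmethod
    def from_hdf5(cls, path) -> "TuningCurve4D":
        import h5py

        with h5py.File(path, "r") as f:
            pos_edges = f["pos_edges"][:]
            vel_edges = f["vel_edges"][:]
            spec = BinningSpec(
                pos_bin=float(pos_edges[1] - pos_edges[0]),
                pos_range=float(pos_edges[-1]),
                vel_bin=float(vel_edges[1] - vel_edges[0]),
                vel_range=float(vel_edges[-1]),
                speed_cutoff=float(f.attrs["speed_cutoff"]),
                occupancy_threshold=int(f.attrs["occupancy_threshold"]),
            )
            return cls(
                rate=f["rate"][:],
                occupancy=Occupancy4D(seconds=f["seconds"][:], visits=f["visits"][:]),
                mask_high=f["mask_high"][:].astype(bool),
                spec=spec,
                spike_counts=f["spike_counts"][:],
                cell_id=int(f.attrs["cell_id"]),
            )

    def to_csv(self, path) -> None:
        import pandas as pd

        idx = np.indices(self.spec.shape).reshape(4, -1)
        cx, cy, cvx, cvy = self.bin_centers
        pd.DataFrame(
            {
                "x": cx[idx[0]],
                "y": cy[idx[1]],
                "vx": cvx[idx[2]],
                "vy": cvy[idx[3]],
                "rate": self.rate.ravel(),
                "visits": self.occupancy.visits.ravel(),
            }
        ).to_csv(path, index=False)


def compute_velocity(session: Session, smooth_window: float = 0.050):
    """Per-sample (vx, vy) from the smoothed trajectory.

    The trajectory is smoothed with a Gaussian kernel (sigma =
    ``smooth_window`` seconds, reflected boundaries) and differenced:
    ``vx[i] = (x~[i+1] - x~[i]) / dt``; the final sample replicates the
    previous velocity so lengths match.  Motion toward negative x gives
    negative vx.
    """
    if session.n_samples < 2:
        raise ValueError("need at least 2 samples to compute velocity")
    sigma = smooth_window / session.dt
    if sigma > 0:
        xs = gaussian_filter1d(session.x, sigma, mode="reflect")
        ys = gaussian_filter1d(session.y, sigma, mode="reflect")
    else:
        xs, ys = session.x, session.y
    vx = np.empty_like(xs)
    vy = np.empty_like(ys)
    vx[:-1] = np.diff(xs) / session.dt
    vy[:-1] = np.diff(ys) / session.dt
    vx[-1] = vx[-2]
    vy[-1] = vy[-2]
    return vx, vy


def filter_speed(vx: np.ndarray, vy: np.ndarray, spec: BinningSpec) -> np.ndarray:
    """Boolean mask of retained samples: |vx| and |vy| both <= cutoff."""
    c = spec.speed_cutoff
    return (np.abs(vx) <= c) & (np.abs(vy) <= c)


def _bin_index(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Half-open [lo, hi) bin index, final bin closed; -1 out of range."""
    idx = np.searchsorted(edges, values, side="right") - 1
    idx[values == edges[-1]] = len(edges) - 2
    out = (values < edges[0]) | (values > edges[-1])
    idx[out] = -1
    return idx


def bin_4d(
    session: Session,
    vx: np.ndarray,
    vy: np.ndarray,
    spec: BinningSpec | None = None,
    cell: int = 0,
    retained: np.ndarray | None = None,
) -> TuningCurve4D:
    """Bin one cell's spikes into the 4D (x, y, vx, vy) tuning curve.

    ``retained`` is the artifact-filter mask from :func:`filter_speed`
    (computed here if omitted).  Retained samples whose velocity falls
    outside the +/-25 cm/s range are excluded from both occupancy and spike
    totals.
    """
    if spec is None:
        spec = BinningSpec()
    if session.n_samples == 0:
        raise ValueError("empty session")
    if retained is None:
        retained = filter_speed(vx, vy, spec)

    ix = _bin_index(session.x, spec.pos_edges)
    iy = _bin_index(session.y, spec.pos_edges)
    ivx = _bin_index(vx, spec.vel_edges)
    ivy = _bin_index(vy, spec.vel_edges)
    ok = retained & (ix >= 0) & (iy >= 0) & (ivx >= 0) & (ivy >= 0)

    shape = spec.shape
    flat = np.ravel_multi_index(
        (ix[ok], iy[ok], ivx[ok], ivy[ok]), shape
    )
    visits = np.bincount(flat, minlength=spec.n_bins).reshape(shape)
    spikes = np.bincount(
        flat, weights=session.spikes[ok, cell], minlength=spec.n_bins
    ).reshape(shape)
    seconds = visits * session.dt
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(visits > 0, spikes / seconds, np.nan)
    return TuningCurve4D(
        rate=rate,
        occupancy=Occupancy4D(seconds=seconds, visits=visits),
        mask_high=visits >= spec.occupancy_threshold,
        spec=spec,
        spike_counts=spikes,
        cell_id=int(session.cell_ids[cell]),
    )


def bin_position_2d(
    session: Session, spec: BinningSpec | None = None, cell: int = 0
):
    """2D position tuning curve (rate, seconds, visits), ignoring velocity."""
    if spec is None:
        spec = BinningSpec()
    ix = _bin_index(session.x, spec.pos_edges)
    iy = _bin_index(session.y, spec.pos_edges)
    ok = (ix >= 0) & (iy >= 0)
    n = spec.n_pos
    flat = ix[ok] * n + iy[ok]
    visits = np.bincount(flat, minlength=n * n).reshape(n, n)
    spikes = np.bincount(
        flat, weights=session.spikes[ok, cell], minlength=n * n
    ).reshape(n, n)
    seconds = visits * session.dt
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(visits > 0, spikes / seconds, np.nan)
    return rate, seconds, visits


def marginal_position_tuning(tc: TuningCurve4D) -> np.ndarray:
    """Velocity-marginalised 2D position map: occupancy-weighted mean.

    Equals total spikes over total seconds at each position; NaN at
    positions never visited (within the velocity range).
    """
    spikes = tc.spike_counts.sum(axis=(2, 3))
    seconds = tc.occupancy.seconds.sum(axis=(2, 3))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(seconds > 0, spikes / seconds, np.nan)


def slice_by_velocity(tc: TuningCurve4D, i: int, j: int) -> np.ndarray:
    """2D position map restricted to velocity bin (i, j), NaN flags kept."""
    n_vel = tc.spec.n_vel
    if not (0 <= i < n_vel and 0 <= j < n_vel):
        raise IndexError(f"velocity bin ({i}, {j}) outside [0, {n_vel})")
    return tc.rate[:, :, i, j]
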