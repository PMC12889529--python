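"""Session container: time-aligned trajectory plus per-cell spike counts.

A session is the unit of analysis: an animal's (or simulated agent's) 2D
trajectory sampled at a fixed time resolution (10 ms by default) together
with spike counts for each cell in matching time bins.  Sessions round-trip
through HDF5 (the working format) or plain CSV (for small fixtures).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ArenaSpec:
    """Square open-field arena centred on the origin.

    Coordinates span ``[-half_width, +half_width]`` cm on both axes; the
    arena centre is (0, 0).  The default reproduces a 1.5 m x 1.5 m box.
    """

    half_width: float = 75.0

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")


@dataclass
class Session:
    """Trajectory and spikes on a common 10-ms (default) time base.

    Attributes
    ----------
    dt : float
        Time-bin width in seconds.
    t : ndarray, shape (n,)
        Bin start times in seconds.
    x, y : ndarray, shape (n,)
        Position in cm, arena-centred coordinates.
    spikes : ndarray, shape (n, n_cells), integer
        Spike counts per time bin and cell.  May have zero columns for a
        trajectory-only session.
    cell_ids, module_ids : ndarray, shape (n_cells,)
        Integer labels; module membership is taken as given.
    """

    dt: float
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    spikes: np.ndarray
    cell_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    module_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.spikes = np.asarray(self.spikes)
        if self.spikes.ndim == 1:
            self.spikes = self.spikes[:, None]
        n = len(self.t)
        if not (len(self.x) == len(self.y) == self.spikes.shape[0] == n):
            raise ValueError("t, x, y and spikes must share the time dimension")
        if self.spikes.size and (
            np.any(self.spikes < 0) or not np.issubdtype(self.spikes.dtype, np.integer)
        ):
            raise ValueError("spike counts must be nonnegative integers")
        if self.cell_ids is None:
            self.cell_ids = np.arange(self.n_cells)
        if self.module_ids is None:
            self.module_ids = np.zeros(self.n_cells, dtype=int)
        self.cell_ids = np.asarray(self.cell_ids)
        self.module_ids = np.asarray(self.module_ids)

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def n_cells(self) -> int:
        return self.spikes.shape[1]

    @property
    def duration(self) -> float:
        """Total session length in seconds (n_samples * dt)."""
        return self.n_samples * self.dt

    def with_spikes(self, spikes: np.ndarray) -> "Session":
        """Copy of the session with the spike matrix replaced."""
        return Session(
            dt=self.dt,
            t=self.t.copy(),
            x=self.x.copy(),
            y=self.y.copy(),
            spikes=np.asarray(spikes),
            cell_ids=self.cell_ids.copy(),
            module_ids=self.module_ids.copy(),
        )

    # ------------------------------------------------------------------ I/O

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["dt"] = self.dt
            f.create_dataset("t", data=self.t)
            f.create_dataset("x", data=self.x)
            f.create_dataset("y", data=self.y)
            f.create_dataset("spikes", data=self.spikes.astype(np.int32))
            f.create_dataset("cell_ids", data=np.asarray(self.cell_ids, dtype=np.int64))
            f.create_dataset("module_ids", data=np.asarray(self.module_ids, dtype=np.int64))

    @classmethod
    def from_hdf5(cls, path) -> "Session":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                dt=float(f.attrs["dt"]),
                t=f["t"][:],
                x=f["x"][:],
                y=f["y"][:],
                spikes=f["spikes"][:],
                cell_ids=f["cell_ids"][:],
                module_ids=f["module_ids"][:],
            )

    def to_csv(self, path) -> None:
        """One row per time bin, one ``cell_<id>`` column per cell."""
        df = pd.DataFrame({"t": self.t, "x": self.x, "y": self.y})
        for j, cid in enumerate(self.cell_ids):
            df[f"cell_{cid}"] = self.spikes[:, j]
        df.attrs["dt"] = self.dt
        with open(path, "w") as fh:
            fh.write(f"# dt={self.dt}\n")
            fh.write(f"# module_ids={','.join(str(m) for m in self.module_ids)}\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "Session":
        dt = None
        module_ids = None
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                key, _, val = line[1:].strip().partition("=")
                if key.strip() == "dt":
                    dt = float(val)
                elif key.strip() == "module_ids":
                    module_ids = np.array(
                        [int(v) for v in val.split(",") if v], dtype=int
                    )
        df = pd.read_csv(path, comment="#")
        cell_cols = [c for c in df.columns if c.startswith("cell_")]
        cell_ids = np.array([int(c.split("_", 1)[1]) for c in cell_cols])
        spikes = df[cell_cols].to_numpy(dtype=np.int64)
        if dt is None:
            dt = float(np.median(np.diff(df["t"]))) if len(df) > 1 else 0.01
        if module_ids is None or len(module_ids) != len(cell_ids):
            module_ids = np.zeros(len(cell_ids), dtype=int)
        return cls(
            dt=dt,
            t=df["t"].to_numpy(),
            x=df["x"].to_numpy(),
            y=df["y"].to_numpy(),
            spikes=spikes,
            cell_ids=cell_ids,
            module_ids=module_ids,
        )
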