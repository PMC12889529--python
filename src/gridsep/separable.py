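"""Factorized (separable) alternative model of the 4D tuning curve.

The separability hypothesis says velocity acts as a pure gain on an
invariant spatial map:

    r_pred(x, y, vx, vy) = f_pos(x, y) * f_vel(vx, vy)

with both factors nonnegative.  The factors are fitted by projected
gradient descent on the squared-error loss summed over the training bins
(a gradient step on both factors simultaneously, then an elementwise
clamp at zero), on exactly the same high-occupancy bins and
cross-validation folds as the GP model, so that the held-out FVE of the
two models — and their difference, delta-FVE — are directly comparable.

The raw gradient is badly scaled: the loss curvature of a factor entry
grows with the number of training bins it touches, which differs by more
than an order of magnitude between the 900-entry position factor and the
25-entry velocity factor and with data density.  Each gradient step is
therefore preconditioned by the per-coordinate curvature (the exact
second derivative of the loss in that coordinate with the other factor
held fixed), making ``lr`` a dimensionless relaxation factor in (0, 1]
that behaves identically across cells, firing-rate scales and training
densities.  As a gauge convention the returned ``f_vel`` is normalised
to unit mean with the scale absorbed into ``f_pos`` — predictions are
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .binning import TuningCurve4D
from .gp import GPTuningResults, fve, make_cv_splits

__all__ = [
    "SeparableTuningModel",
    "SeparableTuningResults",
    "fit_separable_factors",
    "compare_models",
]


def fit_separable_factors(
    targets: np.ndarray,
    pos_idx: np.ndarray,
    vel_idx: np.ndarray,
    pos_size: int,
    vel_size: int,
    lr: float = 0.3,
    iters: int = 5000,
    seed: int = 0,
    tol: float = 1e-8,
    patience: int = 100,
    weights: np.ndarray | None = None,
):
    """Projected gradient descent for nonnegative rank-1 factors.

    Parameters
    ----------
    targets : (n,) array
        Observed rates at the training bins.
    pos_idx, vel_idx : (n,) int arrays
        Flattened position-bin and velocity-bin index of each training bin.
    pos_size, vel_size : int
        Number of position bins (e.g. 900) and velocity bins (e.g. 25).
    lr : float
        Relaxation factor in (0, 1] for the curvature-preconditioned
        gradient step; 1 is an undamped (Jacobi-style) step.
    iters : int
        Iteration cap.
    tol, patience : float, int
        Early stop when the relative best-loss improvement over
        ``patience`` iterations falls below ``tol``.
    weights : (n,) array, optional
        Per-bin weights for the squared error (normalised to unit mean).
        Weighting by occupancy seconds (inverse sampling variance of a
        binned rate) puts the separable fit on the same noise model as
        the heteroscedastic GP, so the model comparison reflects
        separability rather than noise handling.  Default: unweighted.

    Returns ``(f_pos, f_vel, loss_history)`` with the best-loss iterate's
    factors (flat arrays) and the per-iteration loss (sum of squared
    residuals, in the targets' units squared).
    """
    if lr <= 0 or iters <= 0:
        raise ValueError("lr and iters must be positive")
    if lr > 1:
        raise ValueError("lr is a relaxation factor and must be <= 1")
    targets = np.asarray(targets, dtype=float)
    n = targets.size
    if n == 0:
        raise ValueError("no training bins")
    if not np.all(np.isfinite(targets)):
        raise ValueError("training targets must be finite")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float).ravel()
        if w.shape != targets.shape or np.any(w <= 0):
            raise ValueError("weights must be positive, one per training bin")
        w = w / np.mean(w)

    # unit-RMS targets keep the divergence guard and tolerances scale-free
    scale = float(np.sqrt(np.mean(targets**2)))
    if scale == 0:
        scale = 1.0
    y = targets / scale

    rng = np.random.default_rng(seed)
    # start near sqrt(grand mean) so the initial outer product has the
    # right order of magnitude
    base = np.sqrt(max(np.mean(y), 1e-3))
    F = base * rng.uniform(0.5, 1.5, size=pos_size)
    G = base * rng.uniform(0.5, 1.5, size=vel_size)

    best_loss = np.inf
    best = (F.copy(), G.copy())
    loss_history = np.empty(iters)
    last_check = np.inf
    it = 0
    for it in range(iters):
        pred = F[pos_idx] * G[vel_idx]
        r = pred - y
        loss = float(w @ (r * r))
        loss_history[it] = loss
        if not np.isfinite(loss) or loss > 1e12:
            raise FloatingPointError(
                f"separable fit diverged at iteration {it} (loss={loss:.3g}); "
                "reduce lr"
            )
        if loss < best_loss:
            best_loss = loss
            best = (F.copy(), G.copy())
        if it % patience == 0:
            if last_check - best_loss <= tol * max(best_loss, 1e-30):
                loss_history = loss_history[: it + 1]
                break
            last_check = best_loss
        wr = w * r
        gF = 2.0 * np.bincount(pos_idx, weights=wr * G[vel_idx], minlength=pos_size)
        gG = 2.0 * np.bincount(vel_idx, weights=wr * F[pos_idx], minlength=vel_size)
        # exact per-coordinate curvature with the other factor held fixed
        hF = 2.0 * np.bincount(pos_idx, weights=w * G[vel_idx] ** 2, minlength=pos_size)
        hG = 2.0 * np.bincount(vel_idx, weights=w * F[pos_idx] ** 2, minlength=vel_size)
        F = np.maximum(F - lr * gF / np.maximum(hF, 1e-12), 0.0)
        G = np.maximum(G - lr * gG / np.maximum(hG, 1e-12), 0.0)
    else:
        loss_history = loss_history[: it + 1]

    F, G = best
    # restore units and fix the gauge: f_vel has unit mean where nonzero
    F = F * scale
    gmean = G.mean()
    if gmean > 0:
        F = F * gmean
        G = G / gmean
    return F, G, loss_history * scale**2


class SeparableTuningModel:
    """Nonnegative rank-1 model of one cell's 4D tuning curve.

    Mirrors :class:`~gridsep.gp.GPTuningModel`: ``fit()`` runs the same
    k-fold protocol on the high-occupancy bins and returns a
    :class:`SeparableTuningResults`.  Pass the same ``splits`` given to
    the GP model to guarantee an identical partition.
    """

    def __init__(
        self,
        tc: TuningCurve4D,
        k: int = 5,
        lr: float = 0.3,
        iters: int = 5000,
        weighting: str = "occupancy",
    ):
        if lr <= 0 or iters <= 0:
            raise ValueError("lr and iters must be positive")
        if weighting not in ("occupancy", "none"):
            raise ValueError("weighting must be 'occupancy' or 'none'")
        self.tc = tc
        self.k = int(k)
        self.lr = float(lr)
        self.iters = int(iters)
        self.weighting = weighting
        self.high_idx = np.flatnonzero(tc.mask_high.ravel())

    def _weights(self, flat_idx: np.ndarray):
        if self.weighting == "none":
            return None
        return self.tc.occupancy.seconds.ravel()[flat_idx]

    def _split_indices(self, flat_idx: np.ndarray):
        sh = self.tc.spec.shape
        ii = np.unravel_index(flat_idx, sh)
        pos = ii[0] * sh[1] + ii[1]
        vel = ii[2] * sh[3] + ii[3]
        return pos, vel

    def fit(self, seed: int = 0, splits: list | None = None) -> "SeparableTuningResults":
        """Cross-validated fit on (train, validation) ``splits`` — pass
        the same list given to the GP model for a comparable delta-FVE."""
        if len(self.high_idx) < self.k:
            raise ValueError(
                f"only {len(self.high_idx)} high-occupancy bins; need >= k={self.k}"
            )
        if splits is None:
            splits = make_cv_splits(self.high_idx, self.k, seed)
        sh = self.tc.spec.shape
        n_pos = sh[0] * sh[1]
        n_vel = sh[2] * sh[3]
        rates = self.tc.rate.ravel()
        ss = np.random.SeedSequence([int(seed), 0x5EB])
        fit_seeds = ss.generate_state(len(splits) + 1)

        pred_sum = np.zeros(self.tc.spec.n_bins)
        fve_folds = []
        factors = []
        for fi, (train_idx, fold) in enumerate(splits):
            p, q = self._split_indices(train_idx)
            F, G, _ = fit_separable_factors(
                rates[train_idx], p, q, n_pos, n_vel,
                lr=self.lr, iters=self.iters, seed=fit_seeds[fi],
                weights=self._weights(train_idx),
            )
            pv, qv = self._split_indices(fold)
            fve_folds.append(fve(F[pv] * G[qv], rates[fold]))
            pred_sum += np.outer(F, G).ravel()
            factors.append((F.reshape(sh[0], sh[1]), G.reshape(sh[2], sh[3])))

        # consensus factors from all high-occupancy bins (for reporting)
        p, q = self._split_indices(self.high_idx)
        F, G, loss_history = fit_separable_factors(
            rates[self.high_idx], p, q, n_pos, n_vel,
            lr=self.lr, iters=self.iters, seed=fit_seeds[-1],
            weights=self._weights(self.high_idx),
        )
        return SeparableTuningResults(
            model=self,
            f_pos=F.reshape(sh[0], sh[1]),
            f_vel=G.reshape(sh[2], sh[3]),
            loss_history=loss_history,
            pred4d=(pred_sum / len(splits)).reshape(sh),
            fve_per_fold=np.array(fve_folds),
            splits=splits,
            factors_per_fold=factors,
        )


@dataclass
class SeparableTuningResults:
    """Fitted nonnegative factors and cross-validated FVE.

    ``pred4d`` is the across-fold average of the rank-1 predictions (the
    analogue of the GP's fold-averaged ``mean4d``); ``f_pos``/``f_vel``
    are consensus factors fitted on all high-occupancy bins, gauge-fixed
    to unit-mean ``f_vel``.
    """

    model: SeparableTuningModel
    f_pos: np.ndarray
    f_vel: np.ndarray
    loss_history: np.ndarray
    pred4d: np.ndarray
    fve_per_fold: np.ndarray
    splits: list
    factors_per_fold: list

    @property
    def folds(self) -> list:
        """Validation folds (second element of each split)."""
        return [val for _, val in self.splits]

    @property
    def fve(self) -> float:
        return float(np.mean(self.fve_per_fold)) if len(self.fve_per_fold) else np.nan

    def predict(self, flat_idx: np.ndarray | None = None) -> np.ndarray:
        """Outer-product prediction of the consensus factors."""
        full = np.multiply.outer(self.f_pos, self.f_vel)
        if flat_idx is None:
            return full
        return full.ravel()[flat_idx]

    def summary(self) -> str:
        lines = ["Separable tuning-curve model (nonnegative rank-1)"]
        lines.append("=" * 52)
        lines.append(f"cell id:              {self.model.tc.cell_id}")
        lines.append(f"high-occupancy bins:  {len(self.model.high_idx)}")
        lines.append(f"folds:                {len(self.folds)}")
        per = ", ".join(f"{v:.3f}" for v in self.fve_per_fold)
        lines.append(f"FVE per fold:         {per}")
        lines.append(f"FVE (mean):           {self.fve:.3f}")
        lines.append(f"final loss:           {self.loss_history[-1]:.4g}")
        lines.append(f"iterations:           {len(self.loss_history)}")
        return "\n".join(lines)

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("f_pos", data=self.f_pos)
            f.create_dataset("f_vel", data=self.f_vel)
            f.create_dataset("loss_history", data=self.loss_history)
            f.create_dataset("pred4d", data=self.pred4d)
            f.create_dataset("fve_per_fold", data=self.fve_per_fold)
            for i, (train, val) in enumerate(self.splits):
                f.create_dataset(f"splits/{i}/train", data=train)
                f.create_dataset(f"splits/{i}/val", data=val)


def compare_models(gp: GPTuningResults, sep: SeparableTuningResults) -> float:
    """delta-FVE = FVE(GP) - FVE(separable), on identical folds.

    Positive values mean variance attributable to a position x velocity
    interaction that the factorized model cannot express.
    """
    if len(gp.splits) != len(sep.splits) or any(
        not (np.array_equal(tr_a, tr_b) and np.array_equal(va_a, va_b))
        for (tr_a, va_a), (tr_b, va_b) in zip(gp.splits, sep.splits)
    ):
        raise ValueError("GP and separable fits used different train/validation splits")
    return float(gp.fve - sep.fve)
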