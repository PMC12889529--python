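"""Gaussian-process estimation of tuning curves.

The binned tuning curve observes the rate only at visited bins; a GP prior
over the 4D behaviour space interpolates it everywhere and attaches a
predictive standard deviation.  The model is

    f(b) ~ GP(mu, k(b, b'))            b = (x, y, vx, vy)

with a constant mean (the mean of the training targets), a Matérn nu=5/2
kernel with one lengthscale per dimension (automatic-relevance form),

    k(b, b') = s2 * (1 + sqrt(5) d + 5/3 d^2) * exp(-sqrt(5) d),
    d^2 = sum_m ((b_m - b'_m) / ell_m)^2,

and a Gaussian likelihood with noise variance sn2.  Hyperparameters are
initialised at lengthscale 10 per dimension and signal variance 0.3 and
optimised by maximising the log marginal likelihood (quasi-Newton on log
parameters, analytic gradients).

Model selection and scoring follow a k-fold protocol on the
"high-occupancy" bins (>= 10 visits): the bins are split into k=5 folds,
one GP is trained per fold on the other 80%, the fraction of variance
explained (FVE) is computed on the held-out fold, and the reported 4D
estimate is the average of the k predictive means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize

from .binning import TuningCurve4D

__all__ = [
    "GPHyperparams",
    "matern52",
    "fve",
    "make_folds",
    "make_cv_splits",
    "GaussianProcessRegression",
    "GPTuningModel",
    "GPTuningResults",
]

_SQRT5 = np.sqrt(5.0)
_JITTER_REL = 1e-6  # diagonal jitter as a fraction of signal variance


@dataclass
class GPHyperparams:
    """Kernel and likelihood hyperparameters.

    ``noise_variance=None`` means "initialise to 0.1 x Var(train targets)"
    at fit time.  ``nu`` is fixed at 5/2; it is recorded for provenance.
    """

    lengthscales: np.ndarray = field(default_factory=lambda: np.full(4, 10.0))
    signal_variance: float = 0.3
    noise_variance: float | None = None
    nu: float = 2.5

    def __post_init__(self) -> None:
        self.lengthscales = np.atleast_1d(np.asarray(self.lengthscales, dtype=float))
        if np.any(self.lengthscales <= 0):
            raise ValueError("lengthscales must be positive")
        if self.signal_variance <= 0:
            raise ValueError("signal_variance must be positive")
        if self.noise_variance is not None and self.noise_variance <= 0:
            raise ValueError("noise_variance must be positive")


def matern52(X1, X2, lengthscales, signal_variance: float) -> np.ndarray:
    """Matérn nu=5/2 covariance matrix between two sets of points.

    Distances are Euclidean after scaling each dimension by its
    lengthscale, so ``k(b, b) = signal_variance`` and the kernel decays as
    a second-order polynomial times an exponential in the scaled distance.
    """
    lengthscales = np.atleast_1d(np.asarray(lengthscales, dtype=float))
    if np.any(lengthscales <= 0):
        raise ValueError("lengthscales must be positive")
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    U1 = X1 / lengthscales
    U2 = X2 / lengthscales
    d2 = (
        np.sum(U1**2, axis=1)[:, None]
        + np.sum(U2**2, axis=1)[None, :]
        - 2.0 * U1 @ U2.T
    )
    d = np.sqrt(np.maximum(d2, 0.0))
    return signal_variance * (1.0 + _SQRT5 * d + (5.0 / 3.0) * d * d) * np.exp(-_SQRT5 * d)


def fve(pred: np.ndarray, held: np.ndarray) -> float:
    """Fraction of variance explained, 1 - Var(held - pred) / Var(held).

    Population variances.  A constant ``held`` has no variance to explain;
    the score is undefined and NaN is returned with a warning.
    """
    pred = np.asarray(pred, dtype=float).ravel()
    held = np.asarray(held, dtype=float).ravel()
    if pred.shape != held.shape or held.size < 2:
        raise ValueError("pred and held must be equal-length vectors (>= 2)")
    var_y = np.var(held)
    if var_y == 0:
        warnings.warn("held-out data has zero variance; FVE undefined")
        return np.nan
    return float(1.0 - np.var(held - pred) / var_y)


def make_folds(indices: np.ndarray, k: int, seed: int) -> list:
    """Split ``indices`` into k disjoint validation folds, seeded.

    Fold sizes differ by at most one.  The same fold list must be handed to
    every model being compared.
    """
    indices = np.asarray(indices)
    if len(indices) < k:
        raise ValueError(f"need at least {k} bins to make {k} folds, got {len(indices)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(indices)
    return [np.sort(fold) for fold in np.array_split(perm, k)]


def make_cv_splits(
    indices: np.ndarray, k: int, seed: int, max_train: int | None = None
) -> list:
    """k-fold (train, validation) splits shared across models.

    Validation folds partition ``indices`` as in :func:`make_folds`; each
    training set is the complement, subsampled uniformly at random
    (seeded) to ``max_train`` bins when larger.  Model comparison is only
    fair when every model trains and validates on these exact sets, so
    the subsampling happens here, once, rather than inside any one model.
    """
    folds = make_folds(indices, k, seed)
    indices = np.asarray(indices)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5B5]))
    splits = []
    for fold in folds:
        train = np.setdiff1d(indices, fold)
        if max_train is not None and len(train) > max_train:
            train = np.sort(rng.choice(train, size=max_train, replace=False))
        splits.append((train, fold))
    return splits


class GaussianProcessRegression:
    """Exact GP regression with a Matérn-5/2 ARD kernel and constant mean.

    This is the engine behind :class:`GPTuningModel`; it works for any
    input dimension.  ``fit()`` maximises the log marginal likelihood over
    (lengthscales, signal variance, noise variance) on the log scale with
    L-BFGS-B and analytic gradients; ``predict()`` returns the latent
    (noise-free) posterior mean and standard deviation.

    Parameters
    ----------
    X : (n, d) array
        Training inputs (bin centres).
    y : (n,) array
        Training targets (bin rates, Hz).
    hyper : GPHyperparams
        Initial values; lengthscales are broadcast to d if scalar.
    noise_weights : (n,) array, optional
        Per-point noise scaling: the likelihood noise of point i is
        ``noise_variance * noise_weights[i]``.  For rates formed as
        (spike count)/(time in bin), the sampling variance scales as
        1/(time in bin), so weights proportional to 1/occupancy give a
        heteroscedastic Gaussian approximation to the binned-Poisson
        noise.  Weights are normalised to unit mean so ``noise_variance``
        keeps its usual scale.  Default: homoscedastic (all ones).
    """

    def __init__(self, X, y, hyper: GPHyperparams | None = None, noise_weights=None):
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.y = np.asarray(y, dtype=float).ravel()
        if self.X.shape[0] != self.y.size:
            raise ValueError("X and y disagree on the number of points")
        if self.X.shape[0] < 2:
            raise ValueError("need at least 2 training points")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("training targets must be finite")
        d = self.X.shape[1]
        if hyper is None:
            hyper = GPHyperparams(lengthscales=np.full(d, 10.0))
        ls = hyper.lengthscales
        if ls.size == 1:
            ls = np.full(d, ls[0])
        if ls.size != d:
            raise ValueError("lengthscales do not match input dimension")
        var_y = np.var(self.y)
        noise = hyper.noise_variance
        if noise is None:
            noise = 0.1 * var_y if var_y > 0 else 1e-4
        self.hyper = GPHyperparams(
            lengthscales=ls,
            signal_variance=hyper.signal_variance,
            noise_variance=noise,
            nu=hyper.nu,
        )
        if noise_weights is None:
            self.noise_weights = np.ones(self.y.size)
        else:
            w = np.asarray(noise_weights, dtype=float).ravel()
            if w.shape != self.y.shape or np.any(w <= 0):
                raise ValueError("noise_weights must be positive, one per point")
            self.noise_weights = w / np.mean(w)
        self.mean_const = float(np.mean(self.y))
        self.converged: bool | None = None
        self.final_nll: float | None = None
        self._post = None
        self._D2_cache = None

    @property
    def _D2(self):
        # per-dimension squared differences, built lazily (an (n, n, d)
        # array is only needed by the optimiser, not for prediction)
        if self._D2_cache is None:
            self._D2_cache = (self.X[:, None, :] - self.X[None, :, :]) ** 2
        return self._D2_cache

    # ------------------------------------------------------------ likelihood

    def _nll_and_grad(self, theta: np.ndarray):
        d = self.X.shape[1]
        ell = np.exp(theta[:d])
        s2 = np.exp(theta[d])
        sn2 = np.exp(theta[d + 1])
        n = self.y.size

        scaled = self._D2 / ell**2  # (n, n, d)
        d2 = scaled.sum(axis=-1)
        dist = np.sqrt(np.maximum(d2, 0.0))
        E = np.exp(-_SQRT5 * dist)
        Kf = s2 * (1.0 + _SQRT5 * dist + (5.0 / 3.0) * d2) * E
        jitter = _JITTER_REL * s2
        K = Kf + np.diag(sn2 * self.noise_weights + jitter)

        try:
            L, low = cho_factor(K, lower=True)
        except np.linalg.LinAlgError:
            return np.inf, np.zeros_like(theta)
        yc = self.y - self.mean_const
        alpha = cho_solve((L, low), yc)
        nll = (
            0.5 * yc @ alpha
            + np.sum(np.log(np.diag(L)))
            + 0.5 * n * np.log(2.0 * np.pi)
        )

        Kinv = cho_solve((L, low), np.eye(n))
        A = np.outer(alpha, alpha) - Kinv

        grad = np.empty_like(theta)
        # dK/dlog(ell_m) = s2 * 5/3 * (1 + sqrt5 d) * exp(-sqrt5 d) * (D2_m/ell_m^2)
        W = s2 * (5.0 / 3.0) * (1.0 + _SQRT5 * dist) * E
        for m in range(d):
            grad[m] = -0.5 * np.sum(A * (W * scaled[..., m]))
        grad[d] = -0.5 * (np.sum(A * Kf) + jitter * np.trace(A))
        grad[d + 1] = -0.5 * sn2 * float(np.diag(A) @ self.noise_weights)
        return nll, grad

    def log_marginal_likelihood(self, hyper: GPHyperparams | None = None) -> float:
        h = hyper if hyper is not None else self.hyper
        theta = np.concatenate(
            [np.log(h.lengthscales), [np.log(h.signal_variance), np.log(h.noise_variance)]]
        )
        nll, _ = self._nll_and_grad(theta)
        return -nll

    # -------------------------------------------------------------- fitting

    def fit(
        self,
        optimize: bool = True,
        maxiter: int = 200,
        gtol: float = 1e-5,
        lengthscale_bounds=None,
    ):
        """Optimise hyperparameters (unless ``optimize=False``) and cache
        the posterior.  Returns self.

        ``lengthscale_bounds`` — optional (d, 2) array of per-dimension
        (low, high) lengthscale bounds.  On binned inputs a lengthscale
        below the bin width is unidentifiable and lets the optimiser fall
        into a degenerate mode that reproduces per-bin noise; callers that
        know the data resolution should bound lengthscales away from it.
        """
        d = self.X.shape[1]
        h = self.hyper
        theta0 = np.concatenate(
            [np.log(h.lengthscales), [np.log(h.signal_variance), np.log(h.noise_variance)]]
        )
        if optimize:
            # keep parameters in a numerically sane range
            bounds = [(-10.0, 12.0)] * (d + 2)
            if lengthscale_bounds is not None:
                lb = np.atleast_2d(np.asarray(lengthscale_bounds, dtype=float))
                if lb.shape != (d, 2) or np.any(lb <= 0):
                    raise ValueError("lengthscale_bounds must be (d, 2) and positive")
                bounds[:d] = [(np.log(lo), np.log(hi)) for lo, hi in lb]
                theta0[:d] = np.clip(
                    theta0[:d], np.log(lb[:, 0]), np.log(lb[:, 1])
                )
            res = minimize(
                self._nll_and_grad,
                theta0,
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": maxiter, "gtol": gtol},
                bounds=bounds,
            )
            nll0, _ = self._nll_and_grad(theta0)
            theta, best_nll = (res.x, res.fun) if res.fun <= nll0 else (theta0, nll0)
            self.converged = bool(res.success)
            if not res.success:
                warnings.warn(
                    f"hyperparameter optimisation did not converge ({res.message}); "
                    "using best parameters found"
                )
            self.hyper = GPHyperparams(
                lengthscales=np.exp(theta[:d]),
                signal_variance=float(np.exp(theta[d])),
                noise_variance=float(np.exp(theta[d + 1])),
                nu=h.nu,
            )
            self.final_nll = float(best_nll)
        self._factorize()
        return self

    def _factorize(self) -> None:
        h = self.hyper
        n = self.y.size
        K = matern52(self.X, self.X, h.lengthscales, h.signal_variance)
        K[np.diag_indices(n)] += (
            h.noise_variance * self.noise_weights + _JITTER_REL * h.signal_variance
        )
        try:
            L, low = cho_factor(K, lower=True)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"kernel matrix singular after jitter (n={n}, "
                f"noise_variance={h.noise_variance:.3g}): {err}"
            ) from err
        alpha = cho_solve((L, low), self.y - self.mean_const)
        self._post = (L, low, alpha)

    def predict(self, Xstar, chunk: int = 2048, return_std: bool = True):
        """Latent posterior mean (and standard deviation) at ``Xstar``.

        Evaluation is chunked to keep temporaries cache- and
        allocator-friendly.  ``return_std=False`` skips the triangular
        solves and returns ``(mean, None)``.
        """
        if self._post is None:
            self._factorize()
        L, low, alpha = self._post
        h = self.hyper
        Xstar = np.atleast_2d(np.asarray(Xstar, dtype=float))
        mean = np.empty(Xstar.shape[0])
        var = np.empty(Xstar.shape[0]) if return_std else None
        for lo in range(0, Xstar.shape[0], chunk):
            hi = min(lo + chunk, Xstar.shape[0])
            Ks = matern52(Xstar[lo:hi], self.X, h.lengthscales, h.signal_variance)
            mean[lo:hi] = self.mean_const + Ks @ alpha
            if return_std:
                tmp = solve_triangular(L if low else L.T, Ks.T, lower=True)
                var[lo:hi] = h.signal_variance - np.sum(tmp**2, axis=0)
        if not return_std:
            return mean, None
        return mean, np.sqrt(np.maximum(var, 0.0))


# ---------------------------------------------------------------- 4D model


class GPTuningModel:
    """GP model of one cell's 4D tuning curve (statsmodels-style).

    Built from a :class:`~gridsep.binning.TuningCurve4D`; ``fit()`` runs
    the k-fold cross-validation protocol on the high-occupancy bins and
    returns a :class:`GPTuningResults`.

    Parameters
    ----------
    tc : TuningCurve4D
    k : int
        Number of cross-validation folds (default 5 — an 80/20 split).
    init : GPHyperparams
        Initial hyperparameters (default: lengthscale 10 per dimension,
        signal variance 0.3).
    max_train_bins : int
        Exact-GP posterior budget; larger training sets are subsampled
        uniformly at random (seeded).
    hyper_train_bins : int
        Budget for the hyperparameter-optimisation stage.  Maximising the
        marginal likelihood costs O(n^3) per optimiser step, while
        conditioning the posterior costs one O(n^3) factorisation, so the
        fit is two-stage: hyperparameters are optimised on a random
        subset of at most this many training bins, then the posterior is
        conditioned on up to ``max_train_bins`` bins with those
        hyperparameters.  When the training set fits the hyper budget the
        two stages coincide and the fit is a plain exact GP.
    maxiter : int
        Optimiser iteration cap per fold.
    train_selection : {"occupancy", "random"}
        How to reduce an oversized training set: keeping the most-visited
        bins (default; the least-noisy rate estimates, with seeded random
        tie-breaking) or uniformly at random.  Occupancy ranking
        concentrates on well-sampled behaviour, which at the default
        posterior budget empirically yields better-calibrated estimates
        than random subsampling; random selection spreads coverage and
        can be preferable at small budgets.
    heteroscedastic : bool
        Scale each training bin's likelihood noise by 1/occupancy-seconds
        (the sampling variance of a binned rate), so sparsely visited bins
        are not over-trusted.  Default True.
    """

    def __init__(
        self,
        tc: TuningCurve4D,
        k: int = 5,
        init: GPHyperparams | None = None,
        max_train_bins: int = 3000,
        hyper_train_bins: int = 1000,
        maxiter: int = 200,
        optimize: bool = True,
        train_selection: str = "occupancy",
        heteroscedastic: bool = True,
    ):
        if train_selection not in ("occupancy", "random"):
            raise ValueError("train_selection must be 'occupancy' or 'random'")
        self.tc = tc
        self.k = int(k)
        self.init = init if init is not None else GPHyperparams()
        self.max_train_bins = int(max_train_bins)
        self.hyper_train_bins = min(int(hyper_train_bins), self.max_train_bins)
        self.maxiter = int(maxiter)
        self.optimize = optimize
        self.train_selection = train_selection
        self.heteroscedastic = heteroscedastic
        self.high_idx = np.flatnonzero(tc.mask_high.ravel())

    def _subsample(self, idx: np.ndarray, size: int, rng: np.random.Generator):
        """Reduce ``idx`` to ``size`` bins: either the most-visited bins
        (deterministic, least-noisy rate estimates) or uniformly at
        random (seeded)."""
        if len(idx) <= size:
            return idx
        if self.train_selection == "occupancy":
            visits = self.tc.occupancy.visits.ravel()[idx]
            # seeded random tie-break so equal-occupancy bins are not
            # selected in (spatially structured) index order
            order = np.lexsort((rng.random(len(idx)), -visits))
            return np.sort(idx[order[:size]])
        return np.sort(rng.choice(idx, size=size, replace=False))

    def _noise_weights(self, idx: np.ndarray):
        """1/occupancy-seconds weights (binned-Poisson variance scaling)."""
        if not self.heteroscedastic:
            return None
        seconds = self.tc.occupancy.seconds.ravel()[idx]
        return 1.0 / np.maximum(seconds, 1e-12)

    def _grid_coords(self) -> np.ndarray:
        return self.tc.bin_center_coords(np.arange(self.tc.spec.n_bins))

    def _lengthscale_bounds(self) -> np.ndarray:
        """Per-dimension lengthscale bounds: one bin width (below which a
        lengthscale is unidentifiable on binned data) up to ten times the
        full range of the dimension."""
        s = self.tc.spec
        return np.array(
            [
                (s.pos_bin, 20.0 * s.pos_range),
                (s.pos_bin, 20.0 * s.pos_range),
                (s.vel_bin, 20.0 * s.vel_range),
                (s.vel_bin, 20.0 * s.vel_range),
            ]
        )

    def _fit_one(self, train_idx: np.ndarray, rng: np.random.Generator):
        rates = self.tc.rate.ravel()
        train_idx = self._subsample(train_idx, self.max_train_bins, rng)
        hyper = self.init
        if self.optimize:
            hyper_idx = self._subsample(train_idx, self.hyper_train_bins, rng)
            # the marginal-likelihood surface is multimodal on noisy binned
            # rates; start from the standard init and from a velocity-smooth
            # init and keep the better optimum
            s = self.tc.spec
            smooth_init = GPHyperparams(
                lengthscales=np.array(
                    [
                        self.init.lengthscales[0],
                        self.init.lengthscales[1],
                        2.0 * s.vel_range,
                        2.0 * s.vel_range,
                    ]
                ),
                signal_variance=self.init.signal_variance,
                noise_variance=self.init.noise_variance,
            )
            X_h = self.tc.bin_center_coords(hyper_idx)
            y_h = rates[hyper_idx]
            w_h = self._noise_weights(hyper_idx)
            gp_h = None
            for init in (self.init, smooth_init):
                cand = GaussianProcessRegression(X_h, y_h, hyper=init, noise_weights=w_h)
                cand.fit(
                    optimize=True,
                    maxiter=self.maxiter,
                    lengthscale_bounds=self._lengthscale_bounds(),
                )
                if gp_h is None or cand.final_nll < gp_h.final_nll:
                    gp_h = cand
            if len(hyper_idx) == len(train_idx):
                return gp_h
            hyper = gp_h.hyper
        gp = GaussianProcessRegression(
            self.tc.bin_center_coords(train_idx),
            rates[train_idx],
            hyper=hyper,
            noise_weights=self._noise_weights(train_idx),
        )
        gp.fit(optimize=False)
        return gp

    def fit(
        self,
        seed: int = 0,
        splits: list | None = None,
        predict_grid: bool = True,
    ) -> "GPTuningResults":
        """Cross-validated fit.

        ``splits`` — a list of (train, validation) flat-index pairs from
        :func:`make_cv_splits` — may be supplied to share the exact fold
        partition with the separable model; otherwise it is derived from
        ``seed``.  ``predict_grid=False`` skips the full 22,500-bin
        prediction (``mean4d``/``std4d`` become NaN) when only the
        cross-validated FVE is needed.
        """
        if len(self.high_idx) < self.k:
            raise ValueError(
                f"only {len(self.high_idx)} high-occupancy bins; need >= k={self.k}"
            )
        if splits is None:
            splits = make_cv_splits(self.high_idx, self.k, seed)
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x6701]))
        rates = self.tc.rate.ravel()
        shape = self.tc.spec.shape
        grid = self._grid_coords() if predict_grid else None

        mean_sum = np.zeros(self.tc.spec.n_bins)
        std_sum = np.zeros(self.tc.spec.n_bins)
        fve_folds = []
        hypers = []
        for train_idx, fold in splits:
            gp = self._fit_one(train_idx, rng)
            mu_val, _ = gp.predict(self.tc.bin_center_coords(fold), return_std=False)
            fve_folds.append(fve(mu_val, rates[fold]))
            if predict_grid:
                mu, sd = gp.predict(grid)
                mean_sum += mu
                std_sum += sd
            hypers.append(gp.hyper)
        kk = len(splits)
        if not predict_grid:
            mean_sum[:] = np.nan
            std_sum[:] = np.nan
            kk = 1
        return GPTuningResults(
            model=self,
            mean4d=(mean_sum / kk).reshape(shape),
            std4d=(std_sum / kk).reshape(shape),
            fve_per_fold=np.array(fve_folds),
            splits=splits,
            hyper_per_fold=hypers,
        )

    def fit_single(self, seed: int = 0, return_std: bool = True) -> "GPTuningResults":
        """One GP on all high-occupancy bins; no cross-validated FVE.

        Used where only the 4D estimate is needed (e.g. the null-model
        SDCS distribution), at a fifth of the cost of the k-fold fit.
        """
        if len(self.high_idx) < 2:
            raise ValueError("need at least 2 high-occupancy bins")
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x6702]))
        gp = self._fit_one(self.high_idx, rng)
        shape = self.tc.spec.shape
        mu, sd = gp.predict(self._grid_coords(), return_std=return_std)
        return GPTuningResults(
            model=self,
            mean4d=mu.reshape(shape),
            std4d=sd.reshape(shape) if sd is not None else np.full(shape, np.nan),
            fve_per_fold=np.array([]),
            splits=[],
            hyper_per_fold=[gp.hyper],
        )


@dataclass
class GPTuningResults:
    """Cross-validated GP estimate of a 4D tuning curve.

    ``mean4d``/``std4d`` are defined at all bins, visited or not, and are
    the across-fold averages of the per-fold posterior mean and standard
    deviation.  ``fve`` is the mean held-out fraction of variance
    explained.
    """

    model: GPTuningModel
    mean4d: np.ndarray
    std4d: np.ndarray
    fve_per_fold: np.ndarray
    splits: list
    hyper_per_fold: list

    @property
    def folds(self) -> list:
        """Validation folds (second element of each split)."""
        return [val for _, val in self.splits]

    @property
    def fve(self) -> float:
        return float(np.mean(self.fve_per_fold)) if len(self.fve_per_fold) else np.nan

    def summary(self) -> str:
        lines = ["GP tuning-curve model (Matérn nu=5/2, ARD)"]
        lines.append("=" * 52)
        tc = self.model.tc
        lines.append(f"cell id:              {tc.cell_id}")
        lines.append(f"high-occupancy bins:  {len(self.model.high_idx)}")
        lines.append(f"folds:                {len(self.folds)}")
        if len(self.fve_per_fold):
            per = ", ".join(f"{v:.3f}" for v in self.fve_per_fold)
            lines.append(f"FVE per fold:         {per}")
            lines.append(f"FVE (mean):           {self.fve:.3f}")
        for i, h in enumerate(self.hyper_per_fold):
            ls = ", ".join(f"{v:.2f}" for v in h.lengthscales)
            lines.append(
                f"fold {i}: lengthscales=({ls})  s2={h.signal_variance:.3f}  "
                f"sn2={h.noise_variance:.4f}"
            )
        return "\n".join(lines)

    def to_json(self, path) -> None:
        """Compact summary: hyperparameters per fold and FVE."""
        import json

        payload = {
            "cell_id": int(self.model.tc.cell_id),
            "fve": None if np.isnan(self.fve) else self.fve,
            "fve_per_fold": [float(v) for v in self.fve_per_fold],
            "hyper_per_fold": [
                {
                    "lengthscales": [float(v) for v in h.lengthscales],
                    "signal_variance": float(h.signal_variance),
                    "noise_variance": float(h.noise_variance),
                    "nu": float(h.nu),
                }
                for h in self.hyper_per_fold
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("mean4d", data=self.mean4d)
            f.create_dataset("std4d", data=self.std4d)
            f.create_dataset("fve_per_fold", data=self.fve_per_fold)
            for i, (train, val) in enumerate(self.splits):
                f.create_dataset(f"splits/{i}/train", data=train)
                f.create_dataset(f"splits/{i}/val", data=val)
            for i, h in enumerate(self.hyper_per_fold):
                g = f.create_group(f"hyper/{i}")
                g.create_dataset("lengthscales", data=h.lengthscales)
                g.attrs["signal_variance"] = h.signal_variance
                g.attrs["noise_variance"] = h.noise_variance
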