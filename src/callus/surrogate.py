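"""Gaussian-process surrogate with squared-exponential (Gaussian) covariance.

:class:`GPSurrogate` is a scikit-learn style estimator wrapping a GP
regression with an anisotropic squared-exponential kernel (one lengthscale
per factor), a signal-variance amplitude and a nugget.  Inputs are scaled to
the unit box defined by the factor ranges before fitting and the response is
standardized, so the fitted ARD lengthscales are comparable across factors.
Hyperparameters are chosen by marginal-likelihood maximization with seeded
multi-start.

Diagnostics follow emulator practice: leave-one-out (LOO) predictions at
fixed hyperparameters via the closed-form identities
``mu_i = y_i - [K^-1 y]_i / [K^-1]_ii``, compared against the 45-degree line
to flag responses the surrogate does not capture.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.utils.validation import check_is_fitted


class GPSurrogate(RegressorMixin, BaseEstimator):
    """GP regression surrogate over a box-bounded factor space.

    Parameters
    ----------
    ranges : sequence of (lo, hi) or None
        Factor ranges used to scale inputs to the unit box.  If None, the
        ranges are taken from the training data.
    n_restarts : int
        Multi-start count for hyperparameter optimization.
    nugget_floor_rel : float
        Lower bound of the white-noise variance, relative to the response
        variance.
    random_state : int
        Seed for the multi-start optimizer (refits are deterministic).

    Attributes
    ----------
    gp_ : fitted :class:`GaussianProcessRegressor`
    ranges_ : array (d, 2), the box used for scaling
    lengthscales_ : array (d,), fitted ARD lengthscales (unit-box units)
    y_mean_, y_std_ : response standardization
    constant_fit_ : True when the response was (numerically) constant
    """

    def __init__(self, ranges=None, n_restarts: int = 8,
                 nugget_floor_rel: float = 1e-8, random_state: int = 0):
        self.ranges = ranges
        self.n_restarts = n_restarts
        self.nugget_floor_rel = nugget_floor_rel
        self.random_state = random_state

    # -- scaling -----------------------------------------------------------
    def _to_unit(self, X: np.ndarray) -> np.ndarray:
        lo, hi = self.ranges_[:, 0], self.ranges_[:, 1]
        span = np.where(hi > lo, hi - lo, 1.0)
        return (X - lo) / span

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, float).ravel()
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one row per response value")
        if len(y) < 2:
            raise ValueError("need at least two training rows")
        if not np.all(np.isfinite(y)):
            raise ValueError("response contains non-finite values")
        if self.ranges is not None:
            self.ranges_ = np.asarray(self.ranges, float)
        else:
            self.ranges_ = np.column_stack([X.min(axis=0), X.max(axis=0)])
        self.n_features_in_ = X.shape[1]
        U = self._to_unit(X)

        self.y_mean_ = float(y.mean())
        y_std = float(y.std())
        self.constant_fit_ = y_std < 1e-12 * max(1.0, abs(self.y_mean_)) or y_std == 0.0
        if self.constant_fit_:
            self.y_std_ = 1.0
            self.gp_ = None
            self.X_train_ = U
            self.y_train_ = y
            self.lengthscales_ = np.full(self.n_features_in_, np.inf)
            return self
        self.y_std_ = y_std
        ys = (y - self.y_mean_) / y_std

        d = self.n_features_in_
        nugget_floor = max(self.nugget_floor_rel, 1e-12)
        kernel = (ConstantKernel(1.0, (1e-3, 1e3))
                  * RBF(np.full(d, 0.5), (1e-2, 1e2))
                  + WhiteKernel(1e-4, (nugget_floor, 1e1)))
        self.gp_ = GaussianProcessRegressor(
            kernel=kernel, n_restarts_optimizer=self.n_restarts,
            normalize_y=False, random_state=self.random_state)
        with warnings.catch_warnings():
            # inert factors drive their ARD lengthscale to the upper bound;
            # that is the expected fit, not a failure
            warnings.simplefilter("ignore", ConvergenceWarning)
            self.gp_.fit(U, ys)
        k1 = self.gp_.kernel_.k1
        self.lengthscales_ = np.atleast_1d(np.asarray(k1.k2.length_scale, float))
        if self.lengthscales_.size == 1:
            self.lengthscales_ = np.full(d, float(self.lengthscales_[0]))
        self.signal_variance_ = float(k1.k1.constant_value)
        self.nugget_ = float(self.gp_.kernel_.k2.noise_level)
        self.X_train_ = U
        self.y_train_ = y
        return self

    def predict(self, X, return_std: bool = False):
        check_is_fitted(self, "X_train_")
        X = np.asarray(X, float)
        U = self._to_unit(X)
        if self.constant_fit_:
            mu = np.full(len(U), self.y_mean_)
            return (mu, np.zeros(len(U))) if return_std else mu
        if return_std:
            mu, sd = self.gp_.predict(U, return_std=True)
            return self.y_mean_ + self.y_std_ * mu, self.y_std_ * sd
        return self.y_mean_ + self.y_std_ * self.gp_.predict(U)

    # -- diagnostics -------------------------------------------------------
    def loo_predictions(self) -> np.ndarray:
        """Leave-one-out posterior means at fixed hyperparameters."""
        check_is_fitted(self, "X_train_")
        if self.constant_fit_:
            return np.full(len(self.y_train_), self.y_mean_)
        K = self.gp_.kernel_(self.X_train_)
        # same diagonal regularization the regression itself applies
        Kinv = np.linalg.inv(K + self.gp_.alpha * np.eye(len(K)))
        ys = (self.y_train_ - self.y_mean_) / self.y_std_
        alpha = Kinv @ ys
        loo = ys - alpha / np.diag(Kinv)
        return self.y_mean_ + self.y_std_ * loo


def fit_gp(design: np.ndarray, response: np.ndarray, ranges=None,
           seed: int = 0, n_restarts: int = 8) -> GPSurrogate:
    """Fit a Gaussian-covariance GP surrogate to one response column.

    Rows with non-finite response (failed runs) are dropped; at least 10
    valid rows are required.
    """
    design = np.asarray(design, float)
    response = np.asarray(response, float).ravel()
    ok = np.isfinite(response)
    if ok.sum() < 10:
        raise ValueError(f"need >= 10 valid rows, got {int(ok.sum())}")
    return GPSurrogate(ranges=ranges, n_restarts=n_restarts,
                       random_state=seed).fit(design[ok], response[ok])


def actual_vs_predicted(gp: GPSurrogate, band: float = 0.1) -> dict:
    """Actual-vs-predicted diagnostic from LOO predictions.

    Returns the paired (actual, predicted) arrays, the LOO RMSE, the share of
    points whose prediction falls within ``band`` * response range of the
    45-degree line, and a ``poor_fit`` flag (share below one half) used to
    exclude responses the surrogate does not capture.
    """
    actual = gp.y_train_
    predicted = gp.loo_predictions()
    resid = actual - predicted
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    span = float(actual.max() - actual.min()) or 1.0
    within = float(np.mean(np.abs(resid) <= band * span))
    return {"actual": actual, "predicted": predicted, "rmse": rmse,
            "share_within_band": within, "poor_fit": within < 0.5}
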