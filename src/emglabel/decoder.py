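"""Gaussian-process velocity decoding.

One GP regressor per degree of freedom maps a 32-element TD feature frame to
a signed proportional velocity command in [-1, 1].  The kernel is a squared
exponential with an observation-noise term; hyperparameters are set by
marginal-likelihood ascent.  Features are standardized over the training
rows, and training sets beyond a row budget are uniformly subsampled to keep
the cubic GP cost tractable.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.preprocessing import StandardScaler
from sklearn.utils import check_random_state
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = ["VelocityCommand", "GPVelocityDecoder", "train_decoder",
           "predict_velocity"]


class VelocityCommand(NamedTuple):
    vx: float
    vy: float


class _MeanModel:
    """Degenerate per-DoF model used when the labels are constant."""

    def __init__(self, mean: float):
        self.mean = float(mean)

    def predict(self, X):
        return np.full(np.asarray(X).shape[0], self.mean)


class GPVelocityDecoder(RegressorMixin, BaseEstimator):
    """Per-DoF Gaussian-process regression from feature frames to velocities.

    Parameters
    ----------
    budget : int
        Maximum training rows per DoF; larger sets are uniformly subsampled.
    length_scale, noise_level : float
        Initial RBF length scale (on standardized features) and white-noise
        variance; both optimized unless ``optimize=False``.
    optimize : bool
        Maximize the log marginal likelihood over the kernel hyperparameters.
    n_restarts : int
        Extra random restarts of the hyperparameter optimizer.
    random_state : int | Generator | None
        Controls subsampling and optimizer restarts.

    Attributes
    ----------
    models_ : list of fitted per-DoF regressors (x then y).
    scaler_ : fitted feature standardizer.
    n_features_in_ : number of feature columns seen during fit.
    """

    def __init__(self, budget: int = 2000, length_scale: float = 3.0,
                 noise_level: float = 1e-2, optimize: bool = True,
                 n_restarts: int = 0, random_state=None):
        self.budget = budget
        self.length_scale = length_scale
        self.noise_level = noise_level
        self.optimize = optimize
        self.n_restarts = n_restarts
        self.random_state = random_state

    def _kernel(self):
        return (ConstantKernel(1.0, (1e-3, 1e3))
                * RBF(self.length_scale, (1e-2, 1e4))
                + WhiteKernel(self.noise_level, (1e-8, 1e1)))

    def fit(self, X, y) -> "GPVelocityDecoder":
        X = check_array(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y row counts differ")
        if not np.all(np.isfinite(y)):
            raise ValueError("labels must be finite")
        if np.any(np.abs(y) > 1 + 1e-9):
            raise ValueError("labels must lie in [-1, 1]")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 training rows")

        rng = check_random_state(self.random_state)
        if X.shape[0] > self.budget:
            pick = np.sort(rng.choice(X.shape[0], self.budget, replace=False))
            X, y = X[pick], y[pick]

        self.scaler_ = StandardScaler().fit(X)
        Xs = self.scaler_.transform(X)
        self.models_ = []
        for dof in range(y.shape[1]):
            col = y[:, dof]
            if np.ptp(col) == 0.0:
                warnings.warn(
                    f"constant labels on DoF {dof}; fitting mean-only model",
                    UserWarning, stacklevel=2)
                self.models_.append(_MeanModel(col[0]))
                continue
            gp = GaussianProcessRegressor(
                kernel=self._kernel(),
                optimizer="fmin_l_bfgs_b" if self.optimize else None,
                n_restarts_optimizer=self.n_restarts,
                normalize_y=False,
                random_state=rng.randint(2**31 - 1),
            )
            gp.fit(Xs, col)
            self.models_.append(gp)
        self.n_features_in_ = X.shape[1]
        self.n_dofs_ = y.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        """Posterior-mean velocity per DoF, clipped to [-1, 1]."""
        check_is_fitted(self, "models_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}")
        Xs = self.scaler_.transform(X)
        out = np.column_stack([m.predict(Xs) for m in self.models_])
        return np.clip(out, -1.0, 1.0)

    def predict_command(self, frame) -> VelocityCommand:
        """Velocity command for a single feature frame."""
        frame = np.asarray(frame, dtype=float).ravel()
        v = self.predict(frame[None, :])[0]
        vx = float(v[0])
        vy = float(v[1]) if self.n_dofs_ > 1 else 0.0
        return VelocityCommand(vx, vy)


def train_decoder(X, y_x, y_y, **params) -> GPVelocityDecoder:
    """Fit a two-DoF decoder from feature rows and per-DoF label columns."""
    Y = np.column_stack([np.asarray(y_x, float), np.asarray(y_y, float)])
    return GPVelocityDecoder(**params).fit(X, Y)


def predict_velocity(model: GPVelocityDecoder, frame) -> VelocityCommand:
    return model.predict_command(frame)
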