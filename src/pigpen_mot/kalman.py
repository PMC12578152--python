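"""Constant-velocity Kalman filter over box state (cx, cy, a, h).

The 8-dimensional state carries the box center, aspect ratio a = w/h,
height, and their velocities; the transition is a single Euler step per
frame (dt = 1).  Process and measurement noise follow the de-facto
DeepSORT convention: standard deviations proportional to the box height
with position weight 1/20 and velocity weight 1/160, which makes the
filter scale-free across near/far animals in the pen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = ["KalmanState", "KalmanFilter", "CHI2_95_4DOF"]

# 0.95 quantile of chi-square with 4 degrees of freedom, used for gating
CHI2_95_4DOF = 9.487729036781154

_STD_WEIGHT_POSITION = 1.0 / 20.0
_STD_WEIGHT_VELOCITY = 1.0 / 160.0


@dataclass
class KalmanState:
    """Gaussian state estimate: 8-vector mean and 8x8 covariance."""

    mean: np.ndarray
    covariance: np.ndarray


class KalmanFilter:
    """Shared-dynamics filter applied to every track."""

    def __init__(self) -> None:
        self._F = np.eye(8)
        self._F[:4, 4:] = np.eye(4)
        self._H = np.eye(4, 8)

    def initiate(self, measurement: np.ndarray) -> KalmanState:
        """New state from a first measurement (cx, cy, a, h); zero velocity."""
        z = np.asarray(measurement, dtype=float)
        mean = np.concatenate([z, np.zeros(4)])
        h = z[3]
        std = np.array([
            2 * _STD_WEIGHT_POSITION * h,
            2 * _STD_WEIGHT_POSITION * h,
            1e-2,
            2 * _STD_WEIGHT_POSITION * h,
            10 * _STD_WEIGHT_VELOCITY * h,
            10 * _STD_WEIGHT_VELOCITY * h,
            1e-5,
            10 * _STD_WEIGHT_VELOCITY * h,
        ])
        return KalmanState(mean, np.diag(std**2))

    def predict(self, state: KalmanState) -> KalmanState:
        """One-frame time update; additive PSD process noise."""
        h = state.mean[3]
        std = np.array([
            _STD_WEIGHT_POSITION * h,
            _STD_WEIGHT_POSITION * h,
            1e-2,
            _STD_WEIGHT_POSITION * h,
            _STD_WEIGHT_VELOCITY * h,
            _STD_WEIGHT_VELOCITY * h,
            1e-5,
            _STD_WEIGHT_VELOCITY * h,
        ])
        mean = self._F @ state.mean
        cov = self._F @ state.covariance @ self._F.T + np.diag(std**2)
        return KalmanState(mean, cov)

    def _innovation_cov(self, state: KalmanState) -> tuple[np.ndarray, np.ndarray]:
        h = state.mean[3]
        std = np.array([
            _STD_WEIGHT_POSITION * h,
            _STD_WEIGHT_POSITION * h,
            1e-1,
            _STD_WEIGHT_POSITION * h,
        ])
        projected_mean = self._H @ state.mean
        s = self._H @ state.covariance @ self._H.T + np.diag(std**2)
        return projected_mean, s

    def update(self, state: KalmanState, measurement: np.ndarray) -> KalmanState:
        """Measurement update with z = (cx, cy, a, h)."""
        z = np.asarray(measurement, dtype=float)
        projected_mean, s = self._innovation_cov(state)
        chol, lower = scipy.linalg.cho_factor(s, lower=True, check_finite=False)
        gain = scipy.linalg.cho_solve(
            (chol, lower), (state.covariance @ self._H.T).T, check_finite=False
        ).T
        mean = state.mean + gain @ (z - projected_mean)
        cov = state.covariance - gain @ s @ gain.T
        # symmetrize to keep round-off from breaking PSD over long runs
        cov = (cov + cov.T) / 2.0
        return KalmanState(mean, cov)

    def gating_distance(self, state: KalmanState, measurements: np.ndarray) -> np.ndarray:
        """Squared Mahalanobis distance of measurements (N x 4) to the prediction."""
        z = np.atleast_2d(np.asarray(measurements, dtype=float))
        projected_mean, s = self._innovation_cov(state)
        chol = np.linalg.cholesky(s)
        d = z - projected_mean
        y = scipy.linalg.solve_triangular(chol, d.T, lower=True, check_finite=False)
        return np.sum(y * y, axis=0)
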