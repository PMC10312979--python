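"""Gaussian belief propagation for the group cessation rates.

The rates follow a zero-mean random walk; rather than specifying a process
noise covariance directly, the prior covariance for the next year is the
posterior covariance inflated by a forgetting factor lambda in (0, 1]
(prior = posterior / lambda, i.e. Q = (1/lambda - 1) * posterior).  The
measurement update is a second-order Central Difference Kalman Filter
(Stirling-interpolation sigma points at mean +/- h * columns of a covariance
square root), which needs no Jacobian of the model-to-prevalence map and
reduces exactly to the linear Kalman filter when the map is affine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.linalg

logger = logging.getLogger(__name__)

DEFAULT_CDKF_H = float(np.sqrt(3.0))  # optimal step for Gaussian priors


class ConfigError(ValueError):
    pass


class NumericError(ArithmeticError):
    pass


@dataclass(frozen=True)
class ParamBelief:
    """Gaussian belief over the group cessation rates for one year."""

    mean: np.ndarray
    cov: np.ndarray
    year: int | None = None

    def __post_init__(self) -> None:
        m = np.atleast_1d(np.asarray(self.mean, dtype=float))
        P = np.atleast_2d(np.asarray(self.cov, dtype=float))
        object.__setattr__(self, "mean", m)
        object.__setattr__(self, "cov", P)
        if not np.all(np.isfinite(m)):
            raise NumericError(f"belief mean not finite: {m}")
        if P.shape != (m.size, m.size):
            raise ConfigError(f"cov shape {P.shape} does not match mean size {m.size}")
        if not np.allclose(P, P.T, atol=1e-8):
            raise NumericError("belief covariance is not symmetric")
        if np.linalg.eigvalsh(P).min() < -1e-10:
            raise NumericError("belief covariance is not PSD within tolerance")

    @property
    def sd(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))


@dataclass(frozen=True)
class MeasurementSpec:
    """One year's grouped-prevalence observation and the pure map from a
    candidate rate vector to the model-predicted prevalence vector."""

    observation: np.ndarray
    noise_sd: np.ndarray
    measurement_fn: Callable[[np.ndarray], np.ndarray]

    def __post_init__(self) -> None:
        y = np.atleast_1d(np.asarray(self.observation, dtype=float))
        s = np.atleast_1d(np.asarray(self.noise_sd, dtype=float))
        object.__setattr__(self, "observation", y)
        object.__setattr__(self, "noise_sd", s)
        if np.any(s <= 0):
            raise ConfigError(f"noise SDs must be > 0; got {s}")
        if y.shape != s.shape:
            raise ConfigError("observation and noise_sd shapes differ")


@dataclass(frozen=True)
class FilterConfig:
    """Tunables of the annual predict-update cycle.

    forgetting_lambda: covariance inflation per year; 1 = no forgetting.
    cdkf_step_h: sigma-point half-width; sqrt(3) is optimal for Gaussians.
    prior_mean / prior_sd: diagonal Gaussian prior for the first year.
    param_space: "natural" filters the rates directly (sigma points clipped
        to [0, 1] before evaluation); "logit" filters log-odds instead.
    """

    forgetting_lambda: float = 0.98
    cdkf_step_h: float = DEFAULT_CDKF_H
    prior_mean: tuple[float, ...] = (0.04, 0.04, 0.04)
    prior_sd: tuple[float, ...] = (0.02, 0.02, 0.02)
    clip_bounds: tuple[float, float] = (0.0, 1.0)
    param_space: str = "natural"

    def __post_init__(self) -> None:
        if not (0.0 < self.forgetting_lambda <= 1.0):
            raise ConfigError(
                f"forgetting_lambda must be in (0, 1]; got {self.forgetting_lambda}"
            )
        if self.cdkf_step_h <= 0:
            raise ConfigError(f"cdkf_step_h must be > 0; got {self.cdkf_step_h}")
        if self.param_space not in ("natural", "logit"):
            raise ConfigError(f"param_space must be natural|logit; got {self.param_space}")
        if any(s <= 0 for s in self.prior_sd):
            raise ConfigError("prior SDs must be > 0")

    def initial_belief(self, year: int | None = None) -> ParamBelief:
        return ParamBelief(
            mean=np.asarray(self.prior_mean, dtype=float),
            cov=np.diag(np.square(self.prior_sd)),
            year=year,
        )


def matrix_sqrt(cov: np.ndarray) -> np.ndarray:
    """Lower-triangular L with L @ L.T == cov (Cholesky, jitter fallback)."""
    P = np.atleast_2d(np.asarray(cov, dtype=float))
    P = 0.5 * (P + P.T)
    scale = max(np.trace(P) / P.shape[0], 1e-300)
    for jitter in (0.0, 1e-14, 1e-12, 1e-10, 1e-8):
        try:
            L = scipy.linalg.cholesky(P + jitter * scale * np.eye(P.shape[0]), lower=True)
            if jitter:
                logger.warning("matrix_sqrt: Cholesky needed jitter %.1e", jitter * scale)
            return L
        except scipy.linalg.LinAlgError:
            continue
    raise NumericError("covariance is indefinite beyond repair tolerance")


def make_psd(P: np.ndarray, tol: float = 0.0) -> np.ndarray:
    """Re-symmetrize and clip negative eigenvalues at zero (repairs logged)."""
    P = 0.5 * (P + P.T)
    vals, vecs = np.linalg.eigh(P)
    if vals.min() < tol:
        logger.warning("PSD repair: clipping eigenvalue %.3e at 0", vals.min())
        vals = np.clip(vals, 0.0, None)
        P = (vecs * vals) @ vecs.T
        P = 0.5 * (P + P.T)
    return P


def predict_params(posterior: ParamBelief, forgetting_lambda: float) -> ParamBelief:
    """Random-walk predict: mean unchanged, covariance inflated by 1/lambda,
    year advanced by one."""
    if not (0.0 < forgetting_lambda <= 1.0):
        raise ConfigError(
            f"forgetting factor must be in (0, 1]; got {forgetting_lambda}"
        )
    return ParamBelief(
        mean=posterior.mean.copy(),
        cov=posterior.cov / forgetting_lambda,
        year=None if posterior.year is None else posterior.year + 1,
    )


def cdkf_update(
    prior: ParamBelief,
    spec: MeasurementSpec,
    h: float = DEFAULT_CDKF_H,
    clip_bounds: tuple[float, float] | None = None,
) -> ParamBelief:
    """Central-difference measurement update of a Gaussian belief.

    Evaluates the measurement map at the prior mean and at mean +/- h * L_i
    (L a covariance square root), forms the second-order predicted-measurement
    mean, its covariance plus diagonal observation noise, and the state-
    measurement cross covariance, then applies the Kalman gain.  Sigma points
    are clipped to ``clip_bounds`` before evaluation when bounds are given
    (the rates live in [0, 1]); clips are logged.
    """
    if h <= 0:
        raise ConfigError(f"cdkf step h must be > 0; got {h}")
    x = prior.mean
    n = x.size
    h2 = h * h
    L = matrix_sqrt(prior.cov)

    def evaluate(point: np.ndarray, tag: str) -> np.ndarray:
        p = point
        if clip_bounds is not None:
            clipped = np.clip(point, *clip_bounds)
            if not np.array_equal(clipped, point):
                logger.warning("sigma point %s clipped to %s", tag, clip_bounds)
            p = clipped
        y = np.atleast_1d(np.asarray(spec.measurement_fn(p), dtype=float))
        if not np.all(np.isfinite(y)):
            raise NumericError(f"measurement_fn returned non-finite values at sigma point {tag}")
        return y

    y0 = evaluate(x, "mean")
    m = y0.size
    y_plus = np.empty((n, m))
    y_minus = np.empty((n, m))
    for i in range(n):
        y_plus[i] = evaluate(x + h * L[:, i], f"+{i}")
        y_minus[i] = evaluate(x - h * L[:, i], f"-{i}")

    # Stirling second-order statistics of the pushforward
    y_hat = ((h2 - n) / h2) * y0 + (y_plus + y_minus).sum(axis=0) / (2.0 * h2)
    d1 = (y_plus - y_minus) / (2.0 * h)  # first-order divided differences
    d2 = (y_plus + y_minus - 2.0 * y0) * (np.sqrt(h2 - 1.0) / (2.0 * h2))
    R = np.diag(np.square(spec.noise_sd))
    Pyy = d1.T @ d1 + d2.T @ d2 + R
    Pxy = L @ d1  # (n, m): h * L_i * (y+ - y-)/(2h)

    K = np.linalg.solve(Pyy, Pxy.T).T
    innovation = spec.observation - y_hat
    mean_post = x + K @ innovation
    cov_post = make_psd(prior.cov - K @ Pyy @ K.T)
    logger.debug(
        "cdkf_update year=%s |innov|=%.3e |K|=%.3e",
        prior.year,
        np.linalg.norm(innovation),
        np.linalg.norm(K),
    )
    return ParamBelief(mean=mean_post, cov=cov_post, year=prior.year)


# --- logit-space helpers (optional filtering space) ------------------------


def logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(np.asarray(p, dtype=float), 1e-12, 1.0 - 1e-12)
    return np.log(p / (1.0 - p))


def expit(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))
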