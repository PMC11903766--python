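"""Variance-preserving noise schedules and the forward/reverse diffusion
operations over pharmacophore clouds.

The latent state is the pair (coords, feats): continuous 3D coordinates plus
a continuous relaxation of the one-hot category matrix.  The noising process
is

    q(z_t | z_0) = N(z_t | alpha_t z_0, sigma_t^2 I),    alpha_t^2 + sigma_t^2 = 1

and the exact denoising transition from t to s < t is Gaussian with

    mean = (alpha_{t|s} sigma_s^2 / sigma_t^2) z_t
         + (alpha_s sigma_{t|s}^2 / sigma_t^2) z_0
    var  = sigma_{t|s}^2 sigma_s^2 / sigma_t^2

where alpha_{t|s} = alpha_t / alpha_s and sigma_{t|s}^2 = sigma_t^2 -
alpha_{t|s}^2 sigma_s^2.  A noise predictor supplies eps_hat, from which the
clean-state estimate is z0_hat = z_t / alpha_t - (sigma_t / alpha_t) eps_hat.

Translations are handled by expressing all coordinates in a frame anchored on
the pocket centroid (the pocket is fixed, noise-free context); the ligand
cloud's center of mass is then an ordinary diffused coordinate.  Projecting
ligand noise onto the zero-CoM subspace instead would make the translational
component of the chain noise-free and hence unlearnable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NoiseSchedule",
    "DiffusionState",
    "build_schedule",
    "forward_noise",
    "predict_clean",
    "posterior_step",
    "posterior_coefficients",
    "project_zero_com",
]


@dataclass(frozen=True)
class NoiseSchedule:
    """alpha/sigma arrays indexed by t = 0..T (alpha[0] ~ 1, alpha[T] ~ 0)."""

    T: int
    alpha: np.ndarray
    sigma: np.ndarray
    kind: str

    def alpha_ts(self, t: int, s: int) -> float:
        return float(self.alpha[t] / self.alpha[s])

    def sigma2_ts(self, t: int, s: int) -> float:
        return float(self.sigma[t] ** 2 - self.alpha_ts(t, s) ** 2 * self.sigma[s] ** 2)


@dataclass
class DiffusionState:
    """Noisy latent: (N, 3) coordinates in Å and (N, 8) continuous features."""

    coords: np.ndarray
    feats: np.ndarray
    t: int = 0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.feats = np.asarray(self.feats, dtype=np.float64)
        if self.coords.shape[0] != self.feats.shape[0]:
            raise ValueError("coords and feats must have the same number of rows")


def build_schedule(T: int = 500, kind: str = "polynomial") -> NoiseSchedule:
    """Construct a variance-preserving schedule with alpha_t^2 + sigma_t^2 = 1.

    "polynomial": alpha_t = (1 - (t/T)^2)(1 - 2s) + s with s = 1e-4 — the
    quadratic decay used in the equivariant-diffusion lineage.  "cosine":
    alpha_t = cos(pi/2 * (t/T + s)/(1 + s)) with s = 8e-3, clipped away from 0.
    """
    if T < 2:
        raise ValueError(f"schedule needs T >= 2, got {T}")
    t = np.arange(T + 1, dtype=np.float64) / T
    if kind == "polynomial":
        eps = 1e-4
        alpha = (1.0 - t**2) * (1.0 - 2.0 * eps) + eps
    elif kind == "cosine":
        s = 8e-3
        alpha = np.cos(0.5 * np.pi * (t + s) / (1.0 + s))
        alpha = np.clip(alpha, 1e-4, 1.0 - 1e-6)
    else:
        raise ValueError(f"unknown schedule kind {kind!r}")
    sigma = np.sqrt(1.0 - alpha**2)
    return NoiseSchedule(T=T, alpha=alpha, sigma=sigma, kind=kind)


def project_zero_com(coords: np.ndarray) -> np.ndarray:
    """Remove the mean (center of mass) from a coordinate array."""
    return coords - coords.mean(axis=0, keepdims=True)


def forward_noise(z0: DiffusionState, t: int, eps: DiffusionState,
                  schedule: NoiseSchedule) -> DiffusionState:
    """q(z_t | z_0): returns alpha_t z_0 + sigma_t eps exactly."""
    if eps.coords.shape != z0.coords.shape or eps.feats.shape != z0.feats.shape:
        raise ValueError("noise shape does not match the clean state")
    a, s = schedule.alpha[t], schedule.sigma[t]
    return DiffusionState(a * z0.coords + s * eps.coords,
                          a * z0.feats + s * eps.feats, t=t)


def predict_clean(z_t: DiffusionState, eps_hat: DiffusionState,
                  schedule: NoiseSchedule, t: int) -> DiffusionState:
    """z0_hat = z_t / alpha_t - (sigma_t / alpha_t) eps_hat."""
    a = float(schedule.alpha[t])
    if a <= 0.0:
        raise ZeroDivisionError(
            f"alpha_{t} = 0: the clean-state estimate is undefined at this step"
        )
    s = float(schedule.sigma[t])
    return DiffusionState(z_t.coords / a - (s / a) * eps_hat.coords,
                          z_t.feats / a - (s / a) * eps_hat.feats, t=0)


def posterior_coefficients(schedule: NoiseSchedule, t: int, s: int
                           ) -> tuple[float, float, float]:
    """(coefficient of z_t, coefficient of z0_hat, variance) of the
    denoising transition t -> s."""
    if not 0 <= s < t <= schedule.T:
        raise ValueError(f"need 0 <= s < t <= T, got s={s}, t={t}")
    a_ts = schedule.alpha_ts(t, s)
    s2_ts = schedule.sigma2_ts(t, s)
    s2_t = float(schedule.sigma[t]) ** 2
    s2_s = float(schedule.sigma[s]) ** 2
    c_zt = a_ts * s2_s / s2_t
    c_z0 = float(schedule.alpha[s]) * s2_ts / s2_t
    var = s2_ts * s2_s / s2_t
    return c_zt, c_z0, var


def posterior_step(z_t: DiffusionState, z0_hat: DiffusionState, t: int, s: int,
                   schedule: NoiseSchedule, rng: np.random.Generator,
                   noise: tuple[np.ndarray, np.ndarray] | None = None
                   ) -> DiffusionState:
    """Sample z_s from the denoising transition q(z_s | z0_hat, z_t).

    `noise` lets callers inject the standard-normal draws (coords, feats)
    explicitly, e.g. for equivariance checks.
    """
    c_zt, c_z0, var = posterior_coefficients(schedule, t, s)
    std = float(np.sqrt(var))
    if noise is None:
        n_coords = rng.standard_normal(z_t.coords.shape)
        n_feats = rng.standard_normal(z_t.feats.shape)
    else:
        n_coords, n_feats = noise
    n_coords = np.asarray(n_coords, dtype=np.float64)
    coords = c_zt * z_t.coords + c_z0 * z0_hat.coords + std * n_coords
    feats = c_zt * z_t.feats + c_z0 * z0_hat.feats + std * np.asarray(n_feats)
    return DiffusionState(coords, feats, t=s)
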