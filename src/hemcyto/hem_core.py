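"""Heterogeneous mixture EM for low-magnification spot photometry.

A detected bright spot is modelled as a mixture of N bivariate Gaussian
components (one per cell) plus one uniform component for the local
background.  The EM is intensity-weighted: responsibilities are computed
once per pixel and every M-step sum weights each pixel's contribution by
its photon count I(x), which is equivalent to (and far cheaper than)
treating each photon as an independent observation.

Model, with x ranging over pixel-center positions of the patch:

    f_c(x) = N(x | mu_c, Sigma_c)                 c = 1..N   (cells)
    f_{N+1}(x) = 1 / (width * height)                        (background)
    z_c(x) = pi_c f_c(x) / sum_n pi_n f_n(x)                 (E-step)

M-step (intensity-weighted):

    pi_c    = sum_x z_c(x) I(x) / sum_x I(x)
    mu_c    = sum_x z_c(x) I(x) x / sum_x z_c(x) I(x)
    Sigma_c = sum_x z_c(x) I(x) (x - mu_c)(x - mu_c)' / sum_x z_c(x) I(x)

The objective is the intensity-weighted log-likelihood
L = sum_x I(x) ln( sum_c pi_c f_c(x) ), which is non-decreasing over
iterations.  After convergence, per-cell fluorescence is the
responsibility-weighted intensity sum F_c = sum_x z_c(x) I(x), and the
physical diameter is pixel_size * FWHM of the fitted Gaussian, using the
rotation-invariant effective spread sigma_eff = |Sigma|^(1/4).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))

#: eigenvalue floor for fitted covariances (px^2); prevents collapse onto
#: a single bright pixel before the outlier rules can run
DEFAULT_COV_FLOOR = 0.04
DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 200
#: expected cell diameter used for covariance initialization (µm)
DEFAULT_INIT_DIAMETER_UM = 10.0

_LOG_TINY = -745.0  # below this, exp() underflows to 0 in float64


@dataclass
class GaussianComponent:
    """One cell: bivariate Gaussian with mixing weight."""

    mean: np.ndarray  # (row, col), sub-pixel
    covariance: np.ndarray  # 2x2 symmetric positive definite, px^2
    weight: float

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.covariance.shape != (2, 2):
            raise ValueError("covariance must be 2x2")

    def eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvalsh(self.covariance)

    @property
    def sigma_eff_px(self) -> float:
        """Geometric mean of the principal standard deviations."""
        det = float(np.linalg.det(self.covariance))
        return det ** 0.25 if det > 0 else 0.0


@dataclass
class BackgroundComponent:
    """Uniform background over the patch (or frame) domain."""

    weight: float
    domain_height: float
    domain_width: float

    @property
    def density(self) -> float:
        return 1.0 / (self.domain_width * self.domain_height)


@dataclass
class MixtureFit:
    components: list[GaussianComponent]
    background: BackgroundComponent
    log_likelihood_trace: list[float] = field(default_factory=list)
    converged: bool = False
    n_iterations: int = 0

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components] + [self.background.weight])

    def copy(self) -> "MixtureFit":
        return MixtureFit(
            components=[
                GaussianComponent(c.mean.copy(), c.covariance.copy(), c.weight)
                for c in self.components
            ],
            background=BackgroundComponent(
                self.background.weight, self.background.domain_height, self.background.domain_width
            ),
            log_likelihood_trace=list(self.log_likelihood_trace),
            converged=self.converged,
            n_iterations=self.n_iterations,
        )


@dataclass
class CellMeasurement:
    """Per-cell output record."""

    location: tuple[float, float]
    fluorescence: float
    diameter_um: float
    sigma_eff_px: float
    qc_status: str = "valid"


def gaussian_density(x: np.ndarray, mean: np.ndarray, covariance: np.ndarray) -> np.ndarray:
    """Bivariate normal density at positions x (shape (..., 2))."""
    return np.exp(gaussian_log_density(x, mean, covariance))


def gaussian_log_density(x: np.ndarray, mean: np.ndarray, covariance: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    mean = np.asarray(mean, dtype=float)
    a, b = covariance[0, 0], covariance[0, 1]
    c, d = covariance[1, 0], covariance[1, 1]
    det = a * d - b * c
    if det <= 0 or a <= 0 or d <= 0:
        raise ValueError("covariance must be positive definite")
    diff = x - mean
    dr, dc = diff[..., 0], diff[..., 1]
    # analytic 2x2 inverse; quadratic form of the Mahalanobis distance
    quad = (d * dr * dr - (b + c) * dr * dc + a * dc * dc) / det
    return -0.5 * quad - math.log(2.0 * math.pi) - 0.5 * math.log(det)


def uniform_density(domain_width: float, domain_height: float) -> float:
    if domain_width <= 0 or domain_height <= 0:
        raise ValueError("domain dimensions must be > 0")
    return 1.0 / (domain_width * domain_height)


def pixel_grid(shape: tuple[int, int]) -> np.ndarray:
    """(H, W, 2) array of pixel-center positions (row, col)."""
    rr, cc = np.indices(shape)
    return np.stack([rr, cc], axis=-1).astype(float)


def _component_log_densities(patch_shape: tuple[int, int], fit: MixtureFit) -> np.ndarray:
    """(n_components+1, H, W) log densities, background last."""
    grid = pixel_grid(patch_shape)
    logs = np.empty((len(fit.components) + 1,) + patch_shape)
    for i, comp in enumerate(fit.components):
        logs[i] = gaussian_log_density(grid, comp.mean, comp.covariance)
    logs[-1] = math.log(fit.background.density)
    return logs


def _weighted_log_mixture(patch_shape: tuple[int, int], fit: MixtureFit) -> np.ndarray:
    """Per-pixel ln( sum_c pi_c f_c(x) ), clamped against total underflow."""
    logs = _component_log_densities(patch_shape, fit)
    w = fit.weights
    with np.errstate(divide="ignore"):
        logw = np.where(w > 0, np.log(np.maximum(w, 1e-300)), -np.inf)
    lse = logsumexp(logs + logw[:, None, None], axis=0)
    return np.maximum(lse, _LOG_TINY)


def log_likelihood(patch: np.ndarray, fit: MixtureFit) -> float:
    """Intensity-weighted log-likelihood sum_x I(x) ln(mixture(x))."""
    patch = np.asarray(patch, dtype=float)
    return float(np.sum(patch * _weighted_log_mixture(patch.shape, fit)))


def e_step(patch: np.ndarray, fit: MixtureFit) -> np.ndarray:
    """Responsibilities z_c(x), shape (n_components+1, H, W), background last.

    Computed once per pixel; pixels where every weighted density
    underflows are assigned entirely to the background component.
    """
    patch = np.asarray(patch, dtype=float)
    logs = _component_log_densities(patch.shape, fit)
    w = fit.weights
    with np.errstate(divide="ignore"):
        logw = np.where(w > 0, np.log(np.maximum(w, 1e-300)), -np.inf)
    logz = logs + logw[:, None, None]
    norm = logsumexp(logz, axis=0)
    # every component's weighted density is zero in float64 at these pixels
    underflow = ~np.isfinite(norm) | (norm < _LOG_TINY)
    with np.errstate(invalid="ignore"):
        z = np.exp(logz - norm)
    if np.any(underflow):
        z[:, underflow] = 0.0
        z[-1, underflow] = 1.0
    return z


def _floor_covariance(cov: np.ndarray, floor: float) -> np.ndarray:
    vals, vecs = np.linalg.eigh(cov)
    vals = np.maximum(vals, floor)
    return (vecs * vals) @ vecs.T


def m_step(
    patch: np.ndarray,
    z: np.ndarray,
    fit: MixtureFit,
    cov_floor: float = DEFAULT_COV_FLOOR,
) -> MixtureFit:
    """Intensity-weighted parameter updates; returns a new MixtureFit.

    A Gaussian whose weighted responsibility mass vanishes keeps its
    location/shape but gets weight 0 (the refiner culls it).
    """
    patch = np.asarray(patch, dtype=float)
    total = float(patch.sum())
    if total <= 0:
        raise ValueError("patch must contain positive total intensity")
    grid = pixel_grid(patch.shape)
    new = fit.copy()
    wz = z * patch[None, :, :]  # z_c(x) I(x)
    masses = wz.sum(axis=(1, 2))
    for i, comp in enumerate(new.components):
        mass = masses[i]
        comp.weight = mass / total
        if mass <= 1e-12 * total:
            comp.weight = 0.0
            continue
        mu = (wz[i, :, :, None] * grid).sum(axis=(0, 1)) / mass
        diff = grid - mu
        cov = np.einsum("hw,hwi,hwj->ij", wz[i], diff, diff) / mass
        comp.mean = mu
        comp.covariance = _floor_covariance(cov, cov_floor)
    new.background.weight = masses[-1] / total
    return new


def fit_hem(
    patch: np.ndarray,
    init: MixtureFit,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    cov_floor: float = DEFAULT_COV_FLOOR,
) -> MixtureFit:
    """Run EM to convergence of the intensity-weighted log-likelihood.

    Stops when the relative likelihood change drops below tol or after
    max_iter iterations; the per-iteration trace is recorded on the
    returned fit.
    """
    patch = np.asarray(patch, dtype=float)
    if not init.components:
        raise ValueError("init must contain at least one Gaussian component")
    fit = init.copy()
    trace = [log_likelihood(patch, fit)]
    if not np.isfinite(trace[0]):
        raise FloatingPointError("non-finite initial likelihood")
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        z = e_step(patch, fit)
        fit = m_step(patch, z, fit, cov_floor=cov_floor)
        ll = log_likelihood(patch, fit)
        if not np.isfinite(ll):
            raise FloatingPointError("non-finite likelihood during EM")
        trace.append(ll)
        denom = max(abs(trace[-2]), 1.0)
        if abs(ll - trace[-2]) / denom < tol:
            converged = True
            break
    fit.log_likelihood_trace = trace
    fit.converged = converged
    fit.n_iterations = it
    return fit


def initial_fit(
    patch_shape: tuple[int, int],
    centers: Sequence[tuple[float, float]],
    pixel_size_um: float = 3.0,
    init_diameter_um: float = DEFAULT_INIT_DIAMETER_UM,
    background_weight: float = 0.5,
    background_domain: tuple[int, int] | None = None,
) -> MixtureFit:
    """Scale-matched starting point: Gaussians at the given centers with an
    isotropic covariance sized to the expected cell diameter; the Gaussians
    share (1 - background_weight) equally.

    background_domain overrides the uniform component's domain (e.g. the
    full frame in global-background mode); default is the local patch.
    """
    sigma0 = init_diameter_um / (FWHM_PER_SIGMA * pixel_size_um)
    n = len(centers)
    if n == 0:
        raise ValueError("need at least one center")
    comps = [
        GaussianComponent(
            mean=np.asarray(c, dtype=float),
            covariance=np.eye(2) * sigma0**2,
            weight=(1.0 - background_weight) / n,
        )
        for c in centers
    ]
    domain = background_domain or patch_shape
    bg = BackgroundComponent(
        weight=background_weight,
        domain_height=float(domain[0]),
        domain_width=float(domain[1]),
    )
    return MixtureFit(components=comps, background=bg)


def measure_fluorescence(fit: MixtureFit, patch: np.ndarray, c: int) -> float:
    """F_c = sum_x z_c(x) I(x) with the converged responsibilities.

    c indexes the Gaussian components; c = len(components) addresses the
    background share.
    """
    patch = np.asarray(patch, dtype=float)
    z = e_step(patch, fit)
    return float((z[c] * patch).sum())


def measure_all_fluorescences(fit: MixtureFit, patch: np.ndarray) -> np.ndarray:
    """Fluorescence of every component (background last); sums to sum I."""
    patch = np.asarray(patch, dtype=float)
    z = e_step(patch, fit)
    return (z * patch[None]).sum(axis=(1, 2))


def estimate_diameter(fit: MixtureFit, c: int, pixel_size_um: float) -> float:
    """Physical diameter: pixel size times the FWHM of the fitted Gaussian.

    For elliptical fits the effective spread is the rotation-invariant
    |Sigma|^(1/4), the geometric mean of the principal standard
    deviations; FWHM = 2 sqrt(2 ln 2) sigma_eff.
    """
    comp = fit.components[c]
    det = float(np.linalg.det(comp.covariance))
    if det <= 0:
        raise ValueError("degenerate covariance")
    return pixel_size_um * FWHM_PER_SIGMA * det**0.25
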