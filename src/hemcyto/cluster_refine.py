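"""Outlier rejection and BIC-controlled recursive cluster splitting.

White blood cells and small cell clusters obey shape and size
constraints, so a fitted Gaussian can be vetted purely from its
covariance.  Three rejection rules apply: a component too small to cover
a single pixel (3 sigma < 1 px), one larger than any plausible cell
cluster, and a degenerate (near-singular) covariance.

Sliding-window detection often returns one event for a doublet or
triplet.  The splitter resolves these deterministically: the component
with the largest covariance eigenvalue is split along its leading
eigenvector, offset by sqrt(lambda_max) on each side (the exact
decomposition when one Gaussian has absorbed two equal spots), the
mixture is refit, and the split is kept only if the Bayesian information
criterion improves by more than a configurable threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .hem_core import (
    DEFAULT_COV_FLOOR,
    DEFAULT_MAX_ITER,
    DEFAULT_TOL,
    GaussianComponent,
    MixtureFit,
    fit_hem,
    log_likelihood,
)

#: default BIC improvement required to accept a split (strong-evidence gap)
DEFAULT_BIC_DROP = 10.0
#: free parameters per Gaussian: 2 mean + 3 covariance + 1 weight (the
#: sum-to-one constraint absorbs the parameter-free background's weight)
PARAMS_PER_GAUSSIAN = 6


def default_footprint_bound_px2(pixel_size_um: float = 3.0, max_cell_diameter_um: float = 20.0) -> float:
    """Area bound (px^2) on the 3-sigma ellipse: anything larger than a
    compact cluster of more than three maximal cells (four-cell area) is
    the fitter latching onto background, not a cell event."""
    cell_area_um2 = math.pi * (max_cell_diameter_um / 2.0) ** 2
    return 4.0 * cell_area_um2 / pixel_size_um**2


@dataclass(frozen=True)
class QcLimits:
    min_three_sigma: float = 1.0  # px; 3*sigma_min below this cannot cover a pixel
    max_footprint_px2: float = field(default_factory=default_footprint_bound_px2)
    max_condition_number: float = 100.0
    min_eigenvalue: float = DEFAULT_COV_FLOOR  # px^2

    @classmethod
    def for_pixel_size(cls, pixel_size_um: float, max_cell_diameter_um: float = 20.0) -> "QcLimits":
        return cls(max_footprint_px2=default_footprint_bound_px2(pixel_size_um, max_cell_diameter_um))


@dataclass(frozen=True)
class SplitDecision:
    parent_index: int
    child_means: tuple[np.ndarray, np.ndarray]
    direction: np.ndarray  # unit vector, leading eigenvector
    magnitude: float  # px, sqrt(largest eigenvalue)
    delta_bic: float | None = None


def validate_component(g: GaussianComponent, limits: QcLimits) -> str:
    """Returns 'valid' or 'rejected(reason)' per the three covariance rules."""
    vals = np.linalg.eigvalsh(g.covariance)
    lo, hi = float(vals[0]), float(vals[1])
    if lo <= 0 or lo < limits.min_eigenvalue or hi / max(lo, 1e-300) > limits.max_condition_number:
        return "rejected(degenerate)"
    if 3.0 * math.sqrt(lo) < limits.min_three_sigma:
        return "rejected(too_small)"
    if math.pi * (3.0 * math.sqrt(hi)) * (3.0 * math.sqrt(lo)) > limits.max_footprint_px2:
        return "rejected(too_large)"
    return "valid"


def _leading_eigenpair(cov: np.ndarray) -> tuple[float, np.ndarray]:
    vals, vecs = np.linalg.eigh(cov)
    lam = float(vals[-1])
    if abs(vals[-1] - vals[0]) < 1e-12 * max(abs(vals[-1]), 1.0):
        # isotropic: eigenvectors are arbitrary; fix the row axis for determinism
        v = np.array([1.0, 0.0])
    else:
        v = vecs[:, -1]
    if v[0] < 0 or (v[0] == 0 and v[1] < 0):
        v = -v
    return lam, v


def propose_split(g: GaussianComponent, parent_index: int = 0) -> SplitDecision:
    """Split geometry from the covariance eigendecomposition.

    Direction is the leading unit eigenvector (largest variance axis);
    magnitude is sqrt(lambda_max), the offset at which a single Gaussian
    exactly absorbs two equal spots.  Isotropic covariances break the tie
    along the row axis with non-negative first component.
    """
    lam, v = _leading_eigenpair(g.covariance)
    mag = math.sqrt(max(lam, 0.0))
    children = (g.mean + mag * v, g.mean - mag * v)
    return SplitDecision(parent_index=parent_index, child_means=children, direction=v, magnitude=mag)


def split_component(
    g: GaussianComponent, cov_floor: float = DEFAULT_COV_FLOOR
) -> tuple[GaussianComponent, GaussianComponent]:
    """Replace a Gaussian by two children along its leading eigenvector.

    Each child starts from the parent scatter minus the between-centers
    spread along the split axis, with the parent weight shared equally —
    the decomposition implied by the two-equal-spots argument behind the
    split magnitude.  Child eigenvalues are floored at the parent's minor
    eigenvalue (never below the global covariance floor): for two equal
    round spots the residual spread along the split axis is exactly the
    per-spot variance, and a thinner init leaves EM stuck in a
    degenerate needle-shaped optimum.
    """
    dec = propose_split(g)
    lam = dec.magnitude**2
    child_cov = g.covariance - lam * np.outer(dec.direction, dec.direction)
    vals, vecs = np.linalg.eigh(child_cov)
    lam_min_parent = float(np.linalg.eigvalsh(g.covariance)[0])
    vals = np.maximum(vals, max(cov_floor, lam_min_parent))
    child_cov = (vecs * vals) @ vecs.T
    return (
        GaussianComponent(dec.child_means[0].copy(), child_cov.copy(), g.weight / 2.0),
        GaussianComponent(dec.child_means[1].copy(), child_cov.copy(), g.weight / 2.0),
    )


def compute_bic(fit: MixtureFit, patch: np.ndarray, n_eff_mode: str = "intensity") -> float:
    """BIC = k ln(n_eff) - 2 L with the intensity-weighted log-likelihood.

    n_eff is the total photon count sum_x I(x) by default (each photon is
    one observation); 'pixels' uses the pixel count instead.  k counts 6
    free parameters per Gaussian.
    """
    patch = np.asarray(patch, dtype=float)
    if n_eff_mode == "intensity":
        n_eff = float(patch.sum())
    elif n_eff_mode == "pixels":
        n_eff = float(patch.size)
    else:
        raise ValueError(f"unknown n_eff_mode {n_eff_mode!r}")
    if n_eff <= 0:
        raise ValueError("effective sample size is zero")
    k = PARAMS_PER_GAUSSIAN * len(fit.components)
    return k * math.log(n_eff) - 2.0 * log_likelihood(patch, fit)


def residual_reseed_candidate(
    patch: np.ndarray,
    fit: MixtureFit,
    idx: int,
    min_distance_px: float = 1.5,
    smooth_sigma: float = 1.0,
) -> list[GaussianComponent] | None:
    """Alternative split proposal driven by the background residual.

    The covariance-based split assumes the parent Gaussian has absorbed
    two spots.  When cells differ strongly in brightness, the single
    Gaussian instead locks onto the brightest cell and the *uniform
    component* absorbs its dimmer neighbours, so the parent covariance
    carries no trace of them.  This proposal keeps one child at the
    parent location and seeds the other at the peak of the (smoothed)
    background-attributed intensity z_bg(x) I(x) — still a deterministic
    function of the image.  Returns None when the residual peak sits on
    an existing component.
    """
    from .hem_core import e_step

    z = e_step(patch, fit)
    resid = ndimage.gaussian_filter(z[-1] * patch, smooth_sigma, mode="constant")
    peak = np.unravel_index(int(np.argmax(resid)), resid.shape)
    pos = np.array(peak, dtype=float)
    if any(np.linalg.norm(pos - c.mean) <= min_distance_px for c in fit.components):
        return None
    parent = fit.components[idx]
    lam_min = float(np.linalg.eigvalsh(parent.covariance)[0])
    seed_cov = np.eye(2) * lam_min
    return [
        GaussianComponent(parent.mean.copy(), parent.covariance.copy(), parent.weight / 2.0),
        GaussianComponent(pos, seed_cov, parent.weight / 2.0),
    ]


@dataclass
class RefineLogEntry:
    n_components_before: int
    bic_before: float
    bic_after: float
    accepted: bool
    culled: int = 0


def _cull_weightless(fit: MixtureFit) -> tuple[MixtureFit, int]:
    """Drop components whose responsibility mass vanished during a refit."""
    keep = [c for c in fit.components if c.weight > 1e-9]
    dropped = len(fit.components) - len(keep)
    if dropped == 0:
        return fit, 0
    out = fit.copy()
    out.components = [GaussianComponent(c.mean.copy(), c.covariance.copy(), c.weight) for c in keep]
    out.background.weight += sum(c.weight for c in fit.components) - sum(c.weight for c in keep)
    return out, dropped


def _cull_invalid(fit: MixtureFit, limits: QcLimits) -> tuple[MixtureFit, int]:
    """Drop rejected or weightless components, giving their weight to the
    background so the mixture stays normalized."""
    keep = [
        c
        for c in fit.components
        if c.weight > 1e-9 and validate_component(c, limits) == "valid"
    ]
    dropped = len(fit.components) - len(keep)
    if dropped == 0:
        return fit, 0
    out = fit.copy()
    lost = sum(c.weight for c in out.components) - sum(c.weight for c in keep)
    out.components = [GaussianComponent(c.mean.copy(), c.covariance.copy(), c.weight) for c in keep]
    out.background.weight += lost
    return out, dropped


def refine_event(
    patch: np.ndarray,
    init_fit: MixtureFit,
    bic_drop_threshold: float = DEFAULT_BIC_DROP,
    limits: QcLimits | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    cov_floor: float = DEFAULT_COV_FLOOR,
    n_eff_mode: str = "intensity",
    max_components: int = 6,
    log: list[RefineLogEntry] | None = None,
) -> MixtureFit:
    """Recursive BIC-controlled splitting.

    Each round splits the component with the largest covariance
    eigenvalue (ties broken by index).  Two deterministic proposals
    compete on refit BIC: the covariance-eigenvector split, and a
    residual-guided reseed for the strong-brightness-contrast regime
    where the dim neighbour hides in the background component.  The
    better trial is kept only if the BIC drops by more than
    bic_drop_threshold; otherwise the pre-split fit is returned.
    Weightless components are culled between rounds and the returned fit
    is vetted against the QC limits.  The procedure is deterministic: it
    uses only image information.
    """
    limits = limits or QcLimits()
    patch = np.asarray(patch, dtype=float)
    current = init_fit if init_fit.converged else fit_hem(patch, init_fit, tol, max_iter, cov_floor)
    while current.components and len(current.components) < max_components:
        bic_now = compute_bic(current, patch, n_eff_mode)
        # largest leading eigenvalue selects the split candidate; an
        # oversized component is exactly what a cluster looks like before
        # splitting, so QC culling only applies to post-split children
        lams = [float(np.linalg.eigvalsh(c.covariance)[-1]) for c in current.components]
        idx = int(np.argmax(lams))
        proposals: list[list[GaussianComponent]] = [list(split_component(current.components[idx], cov_floor))]
        reseed = residual_reseed_candidate(patch, current, idx)
        if reseed is not None:
            proposals.append(reseed)
        trial = None
        bic_trial = math.inf
        culled = 0
        for children in proposals:
            cand = current.copy()
            cand.components[idx : idx + 1] = children
            cand.converged = False
            cand = fit_hem(patch, cand, tol, max_iter, cov_floor)
            cand, cand_culled = _cull_weightless(cand)
            cand_bic = compute_bic(cand, patch, n_eff_mode)
            if cand_bic < bic_trial:
                trial, bic_trial, culled = cand, cand_bic, cand_culled
        accepted = bic_trial < bic_now - bic_drop_threshold and len(trial.components) > len(
            current.components
        )
        if log is not None:
            log.append(
                RefineLogEntry(
                    n_components_before=len(current.components),
                    bic_before=bic_now,
                    bic_after=bic_trial,
                    accepted=accepted,
                    culled=culled,
                )
            )
        if not accepted:
            break
        current = trial
    # final vetting: the returned fit never carries an invalid component
    current, _ = _cull_invalid(current, limits)
    return current
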