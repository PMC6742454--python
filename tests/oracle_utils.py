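"""Independent oracles shared across test modules.

These deliberately avoid the package's EM/eigendecomposition code paths:
the weighted likelihood is written out directly and optimized by grid
search plus Nelder-Mead profiling, so agreement with the EM is a real
cross-check rather than a tautology.
"""

import math

import numpy as np
from scipy.optimize import minimize


def weighted_loglik(patch, mu_r, mu_c, log_s2, logit_pi):
    """Intensity-weighted log-likelihood of an isotropic Gaussian plus
    patch-uniform background, written independently of the EM code."""
    s2 = math.exp(log_s2)
    pi_g = 1.0 / (1.0 + math.exp(-logit_pi))
    rr, cc = np.indices(patch.shape)
    quad = ((rr - mu_r) ** 2 + (cc - mu_c) ** 2) / s2
    gauss = np.exp(-0.5 * quad) / (2 * math.pi * s2)
    unif = 1.0 / (patch.shape[0] * patch.shape[1])
    mix = pi_g * gauss + (1 - pi_g) * unif
    return float(np.sum(patch * np.log(mix)))


def grid_search_single_spot(patch, half_range=0.2, step=0.01):
    """Exhaustive mu search on a step-px grid around the intensity
    centroid, profiling (sigma, pi) by Nelder-Mead at each grid point.

    Returns (best_loglik, (mu_r, mu_c), sigma).
    """
    total = patch.sum()
    rr, cc = np.indices(patch.shape)
    r0 = float((patch * rr).sum() / total)
    c0 = float((patch * cc).sum() / total)

    def profiled(mu):
        res = minimize(
            lambda q: -weighted_loglik(patch, mu[0], mu[1], q[0], q[1]),
            x0=[math.log(0.64), 0.0],
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-8},
        )
        return -res.fun, res.x

    best = (-np.inf, None, None)
    for dr in np.arange(-half_range, half_range + step / 2, step):
        for dc in np.arange(-half_range, half_range + step / 2, step):
            ll, q = profiled((r0 + dr, c0 + dc))
            if ll > best[0]:
                best = (ll, (r0 + dr, c0 + dc), math.sqrt(math.exp(q[0])))
    return best


def single_spot_patches(n, seed, size=5, photons=4000.0, background=10.0, sigma=0.8):
    """Poisson-noise single-spot patches with sub-pixel random centers."""
    from hemcyto import simgen

    rng = np.random.default_rng(seed)
    mid = (size - 1) / 2.0
    out = []
    for _ in range(n):
        center = (mid + rng.uniform(-0.4, 0.4), mid + rng.uniform(-0.4, 0.4))
        spec = simgen.FieldSpec(
            image_size=(size, size),
            background_level=background,
            noise_model="poisson",
            spots=(simgen.SpotTruth(center=center, total_photons=photons, sigma=(sigma, sigma)),),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        image, _ = simgen.render_field(spec)
        out.append(image.pixels)
    return out
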