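"""Synthetic benchmark batteries over the full pipeline.

Because real micrographs of labeled cells are not distributable with the
package, pipeline performance is characterized on the simulator's bead
and cluster fields, where ground truth is exact: detection operating
point, photometry/diameter recovery on the three-tier bead series, and
component-count accuracy of the cluster splitter.  The same batteries
back both the test suite and the reproduction script.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import cluster_refine, detector as det_mod, hem_core, pipeline as pipe_mod, simgen

#: match radius (px) between an estimated location and a truth center
MATCH_RADIUS_PX = 2.0
#: windows closer than this to a true center are excluded from the
#: false-positive pool (they overlap genuine signal)
FP_EXCLUSION_RADIUS_PX = 4.0


def detection_benchmark(
    seed: int,
    detector: det_mod.LdaDetector | None = None,
    n_images: int = 20,
    n_spots: int = 15,
    snr: float = 20.0,
    image_size: tuple[int, int] = (192, 192),
) -> dict:
    """Spot-level TPR and per-window FPR on isolated-spot fields."""
    rng = np.random.default_rng(seed)
    detector = detector or det_mod.train_calibrated_detector(seed=int(rng.integers(0, 2**31 - 1)))
    tp = total = fp = n_windows = 0
    for _ in range(n_images):
        image, truth = simgen.scatter_field(
            n_spots, snr=snr, seed=int(rng.integers(0, 2**31 - 1)), image_size=image_size
        )
        pm = det_mod.scan(image, detector)
        events = det_mod.detect(pm, detector.threshold)
        cents = np.array([e.centroid for e in events]) if events else np.zeros((0, 2))
        for t in truth:
            total += 1
            if len(cents) and np.min(np.sum((cents - np.array(t.center)) ** 2, axis=1)) <= MATCH_RADIUS_PX**2:
                tp += 1
        rr, cc = np.indices(pm.values.shape)
        negative = ~np.isnan(pm.values)
        for t in truth:
            negative &= (rr - t.center[0]) ** 2 + (cc - t.center[1]) ** 2 > FP_EXCLUSION_RADIUS_PX**2
        fp += int((pm.values[negative] >= detector.threshold).sum())
        n_windows += int(negative.sum())
    return {
        "tpr": tp / total,
        "fpr_per_window": fp / n_windows,
        "n_spots": total,
        "n_windows": n_windows,
    }


def _cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    pooled = math.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    return float((a.mean() - b.mean()) / pooled)


def bead_benchmark(
    seed: int,
    detector: det_mod.LdaDetector | None = None,
    n_per_level: int = 300,
) -> dict:
    """Photometry and diameter recovery on the three-tier bead series.

    Runs the full pipeline on each rendered field and matches valid
    measurements to truth; reports per-tier mean fluorescence against
    the true photon totals (squared correlation of tier means), the
    effect size between adjacent tiers, diameter recovery against the
    true 7.5 µm, and the measured image SNR per tier.
    """
    rng = np.random.default_rng(seed)
    detector = detector or det_mod.train_calibrated_detector(seed=int(rng.integers(0, 2**31 - 1)))
    fields = simgen.bead_series(n_per_level=n_per_level, seed=int(rng.integers(0, 2**31 - 1)))
    per_tier = len(fields) // 3
    config = pipe_mod.PipelineConfig()
    fl: list[list[float]] = [[], [], []]
    diam: list[list[float]] = [[], [], []]
    snrs: list[list[float]] = [[], [], []]
    true_photons = [0.0, 0.0, 0.0]
    for i, (image, truth) in enumerate(fields):
        tier = i // per_tier
        true_photons[tier] = truth[0].total_photons
        snrs[tier].append(simgen.measure_snr(image, truth))
        table = pipe_mod.run_pipeline(image, detector, config)
        valid = table[(table["qc_status"] == "valid") & (~table["edge"].astype(bool))]
        for t in truth:
            d2 = (valid["row"] - t.center[0]) ** 2 + (valid["col"] - t.center[1]) ** 2
            if len(d2) and d2.min() <= MATCH_RADIUS_PX**2:
                j = d2.idxmin()
                fl[tier].append(float(valid.loc[j, "fluorescence"]))
                diam[tier].append(float(valid.loc[j, "diameter_um"]))
    tier_means = [float(np.mean(f)) for f in fl]
    r = np.corrcoef(tier_means, true_photons)[0, 1]
    all_diams = np.concatenate([np.asarray(d) for d in diam])
    return {
        "tier_mean_fluorescence": tier_means,
        "tier_true_photons": true_photons,
        "fluorescence_r2": float(r * r),
        "cohens_d_tier12": _cohens_d(np.asarray(fl[0]), np.asarray(fl[1])),
        "cohens_d_tier23": _cohens_d(np.asarray(fl[1]), np.asarray(fl[2])),
        "diameter_mean_um": float(all_diams.mean()),
        "diameter_cv_pct_low_snr": float(
            100.0 * np.std(diam[0]) / np.mean(diam[0])
        ),
        "measured_snr_tiers": [float(np.mean(s)) for s in snrs],
        "n_matched": [len(f) for f in fl],
    }


def split_benchmark(seed: int, n_cases: int = 200) -> dict:
    """Component-count accuracy on the doublet/triplet battery:
    separations 4-8 px, brightness ratios 1-3, SNR 10-30."""
    rng = np.random.default_rng(seed)
    correct = 0
    for _ in range(n_cases):
        k = int(rng.integers(2, 4))
        sep = float(rng.uniform(4, 8))
        ratio = float(rng.uniform(1, 3))
        snr = float(rng.uniform(10, 30))
        angle = float(rng.uniform(0, math.pi))
        image, _ = simgen.cluster_field(
            k=k,
            separation_px=sep,
            seed=int(rng.integers(0, 2**31 - 1)),
            snr=snr,
            brightness_ratios=[1.0] * (k - 1) + [ratio],
            axis_angle=angle,
        )
        patch = image.pixels
        ctr = ((patch.shape[0] - 1) / 2, (patch.shape[1] - 1) / 2)
        fit = cluster_refine.refine_event(patch, hem_core.initial_fit(patch.shape, [ctr]))
        correct += len(fit.components) == k
    return {"accuracy": correct / n_cases, "n_cases": n_cases}


def spurious_split_benchmark(seed: int, n_cases: int = 50) -> dict:
    """Number of isolated single spots wrongly resolved into >1 component."""
    rng = np.random.default_rng(seed)
    spurious = 0
    for _ in range(n_cases):
        spec = simgen.FieldSpec(
            image_size=(40, 40),
            background_level=30.0,
            spots=(
                simgen.SpotTruth(
                    center=(19.5 + rng.uniform(-1, 1), 19.5 + rng.uniform(-1, 1)),
                    total_photons=float(rng.uniform(2000, 10000)),
                    sigma=(simgen.sigma_px_for_diameter(7.5), simgen.sigma_px_for_diameter(7.5)),
                ),
            ),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        image, _ = simgen.render_field(spec)
        ctr = (19.5, 19.5)
        fit = cluster_refine.refine_event(
            image.pixels, hem_core.initial_fit(image.pixels.shape, [ctr])
        )
        spurious += len(fit.components) != 1
    return {"spurious": spurious, "n_cases": n_cases}
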