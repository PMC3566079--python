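"""Calibration and pattern-recovery diagnostics for the synthetic pipeline.

These routines re-measure, from freshly generated data, the properties the
synthetic experiment is calibrated to reproduce: the printed group means
of the microwear variables, the directional group contrasts (more pits
and shorter scratches on low-silica diets, larger closed-dale areas on
high-silica diets), the variability ordering, the discriminant factor-
space geometry, and the operating characteristics of the statistical
protocol (omnibus type-I error, centroid-ellipse coverage).
"""

from __future__ import annotations

import numpy as np

from facetwear import discriminant as da
from facetwear import pipeline
from facetwear.group_stats import wy_omnibus
from facetwear.synthetic import default_group_configs, generate_counting_features
from facetwear.microwear import count_microwear

__all__ = [
    "microwear_calibration",
    "pattern_recovery",
    "wy_type1_error",
    "ellipse_coverage",
]


def microwear_calibration(n_replicates: int = 20, base_seed: int = 0) -> dict:
    """Group means of Np and Ls over replicate synthetic cohorts.

    Only the 2D counting fields are generated (the 3D stage does not enter
    the microwear variables). Returns group -> {"Np": mean, "Ls": mean}.
    """
    configs = default_group_configs()
    sums = {c.label: {"Np": [], "Ls": []} for c in configs}
    for r in range(n_replicates):
        seed = int(base_seed) + r
        for cfg in configs:
            for i in range(cfg.n_animals):
                feats = generate_counting_features(cfg, i, seed)
                counts = count_microwear(feats)
                sums[cfg.label]["Np"].append(counts.Np)
                if counts.Ls_um is not None:
                    sums[cfg.label]["Ls"].append(counts.Ls_um)
    return {g: {k: float(np.mean(v)) for k, v in d.items()}
            for g, d in sums.items()}


def _iqr(v):
    q1, q3 = np.quantile(v, [0.25, 0.75])
    return q3 - q1


def pattern_recovery(seeds) -> dict:
    """Run one full (headline) experiment per seed and score the seven
    directional pattern checks of the study.

    Returns check name -> number of replicates in which it held.
    """
    tallies = {k: 0 for k in ("np_direction", "ls_direction", "sda_direction",
                              "iqr_np", "iqr_sp", "gl_disjoint",
                              "golo_overlap")}
    for seed in seeds:
        rep = pipeline.run_experiment(master_seed=int(seed),
                                      full_texture=False)
        wide = rep["headline"]

        def vals(group, var):
            return wide.loc[wide["group"] == group, var].dropna().to_numpy()

        tallies["np_direction"] += (vals("L", "Np").mean()
                                    > vals("G", "Np").mean())
        tallies["ls_direction"] += (vals("G", "Ls").mean()
                                    > vals("L", "Ls").mean())
        tallies["sda_direction"] += (vals("G", "Sda|primary").mean()
                                     > vals("L", "Sda|primary").mean())
        tallies["iqr_np"] += _iqr(vals("L", "Np")) > _iqr(vals("G", "Np"))
        tallies["iqr_sp"] += (_iqr(vals("L", "Sp|S-L"))
                              > _iqr(vals("G", "Sp|S-L")))
        ell = rep["ellipses"]
        tallies["gl_disjoint"] += not da.ellipses_overlap(ell["G"], ell["L"])
        tallies["golo_overlap"] += da.ellipses_overlap(ell["GO"], ell["LO"])
    return tallies


def wy_type1_error(n_sim: int = 10_000, seed: int = 0,
                   alpha: float = 0.05, trim: float = 0.15) -> float:
    """Monte-Carlo type-I error of the omnibus test under the null with
    unequal variances at the experiment's group sizes (n = 7, 6, 7, 6)."""
    rng = np.random.default_rng(seed)
    sds = (1.0, 2.0, 1.5, 3.0)
    ns = (7, 6, 7, 6)
    rej = 0
    for _ in range(n_sim):
        groups = [rng.normal(0.0, s, n) for s, n in zip(sds, ns)]
        rej += wy_omnibus(groups, trim)[3] <= alpha
    return rej / n_sim


def ellipse_coverage(n_replicates: int = 5_000, n_group: int = 150,
                     confidence: float = 0.90, seed: int = 0) -> float:
    """Monte-Carlo coverage of the centroid confidence ellipse: fraction
    of replicates in which the true mean falls inside the region."""
    rng = np.random.default_rng(seed)
    mean = np.array([1.0, -2.0])
    L = np.linalg.cholesky(np.array([[2.0, 0.6], [0.6, 1.0]]))
    labels = ["g"] * n_group
    cover = 0
    for _ in range(n_replicates):
        pts = rng.normal(size=(n_group, 2)) @ L.T + mean
        ell = da.centroid_ellipses(pts, labels, confidence)["g"]
        cover += bool(da._inside(ell, mean[None, :])[0])
    return cover / n_replicates
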