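"""Replication experiments on synthetic cohorts.

These are the package's calibration and validation studies, each a small,
fully seeded end-to-end run of generator -> preprocessing -> site-matched
L2O evaluation:

* :func:`null_calibration` — type-I error of the permutation test and
  chance-level behaviour of the CV accuracy when no effect is planted;
* :func:`effect_recovery` — accuracy as a function of the planted
  illness-course effect size (parameter recovery / monotonicity);
* :func:`pooling_comparison` — pooled multi-site model vs a single small
  site's own model on a shared planted effect, the qualitative motivation
  for multi-center pooling.

Problem sizes (16^3 grids, tens of subjects, hundreds of permutations) are
desk-scale by design: large enough for stable rates, small enough to run
in minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import imaging
from .evaluation import (
    _derive_seed,
    bootstrap_ensemble,
    permutation_test,
)
from .simulate import (
    EffectMap,
    SiteProfile,
    SyntheticConfig,
    generate_cohort,
    preset_config,
)

SINGLE_C_GRID = (1.0,)


def _prepare(config: SyntheticConfig):
    maps, cohort = generate_cohort(config)
    features = imaging.preprocess(maps, cohort)
    return cohort, features


def null_calibration(
    n_datasets: int = 50,
    n_permutations: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Type-I calibration of the permutation test on no-effect cohorts.

    Each replicate draws a fresh two-site cohort (20 subjects per course
    class, every planted effect 0), runs the L2O pipeline, and permutes
    the course labels within site.  Under the null the p-values should be
    uniform, so the rejection rate at ``alpha`` estimates the type-I
    error, and the observed CV accuracies should concentrate at 0.5.

    A single-value C grid is used here: with no signal anywhere, the
    inner-loop search adds cost but no information to a calibration of the
    outer test.
    """
    p_values = []
    accuracies = []
    for d in range(n_datasets):
        config = replace(preset_config("null"), seed=_derive_seed(seed, 100, d))
        cohort, features = _prepare(config)
        res = permutation_test(
            cohort,
            features,
            "course_label",
            n_permutations=n_permutations,
            seed=_derive_seed(seed, 200, d),
            c_grid=SINGLE_C_GRID,
            n_bootstraps=1,
        )
        p_values.append(res.p_value)
        accuracies.append(res.observed)
    p = np.asarray(p_values)
    return {
        "n_datasets": n_datasets,
        "n_permutations": n_permutations,
        "alpha": alpha,
        "p_values": p_values,
        "accuracies": accuracies,
        "rejection_rate": float(np.mean(p < alpha)),
        "mean_accuracy": float(np.mean(accuracies)),
    }


def _recovery_config(effect_size: float, seed: int) -> SyntheticConfig:
    base = preset_config("tiny", seed=seed)
    effects = (
        EffectMap(target_factor="course", effect_size=float(effect_size),
                  center_frac=(0.62, 0.58, 0.45), n_voxels=50),
    )
    return replace(base, effects=effects)


def effect_recovery(
    effect_sizes=(0.0, 1.0, 3.0),
    seed: int = 0,
    n_bootstraps: int = 10,
) -> dict:
    """Mean L2O per-class accuracies vs planted course effect size.

    A 50-voxel spherical region carries an additive continuous-vs-remitting
    shift of d noise units; 40 subjects over two sites.  The nested C
    search runs with its default grid.  Accuracy should rise from chance
    at d=0 toward 1 as d grows.
    """
    out: dict = {"effect_sizes": list(map(float, effect_sizes)), "results": {}}
    for e in effect_sizes:
        config = _recovery_config(e, seed=_derive_seed(seed, 300, int(round(e * 1000))))
        cohort, features = _prepare(config)
        ens = bootstrap_ensemble(
            cohort,
            features,
            "course_label",
            n_bootstraps=n_bootstraps,
            seed=_derive_seed(seed, 400, int(round(e * 1000))),
        )
        out["results"][float(e)] = dict(ens.mean_metrics)
    return out


_POOLING_SITES = (
    SiteProfile("small", intensity_offset=0.015, intensity_gain=1.04, noise_sd=0.08, psf_fwhm_mm=0.0),
    SiteProfile("big_b", intensity_offset=-0.010, intensity_gain=0.97, noise_sd=0.09, psf_fwhm_mm=1.5),
    SiteProfile("big_c", intensity_offset=0.005, intensity_gain=1.00, noise_sd=0.07, psf_fwhm_mm=2.5),
)


def pooling_config(effect_size: float = 0.6, seed: int = 0) -> SyntheticConfig:
    """Three sites sharing one sex-effect region; one site is small.

    The small site contributes 10 subjects (5 per sex), the two large
    sites 30 each, so its own model trains on 8 subjects per fold while
    the pooled model trains on 68.  The planted effect and noise are set
    so the small-site model is clearly off ceiling — the regime where
    pooling can help.
    """
    counts = {}
    for site, per_sex in (("small", 5), ("big_b", 15), ("big_c", 15)):
        for sex in ("male", "female"):
            half = per_sex // 2
            counts[(site, sex, "continuous")] = half
            counts[(site, sex, "remitting")] = per_sex - half
    effects = (
        EffectMap(target_factor="sex", effect_size=float(effect_size),
                  center_frac=(0.42, 0.45, 0.55), n_voxels=50),
    )
    return SyntheticConfig(sites=_POOLING_SITES, per_site_counts=counts,
                           effects=effects, seed=seed)


def pooling_comparison(
    seed: int = 0,
    n_replicates: int = 10,
    n_bootstraps: int = 4,
    effect_size: float = 0.6,
) -> dict:
    """Pooled vs single-site sex model, judged on the small site.

    For each replicate cohort, runs the bootstrap ensemble once on the
    pooled three-site data and once on the small site alone (with its own
    preprocessing, as a center analysing only its own data would), and
    records the mean balanced accuracy on the small site's subjects under
    each model.  Averaging over replicate cohorts (n_replicates x
    n_bootstraps repetitions in total) smooths out the coarse granularity
    of a 10-subject test set.
    """
    pooled_accs = []
    single_accs = []
    for r in range(n_replicates):
        config = pooling_config(effect_size=effect_size, seed=_derive_seed(seed, 500, r))
        maps, cohort = generate_cohort(config)
        features = imaging.preprocess(maps, cohort)
        pooled = bootstrap_ensemble(
            cohort, features, "sex", n_bootstraps=n_bootstraps,
            seed=_derive_seed(seed, 510, r), c_grid=SINGLE_C_GRID,
        )
        small_idx = [i for i, s in enumerate(cohort) if s.site == "small"]
        small_cohort = cohort.subset(small_idx)
        small_maps = [maps[i] for i in small_idx]
        small_features = imaging.preprocess(small_maps, small_cohort)
        single = bootstrap_ensemble(
            small_cohort, small_features, "sex", n_bootstraps=n_bootstraps,
            seed=_derive_seed(seed, 520, r), c_grid=SINGLE_C_GRID,
        )
        pooled_accs.append(pooled.per_site["small"]["balanced_accuracy"])
        single_accs.append(single.per_site["overall"]["balanced_accuracy"])
    return {
        "n_replicates": n_replicates,
        "n_bootstraps": n_bootstraps,
        "effect_size": float(effect_size),
        "pooled_small_site_accuracy": float(np.mean(pooled_accs)),
        "single_small_site_accuracy": float(np.mean(single_accs)),
        "per_replicate_pooled": pooled_accs,
        "per_replicate_single": single_accs,
    }
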