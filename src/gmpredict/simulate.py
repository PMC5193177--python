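"""Synthetic multi-site gray-matter cohorts with planted effects.

Real multi-center morphometry data cannot be redistributed, so this module
generates post-segmentation stand-ins: modulated gray-matter probability
volumes on a common grid, with

* a smooth "pseudo-brain" baseline (Gaussian blobs inside an ellipsoid
  support, values in [0.05, 0.95] inside and 0 outside);
* per-site acquisition differences — additive intensity offset,
  multiplicative gain, per-voxel Gaussian noise, and a site point-spread
  blur — standing in for scanner/protocol heterogeneity;
* spatially localised class effects: a strong sex effect and a weaker
  illness-course effect, each an additive shift on a compact voxel region
  applied to the positive class (males / continuous patients).

Effect sizes are expressed in units of the site noise standard deviation
*before* the site gain is applied, so an ``effect_size`` of 2 reads as a
per-voxel Cohen's d of about 2 (site blur then attenuates both signal and
noise).  A subject volume is built as::

    clip01(baseline + sum(effects) * noise_sd + offset) * gain + noise
    -> blur by site PSF -> clip01

Generation is a pure function of the configuration: per-subject seeds are
derived from the master seed and the subject counter through a
``SeedSequence``, independent of generation order.

The module also carries the demographic roster of the five-center
first-episode psychosis study this pipeline models (per-site sex and
illness-course counts), used as a bookkeeping fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml
from scipy import ndimage

from .cohort import (
    COURSES,
    SEXES,
    Cohort,
    CohortError,
    EpisodeHistory,
    Subject,
    classify_illness_course,
)
from .imaging import GrayMatterMap, fwhm_to_sigma_voxels

_TEMPLATE_SEED = 731209  # fixed: the baseline template is part of the model

#: Which class receives the additive shift of each effect type.
EFFECT_POSITIVE_CLASS = {"sex": "male", "course": "continuous"}


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Configuration types


@dataclass(frozen=True)
class SiteProfile:
    """Acquisition-site characteristics (scanner/protocol stand-in)."""

    site_id: str
    intensity_offset: float = 0.0
    intensity_gain: float = 1.0
    noise_sd: float = 0.05
    psf_fwhm_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.intensity_gain <= 0:
            raise SimulationError(f"intensity_gain must be positive, got {self.intensity_gain}")
        if self.noise_sd < 0 or self.psf_fwhm_mm < 0:
            raise SimulationError("noise_sd and psf_fwhm_mm must be nonnegative")


@dataclass(frozen=True)
class EffectMap:
    """A localised additive class effect.

    The region is a sphere of ``n_voxels`` voxels (nearest voxels to
    ``center_frac``, fractional grid coordinates), optionally restricted to
    the baseline support.  ``effect_size`` is in units of the site noise
    standard deviation and is added for the positive class of
    ``target_factor`` (male for ``sex``, continuous for ``course``).
    """

    target_factor: str
    effect_size: float
    center_frac: tuple[float, float, float] = (0.5, 0.5, 0.5)
    n_voxels: int = 50

    def __post_init__(self) -> None:
        if self.target_factor not in EFFECT_POSITIVE_CLASS:
            raise SimulationError(f"unknown target_factor {self.target_factor!r}")
        if not np.isfinite(self.effect_size):
            raise SimulationError("effect_size must be finite")
        if self.n_voxels < 1:
            raise SimulationError("region must contain at least one voxel")

    def region(self, grid_shape, support: Optional[np.ndarray] = None) -> np.ndarray:
        return sphere_region(grid_shape, self.center_frac, self.n_voxels, support)


@dataclass(frozen=True)
class SyntheticConfig:
    grid_shape: tuple[int, int, int] = (16, 16, 16)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    sites: tuple[SiteProfile, ...] = ()
    #: counts keyed by (site_id, sex, course)
    per_site_counts: dict = field(default_factory=dict)
    effects: tuple[EffectMap, ...] = ()
    #: scalar baseline value, or None for the pseudo-brain template
    baseline_value: Optional[float] = None
    follow_up_years_range: tuple[float, float] = (3.0, 7.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(n) <= 0 for n in self.grid_shape):
            raise SimulationError("grid_shape entries must be positive")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise SimulationError("voxel sizes must be positive")
        site_ids = [s.site_id for s in self.sites]
        if len(set(site_ids)) != len(site_ids):
            raise SimulationError("duplicate site ids")
        for (site, sex, course), count in self.per_site_counts.items():
            if site not in site_ids:
                raise SimulationError(f"count refers to unknown site {site!r}")
            if sex not in SEXES or course not in COURSES:
                raise SimulationError(f"invalid count key ({site}, {sex}, {course})")
            if count < 0:
                raise SimulationError("counts must be nonnegative")
        if self.baseline_value is not None and not 0.0 <= self.baseline_value <= 1.0:
            raise SimulationError("baseline_value must be in [0, 1]")

    def site(self, site_id: str) -> SiteProfile:
        for s in self.sites:
            if s.site_id == site_id:
                return s
        raise SimulationError(f"unknown site {site_id!r}")

    def baseline(self) -> np.ndarray:
        if self.baseline_value is not None:
            return np.full(self.grid_shape, float(self.baseline_value))
        return pseudo_brain(self.grid_shape)


# ---------------------------------------------------------------------------
# Baseline template and regions


def pseudo_brain(grid_shape) -> np.ndarray:
    """Smooth synthetic baseline: Gaussian blobs inside an ellipsoid.

    Values lie in [0.05, 0.95] inside the ellipsoid support and are 0
    outside, giving a nonuniform template whose low-probability exterior is
    removed by the standard 0.03 gray-matter mask.  Deterministic in
    ``grid_shape``.
    """
    shape = tuple(int(n) for n in grid_shape)
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    coords = np.stack(grids, axis=-1)
    center = (np.asarray(shape) - 1) / 2.0
    semi = np.asarray(shape) * 0.45
    u = np.sum(((coords - center) / semi) ** 2, axis=-1)
    support = u <= 1.0
    rng = np.random.default_rng(_TEMPLATE_SEED)
    blob_field = np.zeros(shape)
    for _ in range(12):
        c = center + rng.uniform(-0.55, 0.55, size=3) * semi
        width = rng.uniform(0.12, 0.30) * float(np.mean(shape))
        amp = rng.uniform(0.4, 1.0)
        d2 = np.sum((coords - c) ** 2, axis=-1)
        blob_field += amp * np.exp(-d2 / (2.0 * width * width))
    inside = blob_field[support]
    lo, hi = float(inside.min()), float(inside.max())
    out = np.zeros(shape)
    out[support] = 0.05 + 0.90 * (blob_field[support] - lo) / (hi - lo)
    return out


def sphere_region(
    grid_shape, center_frac, n_voxels: int, support: Optional[np.ndarray] = None
) -> np.ndarray:
    """Boolean mask of the ``n_voxels`` voxels nearest a fractional center."""
    shape = tuple(int(n) for n in grid_shape)
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    center = np.asarray(center_frac) * (np.asarray(shape) - 1)
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    flat = d2.ravel()
    order = np.lexsort((np.arange(flat.size), flat))  # stable tie-break by index
    if support is not None:
        ok = support.ravel()[order]
        order = order[ok]
    if order.size < n_voxels:
        raise SimulationError(
            f"region of {n_voxels} voxels does not fit (only {order.size} available)"
        )
    mask = np.zeros(flat.size, dtype=bool)
    mask[order[:n_voxels]] = True
    return mask.reshape(shape)


# ---------------------------------------------------------------------------
# Volume generation


def generate_subject_map(
    config: SyntheticConfig,
    site: str,
    sex: str,
    course: str,
    subject_seed: int,
    add_noise: bool = True,
) -> GrayMatterMap:
    """One subject's gray-matter probability volume.

    Bit-for-bit reproducible given (config, site, sex, course,
    subject_seed).  ``add_noise=False`` disables the per-voxel noise draw
    while keeping the effect scaling (useful for inspecting the planted
    signal).
    """
    profile = config.site(site)
    if sex not in SEXES:
        raise SimulationError(f"unknown sex {sex!r}")
    if course not in COURSES:
        raise SimulationError(f"unknown course {course!r}")
    values = config.baseline().astype(np.float64)
    support = values > 0
    labels = {"sex": sex, "course": course}
    for eff in config.effects:
        if labels[eff.target_factor] == EFFECT_POSITIVE_CLASS[eff.target_factor]:
            values[eff.region(config.grid_shape, support)] += eff.effect_size * profile.noise_sd
    values += profile.intensity_offset
    np.clip(values, 0.0, 1.0, out=values)
    values *= profile.intensity_gain
    if add_noise and profile.noise_sd > 0:
        rng = np.random.default_rng(subject_seed)
        values += rng.normal(0.0, profile.noise_sd, size=values.shape)
    if profile.psf_fwhm_mm > 0:
        sigma = fwhm_to_sigma_voxels(profile.psf_fwhm_mm, config.voxel_size_mm)
        values = ndimage.gaussian_filter(values, sigma=sigma, mode="reflect")
    np.clip(values, 0.0, 1.0, out=values)
    return GrayMatterMap(values, config.voxel_size_mm)


def _subject_seed(master: int, counter: int, stream: int = 0) -> int:
    """Counter-based per-subject seed; independent of generation order."""
    ss = np.random.SeedSequence([int(master) & 0x7FFFFFFF, int(counter), int(stream)])
    return int(ss.generate_state(1)[0])


def generate_cohort(
    config: SyntheticConfig, add_noise: bool = True
) -> tuple[list[GrayMatterMap], Cohort]:
    """Generate one volume + metadata record per requested subject.

    Subjects are enumerated in sorted (site, sex, course) key order with a
    running counter, so the full cohort is a pure function of the
    configuration.  Course labels are materialised by generating a
    follow-up episode history that classifies to the requested label.
    """
    maps: list[GrayMatterMap] = []
    subjects: list[Subject] = []
    counter = 0
    for (site, sex, course), count in sorted(config.per_site_counts.items()):
        for _ in range(count):
            demo_rng = np.random.default_rng(_subject_seed(config.seed, counter, 2))
            lo, hi = config.follow_up_years_range
            follow_up_years = float(demo_rng.uniform(lo, hi))
            age = float(demo_rng.uniform(18.0, 45.0))
            history = simulate_episode_history(
                course, follow_up_years, _subject_seed(config.seed, counter, 1)
            )
            maps.append(
                generate_subject_map(
                    config, site, sex, course, _subject_seed(config.seed, counter, 0), add_noise
                )
            )
            subjects.append(
                Subject(
                    subject_id=f"{site}-{counter:04d}",
                    site=site,
                    sex=sex,
                    age_years=round(age, 1),
                    history=history,
                    course_label=course,
                )
            )
            counter += 1
    return maps, Cohort(tuple(subjects))


# ---------------------------------------------------------------------------
# Episode histories


def simulate_episode_history(course: str, follow_up_years: float, seed: int) -> EpisodeHistory:
    """Construct a follow-up history whose classification is ``course``.

    The construction is randomised (interval lengths vary with the seed)
    but round-trips by design: ``classify_illness_course`` on the result
    returns exactly the requested label.  Requires a follow-up of at least
    400 days so the defining intervals fit.
    """
    if course not in COURSES:
        raise SimulationError(f"unknown course {course!r}")
    if follow_up_years <= 0:
        raise SimulationError(f"follow-up must be positive, got {follow_up_years}")
    fu = int(round(follow_up_years * 365.25))
    if fu < 400:
        raise SimulationError(f"follow-up of {fu} days is too short to build a {course} history")
    rng = np.random.default_rng(seed)
    T = 183
    if course == "remitting":
        e1 = int(rng.integers(30, 151))
        gap = int(rng.integers(7, 31))
        r_hi = min(T + 120, fu - e1 - gap)
        r = int(rng.integers(T, r_hi + 1))
        episodes = [(0, e1)]
        remissions = [(e1 + gap, r)]
        # sometimes a second short episode after the long remission,
        # exercising the multi-episode remitting clause
        rest = fu - (e1 + gap + r)
        if rest >= 40 and rng.random() < 0.5:
            episodes.append((e1 + gap + r, int(rng.integers(30, min(90, rest) + 1))))
    elif course == "continuous":
        e1 = int(rng.integers(T + 10, min(T + 160, fu - 120) + 1))
        r = int(rng.integers(30, min(150, fu - e1 - 60) + 1))
        e2 = int(rng.integers(30, min(90, fu - e1 - r) + 1))
        episodes = [(0, e1), (e1 + r, e2)]
        remissions = [(e1, r)]
    else:  # excluded: long remission together with a long episode
        e1 = int(rng.integers(T + 1, min(T + 120, fu - T - 1) + 1))
        r = int(rng.integers(T, fu - e1 + 1))
        episodes = [(0, e1)]
        remissions = [(e1, r)]
    history = EpisodeHistory(
        episodes=tuple(episodes), remissions=tuple(remissions), follow_up_days=fu
    )
    got = classify_illness_course(history)
    if got != course:  # pragma: no cover - construction guarantee
        raise SimulationError(f"constructed history classifies as {got}, wanted {course}")
    return history


# ---------------------------------------------------------------------------
# Five-center demographic roster (bookkeeping fixture)

# Per-site counts (male/female x remitting/continuous/excluded) transcribed
# from the published demographics of the five-center first-episode
# psychosis cohort this pipeline models.  "excluded" holds the patients
# whose illness course fit neither extreme group; they take part in sex
# models only.
_ROSTER = {
    # site: (m_remit, m_cont, f_remit, f_cont, m_excl, f_excl)
    "london": (13, 22, 14, 8, 26, 14),
    "utrecht": (14, 21, 1, 3, 23, 5),
    "melbourne": (9, 12, 7, 2, 16, 8),
    "santander": (21, 12, 20, 4, 29, 21),
    "saopaulo": (9, 8, 10, 2, 21, 14),
}


def five_center_roster() -> dict:
    """Per-(site, sex, course) counts of the five-center reference cohort.

    Totals: 389 subjects (256 males, 133 females); 94 continuous and 118
    remitting outcome patients, of whom 141 are male (75 continuous, 66
    remitting).
    """
    counts: dict = {}
    for site, (mr, mc, fr, fc, mx, fx) in _ROSTER.items():
        counts[(site, "male", "remitting")] = mr
        counts[(site, "male", "continuous")] = mc
        counts[(site, "female", "remitting")] = fr
        counts[(site, "female", "continuous")] = fc
        counts[(site, "male", "excluded")] = mx
        counts[(site, "female", "excluded")] = fx
    return counts


# ---------------------------------------------------------------------------
# Preset configurations

_DEFAULT_EFFECTS = (
    EffectMap(target_factor="sex", effect_size=3.0, center_frac=(0.38, 0.42, 0.52), n_voxels=50),
    EffectMap(target_factor="course", effect_size=1.0, center_frac=(0.62, 0.58, 0.45), n_voxels=50),
)

_TWO_SITE_PROFILES = (
    SiteProfile("site_a", intensity_offset=0.010, intensity_gain=1.03, noise_sd=0.05, psf_fwhm_mm=0.0),
    SiteProfile("site_b", intensity_offset=-0.015, intensity_gain=0.97, noise_sd=0.06, psf_fwhm_mm=1.5),
)

_FIVE_SITE_PROFILES = (
    SiteProfile("london", intensity_offset=0.000, intensity_gain=1.00, noise_sd=0.05, psf_fwhm_mm=0.0),
    SiteProfile("utrecht", intensity_offset=0.015, intensity_gain=1.04, noise_sd=0.055, psf_fwhm_mm=1.0),
    SiteProfile("melbourne", intensity_offset=-0.010, intensity_gain=0.96, noise_sd=0.06, psf_fwhm_mm=1.5),
    SiteProfile("santander", intensity_offset=0.020, intensity_gain=1.02, noise_sd=0.05, psf_fwhm_mm=2.0),
    SiteProfile("saopaulo", intensity_offset=-0.020, intensity_gain=0.98, noise_sd=0.065, psf_fwhm_mm=1.0),
)


def preset_config(name: str, seed: int = 0) -> SyntheticConfig:
    """Named study configurations.

    ``tiny``
        2 sites x 20 subjects (5 per sex x extreme course), planted sex
        (d=3) and course (d=1) effects; fast end-to-end runs.
    ``null``
        the tiny layout with every effect size set to 0; downstream
        accuracies should sit at chance.
    ``roster``
        the five-center reference roster (389 subjects) with per-site
        acquisition differences and the default planted effects.
    """
    if name == "tiny" or name == "null":
        counts = {
            (site, sex, course): 5
            for site in ("site_a", "site_b")
            for sex in SEXES
            for course in ("continuous", "remitting")
        }
        effects = _DEFAULT_EFFECTS
        if name == "null":
            effects = tuple(
                EffectMap(e.target_factor, 0.0, e.center_frac, e.n_voxels) for e in _DEFAULT_EFFECTS
            )
        return SyntheticConfig(
            sites=_TWO_SITE_PROFILES, per_site_counts=counts, effects=effects, seed=seed
        )
    if name == "roster":
        return SyntheticConfig(
            sites=_FIVE_SITE_PROFILES,
            per_site_counts=five_center_roster(),
            effects=_DEFAULT_EFFECTS,
            seed=seed,
        )
    raise SimulationError(f"unknown preset {name!r}")


# ---------------------------------------------------------------------------
# YAML round-trip


def config_to_yaml(config: SyntheticConfig, path) -> None:
    doc = {
        "grid_shape": list(config.grid_shape),
        "voxel_size_mm": list(config.voxel_size_mm),
        "sites": [
            {
                "site_id": s.site_id,
                "intensity_offset": s.intensity_offset,
                "intensity_gain": s.intensity_gain,
                "noise_sd": s.noise_sd,
                "psf_fwhm_mm": s.psf_fwhm_mm,
            }
            for s in config.sites
        ],
        "per_site_counts": [
            {"site": k[0], "sex": k[1], "course": k[2], "count": v}
            for k, v in sorted(config.per_site_counts.items())
        ],
        "effects": [
            {
                "target_factor": e.target_factor,
                "effect_size": e.effect_size,
                "center_frac": list(e.center_frac),
                "n_voxels": e.n_voxels,
            }
            for e in config.effects
        ],
        "baseline_value": config.baseline_value,
        "follow_up_years_range": list(config.follow_up_years_range),
        "seed": config.seed,
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def config_from_yaml(path) -> SyntheticConfig:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    try:
        return SyntheticConfig(
            grid_shape=tuple(doc["grid_shape"]),
            voxel_size_mm=tuple(doc["voxel_size_mm"]),
            sites=tuple(SiteProfile(**s) for s in doc["sites"]),
            per_site_counts={
                (c["site"], c["sex"], c["course"]): int(c["count"])
                for c in doc["per_site_counts"]
            },
            effects=tuple(
                EffectMap(
                    target_factor=e["target_factor"],
                    effect_size=float(e["effect_size"]),
                    center_frac=tuple(e["center_frac"]),
                    n_voxels=int(e["n_voxels"]),
                )
                for e in doc["effects"]
            ),
            baseline_value=doc.get("baseline_value"),
            follow_up_years_range=tuple(doc.get("follow_up_years_range", (3.0, 7.0))),
            seed=int(doc.get("seed", 0)),
        )
    except (KeyError, TypeError) as exc:
        raise SimulationError(f"malformed simulation config {path}: {exc}") from exc
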