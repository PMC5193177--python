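"""Experiment configuration, pipeline driver, and report generation.

An :class:`ExperimentConfig` captures everything needed to reproduce one
classification experiment — task (sex or illness course), scope (pooled
multi-site or one site), preprocessing parameters, resampling sizes, and
the master seed.  :func:`run_experiment` executes the full pipeline on a
fixture directory (NIfTI volumes + metadata TSV) and writes:

``report.json``
    mean and per-site metrics, permutation p-value (if requested), and an
    embedded copy of the configuration; byte-identical across re-runs of
    the same configuration;
``report.tsv``
    a flat per-site metrics table (per-class accuracies for the sex task,
    PPA/NPA for the outcome task), one row per site plus an overall row;
``decision_values.tsv``
    per-subject mean decision values for decision-boundary plots;
``manifest.json``
    configuration hash, seed, and software versions.
"""

from __future__ import annotations

import hashlib
import json
import shutil
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import imaging
from .classifier import DEFAULT_C_GRID, DEFAULT_INNER_FOLDS
from .cohort import Cohort, label_cohort, read_metadata, select_outcome_cohort, write_metadata
from .evaluation import bootstrap_ensemble, permutation_test
from .simulate import config_to_yaml, generate_cohort, preset_config

FIXTURE_PRESETS = ("roster", "tiny", "null")


class ExperimentError(RuntimeError):
    pass


@dataclass(frozen=True)
class ExperimentConfig:
    task: str = "sex"  # "sex" | "outcome"
    scope: str = "multi_site"  # "multi_site" or a site label
    males_only: bool = False
    mask_threshold: float = imaging.DEFAULT_MASK_THRESHOLD
    mask_rule: str = "mean"
    smooth_fwhm_mm: float = imaging.DEFAULT_FWHM_MM
    n_bootstraps: int = 100
    n_permutations: int = 1000
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    inner_folds: int = DEFAULT_INNER_FOLDS
    seed: int = 0
    input_dir: str = "."
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.task not in ("sex", "outcome"):
            raise ExperimentError(f"unknown task {self.task!r}")
        object.__setattr__(self, "c_grid", tuple(float(c) for c in self.c_grid))

    @property
    def class_field(self) -> str:
        return "sex" if self.task == "sex" else "course_label"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["c_grid"] = list(self.c_grid)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path, **overrides) -> "ExperimentConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        doc.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**doc)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def make_fixture(out_dir, preset: str = "tiny", seed: int = 0) -> Path:
    """Write a synthetic fixture: volumes, metadata TSV, simulation YAML.

    ``roster`` reproduces the five-center demographic roster (389
    subjects); ``tiny`` is a 40-subject two-site cohort for fast runs;
    ``null`` is the tiny layout with all effect sizes 0.
    """
    if preset not in FIXTURE_PRESETS:
        raise ExperimentError(f"unknown preset {preset!r}; choose from {FIXTURE_PRESETS}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = preset_config(preset, seed=seed)
    maps, cohort = generate_cohort(config)
    for gm, subject in zip(maps, cohort):
        imaging.write_volume(gm, out / f"{subject.subject_id}.nii.gz")
    write_metadata(cohort, out / "metadata.tsv")
    config_to_yaml(config, out / "simulation.yaml")
    return out


def load_fixture(input_dir) -> tuple[list, Cohort]:
    """Read a fixture directory (metadata.tsv + one NIfTI per subject)."""
    input_dir = Path(input_dir)
    meta = input_dir / "metadata.tsv"
    if not meta.exists():
        raise ExperimentError(f"no metadata.tsv in {input_dir}")
    cohort = read_metadata(meta)
    maps = []
    for s in cohort:
        vol = input_dir / f"{s.subject_id}.nii.gz"
        if not vol.exists():
            vol = input_dir / f"{s.subject_id}.nii"
        if not vol.exists():
            raise ExperimentError(f"no volume for subject {s.subject_id} in {input_dir}")
        maps.append(imaging.read_volume(vol))
    return maps, cohort


def _software_versions() -> dict:
    import nibabel
    import scipy
    import sklearn

    from . import __version__

    return {
        "gmpredict": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
        "nibabel": nibabel.__version__,
        "pandas": pd.__version__,
    }


def _report_table(per_site: dict, task: str, sites: Sequence[str]) -> pd.DataFrame:
    rows = []
    for site in list(sites) + ["overall"]:
        m = per_site.get(site, {})

        def pct(key):
            v = m.get(key)
            return "" if v is None else f"{100 * v:.1f}"

        if task == "sex":
            rows.append(
                {"site": site, "male_pct": pct("pos_class_accuracy"),
                 "female_pct": pct("neg_class_accuracy")}
            )
        else:
            rows.append({"site": site, "ppa_pct": pct("ppa"), "npa_pct": pct("npa")})
    return pd.DataFrame(rows)


def _decision_table(ensemble) -> pd.DataFrame:
    frames = []
    for r in ensemble.per_bootstrap:
        t = r.per_subject[r.per_subject.times_tested > 0]
        frames.append(t[["subject_id", "site", "true_label", "decision_value"]])
    allt = pd.concat(frames, ignore_index=True)
    out = (
        allt.groupby(["subject_id", "site", "true_label"], as_index=False)
        .agg(mean_decision_value=("decision_value", "mean"), n_tested=("decision_value", "size"))
        .sort_values("subject_id", kind="stable")
        .reset_index(drop=True)
    )
    return out


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute generate/load -> label -> preprocess -> evaluate -> report.

    Any stage failure aborts with a stage-named message and removes the
    partially written output directory.
    """
    out_dir = Path(config.output_dir)
    created = not out_dir.exists()
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        maps, cohort = load_fixture(config.input_dir)

        stage = "label"
        cohort = label_cohort(cohort)
        if config.task == "outcome":
            selected = select_outcome_cohort(cohort, males_only=config.males_only)
        else:
            selected = cohort
            if config.males_only:
                raise ExperimentError("males_only applies to the outcome task")
        if config.scope != "multi_site":
            keep = [i for i, s in enumerate(selected) if s.site == config.scope]
            if not keep:
                raise ExperimentError(f"no subjects at site {config.scope!r}")
            selected = selected.subset(keep)

        stage = "preprocess"
        row_of = cohort.row_index()
        sel_maps = [maps[row_of[s.subject_id]] for s in selected]
        features = imaging.preprocess(
            sel_maps,
            selected,
            fwhm_mm=config.smooth_fwhm_mm,
            threshold=config.mask_threshold,
            rule=config.mask_rule,
        )

        stage = "evaluate"
        ensemble = bootstrap_ensemble(
            selected,
            features,
            config.class_field,
            n_bootstraps=config.n_bootstraps,
            seed=config.seed,
            c_grid=config.c_grid,
            inner_folds=config.inner_folds,
        )
        perm = None
        if config.n_permutations > 0:
            perm = permutation_test(
                selected,
                features,
                config.class_field,
                n_permutations=config.n_permutations,
                seed=config.seed,
                n_bootstraps=config.n_bootstraps,
                c_grid=config.c_grid,
                inner_folds=config.inner_folds,
            )

        stage = "report"
        report = {
            "config": self_config_dict(config),
            "n_subjects": len(selected),
            "n_features": features.mask.n_features,
            "class_labels": list(ensemble.class_labels),
            "mean_metrics": ensemble.mean_metrics,
            "per_site": ensemble.per_site,
        }
        if perm is not None:
            report["permutation"] = {
                "metric": perm.metric,
                "observed": perm.observed,
                "p_value": perm.p_value,
                "n_permutations": config.n_permutations,
            }
        (out_dir / "report.json").write_text(
            json.dumps(report, sort_keys=True, indent=1) + "\n", encoding="utf-8"
        )
        _report_table(ensemble.per_site, config.task, selected.sites).to_csv(
            out_dir / "report.tsv", sep="\t", index=False
        )
        _decision_table(ensemble).to_csv(out_dir / "decision_values.tsv", sep="\t", index=False)
        manifest = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "software": _software_versions(),
        }
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, sort_keys=True, indent=1) + "\n", encoding="utf-8"
        )
        return report
    except Exception as exc:
        if created:
            shutil.rmtree(out_dir, ignore_errors=True)
        else:
            for name in ("report.json", "report.tsv", "decision_values.tsv", "manifest.json"):
                (out_dir / name).unlink(missing_ok=True)
        raise ExperimentError(f"stage {stage!r} failed: {exc}") from exc


def self_config_dict(config: ExperimentConfig) -> dict:
    d = config.to_dict()
    # paths are environment-specific; the hash covers the scientific settings
    d["input_dir"] = str(d["input_dir"])
    d["output_dir"] = str(d["output_dir"])
    return d
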