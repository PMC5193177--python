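"""Volume-level preprocessing of gray-matter probability maps.

Input volumes are modulated, spatially normalized gray-matter probability
maps on a shared grid (segmentation and normalization happen upstream).
This module implements the three steps between those maps and the
classifier: Gaussian smoothing, group-level gray-matter masking, and
flattening masked volumes into a subjects x voxels feature matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import nibabel as nib
from scipy import ndimage

from .cohort import Cohort

#: FWHM of a Gaussian = sigma * 2 sqrt(2 ln 2)
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

#: Gray-matter probability below which a voxel is excluded from analysis.
DEFAULT_MASK_THRESHOLD = 0.03

#: Default smoothing kernel width in mm.
DEFAULT_FWHM_MM = 4.0


class ImagingError(ValueError):
    pass


@dataclass(frozen=True)
class GrayMatterMap:
    """A 3D gray-matter probability volume with isotropic-or-not voxel size."""

    values: np.ndarray
    voxel_size_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 3:
            raise ImagingError(f"expected a 3D volume, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ImagingError("volume contains non-finite values")
        object.__setattr__(self, "values", v)
        vs = tuple(float(x) for x in self.voxel_size_mm)
        if len(vs) != 3 or any(x <= 0 for x in vs):
            raise ImagingError(f"voxel_size_mm must be 3 positive reals, got {vs}")
        object.__setattr__(self, "voxel_size_mm", vs)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass(frozen=True)
class VoxelMask:
    """Boolean inclusion mask defining the shared feature space."""

    include: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        inc = np.asarray(self.include, dtype=bool)
        object.__setattr__(self, "include", inc)
        if not 0.0 <= self.threshold <= 1.0:
            raise ImagingError(f"threshold must be in [0, 1], got {self.threshold}")

    @property
    def n_features(self) -> int:
        return int(self.include.sum())


@dataclass(frozen=True)
class FeatureMatrix:
    """Subjects x masked-voxels matrix of gray-matter probabilities.

    Row i holds the masked voxels of subject i in the cohort order used at
    extraction time; columns follow row-major (C-order) voxel order so that
    weight vectors can be folded back into volumes reproducibly.
    """

    values: np.ndarray
    subject_ids: tuple[str, ...]
    mask: VoxelMask

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))
        if v.ndim != 2 or v.shape[0] != len(self.subject_ids):
            raise ImagingError("feature matrix rows must match subject ids")
        if v.shape[1] != self.mask.n_features:
            raise ImagingError("feature matrix columns must match mask.n_features")

    def rows_for(self, cohort: Cohort) -> np.ndarray:
        """Row indices of the given cohort's subjects, in cohort order."""
        pos = {sid: i for i, sid in enumerate(self.subject_ids)}
        try:
            return np.array([pos[s.subject_id] for s in cohort], dtype=int)
        except KeyError as exc:
            raise ImagingError(f"subject {exc} has no feature row") from exc


def fwhm_to_sigma_voxels(fwhm_mm: float, voxel_size_mm: Sequence[float]) -> np.ndarray:
    """Per-axis Gaussian sigma in voxel units for a kernel width in mm."""
    return np.asarray([fwhm_mm / (vs * FWHM_PER_SIGMA) for vs in voxel_size_mm])


def smooth(gm: GrayMatterMap, fwhm_mm: float, clip: bool = True) -> GrayMatterMap:
    """Separable Gaussian smoothing with reflect (mirror) boundary padding.

    ``fwhm_mm = 0`` is the identity.  Reflect padding keeps mass in the
    field of view near edges, the standard choice for neuroimaging
    smoothers.  Clipping to [0, 1] (on by default) keeps the output a valid
    probability map; pass ``clip=False`` to study the raw linear operator.
    """
    if fwhm_mm < 0:
        raise ImagingError(f"fwhm_mm must be nonnegative, got {fwhm_mm}")
    if fwhm_mm == 0:
        return gm
    sigma = fwhm_to_sigma_voxels(fwhm_mm, gm.voxel_size_mm)
    out = ndimage.gaussian_filter(gm.values, sigma=sigma, mode="reflect")
    if clip:
        out = np.clip(out, 0.0, 1.0)
    return GrayMatterMap(out, gm.voxel_size_mm)


def build_mask(
    maps: Sequence[GrayMatterMap],
    threshold: float = DEFAULT_MASK_THRESHOLD,
    rule: str = "mean",
) -> VoxelMask:
    """Group-level gray-matter mask: one shared feature space for the cohort.

    ``rule="mean"`` (default): a voxel is included iff the cohort-mean
    probability is at least ``threshold``.  ``rule="all"``: included iff
    every subject reaches ``threshold`` at that voxel.  A single shared
    mask is required so that every subject maps onto the same feature
    vector.
    """
    if len(maps) == 0:
        raise ImagingError("need at least one map to build a mask")
    shape = maps[0].grid_shape
    for m in maps:
        if m.grid_shape != shape:
            raise ImagingError(f"mixed grid shapes: {m.grid_shape} vs {shape}")
    if rule == "mean":
        agg = np.mean([m.values for m in maps], axis=0)
    elif rule == "all":
        agg = np.min([m.values for m in maps], axis=0)
    else:
        raise ImagingError(f"unknown mask rule {rule!r}")
    return VoxelMask(include=agg >= threshold, threshold=threshold)


def extract_features(
    maps: Sequence[GrayMatterMap], mask: VoxelMask, cohort: Cohort
) -> FeatureMatrix:
    """Flatten masked voxels into a feature matrix aligned with the cohort.

    Row i corresponds to ``cohort[i]``; columns follow C-order (row-major)
    voxel indexing, fixed so trained weight maps are reproducible.
    """
    if len(maps) != len(cohort):
        raise ImagingError(f"{len(maps)} maps for {len(cohort)} subjects")
    for m in maps:
        if m.grid_shape != mask.include.shape:
            raise ImagingError("map grid does not match mask grid")
    values = np.empty((len(maps), mask.n_features), dtype=np.float64)
    for i, m in enumerate(maps):
        values[i] = m.values[mask.include]  # boolean indexing is C-ordered
    return FeatureMatrix(values, tuple(s.subject_id for s in cohort), mask)


def preprocess(
    maps: Sequence[GrayMatterMap],
    cohort: Cohort,
    fwhm_mm: float = DEFAULT_FWHM_MM,
    threshold: float = DEFAULT_MASK_THRESHOLD,
    rule: str = "mean",
) -> FeatureMatrix:
    """Smooth, mask, and flatten a cohort's volumes into features.

    Smoothing precedes mask construction, so the mask reflects the
    probabilities actually fed to the classifier.
    """
    smoothed = [smooth(m, fwhm_mm) for m in maps]
    mask = build_mask(smoothed, threshold=threshold, rule=rule)
    return extract_features(smoothed, mask, cohort)


# ---------------------------------------------------------------------------
# NIfTI I/O


def write_volume(gm: GrayMatterMap, path) -> None:
    affine = np.diag([*gm.voxel_size_mm, 1.0])
    nib.save(nib.Nifti1Image(gm.values.astype(np.float32), affine), str(path))


def read_volume(path) -> GrayMatterMap:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return GrayMatterMap(data, voxel_size)


def write_mask(mask: VoxelMask, voxel_size_mm: Sequence[float], path) -> None:
    affine = np.diag([*voxel_size_mm, 1.0])
    nib.save(nib.Nifti1Image(mask.include.astype(np.uint8), affine), str(path))


def read_mask(path, threshold: float) -> VoxelMask:
    img = nib.load(str(path))
    return VoxelMask(include=np.asarray(img.get_fdata()) > 0.5, threshold=threshold)


def write_features_tsv(features: FeatureMatrix, path) -> None:
    """Flat TSV export (subject_id + one column per masked voxel)."""
    import pandas as pd

    df = pd.DataFrame(features.values, columns=[f"v{j}" for j in range(features.values.shape[1])])
    df.insert(0, "subject_id", list(features.subject_ids))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
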