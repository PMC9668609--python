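"""Lesion mapping: z-map thresholding, %RL, whole-brain and group maps.

Per-voxel z-scores from the normative manifold are thresholded at a
Bonferroni-adjusted normal quantile (about +/-4.8 SD for a ~31,500-voxel
family at alpha = 0.05). Deviant-voxel masks give the relative lesion
percentage (%RL = deviant voxels / tract voxels) per tract and patient, are
merged across bundles into whole-brain maps, and aggregated into group
lesion-probability maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .manifold import AnomalyResult


@dataclass
class LesionMap:
    """Binary deviance mask for one tract (or merged whole brain)."""

    tract_label: str
    voxel_index: np.ndarray          # (V, 3)
    deviant_mask: np.ndarray         # (V,) bool
    z_threshold: float
    direction: str                   # 'two-sided' | 'negative'
    z_scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.deviant_mask = np.asarray(self.deviant_mask, dtype=bool)
        if self.deviant_mask.shape[0] != self.voxel_index.shape[0]:
            raise ValueError("mask must align with voxel index")

    @property
    def n_deviant(self) -> int:
        return int(self.deviant_mask.sum())

    @property
    def rl_percent(self) -> float:
        return relative_lesion_percent(self.n_deviant, self.deviant_mask.shape[0])


@dataclass
class GroupProbabilityMap:
    """Per-voxel fraction of patients deviant, on the template grid."""

    grid: np.ndarray
    n_patients: int

    def __post_init__(self) -> None:
        if self.grid.size and (self.grid.min() < 0 or self.grid.max() > 1):
            raise ValueError("probabilities must lie in [0, 1]")


def bonferroni_z_threshold(n_voxels: int, family_alpha: float = 0.05) -> float:
    """Two-sided Bonferroni-adjusted z threshold over a voxel family.

    z* = Phi^-1 survival quantile at (alpha/2)/n. For ~31,500 voxels at
    alpha = 0.05 this is about 4.80 SD.
    """
    if n_voxels < 1:
        raise ValueError("n_voxels must be >= 1")
    return float(norm.isf(family_alpha / 2.0 / n_voxels))


def threshold_zmap(anomaly: AnomalyResult, z_star: float,
                   direction: str = "two-sided") -> LesionMap:
    """Flag voxels whose z exceeds the adjusted threshold.

    'two-sided' flags |z| > z*; 'negative' flags only z < -z* (the
    decrease-only display mode for metrics where damage lowers the value).
    """
    if z_star <= 0:
        raise ValueError("z_star must be positive")
    z = anomaly.z_scores
    if direction == "two-sided":
        mask = np.abs(z) > z_star
    elif direction == "negative":
        mask = z < -z_star
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return LesionMap(
        tract_label=anomaly.tract_label,
        voxel_index=anomaly.voxel_index,
        deviant_mask=mask,
        z_threshold=z_star,
        direction=direction,
        z_scores=z,
    )


def relative_lesion_percent(deviant_count: int, total_count: int) -> float:
    """%RL = 100 x deviant voxels / tract voxels, reported to 2 decimals."""
    if total_count <= 0:
        raise ValueError("total voxel count must be positive")
    if deviant_count > total_count:
        raise ValueError("deviant count exceeds total count")
    return round(100.0 * deviant_count / total_count, 2)


def merge_tract_maps(maps: list[LesionMap], template_shape: tuple[int, int, int]) -> LesionMap:
    """Union of per-tract deviance masks on the template grid.

    A voxel is deviant if deviant in ANY overlapping tract; the stored z is
    the signed maximum-|z| across the tracts covering the voxel.
    """
    if not maps:
        raise ValueError("no tract maps to merge")
    shape = tuple(template_shape)
    deviant = np.zeros(shape, dtype=bool)
    best_z = np.zeros(shape, dtype=float)
    covered = np.zeros(shape, dtype=bool)
    for m in maps:
        if np.any(m.voxel_index.max(axis=0) >= np.array(shape)) or np.any(m.voxel_index < 0):
            raise ValueError(f"{m.tract_label}: voxel index outside template grid {shape}")
        i, j, k = m.voxel_index.T
        deviant[i, j, k] |= m.deviant_mask
        if m.z_scores is not None:
            cur = best_z[i, j, k]
            z = m.z_scores
            take = ~covered[i, j, k] | (np.abs(z) > np.abs(cur))
            new = np.where(take, z, cur)
            best_z[i, j, k] = new
        covered[i, j, k] = True
    idx = np.argwhere(covered)
    return LesionMap(
        tract_label="wholebrain",
        voxel_index=idx,
        deviant_mask=deviant[idx[:, 0], idx[:, 1], idx[:, 2]],
        z_threshold=maps[0].z_threshold,
        direction=maps[0].direction,
        z_scores=best_z[idx[:, 0], idx[:, 1], idx[:, 2]],
    )


def group_probability_map(wholebrain_maps: list[LesionMap],
                          template_shape: tuple[int, int, int]) -> GroupProbabilityMap:
    """Per-voxel fraction of patients deviant across individual maps."""
    if not wholebrain_maps:
        raise ValueError("need at least one patient map")
    shape = tuple(template_shape)
    acc = np.zeros(shape, dtype=float)
    for m in wholebrain_maps:
        i, j, k = m.voxel_index.T
        acc[i, j, k] += m.deviant_mask.astype(float)
    return GroupProbabilityMap(grid=acc / len(wholebrain_maps),
                               n_patients=len(wholebrain_maps))


def export_nifti(grid: np.ndarray, affine: np.ndarray, path) -> None:
    """Write a scalar template-grid map as NIfTI-1."""
    import nibabel as nib

    nib.save(nib.Nifti1Image(np.asarray(grid, dtype=np.float32), affine), str(path))
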