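"""From voxelwise score maps to anatomical findings.

Connected supra-threshold clusters with sizes (voxels and mm^3), peak
world coordinates and a direction-of-effect test on subject cluster-mean
GM; plus brain-behaviour association tables (Pearson r of region GM
against behavioural factor scores and severity).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .simulate import FACTOR_NAMES, SubjectPhenotype
from .volumes import CASE_LABEL, CONTROL_LABEL, VoxelMatrix

__all__ = [
    "Cluster",
    "AssociationResult",
    "extract_clusters",
    "cluster_volume_mm3",
    "cluster_peak",
    "direction_of_effect",
    "subject_cluster_means",
    "cluster_table",
    "association_table",
    "severity_correlation",
]


@dataclass
class Cluster:
    """A connected component of supra-threshold voxels."""

    id: int
    member_voxels: np.ndarray  # (n, 3) grid coordinates
    n_voxels: int
    volume_mm3: float
    peak_voxel: tuple[int, int, int]
    peak_world: tuple[float, float, float]
    direction: str | None = None  # "case>control" / "control>case"
    direction_p: float | None = None


@dataclass(frozen=True)
class AssociationResult:
    region: str
    measure: str
    r: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("Pearson correlation needs n >= 3")


def cluster_volume_mm3(
    n_voxels: int, voxel_size_mm: Sequence[float]
) -> float:
    """Cluster volume: voxel count times the voxel volume (8 mm^3 on a
    2 mm isotropic grid)."""
    if n_voxels <= 0:
        raise ValueError("n_voxels must be positive")
    size = np.asarray(voxel_size_mm, dtype=float)
    if np.any(size <= 0):
        raise ValueError("voxel dimensions must be positive")
    return float(n_voxels * np.prod(size))


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 18:
        return ndimage.generate_binary_structure(3, 2)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError("connectivity must be 6, 18 or 26")


def cluster_peak(
    member_voxels: np.ndarray, stat_volume: np.ndarray, affine: np.ndarray
) -> tuple[tuple[int, int, int], tuple[float, float, float]]:
    """Member voxel with maximal |stat| and its world-mm coordinates.

    Ties go to the earliest voxel in scan order (members are produced in
    row-major order by extraction).
    """
    member_voxels = np.asarray(member_voxels)
    if len(member_voxels) == 0:
        raise ValueError("cluster has no member voxels")
    vals = np.abs(stat_volume[tuple(member_voxels.T)])
    best = member_voxels[int(np.argmax(vals))]
    world = (np.asarray(affine) @ np.r_[best, 1.0])[:3]
    return tuple(int(v) for v in best), tuple(float(v) for v in world)


def extract_clusters(
    score_volume: np.ndarray,
    threshold: float,
    affine: np.ndarray,
    connectivity: int = 26,
    min_size: int = 10,
    stat_volume: np.ndarray | None = None,
) -> list[Cluster]:
    """Connected components of voxels with score >= threshold.

    NaN marks unscored voxels and never enters a cluster.  Components
    smaller than ``min_size`` are dropped; the result is sorted by size,
    largest first.  Peaks are located on ``stat_volume`` when given
    (e.g. the group-difference map, which is sharply peaked) and on the
    score map itself otherwise — importance ratios plateau inside a
    discriminative region, so their argmax is a poor peak estimate.
    """
    score = np.asarray(score_volume, dtype=float)
    peak_stat = (
        score if stat_volume is None else np.asarray(stat_volume, dtype=float)
    )
    supra = np.where(np.isnan(score), False, score >= threshold)
    if not supra.any():
        return []
    labelled, n_comp = ndimage.label(
        supra, structure=_connectivity_structure(connectivity)
    )
    voxel_size = np.sqrt((np.asarray(affine)[:3, :3] ** 2).sum(axis=0))
    clusters: list[Cluster] = []
    for comp in range(1, n_comp + 1):
        members = np.argwhere(labelled == comp)
        if len(members) < min_size:
            continue
        peak_vox, peak_world = cluster_peak(
            members, np.nan_to_num(peak_stat), affine
        )
        clusters.append(
            Cluster(
                id=0,  # assigned after sorting
                member_voxels=members,
                n_voxels=len(members),
                volume_mm3=cluster_volume_mm3(len(members), voxel_size),
                peak_voxel=peak_vox,
                peak_world=peak_world,
            )
        )
    clusters.sort(key=lambda c: -c.n_voxels)
    for i, c in enumerate(clusters):
        c.id = i + 1
    return clusters


def subject_cluster_means(
    matrix: VoxelMatrix, cluster: Cluster
) -> np.ndarray:
    """Per-subject mean GM over the cluster's member voxels.

    The mean (not the sum) makes values comparable across cluster sizes.
    Member voxels outside the matrix mask are ignored.
    """
    grid_cols = -np.ones(matrix.grid_shape, dtype=np.intp)
    i, j, k = matrix.voxel_index.T
    grid_cols[i, j, k] = np.arange(matrix.n_voxels)
    cols = grid_cols[tuple(cluster.member_voxels.T)]
    cols = cols[cols >= 0]
    if len(cols) == 0:
        raise ValueError("cluster has no voxels inside the analysis mask")
    return matrix.values[:, cols].mean(axis=1)


def direction_of_effect(
    cluster_means: np.ndarray, labels: np.ndarray
) -> tuple[str, float]:
    """Which group has larger GM in a region, with a Welch two-sample t.

    Returns (direction, two-sided p); direction is the sign of
    mean(case) − mean(control).
    """
    labels = np.asarray(labels)
    case_vals = cluster_means[labels == CASE_LABEL]
    control_vals = cluster_means[labels == CONTROL_LABEL]
    if len(case_vals) < 2 or len(control_vals) < 2:
        raise ValueError("need >= 2 subjects per class for the direction test")
    direction = (
        "case>control"
        if case_vals.mean() > control_vals.mean()
        else "control>case"
    )
    t = stats.ttest_ind(case_vals, control_vals, equal_var=False)
    return direction, float(t.pvalue)


def cluster_table(
    clusters: Sequence[Cluster],
    matrix: VoxelMatrix | None = None,
) -> pd.DataFrame:
    """Cluster report: peak mm coordinates, sizes, direction of effect.

    When ``matrix`` is given, each cluster also gets a direction test on
    subject cluster-mean GM.
    """
    rows = []
    for c in clusters:
        direction, p = c.direction, c.direction_p
        if matrix is not None:
            means = subject_cluster_means(matrix, c)
            direction, p = direction_of_effect(means, matrix.labels)
            c.direction, c.direction_p = direction, p
        rows.append(
            {
                "cluster_id": c.id,
                "peak_x_mm": c.peak_world[0],
                "peak_y_mm": c.peak_world[1],
                "peak_z_mm": c.peak_world[2],
                "volume_mm3": c.volume_mm3,
                "n_voxels": c.n_voxels,
                "direction": direction,
                "direction_p": p,
            }
        )
    return pd.DataFrame(rows)


def association_table(
    region_means: dict[str, np.ndarray],
    phenotypes: Sequence[SubjectPhenotype] | pd.DataFrame,
) -> list[AssociationResult]:
    """Pearson correlations of region GM with the five behavioural factor
    scores and severity, uncorrected two-sided p per pair."""
    if not isinstance(phenotypes, pd.DataFrame):
        from .simulate import phenotypes_to_frame

        phenotypes = phenotypes_to_frame(phenotypes)
    measures = list(FACTOR_NAMES) + ["severity"]
    results: list[AssociationResult] = []
    for region, means in region_means.items():
        means = np.asarray(means, dtype=float)
        if len(means) != len(phenotypes):
            raise ValueError(
                f"region '{region}' has {len(means)} subjects but the "
                f"phenotype table has {len(phenotypes)}"
            )
        for measure in measures:
            y = phenotypes[measure].to_numpy(dtype=float)
            r, p = stats.pearsonr(means, y)
            results.append(
                AssociationResult(
                    region=region,
                    measure=measure,
                    r=float(r),
                    p=float(p),
                    n=len(means),
                )
            )
    return results


def association_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "region": a.region,
                "measure": a.measure,
                "r": a.r,
                "p": a.p,
                "n": a.n,
            }
            for a in results
        ]
    )


def severity_correlation(
    classifier_severity: np.ndarray, behavioural_severity: np.ndarray
) -> AssociationResult:
    """Correlation between classification-certainty severity and the
    behavioural severity score."""
    x = np.asarray(classifier_severity, dtype=float)
    y = np.asarray(behavioural_severity, dtype=float)
    if x.shape != y.shape:
        raise ValueError("severity vectors must align")
    r, p = stats.pearsonr(x, y)
    return AssociationResult(
        region="classifier", measure="severity", r=float(r), p=float(p), n=len(x)
    )
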