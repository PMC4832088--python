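"""Synthetic cohorts of smoothed gray-matter-like volumes with planted effects.

The generator is the ground-truth test bed for the classification pipeline.
It emulates the statistical structure of modulated, smoothed GM
partial-volume maps on a common 2 mm grid: a smooth shared template texture,
spherical group-effect clusters of either sign (case > control or
control > case), per-subject Gaussian noise, and Gaussian smoothing of the
final image.  Alongside each volume it generates a behavioural phenotype:
a continuous severity score driven by the subject's planted effect "dose",
and five standardized factor scores (spelling, phonology, short-term memory,
visual/attentional confusion, whole-word reading) whose correlations with
cluster GM mirror the sign structure seen in the study population —
spelling and phonology tied positively to the control>case cluster,
whole-word reading tied negatively to a case>control cluster, and the two
remaining factors independent of the brain.

It makes no attempt at realistic anatomy: the template is smooth synthetic
texture, not a brain atlas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import CASE_LABEL, CONTROL_LABEL, GMVolume

__all__ = [
    "ClusterSpec",
    "CohortConfig",
    "SubjectPhenotype",
    "FACTOR_NAMES",
    "generate_cohort",
    "smooth_volume",
    "default_clusters",
    "write_cohort",
    "phenotypes_to_frame",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: The five behavioural factor scores, in canonical column order.
FACTOR_NAMES = (
    "spelling",
    "phonology",
    "stm",
    "visual_attentional",
    "whole_word_reading",
)


@dataclass(frozen=True)
class ClusterSpec:
    """A spherical planted group-effect.

    amplitude > 0 means the case group has larger GM inside the sphere;
    amplitude < 0 means the control group is larger.
    """

    center: tuple[int, int, int]
    radius: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("cluster radius must be >= 1 voxel")
        if self.amplitude == 0:
            raise ValueError("cluster amplitude must be nonzero")

    def support(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        """Boolean mask of the hard-sphere support on the grid."""
        lo = np.array(self.center) - self.radius
        hi = np.array(self.center) + self.radius
        if np.any(lo < 0) or np.any(hi > np.array(grid_shape) - 1):
            raise ValueError(
                f"cluster at {self.center} radius {self.radius} exceeds "
                f"grid {grid_shape}"
            )
        grids = np.ogrid[tuple(slice(0, s) for s in grid_shape)]
        dist2 = sum((g - c) ** 2 for g, c in zip(grids, self.center))
        return dist2 <= self.radius**2


@dataclass
class CohortConfig:
    """Study-condition parameters for one synthetic cohort.

    Defaults reproduce the study's design: 22 cases vs 27 controls on a
    2 mm isotropic grid, images smoothed with a 4 mm FWHM Gaussian kernel.
    The 32^3 grid keeps simulation fast while leaving room for well
    separated clusters.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    n_cases: int = 22
    n_controls: int = 27
    clusters: list[ClusterSpec] = field(default_factory=list)
    subject_noise_sd: float = 0.1
    smoothing_fwhm_mm: float = 4.0
    dose_sd: float = 0.3
    effect_scale: float = 1.0  # 0 gives an exact null cohort
    template_mean: float = 0.5
    template_texture_sd: float = 0.08
    severity_noise_sd: float = 0.2
    factor_signal: float = 0.33  # slope of factor on standardized cluster GM
    factor_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 2 or self.n_controls < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.subject_noise_sd <= 0:
            raise ValueError("subject_noise_sd must be > 0")
        if self.smoothing_fwhm_mm < 0:
            raise ValueError("smoothing_fwhm_mm must be >= 0")

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size_mm) + [1.0])
        # centre the grid on the world origin, MNI-style negative offsets
        aff[:3, 3] = -0.5 * np.array(self.grid_shape) * np.array(
            self.voxel_size_mm
        )
        return aff


@dataclass
class SubjectPhenotype:
    """Behavioural phenotype paired with one synthetic volume."""

    subject_id: str
    label: str
    severity: float
    factors: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.factors) != set(FACTOR_NAMES):
            raise ValueError(
                f"expected factors {FACTOR_NAMES}, got {tuple(self.factors)}"
            )
        if not np.isfinite(self.severity):
            raise ValueError("severity must be finite")


def default_clusters(
    grid_shape: tuple[int, int, int] = (32, 32, 32),
    amplitude: float = 0.08,
) -> list[ClusterSpec]:
    """Three planted clusters mirroring the study's reported effect layout:
    two case>control spheres and one smaller control>case sphere.

    Sizes (radius 3.3, 3.5, 2.5 voxels -> roughly 150, 180, 65 voxels)
    echo the reported cluster extents on a 2 mm grid.
    """
    sx, sy, sz = grid_shape
    q = lambda fx, fy, fz: (int(sx * fx), int(sy * fy), int(sz * fz))
    return [
        ClusterSpec(center=q(0.30, 0.30, 0.35), radius=3.3, amplitude=amplitude),
        ClusterSpec(center=q(0.70, 0.30, 0.35), radius=3.5, amplitude=amplitude),
        ClusterSpec(center=q(0.45, 0.70, 0.65), radius=2.5, amplitude=-amplitude),
    ]


def smooth_volume(
    volume: GMVolume, fwhm_mm: float | Sequence[float]
) -> GMVolume:
    """Gaussian-smooth a GM map.

    sigma per axis is ``fwhm / (2 sqrt(2 ln 2))`` converted from mm to
    voxels via the affine's voxel size.  Boundaries are handled by
    nearest-edge replication, which preserves the total image sum up to
    edge effects and avoids wrap-around artefacts.
    """
    fwhm = np.broadcast_to(np.asarray(fwhm_mm, dtype=float), (3,))
    if np.any(fwhm < 0):
        raise ValueError("fwhm must be >= 0")
    sigma_vox = fwhm * FWHM_TO_SIGMA / volume.voxel_size_mm
    if np.all(sigma_vox == 0):
        data = volume.data.copy()
    else:
        data = ndimage.gaussian_filter(volume.data, sigma=sigma_vox, mode="nearest")
    return GMVolume(data=data, affine=volume.affine.copy(), subject_id=volume.subject_id)


def _make_template(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Smooth synthetic texture shared by all subjects of a cohort."""
    rough = rng.normal(0.0, 1.0, size=config.grid_shape)
    texture = ndimage.gaussian_filter(rough, sigma=2.0, mode="nearest")
    sd = texture.std()
    if sd > 0:
        texture *= config.template_texture_sd / sd
    return np.clip(config.template_mean + texture, 0.0, None)


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[GMVolume], list[SubjectPhenotype]]:
    """Generate one cohort of volumes and phenotypes.

    Each subject's image is ``smooth(template + dose_i * effect * [case]
    + noise)`` clipped to be non-negative, where ``effect`` is the sum of
    the hard-sphere cluster fields and ``dose_i ~ Normal(1, dose_sd)``
    scales how strongly the planted effect is expressed in that subject.
    The same dose drives the behavioural severity score, so severity and
    anatomy share a common cause exactly as a severity-graded disorder
    would.  Fully deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    affine = config.affine
    template = _make_template(config, rng)

    effect = np.zeros(config.grid_shape)
    for spec in config.clusters:
        effect[spec.support(config.grid_shape)] += spec.amplitude
    effect *= config.effect_scale

    n_total = config.n_cases + config.n_controls
    labels = [CASE_LABEL] * config.n_cases + [CONTROL_LABEL] * config.n_controls
    doses = rng.normal(1.0, config.dose_sd, size=n_total)
    sigma_vox = (
        np.asarray([config.smoothing_fwhm_mm] * 3)
        * FWHM_TO_SIGMA
        / np.asarray(config.voxel_size_mm)
    )

    volumes: list[GMVolume] = []
    for i, label in enumerate(labels):
        raw = template + rng.normal(
            0.0, config.subject_noise_sd, size=config.grid_shape
        )
        if label == CASE_LABEL:
            raw = raw + doses[i] * effect
        if config.smoothing_fwhm_mm > 0:
            raw = ndimage.gaussian_filter(raw, sigma=sigma_vox, mode="nearest")
        raw = np.clip(raw, 0.0, None)
        prefix = "case" if label == CASE_LABEL else "ctrl"
        n_in_group = i if label == CASE_LABEL else i - config.n_cases
        volumes.append(
            GMVolume(
                data=raw,
                affine=affine.copy(),
                subject_id=f"{prefix}-{n_in_group:03d}",
            )
        )

    phenotypes = _make_phenotypes(config, rng, volumes, labels, doses)
    return volumes, phenotypes


def _cluster_means(
    volumes: Sequence[GMVolume],
    spec: ClusterSpec,
    grid_shape: tuple[int, int, int],
) -> np.ndarray:
    mask = spec.support(grid_shape)
    return np.array([v.data[mask].mean() for v in volumes])


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def _make_phenotypes(
    config: CohortConfig,
    rng: np.random.Generator,
    volumes: Sequence[GMVolume],
    labels: Sequence[str],
    doses: np.ndarray,
) -> list[SubjectPhenotype]:
    n = len(volumes)
    # severity: expressed dose for cases, baseline 0 for controls
    is_case = np.array([lab == CASE_LABEL for lab in labels], dtype=float)
    severity = doses * is_case + rng.normal(0.0, config.severity_noise_sd, size=n)

    negative = [c for c in config.clusters if c.amplitude < 0]
    positive = [c for c in config.clusters if c.amplitude > 0]
    neg_gm = (
        _standardize(_cluster_means(volumes, negative[0], config.grid_shape))
        if negative
        else np.zeros(n)
    )
    pos_gm = (
        _standardize(_cluster_means(volumes, positive[0], config.grid_shape))
        if positive
        else np.zeros(n)
    )

    b = config.factor_signal
    noise = lambda: rng.normal(0.0, config.factor_noise_sd, size=n)
    raw_factors = {
        "spelling": b * neg_gm + noise(),
        "phonology": b * neg_gm + noise(),
        "stm": noise(),
        "visual_attentional": noise(),
        "whole_word_reading": -b * pos_gm + noise(),
    }
    z_factors = {k: _standardize(v) for k, v in raw_factors.items()}

    return [
        SubjectPhenotype(
            subject_id=volumes[i].subject_id,
            label=labels[i],
            severity=float(severity[i]),
            factors={k: float(z_factors[k][i]) for k in FACTOR_NAMES},
        )
        for i in range(n)
    ]


def standardized_cluster_difference(
    volumes: Sequence[GMVolume],
    labels: Sequence[str],
    spec: ClusterSpec,
) -> float:
    """Cohen's d of the subject cluster-mean GM between groups.

    Diagnostic used to confirm that a planted amplitude produces the
    intended effect size after smoothing and noise.
    """
    means = _cluster_means(volumes, spec, volumes[0].data.shape)
    labels = np.asarray(labels)
    a = means[labels == CASE_LABEL]
    b = means[labels == CONTROL_LABEL]
    pooled = np.sqrt(
        ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
        / (len(a) + len(b) - 2)
    )
    return float((a.mean() - b.mean()) / pooled)


def phenotypes_to_frame(phenotypes: Sequence[SubjectPhenotype]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": p.subject_id,
            "label": p.label,
            "severity": p.severity,
            **{k: p.factors[k] for k in FACTOR_NAMES},
        }
        for p in phenotypes
    ]
    return pd.DataFrame(rows)


def write_cohort(
    volumes: Sequence[GMVolume],
    phenotypes: Sequence[SubjectPhenotype],
    out_dir: str | Path,
) -> Path:
    """Write volumes as .nii.gz plus a phenotype CSV into ``out_dir``."""
    from .volumes import write_gm_volume

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for v in volumes:
        write_gm_volume(v, out_dir / f"{v.subject_id}.nii.gz")
    phenotypes_to_frame(phenotypes).to_csv(
        out_dir / "subjects.csv", index=False
    )
    return out_dir
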