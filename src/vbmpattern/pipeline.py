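"""End-to-end orchestration of the analysis stages.

One YAML config drives: cohort simulation (optional, when no volumes are
supplied) -> matrix assembly -> repeated-CV classification -> performance
report (+ optional permutation test) -> subsampling importance ->
cluster extraction on the importance map -> brain-behaviour associations
-> optional external validation.  Every stage writes its artifacts into
the run directory and the run closes with a manifest (config echo, seed,
package versions, stage checksums) so a rerun with the same seed can be
verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clusters import (
    association_frame,
    association_table,
    cluster_table,
    extract_clusters,
    severity_correlation,
    subject_cluster_means,
)
from .importance import ImportanceConfig, importance_scores
from .model import CVConfig, PatternClassificationModel
from .selection import SelectionConfig
from .simulate import ClusterSpec, CohortConfig, default_clusters, write_cohort
from .volumes import read_gm_volume, write_mask

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_config", "run_full_analysis"]


@dataclass
class ClusterSettings:
    percentile: float = 99.0  # importance-ratio percentile for thresholding
    connectivity: int = 26
    min_size: int = 10


@dataclass
class PermutationSettings:
    n_permutations: int = 0  # 0 disables the stage
    iterations_per_perm: int | None = None


@dataclass
class RunConfig:
    """Aggregate configuration for one full run."""

    seed: int = 0
    volumes_dir: str | None = None  # None -> simulate a cohort
    subjects_csv: str | None = None
    mask_min_mean: float = 0.05
    cohort: CohortConfig = field(default_factory=CohortConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    importance: ImportanceConfig | None = field(default_factory=ImportanceConfig)
    permutation: PermutationSettings = field(default_factory=PermutationSettings)
    clusters: ClusterSettings = field(default_factory=ClusterSettings)


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from a YAML file with per-stage blocks.

    Unknown keys raise; omitted blocks fall back to the study defaults
    (z 4.25, 10,000 CV iterations, 20% subset fraction, 100,000
    importance iterations).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return build_config(raw)


def build_config(raw: dict) -> RunConfig:
    def sub(cls, block: dict | None, **extra):
        block = dict(block or {})
        block.update(extra)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(block) - known
        if unknown:
            raise ValueError(
                f"unknown {cls.__name__} keys: {sorted(unknown)}"
            )
        return cls(**block)

    seed = int(raw.get("seed", 0))
    cohort_block = dict(raw.get("cohort") or {})
    clusters_block = cohort_block.pop("clusters", None)
    for tuple_key in ("grid_shape", "voxel_size_mm"):
        if tuple_key in cohort_block:
            cohort_block[tuple_key] = tuple(cohort_block[tuple_key])
    cohort = sub(CohortConfig, cohort_block, seed=cohort_block.pop("seed", seed))
    if clusters_block is None:
        cohort.clusters = default_clusters(cohort.grid_shape)
    else:
        cohort.clusters = [
            ClusterSpec(
                center=tuple(c["center"]),
                radius=float(c["radius"]),
                amplitude=float(c["amplitude"]),
            )
            for c in clusters_block
        ]
    selection = sub(SelectionConfig, raw.get("selection"))
    cv_block = dict(raw.get("cv") or {})
    cv = sub(CVConfig, cv_block, selection=selection,
             seed=cv_block.pop("seed", seed))
    imp_block = raw.get("importance")
    if imp_block is False:
        importance = None
    else:
        imp_block = dict(imp_block or {})
        importance = sub(ImportanceConfig, imp_block,
                         seed=imp_block.pop("seed", seed))
    return RunConfig(
        seed=seed,
        volumes_dir=raw.get("volumes_dir"),
        subjects_csv=raw.get("subjects_csv"),
        mask_min_mean=float(raw.get("mask_min_mean", 0.05)),
        cohort=cohort,
        selection=selection,
        cv=cv,
        importance=importance,
        permutation=sub(PermutationSettings, raw.get("permutation")),
        clusters=sub(ClusterSettings, raw.get("clusters")),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_full_analysis(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute every configured stage into ``out_dir``; see module doc."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        if config.volumes_dir is None:
            logger.info("simulating cohort (%d cases, %d controls)",
                        config.cohort.n_cases, config.cohort.n_controls)
            from .simulate import generate_cohort

            volumes, phenotypes = generate_cohort(config.cohort)
            sim_dir = out_dir / "cohort"
            write_cohort(volumes, phenotypes, sim_dir)
            volumes_dir, subjects_csv = sim_dir, sim_dir / "subjects.csv"
        else:
            volumes_dir = Path(config.volumes_dir)
            subjects_csv = Path(config.subjects_csv)
            if not subjects_csv.exists():
                raise FileNotFoundError(
                    f"subject table not found: {subjects_csv}"
                )

        stage = "assemble"
        subjects = pd.read_csv(subjects_csv)
        model = PatternClassificationModel.from_directory(
            volumes_dir, subjects_csv, config.cv,
            mask_min_mean=config.mask_min_mean,
        )
        mask3d = np.zeros(model.matrix.grid_shape, dtype=bool)
        idx = model.matrix.voxel_index
        mask3d[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        write_mask(mask3d, model.matrix.affine, out_dir / "mask.nii.gz")

        stage = "cv"
        logger.info("repeated CV: %d iterations", config.cv.n_iterations)
        results = model.fit()
        results.iteration_records.to_csv(
            out_dir / "iteration_records.csv", index=False
        )
        results.subject_summaries.to_csv(
            out_dir / "subject_summaries.csv", index=False
        )

        stage = "performance"
        perf = results.performance()
        (out_dir / "performance.json").write_text(
            json.dumps(perf.to_dict(), indent=2)
        )
        (out_dir / "performance.txt").write_text(results.summary() + "\n")

        if config.permutation.n_permutations > 0:
            stage = "permutation"
            logger.info("permutation test: %d permutations",
                        config.permutation.n_permutations)
            perm = results.permutation_test(
                n_permutations=config.permutation.n_permutations,
                iterations_per_perm=config.permutation.iterations_per_perm,
            )
            pd.DataFrame({"null_accuracy": perm.null_accuracies}).to_csv(
                out_dir / "null_accuracies.csv", index=False
            )
            perf.permutation_p = perm.p_value
            perf.permutation_p_str = perm.p_str
            perf.n_permutations = perm.n_permutations
            (out_dir / "performance.json").write_text(
                json.dumps(perf.to_dict(), indent=2)
            )

        region_means: dict[str, np.ndarray] = {}
        if config.importance is not None:
            stage = "importance"
            logger.info("importance: %d iterations",
                        config.importance.n_iterations)
            imp = results.importance(config.importance)
            imp.to_frame().to_csv(out_dir / "importance.csv", index=False)
            ratio_vol = imp.ratio_volume(model.matrix)
            nib.save(
                nib.Nifti1Image(
                    ratio_vol.astype(np.float32), model.matrix.affine
                ),
                str(out_dir / "importance_ratio.nii.gz"),
            )

            stage = "clusters"
            scored = ratio_vol[np.isfinite(ratio_vol)]
            drawn_enough = imp.times_drawn >= config.importance.min_selected
            scored = imp.ratio[drawn_enough]
            if scored.size:
                from .selection import difference_zmap

                thr = float(np.percentile(scored, config.clusters.percentile))
                diff_vol = model.matrix.unmask(
                    np.abs(difference_zmap(model.matrix).diff), fill=0.0
                )
                found = extract_clusters(
                    ratio_vol,
                    thr,
                    model.matrix.affine,
                    connectivity=config.clusters.connectivity,
                    min_size=config.clusters.min_size,
                    stat_volume=diff_vol,
                )
                table = cluster_table(found, model.matrix)
                table.to_csv(out_dir / "clusters.csv", index=False)
                for c in found:
                    region_means[f"cluster_{c.id}"] = subject_cluster_means(
                        model.matrix, c
                    )

        stage = "associations"
        if region_means and {"severity"}.issubset(subjects.columns):
            assoc = association_table(region_means, subjects)
            association_frame(assoc).to_csv(
                out_dir / "associations.csv", index=False
            )
        if "severity" in subjects.columns:
            sev = severity_correlation(
                results.severity_scores.loc[
                    subjects["subject_id"].astype(str)
                ].to_numpy(),
                subjects["severity"].to_numpy(),
            )
            (out_dir / "severity_correlation.json").write_text(
                json.dumps({"r": sev.r, "p": sev.p, "n": sev.n}, indent=2)
            )

        stage = "manifest"
        artifacts = sorted(
            p for p in out_dir.rglob("*") if p.is_file() and p.name != "manifest.json"
        )
        manifest = {
            "package": "vbmpattern",
            "version": __version__,
            "seed": config.seed,
            "config": _config_echo(config),
            "checksums": {
                str(p.relative_to(out_dir)): _sha256(p) for p in artifacts
            },
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception as err:
        raise RuntimeError(f"stage '{stage}' failed: {err}") from err
    return out_dir


def _config_echo(config: RunConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        return obj

    return {
        f.name: enc(getattr(config, f.name))
        for f in dataclasses.fields(RunConfig)
    }
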