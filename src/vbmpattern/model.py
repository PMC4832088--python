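"""Repeated random-split SVM classification of gray-matter patterns.

The estimation scheme: in each of many iterations, draw ``n_train_per_group``
subjects per diagnostic group at random (21 of 22 cases and 21 of 27
controls at the study's sizes), select discriminating voxels from the
training subjects via the z-thresholded difference image, fit a linear
soft-margin SVM on those voxels, and classify one held-out case and one
randomly drawn held-out control.  Aggregated over iterations this yields,
per subject, the proportion of correct test classifications; a subject is
counted as correctly classified when that proportion is >= 0.5 (majority
vote), and the proportion itself doubles as a continuous classification-
certainty score.

Usage follows the statsmodels convention::

    model = PatternClassificationModel.from_volumes(volumes, labels)
    results = model.fit()
    print(results.summary())
    perm = results.permutation_test(n_permutations=1000)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .performance import (
    PerformanceReport,
    PermutationResult,
    confusion_counts,
    performance_report,
    permutation_test,
)
from .selection import SelectionConfig, difference_zmap, select_voxels
from .svm import LinearClassifier, train_linear_svm
from .volumes import (
    CASE_LABEL,
    CONTROL_LABEL,
    GMVolume,
    VoxelMatrix,
    assemble_matrix,
    compute_mask,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CVConfig",
    "PatternClassificationModel",
    "PatternClassificationResults",
    "apply_to_external",
]


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation settings.

    n_train_per_group : int or None
        Training subjects drawn from each group per iteration; ``None``
        resolves to ``min(n_cases, n_controls) - 1`` (21 at the study's
        22/27 sizes).
    n_iterations : int
        Number of random splits (study default 10,000).
    regularization : float
        Soft-margin constant C of the linear SVM (library default 1.0).
    selection : SelectionConfig
        Feature-selection settings, including the z-threshold and whether
        the z-map is recomputed per split or fixed on the full sample.
    seed : int
        Master seed; per-iteration substreams are derived by iteration
        counter, so results are independent of execution order.
    """

    n_train_per_group: int | None = None
    n_iterations: int = 10_000
    regularization: float = 1.0
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.regularization <= 0:
            raise ValueError("regularization must be > 0")


class PatternClassificationModel:
    """Two-group MVPA classifier over a subjects x voxels matrix.

    Parameters
    ----------
    matrix : VoxelMatrix
        In-mask GM values with per-subject diagnostic labels.
    config : CVConfig, optional
        Cross-validation settings; defaults reproduce the study design.
    """

    def __init__(self, matrix: VoxelMatrix, config: CVConfig | None = None):
        self.matrix = matrix
        self.config = config if config is not None else CVConfig()
        n_cases = len(matrix.case_rows)
        n_controls = len(matrix.control_rows)
        if n_cases == 0 or n_controls == 0:
            raise ValueError("matrix must contain both classes")
        n_train = self.config.n_train_per_group
        if n_train is None:
            n_train = min(n_cases, n_controls) - 1
        if n_train < 1:
            raise ValueError("n_train_per_group must be >= 1")
        if n_train >= n_cases or n_train >= n_controls:
            raise ValueError(
                f"n_train_per_group={n_train} does not fit group sizes "
                f"({n_cases} cases, {n_controls} controls)"
            )
        self.n_train_per_group = n_train

    # ------------------------------------------------------------------
    # constructors
    # ------------------------------------------------------------------
    @classmethod
    def from_volumes(
        cls,
        volumes: Sequence[GMVolume],
        labels: Sequence[str],
        config: CVConfig | None = None,
        mask: np.ndarray | None = None,
        mask_min_mean: float = 0.05,
    ) -> "PatternClassificationModel":
        """Build the model straight from GM volumes, masking voxels whose
        cross-subject mean GM falls below ``mask_min_mean``."""
        if mask is None:
            mask = compute_mask(volumes, min_mean=mask_min_mean)
        matrix = assemble_matrix(volumes, labels, mask)
        return cls(matrix, config)

    @classmethod
    def from_directory(
        cls,
        volumes_dir: str | Path,
        subjects_csv: str | Path,
        config: CVConfig | None = None,
        mask_min_mean: float = 0.05,
    ) -> "PatternClassificationModel":
        """Load ``<subject_id>.nii.gz`` volumes listed in a subject table.

        The CSV needs columns ``subject_id`` and ``label`` (case/control);
        behavioural columns are ignored here.
        """
        from .volumes import read_gm_volume

        volumes_dir = Path(volumes_dir)
        subjects_csv = Path(subjects_csv)
        if not subjects_csv.exists():
            raise FileNotFoundError(f"subject table not found: {subjects_csv}")
        table = pd.read_csv(subjects_csv)
        volumes = []
        for sid in table["subject_id"]:
            path = volumes_dir / f"{sid}.nii.gz"
            if not path.exists():
                path = volumes_dir / f"{sid}.nii"
            volumes.append(read_gm_volume(path, subject_id=str(sid)))
        return cls.from_volumes(
            volumes, table["label"].to_numpy(), config, mask_min_mean=mask_min_mean
        )

    # ------------------------------------------------------------------
    # one CV iteration (shared with the importance resampler)
    # ------------------------------------------------------------------
    def draw_split(
        self, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray]:
        """Random train rows (both groups) and test rows (one per group)."""
        m = self.matrix
        train_cases = rng.choice(
            m.case_rows, size=self.n_train_per_group, replace=False
        )
        train_controls = rng.choice(
            m.control_rows, size=self.n_train_per_group, replace=False
        )
        held_cases = np.setdiff1d(m.case_rows, train_cases)
        held_controls = np.setdiff1d(m.control_rows, train_controls)
        test = np.array(
            [rng.choice(held_cases), rng.choice(held_controls)], dtype=np.intp
        )
        train = np.concatenate([train_cases, train_controls])
        return train, test

    def select_for_split(self, train_rows: np.ndarray) -> np.ndarray:
        """Voxel columns for one split, honouring the selection scope."""
        cfg = self.config.selection
        if cfg.scope == "full":
            if not hasattr(self, "_full_selection"):
                zmap = difference_zmap(self.matrix)
                self._full_selection = select_voxels(zmap, cfg)
            return self._full_selection
        zmap = difference_zmap(self.matrix, train_rows)
        return select_voxels(zmap, cfg)

    def _iteration_rng(self, iteration: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([self.config.seed, iteration])
        )

    # ------------------------------------------------------------------
    # fitting
    # ------------------------------------------------------------------
    def fit(
        self, progress: Callable[[int], None] | None = None
    ) -> "PatternClassificationResults":
        """Run the repeated random-split cross-validation.

        Iterations whose voxel selection comes out empty are recorded as
        skipped and excluded from all tallies.
        """
        m = self.matrix
        cfg = self.config
        records: list[tuple] = []
        n_skipped = 0
        for it in range(cfg.n_iterations):
            rng = self._iteration_rng(it)
            train_rows, test_rows = self.draw_split(rng)
            selected = self.select_for_split(train_rows)
            if len(selected) == 0:
                n_skipped += 1
                records.append((it, -1, "", "", False, 0, True))
                records.append((it, -1, "", "", False, 0, True))
                continue
            clf = train_linear_svm(
                m.values[np.ix_(train_rows, selected)],
                m.labels[train_rows],
                regularization=cfg.regularization,
                selected_columns=selected,
            )
            predicted = clf.predict(m.values[test_rows])
            for row, pred in zip(test_rows, predicted):
                truth = m.labels[row]
                records.append(
                    (it, int(row), truth, pred, pred == truth, len(selected), False)
                )
            if progress is not None:
                progress(it + 1)
        if n_skipped:
            logger.info(
                "%d/%d iterations skipped (empty voxel selection)",
                n_skipped,
                cfg.n_iterations,
            )
        frame = pd.DataFrame(
            records,
            columns=[
                "iteration",
                "subject_row",
                "true_label",
                "predicted_label",
                "correct",
                "n_selected",
                "skipped",
            ],
        )
        return PatternClassificationResults(self, frame, n_skipped)

    def train_final_classifier(self) -> LinearClassifier:
        """One classifier from the whole sample: full-sample voxel
        selection at the configured threshold, then a single SVM fit on
        every subject.  This is the model applied to external cohorts."""
        zmap = difference_zmap(self.matrix)
        selected = select_voxels(zmap, self.config.selection)
        if len(selected) == 0:
            raise ValueError(
                "empty voxel selection at z-threshold "
                f"{self.config.selection.z_threshold}: cannot train"
            )
        return train_linear_svm(
            self.matrix.values[:, selected],
            self.matrix.labels,
            regularization=self.config.regularization,
            selected_columns=selected,
        )


class PatternClassificationResults:
    """Aggregated output of the repeated-CV fit.

    Attributes
    ----------
    iteration_records : DataFrame
        One row per test prediction (two per non-skipped iteration).
    subject_summaries : DataFrame
        Per-subject tallies: times tested, times predicted case,
        proportion correct, majority vote, mean classification accuracy
        (MCA) and the continuous severity score (proportion of test
        appearances classified as case).
    """

    def __init__(
        self,
        model: PatternClassificationModel,
        iteration_records: pd.DataFrame,
        n_skipped: int,
    ):
        self.model = model
        self.iteration_records = iteration_records
        self.n_skipped = n_skipped
        self.subject_summaries = self._summarize()

    def _summarize(self) -> pd.DataFrame:
        m = self.model.matrix
        valid = self.iteration_records[~self.iteration_records["skipped"]]
        rows = []
        for row_idx in range(m.n_subjects):
            mine = valid[valid["subject_row"] == row_idx]
            n_tested = len(mine)
            n_pred_case = int((mine["predicted_label"] == CASE_LABEL).sum())
            prop_correct = (
                float(mine["correct"].mean()) if n_tested else np.nan
            )
            majority_correct = bool(prop_correct >= 0.5) if n_tested else False
            mca = (
                max(prop_correct, 1.0 - prop_correct) if n_tested else np.nan
            )
            rows.append(
                {
                    "subject_id": m.subject_ids[row_idx],
                    "label": m.labels[row_idx],
                    "n_tested": n_tested,
                    "n_predicted_case": n_pred_case,
                    "prop_correct": prop_correct,
                    "majority_correct": majority_correct,
                    "mca": mca,
                    "severity_score": (
                        n_pred_case / n_tested if n_tested else np.nan
                    ),
                }
            )
        return pd.DataFrame(rows)

    # ------------------------------------------------------------------
    # headline numbers
    # ------------------------------------------------------------------
    @property
    def tested(self) -> pd.DataFrame:
        return self.subject_summaries[self.subject_summaries["n_tested"] > 0]

    @property
    def majority_accuracy(self) -> float:
        """Proportion of subjects correctly classified by majority vote —
        the study's headline 'prediction accuracy'."""
        t = self.tested
        if len(t) == 0:
            return np.nan
        return float(t["majority_correct"].mean())

    @property
    def prediction_accuracy(self) -> float:
        """Proportion of individual test predictions that were correct."""
        valid = self.iteration_records[~self.iteration_records["skipped"]]
        if len(valid) == 0:
            return np.nan
        return float(valid["correct"].mean())

    @property
    def mean_mca(self) -> float:
        return float(self.tested["mca"].mean())

    def majority_predictions(self) -> tuple[np.ndarray, np.ndarray]:
        """(true labels, majority-vote predicted labels) over tested
        subjects; a 0.5 tie counts as correctly classified."""
        t = self.tested
        truths = t["label"].to_numpy()
        predicted = np.where(
            t["prop_correct"] >= 0.5,
            truths,
            np.where(truths == CASE_LABEL, CONTROL_LABEL, CASE_LABEL),
        )
        return truths, predicted

    def performance(self) -> PerformanceReport:
        truths, predicted = self.majority_predictions()
        return performance_report(confusion_counts(truths, predicted))

    @property
    def severity_scores(self) -> pd.Series:
        """Classification-certainty-as-severity: per subject, the fraction
        of test appearances classified as case, in [0, 1]."""
        return self.subject_summaries.set_index("subject_id")["severity_score"]

    # ------------------------------------------------------------------
    # downstream analyses
    # ------------------------------------------------------------------
    def permutation_test(
        self,
        n_permutations: int = 1000,
        seed: int | None = None,
        iterations_per_perm: int | None = None,
        progress: Callable[[int], None] | None = None,
    ) -> PermutationResult:
        """Label-permutation null for the majority-vote accuracy.

        ``iterations_per_perm`` scales down the CV repetitions inside
        each permutation (the observed accuracy keeps its full count).
        """
        cfg = self.model.config
        if iterations_per_perm is not None:
            cfg = replace(cfg, n_iterations=iterations_per_perm)
        return permutation_test(
            self.model.matrix,
            cfg,
            n_permutations=n_permutations,
            seed=seed if seed is not None else self.model.config.seed,
            observed_accuracy=self.majority_accuracy,
            progress=progress,
        )

    def importance(self, imp_config=None, progress=None):
        """Voxel-importance by random feature subsampling; see
        :func:`vbmpattern.importance.run_importance`."""
        from .importance import ImportanceConfig, run_importance

        if imp_config is None:
            imp_config = ImportanceConfig()
        return run_importance(
            self.model.matrix, self.model.config, imp_config, progress=progress
        )

    def final_classifier(self) -> LinearClassifier:
        if not hasattr(self, "_final_classifier"):
            self._final_classifier = self.model.train_final_classifier()
        return self._final_classifier

    def predict_external(
        self, external: VoxelMatrix, ensemble: bool = False, n_models: int = 100
    ) -> np.ndarray:
        """Classify an external cohort without refitting.

        Default applies the single full-sample classifier; ``ensemble``
        instead takes a majority vote over ``n_models`` split-trained
        classifiers (seeded like the CV iterations).
        """
        if not ensemble:
            return apply_to_external(self.final_classifier(), self.model, external)
        votes = np.zeros(external.n_subjects)
        used = 0
        for it in range(n_models):
            rng = self.model._iteration_rng(it)
            train_rows, _ = self.model.draw_split(rng)
            selected = self.model.select_for_split(train_rows)
            if len(selected) == 0:
                continue
            clf = train_linear_svm(
                self.model.matrix.values[np.ix_(train_rows, selected)],
                self.model.matrix.labels[train_rows],
                regularization=self.model.config.regularization,
                selected_columns=selected,
            )
            votes += apply_to_external(clf, self.model, external) == CASE_LABEL
            used += 1
        if used == 0:
            raise ValueError("all ensemble members had empty selections")
        return np.where(votes / used >= 0.5, CASE_LABEL, CONTROL_LABEL)

    # ------------------------------------------------------------------
    # presentation
    # ------------------------------------------------------------------
    def summary(self) -> str:
        perf = self.performance()
        lines = [
            "Repeated random-split SVM classification",
            "=" * 42,
            f"Subjects: {len(self.model.matrix.case_rows)} cases, "
            f"{len(self.model.matrix.control_rows)} controls, "
            f"{self.model.matrix.n_voxels} in-mask voxels",
            f"Iterations: {self.model.config.n_iterations} "
            f"({self.n_skipped} skipped, empty selection)",
            f"Train per group: {self.model.n_train_per_group}; "
            f"z-threshold: {self.model.config.selection.z_threshold}; "
            f"scope: {self.model.config.selection.scope}",
            f"Mean selected voxels: "
            f"{self._mean_selected():.0f}",
            f"Per-prediction accuracy: {self.prediction_accuracy:.3f}",
            f"Mean classification accuracy (MCA): {self.mean_mca:.2f}",
            "",
            perf.summary(),
        ]
        return "\n".join(lines)

    def _mean_selected(self) -> float:
        valid = self.iteration_records[~self.iteration_records["skipped"]]
        return float(valid["n_selected"].mean()) if len(valid) else 0.0

    def plot_subject_certainty(self, ax=None):
        """Bar plot of per-subject classification certainty (severity
        score), cases and controls side by side."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        t = self.subject_summaries.sort_values(["label", "severity_score"])
        colors = np.where(t["label"] == CASE_LABEL, "C3", "C0")
        ax.bar(range(len(t)), t["severity_score"], color=colors)
        ax.axhline(0.5, color="k", lw=0.8, ls="--")
        ax.set_ylabel("P(predicted case)")
        ax.set_xlabel("subject (sorted within group)")
        return ax


def apply_to_external(
    classifier: LinearClassifier,
    model: PatternClassificationModel,
    external: VoxelMatrix,
) -> np.ndarray:
    """Apply a trained classifier to an external cohort's matrix.

    The external matrix must live on the same grid and mask as the
    training matrix so that column indices line up.
    """
    train = model.matrix
    if external.grid_shape != train.grid_shape:
        raise ValueError(
            f"grid mismatch: external {external.grid_shape} vs "
            f"training {train.grid_shape}"
        )
    if external.n_voxels != train.n_voxels or not np.array_equal(
        external.voxel_index, train.voxel_index
    ):
        raise ValueError(
            "external matrix mask does not match the training mask"
        )
    return classifier.predict(external.values)
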