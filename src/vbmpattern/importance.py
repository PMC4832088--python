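"""Voxel importance by random feature subsampling.

The classification procedure is repeated, but each iteration trains on a
random 20% subset of the voxels selected for that split.  Per voxel this
accumulates how often it was drawn and how often a classification it took
part in was correct; the ratio of the two expresses the voxel's importance
for the discrimination.  By default a "classification" is one test
prediction (two per iteration), so a drawn voxel's counts advance by 2 and
0–2 respectively; a per-iteration counting mode (advance by 1, correct
only if both test subjects were right) is available behind a flag.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Callable

import numpy as np
import pandas as pd

from .svm import train_linear_svm

if TYPE_CHECKING:  # pragma: no cover
    from .model import CVConfig
    from .volumes import VoxelMatrix

logger = logging.getLogger(__name__)

__all__ = ["ImportanceConfig", "ImportanceMap", "run_importance", "importance_scores"]


@dataclass(frozen=True)
class ImportanceConfig:
    """Settings for the subsampling importance procedure.

    subset_fraction : float
        Fraction of the selected voxels drawn per iteration (default 0.20).
    n_iterations : int
        Number of subsampled classification iterations (study default
        100,000).
    min_selected : int
        Minimum times-drawn count for a voxel's ratio to be reported.
    count_per_prediction : bool
        Count each of the two test predictions separately (default) or
        the iteration as a single classification.
    """

    subset_fraction: float = 0.20
    n_iterations: int = 100_000
    min_selected: int = 50
    count_per_prediction: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.subset_fraction <= 1:
            raise ValueError("subset_fraction must lie in (0, 1]")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class ImportanceMap:
    """Per-voxel draw/correct counts over the whole matrix column space.

    Voxels that were never part of a selection keep zero counts and an
    undefined (NaN) ratio.
    """

    times_drawn: np.ndarray
    times_correct: np.ndarray
    voxel_index: np.ndarray
    n_iterations: int
    n_skipped: int
    min_selected: int

    @property
    def ratio(self) -> np.ndarray:
        """times_correct / times_drawn, NaN where never drawn."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.times_drawn > 0,
                self.times_correct / np.maximum(self.times_drawn, 1),
                np.nan,
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "column": np.arange(len(self.times_drawn)),
                "i": self.voxel_index[:, 0],
                "j": self.voxel_index[:, 1],
                "k": self.voxel_index[:, 2],
                "times_drawn": self.times_drawn,
                "times_correct": self.times_correct,
                "ratio": self.ratio,
            }
        )

    def ratio_volume(self, matrix: "VoxelMatrix") -> np.ndarray:
        """Importance ratio scattered onto the 3D grid (NaN off-support)."""
        return matrix.unmask(self.ratio, fill=np.nan)

    def drawn_volume(self, matrix: "VoxelMatrix") -> np.ndarray:
        return matrix.unmask(self.times_drawn.astype(float), fill=0.0)


def run_importance(
    matrix: "VoxelMatrix",
    cv_config: "CVConfig",
    imp_config: ImportanceConfig | None = None,
    progress: Callable[[int], None] | None = None,
) -> ImportanceMap:
    """Run the subsampled classification loop and tally per-voxel counts.

    Each iteration replays a CV iteration (random split, per-split voxel
    selection) and then draws ``ceil(fraction * k)`` of the k selected
    voxels without replacement — at least one — to train and test on.
    Reproducible from ``imp_config.seed``.
    """
    from .model import PatternClassificationModel

    if imp_config is None:
        imp_config = ImportanceConfig()
    model = PatternClassificationModel(matrix, cv_config)
    times_drawn = np.zeros(matrix.n_voxels, dtype=np.int64)
    times_correct = np.zeros(matrix.n_voxels, dtype=np.int64)
    n_skipped = 0
    for it in range(imp_config.n_iterations):
        rng = np.random.default_rng(
            np.random.SeedSequence([imp_config.seed, 0x1A9, it])
        )
        train_rows, test_rows = model.draw_split(rng)
        selected = model.select_for_split(train_rows)
        if len(selected) == 0:
            n_skipped += 1
            continue
        n_draw = max(1, math.ceil(imp_config.subset_fraction * len(selected)))
        drawn = rng.choice(selected, size=n_draw, replace=False)
        clf = train_linear_svm(
            matrix.values[np.ix_(train_rows, drawn)],
            matrix.labels[train_rows],
            regularization=cv_config.regularization,
            selected_columns=drawn,
        )
        predicted = clf.predict(matrix.values[test_rows])
        correct = predicted == matrix.labels[test_rows]
        if imp_config.count_per_prediction:
            times_drawn[drawn] += len(test_rows)
            times_correct[drawn] += int(correct.sum())
        else:
            times_drawn[drawn] += 1
            times_correct[drawn] += int(correct.all())
        if progress is not None:
            progress(it + 1)
    if n_skipped:
        logger.info(
            "%d/%d importance iterations skipped (empty selection)",
            n_skipped,
            imp_config.n_iterations,
        )
    return ImportanceMap(
        times_drawn=times_drawn,
        times_correct=times_correct,
        voxel_index=matrix.voxel_index,
        n_iterations=imp_config.n_iterations,
        n_skipped=n_skipped,
        min_selected=imp_config.min_selected,
    )


def importance_scores(
    imp_map: ImportanceMap, min_selected: int | None = None
) -> pd.DataFrame:
    """Voxels ranked by importance ratio, descending.

    Voxels drawn fewer than ``min_selected`` times are dropped (their
    ratio estimate would be too noisy to rank); ties on the ratio are
    broken by the higher draw count, stably.
    """
    if min_selected is None:
        min_selected = imp_map.min_selected
    frame = imp_map.to_frame()
    frame = frame[frame["times_drawn"] >= min_selected]
    if len(frame) == 0:
        logger.warning(
            "no voxel reached the minimum draw count of %d", min_selected
        )
        return frame
    return frame.sort_values(
        ["ratio", "times_drawn"], ascending=[False, False], kind="stable"
    ).reset_index(drop=True)
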