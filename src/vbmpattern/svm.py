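"""Linear soft-margin SVM training on selected voxels.

A thin wrapper around libsvm (via scikit-learn's SVC) that fixes the
conventions used throughout the pipeline: cases map to the positive side
of the hyperplane, no feature scaling is applied (GM values share a common
scale), and the regularization constant defaults to the library default
C = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .volumes import CASE_LABEL, CONTROL_LABEL

__all__ = ["LinearClassifier", "train_linear_svm"]


@dataclass
class LinearClassifier:
    """A fitted separating hyperplane over a set of selected voxels.

    decision(x) = w . x[selected_columns] + b; sign > 0 predicts case.
    """

    weights: np.ndarray
    intercept: float
    selected_columns: np.ndarray

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.selected_columns):
            raise ValueError("one weight per selected voxel required")

    def decision_function(self, values: np.ndarray) -> np.ndarray:
        """Signed distance-like score for full-width subject rows."""
        values = np.atleast_2d(values)
        return values[:, self.selected_columns] @ self.weights + self.intercept

    def predict(self, values: np.ndarray) -> np.ndarray:
        """Predicted labels ('case'/'control') for full-width rows."""
        scores = self.decision_function(values)
        return np.where(scores > 0, CASE_LABEL, CONTROL_LABEL)


def train_linear_svm(
    train_values: np.ndarray,
    train_labels: np.ndarray,
    regularization: float = 1.0,
    selected_columns: np.ndarray | None = None,
) -> LinearClassifier:
    """Fit a linear soft-margin SVM on an n_subjects x k feature block.

    ``train_values`` holds only the selected features (k columns);
    ``selected_columns`` records which matrix columns they came from so
    the classifier can later be applied to full-width rows.
    """
    train_values = np.asarray(train_values, dtype=np.float64)
    train_labels = np.asarray(train_labels)
    if train_values.ndim != 2 or train_values.shape[1] == 0:
        raise ValueError("no voxels selected: cannot train a classifier")
    classes = set(train_labels)
    if classes != {CASE_LABEL, CONTROL_LABEL}:
        raise ValueError(
            f"training set must contain both classes, got {sorted(classes)}"
        )
    # y = +1 for case so the decision function is positive on the case side
    y = np.where(train_labels == CASE_LABEL, 1, -1)
    clf = SVC(kernel="linear", C=regularization)
    clf.fit(train_values, y)
    if selected_columns is None:
        selected_columns = np.arange(train_values.shape[1])
    return LinearClassifier(
        weights=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        selected_columns=np.asarray(selected_columns, dtype=np.intp),
    )
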