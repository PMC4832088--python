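"""Signal-detection accounting for the classifier's subject-level output.

Covers the confusion matrix and its derived rates (accuracy, sensitivity,
specificity, PPV, NPV), the d-prime separation index
``Z(hit rate) − Z(false-alarm rate)``, extrapolation of the predictive
values to a different case/control prevalence, and the label-permutation
significance test that reruns the whole cross-validation pipeline under
shuffled diagnoses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Callable

import numpy as np
from scipy.stats import norm

from .volumes import CASE_LABEL, CONTROL_LABEL

if TYPE_CHECKING:  # pragma: no cover
    from .model import CVConfig
    from .volumes import VoxelMatrix

__all__ = [
    "ConfusionCounts",
    "PerformanceReport",
    "confusion_counts",
    "performance_report",
    "dprime",
    "extrapolate_predictive_values",
    "permutation_test",
    "PermutationResult",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 diagnostic counts: rows true status, columns predicted status."""

    hits: int  # cases predicted case
    misses: int  # cases predicted control
    false_alarms: int  # controls predicted case
    correct_rejections: int

    def __post_init__(self) -> None:
        for name in ("hits", "misses", "false_alarms", "correct_rejections"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_cases(self) -> int:
        return self.hits + self.misses

    @property
    def n_controls(self) -> int:
        return self.false_alarms + self.correct_rejections

    @property
    def total(self) -> int:
        return self.n_cases + self.n_controls


@dataclass
class PerformanceReport:
    """Derived diagnostic rates. Raw proportions are retained; the
    ``summary`` method rounds percentages half-up to integers and d' to
    2 decimals for display."""

    counts: ConfusionCounts
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float | None
    npv: float | None
    d_prime: float
    permutation_p: float | None = None
    permutation_p_str: str | None = None
    n_permutations: int | None = None

    def summary(self) -> str:
        c = self.counts
        lines = [
            "Classification performance",
            "=" * 42,
            f"{'':24s}Predicted case  Predicted control",
            f"{'True case':24s}{c.hits:>9d} {c.misses:>16d}",
            f"{'True control':24s}{c.false_alarms:>9d} {c.correct_rejections:>16d}",
            "-" * 42,
            f"Accuracy      {_pct(self.accuracy)}",
            f"Sensitivity   {_pct(self.sensitivity)}",
            f"Specificity   {_pct(self.specificity)}",
            f"PPV           {_pct(self.ppv)}",
            f"NPV           {_pct(self.npv)}",
            f"d-prime       {self.d_prime:.2f}",
        ]
        if self.permutation_p_str is not None:
            lines.append(
                f"Permutation p {self.permutation_p_str}"
                f" ({self.n_permutations} permutations)"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "hits": self.counts.hits,
            "misses": self.counts.misses,
            "false_alarms": self.counts.false_alarms,
            "correct_rejections": self.counts.correct_rejections,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "d_prime": self.d_prime,
            "permutation_p": self.permutation_p,
            "permutation_p_str": self.permutation_p_str,
            "n_permutations": self.n_permutations,
        }


def _pct(x: float | None) -> str:
    if x is None:
        return "   --"
    return f"{round_half_up_percent(x):>4d}%"


def round_half_up_percent(proportion: float) -> int:
    """Percent rounding with ties away from zero (0.805 -> 81%)."""
    return int(np.floor(proportion * 100 + 0.5))


def confusion_counts(
    true_labels: np.ndarray, predicted_labels: np.ndarray
) -> ConfusionCounts:
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if true_labels.shape != predicted_labels.shape:
        raise ValueError(
            f"length mismatch: {true_labels.shape} vs {predicted_labels.shape}"
        )
    for arr, name in ((true_labels, "true"), (predicted_labels, "predicted")):
        bad = set(arr) - {CASE_LABEL, CONTROL_LABEL}
        if bad:
            raise ValueError(f"non-binary {name} labels: {sorted(bad)}")
    is_case = true_labels == CASE_LABEL
    pred_case = predicted_labels == CASE_LABEL
    return ConfusionCounts(
        hits=int(np.sum(is_case & pred_case)),
        misses=int(np.sum(is_case & ~pred_case)),
        false_alarms=int(np.sum(~is_case & pred_case)),
        correct_rejections=int(np.sum(~is_case & ~pred_case)),
    )


def dprime(
    hit_rate: float, fa_rate: float, n_cases: int, n_controls: int
) -> float:
    """Signal-detection d': Phi^-1(hit rate) − Phi^-1(false-alarm rate).

    Boundary rates of exactly 0 or 1 are clipped to 1/(2n) and 1−1/(2n)
    of the relevant marginal so the quantiles stay finite.
    """
    if not (0 <= hit_rate <= 1 and 0 <= fa_rate <= 1):
        raise ValueError("rates must lie in [0, 1]")
    hr = _clip_rate(hit_rate, n_cases)
    fr = _clip_rate(fa_rate, n_controls)
    return float(norm.ppf(hr) - norm.ppf(fr))


def _clip_rate(rate: float, n: int) -> float:
    if rate <= 0:
        return 1.0 / (2 * n)
    if rate >= 1:
        return 1.0 - 1.0 / (2 * n)
    return rate


def performance_report(counts: ConfusionCounts) -> PerformanceReport:
    """All derived rates from a confusion table.

    PPV/NPV are ``None`` when their denominator (predicted-positive or
    predicted-negative margin) is empty.
    """
    if counts.n_cases == 0 or counts.n_controls == 0:
        raise ValueError("both true-status marginals must be > 0")
    sens = counts.hits / counts.n_cases
    spec = counts.correct_rejections / counts.n_controls
    pred_pos = counts.hits + counts.false_alarms
    pred_neg = counts.correct_rejections + counts.misses
    return PerformanceReport(
        counts=counts,
        accuracy=(counts.hits + counts.correct_rejections) / counts.total,
        sensitivity=sens,
        specificity=spec,
        ppv=counts.hits / pred_pos if pred_pos > 0 else None,
        npv=counts.correct_rejections / pred_neg if pred_neg > 0 else None,
        d_prime=dprime(sens, 1 - spec, counts.n_cases, counts.n_controls),
    )


def extrapolate_predictive_values(
    sensitivity: float,
    specificity: float,
    n_cases: int,
    n_controls: int,
) -> tuple[float, float]:
    """PPV and NPV expected at a different prevalence.

    Predictive values are sample specific; a balanced case/control study
    overstates PPV relative to a realistic population.  This computes the
    expected hits ``sens * n_cases`` and false alarms
    ``(1 − spec) * n_controls`` at the given group sizes and returns the
    predictive values implied by those expected counts.
    """
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValueError("rates must lie in [0, 1]")
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("group sizes must be positive")
    e_hits = sensitivity * n_cases
    e_misses = (1 - sensitivity) * n_cases
    e_fa = (1 - specificity) * n_controls
    e_cr = specificity * n_controls
    ppv = e_hits / (e_hits + e_fa) if e_hits + e_fa > 0 else np.nan
    npv = e_cr / (e_cr + e_misses) if e_cr + e_misses > 0 else np.nan
    return float(ppv), float(npv)


def predicted_case_fraction(
    sensitivity: float, specificity: float, n_cases: int, n_controls: int
) -> float:
    """Expected fraction of all subjects the classifier labels as case."""
    e_pos = sensitivity * n_cases + (1 - specificity) * n_controls
    return float(e_pos / (n_cases + n_controls))


@dataclass
class PermutationResult:
    p_value: float
    p_str: str
    observed_accuracy: float
    null_accuracies: np.ndarray
    n_permutations: int


def format_permutation_p(n_greater_equal: int, n_permutations: int) -> str:
    """Raw-proportion convention: 0 exceedances is reported as the bound
    '< 1/N' rather than 0."""
    if n_greater_equal == 0:
        return f"< {1 / n_permutations:g}"
    return f"{n_greater_equal / n_permutations:g}"


def permutation_test(
    matrix: "VoxelMatrix",
    cv_config: "CVConfig",
    n_permutations: int,
    seed: int,
    observed_accuracy: float | None = None,
    progress: Callable[[int], None] | None = None,
) -> PermutationResult:
    """Empirical significance of the observed subject-level accuracy.

    Each permutation shuffles the diagnosis labels across subjects
    (preserving the group sizes) and reruns the full cross-validation
    pipeline — including per-split voxel selection — recording the
    majority-vote accuracy.  ``p = #{null >= observed} / N``, reported as
    the bound "< 1/N" when no null value reaches the observed one.
    """
    from .model import PatternClassificationModel

    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    if observed_accuracy is None:
        observed = (
            PatternClassificationModel(matrix, cv_config)
            .fit(progress=None)
            .majority_accuracy
        )
    else:
        observed = observed_accuracy

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7E57]))
    null_acc = np.empty(n_permutations)
    for b in range(n_permutations):
        perm_labels = rng.permutation(matrix.labels)
        perm_matrix = _relabel(matrix, perm_labels)
        perm_cfg = _reseed(cv_config, int(rng.integers(2**31 - 1)))
        res = PatternClassificationModel(perm_matrix, perm_cfg).fit(progress=None)
        null_acc[b] = res.majority_accuracy
        if progress is not None:
            progress(b + 1)
    n_ge = int(np.sum(null_acc >= observed))
    return PermutationResult(
        p_value=n_ge / n_permutations,
        p_str=format_permutation_p(n_ge, n_permutations),
        observed_accuracy=observed,
        null_accuracies=null_acc,
        n_permutations=n_permutations,
    )


def _relabel(matrix: "VoxelMatrix", labels: np.ndarray) -> "VoxelMatrix":
    from .volumes import VoxelMatrix

    return VoxelMatrix(
        values=matrix.values,
        voxel_index=matrix.voxel_index,
        labels=labels,
        affine=matrix.affine,
        grid_shape=matrix.grid_shape,
        subject_ids=matrix.subject_ids,
    )


def _reseed(cv_config: "CVConfig", seed: int) -> "CVConfig":
    from dataclasses import replace

    return replace(cv_config, seed=seed)
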