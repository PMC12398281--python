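"""Evaluation metrics for group-specific models.

Balanced accuracy, the group specificity index (GSI), accuracy gaps and
pairwise model-weight correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GroupedEvaluation",
    "balanced_accuracy",
    "gsi",
    "accuracy_gap",
    "weight_correlation_matrix",
]


def balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """(TPR + TNR) / 2 for {0, 1} labels.

    If one class is absent from ``y_true`` the undefined rate is skipped
    and the defined rate is returned alone, with a warning.  Equals plain
    accuracy when class counts are equal.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    pos = y_true == 1
    neg = y_true == 0
    rates = []
    if pos.any():
        rates.append(float(np.mean(y_pred[pos] == 1)))
    if neg.any():
        rates.append(float(np.mean(y_pred[neg] == 0)))
    if len(rates) == 1:
        warnings.warn(
            "one class absent from y_true; returning the defined rate only",
            stacklevel=2,
        )
    return float(np.mean(rates))


@dataclass(frozen=True)
class GroupedEvaluation:
    """Balanced accuracies of one model on target / nontarget test samples."""

    bat: float
    bant: float
    n_target: int = 0
    n_nontarget: int = 0

    def __post_init__(self) -> None:
        for name in ("bat", "bant"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    @property
    def considered(self) -> bool:
        """False when the model is worse than chance on its own group."""
        return self.bat >= 0.5

    @property
    def gsi(self) -> float:
        return gsi(self)


def gsi(evaluation: GroupedEvaluation | float, bant: float | None = None) -> float:
    """Group specificity index ``2 * BAT * (BAT - 0.5 - |BANT - 0.5|)``.

    Accepts a :class:`GroupedEvaluation` or two floats ``(bat, bant)``.
    The raw value is returned even when negative (BANT farther from chance
    than BAT's margin) or when BAT < 0.5 (such models are conventionally
    not considered; see :attr:`GroupedEvaluation.considered`).
    """
    if isinstance(evaluation, GroupedEvaluation):
        bat, bant = evaluation.bat, evaluation.bant
    else:
        bat = float(evaluation)
        if bant is None:
            raise TypeError("gsi() needs a GroupedEvaluation or (bat, bant)")
    if not (0.0 <= bat <= 1.0 and 0.0 <= bant <= 1.0):
        raise ValueError(f"bat={bat}, bant={bant} must lie in [0, 1]")
    return 2.0 * bat * (bat - 0.5 - abs(bant - 0.5))


def accuracy_gap(acc_target: float, acc_nontarget: float) -> float:
    """Absolute accuracy difference, on the callers' (consistent) scale."""
    return abs(float(acc_target) - float(acc_nontarget))


def weight_correlation_matrix(models) -> np.ndarray:
    """Pairwise Pearson correlations between model weight vectors.

    ``models`` is a sequence of equal-length 1-D weight vectors (bias
    already excluded by the caller; lateralization patterns live in the
    connection weights).  Zero-variance vectors yield NaN rows/columns.
    """
    W = np.asarray([np.asarray(w, dtype=float) for w in models])
    if W.ndim != 2 or W.shape[0] < 2:
        raise ValueError("need at least 2 equal-length weight vectors")
    sd = W.std(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(W)
    corr = np.asarray(corr, dtype=float)
    degenerate = sd == 0
    corr[degenerate, :] = np.nan
    corr[:, degenerate] = np.nan
    ok = ~degenerate
    corr[np.ix_(ok, ok)] = np.clip(corr[np.ix_(ok, ok)], -1.0, 1.0)
    for i in np.flatnonzero(ok):
        corr[i, i] = 1.0
    return corr
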