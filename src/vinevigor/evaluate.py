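"""Classification evaluation: confusion matrices with user/producer
accuracy, neighbor-inclusive match rates, Mann-Whitney U comparisons with
significance stars, and per-vine prediction differences.

Classes are ordinal in the sequence (0, 1, 3, 5, 7, 9); "neighbor" means
adjacency in that sequence, not numeric distance.  The edge convention for
neighbor matches follows the reference survey's marking: the lowest class
counts its two nearest upward classes (0 matches 1 and 3), the highest
counts only its single downward neighbor; a strict +/-1 convention is
available for comparison.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .geodata import GROWTH_CLASSES, VineRecord

__all__ = [
    "ConfusionMatrix",
    "PairwiseTestResult",
    "confusion_matrix",
    "neighbor_match_rate",
    "mann_whitney_u",
    "significance_stars",
    "prediction_difference",
]

_DEFAULT_STARS = {0.001: "***", 0.01: "**", 0.05: "*"}


@dataclass
class ConfusionMatrix:
    """Counts with rows = labeled class (GL) and columns = predicted (GP)."""

    counts: np.ndarray
    classes: tuple[int, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n = len(self.classes)
        if self.counts.shape != (n, n):
            raise ValueError("counts shape does not match the class list")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_percent(self) -> np.ndarray:
        """Rows normalized to percentages (NaN rows for absent classes)."""
        sums = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(sums > 0, self.counts / sums * 100.0, np.nan)

    def user_accuracy(self) -> np.ndarray:
        """Per labeled class: correct / all with that label, in %."""
        return np.diagonal(self.row_percent())

    def producer_accuracy(self) -> np.ndarray:
        """Per predicted class: correct / all predicted as it, in %."""
        col = self.counts.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(col > 0, np.diagonal(self.counts) / col * 100.0, np.nan)


def confusion_matrix(
    y_true: Sequence[int],
    y_pred: Sequence[int],
    classes: Sequence[int] | None = None,
) -> ConfusionMatrix:
    """Confusion matrix in growth-class order; unknown labels are an error.

    ``classes`` defaults to the classes present, in the ordinal sequence.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    seen = set(np.unique(y_true)) | set(np.unique(y_pred))
    unknown = seen - set(GROWTH_CLASSES)
    if unknown:
        raise ValueError(f"labels {sorted(unknown)} are not growth classes {GROWTH_CLASSES}")
    if classes is None:
        classes = tuple(c for c in GROWTH_CLASSES if c in seen)
    else:
        classes = tuple(classes)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        counts[index[int(t)], index[int(p)]] += 1
    return ConfusionMatrix(counts, classes)


def neighbor_match_rate(cm: ConfusionMatrix, strict: bool = False) -> dict[int, float]:
    """Per labeled class: % of its samples predicted as itself or an
    ordinal-neighbor class.

    Default edge convention: the first class also counts its second upward
    neighbor (class 0 matches 1 and 3); the last class counts only its
    downward neighbor.  ``strict=True`` uses plain +/-1 adjacency.
    """
    rp = cm.row_percent()
    n = len(cm.classes)
    rates: dict[int, float] = {}
    for i, cls in enumerate(cm.classes):
        neighbors = {i - 1, i, i + 1}
        if not strict and i == 0 and n > 2:
            neighbors.add(2)
        cols = [j for j in neighbors if 0 <= j < n]
        rates[cls] = float(np.nansum(rp[i, cols])) if not np.all(np.isnan(rp[i])) else float("nan")
    return rates


@dataclass(frozen=True)
class PairwiseTestResult:
    U: float
    p: float
    stars: str
    method: str  # 'exact' or 'asymptotic'


def mann_whitney_u(
    a: Sequence[float],
    b: Sequence[float],
    star_mapping: Mapping[float, str] | None = None,
) -> PairwiseTestResult:
    """Two-sided Mann-Whitney U test (midrank ties).

    The p-value is exact (full enumeration) when n1+n2 <= 12 and the pooled
    sample is tie-free, else a normal approximation with tie and continuity
    corrections.  Identical samples yield U = n1*n2/2, p = 1 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        warnings.warn("all values identical across both samples; p = 1", stacklevel=2)
        return PairwiseTestResult(a.size * b.size / 2.0, 1.0, "", "degenerate")
    has_ties = np.unique(pooled).size < pooled.size
    if a.size + b.size <= 12 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    p = float(min(res.pvalue, 1.0))
    return PairwiseTestResult(float(res.statistic), p, significance_stars(p, star_mapping), method)


def significance_stars(p: float, mapping: Mapping[float, str] | None = None) -> str:
    """Map a p-value onto star codes; default *** <0.001, ** <0.01, * <0.05."""
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p must lie in (0, 1], got {p}")
    mapping = dict(mapping) if mapping else dict(_DEFAULT_STARS)
    for threshold in sorted(mapping):
        if p < threshold:
            return mapping[threshold]
    return ""


_RANK_OF = {c: i for i, c in enumerate(GROWTH_CLASSES)}


def prediction_difference(
    vines: Sequence[VineRecord] | None,
    y_true: Sequence[int],
    y_pred: Sequence[int],
) -> list[dict]:
    """Signed ordinal rank difference (true - predicted) per vine.

    Positive values mean the model underestimated the growth class.  With
    ``vines`` given, stem coordinates are attached for mapping.
    """
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must align")
    if vines is not None and len(vines) != len(y_true):
        raise ValueError("vines must align with the label vectors")
    out = []
    for i, (t, p) in enumerate(zip(y_true, y_pred)):
        entry = {"true": int(t), "predicted": int(p), "difference": _RANK_OF[int(t)] - _RANK_OF[int(p)]}
        if vines is not None:
            entry.update(vine_id=vines[i].vine_id, easting=vines[i].easting, northing=vines[i].northing)
        out.append(entry)
    return out
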