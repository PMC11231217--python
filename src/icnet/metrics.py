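"""Evaluation metrics for label volumes.

Two equivalent routes are provided: pixel-wise confusion counts
(accuracy, precision, recall) and region sets (sensitivity, specificity,
Dice), plus the BraTS composite regions — whole tumor (WT, classes
{1,2,3} after mapping), tumor core (TC, {1,3}) and enhancing tumor
(ET, {3}).

Conventions (documented and tested): Dice of two empty sets is 1.0;
any rate with a zero denominator is 0.0 and raises a warning.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "ConfusionCounts",
    "RegionSets",
    "confusion",
    "accuracy",
    "precision",
    "recall",
    "sensitivity",
    "specificity",
    "overall_accuracy",
    "dice",
    "region_dice",
    "MetricReport",
]

COMPOSITE_REGIONS = {"WT": (1, 2, 3), "TC": (1, 3), "ET": (3,)}
CLASS_NAMES = {0: "background", 1: "necrotic", 2: "edema", 3: "enhancing"}


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel-wise confusion counts for one positive class."""

    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class RegionSets:
    """Predicted / ground-truth tumor and non-tumor pixel sets (boolean masks)."""

    C1: np.ndarray  # predicted tumor
    C0: np.ndarray  # predicted non-tumor
    G1: np.ndarray  # true tumor
    G0: np.ndarray  # true non-tumor

    @classmethod
    def from_labels(cls, pred: np.ndarray, truth: np.ndarray, positive_class=1) -> "RegionSets":
        pred = np.asarray(pred)
        truth = np.asarray(truth)
        if pred.shape != truth.shape:
            raise ValueError(f"pred shape {pred.shape} != truth shape {truth.shape}")
        classes = np.atleast_1d(positive_class)
        c1 = np.isin(pred, classes)
        g1 = np.isin(truth, classes)
        return cls(C1=c1, C0=~c1, G1=g1, G0=~g1)


def _zero_denominator(name: str) -> float:
    warnings.warn(f"{name}: zero denominator, returning 0.0 by convention", stacklevel=3)
    return 0.0


def confusion(pred: np.ndarray, truth: np.ndarray, positive_class=1) -> ConfusionCounts:
    """Exact confusion counts treating ``positive_class`` (scalar or tuple) as positive."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"pred shape {pred.shape} != truth shape {truth.shape}")
    classes = np.atleast_1d(positive_class)
    p = np.isin(pred, classes)
    t = np.isin(truth, classes)
    return ConfusionCounts(
        TP=int(np.sum(p & t)),
        TN=int(np.sum(~p & ~t)),
        FP=int(np.sum(p & ~t)),
        FN=int(np.sum(~p & t)),
    )


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    if c.total == 0:
        return _zero_denominator("accuracy")
    return (c.TP + c.TN) / c.total


def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP)."""
    if c.TP + c.FP == 0:
        return _zero_denominator("precision")
    return c.TP / (c.TP + c.FP)


def recall(c: ConfusionCounts) -> float:
    """TP / (TP + FN)."""
    if c.TP + c.FN == 0:
        return _zero_denominator("recall")
    return c.TP / (c.TP + c.FN)


def sensitivity(sets: RegionSets) -> float:
    """|C1 ∩ G1| / |G1| — fraction of true tumor pixels predicted as tumor."""
    denom = int(sets.G1.sum())
    if denom == 0:
        return _zero_denominator("sensitivity")
    return float(np.sum(sets.C1 & sets.G1)) / denom


def specificity(sets: RegionSets) -> float:
    """|C0 ∩ G0| / |G0| — fraction of true non-tumor pixels predicted as such."""
    denom = int(sets.G0.sum())
    if denom == 0:
        return _zero_denominator("specificity")
    return float(np.sum(sets.C0 & sets.G0)) / denom


def overall_accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    """Multi-class pixel accuracy: fraction of pixels with the correct label."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"pred shape {pred.shape} != truth shape {truth.shape}")
    if pred.size == 0:
        return _zero_denominator("overall_accuracy")
    return float(np.mean(pred == truth))


def dice(set_c: np.ndarray, set_d: np.ndarray) -> float:
    """Dice similarity 2|C ∩ D| / (|C| + |D|); 1.0 when both sets are empty."""
    set_c = np.asarray(set_c, dtype=bool)
    set_d = np.asarray(set_d, dtype=bool)
    if set_c.shape != set_d.shape:
        raise ValueError(f"set shapes differ: {set_c.shape} vs {set_d.shape}")
    denom = int(set_c.sum()) + int(set_d.sum())
    if denom == 0:
        return 1.0
    return 2.0 * float(np.sum(set_c & set_d)) / denom


def region_dice(pred: np.ndarray, truth: np.ndarray) -> dict:
    """Dice for the composite regions WT / TC / ET on mapped labels {0..3}."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    for name, arr in (("pred", pred), ("truth", truth)):
        bad = np.setdiff1d(np.unique(arr), [0, 1, 2, 3])
        if bad.size:
            raise ValueError(f"{name} contains labels outside {{0..3}}: {bad.tolist()}")
    return {
        region: dice(np.isin(pred, classes), np.isin(truth, classes))
        for region, classes in COMPOSITE_REGIONS.items()
    }


class MetricReport(dict):
    """Flat name -> value metric table with CSV/JSON serialization."""

    @classmethod
    def evaluate(cls, pred: np.ndarray, truth: np.ndarray, num_classes: int = 4) -> "MetricReport":
        """Full evaluation of predicted vs true label volumes (mapped labels).

        Reports overall pixel accuracy, whole-tumor sensitivity/specificity/
        precision, per-class one-vs-rest Dice, the WT/TC/ET composite Dice,
        and per-class sensitivity averages.
        """
        report = cls()
        report["accuracy"] = overall_accuracy(pred, truth)
        tumor_classes = tuple(range(1, num_classes))
        sets = RegionSets.from_labels(pred, truth, tumor_classes)
        report["sensitivity"] = sensitivity(sets)
        report["specificity"] = specificity(sets)
        report["precision"] = precision(confusion(pred, truth, tumor_classes))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # absent classes fall back to conventions
            per_class_sens = []
            for c in range(1, num_classes):
                name = CLASS_NAMES.get(c, f"class{c}")
                report[f"dice_coef_{name}"] = dice(pred == c, truth == c)
                per_class_sens.append(sensitivity(RegionSets.from_labels(pred, truth, c)))
            report["sensitivity_per_class_mean"] = float(np.mean(per_class_sens))
        fg = [report[f"dice_coef_{CLASS_NAMES.get(c, f'class{c}')}"] for c in range(1, num_classes)]
        report["dice_coef"] = float(np.mean(fg))
        if num_classes == 4:  # composite regions are defined on the 4-class mapping
            for region, value in region_dice(pred, truth).items():
                report[f"dice_{region}"] = value
        return report

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({k: float(v) for k, v in self.items()}, indent=2))

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["metric", "value"])
            for key, value in self.items():
                writer.writerow([key, f"{float(value):.6f}"])
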