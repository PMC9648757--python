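"""Segmentation scoring: pixel confusion counts, Jaccard and Dice indices.

With TP/FP/FN/TN the usual pixel counts (255 = lesion),

    Jaccard = TP / (TP + FP + FN)
    Dice    = 2·TP / ((FP + TP) + (TP + FN))

and the algebraic identity J = D / (2 − D) holds for every pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .image_core import InvalidInputError, read_mask, validate_mask

__all__ = [
    "ConfusionCounts",
    "MetricRecord",
    "confusion",
    "jaccard",
    "dice",
    "score_pair",
    "evaluate_batch",
    "write_report",
]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricRecord:
    image_id: str
    jaccard: float
    dice: float


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixelwise confusion counts between two binary masks."""
    pred = validate_mask(pred)
    truth = validate_mask(truth)
    if pred.shape != truth.shape:
        raise InvalidInputError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    p = pred == 255
    t = truth == 255
    return ConfusionCounts(
        tp=int((p & t).sum()),
        fp=int((p & ~t).sum()),
        fn=int((~p & t).sum()),
        tn=int((~p & ~t).sum()),
    )


def _handle_empty(empty_is_perfect: bool) -> float:
    if empty_is_perfect:
        warnings.warn("both masks empty; reporting 1.0 by convention", stacklevel=3)
        return 1.0
    return float("nan")


def jaccard(c: ConfusionCounts, empty_is_perfect: bool = True) -> float:
    """TP / (TP + FP + FN); both-empty masks score 1.0 (with a warning) by default."""
    denom = c.tp + c.fp + c.fn
    if denom == 0:
        return _handle_empty(empty_is_perfect)
    return c.tp / denom


def dice(c: ConfusionCounts, empty_is_perfect: bool = True) -> float:
    """2·TP / ((FP + TP) + (TP + FN)); both-empty masks score 1.0 by default."""
    denom = (c.fp + c.tp) + (c.tp + c.fn)
    if denom == 0:
        return _handle_empty(empty_is_perfect)
    return 2.0 * c.tp / denom


def score_pair(pred: np.ndarray, truth: np.ndarray, image_id: str = "", empty_is_perfect: bool = True) -> MetricRecord:
    c = confusion(pred, truth)
    return MetricRecord(image_id=image_id, jaccard=jaccard(c, empty_is_perfect), dice=dice(c, empty_is_perfect))


def evaluate_batch(pairs: list[tuple[str, str]], empty_is_perfect: bool = True) -> pd.DataFrame:
    """Score a list of ``(pred_path, truth_path)`` mask files.

    Returns a frame with columns image_id/jaccard/dice/error sorted by
    image id; unreadable or mismatched pairs carry the error message and are
    excluded from the mean rows appended by :func:`write_report`.
    """
    rows = []
    for pred_path, truth_path in pairs:
        image_id = str(pred_path)
        try:
            rec = score_pair(read_mask(pred_path), read_mask(truth_path), image_id, empty_is_perfect)
            rows.append({"image_id": image_id, "jaccard": rec.jaccard, "dice": rec.dice, "error": ""})
        except Exception as exc:  # noqa: BLE001 - reported per image, batch continues
            rows.append({"image_id": image_id, "jaccard": np.nan, "dice": np.nan, "error": str(exc)})
    frame = pd.DataFrame(rows, columns=["image_id", "jaccard", "dice", "error"])
    return frame.sort_values("image_id", kind="stable").reset_index(drop=True)


def write_report(frame: pd.DataFrame, path: str) -> None:
    """Write the per-image CSV report with mean_jaccard / mean_dice rows."""
    out = frame.copy()
    ok = out["error"] == ""
    if len(out):
        means = pd.DataFrame(
            [
                {"image_id": "mean_jaccard", "jaccard": out.loc[ok, "jaccard"].mean(), "dice": np.nan, "error": ""},
                {"image_id": "mean_dice", "jaccard": np.nan, "dice": out.loc[ok, "dice"].mean(), "error": ""},
            ]
        )
        out = pd.concat([out, means], ignore_index=True)
    out.to_csv(path, index=False)
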