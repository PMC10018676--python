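"""Segmentation evaluation: Dice overlap and Hausdorff boundary distance.

Dice is |P ∩ T| / ((|P| + |T|) / 2).  The Hausdorff distance is the exact
max-of-min (not the 95th-percentile variant) between the two boundary point
sets, where a boundary pixel is a mask pixel with at least one background
4-neighbor; distances are Euclidean, optionally scaled by per-axis pixel
spacing (mm).

Per-case evaluation groups the label vocabulary the way pathology studies
report it: infarction alone (MI), infarction + edema union (MI+ME), and the
three anatomy classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion
from scipy.spatial import cKDTree

from .errors import ShapeError
from .vocab import EVAL_GROUPS, NUM_CLASSES

__all__ = ["dice", "hausdorff", "evaluate_case", "CaseResult", "write_report"]


def dice(P: np.ndarray, T: np.ndarray) -> float:
    """Dice similarity of two binary masks in [0, 1].

    Both masks empty -> 1.0 (vacuous agreement); exactly one empty -> 0.0.
    """
    P = np.asarray(P, dtype=bool)
    T = np.asarray(T, dtype=bool)
    if P.shape != T.shape:
        raise ShapeError(f"mask shapes differ: {P.shape} vs {T.shape}")
    p, t = int(P.sum()), int(T.sum())
    if p == 0 and t == 0:
        return 1.0
    inter = int((P & T).sum())
    return inter / ((p + t) / 2.0)


_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def _boundary_points(mask: np.ndarray) -> np.ndarray:
    interior = binary_erosion(mask, structure=_CROSS, border_value=0)
    return np.argwhere(mask & ~interior)


def hausdorff(P: np.ndarray, T: np.ndarray, spacing=None) -> float:
    """Exact symmetric Hausdorff distance between mask boundaries.

    Returns ``inf`` if either mask is empty (the caller decides how to report
    that; it is never silently zero).
    """
    P = np.asarray(P, dtype=bool)
    T = np.asarray(T, dtype=bool)
    if P.shape != T.shape:
        raise ShapeError(f"mask shapes differ: {P.shape} vs {T.shape}")
    if not P.any() or not T.any():
        return math.inf
    sp = np.ones(P.ndim) if spacing is None else np.asarray(spacing, dtype=float)
    bp = _boundary_points(P) * sp
    bt = _boundary_points(T) * sp
    d_pt = cKDTree(bt).query(bp)[0].max()
    d_tp = cKDTree(bp).query(bt)[0].max()
    return float(max(d_pt, d_tp))


@dataclass
class CaseResult:
    """Per-group Dice and Hausdorff distance for one case."""

    dice: dict
    hd: dict
    warnings: list = field(default_factory=list)


def group_mask(labels: np.ndarray, group: str) -> np.ndarray:
    return np.isin(labels, EVAL_GROUPS[group])


def evaluate_case(pred: np.ndarray, truth: np.ndarray, spacing=None) -> CaseResult:
    """Dice and Hausdorff for the five evaluation groups of one label map pair."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ShapeError(f"label shapes differ: {pred.shape} vs {truth.shape}")
    values = set(np.unique(pred)) | set(np.unique(truth))
    bad = sorted(int(v) for v in values if not 0 <= v < NUM_CLASSES)
    if bad:
        raise ValueError(f"unknown label values: {bad}")
    d, h, warnings = {}, {}, []
    for name in EVAL_GROUPS:
        mp, mt = group_mask(pred, name), group_mask(truth, name)
        d[name] = dice(mp, mt)
        h[name] = hausdorff(mp, mt, spacing)
        if math.isinf(h[name]):
            warnings.append(f"{name}: empty mask, Hausdorff undefined (inf)")
    return CaseResult(dice=d, hd=h, warnings=warnings)


def write_report(results: dict, path) -> pd.DataFrame:
    """Write per-case, per-group dice/hd rows plus mean and std aggregate rows.

    `results` maps case ids to CaseResult.  Infinite Hausdorff values are kept
    as-is in per-case rows and excluded from the aggregates.
    """
    rows = [
        {"case_id": cid, "group": g, "dice": res.dice[g], "hd": res.hd[g]}
        for cid, res in results.items()
        for g in EVAL_GROUPS
    ]
    df = pd.DataFrame(rows, columns=["case_id", "group", "dice", "hd"])
    finite = df.replace([np.inf, -np.inf], np.nan)
    for stat in ("mean", "std"):
        agg = finite.groupby("group", sort=False).agg({"dice": stat, "hd": stat}).reset_index()
        agg.insert(0, "case_id", stat)
        df = pd.concat([df, agg], ignore_index=True)
    df.to_csv(path, index=False)
    return df
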