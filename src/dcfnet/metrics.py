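"""Evaluation indicators: Dice overlap, Hausdorff boundary distances
(maximum and 95th percentile), and binary confusion-matrix metrics.

Conventions (documented, fixed):

* Empty-class Dice — both masks empty: 1; exactly one empty: 0.
* Boundaries are mask pixels with at least one background 4-neighbor
  (image border counts as background); distances are Euclidean, in pixel
  units unless a spacing vector is given.
* HD is the symmetric maximum of directed boundary distances; HD95 takes
  the 95th percentile of each directed distance set before the max, so
  HD95 <= HD always.
* Multi-slice cases can be stacked to 3D volumes per case before
  computing DSC/HD (the volume-wise protocol of multi-organ CT / cardiac
  MR evaluation); per-slice evaluation is the default for 2D data.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "MetricReport",
    "dsc_metric",
    "boundary_points",
    "hausdorff",
    "confusion_metrics",
    "evaluate_case",
    "evaluate_dataset",
    "write_report",
]


@dataclass
class MetricReport:
    """Per-class and aggregate metric record for one case or a dataset."""

    per_class_dsc: list = field(default_factory=list)
    mean_dsc: float = float("nan")
    hd: float = float("nan")
    hd95: float = float("nan")
    ac: float = float("nan")
    pr: float = float("nan")
    se: float = float("nan")
    sp: float = float("nan")
    iou: float = float("nan")

    def as_dict(self) -> dict:
        return asdict(self)


def dsc_metric(P_mask, L_mask, cls: int | None = None) -> float:
    """Dice coefficient 2|P∩L| / (|P|+|L|) of binarized class masks.

    With ``cls`` given, masks are binarized at that class index;
    otherwise they are treated as already-binary. Both-empty masks score
    1, one-empty scores 0.
    """
    P = np.asarray(P_mask)
    L = np.asarray(L_mask)
    if P.shape != L.shape:
        raise ValueError(f"mask shape mismatch: {P.shape} vs {L.shape}")
    if cls is not None:
        P, L = P == cls, L == cls
    else:
        P, L = P.astype(bool), L.astype(bool)
    sp, sl = int(P.sum()), int(L.sum())
    if sp == 0 and sl == 0:
        return 1.0
    inter = int(np.logical_and(P, L).sum())
    return 2.0 * inter / (sp + sl)


def boundary_points(mask: np.ndarray) -> np.ndarray:
    """Coordinates of mask pixels with >= 1 background 4-neighbor (n, ndim)."""
    mask = np.asarray(mask).astype(bool)
    if mask.ndim not in (2, 3):
        raise ValueError("masks must be 2D or 3D")
    interior = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(mask.ndim, 1),
        border_value=0)
    return np.argwhere(mask & ~interior)


def hausdorff(P_mask, L_mask, percentile: float = 100.0,
              spacing=None) -> float:
    """Symmetric (percentile) Hausdorff distance between mask boundaries.

    Returns NaN with a warning if either boundary is empty.
    """
    if not (0 < percentile <= 100):
        raise ValueError("percentile must lie in (0, 100]")
    bp = boundary_points(P_mask)
    bl = boundary_points(L_mask)
    if len(bp) == 0 or len(bl) == 0:
        warnings.warn("empty boundary: Hausdorff distance undefined, reporting NaN")
        return float("nan")
    if spacing is not None:
        sp = np.asarray(spacing, dtype=float)
        bp = bp * sp
        bl = bl * sp
    d_pl = cKDTree(bl).query(bp, k=1)[0]
    d_lp = cKDTree(bp).query(bl, k=1)[0]
    if percentile >= 100:
        return float(max(d_pl.max(), d_lp.max()))
    return float(max(np.percentile(d_pl, percentile), np.percentile(d_lp, percentile)))


def confusion_metrics(P_mask, L_mask) -> MetricReport:
    """Accuracy / precision / sensitivity / specificity / IoU of binary masks.

    Undefined ratios (zero denominators) are reported as NaN.
    """
    P = np.asarray(P_mask).astype(bool)
    L = np.asarray(L_mask).astype(bool)
    if P.shape != L.shape:
        raise ValueError(f"mask shape mismatch: {P.shape} vs {L.shape}")
    tp = int((P & L).sum())
    fp = int((P & ~L).sum())
    fn = int((~P & L).sum())
    tn = int((~P & ~L).sum())

    def ratio(num, den):
        return num / den if den else float("nan")

    return MetricReport(
        per_class_dsc=[dsc_metric(P, L)],
        mean_dsc=dsc_metric(P, L),
        ac=ratio(tp + tn, tp + fp + fn + tn),
        pr=ratio(tp, tp + fp),
        se=ratio(tp, tp + fn),
        sp=ratio(tn, tn + fp),
        iou=ratio(tp, tp + fp + fn),
    )


def evaluate_case(pred: np.ndarray, label: np.ndarray, num_classes: int,
                  spacing=None) -> MetricReport:
    """Foreground per-class DSC plus HD/HD95 over the union of foreground
    boundaries; adds confusion metrics in the binary case."""
    pred = np.asarray(pred)
    label = np.asarray(label)
    dscs = [dsc_metric(pred, label, cls=c) for c in range(1, num_classes)]
    hds, hd95s = [], []
    for c in range(1, num_classes):
        p, l = pred == c, label == c
        if p.any() and l.any():
            hds.append(hausdorff(p, l, 100.0, spacing))
            hd95s.append(hausdorff(p, l, 95.0, spacing))
    rep = MetricReport(
        per_class_dsc=dscs,
        mean_dsc=float(np.mean(dscs)) if dscs else float("nan"),
        hd=float(np.mean(hds)) if hds else float("nan"),
        hd95=float(np.mean(hd95s)) if hd95s else float("nan"),
    )
    if num_classes == 2:
        cm = confusion_metrics(pred == 1, label == 1)
        rep.ac, rep.pr, rep.se, rep.sp, rep.iou = cm.ac, cm.pr, cm.se, cm.sp, cm.iou
    return rep


def evaluate_dataset(preds, labels, num_classes: int, spacing=None):
    """Per-case reports plus their aggregate (nan-mean over cases)."""
    cases = [evaluate_case(p, l, num_classes, spacing) for p, l in zip(preds, labels)]
    if not cases:
        raise ValueError("no cases to evaluate")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        agg = MetricReport(
            per_class_dsc=list(np.nanmean([c.per_class_dsc for c in cases], axis=0)),
            mean_dsc=float(np.nanmean([c.mean_dsc for c in cases])),
            hd=float(np.nanmean([c.hd for c in cases])),
            hd95=float(np.nanmean([c.hd95 for c in cases])),
            ac=float(np.nanmean([c.ac for c in cases])),
            pr=float(np.nanmean([c.pr for c in cases])),
            se=float(np.nanmean([c.se for c in cases])),
            sp=float(np.nanmean([c.sp for c in cases])),
            iou=float(np.nanmean([c.iou for c in cases])),
        )
    return cases, agg


def write_report(path_prefix, cases, agg) -> None:
    """Write per-case and aggregate metrics as CSV and JSON."""
    rows = [{"case": i, **c.as_dict()} for i, c in enumerate(cases)]
    rows.append({"case": "mean", **agg.as_dict()})
    with open(str(path_prefix) + ".json", "w") as fh:
        json.dump(rows, fh, indent=2, default=float)
    with open(str(path_prefix) + ".csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        for r in rows:
            r = dict(r)
            r["per_class_dsc"] = "|".join(f"{v:.6f}" for v in r["per_class_dsc"])
            writer.writerow(r)
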