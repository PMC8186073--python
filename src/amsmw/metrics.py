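"""Segmentation evaluation metrics.

Area metrics compare binary masks pixelwise (Acc, TPR, FPR, JI, DSC, AER
plus the confusion-matrix set DC, Sen, Sp, F1, Pc, M-IOU); contour metrics
(Hausdorff error HE and mean absolute contour error MAE) compare boundary
point sets in pixel units. Note the field conventions: FPR and AER are
normalised by the ground-truth area (not by the background), so both can
exceed 1 for gross over-segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import DomainError
from .image_model import as_binary_mask

__all__ = [
    "AreaMetrics",
    "area_metrics",
    "hausdorff",
    "mean_absolute_error",
    "evaluate_batch",
]


@dataclass(frozen=True)
class AreaMetrics:
    Acc: float
    TPR: float
    FPR: float
    JI: float
    DSC: float
    AER: float
    Sp: float
    Pc: float
    F1: float
    M_IOU: float

    # aliases used for the open-dataset metric set
    @property
    def DC(self) -> float:
        return self.DSC

    @property
    def Sen(self) -> float:
        return self.TPR

    def as_dict(self) -> dict[str, float]:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["DC"] = self.DC
        d["Sen"] = self.Sen
        return d


def area_metrics(gt: np.ndarray, pred: np.ndarray) -> AreaMetrics:
    """Pixelwise overlap metrics between ground truth and prediction.

    Acc = (TP + TN)/|A|; TPR = TP/|A_G|; FPR = |A_G∪A_S − A_G|/|A_G|;
    JI = |∩|/|∪|; DSC = 2|∩|/(|A_G|+|A_S|); AER = (|∪|−|∩|)/|A_G|;
    Sp = TN/(TN+FP); Pc = TP/(TP+FP); F1 = harmonic mean of Pc and TPR;
    M-IOU = mean of foreground and background IoU.
    """
    gt = as_binary_mask(gt)
    pred = as_binary_mask(pred, gt.shape)
    n_gt = int(gt.sum())
    if n_gt == 0:
        raise DomainError("ground-truth mask is empty")
    tp = int((gt & pred).sum())
    fp = int((~gt & pred).sum())
    fn = int((gt & ~pred).sum())
    tn = int((~gt & ~pred).sum())
    total = gt.size
    union = tp + fp + fn
    iou_fg = tp / union if union else 1.0
    bg_union = tn + fp + fn
    iou_bg = tn / bg_union if bg_union else 1.0
    pc = tp / (tp + fp) if (tp + fp) else 0.0
    tpr = tp / n_gt
    f1 = 2 * pc * tpr / (pc + tpr) if (pc + tpr) else 0.0
    return AreaMetrics(
        Acc=(tp + tn) / total,
        TPR=tpr,
        FPR=fp / n_gt,
        JI=iou_fg,
        DSC=2 * tp / (n_gt + tp + fp) if (n_gt + tp + fp) else 0.0,
        AER=(union - tp) / n_gt,
        Sp=tn / (tn + fp) if (tn + fp) else 1.0,
        Pc=pc,
        F1=f1,
        M_IOU=0.5 * (iou_fg + iou_bg),
    )


def _contour_points(c: np.ndarray) -> np.ndarray:
    pts = np.asarray(c, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) == 0:
        raise DomainError("contour must be a non-empty (N, 2) array")
    return pts


def hausdorff(c1: np.ndarray, c2: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two contour point sets
    (Euclidean, pixel-centre coordinates)."""
    p1, p2 = _contour_points(c1), _contour_points(c2)
    d = cdist(p1, p2)
    return float(max(d.min(axis=1).max(), d.min(axis=0).max()))


def mean_absolute_error(c1: np.ndarray, c2: np.ndarray) -> float:
    """Half the sum of the two mean nearest-point distances between the
    contours; symmetric in its arguments and bounded above by HE."""
    p1, p2 = _contour_points(c1), _contour_points(c2)
    d = cdist(p1, p2)
    return float(0.5 * (d.min(axis=1).mean() + d.min(axis=0).mean()))


_METRIC_COLUMNS = ["Acc", "TPR", "FPR", "JI", "DSC", "AER", "Sp", "Pc", "F1", "M_IOU"]


def evaluate_batch(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    strata: list[str] | None = None,
    contours: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-pair metric table plus per-stratum and overall mean/std summary.

    ``pairs`` holds (ground truth, prediction) mask pairs; ``strata`` an
    optional per-pair label (e.g. benign/malignant). With ``contours`` the
    boundary metrics HE and MAE are added (outer boundaries of the masks).
    Returns (per_pair, summary); the summary reports mean and the
    per-image standard deviation for every metric.
    """
    if not pairs:
        raise DomainError("empty evaluation batch")
    if strata is not None and len(strata) != len(pairs):
        raise DomainError("strata length does not match number of pairs")
    rows = []
    for i, (gt, pred) in enumerate(pairs):
        try:
            m = area_metrics(gt, pred)
        except DomainError as exc:
            raise DomainError(f"pair {i}: {exc}") from exc
        row: dict[str, float | str | int] = {"pair": i, **{k: getattr(m, k) for k in _METRIC_COLUMNS}}
        if contours:
            from .image_model import mask_to_contour

            if not np.asarray(pred).any():
                row["HE"] = np.nan
                row["MAE"] = np.nan
            else:
                cg = mask_to_contour(gt)
                cs = mask_to_contour(pred)
                row["HE"] = hausdorff(cg, cs)
                row["MAE"] = mean_absolute_error(cg, cs)
        if strata is not None:
            row["stratum"] = strata[i]
        rows.append(row)
    per_pair = pd.DataFrame(rows).set_index("pair")
    value_cols = [c for c in per_pair.columns if c != "stratum"]
    groups: list[tuple[str, pd.DataFrame]] = [("overall", per_pair)]
    if strata is not None:
        for name, sub in per_pair.groupby("stratum"):
            groups.append((str(name), sub))
    summary_rows = []
    for name, sub in groups:
        means = sub[value_cols].mean()
        stds = sub[value_cols].std(ddof=0)
        rec: dict[str, float | str] = {"stratum": name, "n": len(sub)}
        for c in value_cols:
            rec[f"{c}_mean"] = means[c]
            rec[f"{c}_std"] = stds[c]
        summary_rows.append(rec)
    summary = pd.DataFrame(summary_rows).set_index("stratum")
    return per_pair, summary
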