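"""Pixel-level evaluation: confusion counts, the five metrics, bootstrap CIs.

Accuracy, sensitivity, specificity and F1 are integer-ratio formulas on
the in-FOV confusion counts at threshold 0.5; AUROC is the Mann–Whitney
rank statistic (ties counted one half), which equals the area under the
empirical ROC curve exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ContingencyCounts",
    "MetricsReport",
    "confusion_counts",
    "compute_metrics",
    "auroc",
    "bootstrap_ci",
    "format_report_table",
]

METRIC_NAMES = ("acc", "se", "sp", "f1", "auroc")


@dataclass
class ContingencyCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    acc: float
    se: float
    sp: float
    f1: float
    auroc: float = float("nan")
    ci: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def _binary(arr, name: str) -> np.ndarray:
    a = np.asarray(arr)
    if a.dtype != bool:
        uniq = np.unique(a)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError(f"{name} must be binary, got values {uniq[:5]}")
        a = a.astype(bool)
    return a


def confusion_counts(pred, gt, fov=None) -> ContingencyCounts:
    """Count TP/FP/TN/FN over the pixels inside the FOV mask (if given)."""
    pred = _binary(pred, "pred")
    gt = _binary(gt, "gt")
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    if fov is not None:
        fov = _binary(fov, "fov")
        if fov.shape != gt.shape:
            raise ValueError(f"shape mismatch: fov {fov.shape} vs gt {gt.shape}")
        pred, gt = pred[fov], gt[fov]
    tp = int(np.count_nonzero(pred & gt))
    fp = int(np.count_nonzero(pred & ~gt))
    tn = int(np.count_nonzero(~pred & ~gt))
    fn = int(np.count_nonzero(~pred & gt))
    return ContingencyCounts(tp, fp, tn, fn)


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN",
                      RuntimeWarning, stacklevel=3)
        return float("nan")
    return num / den


def compute_metrics(c: ContingencyCounts) -> MetricsReport:
    """Acc, SE, SP and F1 from confusion counts (AUROC left NaN)."""
    if c.total == 0:
        raise ValueError("no pixels evaluated")
    return MetricsReport(
        acc=_ratio(c.tp + c.tn, c.total, "accuracy"),
        se=_ratio(c.tp, c.tp + c.fn, "sensitivity"),
        sp=_ratio(c.tn, c.tn + c.fp, "specificity"),
        f1=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, "f1"),
    )


def auroc(probs, labels) -> float:
    """Area under the ROC curve via the Mann–Whitney U statistic."""
    p = np.asarray(probs, dtype=np.float64).ravel()
    y = _binary(labels, "labels").ravel()
    if p.shape != y.shape:
        raise ValueError("probs and labels must have the same length")
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined: both classes must be present")
    ranks = rankdata(p)  # average ranks -> ties counted 1/2
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def bootstrap_ci(per_image_metrics, n_boot: int = 1000, alpha: float = 0.05,
                 seed: int = 0) -> dict:
    """Percentile bootstrap of the per-image mean, per metric.

    ``per_image_metrics``: sequence of dicts (one per test image) mapping
    metric name to value.  Returns ``{metric: (low, high)}``.
    """
    if len(per_image_metrics) < 2:
        raise ValueError("need at least two test images for an interval")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable intervals", RuntimeWarning)
    rng = np.random.default_rng(seed)
    names = list(per_image_metrics[0])
    values = np.array([[m[name] for name in names] for m in per_image_metrics])
    n = values.shape[0]
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_means = np.nanmean(values[idx], axis=1)  # n_boot x n_metrics
    lo = np.percentile(boot_means, 100 * alpha / 2, axis=0)
    hi = np.percentile(boot_means, 100 * (1 - alpha / 2), axis=0)
    return {name: (float(l), float(h)) for name, l, h in zip(names, lo, hi)}


def format_report_table(rows: dict, fmt: str = "markdown") -> str:
    """Render ``{method: {metric: (mean, low, high)}}`` as a table.

    Values are scaled to percent and printed as ``mean (low, high)``.
    """
    header = ["Methods"] + [m.upper() for m in METRIC_NAMES]
    lines = []
    for method, metrics in rows.items():
        cells = [method]
        for name in METRIC_NAMES:
            mean, lo, hi = metrics[name]
            cells.append(f"{100 * mean:.1f} ({100 * lo:.1f}, {100 * hi:.1f})")
        lines.append(cells)
    if fmt == "csv":
        out = [",".join(header)]
        out += [",".join(f'"{c}"' if "," in c else c for c in row) for row in lines]
        return "\n".join(out) + "\n"
    out = ["| " + " | ".join(header) + " |",
           "|" + "---|" * len(header)]
    out += ["| " + " | ".join(row) + " |" for row in lines]
    return "\n".join(out) + "\n"
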