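"""Segmentation metrics, percent-non-vitrified quantification, k-shot curves.

The headline quantity for end users is the percentage of non-vitrified
(crystalline) area per micrograph, aggregated per dataset as mean ± a 95%
normal-approximation confidence interval over micrographs. IoU and F1 are the
model-comparison metrics; for binary masks they satisfy F1 = 2·IoU/(1+IoU)
exactly, which the tests exploit as an internal consistency check.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .io_formats import SegmentationMask
from .synthetic import Task

__all__ = [
    "iou", "f1", "percent_nonvitrified", "aggregate_ci",
    "DatasetReport", "KShotCurve", "kshot_curve",
    "write_report_csv", "write_report_json", "format_percent_ci",
    "plot_kshot_curve",
]

Z_975 = 1.959964  # standard-normal 97.5% quantile, for the 95% CI


def _mask_array(m) -> np.ndarray:
    arr = m.mask if isinstance(m, SegmentationMask) else np.asarray(m)
    return arr.astype(bool)


def iou(pred, gt) -> float:
    """Intersection over union; both-empty pairs score 1.0 (a clean lamella
    predicted clean is a success)."""
    p, g = _mask_array(pred), _mask_array(gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    union = np.logical_or(p, g).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(p, g).sum() / union)


def f1(pred, gt) -> float:
    """Dice / F1 overlap; both-empty pairs score 1.0."""
    p, g = _mask_array(pred), _mask_array(gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    denom = p.sum() + g.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(p, g).sum() / denom)


def percent_nonvitrified(mask) -> float:
    """Foreground pixels as a percentage of all pixels, in [0, 100]."""
    m = _mask_array(mask)
    return float(100.0 * m.sum() / m.size)


def aggregate_ci(values: Sequence[float], level: float = 0.95) -> tuple[float, float]:
    """Mean and half-width of a normal-approximation CI over the values.

    Half-width = z_{(1+level)/2} · s / √n with the sample (ddof=1) standard
    deviation; needs n ≥ 2.
    """
    vals = np.asarray(values, dtype=np.float64)
    if vals.size < 2:
        raise ValueError("confidence interval needs at least 2 values")
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    from scipy.stats import norm
    z = float(norm.ppf(0.5 + level / 2.0))
    mean = float(vals.mean())
    half = z * float(vals.std(ddof=1)) / np.sqrt(vals.size)
    return mean, float(half)


@dataclass
class DatasetReport:
    """Per-dataset quantification: one percent value per micrograph."""

    per_image_percent: list[float]
    mean_percent: float
    ci95_halfwidth: float
    image_ids: list[str] = field(default_factory=list)
    ci_method: str = "normal-approximation, per-image replication"

    @classmethod
    def from_percents(cls, percents: Sequence[float],
                      image_ids: Sequence[str] | None = None) -> "DatasetReport":
        percents = [float(p) for p in percents]
        if any(not (0.0 <= p <= 100.0) for p in percents):
            raise ValueError("percent values must lie in [0, 100]")
        if len(percents) >= 2:
            mean, half = aggregate_ci(percents)
        elif len(percents) == 1:
            mean, half = percents[0], float("nan")
        else:
            mean, half = float("nan"), float("nan")
        return cls(per_image_percent=percents, mean_percent=mean,
                   ci95_halfwidth=half,
                   image_ids=list(image_ids) if image_ids else [])


def format_percent_ci(report: DatasetReport) -> str:
    """Render as 'mean% ± halfwidth%' (the per-dataset summary line)."""
    return f"{report.mean_percent:.2f}% ± {report.ci95_halfwidth:.2f}%"


def write_report_csv(path, report: DatasetReport) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["image_id", "percent_nonvitrified"])
        ids = report.image_ids or [str(i) for i in range(len(report.per_image_percent))]
        for iid, p in zip(ids, report.per_image_percent):
            w.writerow([iid, f"{p:.6f}"])


def write_report_json(path, report: DatasetReport) -> None:
    payload = {
        "per_image_percent": [round(p, 6) for p in report.per_image_percent],
        "mean_percent": round(report.mean_percent, 6)
        if np.isfinite(report.mean_percent) else None,
        "ci95_halfwidth": round(report.ci95_halfwidth, 6)
        if np.isfinite(report.ci95_halfwidth) else None,
        "summary": format_percent_ci(report)
        if np.isfinite(report.mean_percent) and np.isfinite(report.ci95_halfwidth)
        else None,
        "ci_method": report.ci_method,
        "image_ids": report.image_ids,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# k-shot evaluation curves
# ---------------------------------------------------------------------------

@dataclass
class KShotCurve:
    """Mean (IoU, F1) per k for each method, on a fixed evaluation task set."""

    k_values: list[int]
    per_method: dict[str, list[tuple[float, float]]]

    def __post_init__(self):
        for name, vals in self.per_method.items():
            if len(vals) != len(self.k_values):
                raise ValueError(f"method {name!r}: {len(vals)} entries for "
                                 f"{len(self.k_values)} k values")
            for i_, f_ in vals:
                if not (0.0 <= i_ <= 1.0 and 0.0 <= f_ <= 1.0):
                    raise ValueError("metric values must lie in [0, 1]")


def kshot_curve(models: Mapping[str, "object"], tasks: Sequence[Task],
                ks: Sequence[int], cfg,
                adapt: Callable | None = None) -> KShotCurve:
    """Evaluate each model's k-shot adaptation across evaluation tasks.

    models maps a method name (e.g. "maml", "baseline", "random") to its
    initial parameters. For each k, each model is adapted on the *first* k
    support pairs of every task (supports are nested across k so curves are
    comparable) and scored by mean IoU/F1 on the query set.

    adapt(theta, pairs, cfg) -> adapted parameters; defaults to the inner-loop
    gradient descent used at meta-test time.
    """
    from .meta import K_SHOT_MAX, K_SHOT_MIN, evaluate_pairs, inner_adapt
    ks = [int(k) for k in ks]
    if any(k < K_SHOT_MIN or k > K_SHOT_MAX for k in ks):
        raise ValueError(f"every k must lie in [{K_SHOT_MIN}, {K_SHOT_MAX}]")
    kmax = max(ks)
    for t in tasks:
        if len(t.support) < kmax:
            raise ValueError(
                f"task {t.dataset_id!r} has {len(t.support)} support pairs; "
                f"needs >= {kmax}")
    if adapt is None:
        adapt = lambda theta, pairs, c: inner_adapt(theta, pairs, c).phi
    per_method: dict[str, list[tuple[float, float]]] = {}
    for name, theta in models.items():
        rows = []
        for k in ks:
            ious, f1s = [], []
            for t in tasks:
                phi = adapt(theta, t.support[:k], cfg)
                mi, mf = evaluate_pairs(phi, t.query)
                ious.append(mi)
                f1s.append(mf)
            rows.append((float(np.mean(ious)), float(np.mean(f1s))))
        per_method[name] = rows
    return KShotCurve(k_values=ks, per_method=per_method)


def plot_kshot_curve(curve: KShotCurve, path) -> None:
    """Two-panel (IoU, F1) comparison plot across k-shot scenarios."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharex=True)
    for name, vals in curve.per_method.items():
        axes[0].plot(curve.k_values, [v[0] for v in vals], marker="o", label=name)
        axes[1].plot(curve.k_values, [v[1] for v in vals], marker="o", label=name)
    axes[0].set_ylabel("IoU")
    axes[1].set_ylabel("F1")
    for ax in axes:
        ax.set_xlabel("k (shots)")
        ax.set_ylim(0, 1)
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
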