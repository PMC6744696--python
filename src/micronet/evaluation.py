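"""Detection scoring against point annotations.

Each annotated center defines a gold-standard disk of ``radius`` pixels
(16 by default).  Detections are assigned to annotations one-to-one by the
Hungarian algorithm minimizing total Euclidean distance, with pairs farther
apart than the radius forbidden.  Assigned pairs are true positives,
unassigned detections false positives, unassigned annotations false
negatives; precision, recall, F1 and the mean Euclidean distance over true
positives summarize a report.  Precision-recall curves sweep the
suppression threshold xi, and the operating xi is chosen by maximizing F1
on a validation set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .inference import DEFAULT_MIN_DISTANCE, DetectionSet, detect, predict_batch

__all__ = [
    "MatchReport",
    "MetricSummary",
    "match",
    "metrics",
    "pr_curve",
    "select_xi",
    "aggregate",
    "GOLD_RADIUS",
]

#: radius of the gold-standard disk around an annotated center, in pixels
GOLD_RADIUS = 16.0


@dataclass
class MatchReport:
    """Outcome of matching one image's detections against its annotations."""

    tp_pairs: list[tuple[tuple[float, float], tuple[float, float], float]] = field(
        default_factory=list
    )
    fp: list[tuple[float, float]] = field(default_factory=list)
    fn: list[tuple[float, float]] = field(default_factory=list)
    radius: float = GOLD_RADIUS

    @property
    def tp(self) -> int:
        return len(self.tp_pairs)


@dataclass
class MetricSummary:
    precision: float
    recall: float
    f1: float
    mean_ed: float
    tp: int
    fp: int
    fn: int


def _points(obj) -> list[tuple[float, float]]:
    if isinstance(obj, DetectionSet):
        return list(obj.points)
    return [(float(r), float(c)) for r, c in obj]


def match(detections, annotations, radius: float = GOLD_RADIUS) -> MatchReport:
    """Hungarian matching of detections to annotations.

    Only pairs within ``radius`` are assignable; the cost of an assignable
    pair is its Euclidean distance, all other pairs carry a sentinel cost
    large enough that the solver only uses them when no valid pairing is
    left, and such pairs are dissolved into an FP + FN afterwards.
    """
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    dets = _points(detections)
    anns = _points(annotations)
    if not dets or not anns:
        return MatchReport(fp=dets, fn=anns, radius=radius)
    d = np.asarray(dets, dtype=float)
    a = np.asarray(anns, dtype=float)
    dist = np.sqrt(((d[:, None, :] - a[None, :, :]) ** 2).sum(axis=2))
    sentinel = (len(dets) + len(anns) + 1) * (radius + 1.0)
    cost = np.where(dist <= radius, dist, sentinel)
    rows, cols = linear_sum_assignment(cost)
    report = MatchReport(radius=radius)
    matched_d, matched_a = set(), set()
    for i, j in zip(rows, cols):
        if dist[i, j] <= radius:
            report.tp_pairs.append((dets[i], anns[j], float(dist[i, j])))
            matched_d.add(i)
            matched_a.add(j)
    report.fp = [dets[i] for i in range(len(dets)) if i not in matched_d]
    report.fn = [anns[j] for j in range(len(anns)) if j not in matched_a]
    return report


def metrics(report: MatchReport) -> MetricSummary:
    """Precision, recall, F1 and mean Euclidean distance of a match report.

    Degenerate conventions: with annotations but no detections (or vice
    versa) the undefined ratio is 0; with neither, P = R = F1 = 1.
    """
    tp, fp, fn = report.tp, len(report.fp), len(report.fn)
    return _metrics_from_counts(
        tp, fp, fn, mean_ed=float(np.mean([d for _, _, d in report.tp_pairs])) if tp else 0.0
    )


def _metrics_from_counts(tp: int, fp: int, fn: int, mean_ed: float = 0.0) -> MetricSummary:
    if tp + fp + fn == 0:
        return MetricSummary(1.0, 1.0, 1.0, mean_ed, 0, 0, 0)
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return MetricSummary(p, r, f1, mean_ed, tp, fp, fn)


def pooled_metrics(reports: Sequence[MatchReport], average: str = "micro") -> MetricSummary:
    """Multi-image metrics.

    ``micro`` (default) pools TP/FP/FN counts (and TP distances) across
    images before forming the ratios — robust to images with few nuclei.
    ``macro`` averages each image's own P/R/F1/ED, weighting images
    equally.
    """
    if average == "macro":
        per = [metrics(r) for r in reports]
        return MetricSummary(
            float(np.mean([s.precision for s in per])),
            float(np.mean([s.recall for s in per])),
            float(np.mean([s.f1 for s in per])),
            float(np.mean([s.mean_ed for s in per])),
            sum(s.tp for s in per),
            sum(s.fp for s in per),
            sum(s.fn for s in per),
        )
    if average != "micro":
        raise ValueError(f"average must be 'micro' or 'macro', got {average!r}")
    tp = sum(r.tp for r in reports)
    fp = sum(len(r.fp) for r in reports)
    fn = sum(len(r.fn) for r in reports)
    dists = [d for r in reports for _, _, d in r.tp_pairs]
    return _metrics_from_counts(tp, fp, fn, float(np.mean(dists)) if dists else 0.0)


def _evaluate_grid(network, samples, xi_grid, radius, min_distance):
    """Predict each sample once, then score every xi on the shared maps."""
    maps = predict_batch(network, [s.image for s in samples])
    out = []
    for xi in xi_grid:
        reports = [
            match(detect(m, xi, min_distance), s.centers, radius)
            for m, s in zip(maps, samples)
        ]
        out.append(pooled_metrics(reports))
    return out


def pr_curve(
    network,
    samples,
    xi_grid: Sequence[float],
    radius: float = GOLD_RADIUS,
    min_distance: int = DEFAULT_MIN_DISTANCE,
) -> list[tuple[float, float, float]]:
    """One pooled (xi, precision, recall) point per grid value."""
    if len(xi_grid) == 0:
        raise ValueError("xi_grid must be non-empty")
    summaries = _evaluate_grid(network, samples, xi_grid, radius, min_distance)
    return [(float(xi), s.precision, s.recall) for xi, s in zip(xi_grid, summaries)]


def select_xi(
    network,
    validation_samples,
    xi_grid: Sequence[float],
    radius: float = GOLD_RADIUS,
    min_distance: int = DEFAULT_MIN_DISTANCE,
) -> float:
    """The grid xi maximizing pooled validation F1; ties go to the larger xi
    (fewer, more confident detections)."""
    if len(validation_samples) == 0:
        raise ValueError("validation set must be non-empty")
    if len(xi_grid) == 0:
        raise ValueError("xi_grid must be non-empty")
    summaries = _evaluate_grid(network, validation_samples, xi_grid, radius, min_distance)
    best_xi, best_f1 = None, -1.0
    for xi, s in zip(xi_grid, summaries):
        if s.f1 >= best_f1:  # >= : later (larger) grid values win ties
            best_xi, best_f1 = float(xi), s.f1
    return best_xi


def aggregate(summaries: Sequence[MetricSummary]) -> dict[str, tuple[float, float]]:
    """Mean and sample standard deviation of each metric across datasets
    (sd = 0 for a single dataset)."""
    if len(summaries) == 0:
        raise ValueError("need at least one summary")

    def ms(values):
        v = np.asarray(values, dtype=float)
        return float(v.mean()), float(v.std(ddof=1)) if len(v) > 1 else 0.0

    return {
        "precision": ms([s.precision for s in summaries]),
        "recall": ms([s.recall for s in summaries]),
        "f1": ms([s.f1 for s in summaries]),
        "mean_ed": ms([s.mean_ed for s in summaries]),
    }
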