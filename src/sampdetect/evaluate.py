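"""Performance metrics: confusion summaries, detection efficiency against
ground truth, size histograms, field-of-view coverage and throughput.

The confusion summary follows the evaluation protocol of the reference
system: a prediction counts as a correct answer only when the label matches
the truth AND the confidence is at least a threshold (default 90 %).  The
plain label-agreement rate is reported alongside, since the two can differ
when a correct label comes with low confidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import CLASS_ORDER, Prediction
from .report import ParticleRecord
from .simulate import GroundTruthLog

__all__ = ["ConfusionSummary", "EfficiencyResult", "confusion_summary",
           "detection_efficiency", "size_histogram", "fov_coverage",
           "throughput_particles_per_minute"]


@dataclass
class ConfusionSummary:
    """Evaluated-as x true-class counts plus per-class correct-answer rates."""

    counts: np.ndarray                  # [predicted, true] over CLASS_ORDER
    correct_rate_pct: dict              # per true class, with confidence rule
    average_pct: float
    label_only_rate_pct: dict           # ignoring the confidence threshold
    confidence_threshold: float
    n_evaluated: int


@dataclass
class EfficiencyResult:
    efficiency_pct: float
    n_truth: int
    n_matched: int
    n_records: int
    false_positives: int
    merged_pairs: int = 0

    def __float__(self) -> float:
        return self.efficiency_pct


def confusion_summary(predictions: list[Prediction], truths: list[str],
                      confidence_threshold: float = 90.0) -> ConfusionSummary:
    """Per-class correct-answer rates with the confidence rule.

    A correct label with confidence below the threshold counts as
    incorrect.  The average is the unweighted mean of the per-class rates.
    Order-invariant; raises on empty input.
    """
    if len(predictions) == 0:
        raise ValueError("empty evaluation set")
    if len(predictions) != len(truths):
        raise ValueError("predictions and truths must be paired")
    idx = {c: i for i, c in enumerate(CLASS_ORDER)}
    counts = np.zeros((len(CLASS_ORDER), len(CLASS_ORDER)), dtype=int)
    correct = {c: 0 for c in CLASS_ORDER}
    label_ok = {c: 0 for c in CLASS_ORDER}
    n_true = {c: 0 for c in CLASS_ORDER}
    for pred, truth in zip(predictions, truths):
        counts[idx[pred.label], idx[truth]] += 1
        n_true[truth] += 1
        if pred.label == truth:
            label_ok[truth] += 1
            if pred.confidence_pct >= confidence_threshold:
                correct[truth] += 1
    rates = {c: 100.0 * correct[c] / n_true[c] for c in CLASS_ORDER if n_true[c]}
    label_rates = {c: 100.0 * label_ok[c] / n_true[c]
                   for c in CLASS_ORDER if n_true[c]}
    average = float(np.mean(list(rates.values())))
    return ConfusionSummary(counts=counts, correct_rate_pct=rates,
                            average_pct=average,
                            label_only_rate_pct=label_rates,
                            confidence_threshold=confidence_threshold,
                            n_evaluated=len(predictions))


def detection_efficiency(records: list[ParticleRecord], truth: GroundTruthLog,
                         max_match_distance_px: float = 12.0
                         ) -> EfficiencyResult:
    """Fraction of ground-truth window traversers recovered, as a percentage.

    A record matches a truth particle when its counted centroid lies within
    ``max_match_distance_px`` of that particle's rendered position at the
    counted frame; matching is one-to-one, greedy by distance.  Records
    matching no truth particle are reported as false positives, never as
    efficiency.  Merged touching pairs show up as unmatched truths whose
    partner was matched during a touching frame.
    """
    travs = truth.traversers()
    pairs = []
    for ri, rec in enumerate(records):
        for ti, tp in enumerate(travs):
            t = rec.frame_counted
            if not (0 <= t < len(tp.render_offsets)):
                continue
            pos = tp.rendered_centroid(t)
            d = float(np.hypot(pos[0] - rec.centroid[0], pos[1] - rec.centroid[1]))
            if d <= max_match_distance_px:
                pairs.append((round(d, 9), ri, ti))
    pairs.sort()
    used_r: set[int] = set()
    used_t: set[int] = set()
    for _, ri, ti in pairs:
        if ri in used_r or ti in used_t:
            continue
        used_r.add(ri)
        used_t.add(ti)
    n_matched = len(used_t)
    n_truth = len(travs)
    merged = sum(1 for ti, tp in enumerate(travs)
                 if ti not in used_t and tp.touching_frames)
    eff = 100.0 * n_matched / n_truth if n_truth else 100.0
    return EfficiencyResult(efficiency_pct=eff, n_truth=n_truth,
                            n_matched=n_matched, n_records=len(records),
                            false_positives=len(records) - len(used_r),
                            merged_pairs=merged)


def size_histogram(sizes_um, bin_edges_um=None) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of particle sizes; default 50-um bins from 0 to 500 um.

    ``sizes_um`` may be a sequence of numbers or of ParticleRecords.
    Returns (counts, bin_edges); values beyond the last edge are collected
    into the final bin so the counts always partition the input.
    """
    if bin_edges_um is None:
        bin_edges_um = np.arange(0.0, 501.0, 50.0)
    vals = np.array([s.size_um if isinstance(s, ParticleRecord) else float(s)
                     for s in sizes_um])
    edges = np.asarray(bin_edges_um, dtype=float)
    clipped = np.clip(vals, edges[0], np.nextafter(edges[-1], edges[0]))
    counts, _ = np.histogram(clipped, bins=edges)
    return counts, edges


def fov_coverage(view_width_mm: float, channel_width_mm: float) -> float:
    """Percent of the flow-cell channel width covered by the field of view,
    reported to one decimal (11.2 mm of a 12 mm channel -> 93.3)."""
    if channel_width_mm <= 0 or view_width_mm < 0:
        raise ValueError("widths must be positive")
    return round(100.0 * view_width_mm / channel_width_mm, 1)


def throughput_particles_per_minute(n_particles: int, n_frames: int,
                                    frame_rate_fps: float) -> float:
    """Informational throughput; hardware-dependent, never asserted."""
    minutes = n_frames / frame_rate_fps / 60.0
    return n_particles / minutes if minutes > 0 else float("nan")
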