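"""Scoring predictions against annotations.

Two granularities are supported. Segment level counts whole units: a truth
exon is a true positive when some prediction covers at least a fraction
``overlap_rule`` of it, and the negative universe is a count of noncoding
units (by default the gaps between and flanking the truth exons, i.e.
n_exons + 1). Nucleotide level classifies every position.

From the counts the eight standard threshold metrics are computed:

    Sn = TP/(TP+FN)      Sp = TN/(TN+FP)       Ac = (TP+TN)/total
    PP = TP/(TP+FP)      NP = TN/(TN+FN)       ER = (FP+FN)/total
    FDR = FP/(TP+FP)     FOR = FN/(TN+FN)

A ratio with zero denominator is reported as ``None`` (undefined), never
silently coerced to 0 or 1.
"""

from __future__ import annotations

import json
import math
import os
from typing import Optional, Sequence

import numpy as np

from .caller import CallerSpec, call_regions
from .errors import DegenerateInputError, ValidationError
from .types import ConfusionCounts, GenomicIntervals, MetricsReport, NumericSignal, RocCurve


def _overlap_length(iv: tuple[int, int], others: GenomicIntervals) -> int:
    s, e = iv
    total = 0
    for os_, oe in others.intervals:
        total += max(0, min(e, oe) - max(s, os_))
    return total


def segment_confusion(
    predicted: GenomicIntervals,
    truth: GenomicIntervals,
    noncoding_units: Optional[int] = None,
    overlap_rule: float = 0.5,
) -> ConfusionCounts:
    """Whole-exon confusion counts.

    TP: truth exons covered >= overlap_rule of their length by predictions.
    FN: the remaining truth exons.
    FP: predictions overlapping no truth exon at all.
    TN: noncoding_units - FP, floored at 0. ``noncoding_units`` defaults to
    the number of gaps between and flanking the truth exons (len(truth)+1).
    """
    if predicted.sequence_id != truth.sequence_id:
        raise ValidationError(
            f"sequence id mismatch: {predicted.sequence_id!r} vs {truth.sequence_id!r}"
        )
    if not (0.0 < overlap_rule <= 1.0):
        raise ValidationError("overlap_rule must lie in (0, 1]")
    if noncoding_units is None:
        noncoding_units = len(truth) + 1
    if noncoding_units < 0:
        raise ValidationError("noncoding_units must be >= 0")
    tp = sum(
        1
        for iv in truth.intervals
        if _overlap_length(iv, predicted) >= overlap_rule * (iv[1] - iv[0])
    )
    fn = len(truth) - tp
    fp = sum(1 for iv in predicted.intervals if _overlap_length(iv, truth) == 0)
    tn = max(0, noncoding_units - fp)
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn, level="segment")


def nucleotide_confusion(
    predicted: GenomicIntervals,
    truth: GenomicIntervals,
    seq_length: int,
) -> ConfusionCounts:
    """Per-position confusion counts; counts sum to ``seq_length``."""
    if predicted.sequence_id != truth.sequence_id:
        raise ValidationError(
            f"sequence id mismatch: {predicted.sequence_id!r} vs {truth.sequence_id!r}"
        )
    pred = predicted.mask(seq_length)
    pos = truth.mask(seq_length)
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & ~pos))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn, level="nucleotide")


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """The eight threshold metrics from confusion counts (see module docs)."""
    if counts.total == 0:
        raise DegenerateInputError("all confusion counts are zero")
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    return MetricsReport(
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        accuracy=_ratio(tp + tn, counts.total),
        positive_precision=_ratio(tp, tp + fp),
        negative_precision=_ratio(tn, tn + fn),
        error_rate=_ratio(fp + fn, counts.total),
        false_discovery_rate=_ratio(fp, tp + fp),
        false_omission_rate=_ratio(fn, tn + fn),
    )


def roc_curve(
    profile: NumericSignal,
    truth: GenomicIntervals,
    thresholds: Optional[Sequence[float]] = None,
    level: str = "nucleotide",
    caller_spec: Optional[CallerSpec] = None,
    noncoding_units: Optional[int] = None,
) -> RocCurve:
    """Threshold-swept ROC curve with trapezoidal AUC.

    One (FPR, TPR) point per threshold; the curve is anchored at (0, 0) and
    (1, 1) before integration. At nucleotide level the predicted positives at
    threshold t are exactly the positions with profile value >= t; at
    segment level each threshold's calls go through :func:`call_regions`
    (min length 1, no gap merging unless a caller_spec is given).
    """
    if profile.stage != "normalized":
        raise ValidationError("roc_curve expects a normalized profile")
    if thresholds is None:
        thresholds = np.round(np.arange(0.05, 0.951, 0.05), 10).tolist()
    if len(thresholds) < 2:
        raise ValidationError("at least two thresholds are required")
    if level not in ("nucleotide", "segment"):
        raise ValidationError(f"unknown ROC level {level!r}")

    n = len(profile)
    points: list[tuple[float, float]] = []
    if level == "nucleotide":
        pos = truth.mask(n)
        n_pos, n_neg = int(pos.sum()), int((~pos).sum())
        if n_pos == 0 or n_neg == 0:
            raise DegenerateInputError(
                "truth has no positives or no negatives at nucleotide level"
            )
        for t in thresholds:
            pred = profile.values >= t
            tpr = float(np.sum(pred & pos)) / n_pos
            fpr = float(np.sum(pred & ~pos)) / n_neg
            points.append((fpr, tpr))
    else:
        spec = caller_spec or CallerSpec(threshold=0.5, min_region_length=1, merge_gap=0)
        for t in thresholds:
            calls = call_regions(
                profile,
                CallerSpec(
                    threshold=t,
                    min_region_length=spec.min_region_length,
                    merge_gap=spec.merge_gap,
                ),
            )
            c = segment_confusion(calls, truth, noncoding_units=noncoding_units)
            if c.tp + c.fn == 0 or c.fp + c.tn == 0:
                raise DegenerateInputError("degenerate truth at segment level")
            points.append((c.fp / (c.fp + c.tn), c.tp / (c.tp + c.fn)))

    pts = sorted(set(points) | {(0.0, 0.0), (1.0, 1.0)})
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    auc = float(np.trapezoid(ys, xs))
    return RocCurve(points=tuple(pts), auc=auc)


def snr_db(profile: NumericSignal, truth: GenomicIntervals) -> float:
    """Coding/noncoding discrimination in decibels.

    10*log10(mean profile energy inside truth exons / mean outside). Returns
    ``inf`` when the noncoding mean is zero.
    """
    n = len(profile)
    mask = truth.mask(n)
    if not mask.any() or mask.all():
        raise DegenerateInputError(
            "truth must be non-empty and must not cover the whole sequence"
        )
    inside = float(np.mean(profile.values[mask]))
    outside = float(np.mean(profile.values[~mask]))
    if outside <= 0.0:
        return math.inf
    if inside <= 0.0:
        return -math.inf
    return 10.0 * math.log10(inside / outside)


# ---------------------------------------------------------------------------
# report output


def write_metrics(
    counts: ConfusionCounts,
    report: MetricsReport,
    path_prefix: str | os.PathLike,
) -> None:
    """Write a metrics report as ``<prefix>.tsv`` and ``<prefix>.json``."""
    payload = {
        "level": counts.level,
        "counts": {"tp": counts.tp, "fp": counts.fp, "fn": counts.fn, "tn": counts.tn},
        "metrics": report.as_dict(),
    }
    with open(f"{path_prefix}.json", "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
    with open(f"{path_prefix}.tsv", "w") as fh:
        fh.write("metric\tvalue\n")
        for k in ("tp", "fp", "fn", "tn"):
            fh.write(f"{k}\t{payload['counts'][k]}\n")
        for k, v in report.as_dict().items():
            fh.write(f"{k}\t{'NA' if v is None else f'{v:.6f}'}\n")


def write_roc(curve: RocCurve, path: str | os.PathLike) -> None:
    """Write ROC points as TSV with the AUC in a header comment."""
    with open(path, "w") as fh:
        fh.write(f"# auc\t{curve.auc:.6f}\n")
        fh.write("fpr\ttpr\n")
        for fpr, tpr in curve.points:
            fh.write(f"{fpr:.6f}\t{tpr:.6f}\n")
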