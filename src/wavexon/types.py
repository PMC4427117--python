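"""Core domain types shared by every pipeline stage.

Coordinates are 0-based half-open everywhere inside the package; conversion
to/from 1-based formats happens only at the I/O boundary (:mod:`wavexon.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import ValidationError

DNA_ALPHABET = frozenset("ACGTN")

#: Pipeline stages a :class:`NumericSignal` can be in, in processing order.
STAGES = ("eiip", "bandpassed", "energy", "denoised", "normalized")


@dataclass(frozen=True)
class DnaSequence:
    """A named DNA string over {A, C, G, T, N}.

    The sequence is uppercased on construction; any character outside the
    alphabet raises :class:`ValidationError` naming its position.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        seq = self.seq.upper()
        object.__setattr__(self, "seq", seq)
        for i, ch in enumerate(seq):
            if ch not in DNA_ALPHABET:
                raise ValidationError(
                    f"sequence {self.id!r}: invalid character {ch!r} at position {i}"
                )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GenomicIntervals:
    """Ordered, non-overlapping half-open intervals on one sequence."""

    sequence_id: str
    intervals: tuple[tuple[int, int], ...]
    label: str = "predicted"

    def __post_init__(self) -> None:
        ivs = tuple((int(s), int(e)) for s, e in self.intervals)
        object.__setattr__(self, "intervals", ivs)
        prev_end = None
        for s, e in ivs:
            if not (0 <= s < e):
                raise ValidationError(
                    f"{self.sequence_id}: invalid interval [{s}, {e}) "
                    "(need 0 <= start < end)"
                )
            if prev_end is not None and s < prev_end:
                raise ValidationError(
                    f"{self.sequence_id}: intervals unsorted or overlapping at [{s}, {e})"
                )
            prev_end = e

    @classmethod
    def from_unsorted(
        cls,
        sequence_id: str,
        intervals: Iterable[tuple[int, int]],
        label: str = "predicted",
    ) -> "GenomicIntervals":
        """Build from arbitrary (start, end) pairs: sort and merge overlaps."""
        ivs = sorted((int(s), int(e)) for s, e in intervals)
        merged: list[tuple[int, int]] = []
        for s, e in ivs:
            if not (0 <= s < e):
                raise ValidationError(
                    f"{sequence_id}: invalid interval [{s}, {e}) (need 0 <= start < end)"
                )
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        return cls(sequence_id, tuple(merged), label)

    def total_length(self) -> int:
        return sum(e - s for s, e in self.intervals)

    def mask(self, length: int) -> np.ndarray:
        """Boolean membership mask of the given length."""
        m = np.zeros(length, dtype=bool)
        for s, e in self.intervals:
            if e > length:
                raise ValidationError(
                    f"{self.sequence_id}: interval [{s}, {e}) exceeds length {length}"
                )
            m[s:e] = True
        return m

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class NumericSignal:
    """A per-position real signal derived from a DNA sequence.

    ``stage`` records where the signal sits in the pipeline so downstream
    operations can enforce their preconditions.
    """

    sequence_id: str
    values: np.ndarray
    stage: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValidationError("signal values must be one-dimensional")
        if self.stage not in STAGES:
            raise ValidationError(f"unknown signal stage {self.stage!r}")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValidationError("signal contains non-finite values")

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass
class WaveletDecomposition:
    """Multilevel DWT coefficients plus the metadata needed to invert them.

    ``details[0]`` is the finest (level-1) detail band; ``approx`` is the
    coarsest approximation. ``original_length`` allows exact-length
    reconstruction and energy-profile upsampling.
    """

    sequence_id: str
    wavelet_name: str
    levels: int
    approx: np.ndarray
    details: list[np.ndarray]
    boundary_mode: str
    original_length: int

    def __post_init__(self) -> None:
        if self.levels < 1 or len(self.details) != self.levels:
            raise ValidationError(
                f"expected {self.levels} detail bands, got {len(self.details)}"
            )

    def coefficient_energy(self) -> float:
        total = float(np.sum(self.approx**2))
        for d in self.details:
            total += float(np.sum(d**2))
        return total


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN/TN at segment (whole exon/gap units) or nucleotide granularity."""

    tp: int
    fp: int
    fn: int
    tn: int
    level: str = "nucleotide"

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValidationError(f"negative count {name}")
        if self.level not in ("segment", "nucleotide"):
            raise ValidationError(f"unknown confusion level {self.level!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    """The eight threshold metrics; ``None`` marks a zero-denominator ratio."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    accuracy: Optional[float]
    positive_precision: Optional[float]
    negative_precision: Optional[float]
    error_rate: Optional[float]
    false_discovery_rate: Optional[float]
    false_omission_rate: Optional[float]

    def as_dict(self) -> dict[str, Optional[float]]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "positive_precision": self.positive_precision,
            "negative_precision": self.negative_precision,
            "error_rate": self.error_rate,
            "false_discovery_rate": self.false_discovery_rate,
            "false_omission_rate": self.false_omission_rate,
        }


@dataclass(frozen=True)
class RocCurve:
    """Threshold-swept ROC points (ordered by FPR) and their trapezoidal AUC."""

    points: tuple[tuple[float, float], ...]
    auc: float

    def __post_init__(self) -> None:
        for fpr, tpr in self.points:
            if not (0.0 <= fpr <= 1.0 and 0.0 <= tpr <= 1.0):
                raise ValidationError("ROC rates must lie in [0, 1]")
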