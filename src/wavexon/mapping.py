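"""EIIP numerical mapping of DNA sequences.

The electron-ion interaction potential (EIIP) assigns each nucleotide the
average energy of its delocalised electrons, turning a DNA string into a
single real-valued signal (one number per base, versus four binary indicator
tracks). The default table is the standard one used throughout the genomic
signal processing literature:

====  ======
base  EIIP
====  ======
A     0.1260
G     0.0806
T     0.1335
C     0.1340
====  ======
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import ValidationError
from .types import DnaSequence, NumericSignal

log = logging.getLogger(__name__)

DEFAULT_EIIP = {"A": 0.1260, "G": 0.0806, "T": 0.1335, "C": 0.1340}


@dataclass(frozen=True)
class EiipTable:
    """Per-nucleotide EIIP potentials (dimensionless, Rydberg scale)."""

    values: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_EIIP))

    def __post_init__(self) -> None:
        if set(self.values) != {"A", "C", "G", "T"}:
            raise ValidationError(
                f"EIIP table must have exactly the keys A, C, G, T; got {sorted(self.values)}"
            )
        object.__setattr__(self, "values", dict(self.values))

    @property
    def mean(self) -> float:
        """Mean of the four potentials; the substitution value for N bases."""
        return sum(self.values.values()) / 4.0


def map_eiip(
    seq: DnaSequence,
    table: EiipTable | None = None,
    n_policy: str = "mean",
) -> NumericSignal:
    """Map a DNA sequence position-wise through an EIIP table.

    Parameters
    ----------
    seq
        Validated DNA sequence (characters in {A, C, G, T, N}).
    table
        EIIP potentials; defaults to the standard table.
    n_policy
        ``"mean"`` substitutes the table mean for N bases (with a warning);
        ``"error"`` raises on the first N, naming its position.

    Returns
    -------
    NumericSignal at stage ``"eiip"``, one value per base.
    """
    if table is None:
        table = EiipTable()
    if n_policy not in ("mean", "error"):
        raise ValidationError(f"unknown n_policy {n_policy!r}")

    lut = np.full(128, np.nan)
    for base, v in table.values.items():
        lut[ord(base)] = v
    if n_policy == "mean":
        lut[ord("N")] = table.mean

    codes = np.frombuffer(seq.seq.encode("ascii"), dtype=np.uint8)
    if n_policy == "error":
        n_pos = np.nonzero(codes == ord("N"))[0]
        if n_pos.size:
            raise ValidationError(
                f"sequence {seq.id!r}: ambiguous base N at position {int(n_pos[0])} "
                "(n_policy='error')"
            )
    elif np.any(codes == ord("N")):
        log.warning(
            "sequence %r contains %d N bases; mapping them to the table mean %.6f",
            seq.id, int(np.sum(codes == ord("N"))), table.mean,
        )
    values = lut[codes] if codes.size else np.empty(0)
    return NumericSignal(seq.id, values, stage="eiip")
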