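"""Protein-production rates and top-fraction expression gating.

The production rate of a cell is the difference between its
fluorescence at 48 h and at 0 h (a plain difference, not a ratio).
Ground-truth class labels come from an exact empirical-quantile gate:
the cells with the largest rates — exactly ``round(fraction * n)`` of
them, top 10% by default — are labelled HIGH, the rest LOW_ORDINARY.
Ties at the threshold are broken by ascending cell id (lower id wins
HIGH) so the count is always exact and the gate deterministic.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .errors import InputError

HIGH = "HIGH"
LOW_ORDINARY = "LOW_ORDINARY"

MIN_GATE_SIZE = 10   # below this the empirical quantile is unstable


@dataclass(frozen=True)
class ProductionLabel:
    cell_id: int
    rate: float
    label: str
    threshold_used: float


def production_rate(fl_0h: float, fl_48h: float) -> float:
    """48 h fluorescence minus 0 h fluorescence; may be negative."""
    if not (math.isfinite(fl_0h) and math.isfinite(fl_48h)):
        raise InputError("fluorescence values must be finite")
    return fl_48h - fl_0h


def gate_top_fraction(rates: Sequence[float], fraction: float = 0.10,
                      cell_ids: Sequence[int] | None = None
                      ) -> list[ProductionLabel]:
    """Label the top ``fraction`` of rates HIGH, the rest LOW_ORDINARY.

    Exactly ``round(fraction * n)`` cells are HIGH, chosen as the
    largest rates with ties at the threshold resolved by ascending
    cell id.  ``threshold_used`` is the smallest HIGH rate.  Labels are
    returned in the input order of ``rates``.
    """
    n = len(rates)
    if n < MIN_GATE_SIZE:
        raise InputError(
            f"need at least {MIN_GATE_SIZE} rates to gate, got {n}")
    if not (0.0 < fraction < 1.0):
        raise InputError("fraction must be in (0, 1)")
    if cell_ids is None:
        cell_ids = list(range(n))
    elif len(cell_ids) != n:
        raise InputError("cell_ids and rates must have equal length")

    n_high = round(fraction * n)
    order = sorted(range(n), key=lambda i: (-rates[i], cell_ids[i]))
    high_idx = set(order[:n_high])
    threshold = min((rates[i] for i in high_idx), default=math.inf)
    return [
        ProductionLabel(
            cell_id=cell_ids[i],
            rate=float(rates[i]),
            label=HIGH if i in high_idx else LOW_ORDINARY,
            threshold_used=threshold,
        )
        for i in range(n)
    ]


def labels_to_csv(labels: Sequence[ProductionLabel], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["cell_id", "rate", "label", "threshold_used"])
        for lab in labels:
            writer.writerow([lab.cell_id, lab.rate, lab.label,
                             lab.threshold_used])
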