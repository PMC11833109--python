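"""Cell/marker-bead dispense sequences and their CSV dialect.

A dispense sequence is the ordered stream of tokens leaving the imaging
flow cytometer (or observed on the cell placement platform): CELL tokens
carrying a cell id, interleaved with BEAD tokens carrying a bead label
(size class or color, e.g. A/T/C).  The CSV dialect has columns
``position, token_kind, token_label, cell_id`` with ``cell_id`` empty
for beads and ``token_label`` empty for cells.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from .errors import InputError

CELL = "CELL"
BEAD = "BEAD"


@dataclass(frozen=True)
class Token:
    """One element of a dispense sequence.

    ``label`` is the bead type for BEAD tokens (empty for cells);
    ``ref_id`` is the cell id for CELL tokens (None for beads).
    """

    kind: str
    label: str = ""
    ref_id: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in (CELL, BEAD):
            raise InputError(f"unknown token kind {self.kind!r}")
        if self.kind == BEAD and not self.label:
            raise InputError("BEAD token requires a bead label")
        if self.kind == CELL and self.ref_id is None:
            raise InputError("CELL token requires a cell ref_id")


def cell(ref_id: int) -> Token:
    return Token(CELL, ref_id=ref_id)


def bead(label: str) -> Token:
    return Token(BEAD, label=label)


@dataclass
class DispenseSequence:
    """Ordered cell/bead token stream."""

    tokens: list[Token] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self) -> Iterator[Token]:
        return iter(self.tokens)

    def __getitem__(self, i):
        return self.tokens[i]

    @property
    def cell_ids(self) -> list[int]:
        return [t.ref_id for t in self.tokens if t.kind == CELL]

    @property
    def n_cells(self) -> int:
        return sum(1 for t in self.tokens if t.kind == CELL)

    @property
    def n_beads(self) -> int:
        return sum(1 for t in self.tokens if t.kind == BEAD)

    def bead_labels(self) -> list[str]:
        return [t.label for t in self.tokens if t.kind == BEAD]

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["position", "token_kind", "token_label", "cell_id"])
            for pos, tok in enumerate(self.tokens):
                writer.writerow([
                    pos,
                    tok.kind,
                    tok.label,
                    "" if tok.ref_id is None else tok.ref_id,
                ])

    @classmethod
    def from_csv(cls, path: str | Path) -> "DispenseSequence":
        tokens: list[Token] = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                kind = row["token_kind"]
                if kind == BEAD:
                    tokens.append(bead(row["token_label"]))
                elif kind == CELL:
                    tokens.append(cell(int(row["cell_id"])))
                else:
                    raise InputError(f"unknown token kind {kind!r} in {path}")
        return cls(tokens)
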