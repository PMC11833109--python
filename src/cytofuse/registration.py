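"""Marker-bead sequence registration.

Cells leaving the imaging flow cytometer are dispensed first-in-first-out
onto the placement membrane together with marker beads of distinct
sizes/colors.  The bead-delimited structure of both streams is the key
to matching each imaged cell to its membrane position: a segment C/2/T
means two cells sit between a C bead and a T bead.  If the two bead/count
sequences agree, the cells of each segment are mapped positionally;
segments whose counts disagree are error sections (a missing cell is a
deletion, a surplus one a displacement) and are excluded from analysis.

Bead labels are treated as reliably observed anchors (beads are large
and distinct) while cell counts are the noisy signal: when the bead
label subsequences differ, they are first aligned by longest common
subsequence (leftmost tie-break, for determinism), unaligned spans are
flagged ``bead_mismatch``, and aligned segment pairs are then compared
by count.  Equal counts with different underlying cells — a swap that
never crosses a bead — are undetectable by this scheme and are accepted
as matched; that is an inherent limitation of count-based registration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .errors import InputError, StructuralError
from .sequences import BEAD, CELL, DispenseSequence

__all__ = [
    "Segment", "RegistrationResult", "encode_segments", "match_sequences",
]


@dataclass(frozen=True)
class Segment:
    """The run of cells between two consecutive marker beads.

    Written ``left/count/right`` (e.g. C/2/T).  ``cell_ids`` is known
    on the IFC side only, where each cell token carries its image id.
    """

    left_bead: str
    cell_count: int
    right_bead: str
    cell_ids: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.cell_ids and len(self.cell_ids) != self.cell_count:
            raise InputError("cell_count must equal len(cell_ids)")

    def __str__(self) -> str:
        return f"{self.left_bead}/{self.cell_count}/{self.right_bead}"


@dataclass
class RegistrationResult:
    """Outcome of matching the IFC sequence against the CPP sequence."""

    matched_segments: list[tuple[int, int]] = field(default_factory=list)
    error_segments: list[tuple[int, str]] = field(default_factory=list)
    mapping: list[tuple[int, int]] = field(default_factory=list)
    yield_fraction: float = 0.0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "matched_segments": [list(p) for p in self.matched_segments],
            "error_segments": [[i, r] for i, r in self.error_segments],
            "mapping": [list(p) for p in self.mapping],
            "yield_fraction": self.yield_fraction,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @property
    def mapped_cell_ids(self) -> list[int]:
        return [cid for cid, _ in self.mapping]


def encode_segments(sequence: DispenseSequence) -> list[Segment]:
    """Encode a bead-bounded token sequence into ordered segments.

    One segment per consecutive bead pair; adjacent beads produce a
    zero-count segment.  The concatenated counts equal the total number
    of cell tokens.
    """
    toks = list(sequence)
    if not toks:
        raise StructuralError("empty sequence cannot be segmented")
    if toks[0].kind != BEAD or toks[-1].kind != BEAD:
        raise StructuralError(
            "sequence must begin and end with BEAD tokens")
    segments: list[Segment] = []
    left = toks[0].label
    ids: list[int] = []
    for tok in toks[1:]:
        if tok.kind == CELL:
            ids.append(tok.ref_id)
        elif tok.kind == BEAD:
            segments.append(Segment(left, len(ids), tok.label, tuple(ids)))
            left = tok.label
            ids = []
        else:  # pragma: no cover - Token constructor forbids this
            raise InputError(f"unknown token kind {tok.kind!r}")
    return segments


def _lcs_pairs(a: list[str], b: list[str]) -> list[tuple[int, int]]:
    """Longest-common-subsequence alignment with leftmost tie-break."""
    na, nb = len(a), len(b)
    # L[i][j] = LCS length of a[i:], b[j:]
    L = [[0] * (nb + 1) for _ in range(na + 1)]
    for i in range(na - 1, -1, -1):
        for j in range(nb - 1, -1, -1):
            if a[i] == b[j]:
                L[i][j] = L[i + 1][j + 1] + 1
            else:
                L[i][j] = max(L[i + 1][j], L[i][j + 1])
    pairs: list[tuple[int, int]] = []
    i = j = 0
    while i < na and j < nb:
        if a[i] == b[j] and L[i][j] == L[i + 1][j + 1] + 1:
            pairs.append((i, j))
            i += 1
            j += 1
        elif L[i + 1][j] >= L[i][j + 1]:
            i += 1
        else:
            j += 1
    return pairs


def match_sequences(ifc: list[Segment],
                    cpp: list[Segment]) -> RegistrationResult:
    """Match IFC segments to CPP segments and map cells to positions.

    Aligned segment pairs with equal cell counts are matched and their
    cells mapped in order to consecutive CPP cell positions (global
    0-based ordinals among CPP cells).  A pair with fewer CPP cells is
    flagged ``deletion``, with more ``displacement``; IFC segments with
    no aligned CPP partner are flagged ``bead_mismatch``.  The yield
    fraction is mapped cells over total IFC cells.
    """
    if not ifc or not cpp:
        raise InputError("match_sequences requires non-empty segment lists")

    ifc_beads = [s.left_bead for s in ifc] + [ifc[-1].right_bead]
    cpp_beads = [s.left_bead for s in cpp] + [cpp[-1].right_bead]

    if ifc_beads == cpp_beads:
        seg_pairs = [(i, i) for i in range(len(ifc))]
    else:
        bead_pairs = _lcs_pairs(ifc_beads, cpp_beads)
        # a segment pair exists where two consecutively aligned beads
        # are adjacent on both sides
        seg_pairs = []
        for (i1, j1), (i2, j2) in zip(bead_pairs, bead_pairs[1:]):
            if i2 == i1 + 1 and j2 == j1 + 1:
                seg_pairs.append((i1, j1))

    # global CPP cell ordinal at the start of each CPP segment
    cpp_offsets = [0]
    for seg in cpp:
        cpp_offsets.append(cpp_offsets[-1] + seg.cell_count)

    result = RegistrationResult()
    aligned_ifc = {i for i, _ in seg_pairs}
    for i in range(len(ifc)):
        if i not in aligned_ifc:
            result.error_segments.append((i, "bead_mismatch"))
    for i, j in seg_pairs:
        si, sj = ifc[i], cpp[j]
        if si.cell_count == sj.cell_count:
            result.matched_segments.append((i, j))
            for k, cid in enumerate(si.cell_ids):
                result.mapping.append((cid, cpp_offsets[j] + k))
        elif sj.cell_count < si.cell_count:
            result.error_segments.append((i, "deletion"))
        else:
            result.error_segments.append((i, "displacement"))

    total_cells = sum(s.cell_count for s in ifc)
    result.yield_fraction = (
        len(result.mapping) / total_cells if total_cells else 0.0)
    return result
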