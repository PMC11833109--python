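"""Segment encoding and IFC/CPP sequence matching, checked against
exhaustive enumeration of single deletions and boundary displacements."""

import numpy as np
import pytest

from cytofuse.config import SimConfig
from cytofuse.errors import InputError, StructuralError
from cytofuse.registration import Segment, encode_segments, match_sequences
from cytofuse.sequences import DispenseSequence, bead, cell
from cytofuse import synthetic_data as sd

from conftest import SMALL_IMAGE, make_light_records


def seq(*tokens):
    return DispenseSequence(list(tokens))


def toy_sequence():
    """10 cells spread over 5 segments: A/1/T, T/3/C, C/2/T, T/0/A, A/4/C."""
    tokens = [bead("A"), cell(0), bead("T")]
    tokens += [cell(1), cell(2), cell(3), bead("C")]
    tokens += [cell(4), cell(5), bead("T")]
    tokens += [bead("A")]
    tokens += [cell(6), cell(7), cell(8), cell(9), bead("C")]
    return seq(*tokens)


class TestEncodeSegments:
    @pytest.mark.parametrize("tokens,expected", [
        ([bead("C"), cell(0), cell(1), bead("T")], [("C", 2, "T")]),
        ([bead("A"), bead("A")], [("A", 0, "A")]),
        ([bead("A"), cell(0), bead("T"), cell(1), cell(2), cell(3),
          bead("C")], [("A", 1, "T"), ("T", 3, "C")]),
    ])
    def test_examples(self, tokens, expected):
        segments = encode_segments(seq(*tokens))
        assert [(s.left_bead, s.cell_count, s.right_bead)
                for s in segments] == expected
        assert sum(s.cell_count for s in segments) == sum(
            1 for t in tokens if t.kind == "CELL")

    def test_not_bead_bounded_rejected(self):
        with pytest.raises(StructuralError):
            encode_segments(seq(cell(0), bead("A")))
        with pytest.raises(StructuralError):
            encode_segments(seq(bead("A"), cell(0)))
        with pytest.raises(StructuralError):
            encode_segments(DispenseSequence([]))


class TestMatchSequences:
    def test_identical_sequences_fully_matched(self):
        segments = encode_segments(toy_sequence())
        result = match_sequences(segments, segments)
        assert result.matched_segments == [(i, i) for i in range(5)]
        assert result.error_segments == []
        assert result.yield_fraction == 1.0
        # order-preserving bijection onto 0..9
        assert [cid for cid, _ in result.mapping] == list(range(10))
        assert [pos for _, pos in result.mapping] == list(range(10))

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            match_sequences([], [Segment("A", 0, "A")])

    def test_single_deletion_all_positions(self):
        """Delete each of the 10 cells in turn from the CPP side: exactly
        the containing segment is flagged (deletion), all others match."""
        ifc_tokens = list(toy_sequence())
        cell_positions = [i for i, t in enumerate(ifc_tokens)
                          if t.kind == "CELL"]
        ifc_segments = encode_segments(seq(*ifc_tokens))
        # which segment holds each cell, by construction of the toy
        owner = {0: 0, 1: 1, 2: 1, 3: 1, 4: 2, 5: 2, 6: 4, 7: 4, 8: 4, 9: 4}
        for pos in cell_positions:
            deleted = ifc_tokens[pos].ref_id
            cpp = seq(*(t for i, t in enumerate(ifc_tokens) if i != pos))
            result = match_sequences(ifc_segments, encode_segments(cpp))
            assert result.error_segments == [(owner[deleted], "deletion")]
            matched_ifc = [i for i, _ in result.matched_segments]
            assert matched_ifc == [i for i in range(5) if i != owner[deleted]]
            assert deleted not in result.mapped_cell_ids
            assert result.yield_fraction == pytest.approx(
                (10 - ifc_segments[owner[deleted]].cell_count) / 10)

    def test_boundary_displacement_all_positions(self):
        """Swap each (cell, bead) pair across a segment boundary: exactly
        the two adjacent segments are flagged, all others match."""
        ifc_tokens = list(toy_sequence())
        ifc_segments = encode_segments(seq(*ifc_tokens))
        n_segments = len(ifc_segments)
        bead_positions = [i for i, t in enumerate(ifc_tokens)
                          if t.kind == "BEAD"]
        tested = 0
        for k, pos in enumerate(bead_positions[1:-1], start=1):
            if ifc_tokens[pos - 1].kind != "CELL":
                continue   # no cell to displace across this bead
            cpp_tokens = list(ifc_tokens)
            cpp_tokens[pos - 1], cpp_tokens[pos] = (cpp_tokens[pos],
                                                    cpp_tokens[pos - 1])
            result = match_sequences(ifc_segments,
                                     encode_segments(seq(*cpp_tokens)))
            # the bead between segments k-1 and k moved: losing segment
            # reads as deletion, gaining one as displacement
            assert sorted(i for i, _ in result.error_segments) == [k - 1, k]
            reasons = dict(result.error_segments)
            assert reasons[k - 1] == "deletion"
            assert reasons[k] == "displacement"
            matched_ifc = {i for i, _ in result.matched_segments}
            assert matched_ifc == set(range(n_segments)) - {k - 1, k}
            tested += 1
        assert tested >= 3

    def test_bead_mismatch_flagged(self):
        ifc = encode_segments(seq(bead("A"), cell(0), bead("T"),
                                  cell(1), bead("C")))
        cpp = encode_segments(seq(bead("A"), cell(0), bead("G"),
                                  cell(1), bead("C")))
        result = match_sequences(ifc, cpp)
        flagged = {i for i, r in result.error_segments}
        assert flagged  # the T/G disagreement breaks at least one segment
        for i, reason in result.error_segments:
            assert reason == "bead_mismatch"

    def test_no_cell_mapped_twice_and_only_from_matched(self):
        records = make_light_records(200)
        cfg = SimConfig(n_cells=200, deletion_rate=0.05,
                        displacement_rate=0.05, seed=13, **SMALL_IMAGE)
        dispense = sd.simulate_dispense(records, cfg)
        ifc_segments = encode_segments(dispense.ifc)
        result = match_sequences(ifc_segments,
                                 encode_segments(dispense.cpp))
        ids = result.mapped_cell_ids
        assert len(ids) == len(set(ids))
        matched = {i for i, _ in result.matched_segments}
        for i, segment in enumerate(ifc_segments):
            for cid in segment.cell_ids:
                if cid in ids:
                    assert i in matched

    def test_yield_monotone_in_deletion_rate(self):
        """Expected yield never increases with the deletion rate."""
        records = make_light_records(150)
        mean_yields = []
        for rate in (0.0, 0.05, 0.15, 0.30):
            ys = []
            for seed in range(5):
                cfg = SimConfig(n_cells=150, deletion_rate=rate, seed=seed,
                                **SMALL_IMAGE)
                d = sd.simulate_dispense(records, cfg)
                r = match_sequences(encode_segments(d.ifc),
                                    encode_segments(d.cpp))
                ys.append(r.yield_fraction)
            mean_yields.append(np.mean(ys))
        assert all(a >= b for a, b in zip(mean_yields, mean_yields[1:]))

    def test_round_trip_zero_error_rates(self):
        records = make_light_records(80)
        cfg = SimConfig(n_cells=80, seed=2, **SMALL_IMAGE)
        d = sd.simulate_dispense(records, cfg)
        result = match_sequences(encode_segments(d.ifc),
                                 encode_segments(d.cpp))
        assert result.yield_fraction == 1.0
        assert [cid for cid, _ in result.mapping] == d.ifc.cell_ids
        assert [pos for _, pos in result.mapping] == list(range(80))
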