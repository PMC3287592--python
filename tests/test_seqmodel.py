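"""Candidate enumeration, frame arithmetic, windowing and one-hot coding."""

import re

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tispred import (
    Frame,
    Label,
    MrnaRecord,
    Region,
    WindowSpec,
    decode_4bit,
    encode_4bit,
    enumerate_candidates,
    extract_window,
    filter_records,
    frame_of,
)
from tispred.seqmodel import InvalidRecordError

from .conftest import random_record

seq_strategy = st.text(alphabet="ACGT", min_size=10, max_size=300)


class TestMrnaRecord:
    def test_lowercase_is_normalized(self):
        rec = MrnaRecord(id="r", sequence="ccatgaaa", tis_pos=3)
        assert rec.sequence == "CCATGAAA"

    @pytest.mark.parametrize(
        "seq, tis",
        [
            ("CCCTGAAA", 3),   # annotation not on an ATG
            ("CCATGAAA", 7),   # tis_pos within sequence but not an ATG
            ("CCATGAAA", 0),   # out of range low
            ("CCATGAAA", 8),   # out of range high (no room for codon)
            ("CCATGNAA", 3),   # ambiguity code
            ("", 1),
        ],
    )
    def test_invalid_records_rejected(self, seq, tis):
        with pytest.raises(InvalidRecordError):
            MrnaRecord(id="bad", sequence=seq, tis_pos=tis)


class TestEnumerate:
    def test_regions_and_labels(self):
        rec = MrnaRecord(id="r1", sequence="CATGCCATGC", tis_pos=2)
        sites = enumerate_candidates(rec)
        assert [s.atg_pos for s in sites] == [2, 7]
        assert sites[0].region is Region.tis
        assert sites[0].label is Label.positive
        assert sites[1].region is Region.downstream
        # (7-2) mod 3 == 2 -> out of frame
        assert sites[1].frame is Frame.out_of_frame
        assert sites[1].label is Label.negative

    def test_inaknow_mode_leaves_downstream_unlabeled(self):
        rec = MrnaRecord(id="r1", sequence="CATGCCATGC", tis_pos=2)
        sites = enumerate_candidates(rec, mode="inaknow")
        assert sites[1].label is Label.unlabeled
        # upstream sites stay negative
        rec2 = MrnaRecord(id="r2", sequence="ATGCCCATGAA", tis_pos=7)
        up = enumerate_candidates(rec2, mode="inaknow")[0]
        assert up.region is Region.upstream and up.label is Label.negative

    def test_upstream_in_frame_site(self):
        # ATG at 1 with TIS at 4: (1-4) mod 3 == 0 -> in frame, negative
        rec = MrnaRecord(id="r", sequence="ATGATGATGCC", tis_pos=4)
        first = enumerate_candidates(rec)[0]
        assert first.frame is Frame.in_frame
        assert first.label is Label.negative

    @given(seq=seq_strategy)
    @settings(max_examples=60, deadline=None)
    def test_count_matches_overlapping_regex(self, seq):
        hits = [m.start() + 1 for m in re.finditer(r"(?=ATG)", seq)]
        if not hits:
            return
        rec = MrnaRecord(id="h", sequence=seq, tis_pos=hits[0])
        sites = enumerate_candidates(rec)
        assert [s.atg_pos for s in sites] == hits

    @given(atg=st.integers(1, 10**6), tis=st.integers(1, 10**6))
    def test_frame_is_modular_arithmetic(self, atg, tis):
        expected = Frame.in_frame if (atg - tis) % 3 == 0 else Frame.out_of_frame
        assert frame_of(atg, tis) is expected


class TestWindow:
    def test_example_extraction(self):
        rec = MrnaRecord(id="r", sequence="CCATGAAAT", tis_pos=3)
        assert extract_window(rec, 3, WindowSpec(2, 5)) == "CCATGAA"

    def test_insufficient_upstream_is_absent(self):
        rec = MrnaRecord(id="r", sequence="ATGAAA", tis_pos=1)
        assert extract_window(rec, 1, WindowSpec(2, 4)) is None

    def test_insufficient_downstream_is_absent(self):
        rec = MrnaRecord(id="r", sequence="CCATG", tis_pos=3)
        assert extract_window(rec, 3, WindowSpec(2, 5)) is None

    def test_non_atg_position_is_caller_bug(self):
        rec = MrnaRecord(id="r", sequence="CCATGAAAT", tis_pos=3)
        with pytest.raises(ValueError):
            extract_window(rec, 2, WindowSpec(1, 4))

    def test_never_short_always_full_length(self, rng):
        spec = WindowSpec(6, 12)
        for _ in range(50):
            rec = random_record(rng, 60)
            for site in enumerate_candidates(rec):
                w = extract_window(rec, site.atg_pos, spec)
                assert w is None or len(w) == spec.length

    def test_parse_notation(self):
        spec = WindowSpec.from_string("-10+30")
        assert (spec.upstream, spec.downstream) == (10, 30)
        assert str(spec) == "-10+30"
        with pytest.raises(ValueError):
            WindowSpec.from_string("10+30")
        with pytest.raises(ValueError):
            WindowSpec(upstream=-1)
        with pytest.raises(ValueError):
            WindowSpec(downstream=2)  # must contain the ATG


class TestFilter:
    def test_counts_by_reason(self):
        spec = WindowSpec(10, 30)
        short_utr = [
            MrnaRecord(id=f"s{i}", sequence="ATG" + "C" * 50, tis_pos=1)
            for i in range(2)
        ]
        good = [
            MrnaRecord(id=f"g{i}", sequence="C" * 10 + "ATG" + "A" * 40, tis_pos=11)
            for i in range(3)
        ]
        kept, report = filter_records(short_utr + good, spec)
        assert [r.id for r in kept] == ["g0", "g1", "g2"]
        assert report.discarded == {"insufficient_upstream": 2}
        assert report.kept == 3 and report.total == 5
        assert report.fraction("insufficient_upstream") == pytest.approx(0.4)

    def test_exactly_u_upstream_is_kept(self):
        spec = WindowSpec(10, 30)
        rec = MrnaRecord(id="b", sequence="C" * 10 + "ATG" + "A" * 40, tis_pos=11)
        kept, _ = filter_records([rec], spec)
        assert kept == [rec]

    def test_short_downstream_is_discarded(self):
        spec = WindowSpec(2, 30)
        rec = MrnaRecord(id="d", sequence="CCATGAAA", tis_pos=3)
        kept, report = filter_records([rec], spec)
        assert not kept
        assert report.discarded == {"insufficient_downstream": 1}


class TestEncoding:
    def test_single_nucleotide_codes(self):
        assert encode_4bit("A").tolist() == [1, 0, 0, 0]
        assert encode_4bit("ACGT").tolist() == [1, 0, 0, 0, 0, 1, 0, 0,
                                                0, 0, 1, 0, 0, 0, 0, 1]

    @given(w=st.text(alphabet="ACGT", min_size=1, max_size=40))
    def test_round_trip(self, w):
        assert decode_4bit(encode_4bit(w)) == w

    @given(w=st.text(alphabet="ACGT", min_size=1, max_size=40))
    def test_one_hot_per_position(self, w):
        bits = encode_4bit(w)
        groups = bits.reshape(-1, 4)
        assert (groups.sum(axis=1) == 1).all()
        assert bits.sum() == len(w)

    def test_invalid_character_names_position(self):
        with pytest.raises(ValueError, match="position 3"):
            encode_4bit("ACNT")

    def test_decode_rejects_non_onehot(self):
        with pytest.raises(ValueError):
            decode_4bit(np.array([1, 1, 0, 0]))
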