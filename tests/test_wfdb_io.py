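"""WFDB header/signal/annotation I/O, label mapping and dataset partition."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pvcforest import wfdb_io
from pvcforest.wfdb_io import (
    BEAT_SYMBOLS,
    DS1_RECORDS,
    DS2_RECORDS,
    HeaderParseError,
    RecordHeader,
    SignalSpec,
    annotation_from_symbol,
    decode_212,
    encode_212,
    map_symbol_to_aami,
    partition_records,
    read_annotations,
    read_header,
    read_signal_212,
    to_binary_label,
    write_annotations,
    write_header,
    write_signal_212,
)


class TestHeader:
    def test_parses_mitbih_style_header(self, tmp_path):
        p = tmp_path / "100.hea"
        p.write_text(
            "100 2 360 650000\n"
            "100.dat 212 200 11 1024 995 -22131 0 MLII\n"
            "100.dat 212 200 11 1024 1011 20052 0 V5\n"
        )
        h = read_header(p)
        assert (h.record_name, h.n_signals, h.fs, h.n_samples) == ("100", 2, 360.0, 650000)
        assert h.lead_names() == ["MLII", "V5"]
        # baseline defaults to the ADC zero when not given in parentheses
        assert h.signals[0].baseline == 1024

    def test_round_trips_through_write_header(self, tmp_path):
        h = RecordHeader("tiny", 1, 360.0, 10,
                         [SignalSpec("tiny.dat", 212, gain=100.0, baseline=7,
                                     description="MLII")])
        write_header(h, tmp_path / "tiny.hea")
        h2 = read_header(tmp_path / "tiny.hea")
        assert h2.record_name == "tiny" and h2.n_samples == 10
        assert h2.signals[0].gain == 100.0 and h2.signals[0].baseline == 7
        assert h2.signals[0].description == "MLII"

    def test_header_missing_fields_is_parse_error(self, tmp_path):
        p = tmp_path / "bad.hea"
        p.write_text("bad 1\n")
        with pytest.raises(HeaderParseError):
            read_header(p)


class TestFormat212:
    def test_zero_bytes_decode_to_zero_mv(self, tmp_path):
        (tmp_path / "z.dat").write_bytes(bytes(3))
        h = RecordHeader("z", 1, 360.0, 2,
                         [SignalSpec("z.dat", 212, gain=200.0, baseline=0, description="MLII")])
        rec = read_signal_212(tmp_path / "z.dat", h, "MLII")
        assert np.array_equal(rec.samples, [0.0, 0.0])

    def test_codec_matches_independent_bit_packer(self, rng):
        # independent packer: write each 12-bit value bit by bit per the format
        def pack_pair(a, b):
            ua, ub = a & 0xFFF, b & 0xFFF
            return bytes([ua & 0xFF, ((ua >> 8) & 0x0F) | (((ub >> 8) & 0x0F) << 4), ub & 0xFF])

        vals = rng.integers(-2048, 2048, size=2000)
        blob = b"".join(pack_pair(int(vals[i]), int(vals[i + 1]))
                        for i in range(0, 2000, 2))
        assert np.array_equal(decode_212(blob, 2000), vals)
        assert encode_212(vals) == blob

    @pytest.mark.parametrize("pair", [(-2048, 2047), (2047, -2048), (-1, 0), (0, -1),
                                      (255, 256), (-255, -256), (0, 0)])
    def test_codec_identity_on_boundary_pairs(self, pair):
        assert np.array_equal(decode_212(encode_212(np.array(pair)), 2), pair)

    @given(st.lists(st.integers(-2048, 2047), min_size=1, max_size=64))
    def test_codec_identity_property(self, vals):
        assert np.array_equal(decode_212(encode_212(np.array(vals)), len(vals)), vals)

    def test_out_of_range_values_rejected(self):
        with pytest.raises(ValueError):
            encode_212(np.array([2048]))

    def test_truncated_stream_is_error(self):
        with pytest.raises(ValueError, match="truncated"):
            decode_212(bytes(4), 4)

    def test_missing_lead_error_lists_available(self, tmp_path):
        write_signal_212(tmp_path / "x.dat", np.zeros(4, dtype=np.int64))
        h = RecordHeader("x", 1, 360.0, 4,
                         [SignalSpec("x.dat", 212, description="V5")])
        with pytest.raises(ValueError, match="V5"):
            read_signal_212(tmp_path / "x.dat", h, "MLII")


class TestAnnotations:
    def test_text_dialect_parses_and_labels(self, tmp_path):
        p = tmp_path / "a.txt"
        p.write_text("300 N\n660 V\n")
        anns = read_annotations(p, "text")
        assert [a.sample for a in anns] == [300, 660]
        assert [a.is_pvc for a in anns] == [False, True]

    def test_binary_round_trip_random_beats(self, tmp_path, rng):
        samples = np.cumsum(rng.integers(5, 3000, size=50))  # exercises SKIP escapes
        symbols = rng.choice(list(BEAT_SYMBOLS), size=50)
        anns = [annotation_from_symbol(int(s), sym) for s, sym in zip(samples, symbols)]
        for dialect in ("mit_binary", "text"):
            p = tmp_path / f"r.{dialect}"
            write_annotations(p, anns, dialect)
            assert read_annotations(p, dialect) == anns

    def test_empty_file_gives_empty_sequence(self, tmp_path):
        p = tmp_path / "e.txt"
        p.write_text("")
        assert read_annotations(p, "text") == []

    def test_non_monotone_samples_rejected(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("500 N\n400 N\n")
        with pytest.raises(wfdb_io.AnnotationError):
            read_annotations(p, "text")


class TestLabels:
    @pytest.mark.parametrize("symbol,aami", [
        ("V", "V"), ("E", "V"), ("N", "N"), ("L", "N"), ("R", "N"), ("e", "N"),
        ("j", "N"), ("A", "S"), ("a", "S"), ("J", "S"), ("S", "S"), ("F", "F"),
        ("/", "Q"), ("f", "Q"), ("Q", "Q"),
    ])
    def test_aami_class_table(self, symbol, aami):
        assert map_symbol_to_aami(symbol) == aami

    def test_non_beat_symbol_is_error(self):
        with pytest.raises(ValueError):
            map_symbol_to_aami("+")

    @pytest.mark.parametrize("aami,expected", [
        ("V", True), ("N", False), ("S", False), ("F", False), ("Q", False)])
    def test_only_v_class_is_pvc(self, aami, expected):
        assert to_binary_label(aami) is expected

    def test_label_mapping_total_on_beat_alphabet(self):
        for s in BEAT_SYMBOLS:
            assert to_binary_label(map_symbol_to_aami(s)) in (True, False)


class TestPartition:
    def test_table_assignments(self):
        ds1, ds2, excl = partition_records(["101", "100", "102"])
        assert ds1 == ["101"] and ds2 == ["100"] and excl == ["102"]

    def test_partition_shape(self):
        assert len(DS1_RECORDS) == len(DS2_RECORDS) == 22
        assert not set(DS1_RECORDS) & set(DS2_RECORDS)
        paced = set(wfdb_io.PACED_RECORDS)
        assert paced == {"102", "104", "107", "217"}
        assert not paced & (set(DS1_RECORDS) | set(DS2_RECORDS))

    def test_unknown_name_is_error(self):
        with pytest.raises(ValueError):
            partition_records(["999"])
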