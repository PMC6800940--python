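"""WFDB-style record I/O for MIT-BIH-layout ECG data.

Reads and writes the three files that make up an MIT-BIH arrhythmia record:
the ASCII header (``.hea``), the format-212 signal file (``.dat``, two 12-bit
two's-complement samples packed into three bytes) and beat annotations (MIT
binary stream or a plain two-column text dialect).  Also provides the AAMI
EC57 symbol grouping, the binary PVC/non-PVC labelling, and the standard
DS1/DS2 train/test partition of the 48 MIT-BIH records (paced records
102, 104, 107 and 217 are always excluded).

All sample indices are 0-based.
"""

from __future__ import annotations

import logging
import re
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SignalSpec",
    "RecordHeader",
    "ECGRecord",
    "BeatAnnotation",
    "HeaderParseError",
    "AnnotationError",
    "read_header",
    "write_header",
    "read_signal_212",
    "write_signal_212",
    "decode_212",
    "encode_212",
    "read_annotations",
    "write_annotations",
    "map_symbol_to_aami",
    "to_binary_label",
    "annotation_from_symbol",
    "partition_records",
    "DS1_RECORDS",
    "DS2_RECORDS",
    "PACED_RECORDS",
    "BEAT_SYMBOLS",
]


class HeaderParseError(ValueError):
    """Raised when a .hea file cannot be parsed."""


class AnnotationError(ValueError):
    """Raised on malformed annotation streams."""


# ---------------------------------------------------------------------------
# AAMI EC57 beat-symbol grouping.  V (ventricular ectopic) = {V, E} is the
# PVC-positive class; everything else (N, S, F, Q) maps to non-PVC.
# ---------------------------------------------------------------------------
SYMBOL_TO_AAMI: dict[str, str] = {
    "N": "N", "L": "N", "R": "N", "e": "N", "j": "N",
    "A": "S", "a": "S", "J": "S", "S": "S",
    "V": "V", "E": "V",
    "F": "F",
    "/": "Q", "f": "Q", "Q": "Q",
}
BEAT_SYMBOLS: tuple[str, ...] = tuple(SYMBOL_TO_AAMI)

# MIT annotation type codes for the beat alphabet above.
SYMBOL_TO_CODE: dict[str, int] = {
    "N": 1, "L": 2, "R": 3, "a": 4, "V": 5, "F": 6, "J": 7, "A": 8,
    "S": 9, "E": 10, "j": 11, "/": 12, "Q": 13, "e": 34, "f": 38,
}
CODE_TO_SYMBOL = {v: k for k, v in SYMBOL_TO_CODE.items()}

_SKIP_CODE = 59  # long-interval escape in the binary annotation stream


def map_symbol_to_aami(symbol: str) -> str:
    """Map a beat annotation character to its AAMI class (N, S, V, F or Q)."""
    try:
        return SYMBOL_TO_AAMI[symbol]
    except KeyError:
        raise ValueError(
            f"{symbol!r} is not a beat annotation symbol "
            f"(expected one of {''.join(BEAT_SYMBOLS)})"
        ) from None


def to_binary_label(aami: str) -> bool:
    """True iff the AAMI class is V (ventricular ectopic, i.e. PVC)."""
    if aami not in {"N", "S", "V", "F", "Q"}:
        raise ValueError(f"unknown AAMI class {aami!r}")
    return aami == "V"


@dataclass(frozen=True)
class BeatAnnotation:
    """One annotated heartbeat: location, symbol and derived labels."""

    sample: int
    symbol: str
    aami: str
    is_pvc: bool


def annotation_from_symbol(sample: int, symbol: str) -> BeatAnnotation:
    aami = map_symbol_to_aami(symbol)
    return BeatAnnotation(sample=int(sample), symbol=symbol, aami=aami,
                          is_pvc=to_binary_label(aami))


# ---------------------------------------------------------------------------
# Header
# ---------------------------------------------------------------------------

@dataclass
class SignalSpec:
    """Per-signal line of a .hea file (format-212 subset)."""

    file_name: str
    fmt: int
    gain: float = 200.0      # adu per mV
    baseline: int = 0        # adu at 0 mV
    units: str = "mV"
    adc_res: int = 12
    adc_zero: int = 0
    description: str = ""


@dataclass
class RecordHeader:
    record_name: str
    n_signals: int
    fs: float
    n_samples: int
    signals: list[SignalSpec] = field(default_factory=list)

    def lead_names(self) -> list[str]:
        return [s.description for s in self.signals]

    def lead_index(self, lead: str) -> int:
        try:
            return self.lead_names().index(lead)
        except ValueError:
            raise ValueError(
                f"lead {lead!r} not in record {self.record_name!r}; "
                f"available leads: {self.lead_names()}"
            ) from None


@dataclass
class ECGRecord:
    """One lead of a record, in physical units (mV)."""

    header: RecordHeader
    lead: str
    samples: np.ndarray


_GAIN_RE = re.compile(r"^(?P<gain>-?[\d.]+)(?:\((?P<baseline>-?\d+)\))?(?:/(?P<units>\S+))?$")


def read_header(path: str | Path) -> RecordHeader:
    """Parse a WFDB .hea file (single-segment, format-212 dialect)."""
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines()]
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    if not lines:
        raise HeaderParseError(f"{path}: empty header")
    first = lines[0].split()
    if len(first) < 4:
        raise HeaderParseError(
            f"{path} line 1: expected 'name n_signals fs n_samples', got {lines[0]!r}"
        )
    try:
        name = first[0].split("/")[0]
        n_signals = int(first[1])
        fs = float(first[2])
        n_samples = int(first[3])
    except ValueError as exc:
        raise HeaderParseError(f"{path} line 1: {exc}") from None
    if fs <= 0:
        raise HeaderParseError(f"{path}: sampling frequency must be positive, got {fs}")
    if n_signals < 1:
        raise HeaderParseError(f"{path}: need at least one signal")
    if len(lines) - 1 < n_signals:
        raise HeaderParseError(
            f"{path}: header declares {n_signals} signals but has {len(lines) - 1} signal lines"
        )
    signals: list[SignalSpec] = []
    for i, ln in enumerate(lines[1:1 + n_signals], start=2):
        tok = ln.split()
        if len(tok) < 2:
            raise HeaderParseError(f"{path} line {i}: malformed signal line {ln!r}")
        try:
            fmt = int(tok[1].split("x")[0].split(":")[0].split("+")[0])
        except ValueError:
            raise HeaderParseError(f"{path} line {i}: bad format code {tok[1]!r}") from None
        spec = SignalSpec(file_name=tok[0], fmt=fmt)
        if len(tok) > 2:
            m = _GAIN_RE.match(tok[2])
            if not m:
                raise HeaderParseError(f"{path} line {i}: bad gain field {tok[2]!r}")
            spec.gain = float(m.group("gain"))
            if m.group("units"):
                spec.units = m.group("units")
            if m.group("baseline") is not None:
                spec.baseline = int(m.group("baseline"))
        if len(tok) > 3:
            try:
                spec.adc_res = int(tok[3])
            except ValueError:
                raise HeaderParseError(f"{path} line {i}: bad ADC resolution {tok[3]!r}") from None
        if len(tok) > 4:
            try:
                spec.adc_zero = int(tok[4])
            except ValueError:
                raise HeaderParseError(f"{path} line {i}: bad ADC zero {tok[4]!r}") from None
            if m.group("baseline") is None:
                spec.baseline = spec.adc_zero
        # tokens 5..7 (initial value, checksum, block size) are ignored
        if len(tok) > 8:
            spec.description = " ".join(tok[8:])
        signals.append(spec)
    return RecordHeader(record_name=name, n_signals=n_signals, fs=fs,
                        n_samples=n_samples, signals=signals)


def write_header(header: RecordHeader, path: str | Path) -> None:
    path = Path(path)
    out = [f"{header.record_name} {header.n_signals} {header.fs:g} {header.n_samples}"]
    for s in header.signals:
        gain = f"{s.gain:g}({s.baseline})/{s.units}"
        out.append(
            f"{s.file_name} {s.fmt} {gain} {s.adc_res} {s.adc_zero} 0 0 0 {s.description}".rstrip()
        )
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Format 212 signal codec
# ---------------------------------------------------------------------------

def decode_212(data: bytes, n_values: int) -> np.ndarray:
    """Unpack ``n_values`` 12-bit two's-complement integers from 212 packing.

    Every 3 bytes hold two samples: byte0 = low 8 bits of s1, low nibble of
    byte1 = high 4 bits of s1, high nibble of byte1 = high 4 bits of s2,
    byte2 = low 8 bits of s2.
    """
    n_groups = (n_values + 1) // 2
    if len(data) < 3 * n_groups:
        raise ValueError(
            f"truncated 212 stream: need {3 * n_groups} bytes for "
            f"{n_values} samples, got {len(data)}"
        )
    b = np.frombuffer(data[: 3 * n_groups], dtype=np.uint8).reshape(-1, 3).astype(np.int32)
    s1 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    s2 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
    out = np.empty(2 * n_groups, dtype=np.int32)
    out[0::2] = s1
    out[1::2] = s2
    out[out > 2047] -= 4096  # sign extension of the 12-bit values
    return out[:n_values]


def encode_212(values: np.ndarray | Sequence[int]) -> bytes:
    """Pack 12-bit two's-complement integers into 212 format (zero-padded to even count)."""
    v = np.asarray(values, dtype=np.int64)
    if v.size and (v.min() < -2048 or v.max() > 2047):
        raise ValueError("values outside the 12-bit two's-complement range [-2048, 2047]")
    if v.size % 2:
        v = np.concatenate([v, [0]])
    u = np.where(v < 0, v + 4096, v).astype(np.uint16)
    s1, s2 = u[0::2], u[1::2]
    b = np.empty((s1.size, 3), dtype=np.uint8)
    b[:, 0] = s1 & 0xFF
    b[:, 1] = ((s1 >> 8) & 0x0F) | (((s2 >> 8) & 0x0F) << 4)
    b[:, 2] = s2 & 0xFF
    return b.tobytes()


def read_signal_212(path: str | Path, header: RecordHeader, lead: str = "MLII") -> ECGRecord:
    """Read one lead from a format-212 .dat file into physical units (mV).

    Signals are interleaved sample-by-sample as in MIT-BIH.  The lead is
    located by its header description; a missing lead is an error listing the
    leads that are present (never a silent fallback to channel 0).
    """
    idx = header.lead_index(lead)
    spec = header.signals[idx]
    if spec.fmt != 212:
        raise ValueError(f"signal format {spec.fmt} not supported (only 212)")
    raw = decode_212(Path(path).read_bytes(), header.n_samples * header.n_signals)
    chan = raw.reshape(-1, header.n_signals)[:, idx]
    physical = (chan.astype(np.float64) - spec.baseline) / spec.gain
    return ECGRecord(header=header, lead=lead, samples=physical)


def write_signal_212(path: str | Path, raw_channels: np.ndarray) -> None:
    """Write an (n_samples, n_signals) array of adu integers as interleaved 212."""
    arr = np.asarray(raw_channels)
    if arr.ndim == 1:
        arr = arr[:, None]
    Path(path).write_bytes(encode_212(arr.reshape(-1)))


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

def _check_monotone(samples: Iterable[int]) -> None:
    prev = -1
    for s in samples:
        if s <= prev:
            raise AnnotationError(f"annotation samples not strictly increasing at sample {s}")
        prev = s


def read_annotations(path: str | Path, dialect: str = "mit_binary") -> list[BeatAnnotation]:
    """Read beat annotations.

    ``mit_binary``: MIT .atr stream of little-endian 16-bit words, 6-bit type
    code + 10-bit sample interval, SKIP escape for long intervals, zero word
    terminator.  Non-beat/unknown codes are skipped with a logged warning.
    ``text``: lines of ``sample symbol``.
    """
    path = Path(path)
    anns: list[BeatAnnotation] = []
    if dialect == "text":
        for lineno, ln in enumerate(path.read_text().splitlines(), start=1):
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            tok = ln.split()
            if len(tok) != 2:
                raise AnnotationError(f"{path} line {lineno}: expected 'sample symbol'")
            sample, symbol = int(tok[0]), tok[1]
            if symbol not in SYMBOL_TO_AAMI:
                logger.warning("%s line %d: skipping non-beat symbol %r", path, lineno, symbol)
                continue
            anns.append(annotation_from_symbol(sample, symbol))
    elif dialect == "mit_binary":
        data = path.read_bytes()
        if len(data) % 2:
            raise AnnotationError(f"{path}: odd byte count in binary annotation stream")
        words = np.frombuffer(data, dtype="<u2")
        t = 0
        i = 0
        while i < len(words):
            word = int(words[i])
            code, interval = word >> 10, word & 0x3FF
            i += 1
            if code == 0 and interval == 0:
                break
            if code == _SKIP_CODE:
                if i + 2 > len(words):
                    raise AnnotationError(f"{path}: truncated SKIP escape")
                t += (int(words[i]) << 16) | int(words[i + 1])
                i += 2
                continue
            t += interval
            if code in CODE_TO_SYMBOL:
                anns.append(annotation_from_symbol(t, CODE_TO_SYMBOL[code]))
            else:
                logger.warning("%s: skipping unknown annotation code %d", path, code)
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    _check_monotone(a.sample for a in anns)
    return anns


def write_annotations(path: str | Path, annotations: Sequence[BeatAnnotation],
                      dialect: str = "mit_binary") -> None:
    path = Path(path)
    _check_monotone(a.sample for a in annotations)
    if dialect == "text":
        path.write_text("".join(f"{a.sample} {a.symbol}\n" for a in annotations))
        return
    if dialect != "mit_binary":
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    out = bytearray()
    prev = 0
    for a in annotations:
        dt = a.sample - prev
        prev = a.sample
        if dt > 0x3FF:
            out += struct.pack("<HHH", _SKIP_CODE << 10, (dt >> 16) & 0xFFFF, dt & 0xFFFF)
            dt = 0
        out += struct.pack("<H", (SYMBOL_TO_CODE[a.symbol] << 10) | dt)
    out += struct.pack("<H", 0)
    path.write_bytes(bytes(out))


# ---------------------------------------------------------------------------
# Dataset partition (MIT-BIH arrhythmia database, 44 usable records)
# ---------------------------------------------------------------------------

DS1_RECORDS: tuple[str, ...] = (
    "101", "106", "108", "109", "112", "114", "115", "116", "118", "119",
    "122", "124", "201", "203", "205", "207", "208", "209", "215", "220",
    "223", "230",
)
DS2_RECORDS: tuple[str, ...] = (
    "100", "103", "105", "111", "113", "117", "121", "123", "200", "202",
    "210", "212", "213", "214", "219", "221", "222", "228", "231", "232",
    "233", "234",
)
PACED_RECORDS: tuple[str, ...] = ("102", "104", "107", "217")


def partition_records(record_names: Sequence[str]) -> tuple[list[str], list[str], list[str]]:
    """Split record names into (DS1 training, DS2 test, excluded paced records).

    Synthetic record names carrying a ``synth`` prefix go to DS1 by convention
    unless suffixed ``-test``.  Any other unknown name is an error.
    """
    ds1, ds2, excluded = [], [], []
    for name in record_names:
        if name in DS1_RECORDS:
            ds1.append(name)
        elif name in DS2_RECORDS:
            ds2.append(name)
        elif name in PACED_RECORDS:
            excluded.append(name)
        elif name.startswith("synth"):
            (ds2 if name.endswith("-test") else ds1).append(name)
        else:
            raise ValueError(f"record name {name!r} is in no known partition")
    return ds1, ds2, excluded
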