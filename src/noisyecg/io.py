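"""Reading and writing ECG records and beat annotations.

Supports two on-disk representations:

* WFDB record triplets (``.hea`` header, ``.dat`` signal, ``.atr``
  annotations) as distributed by PhysioNet for the MIT-BIH Arrhythmia
  Database and the European ST-T Database.  Signal formats 212 (packed
  12-bit pairs), 16 (little-endian int16) and 80 (offset-binary 8-bit)
  are implemented, which covers both databases.
* A plain two-column CSV (``time_s,amplitude``) for fixtures and exports.

Samples are always converted to physical units using the header gain and
baseline, and are never resampled: the returned signal has exactly the
header-declared number of samples.
"""

from __future__ import annotations

import csv
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "EcgSignal",
    "AnnotationSet",
    "DEFAULT_BEAT_CODES",
    "read_record",
    "read_beat_annotations",
    "read_csv_signal",
    "write_csv_signal",
    "write_annotations",
    "write_record",
]

#: Standard WFDB beat classes (the convention used by the ``bxb`` tool).
DEFAULT_BEAT_CODES = frozenset(
    ["N", "L", "R", "B", "A", "a", "J", "S", "V", "r",
     "F", "e", "j", "n", "E", "/", "f", "Q"]
)

# MIT annotation code <-> mnemonic table (codes 0..49; 0 is "no annotation").
_CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A",
    9: "S", 10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|",
    18: "s", 19: "T", 20: "*", 21: "D", 22: '"', 23: "=", 24: "p",
    25: "B", 26: "^", 27: "t", 28: "+", 29: "u", 30: "?", 31: "!",
    32: "[", 33: "]", 34: "e", 35: "n", 36: "@", 37: "x", 38: "f",
    39: "(", 40: ")", 41: "r",
}
_SYMBOL_TO_CODE = {s: c for c, s in _CODE_TO_SYMBOL.items()}

# Pseudo-annotation codes of the MIT format.
_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


@dataclass
class EcgSignal:
    """A uniformly sampled single-lead ECG waveform.

    Parameters
    ----------
    samples : ndarray
        Amplitudes in physical units (mV unless ``units`` says otherwise).
    fs : float
        Sampling rate in Hz.
    lead : str
        Free-text lead label.
    t0 : float
        Start offset of the first sample in seconds.
    units : str
        Physical unit label of ``samples``.
    """

    samples: np.ndarray
    fs: float
    lead: str = ""
    t0: float = 0.0
    units: str = "mV"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite (NaN/Inf forbidden on ingest)")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.n) / self.fs


@dataclass
class AnnotationSet:
    """Ordered beat annotations: sample positions plus per-beat codes."""

    indices: np.ndarray
    symbols: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.indices.size and np.any(np.diff(self.indices) <= 0):
            raise ValueError("annotation indices must be strictly increasing")
        if len(self.symbols) != self.indices.size:
            raise ValueError("indices and symbols must have the same length")

    def __len__(self) -> int:
        return int(self.indices.size)


# ---------------------------------------------------------------------------
# WFDB header
# ---------------------------------------------------------------------------

@dataclass
class _SignalSpec:
    file_name: str
    fmt: int
    gain: float
    baseline: int
    units: str
    description: str


@dataclass
class _Header:
    record_name: str
    n_sig: int
    fs: float
    n_samples: int
    signals: list[_SignalSpec]


def _parse_header(path: Path) -> _Header:
    lines = [ln.strip() for ln in path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise IOError(f"empty WFDB header: {path}")
    rec = lines[0].split()
    name = rec[0].split("/")[0]
    n_sig = int(rec[1])
    fs = float(rec[2].split("/")[0]) if len(rec) > 2 else 250.0
    n_samples = int(rec[3]) if len(rec) > 3 else 0
    specs: list[_SignalSpec] = []
    for ln in lines[1:1 + n_sig]:
        toks = ln.split()
        file_name = toks[0]
        # format may carry xN / :skew / +offset modifiers
        fmt_tok = toks[1]
        for sep in ("x", ":", "+"):
            fmt_tok = fmt_tok.split(sep)[0]
        fmt = int(fmt_tok)
        gain, baseline, units = 200.0, None, "mV"
        if len(toks) > 2:
            g = toks[2]
            if "/" in g:
                g, units = g.split("/", 1)
            if "(" in g:
                g, b = g.split("(")
                baseline = int(b.rstrip(")"))
            gain = float(g) if float(g) != 0 else 200.0
        adc_zero = int(toks[4]) if len(toks) > 4 else 0
        if baseline is None:
            baseline = adc_zero
        description = " ".join(toks[8:]) if len(toks) > 8 else ""
        specs.append(_SignalSpec(file_name, fmt, gain, baseline, units, description))
    if len(specs) != n_sig:
        raise IOError(f"header {path} declares {n_sig} signals, found {len(specs)}")
    return _Header(name, n_sig, fs, n_samples, specs)


# ---------------------------------------------------------------------------
# WFDB signal formats
# ---------------------------------------------------------------------------

def _decode_212(raw: bytes, n_values: int) -> np.ndarray:
    """Unpack format 212: two 12-bit two's-complement samples per 3 bytes."""
    triplets = np.frombuffer(raw, dtype=np.uint8)
    n_trip = triplets.size // 3
    if n_trip * 2 + (triplets.size % 3 > 0) < n_values:
        raise IOError("signal file too short for declared sample count")
    t = triplets[: n_trip * 3].reshape(-1, 3).astype(np.int32)
    first = ((t[:, 1] & 0x0F) << 8) | t[:, 0]
    second = ((t[:, 1] & 0xF0) << 4) | t[:, 2]
    out = np.empty(n_trip * 2, dtype=np.int32)
    out[0::2] = first
    out[1::2] = second
    out[out > 2047] -= 4096
    return out[:n_values]


def _encode_212(values: np.ndarray) -> bytes:
    v = np.asarray(values, dtype=np.int32)
    if np.any(v < -2048) or np.any(v > 2047):
        raise ValueError("format 212 requires samples in [-2048, 2047]")
    if v.size % 2:
        v = np.concatenate([v, [0]])
    v = np.where(v < 0, v + 4096, v).astype(np.uint32)
    a, b = v[0::2], v[1::2]
    out = np.empty((a.size, 3), dtype=np.uint8)
    out[:, 0] = a & 0xFF
    out[:, 1] = ((a >> 8) & 0x0F) | (((b >> 8) & 0x0F) << 4)
    out[:, 2] = b & 0xFF
    return out.tobytes()


def _read_dat(path: Path, hdr: _Header) -> np.ndarray:
    """Read the interleaved digital samples, shape (n_samples, n_sig)."""
    fmts = {s.fmt for s in hdr.signals}
    if len(fmts) > 1:
        raise IOError(f"mixed signal formats {fmts} not supported")
    fmt = fmts.pop()
    raw = path.read_bytes()
    total = hdr.n_samples * hdr.n_sig
    if fmt == 212:
        flat = _decode_212(raw, total)
    elif fmt == 16:
        flat = np.frombuffer(raw, dtype="<i2")
        if flat.size < total:
            raise IOError("signal file too short for declared sample count")
        flat = flat[:total].astype(np.int32)
    elif fmt == 80:
        flat = np.frombuffer(raw, dtype=np.uint8)
        if flat.size < total:
            raise IOError("signal file too short for declared sample count")
        flat = flat[:total].astype(np.int32) - 128
    else:
        raise IOError(f"unsupported WFDB signal format {fmt}")
    return flat.reshape(hdr.n_samples, hdr.n_sig)


def read_record(path: str | Path, channel: int = 0) -> EcgSignal:
    """Read one channel of a WFDB record in physical units.

    ``path`` is the record identifier (with or without the ``.hea``
    extension).  The declared sample count is honoured exactly; no
    resampling is ever applied.
    """
    path = Path(path)
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise IOError(f"missing WFDB header file: {hea}")
    hdr = _parse_header(hea)
    if not 0 <= channel < hdr.n_sig:
        raise ValueError(
            f"channel {channel} out of range for {hdr.n_sig}-channel record")
    dat = hea.parent / hdr.signals[channel].file_name
    if not dat.exists():
        raise IOError(f"missing WFDB signal file: {dat}")
    digital = _read_dat(dat, hdr)[:, channel]
    spec = hdr.signals[channel]
    physical = (digital - spec.baseline) / spec.gain
    return EcgSignal(physical, fs=hdr.fs,
                     lead=spec.description or f"ch{channel}", units=spec.units)


def write_record(path: str | Path, signals: np.ndarray, fs: float,
                 gain: float = 200.0, baseline: int = 0, fmt: int = 212,
                 leads: list[str] | None = None) -> None:
    """Write a WFDB record (header + signal file).

    Fixture support for tests and synthetic benchmarks; ``signals`` is
    (n_samples, n_sig) in physical units and is quantised by ``gain``.
    """
    path = Path(path)
    sig = np.atleast_2d(np.asarray(signals, dtype=float))
    if sig.shape[0] < sig.shape[1]:
        sig = sig.T
    n_samples, n_sig = sig.shape
    digital = np.rint(sig * gain + baseline).astype(np.int32)
    if fmt == 212:
        digital = np.clip(digital, -2048, 2047)
        payload = _encode_212(digital.reshape(-1))
        ext = path.stem + ".dat"
    elif fmt == 16:
        digital = np.clip(digital, -32768, 32767)
        payload = digital.reshape(-1).astype("<i2").tobytes()
        ext = path.stem + ".dat"
    else:
        raise ValueError(f"unsupported write format {fmt}")
    leads = leads or [f"ch{i}" for i in range(n_sig)]
    lines = [f"{path.stem} {n_sig} {fs:g} {n_samples}"]
    for i in range(n_sig):
        lines.append(f"{ext} {fmt} {gain:g}({baseline})/mV 12 {baseline} 0 0 0 {leads[i]}")
    path.with_suffix(".hea").write_text("\n".join(lines) + "\n")
    (path.parent / ext).write_bytes(payload)


# ---------------------------------------------------------------------------
# MIT annotation files
# ---------------------------------------------------------------------------

def _iter_annotations(raw: bytes):
    """Yield (sample_index, code) pairs from a MIT-format annotation stream."""
    pos, time = 0, 0
    n = len(raw)
    while pos + 1 < n:
        word = raw[pos] | (raw[pos + 1] << 8)
        pos += 2
        code = word >> 10
        delta = word & 0x3FF
        if code == 0 and delta == 0:       # end of stream
            return
        if code == _SKIP:
            if pos + 3 >= n:
                raise IOError("truncated SKIP annotation")
            hi = raw[pos] | (raw[pos + 1] << 8)
            lo = raw[pos + 2] | (raw[pos + 3] << 8)
            pos += 4
            interval = (hi << 16) | lo
            if interval >= 1 << 31:
                interval -= 1 << 32
            time += interval
        elif code == _AUX:
            pos += delta + (delta & 1)     # aux string, padded to even length
        elif code in (_NUM, _SUB, _CHN):
            continue
        else:
            time += delta
            yield time, code
    raise IOError("annotation stream ended without EOF marker")


def read_beat_annotations(path: str | Path,
                          beat_codes: frozenset[str] | set[str] = DEFAULT_BEAT_CODES,
                          extension: str = "atr") -> AnnotationSet:
    """Read a MIT annotation file, keeping only the requested beat classes."""
    path = Path(path)
    ann = path if path.suffix == f".{extension}" else path.with_suffix(f".{extension}")
    if not ann.exists():
        raise IOError(f"missing annotation file: {ann}")
    try:
        pairs = list(_iter_annotations(ann.read_bytes()))
    except IOError:
        raise
    except Exception as exc:  # malformed stream
        raise IOError(f"unreadable annotation stream {ann}: {exc}") from exc
    indices, symbols = [], []
    for time, code in pairs:
        sym = _CODE_TO_SYMBOL.get(code)
        if sym is not None and sym in beat_codes:
            indices.append(time)
            symbols.append(sym)
    return AnnotationSet(np.asarray(indices, dtype=np.int64), symbols)


def write_annotations(path: str | Path, ann: AnnotationSet,
                      extension: str = "atr") -> None:
    """Write an AnnotationSet as a MIT-format annotation file."""
    path = Path(path)
    out = path if path.suffix == f".{extension}" else path.with_suffix(f".{extension}")
    buf = bytearray()
    prev = 0
    for idx, sym in zip(ann.indices, ann.symbols):
        code = _SYMBOL_TO_CODE.get(sym)
        if code is None:
            raise ValueError(f"symbol {sym!r} has no MIT annotation code")
        delta = int(idx) - prev
        if delta >= 1024 or delta < 0:
            buf += struct.pack("<H", (_SKIP << 10))
            buf += struct.pack("<HH", (delta >> 16) & 0xFFFF, delta & 0xFFFF)
            delta = 0
        buf += struct.pack("<H", (code << 10) | delta)
        prev = int(idx)
    buf += struct.pack("<H", 0)  # EOF marker
    out.write_bytes(bytes(buf))


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def read_csv_signal(path: str | Path, lead: str = "csv") -> EcgSignal:
    """Read a two-column ``time_s,amplitude`` CSV (header row required)."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"missing CSV signal file: {path}")
    t, x = [], []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or len(header) < 2:
            raise IOError(f"CSV {path} lacks the required header row")
        for row in reader:
            if not row:
                continue
            t.append(float(row[0]))
            x.append(float(row[1]))
    if len(t) < 2:
        raise IOError(f"CSV {path} holds fewer than two samples")
    t_arr = np.asarray(t)
    dt = np.diff(t_arr)
    if np.ptp(dt) > 1e-3 * dt.mean():
        raise IOError(f"CSV {path} is not uniformly sampled")
    return EcgSignal(np.asarray(x), fs=1.0 / dt.mean(), lead=lead, t0=t_arr[0])


def write_csv_signal(path: str | Path, signal: EcgSignal) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_s", "amplitude"])
        for ts, amp in zip(signal.times(), signal.samples):
            writer.writerow([f"{ts:.9f}", f"{amp:.9g}"])
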