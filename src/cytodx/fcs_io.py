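"""Reading, writing and transforming list-mode flow-cytometry data.

This module covers the front end of the pipeline: FCS 3.0/3.1 file I/O,
spectral-spillover compensation, and the logicle (inverse-biexponential)
intensity transform with automatic parameter estimation.

The logicle scale is linear around zero and logarithmic at high
intensities; it is parameterized by the top-of-scale value ``T``, the
number of decades ``M``, the linearization width ``W`` (in decades) and
the number of additional negative decades ``A``.  Transformed values are
reported on the normalized scale ``y`` in [0, 1], where ``y = 1``
corresponds to an intensity of ``T``.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "EventMatrix",
    "SpilloverMatrix",
    "LogicleParams",
    "FcsFormatError",
    "FcsCorruptError",
    "read_fcs",
    "write_fcs",
    "read_spillover",
    "read_spillover_csv",
    "compensate",
    "estimate_logicle",
    "logicle",
    "biexponential",
    "logicle_inverse_transform",
    "standard_transform",
    "is_scatter_channel",
    "is_time_channel",
]


class FcsFormatError(ValueError):
    """Unsupported FCS version, data mode or data type."""


class FcsCorruptError(ValueError):
    """File metadata is inconsistent with the data segment."""


def is_scatter_channel(name: str) -> bool:
    return name.upper().startswith(("FSC", "SSC"))


def is_time_channel(name: str) -> bool:
    return name.upper().startswith("TIME")


@dataclass
class EventMatrix:
    """Events x channels intensity matrix with per-event keep mask.

    Parameters
    ----------
    values
        ``(n_events, n_channels)`` float array.  Arbitrary fluorescence
        units before transformation; normalized [0, 1]-scale units for
        channels whose ``transformed`` flag is set.
    channels
        Ordered, unique short channel names ($PnN).
    marker_map
        Optional channel -> marker ($PnS) mapping.
    transformed
        Per-channel boolean flags.
    keep
        Per-event boolean mask; quality control only ever clears bits.
    ranges
        Per-channel instrument range ($PnR, top of scale).
    """

    values: np.ndarray
    channels: list[str]
    marker_map: dict[str, str] = field(default_factory=dict)
    transformed: np.ndarray | None = None
    keep: np.ndarray | None = None
    ranges: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D events x channels matrix")
        self.channels = list(self.channels)
        if len(self.channels) != self.values.shape[1]:
            raise ValueError("number of channel names must match columns")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel names must be unique")
        if self.transformed is None:
            self.transformed = np.zeros(len(self.channels), dtype=bool)
        else:
            self.transformed = np.asarray(self.transformed, dtype=bool)
            if self.transformed.shape != (len(self.channels),):
                raise ValueError("transformed must have one flag per channel")
        if self.keep is None:
            self.keep = np.ones(self.values.shape[0], dtype=bool)
        else:
            self.keep = np.asarray(self.keep, dtype=bool)
            if self.keep.shape != (self.values.shape[0],):
                raise ValueError("keep must have one entry per event")

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def index(self, name: str) -> int:
        """Column index of a channel, resolving marker names too."""
        if name in self.channels:
            return self.channels.index(name)
        for ch, marker in self.marker_map.items():
            if marker == name and ch in self.channels:
                return self.channels.index(ch)
        raise KeyError(f"channel or marker {name!r} not present")

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.index(name)]

    def kept_values(self, names: list[str] | None = None) -> np.ndarray:
        """Values of kept events, optionally restricted to named columns."""
        cols = (
            slice(None)
            if names is None
            else [self.index(n) for n in names]
        )
        return self.values[self.keep][:, cols]

    def copy(self) -> "EventMatrix":
        return EventMatrix(
            values=self.values.copy(),
            channels=list(self.channels),
            marker_map=dict(self.marker_map),
            transformed=self.transformed.copy(),
            keep=self.keep.copy(),
            ranges=dict(self.ranges),
        )


@dataclass
class SpilloverMatrix:
    """Square spillover matrix keyed by fluorescence channel names."""

    matrix: np.ndarray
    channels: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.channels = list(self.channels)
        n = len(self.channels)
        if self.matrix.shape != (n, n):
            raise ValueError("spillover matrix must be square, keyed by channels")


# --------------------------------------------------------------------------
# FCS file I/O
#
# FCS 3.1 layout: a 58-byte ASCII header with segment offsets, a TEXT
# segment of delimiter-separated keyword/value pairs, and a DATA segment.
# We write float32 little-endian list-mode data with an uncommon delimiter
# byte (0x1E) so that channel names containing '/' survive verbatim.

_DELIM = b"\x1e"


def write_fcs(E: EventMatrix, path) -> str:
    """Write an :class:`EventMatrix` as a single-dataset FCS 3.1 file."""
    if E.n_events == 0 or E.n_channels == 0:
        raise ValueError("cannot write an empty event matrix")
    data = np.ascontiguousarray(E.values, dtype="<f4").tobytes()

    kw: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$TOT": str(E.n_events),
        "$PAR": str(E.n_channels),
    }
    for j, ch in enumerate(E.channels, start=1):
        kw[f"$P{j}N"] = ch
        if ch in E.marker_map:
            kw[f"$P{j}S"] = E.marker_map[ch]
        kw[f"$P{j}B"] = "32"
        kw[f"$P{j}E"] = "0,0"
        rng = E.ranges.get(ch)
        if rng is None:
            col = E.values[:, j - 1]
            rng = float(col.max()) if col.size else 1.0
        kw[f"$P{j}R"] = repr(float(rng))

    # data offsets depend on the TEXT length; fixed-width zero padding
    # makes the layout solvable in one pass
    kw["$BEGINDATA"] = "0" * 12
    kw["$ENDDATA"] = "0" * 12

    def render(d: dict[str, str]) -> bytes:
        out = bytearray(_DELIM)
        for k, v in d.items():
            out += k.encode("utf-8") + _DELIM + v.encode("utf-8") + _DELIM
        return bytes(out)

    text_start = 58
    text = render(kw)
    data_start = text_start + len(text)
    data_end = data_start + len(data) - 1
    kw["$BEGINDATA"] = str(data_start).zfill(12)
    kw["$ENDDATA"] = str(data_end).zfill(12)
    text = render(kw)

    header = b"FCS3.1    "
    for off in (text_start, text_start + len(text) - 1, data_start, data_end, 0, 0):
        header += f"{off:>8d}".encode("ascii") if off <= 99_999_999 else b"       0"
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data)
    return str(path)


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    delim = raw[:1]
    # split on the delimiter; escaped (doubled) delimiters re-join tokens
    tokens: list[str] = []
    parts = raw[1:].split(delim)
    i = 0
    buf = ""
    while i < len(parts):
        buf += parts[i].decode("utf-8", errors="replace")
        if i + 1 < len(parts) and parts[i + 1] == b"" and i + 2 < len(parts):
            buf += delim.decode()
            parts[i + 1] = parts[i + 2]
            del parts[i + 2]
            continue
        tokens.append(buf)
        buf = ""
        i += 1
    if tokens and tokens[-1] == "":
        tokens.pop()
    return {
        tokens[i].strip().upper(): tokens[i + 1]
        for i in range(0, len(tokens) - 1, 2)
    }


def _read_segments(path) -> tuple[dict[str, str], bytes]:
    with open(path, "rb") as fh:
        blob = fh.read()
    version = blob[:6].decode("ascii", errors="replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise FcsFormatError(f"unsupported FCS version {version!r}")
    try:
        ts = int(blob[10:18])
        te = int(blob[18:26])
    except ValueError as exc:
        raise FcsCorruptError("unreadable header offsets") from exc
    keywords = _parse_text_segment(blob[ts : te + 1])
    ds = int(keywords.get("$BEGINDATA", blob[26:34] or 0))
    de = int(keywords.get("$ENDDATA", blob[34:42] or 0))
    if ds == 0:
        ds, de = int(blob[26:34]), int(blob[34:42])
    return keywords, blob[ds : de + 1]


def read_fcs(path) -> EventMatrix:
    """Read a single-dataset FCS 3.0/3.1 list-mode file."""
    kw, data = _read_segments(path)
    if kw.get("$MODE", "L") != "L":
        raise FcsFormatError("only list-mode ($MODE=L) files are supported")
    dtype_code = kw.get("$DATATYPE", "F")
    if dtype_code not in ("F", "D", "I"):
        raise FcsFormatError(f"unsupported $DATATYPE {dtype_code!r}")
    tot = int(kw["$TOT"])
    par = int(kw["$PAR"])
    order = kw.get("$BYTEORD", "1,2,3,4")
    endian = "<" if order.startswith("1") else ">"

    if dtype_code == "F":
        np_dtype = np.dtype(endian + "f4")
    elif dtype_code == "D":
        np_dtype = np.dtype(endian + "f8")
    else:
        bits = {int(kw.get(f"$P{j}B", "32")) for j in range(1, par + 1)}
        if len(bits) != 1 or bits.pop() not in (16, 32):
            raise FcsFormatError("integer data requires uniform $PnB of 16 or 32")
        nbytes = int(kw["$P1B"]) // 8
        np_dtype = np.dtype(endian + ("u2" if nbytes == 2 else "u4"))

    expected = tot * par * np_dtype.itemsize
    if len(data) < expected:
        raise FcsCorruptError(
            f"$TOT={tot} implies {expected} data bytes but segment has {len(data)}"
        )
    values = (
        np.frombuffer(data[:expected], dtype=np_dtype)
        .reshape(tot, par)
        .astype(float)
    )
    channels = [kw.get(f"$P{j}N", f"P{j}") for j in range(1, par + 1)]
    marker_map = {
        channels[j - 1]: kw[f"$P{j}S"] for j in range(1, par + 1) if f"$P{j}S" in kw
    }
    ranges = {
        channels[j - 1]: float(kw[f"$P{j}R"])
        for j in range(1, par + 1)
        if f"$P{j}R" in kw
    }
    return EventMatrix(
        values=values, channels=channels, marker_map=marker_map, ranges=ranges
    )


def read_spillover(path) -> SpilloverMatrix | None:
    """Extract the $SPILLOVER/$COMP matrix from an FCS file, if present."""
    kw, _ = _read_segments(path)
    for key in ("$SPILLOVER", "SPILL", "$COMP"):
        if key in kw:
            parts = kw[key].split(",")
            n = int(parts[0])
            chans = parts[1 : 1 + n]
            vals = np.array([float(v) for v in parts[1 + n :]], dtype=float)
            return SpilloverMatrix(vals.reshape(n, n), chans)
    return None


def read_spillover_csv(path) -> SpilloverMatrix:
    """Read a delimited sidecar spillover matrix (first row = channel names)."""
    import csv

    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if r]
    chans = [c.strip() for c in rows[0]]
    vals = np.array([[float(v) for v in r] for r in rows[1:]], dtype=float)
    return SpilloverMatrix(vals, chans)


# --------------------------------------------------------------------------
# Compensation


def compensate(E: EventMatrix, S: SpilloverMatrix) -> EventMatrix:
    """Unmix spectral spillover: observed = true @ S, so true = observed @ S^-1.

    Only the channels named in ``S`` are touched; scatter and time channels
    must not appear in ``S``.
    """
    missing = [c for c in S.channels if c not in E.channels]
    if missing:
        raise KeyError(f"spillover channels absent from events: {missing}")
    try:
        inv = np.linalg.inv(S.matrix)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular spillover matrix over channels {S.channels}"
        ) from exc
    out = E.copy()
    idx = [E.channels.index(c) for c in S.channels]
    out.values[:, idx] = E.values[:, idx] @ inv
    return out


# --------------------------------------------------------------------------
# Logicle transform


@dataclass(frozen=True)
class LogicleParams:
    """Parameters of the logicle scale (top of scale T, decades M,
    linearization width W, additional negative decades A)."""

    T: float
    M: float = 4.5
    W: float = 0.5
    A: float = 0.0

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("T must be positive")
        if self.M <= 0:
            raise ValueError("M must be positive")
        if not (0 <= self.W <= self.M / 2):
            raise ValueError("W must be in [0, M/2]")
        if self.A < 0:
            raise ValueError("A must be non-negative")


def _coefficients(p: LogicleParams) -> tuple[float, float, float, float, float]:
    """Coefficients (a, b, c, d, f) of the biexponential
    S(y) = a*exp(b*y) - c*exp(-d*y) + f with S(x1) = 0 and S(1) = T."""
    w = p.W / (p.M + p.A)
    x2 = p.A / (p.M + p.A)
    x1 = x2 + w
    x0 = x2 + 2 * w
    b = (p.M + p.A) * np.log(10.0)
    if w == 0:
        d = b
    else:
        # d solves 2*(ln d - ln b) + w*(b + d) = 0 on (0, b)
        fun = lambda d: 2 * (np.log(d) - np.log(b)) + w * (b + d)
        d = brentq(fun, 1e-12, b, xtol=1e-14, rtol=1e-14)
    c_a = np.exp(x0 * (b + d))
    mf_a = np.exp(b * x1) - c_a * np.exp(-d * x1)
    a = p.T / ((np.exp(b) - mf_a) - c_a * np.exp(-d))
    c = c_a * a
    f = -mf_a * a
    return a, b, c, d, f


def biexponential(y, p: LogicleParams):
    """Forward biexponential: normalized scale position -> intensity."""
    a, b, c, d, f = _coefficients(p)
    y = np.asarray(y, dtype=float)
    return a * np.exp(b * y) - c * np.exp(-d * y) + f


def logicle_inverse_transform(y, p: LogicleParams):
    """Alias of :func:`biexponential` (scale -> raw intensity)."""
    return biexponential(y, p)


def _logicle_values(x, p: LogicleParams, tol: float = 1e-9) -> np.ndarray:
    """Invert the biexponential by vectorized bisection.

    S is smooth and strictly increasing (S'(y) = ab*e^{by} + cd*e^{-dy} > 0),
    so bisection on a generous bracket converges unconditionally.
    """
    a, b, c, d, f = _coefficients(p)
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("non-finite intensity passed to logicle")
    lo = np.full(x.shape, -1.0)
    hi = np.full(x.shape, 2.0)
    # widen bracket for extreme values (rare)
    for _ in range(60):
        bad_lo = a * np.exp(b * lo) - c * np.exp(-d * lo) + f > x
        bad_hi = a * np.exp(b * hi) - c * np.exp(-d * hi) + f < x
        if not (bad_lo.any() or bad_hi.any()):
            break
        lo[bad_lo] -= 1.0
        hi[bad_hi] += 1.0
    else:
        raise FloatingPointError("logicle bracket expansion failed to converge")
    for _ in range(52):  # resolution well below tol on a span of a few units
        mid = 0.5 * (lo + hi)
        high = a * np.exp(b * mid) - c * np.exp(-d * mid) + f > x
        hi = np.where(high, mid, hi)
        lo = np.where(high, lo, mid)
        if np.max(hi - lo) < tol * 1e-3:
            break
    return 0.5 * (lo + hi)


def estimate_logicle(E: EventMatrix, channel: str) -> LogicleParams:
    """Estimate logicle parameters for one channel from its data.

    T is the instrument range ($PnR) when known, otherwise the observed
    maximum; M = 4.5 decades and A = 0.  The linearization width is
    derived from the 5th percentile r of the negative values,
    W = max(0, (M - log10(T/|r|)) / 2), defaulting to 0.5 when the
    channel has no negative events.
    """
    x = E.column(channel)
    if x.size == 0:
        raise ValueError("cannot estimate logicle parameters without events")
    ch = E.channels[E.index(channel)]
    T = float(E.ranges.get(ch, np.max(x)))
    if T <= 0:
        raise ValueError(f"non-positive top of scale for channel {channel!r}")
    M, A = 4.5, 0.0
    neg = x[x < 0]
    if neg.size == 0:
        W = 0.5
    else:
        r = float(np.percentile(neg, 5))
        W = max(0.0, (M - np.log10(T / abs(r))) / 2)
        W = min(W, M / 2)
    return LogicleParams(T=T, M=M, W=W, A=A)


def logicle(E: EventMatrix, params: dict[str, LogicleParams]) -> EventMatrix:
    """Apply the logicle transform to the given channels.

    Output is on the normalized scale (decades / M), so an intensity of T
    maps to 1.  Channels already flagged as transformed are rejected.
    """
    out = E.copy()
    for name, p in params.items():
        j = E.index(name)
        if out.transformed[j]:
            raise ValueError(f"channel {name!r} is already transformed")
        try:
            out.values[:, j] = _logicle_values(E.values[:, j], p)
        except FloatingPointError as exc:
            raise FloatingPointError(
                f"logicle inversion failed on channel {name!r}: {exc}"
            ) from exc
        out.transformed[j] = True
    return out


def standard_transform(E: EventMatrix) -> EventMatrix:
    """Per-channel default transform used before clustering.

    Fluorescence channels get an estimated logicle transform; scatter
    channels (FSC*/SSC*) are linearly rescaled to [0, 1] by instrument
    range so that all clustering inputs share a common scale.  Time
    channels are left untouched.
    """
    params = {}
    linear = []
    for ch in E.channels:
        if is_time_channel(ch):
            continue
        if is_scatter_channel(ch):
            linear.append(ch)
        else:
            params[ch] = estimate_logicle(E, ch)
    out = logicle(E, params)
    for ch in linear:
        j = out.index(ch)
        rng = float(out.ranges.get(ch, np.max(out.values[:, j]) or 1.0))
        out.values[:, j] = out.values[:, j] / rng
        out.transformed[j] = True
    return out
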