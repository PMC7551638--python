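"""Reading, validity-filtering and windowing of raw ECG sample streams.

A stream is an ordered sequence of raw sensor-unit values at a fixed
sampling rate (100 Hz by default).  Values outside the sensor's valid
range [200, 500] are treated as transmission/initialization errors and
removed before any spectral analysis; the surviving samples are framed
into consecutive non-overlapping windows whose length is a power of two
(256 samples = 2.56 s at 100 Hz) so the radix-2 FFT applies directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_SAMPLE_RATE_HZ = 100.0
VALID_LOW = 200.0
VALID_HIGH = 500.0
DEFAULT_WINDOW_LEN = 256

CSV_HEADER = ("sample_index", "value")


class StreamParseError(ValueError):
    """Raised when a stream CSV is malformed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line


@dataclass(frozen=True)
class EcgStream:
    """Ordered raw ECG samples at a fixed rate.

    ``origin_index`` is the index of the first retained sample within the
    raw acquisition, so a filtered stream remembers where it came from.
    """

    values: np.ndarray
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ
    origin_index: int = 0

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if self.sample_rate_hz <= 0:
            raise ValueError(f"sample_rate_hz must be positive, got {self.sample_rate_hz}")
        if vals.ndim != 1:
            raise ValueError("stream values must be one-dimensional")
        if vals.size and not np.all(np.isfinite(vals)):
            raise ValueError("stream values must be finite")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def duration_s(self) -> float:
        return len(self) / self.sample_rate_hz


@dataclass(frozen=True)
class Window:
    """A fixed-length analysis frame: exactly 2**k samples (k >= 3)."""

    samples: np.ndarray
    source_offset: int = 0

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", s)
        n = s.size
        if n < 8 or (n & (n - 1)) != 0:
            raise ValueError(f"window length must be a power of two >= 8, got {n}")

    def __len__(self) -> int:
        return int(self.samples.size)


def read_stream_csv(path: str | Path, sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ) -> EcgStream:
    """Read a two-column ``sample_index,value`` CSV into an :class:`EcgStream`.

    Malformed numeric cells raise :class:`StreamParseError` naming the
    offending 1-based file line (the header is line 1).  An empty file
    yields an empty stream with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise StreamParseError(f"stream file not found: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        logger.warning("empty stream file: %s", path)
        return EcgStream(np.empty(0), sample_rate_hz=sample_rate_hz)
    if df.shape[1] < 2:
        raise StreamParseError(f"{path}: expected two columns {CSV_HEADER}, got {list(df.columns)}")
    if df.empty:
        logger.warning("stream file has a header but no samples: %s", path)
        return EcgStream(np.empty(0), sample_rate_hz=sample_rate_hz)
    values = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    bad = values.isna() & df.iloc[:, 1].notna() | df.iloc[:, 1].isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        # +2: one for the header line, one for 0- vs 1-based counting
        raise StreamParseError(
            f"{path}: non-numeric value {df.iloc[row, 1]!r} at line {row + 2}", line=row + 2
        )
    return EcgStream(values.to_numpy(dtype=float), sample_rate_hz=sample_rate_hz)


def write_stream_csv(stream: EcgStream, path: str | Path) -> None:
    """Write a stream as ``sample_index,value`` CSV (LF endings, no float noise for ints)."""
    path = Path(path)
    vals = stream.values
    idx = np.arange(stream.origin_index, stream.origin_index + vals.size)
    with open(path, "w", newline="\n") as fh:
        fh.write(",".join(CSV_HEADER) + "\n")
        for i, v in zip(idx, vals):
            fh.write(f"{i},{v:g}\n")


def validity_filter(
    stream: EcgStream, low: float = VALID_LOW, high: float = VALID_HIGH
) -> tuple[EcgStream, int]:
    """Remove samples outside the closed interval [low, high].

    Returns the filtered stream (order preserved) and the number of
    samples removed.  Idempotent: filtering a filtered stream removes
    nothing further.
    """
    if not low < high:
        raise ValueError(f"low must be < high, got [{low}, {high}]")
    vals = stream.values
    keep = (vals >= low) & (vals <= high)
    removed = int(vals.size - keep.sum())
    if removed:
        logger.debug("validity_filter removed %d of %d samples", removed, vals.size)
    first_kept = int(np.flatnonzero(keep)[0]) if keep.any() else 0
    out = EcgStream(
        vals[keep],
        sample_rate_hz=stream.sample_rate_hz,
        origin_index=stream.origin_index + first_kept,
    )
    return out, removed


def frame_windows(stream: EcgStream, window_len: int = DEFAULT_WINDOW_LEN) -> list[Window]:
    """Cut a stream into consecutive non-overlapping windows.

    The trailing partial window is dropped: ``floor(len / window_len)``
    windows are returned, each tagged with its sample offset into the
    (filtered) stream.
    """
    if window_len < 8 or (window_len & (window_len - 1)) != 0:
        raise ValueError(f"window_len must be a power of two >= 8, got {window_len}")
    n = len(stream) // window_len
    return [
        Window(stream.values[k * window_len : (k + 1) * window_len], source_offset=k * window_len)
        for k in range(n)
    ]


def concat_windows(windows: Iterable[Window], sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ) -> EcgStream:
    """Concatenate windows back into a stream (inverse of framing on the covered prefix)."""
    parts = [w.samples for w in windows]
    if not parts:
        return EcgStream(np.empty(0), sample_rate_hz=sample_rate_hz)
    return EcgStream(np.concatenate(parts), sample_rate_hz=sample_rate_hz)
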