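"""Data model and CSV I/O for driving telemetry.

The unit of analysis is a *drive sample*: a fixed-length (by default one
minute) synchronized pair of steering-wheel-angle (SWA) and yaw-angle (YA)
traces, optionally carrying an expert fatigue label and discard flags.
Recordings are plain CSV with a ``time_s`` column plus ``swa_deg`` and
``ya_deg`` in degrees; labels and discard flags travel in a separate
metadata CSV keyed by sample index.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Maximum tolerated deviation of the time column from a uniform grid (s).
TIME_UNIFORMITY_TOL = 1e-6

SIGNAL_COLUMNS = ("time_s", "swa_deg", "ya_deg")

VALID_FLAGS = frozenset({"curved_road", "lane_shift", "no_consensus"})


class FormatError(ValueError):
    """Raised when an input file does not match the expected schema."""


class InsufficientDataError(ValueError):
    """Raised when a series is too short for the requested computation."""


class FatigueLabel(enum.IntEnum):
    """Three-level fatigue scale.

    Numeric codes follow the 0/1/2 convention used in the confusion-matrix
    literature for this problem; display names map each code to the
    behavioural description (alert driver, drowsy driver, severely drowsy
    driver losing the ability to drive).
    """

    AWAKE = 0
    DROWSY = 1
    VERY_DROWSY = 2

    @property
    def display_name(self) -> str:
        return _LEVEL_NAMES[self]

    @classmethod
    def from_name(cls, name: str) -> "FatigueLabel":
        key = name.strip().lower().replace(" ", "_")
        for level, disp in _LEVEL_NAMES.items():
            if disp.replace(" ", "_") == key:
                return level
        raise ValueError(f"unknown fatigue level name: {name!r}")


_LEVEL_NAMES = {
    FatigueLabel.AWAKE: "awake",
    FatigueLabel.DROWSY: "drowsy",
    FatigueLabel.VERY_DROWSY: "very drowsy",
}


@dataclass(frozen=True)
class TimeSeriesSignal:
    """One uniformly sampled telemetry channel.

    Parameters
    ----------
    values : array-like
        Samples in degrees.
    fs : float
        Sampling frequency in Hz; must be positive.
    channel : str
        Either ``"SWA"`` or ``"YA"``.
    """

    values: np.ndarray
    fs: float
    channel: str = "SWA"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size == 0:
            raise ValueError("values must be a non-empty 1-D sequence")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if self.channel not in ("SWA", "YA"):
            raise ValueError("channel must be 'SWA' or 'YA'")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        """Signal duration in seconds (length / fs)."""
        return self.values.size / self.fs


@dataclass
class DriveSample:
    """A synchronized SWA/YA segment, the unit of labeling and classification."""

    swa: TimeSeriesSignal
    ya: TimeSeriesSignal
    start_time: float = 0.0
    label: FatigueLabel | None = None
    discard_flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(self.swa) != len(self.ya) or self.swa.fs != self.ya.fs:
            raise ValueError("SWA and YA channels must share length and fs")
        bad = set(self.discard_flags) - VALID_FLAGS
        if bad:
            raise ValueError(f"unknown discard flags: {sorted(bad)}")

    @property
    def duration_s(self) -> float:
        return self.swa.duration_s


def read_recording(path, fs: float) -> tuple[TimeSeriesSignal, TimeSeriesSignal]:
    """Read a two-channel recording CSV into (SWA, YA) signals.

    The CSV must carry the header ``time_s,swa_deg,ya_deg``. The time column
    is advisory: it is checked for uniformity against ``1/fs`` (within
    ``TIME_UNIFORMITY_TOL``) but the supplied ``fs`` is authoritative, which
    avoids float-accumulation drift defining the sample count.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    for col in SIGNAL_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    if len(df) == 0:
        raise FormatError(f"no data rows in {path}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise FormatError("time_s column must be strictly increasing")
        if np.max(np.abs(dt - 1.0 / fs)) > TIME_UNIFORMITY_TOL:
            raise FormatError(
                f"time_s step deviates from 1/fs={1.0 / fs:g} s by more than "
                f"{TIME_UNIFORMITY_TOL:g} s"
            )
    swa = TimeSeriesSignal(df["swa_deg"].to_numpy(dtype=float), fs, "SWA")
    ya = TimeSeriesSignal(df["ya_deg"].to_numpy(dtype=float), fs, "YA")
    return swa, ya


def write_recording(path, swa: TimeSeriesSignal, ya: TimeSeriesSignal) -> None:
    """Write a two-channel recording to CSV (inverse of :func:`read_recording`)."""
    if len(swa) != len(ya) or swa.fs != ya.fs:
        raise ValueError("channels must share length and fs")
    t = np.arange(len(swa)) / swa.fs
    df = pd.DataFrame({"time_s": t, "swa_deg": swa.values, "ya_deg": ya.values})
    # default float repr is the shortest round-tripping form; no float_format
    df.to_csv(path, index=False)


def segment_recording(
    swa: TimeSeriesSignal,
    ya: TimeSeriesSignal,
    sample_s: float = 60.0,
) -> list[DriveSample]:
    """Cut a recording into fixed-length samples in chronological order.

    A trailing partial segment is dropped, not padded: fixed-length samples
    are the unit of expert evaluation. A recording shorter than one sample
    yields an empty list.
    """
    if len(swa) != len(ya) or swa.fs != ya.fs:
        raise ValueError("channels must share length and fs")
    if not sample_s > 0:
        raise ValueError("sample_s must be positive")
    n_per = int(round(sample_s * swa.fs))
    n_samples = len(swa) // n_per
    out = []
    for k in range(n_samples):
        sl = slice(k * n_per, (k + 1) * n_per)
        out.append(
            DriveSample(
                swa=replace(swa, values=swa.values[sl]),
                ya=replace(ya, values=ya.values[sl]),
                start_time=k * n_per / swa.fs,
            )
        )
    return out


def filter_samples(samples: list[DriveSample]) -> list[DriveSample]:
    """Drop samples carrying any discard flag (curved road, lane shift, no consensus)."""
    kept = [s for s in samples if not s.discard_flags]
    removed = len(samples) - len(kept)
    if removed:
        logger.info("filter_samples: discarded %d of %d samples", removed, len(samples))
    return kept


def read_labels(path) -> pd.DataFrame:
    """Read a label/metadata CSV.

    Schema: ``sample_index, expert1, expert2, expert3, negotiated, flags``
    with ``negotiated`` optional (blank when no negotiation happened) and
    ``flags`` a semicolon-separated list.
    """
    df = pd.read_csv(path)
    required = ("sample_index", "expert1", "expert2", "expert3")
    for col in required:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    if "negotiated" not in df.columns:
        df["negotiated"] = np.nan
    if "flags" not in df.columns:
        df["flags"] = ""
    df["flags"] = df["flags"].fillna("")
    return df


def write_labels(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def parse_flags(raw: str) -> set[str]:
    """Parse a semicolon-separated flag field into a validated set."""
    flags = {f.strip() for f in str(raw).split(";") if f.strip()}
    bad = flags - VALID_FLAGS
    if bad:
        raise FormatError(f"unknown discard flags: {sorted(bad)}")
    return flags
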