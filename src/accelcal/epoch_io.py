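"""Read, validate, reintegrate, and write epoch-level accelerometer count series.

Actigraph-era devices accumulate vertical-axis activity "counts" into fixed
epochs (here 10 s or 60 s). ActiLife exports either a CSV with a ~10-line
metadata header (serial number, start time/date, epoch period) followed by
count rows, or a headerless single-column file. This module models the epoch
stream as a gap-free sequence anchored at a start time: per-row timestamps are
reconstructed as ``start_time + index * epoch_length``.

Only the vertical axis is modeled; extra columns (additional axes, steps,
inclinometer) are ignored with a warning.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EpochSeries",
    "CsvDialect",
    "read_epoch_csv",
    "write_epoch_csv",
    "reintegrate",
    "steady_state_counts",
]

logger = logging.getLogger(__name__)

PLACEMENTS = ("right_hip", "left_hip")


class EpochParseError(ValueError):
    """Malformed epoch file content (carries the offending line number)."""


class EpochConfigError(ValueError):
    """Dialect configuration contradicts file metadata."""


def _validate_epoch_length(epoch_length: int) -> int:
    epoch_length = int(epoch_length)
    if epoch_length <= 0:
        raise ValueError(f"epoch_length must be positive, got {epoch_length}")
    if not (60 % epoch_length == 0 or epoch_length % 60 == 0):
        raise ValueError(
            f"epoch_length must divide 60 or be a multiple of 60, got {epoch_length}"
        )
    return epoch_length


@dataclass(frozen=True)
class EpochSeries:
    """A gap-free sequence of non-negative vertical-axis counts for one subject.

    Parameters
    ----------
    subject_id : str
        Opaque subject identifier.
    placement : str
        Accelerometer placement, ``"right_hip"`` or ``"left_hip"``.
    epoch_length : int
        Epoch duration in seconds; must divide 60 or be a multiple of 60.
    start_time : pandas.Timestamp
        Timestamp of the first epoch's start.
    counts : numpy.ndarray
        Integer counts per epoch, all >= 0. Missing epochs are disallowed;
        gaps must be filled (e.g. with zeros for documented non-wear) before
        construction.
    """

    subject_id: str
    placement: str
    epoch_length: int
    start_time: pd.Timestamp
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "epoch_length", _validate_epoch_length(self.epoch_length))
        if self.placement not in PLACEMENTS:
            raise ValueError(f"placement must be one of {PLACEMENTS}, got {self.placement!r}")
        counts = np.asarray(self.counts)
        if counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if counts.size and not np.issubdtype(counts.dtype, np.number):
            raise ValueError("counts must be numeric")
        if counts.size and np.any(counts < 0):
            bad = int(np.argmax(counts < 0))
            raise ValueError(f"negative count at epoch {bad}: {counts[bad]}")
        object.__setattr__(self, "counts", counts.astype(np.int64))
        object.__setattr__(self, "start_time", pd.Timestamp(self.start_time))

    def __len__(self) -> int:
        return self.counts.size

    @property
    def duration_seconds(self) -> int:
        return len(self) * self.epoch_length

    def timestamps(self) -> pd.DatetimeIndex:
        """Reconstructed per-epoch start timestamps."""
        return self.start_time + pd.to_timedelta(
            np.arange(len(self)) * self.epoch_length, unit="s"
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy representation: subject_id, placement, epoch_index, timestamp, counts."""
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "placement": self.placement,
                "epoch_index": np.arange(len(self)),
                "timestamp": self.timestamps(),
                "counts": self.counts,
            }
        )


@dataclass(frozen=True)
class CsvDialect:
    """How to interpret an epoch CSV file.

    ``header`` is ``"actigraph"`` (10-line ActiLife-style metadata header) or
    ``"none"`` (bare rows of counts). Values parsed from an Actigraph header
    override the dialect defaults; an explicit contradiction between the two
    (e.g. the header declares 10-s epochs while the dialect forces 60 s) is a
    configuration error rather than a silent override.
    """

    header: str = "none"
    epoch_length: int | None = None
    start_time: str | pd.Timestamp | None = None
    subject_id: str = "unknown"
    placement: str = "right_hip"
    strict_epoch: bool = False  # error if header epoch differs from dialect epoch

    def __post_init__(self) -> None:
        if self.header not in ("actigraph", "none"):
            raise ValueError(f"unknown header convention {self.header!r}")


_EPOCH_RE = re.compile(r"epoch\s+period.*?(\d{1,2}):(\d{2}):(\d{2})", re.I)
_START_TIME_RE = re.compile(r"start\s+time\s*[,:]?\s*(\d{1,2}:\d{2}:\d{2})", re.I)
_START_DATE_RE = re.compile(r"start\s+date\s*[,:]?\s*([0-9/.\-]+)", re.I)


def _parse_actigraph_header(lines: list[str]) -> tuple[dict, int]:
    """Extract epoch length / start datetime from an ActiLife metadata header.

    Returns the parsed metadata and the number of header lines consumed. The
    header is delimited by a final dashed line, mirroring ActiLife exports.
    """
    meta: dict = {}
    end = None
    for i, line in enumerate(lines[:15]):
        if m := _EPOCH_RE.search(line):
            h, mnt, s = (int(g) for g in m.groups())
            meta["epoch_length"] = h * 3600 + mnt * 60 + s
        if m := _START_TIME_RE.search(line):
            meta["start_clock"] = m.group(1)
        if m := _START_DATE_RE.search(line):
            meta["start_date"] = m.group(1)
        if i > 0 and line.strip().startswith("---"):
            end = i + 1
            break
    if end is None:
        raise EpochParseError("Actigraph header delimiter ('---' line) not found")
    if "start_clock" in meta and "start_date" in meta:
        meta["start_time"] = pd.Timestamp(f"{meta.pop('start_date')} {meta.pop('start_clock')}")
    return meta, end


def read_epoch_csv(path: str | Path, dialect: CsvDialect) -> EpochSeries:
    """Read one epoch-count CSV file into a validated :class:`EpochSeries`.

    Header metadata (start time, epoch length) overrides dialect defaults when
    present; a header epoch that contradicts a ``strict_epoch`` dialect raises
    :class:`EpochConfigError`. Multi-column rows use the first column as the
    vertical axis and warn about the rest.
    """
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    if not any(line.strip() for line in lines):
        raise EpochParseError(f"{path}: empty epoch file")

    epoch_length = dialect.epoch_length
    start_time = dialect.start_time
    body_start = 0
    if dialect.header == "actigraph":
        meta, body_start = _parse_actigraph_header(lines)
        if "epoch_length" in meta:
            if (
                dialect.strict_epoch
                and epoch_length is not None
                and meta["epoch_length"] != epoch_length
            ):
                raise EpochConfigError(
                    f"{path}: header declares {meta['epoch_length']}-s epochs but "
                    f"dialect forces {epoch_length} s"
                )
            epoch_length = meta["epoch_length"]
        if "start_time" in meta:
            start_time = meta["start_time"]

    if epoch_length is None:
        raise EpochConfigError(f"{path}: epoch length absent from both header and dialect")
    if start_time is None:
        start_time = pd.Timestamp("2000-01-01 00:00:00")

    counts = []
    warned_extra = False
    for lineno, line in enumerate(lines[body_start:], start=body_start + 1):
        line = line.strip()
        if not line:
            continue
        fields = line.split(",")
        if len(fields) > 1 and not warned_extra:
            warnings.warn(
                f"{path}: only the vertical axis (first column) is used; "
                f"{len(fields) - 1} extra column(s) ignored",
                stacklevel=2,
            )
            warned_extra = True
        try:
            value = int(float(fields[0]))
        except ValueError as exc:
            raise EpochParseError(f"{path}: malformed row at line {lineno}: {line!r}") from exc
        if value < 0:
            raise ValueError(f"{path}: negative count at line {lineno}: {value}")
        counts.append(value)
    if not counts:
        raise EpochParseError(f"{path}: no count rows found")

    return EpochSeries(
        subject_id=dialect.subject_id,
        placement=dialect.placement,
        epoch_length=int(epoch_length),
        start_time=pd.Timestamp(start_time),
        counts=np.asarray(counts, dtype=np.int64),
    )


def write_epoch_csv(series: EpochSeries, path: str | Path) -> None:
    """Write the tidy CSV form (subject_id, placement, epoch_index, timestamp, counts)."""
    series.to_frame().to_csv(path, index=False)


def read_tidy_epoch_csv(path: str | Path) -> EpochSeries:
    """Read back a tidy CSV written by :func:`write_epoch_csv`."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    if df.empty:
        raise EpochParseError(f"{path}: empty tidy epoch file")
    ts = pd.DatetimeIndex(df["timestamp"])
    if len(df) > 1:
        steps = np.diff(ts.asi8) / 1e9
        if not np.allclose(steps, steps[0]):
            raise EpochParseError(f"{path}: non-uniform timestamps")
        epoch_length = int(round(steps[0]))
    else:
        epoch_length = 60
    return EpochSeries(
        subject_id=str(df["subject_id"].iloc[0]),
        placement=str(df["placement"].iloc[0]),
        epoch_length=epoch_length,
        start_time=ts[0],
        counts=df["counts"].to_numpy(),
    )


def reintegrate(series: EpochSeries, target_epoch: int) -> EpochSeries:
    """Re-integrate counts into longer epochs by summing consecutive blocks.

    ``target_epoch`` must be a positive multiple of the source epoch length.
    A trailing partial block is dropped (and logged), never zero-padded:
    padding would fabricate wear time. Total counts over complete blocks are
    conserved.
    """
    target_epoch = int(target_epoch)
    if target_epoch <= 0 or target_epoch % series.epoch_length != 0:
        raise ValueError(
            f"target epoch {target_epoch} s is not a positive multiple of the "
            f"source epoch {series.epoch_length} s"
        )
    factor = target_epoch // series.epoch_length
    if factor == 1:
        return series
    n_blocks, remainder = divmod(len(series), factor)
    if remainder:
        logger.info(
            "reintegrate: dropping trailing partial block of %d epoch(s) "
            "(subject %s)", remainder, series.subject_id,
        )
    summed = series.counts[: n_blocks * factor].reshape(n_blocks, factor).sum(axis=1)
    return replace(series, epoch_length=target_epoch, counts=summed)


def steady_state_counts(
    series: EpochSeries, window_start: float, window_end: float
) -> float:
    """Mean counts/min over a time window (offsets in seconds from series start).

    Used to reduce a calibration stage to a single intensity value: the last
    two minutes of each treadmill stage are averaged into counts/min. The
    window must align with epoch boundaries and lie inside the series.
    """
    if window_end <= window_start:
        raise ValueError("window_end must exceed window_start")
    for name, offset in (("window_start", window_start), ("window_end", window_end)):
        if offset % series.epoch_length != 0:
            raise ValueError(f"{name}={offset} s does not align with {series.epoch_length}-s epochs")
    i0 = int(window_start // series.epoch_length)
    i1 = int(window_end // series.epoch_length)
    if i0 < 0 or i1 > len(series):
        raise IndexError(
            f"window [{window_start}, {window_end}) s outside series of "
            f"{series.duration_seconds} s"
        )
    total = float(series.counts[i0:i1].sum())
    return total / ((window_end - window_start) / 60.0)
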