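"""Reading raw EEG CSV exports into in-memory recordings.

Consumer EEG headsets export one CSV row per sample with a column per
channel (10–20 labels), a sample counter, and a marker column; the
researcher presses key "1" to mark task onset.  Raw device units are
unsigned integers around a mid-rail voltage, so conversion to µV is an
affine map described by an explicit :class:`CsvDialect`.

Conventions used throughout the package: sample indices are 0-based and
intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CsvDialect",
    "DEFAULT_DIALECT",
    "Recording",
    "MontageSelection",
    "DEFAULT_MONTAGE",
    "hemisphere_of",
    "read_recording",
    "write_recording",
    "locate_task_onset",
    "trim_to_task",
]


@dataclass(frozen=True)
class CsvDialect:
    """How a raw CSV export maps onto channels and µV.

    ``scale``/``offset`` define the affine raw→µV conversion
    ``uv = (raw - offset) * scale``.  The default dialect assumes data
    already in µV (identity conversion) with a column named ``MARKER``.
    ``column_map`` renames CSV headers to canonical 10–20 labels.
    """

    column_map: dict[str, str] = field(default_factory=dict)
    scale: float = 1.0
    offset: float = 0.0
    marker_column: str = "MARKER"
    sample_column: str | None = "COUNTER"
    delimiter: str = ","

    def to_uv(self, raw: np.ndarray) -> np.ndarray:
        return (np.asarray(raw, dtype=float) - self.offset) * self.scale

    def from_uv(self, uv: np.ndarray) -> np.ndarray:
        return np.asarray(uv, dtype=float) / self.scale + self.offset


DEFAULT_DIALECT = CsvDialect()


def hemisphere_of(label: str) -> str:
    """Hemisphere of a 10–20 label: odd-numbered left, even-numbered right.

    Midline labels (ending in ``z``) and reference sensors are rejected —
    the laterality analysis has no use for them.
    """
    tail = label.strip()[-1]
    if not tail.isdigit():
        raise ValueError(f"channel {label!r} has no 10-20 hemisphere number")
    return "left" if int(tail) % 2 == 1 else "right"


@dataclass(frozen=True)
class MontageSelection:
    """The electrode subset used for the laterality analysis."""

    left_electrodes: tuple[str, ...] = ("F7", "F3")
    right_electrodes: tuple[str, ...] = ("F4", "F8")

    def __post_init__(self):
        if len(self.left_electrodes) != len(self.right_electrodes):
            raise ValueError("left and right electrode sets must have equal size")
        overlap = set(self.left_electrodes) & set(self.right_electrodes)
        if overlap:
            raise ValueError(f"electrodes on both sides: {sorted(overlap)}")
        for lab in self.left_electrodes:
            if hemisphere_of(lab) != "left":
                raise ValueError(f"{lab} is not a left-hemisphere (odd) label")
        for lab in self.right_electrodes:
            if hemisphere_of(lab) != "right":
                raise ValueError(f"{lab} is not a right-hemisphere (even) label")

    @property
    def pairs(self) -> tuple[tuple[str, str], ...]:
        return tuple(zip(self.left_electrodes, self.right_electrodes))

    @property
    def electrodes(self) -> tuple[str, ...]:
        return self.left_electrodes + self.right_electrodes


DEFAULT_MONTAGE = MontageSelection()


@dataclass
class Recording:
    """A multichannel recording in µV.

    ``samples`` is a channels × time float array; ``markers`` is a sparse
    list of ``(sample_index, token)`` pairs from the device marker stream.
    """

    samples: np.ndarray
    fs: int
    channel_labels: tuple[str, ...]
    markers: list[tuple[int, str]] = field(default_factory=list)
    task_onset_sample: int | None = None

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValueError("samples rows must match channel_labels")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> Fraction:
        return Fraction(self.n_samples, self.fs)

    def channel(self, label: str) -> np.ndarray:
        try:
            i = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None
        return self.samples[i]

    def select(self, labels) -> "Recording":
        """A view-copy restricted to ``labels``, order preserved as given."""
        idx = [self.channel_labels.index(lab) for lab in labels]
        return replace(
            self, samples=self.samples[idx].copy(), channel_labels=tuple(labels)
        )


def _marker_token(value) -> str | None:
    """Normalize a marker cell; empty / zero / NaN cells carry no marker."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    tok = str(value).strip()
    if tok.endswith(".0"):
        tok = tok[:-2]
    if tok in ("", "0", "nan"):
        return None
    return tok


def read_recording(
    path,
    dialect: CsvDialect = DEFAULT_DIALECT,
    fs: int = 128,
    allowed_fs: tuple[int, ...] = (128, 256),
    require_channels: tuple[str, ...] | None = None,
) -> Recording:
    """Read a raw CSV export and convert it to a µV :class:`Recording`.

    ``require_channels`` defaults to the standard frontal montage
    (F7, F3, F4, F8); a missing required channel or marker column is an
    error, other absent channels are tolerated.
    """
    if fs not in allowed_fs:
        raise ValueError(f"sampling rate {fs} Hz not in allowed set {allowed_fs}")
    if require_channels is None:
        require_channels = DEFAULT_MONTAGE.electrodes

    df = pd.read_csv(path, sep=dialect.delimiter, dtype=str)
    if df.empty:
        raise ValueError(f"empty recording: {path} has no sample rows")
    df = df.rename(columns=dialect.column_map)

    if dialect.marker_column not in df.columns:
        raise ValueError(
            f"required marker column {dialect.marker_column!r} missing from {path}"
        )
    missing = [c for c in require_channels if c not in df.columns]
    if missing:
        raise ValueError(f"required channel(s) missing from {path}: {missing}")

    skip = {dialect.marker_column}
    if dialect.sample_column is not None:
        skip.add(dialect.sample_column)
    labels = [c for c in df.columns if c not in skip]

    raw = np.empty((len(labels), len(df)), dtype=float)
    for i, lab in enumerate(labels):
        col = pd.to_numeric(df[lab], errors="coerce")
        bad = col.isna() & df[lab].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-numeric value {df[lab].iloc[row]!r} in channel {lab} "
                f"at data row {row}"
            )
        raw[i] = col.to_numpy(dtype=float)

    markers = []
    for idx, cell in enumerate(df[dialect.marker_column].tolist()):
        tok = _marker_token(cell)
        if tok is not None:
            markers.append((idx, tok))

    logger.info("read %d samples x %d channels at %d Hz from %s",
                raw.shape[1], raw.shape[0], fs, path)
    return Recording(
        samples=dialect.to_uv(raw),
        fs=fs,
        channel_labels=tuple(labels),
        markers=markers,
    )


def write_recording(rec: Recording, path, dialect: CsvDialect = DEFAULT_DIALECT):
    """Write a recording back to CSV in the given dialect (inverse of read)."""
    data = {}
    if dialect.sample_column is not None:
        data[dialect.sample_column] = np.arange(rec.n_samples)
    for i, lab in enumerate(rec.channel_labels):
        data[lab] = dialect.from_uv(rec.samples[i])
    marker_col = np.zeros(rec.n_samples, dtype=object)
    marker_col[:] = "0"
    for idx, tok in rec.markers:
        marker_col[idx] = tok
    data[dialect.marker_column] = marker_col
    pd.DataFrame(data).to_csv(
        path, sep=dialect.delimiter, index=False, float_format="%.6f"
    )
    return path


def locate_task_onset(rec: Recording, marker_value: str = "1") -> int:
    """Sample index of the first occurrence of the task-onset marker.

    The protocol presses the key once; if the stream holds several
    occurrences the first wins and a warning is logged.
    """
    if not rec.markers:
        raise ValueError(
            "recording has no markers; supply the task onset manually "
            "(analyze --onset-sample N)"
        )
    hits = [idx for idx, tok in rec.markers if tok == marker_value]
    if not hits:
        raise ValueError(
            f"marker {marker_value!r} not found; supply the task onset manually "
            "(analyze --onset-sample N)"
        )
    if len(hits) > 1:
        logger.warning("marker %r occurs %d times; using the first at sample %d",
                       marker_value, len(hits), hits[0])
    rec.task_onset_sample = hits[0]
    return hits[0]


def trim_to_task(rec: Recording, duration_s=240) -> Recording:
    """Cut the recording to the task section starting at the onset marker.

    Keeps ``min(duration_s × fs, remaining)`` samples; a recording shorter
    than the requested duration is kept whole with a warning.
    """
    if rec.task_onset_sample is None:
        raise ValueError("task onset not set; call locate_task_onset first")
    n_want = int(Fraction(duration_s) * rec.fs)
    if n_want <= 0:
        raise ValueError("requested task duration must be positive")
    start = rec.task_onset_sample
    avail = rec.n_samples - start
    if avail <= 0:
        raise ValueError("task onset lies at or beyond the end of the recording")
    n = min(n_want, avail)
    if n < n_want:
        logger.warning(
            "recording ends %.1f s into the %.1f s task; keeping what exists",
            n / rec.fs, float(Fraction(duration_s)),
        )
    markers = [(i - start, tok) for i, tok in rec.markers if start <= i < start + n]
    return Recording(
        samples=rec.samples[:, start:start + n].copy(),
        fs=rec.fs,
        channel_labels=rec.channel_labels,
        markers=markers,
        task_onset_sample=0,
    )
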