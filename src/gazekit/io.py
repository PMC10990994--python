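"""Gaze-recording containers and file readers/writers.

Two estimator-output dialects are supported:

* *model-based* — a labeled CSV with per-frame gaze angles in degrees and a
  validity column (the output format of model-based estimators that fit an
  eyeball model to facial landmarks);
* *appearance-based* — an unlabeled 14-column CSV whose 2-D gaze estimate
  lives in normalized screen coordinates, with frame timestamps in a sidecar
  text file (one timestamp per line, seconds).

All recordings are converted to one canonical sign convention at load time:
looking left-to-right increases x, looking down-to-up increases y.  Raw
model-based output uses the opposite sign on both axes, so both are flipped.

Manual gaze coding is a CSV of contiguous dwells ``label,start_s,end_s``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, FormatError

AOI_LABELS = ("left_lamp", "parent", "right_lamp", "none")

#: default column names of the model-based dialect (overridable per file)
MODEL_BASED_COLUMNS = {
    "timestamp": "timestamp",
    "valid": "success",
    "x": "gaze_angle_x",
    "y": "gaze_angle_y",
}

APPEARANCE_N_COLUMNS = 14


@dataclass(frozen=True)
class GazeSample:
    """A single gaze estimate.

    ``x``/``y`` are degrees for ``source='angle_degrees'`` recordings and
    dimensionless for ``source='normalized'``.  When ``valid`` is false the
    coordinates are treated as absent by every downstream statistic.
    """

    t: float
    x: float
    y: float
    valid: bool = True


@dataclass
class GazeRecording:
    """A timestamped gaze time series in the canonical sign convention.

    Internally array-backed; ``samples`` offers a per-sample view.

    Parameters
    ----------
    t, x, y : array-like, float
        Timestamps (seconds from recording start) and gaze coordinates.
    valid : array-like, bool
        Per-sample validity.  Invalid samples count toward data loss and are
        excluded from all statistics.
    nominal_rate : float
        Nominal sampling rate in Hz.
    source : {'angle_degrees', 'normalized'}
        Unit of the gaze coordinates.
    meta : dict
        Free-form metadata (participant id, condition, point index, ...).
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    nominal_rate: float
    source: str = "angle_degrees"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.t) == len(self.x) == len(self.y) == len(self.valid)):
            raise DataError("t, x, y, valid must have equal length")
        if self.source not in ("angle_degrees", "normalized"):
            raise ConfigError(f"unknown source {self.source!r}")
        if len(self.t):
            if self.t[0] < 0:
                raise DataError("timestamps must be non-negative")
            if np.any(np.diff(self.t) <= 0):
                raise DataError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def samples(self) -> list[GazeSample]:
        return [
            GazeSample(float(t), float(x), float(y), bool(v))
            for t, x, y, v in zip(self.t, self.x, self.y, self.valid)
        ]

    @property
    def duration(self) -> float:
        """Session span assuming each frame lasts one nominal interval."""
        if not len(self.t):
            return 0.0
        return float(self.t[-1]) + 1.0 / self.nominal_rate

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.t, "x": self.x, "y": self.y, "valid": self.valid}
        )


@dataclass
class ManualDwellFile:
    """Manually coded dwells: contiguous, ordered ``(label, start, end)``.

    The coding partitions the coded span: each dwell ends exactly where the
    next begins, and every moment is assigned to one of the four AOI labels
    (the three physical AOIs plus the residual ``none``).
    """

    entries: list[tuple[str, float, float]]

    def __post_init__(self) -> None:
        for label, start, end in self.entries:
            if label not in AOI_LABELS:
                raise DataError(f"unknown AOI label {label!r}")
            if not end > start:
                raise DataError(f"dwell on {label!r} has end {end} <= start {start}")
        for (la, sa, ea), (lb, sb, eb) in zip(self.entries, self.entries[1:]):
            if not np.isclose(ea, sb, rtol=0.0, atol=1e-9):
                kind = "overlap" if sb < ea else "gap"
                raise DataError(
                    f"{kind} between dwell ({la}, {sa}, {ea}) and ({lb}, {sb}, {eb})"
                )

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def span(self) -> tuple[float, float]:
        return (self.entries[0][1], self.entries[-1][2])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["aoi", "start_s", "end_s"])


def _flip_sign(values: np.ndarray) -> np.ndarray:
    """Raw-to-canonical sign flip.  Involution: applying twice is identity."""
    return -np.asarray(values, dtype=float)


def read_model_based(
    path,
    column_map: Mapping[str, str] | None = None,
    nominal_rate: float = 60.0,
) -> GazeRecording:
    """Read a labeled model-based estimator CSV as a :class:`GazeRecording`.

    Raw model-based output runs positive-to-negative for left-to-right looks
    and negative-to-positive for top-to-bottom looks; both axes are flipped so
    that rightward and upward looks are positive.  Rows whose validity column
    is 0 or whose gaze fields are empty/non-numeric become invalid samples
    (the rows themselves are never dropped).
    """
    cols = dict(MODEL_BASED_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, skipinitialspace=True, float_precision="round_trip")
    df.columns = [c.strip() for c in df.columns]
    missing = [name for name in cols.values() if name not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")

    t = pd.to_numeric(df[cols["timestamp"]], errors="coerce").to_numpy()
    if np.any(~np.isfinite(t)) or (len(t) > 1 and np.any(np.diff(t) <= 0)):
        raise DataError(f"non-monotonic or unparsable timestamps in {path}")
    x_raw = pd.to_numeric(df[cols["x"]], errors="coerce").to_numpy()
    y_raw = pd.to_numeric(df[cols["y"]], errors="coerce").to_numpy()
    ok = pd.to_numeric(df[cols["valid"]], errors="coerce").fillna(0).to_numpy()
    valid = (ok != 0) & np.isfinite(x_raw) & np.isfinite(y_raw)

    return GazeRecording(
        t=t - t[0] if len(t) else t,
        x=_flip_sign(x_raw),
        y=_flip_sign(y_raw),
        valid=valid,
        nominal_rate=nominal_rate,
        source="angle_degrees",
        meta={"path": str(path)},
    )


def read_appearance_based(
    path,
    column_spec: tuple[int, int] = (12, 13),
    timestamp_path=None,
    nominal_rate: float = 60.0,
) -> GazeRecording:
    """Read an unlabeled 14-column appearance-based estimator CSV.

    ``column_spec`` gives the zero-based indices of the two columns holding
    the normalized 2-D gaze estimate (the 14 columns carry no header, so the
    mapping is configuration).  Timestamps come from ``timestamp_path`` (one
    value per line, seconds) when given, otherwise they are synthesized from
    ``nominal_rate``.
    """
    cx, cy = column_spec
    if not (0 <= cx < APPEARANCE_N_COLUMNS and 0 <= cy < APPEARANCE_N_COLUMNS):
        raise ConfigError(
            f"column_spec {column_spec} out of range for "
            f"{APPEARANCE_N_COLUMNS}-column files"
        )
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split(",")
            if len(fields) != APPEARANCE_N_COLUMNS:
                raise FormatError(
                    f"row {i} has {len(fields)} columns, "
                    f"expected {APPEARANCE_N_COLUMNS}"
                )
            rows.append(fields)
    n = len(rows)
    x = np.array([float(r[cx]) if r[cx] != "" else np.nan for r in rows])
    y = np.array([float(r[cy]) if r[cy] != "" else np.nan for r in rows])
    if timestamp_path is not None:
        t = np.loadtxt(timestamp_path, dtype=float, ndmin=1)
        if len(t) != n:
            raise DataError(
                f"timestamp file has {len(t)} entries for {n} data rows"
            )
        t = t - t[0]
        if np.any(np.diff(t) <= 0):
            raise DataError(f"non-monotonic timestamps in {timestamp_path}")
    else:
        t = np.arange(n) / nominal_rate
    valid = np.isfinite(x) & np.isfinite(y)
    return GazeRecording(
        t=t,
        x=x,
        y=y,
        valid=valid,
        nominal_rate=nominal_rate,
        source="normalized",
        meta={"path": str(path)},
    )


def read_manual_coding(path) -> ManualDwellFile:
    """Read a manual-coding dwell CSV (``label,start_s,end_s`` with header)."""
    df = pd.read_csv(path, skipinitialspace=True)
    required = ["aoi", "start_s", "end_s"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    entries = [
        (str(r.aoi), float(r.start_s), float(r.end_s))
        for r in df.itertuples(index=False)
    ]
    for (la, sa, _), (lb, sb, _) in zip(entries, entries[1:]):
        if sb < sa:
            raise DataError(
                f"dwell entries out of order: ({la}, start {sa}) before "
                f"({lb}, start {sb})"
            )
    return ManualDwellFile(entries)


def write_manual_coding(dwells: ManualDwellFile, path) -> None:
    dwells.to_frame().to_csv(path, index=False)


def write_recording(rec: GazeRecording, path) -> None:
    """Write a recording in the labeled (model-based) dialect.

    The canonical-to-raw sign flip is applied on write so that reading the
    file back through :func:`read_model_based` reproduces ``t, x, y, valid``
    exactly (invalid samples get empty gaze fields, preserving the flag).
    """
    if not len(rec):
        raise DataError("refusing to write an empty recording")
    x_raw = _flip_sign(rec.x)
    y_raw = _flip_sign(rec.y)
    df = pd.DataFrame(
        {
            "timestamp": rec.t,
            "success": rec.valid.astype(int),
            "gaze_angle_x": np.where(rec.valid, x_raw, np.nan),
            "gaze_angle_y": np.where(rec.valid, y_raw, np.nan),
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def synthesize_timestamps(n: int, rate: float) -> np.ndarray:
    """Regular frame timestamps 0, 1/rate, ..., (n-1)/rate."""
    if rate <= 0:
        raise ConfigError("rate must be positive")
    return np.arange(n) / rate
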