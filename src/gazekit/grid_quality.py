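"""Data-quality statistics for 9-point fixation-grid sessions.

A grid session is one short recording per stimulus point of an ``n_cols x
n_rows`` grid shown on a screen at a known viewing distance.  Because the
absolute origin of a calibration-free gaze estimator is unknown, quality is
assessed through *relative* quantities:

* **scale ratio** (accuracy of scale) — the median angular separation of
  adjacent fixation medians divided by the physical angular separation of
  adjacent grid points; 1 means faithful scale, <1 under-estimation,
  >1 over-estimation;
* **precision ratio** — the median within-fixation spread (standard
  deviation) divided by the median separation between adjacent fixations;
  near 0 means fixations on neighbouring points are distinguishable;
* **data loss** — the percentage of samples with a missing gaze estimate;
* **blink flagging** — intervals of high vertical gaze velocity, the
  signature that eye closure leaves in estimators that keep reporting a
  (spurious) gaze direction while the eyes are shut.

Both ratios are unit-free, so recordings in degrees and in normalized screen
coordinates can be compared on the same footing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DataError
from .io import GazeRecording

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GridSpec:
    """Physical stimulus-grid and viewing geometry.

    Defaults match a 3 x 3 grid with 18.6 cm horizontal and 11.6 cm vertical
    spacing viewed from 95 cm, i.e. adjacent points separated by roughly 11
    and 7 degrees of visual angle.
    """

    n_cols: int = 3
    n_rows: int = 3
    dx_cm: float = 18.6
    dy_cm: float = 11.6
    screen_distance_cm: float = 95.0
    camera_distance_cm: float = 85.0  # metadata only

    def __post_init__(self) -> None:
        if min(self.dx_cm, self.dy_cm, self.screen_distance_cm) <= 0:
            raise ConfigError("grid distances must be positive")
        if self.n_cols < 2 or self.n_rows < 2:
            raise ConfigError("need at least a 2 x 2 grid for ratio statistics")

    @property
    def n_points(self) -> int:
        return self.n_cols * self.n_rows


def grid_angles(grid: GridSpec) -> tuple[float, float]:
    """Angular separation (degrees) of adjacent grid points per axis.

    Single arctangent of spacing over viewing distance, measured from screen
    centre; one value per axis (eccentricity-dependent per-pair differences
    are deliberately not modelled).
    """
    h = math.degrees(math.atan(grid.dx_cm / grid.screen_distance_cm))
    v = math.degrees(math.atan(grid.dy_cm / grid.screen_distance_cm))
    return h, v


def _adjacent_pairs(grid: GridSpec, axis: str) -> list[tuple[int, int]]:
    """Row-major index pairs of axis-adjacent grid points.

    axis='x': horizontally adjacent within-row pairs (6 on a 3x3 grid);
    axis='y': vertically adjacent within-column pairs.
    """
    if axis not in ("x", "y"):
        raise ConfigError(f"axis must be 'x' or 'y', got {axis!r}")
    pairs = []
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            i = r * grid.n_cols + c
            if axis == "x" and c + 1 < grid.n_cols:
                pairs.append((i, i + 1))
            if axis == "y" and r + 1 < grid.n_rows:
                pairs.append((i, i + grid.n_cols))
    return pairs


def fixation_medians(blocks: list[GazeRecording]) -> np.ndarray:
    """Per-block median gaze position over valid samples.

    Returns an ``(n_blocks, 2)`` array of (median_x, median_y); blocks with
    no valid samples get NaN and a warning (they are excluded downstream).
    """
    out = np.full((len(blocks), 2), np.nan)
    for i, rec in enumerate(blocks):
        v = rec.valid
        if not np.any(v):
            logger.warning("block %d has no valid samples; median undefined", i)
            continue
        out[i, 0] = np.median(rec.x[v])
        out[i, 1] = np.median(rec.y[v])
    return out


def _median_adjacent_separation(
    medians: np.ndarray, grid: GridSpec, axis: str
) -> float:
    col = 0 if axis == "x" else 1
    seps = []
    for i, j in _adjacent_pairs(grid, axis):
        a, b = medians[i, col], medians[j, col]
        if np.isfinite(a) and np.isfinite(b):
            seps.append(abs(b - a))
    if len(seps) < 2:
        raise DataError(
            f"fewer than 2 defined adjacent pairs on axis {axis!r}; "
            "cannot compute a separation median"
        )
    return float(np.median(seps))


def scale_ratio(medians: np.ndarray, grid: GridSpec, axis: str) -> float:
    """Estimated-to-physical angular separation of adjacent fixations.

    Median over axis-adjacent fixation-median differences, divided by the
    grid's angular separation on that axis.  Invariant to additive offsets;
    recovers a multiplicative gain exactly in the noise-free case.
    """
    h, v = grid_angles(grid)
    return _median_adjacent_separation(medians, grid, axis) / (h if axis == "x" else v)


def precision_ratio(blocks: list[GazeRecording], grid: GridSpec, axis: str) -> float:
    """Within-fixation spread over between-fixation separation.

    Numerator: median over blocks of the sample standard deviation of the
    gaze signal within a fixation.  Denominator: median separation between
    axis-adjacent fixation medians.  Jointly affine-invariant, hence
    comparable across degree-valued and normalized-coordinate estimates.
    """
    col = 0 if axis == "x" else 1
    spreads = []
    for i, rec in enumerate(blocks):
        sig = (rec.x if col == 0 else rec.y)[rec.valid]
        if len(sig) < 2:
            logger.warning("block %d has <2 valid samples; spread skipped", i)
            continue
        spreads.append(np.std(sig, ddof=1))
    if not spreads:
        raise DataError("no block with >=2 valid samples")
    medians = fixation_medians(blocks)
    sep = _median_adjacent_separation(medians, grid, axis)
    if sep == 0:
        raise DataError(
            "median adjacent fixation separation is zero; fixations are "
            "degenerate on this axis"
        )
    return float(np.median(spreads) / sep)


def data_loss(recs: GazeRecording | list[GazeRecording]) -> float:
    """Percentage of samples with a missing gaze estimate."""
    if isinstance(recs, GazeRecording):
        recs = [recs]
    n = sum(len(r) for r in recs)
    if n == 0:
        raise DataError("no samples")
    bad = sum(int(np.sum(~r.valid)) for r in recs)
    return 100.0 * bad / n


def flag_blinks(
    rec: GazeRecording,
    velocity_threshold: float = 150.0,
    min_separation: float = 0.1,
) -> list[tuple[float, float]]:
    """Candidate blink intervals from vertical gaze velocity.

    Eye closure makes estimators that track the eyelid-covered eye emit a
    sharp vertical transient, so intervals where ``|dy/dt|`` between
    consecutive valid samples exceeds ``velocity_threshold`` (signal units
    per second) are flagged; flags closer than ``min_separation`` seconds are
    merged into one interval.  A heuristic detector: the threshold default
    suits degree-scaled signals at 30-60 Hz and is fully configurable.
    """
    if velocity_threshold <= 0:
        raise ConfigError("velocity_threshold must be positive")
    t = rec.t[rec.valid]
    y = rec.y[rec.valid]
    if len(t) < 2:
        raise DataError("need at least 2 valid samples")
    vel = np.diff(y) / np.diff(t)
    hit = np.abs(vel) > velocity_threshold
    intervals: list[list[float]] = []
    for k in np.flatnonzero(hit):
        start, end = float(t[k]), float(t[k + 1])
        if intervals and start - intervals[-1][1] < min_separation:
            intervals[-1][1] = end
        else:
            intervals.append([start, end])
    return [(a, b) for a, b in intervals]


@dataclass
class GridQualityResults:
    """Quality report for one grid session; returned by ``GridQuality.fit``."""

    scale_ratio_x: float
    scale_ratio_y: float
    precision_ratio_x: float
    precision_ratio_y: float
    data_loss_pct: float
    per_fixation_medians: np.ndarray
    blink_intervals: list[list[tuple[float, float]]]
    grid: GridSpec
    meta: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "scale_ratio_x": self.scale_ratio_x,
            "scale_ratio_y": self.scale_ratio_y,
            "precision_ratio_x": self.precision_ratio_x,
            "precision_ratio_y": self.precision_ratio_y,
            "data_loss_pct": self.data_loss_pct,
            "n_blink_intervals": sum(len(b) for b in self.blink_intervals),
        }

    def summary(self) -> str:
        h, v = grid_angles(self.grid)
        lines = [
            "Grid session data-quality report",
            "=" * 40,
            f"grid separation        x: {h:6.2f} deg   y: {v:6.2f} deg",
            f"scale ratio            x: {self.scale_ratio_x:6.3f}       "
            f"y: {self.scale_ratio_y:6.3f}",
            f"precision ratio        x: {self.precision_ratio_x:6.3f}       "
            f"y: {self.precision_ratio_y:6.3f}",
            f"data loss              {self.data_loss_pct:6.2f} %",
            f"blink intervals flagged {sum(len(b) for b in self.blink_intervals):5d}",
        ]
        return "\n".join(lines)

    def plot_configuration(self, ax=None):
        """Scatter of all valid samples coloured by stimulus point.

        The visual counterpart of judging whether three rows and columns of
        fixation clusters can be seen.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for i, rec in enumerate(self.meta.get("blocks", [])):
            v = rec.valid
            ax.plot(rec.x[v], rec.y[v], ".", ms=2, alpha=0.5, label=f"point {i}")
        m = self.per_fixation_medians
        ax.plot(m[:, 0], m[:, 1], "k+", ms=12, mew=2)
        ax.set_xlabel("horizontal gaze")
        ax.set_ylabel("vertical gaze")
        return ax


class GridQuality:
    """Quality model for one grid session (one recording per stimulus point).

    Parameters
    ----------
    blocks : list of GazeRecording
        One recording per stimulus point in row-major order (top-left first).
    grid : GridSpec
        Physical grid geometry.

    ``fit`` computes the full quality report.
    """

    def __init__(self, blocks: list[GazeRecording], grid: GridSpec | None = None):
        grid = grid or GridSpec()
        if len(blocks) != grid.n_points:
            raise DataError(
                f"expected {grid.n_points} blocks for a "
                f"{grid.n_cols}x{grid.n_rows} grid, got {len(blocks)}"
            )
        self.blocks = blocks
        self.grid = grid

    def fit(
        self,
        blink_velocity_threshold: float = 150.0,
        blink_min_separation: float = 0.1,
    ) -> GridQualityResults:
        medians = fixation_medians(self.blocks)
        blinks = []
        for rec in self.blocks:
            try:
                blinks.append(
                    flag_blinks(rec, blink_velocity_threshold, blink_min_separation)
                )
            except DataError:
                blinks.append([])
        return GridQualityResults(
            scale_ratio_x=scale_ratio(medians, self.grid, "x"),
            scale_ratio_y=scale_ratio(medians, self.grid, "y"),
            precision_ratio_x=precision_ratio(self.blocks, self.grid, "x"),
            precision_ratio_y=precision_ratio(self.blocks, self.grid, "y"),
            data_loss_pct=data_loss(self.blocks),
            per_fixation_medians=medians,
            blink_intervals=blinks,
            grid=self.grid,
            meta={"blocks": self.blocks},
        )
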