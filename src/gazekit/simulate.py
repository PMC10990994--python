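"""Synthetic gaze sessions with known ground truth.

Two generators mirror the two evaluation settings:

* :func:`simulate_grid_session` — an adult fixating a 3 x 3 stimulus grid,
  3 s per point at 60 Hz.  The estimator is modelled as an affine distortion
  of the true gaze angle per axis (multiplicative *gain* for scale
  compression, additive *offset* for the unknown origin) plus Gaussian
  noise, vertical blink transients, and optional missing samples.
* :func:`simulate_infant_session` — a 90-s infant session at ~30 Hz whose
  gaze alternates among three horizontally separated areas of interest
  (left lamp, parent, right lamp) and off-AOI ("none") looking, following a
  semi-Markov process with log-normal dwell durations.

Both are deterministic given (config, seed): one seeded generator per call,
no global state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .grid_quality import GridSpec, grid_angles
from .io import GazeRecording, ManualDwellFile

logger = logging.getLogger(__name__)

AOIS = ("left_lamp", "parent", "right_lamp")


@dataclass(frozen=True)
class GridSimConfig:
    """Generative model of a grid-session recording.

    Gains default to the scale compression regime actually observed for
    model-based estimates (ratios roughly 0.3-0.7, worse vertically); noise,
    blink and missing-sample parameters are chosen to be realistic for a
    60-Hz webcam-based estimator and are documented as testability choices,
    not empirical claims.
    """

    gain_x: float = 0.5
    gain_y: float = 0.4
    offset_x: float = 2.0  # deg; unknown-origin shift
    offset_y: float = -1.0
    noise_sd_x: float = 0.5  # deg
    noise_sd_y: float = 0.5
    blink_rate: float = 12.0  # events / min
    blink_amplitude: float = -25.0  # deg, vertical transient while eyes shut
    blink_duration: float = 0.1  # s
    p_missing: float = 0.0  # no lost data is the empirically typical case
    rate: float = 60.0  # Hz
    dwell_per_point: float = 3.0  # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gain_x <= 0 or self.gain_y <= 0:
            raise ConfigError("gains must be positive")
        if self.noise_sd_x < 0 or self.noise_sd_y < 0:
            raise ConfigError("noise SDs must be non-negative")
        if not 0 <= self.p_missing <= 1:
            raise ConfigError("p_missing must be in [0, 1]")
        if self.rate <= 0 or self.dwell_per_point <= 0:
            raise ConfigError("rate and dwell_per_point must be positive")


def true_grid_angles(grid: GridSpec) -> np.ndarray:
    """True gaze angle (deg) of each grid point, row-major from top-left.

    Each grid step contributes one screen-centre angular separation
    (``arctan(spacing / distance)``), so adjacent points are separated by
    exactly that angle on both axes — the same convention the scale-ratio
    statistic divides by, which makes gain recovery exact in the noise-free
    limit.  Rightward and upward are positive.
    """
    h, v = grid_angles(grid)
    out = np.empty((grid.n_points, 2))
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            i = r * grid.n_cols + c
            out[i, 0] = (c - (grid.n_cols - 1) / 2) * h
            out[i, 1] = ((grid.n_rows - 1) / 2 - r) * v
    return out


def simulate_grid_session(
    grid: GridSpec | None = None, cfg: GridSimConfig | None = None
) -> tuple[list[GazeRecording], np.ndarray]:
    """Simulate one grid session: one recording per stimulus point.

    Returns ``(blocks, true_angles)`` where ``blocks`` holds one
    :class:`GazeRecording` per point in row-major presentation order and
    ``true_angles`` is the ``(n_points, 2)`` ground truth.

    Per point with true angle ``(tx, ty)`` the samples are
    ``x = gain_x * tx + offset_x + N(0, noise_sd_x^2)`` (same for y); blink
    events (Poisson at ``blink_rate``) add ``blink_amplitude`` to y for
    ``blink_duration`` while leaving the sample *valid* — estimators report
    gaze even with the eyes fully shut, so blinks and missingness are
    independent mechanisms.
    """
    grid = grid or GridSpec()
    cfg = cfg or GridSimConfig()
    rng = np.random.default_rng(cfg.seed)
    angles = true_grid_angles(grid)
    n = int(round(cfg.rate * cfg.dwell_per_point))
    dur = n / cfg.rate
    blocks = []
    for p in range(grid.n_points):
        t = np.arange(n) / cfg.rate
        x = cfg.gain_x * angles[p, 0] + cfg.offset_x
        y = cfg.gain_y * angles[p, 1] + cfg.offset_y
        x = x + rng.normal(0.0, cfg.noise_sd_x, n)
        y = y + rng.normal(0.0, cfg.noise_sd_y, n)
        blink_windows = []
        for _ in range(rng.poisson(cfg.blink_rate * dur / 60.0)):
            start = rng.uniform(0.0, max(dur - cfg.blink_duration, 0.0))
            inside = (t >= start) & (t < start + cfg.blink_duration)
            y[inside] += cfg.blink_amplitude
            blink_windows.append((start, start + cfg.blink_duration))
        valid = rng.random(n) >= cfg.p_missing
        x[~valid] = np.nan
        y[~valid] = np.nan
        blocks.append(
            GazeRecording(
                t=t,
                x=x,
                y=y,
                valid=valid,
                nominal_rate=cfg.rate,
                source="angle_degrees",
                meta={"point": p, "true_blinks": blink_windows},
            )
        )
    return blocks, angles


@dataclass(frozen=True)
class InfantSimConfig:
    """Generative model of a 90-s infant session with three AOIs.

    Looking alternates among the three AOIs and ``none`` via a semi-Markov
    chain (no self-transitions) with log-normal dwell durations truncated
    below at ``min_dwell``.  The rotating lamps are the engaging stimuli, so
    they carry the largest transition weights.  Horizontal gaze during a
    dwell on AOI ``a`` is ``N(aoi_means[a], noise_sd^2)``.  Off-AOI ("none")
    looking is not a structureless wash: infants fixate idiosyncratic
    distractors (the table edge, the door, their own hands), so each session
    draws ``n_distractors`` off-AOI directions beyond the lamps (offset from
    the outer AOI means by a uniform draw over ``distractor_offset_range``)
    and none-samples scatter around them with SD ``none_spread``, kept at
    least ``none_margin`` degrees from every AOI mean — gaze a human coder
    calls off-AOI is, by definition, not directed at an AOI centre.  This
    leaves the histogram valleys between AOI peaks deep, as in real sessions.
    """

    aoi_means: tuple[float, float, float] = (-20.0, 0.0, 20.0)  # deg, L/parent/R
    none_spread: float = 3.0  # deg, scatter around each distractor direction
    none_margin: float = 5.0  # deg
    n_distractors: int = 6
    distractor_offset_range: tuple[float, float] = (25.0, 40.0)  # deg beyond lamps
    noise_sd: float = 2.0  # deg
    transition_weights: dict = field(
        default_factory=lambda: {
            "left_lamp": 3.0,
            "parent": 2.0,
            "right_lamp": 3.0,
            "none": 1.5,
        }
    )
    dwell_log_mean: float = 0.7  # log-seconds; median dwell ~2 s
    dwell_log_sd: float = 0.6
    min_dwell: float = 0.4  # s
    min_aoi_frac: float = 0.08  # minimum share of the session per AOI
    duration: float = 90.0  # s
    rate: float = 30.0  # Hz
    timestamp_jitter_sd: float = 0.002  # s, webcam frame-interval jitter
    vertical_sd: float = 3.0  # deg; vertical channel is unused downstream
    seed: int = 0

    def __post_init__(self) -> None:
        m = self.aoi_means
        if not (m[0] < m[1] < m[2]):
            raise ConfigError("aoi_means must be strictly ordered left < parent < right")
        if self.duration <= 0 or self.rate <= 0:
            raise ConfigError("duration and rate must be positive")
        if self.noise_sd < 0 or self.none_spread <= 0:
            raise ConfigError("noise_sd >= 0 and none_spread > 0 required")
        if self.min_dwell <= 0:
            raise ConfigError("min_dwell must be positive")


def _draw_dwell_schedule(cfg: InfantSimConfig, rng) -> list[tuple[str, float, float]]:
    """Continuous-time state schedule covering [0, duration].

    The elicitation protocol alternates engaging events (the lamps light up
    and rotate on a fixed schedule; the parent is continuously present), so
    every AOI reliably attracts a non-trivial share of looking.  Schedules
    are resampled until each AOI holds at least ``min_aoi_frac`` of the
    session, emulating that protocol rather than an unconstrained wander.
    """
    labels = list(cfg.transition_weights)
    weights = np.array([cfg.transition_weights[l] for l in labels], dtype=float)
    for _ in range(200):
        state = labels[int(rng.choice(len(labels), p=weights / weights.sum()))]
        schedule = []
        now = 0.0
        while now < cfg.duration:
            dur = float(rng.lognormal(cfg.dwell_log_mean, cfg.dwell_log_sd))
            while dur < cfg.min_dwell:  # truncated below, resampled
                dur = float(rng.lognormal(cfg.dwell_log_mean, cfg.dwell_log_sd))
            end = min(now + dur, cfg.duration)
            schedule.append((state, now, end))
            now = end
            others = [l for l in labels if l != state]
            w = np.array([cfg.transition_weights[l] for l in others], dtype=float)
            state = others[int(rng.choice(len(others), p=w / w.sum()))]
        share = {a: 0.0 for a in AOIS}
        for s, t0, t1 in schedule:
            if s in share:
                share[s] += (t1 - t0) / cfg.duration
        if all(v >= cfg.min_aoi_frac for v in share.values()):
            return schedule
    logger.warning("no schedule met min_aoi_frac after 200 draws; using last")
    return schedule


def _draw_none_samples(cfg: InfantSimConfig, n: int, rng) -> np.ndarray:
    """Off-AOI gaze: scatter around per-session distractor directions.

    Distractor directions sit beyond the outer AOIs (alternating sides);
    samples are rejection-kept at least ``none_margin`` from every AOI mean.
    """
    if cfg.n_distractors < 1:
        raise ConfigError("n_distractors must be >= 1")
    lo_off, hi_off = cfg.distractor_offset_range
    # stratified per side so spots spread out instead of coinciding
    n_left = (cfg.n_distractors + 1) // 2
    n_right = cfg.n_distractors - n_left
    dirs = []
    for side, n_side, sign, anchor in (
        ("left", n_left, -1.0, cfg.aoi_means[0]),
        ("right", n_right, 1.0, cfg.aoi_means[2]),
    ):
        if n_side == 0:
            continue
        width = (hi_off - lo_off) / n_side
        for j in range(n_side):
            off = lo_off + (j + rng.uniform()) * width
            dirs.append(anchor + sign * off)
    dirs = np.asarray(dirs)
    out = np.empty(n)
    filled = 0
    while filled < n:
        m = 2 * (n - filled) + 8
        which = rng.integers(0, len(dirs), m)
        cand = rng.normal(dirs[which], cfg.none_spread)
        dist = np.min(
            np.abs(cand[:, None] - np.asarray(cfg.aoi_means)[None, :]), axis=1
        )
        cand = cand[dist >= cfg.none_margin]
        take = min(len(cand), n - filled)
        out[filled : filled + take] = cand[:take]
        filled += take
    return out


def simulate_infant_session(
    cfg: InfantSimConfig | None = None,
) -> tuple[GazeRecording, ManualDwellFile]:
    """Simulate one infant session and its ground-truth dwell coding.

    The ground-truth :class:`ManualDwellFile` is frame-accurate: boundaries
    sit on the timestamps of the frames where each dwell starts (matching
    how a human codes dwells from the same video, frame by frame), and the
    file is contiguous over the whole session.
    """
    cfg = cfg or InfantSimConfig()
    rng = np.random.default_rng(cfg.seed)
    schedule = _draw_dwell_schedule(cfg, rng)

    n = int(round(cfg.duration * cfg.rate))
    dt = np.full(n, 1.0 / cfg.rate)
    if cfg.timestamp_jitter_sd > 0:
        dt = dt + rng.normal(0.0, cfg.timestamp_jitter_sd, n)
        dt = np.maximum(dt, 1e-4)
    t = np.concatenate([[0.0], np.cumsum(dt[:-1])])

    # per-frame state from the continuous schedule
    starts = np.array([s for _, s, _ in schedule])
    idx = np.searchsorted(starts, t, side="right") - 1
    states = np.array([schedule[i][0] for i in idx])

    x = np.empty(n)
    means = dict(zip(AOIS, cfg.aoi_means))
    for label in AOIS:
        sel = states == label
        x[sel] = rng.normal(means[label], cfg.noise_sd, int(sel.sum()))
    sel = states == "none"
    x[sel] = _draw_none_samples(cfg, int(sel.sum()), rng)
    y = rng.normal(0.0, cfg.vertical_sd, n)

    rec = GazeRecording(
        t=t,
        x=x,
        y=y,
        valid=np.ones(n, dtype=bool),
        nominal_rate=cfg.rate,
        source="angle_degrees",
        meta={"condition": "infant"},
    )

    # frame-accurate ground truth: one entry per run of per-frame states
    entries: list[tuple[str, float, float]] = []
    run_start = 0
    for i in range(1, n + 1):
        if i == n or states[i] != states[run_start]:
            start_t = float(t[run_start])
            end_t = rec.duration if i == n else float(t[i])
            entries.append((str(states[run_start]), start_t, end_t))
            run_start = i
    return rec, ManualDwellFile(entries)


def degrade_manual_coding(
    truth: ManualDwellFile, boundary_jitter_sd: float, seed: int
) -> ManualDwellFile:
    """Emulate human-coder boundary uncertainty.

    Internal dwell boundaries are perturbed by ``N(0, jitter^2)`` while the
    session start/end and all labels stay fixed; order and contiguity are
    preserved by clamping (with a logged warning) any perturbation that
    would produce a negative-duration dwell.
    """
    if boundary_jitter_sd == 0:
        return ManualDwellFile(list(truth.entries))
    rng = np.random.default_rng(seed)
    labels = [e[0] for e in truth.entries]
    bounds = [truth.entries[0][1]] + [e[2] for e in truth.entries]
    eps = 1e-6
    for i in range(1, len(bounds) - 1):
        prop = bounds[i] + float(rng.normal(0.0, boundary_jitter_sd))
        lo = bounds[i - 1] + eps
        hi = bounds[i + 1] - eps  # original next boundary caps the shift
        if prop < lo or prop > hi:
            logger.warning(
                "boundary %d jitter clamped to keep dwells positive", i
            )
            prop = min(max(prop, lo), hi)
        bounds[i] = prop
    entries = [
        (labels[i], bounds[i], bounds[i + 1]) for i in range(len(labels))
    ]
    return ManualDwellFile(entries)
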