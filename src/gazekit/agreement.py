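"""Dwell-based measures and absolute-agreement comparison via ICC(A,1).

Two raters — here an automated gaze-estimation pipeline and a human coder —
each produce per-participant dwell measures (relative total dwell time and
mean dwell duration per AOI).  Their agreement is quantified with the
single-measure, absolute-agreement intraclass correlation from a two-way
random-effects ANOVA, ICC(A,1) in the McGraw & Wong taxonomy:

    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n) (MSC - MSE))

with MSR/MSC/MSE the subject, rater and residual mean squares, n subjects
and k raters.  Unlike a Pearson correlation, ICC(A,1) penalizes a constant
offset between raters — essential when the question is whether one method
can *replace* the other, not merely co-vary with it.  Confidence intervals
follow the McGraw-Wong F-based formulation with Satterthwaite denominator
degrees of freedom; the significance test of ICC > 0 uses F = MSR/MSE with
(n-1, (n-1)(k-1)) degrees of freedom, one-sided.  Interval bounds are
interpreted on the Koo-Li scale (<0.5 poor, 0.5-0.75 moderate, 0.75-0.9
good, >0.9 excellent), reported as a label pair for the two CI bounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError
from .io import AOI_LABELS
from .aoi import Dwell

logger = logging.getLogger(__name__)


@dataclass
class DwellMeasures:
    """Per-AOI dwell summary for one session and one rater.

    ``relative_total_dwell_time`` is the fraction of the session spent on
    each AOI (sums to 1 when the dwell list partitions the session);
    ``mean_dwell_duration`` is the arithmetic mean dwell length in seconds,
    reported as absent (NaN) for an AOI with no dwells — never as 0, which
    would bias agreement statistics.
    """

    relative_total_dwell_time: dict
    mean_dwell_duration: dict
    n_dwells: dict
    session_duration: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "relative_total_dwell_time": self.relative_total_dwell_time,
                "mean_dwell_duration": self.mean_dwell_duration,
                "n_dwells": self.n_dwells,
            }
        ).reindex(list(AOI_LABELS))


def dwell_measures(dwells: list[Dwell], session_duration: float) -> DwellMeasures:
    """Relative total dwell time, mean dwell duration and dwell count per AOI."""
    if session_duration <= 0:
        raise ConfigError("session_duration must be positive")
    for d in dwells:
        if d.start < -1e-9 or d.end > session_duration + 1e-9:
            raise DataError(
                f"dwell ({d.aoi}, {d.start}, {d.end}) outside session "
                f"[0, {session_duration}]"
            )
    rel = {a: 0.0 for a in AOI_LABELS}
    mean = {a: float("nan") for a in AOI_LABELS}
    count = {a: 0 for a in AOI_LABELS}
    for a in AOI_LABELS:
        durs = [d.duration for d in dwells if d.aoi == a]
        count[a] = len(durs)
        if durs:
            rel[a] = sum(durs) / session_duration
            mean[a] = float(np.mean(durs))
    return DwellMeasures(rel, mean, count, session_duration)


KOO_LI_CUTS = ((0.5, "poor"), (0.75, "moderate"), (0.9, "good"))


def koo_li_label(value: float) -> str:
    """Koo-Li reliability label for a single ICC value."""
    for cut, name in KOO_LI_CUTS:
        if value < cut:
            return name
    return "excellent"


@dataclass
class ICCResult:
    """ICC(A,1) point estimate with CI, F test and interpretation."""

    icc: float
    ci_low: float
    ci_high: float
    f_stat: float
    df1: float
    df2: float
    p: float
    n: int
    alpha: float = 0.05
    interpretation: tuple[str, str] = ("", "")

    def __post_init__(self) -> None:
        if not self.interpretation[0]:
            self.interpretation = (
                koo_li_label(self.ci_low),
                koo_li_label(self.ci_high),
            )

    @property
    def stars(self) -> str:
        """Conventional significance stars for the ICC > 0 test."""
        for thr, s in ((0.001, "***"), (0.01, "**"), (0.05, "*")):
            if self.p < thr:
                return s
        return ""

    def summary(self) -> str:
        lo_lab, hi_lab = self.interpretation
        return (
            f"ICC(A,1) = {self.icc:.2f}{self.stars}, "
            f"{100 * (1 - self.alpha):.0f}% CI [{self.ci_low:.2f}, "
            f"{self.ci_high:.2f}] "
            f"(F = {self.f_stat:.2f}, df1 = {self.df1:.0f}, "
            f"df2 = {self.df2:.0f}, p = {self.p:.3g}, n = {self.n}); "
            f"{lo_lab} to {hi_lab} reliability"
        )


def _two_way_mean_squares(data: np.ndarray) -> tuple[float, float, float]:
    """Row (subject), column (rater) and residual mean squares."""
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    resid = data - row_means[:, None] - col_means[None, :] + grand
    ss_err = np.sum(resid**2)
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_a1(x, y, alpha: float = 0.05) -> ICCResult:
    """Two-way random-effects, absolute-agreement, single-measure ICC.

    ``x`` and ``y`` are paired per-subject values from the two raters;
    subjects with a missing value in either rater are dropped pairwise with
    a logged warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DataError("raters must provide the same number of subjects")
    keep = np.isfinite(x) & np.isfinite(y)
    dropped = int(np.sum(~keep))
    if dropped:
        logger.warning("dropping %d subject(s) with a missing value", dropped)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise DataError(f"need at least 3 complete subject pairs, got {n}")
    data = np.column_stack([x, y])
    k = 2
    msr, msc, mse = _two_way_mean_squares(data)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise DataError("zero variance in both raters; ICC undefined")
    icc = (msr - mse) / denom

    # significance test of ICC > 0: F = MSR/MSE, one-sided
    df1 = n - 1
    df2 = (n - 1) * (k - 1)
    if mse == 0:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = msr / mse
        p = float(stats.f.sf(f_stat, df1, df2))

    # McGraw-Wong CI with Satterthwaite denominator df
    if icc >= 1.0 or mse == 0:
        lo, hi = icc, icc
    else:
        a = (k * icc) / (n * (1 - icc))
        b = 1 + (k * icc * (n - 1)) / (n * (1 - icc))
        num = (a * msc + b * mse) ** 2
        den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        v = num / den
        f_lo = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_hi = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - f_lo * mse) / (
            f_lo * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi = n * (f_hi * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_hi * msr
        )
    lo = min(lo, icc)
    hi = max(hi, icc)
    return ICCResult(
        icc=float(icc),
        ci_low=float(lo),
        ci_high=float(hi),
        f_stat=float(f_stat),
        df1=float(df1),
        df2=float(df2),
        p=p,
        n=n,
        alpha=alpha,
    )


@dataclass
class MeasureComparison:
    """Agreement report between estimator-derived and manual dwell measures."""

    table: pd.DataFrame
    icc: dict  # (measure, aoi) -> ICCResult
    paired: dict  # (measure, aoi) -> (est values, man values)

    def summary(self) -> str:
        lines = ["Agreement between estimated and manually coded measures",
                 "=" * 60]
        for (measure, aoi), res in self.icc.items():
            lines.append(f"{measure:28s} {aoi:10s} {res.summary()}")
        return "\n".join(lines)

    def plot_pairs(self, measure: str = "relative_total_dwell_time", ax=None):
        """Paired per-subject values by AOI for the two raters."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for i, aoi in enumerate(AOI_LABELS):
            est, man = self.paired[(measure, aoi)]
            xe = np.full(len(est), i - 0.15)
            xm = np.full(len(man), i + 0.15)
            for e, m, a, b in zip(xe, xm, est, man):
                ax.plot([e, m], [a, b], "-", color="0.7", lw=0.5)
            ax.plot(xe, est, "o", color="tab:red", ms=4)
            ax.plot(xm, man, "o", color="tab:blue", ms=4)
            ax.hlines(np.nanmedian(est), i - 0.25, i - 0.05, color="w", zorder=3)
            ax.hlines(np.nanmedian(man), i + 0.05, i + 0.25, color="w", zorder=3)
        ax.set_xticks(range(len(AOI_LABELS)), AOI_LABELS)
        ax.set_ylabel(measure.replace("_", " "))
        return ax


def compare_measures(
    est: dict, man: dict, alpha: float = 0.05
) -> MeasureComparison:
    """Compare per-subject :class:`DwellMeasures` from the two raters.

    ``est`` and ``man`` map subject id -> DwellMeasures; the subject sets
    must match.  For each AOI and each measure the paired values are
    collected (subjects with an undefined value for an AOI dropped pairwise
    inside :func:`icc_a1`) and an ICC(A,1) computed.
    """
    if set(est) != set(man):
        only_e = sorted(set(est) - set(man))
        only_m = sorted(set(man) - set(est))
        raise DataError(
            f"subject sets differ: only in estimates {only_e}, "
            f"only in manual {only_m}"
        )
    subjects = sorted(est)
    icc: dict = {}
    paired: dict = {}
    rows = []
    for measure in ("relative_total_dwell_time", "mean_dwell_duration"):
        for aoi in AOI_LABELS:
            ev = np.array([getattr(est[s], measure)[aoi] for s in subjects])
            mv = np.array([getattr(man[s], measure)[aoi] for s in subjects])
            paired[(measure, aoi)] = (ev, mv)
            try:
                res = icc_a1(ev, mv, alpha=alpha)
            except DataError as exc:
                logger.warning("ICC undefined for %s/%s: %s", measure, aoi, exc)
                res = None
            icc[(measure, aoi)] = res
            rows.append(
                {
                    "measure": measure,
                    "aoi": aoi,
                    "median_estimated": float(np.nanmedian(ev)),
                    "median_manual": float(np.nanmedian(mv)),
                    "icc": res.icc if res else float("nan"),
                    "ci_low": res.ci_low if res else float("nan"),
                    "ci_high": res.ci_high if res else float("nan"),
                    "f_stat": res.f_stat if res else float("nan"),
                    "df1": res.df1 if res else float("nan"),
                    "df2": res.df2 if res else float("nan"),
                    "p": res.p if res else float("nan"),
                    "n": res.n if res else 0,
                }
            )
    icc = {key: r for key, r in icc.items() if r is not None}
    return MeasureComparison(table=pd.DataFrame(rows), icc=icc, paired=paired)
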