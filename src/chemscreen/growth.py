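"""Growth-curve fitness estimation.

Strain fitness is quantified from OD600 microplate growth curves in two
ways: the doubling time during exponential phase (fitness ``W`` of a mutant
is the wild-type doubling time divided by the mutant's), and the area under
the growth curve (AUGC) over a fixed window, which is the more robust
readout when growth is severely inhibited (>50%).  Dose-response series of
fitness values are summarised by a Hill fit yielding an IC50.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "Condition",
    "ODTimeSeries",
    "DoublingTimeFit",
    "FitnessRecord",
    "DoseResponse",
    "NoGrowthError",
    "BelowDetectionError",
    "fit_doubling_time",
    "compute_augc",
    "relative_fitness_doubling",
    "relative_fitness_augc",
    "relative_fitness",
    "fit_dose_response",
]


class NoGrowthError(ValueError):
    """Raised when a trace contains no increasing exponential segment."""


class BelowDetectionError(ValueError):
    """Raised when every reading sits at the blank level."""


@dataclass(frozen=True)
class Condition:
    """Growth condition: medium plus an optional compound at a dose in mM."""

    medium: str = "YPD"
    compound: str | None = None
    dose_mm: float = 0.0

    def label(self) -> str:
        if self.compound is None or self.dose_mm == 0:
            return self.medium
        return f"{self.medium}+{self.compound}@{self.dose_mm:g}mM"


@dataclass
class ODTimeSeries:
    """One well's OD600 trace under a condition.

    Times are minutes from the start of the experiment and must be strictly
    increasing; readings are non-negative and at least four are required.
    """

    well: str
    strain: str
    condition: Condition
    times: np.ndarray
    readings: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.readings = np.asarray(self.readings, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.readings.shape:
            raise ValueError("times and readings must be 1-D and equal length")
        if len(self.times) < 4:
            raise ValueError("a growth trace needs at least 4 points")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.readings < 0):
            raise ValueError("OD readings must be non-negative")


@dataclass(frozen=True)
class DoublingTimeFit:
    """Doubling time (minutes) with the log-linear window it came from."""

    doubling_time: float
    window: tuple[float, float]  # (t_start, t_end) minutes
    n_points: int
    r_squared: float
    low_quality: bool = False


@dataclass(frozen=True)
class FitnessRecord:
    strain: str
    condition: Condition
    W: float
    method: str  # "doubling_time" | "augc"
    D: float | None = None
    AUGC: float | None = None
    n_replicates: int = 1
    sd: float = float("nan")


def _linfit(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and R^2 of y on t."""
    t0 = t - t.mean()
    sst = float(np.sum((y - y.mean()) ** 2))
    stt = float(np.sum(t0 * t0))
    slope = float(np.sum(t0 * y) / stt)
    ssr = sst - slope * slope * stt
    r2 = 1.0 if sst == 0 else max(0.0, 1.0 - ssr / sst)
    return slope, r2


def fit_doubling_time(
    series: ODTimeSeries,
    *,
    blank: float | None = None,
    min_points: int = 5,
    detection_eps: float = 0.01,
    r2_tolerance: float = 0.005,
) -> DoublingTimeFit:
    """Estimate the exponential-phase doubling time of one trace.

    The estimator slides a log-linear fit over every window of at least
    ``min_points`` consecutive readings whose OD lies in the exponential
    band [2*blank, max(OD)/2].  Among windows whose R^2 is within
    ``r2_tolerance`` of the best, the longest wins (earliest start on
    ties): a strict R^2 maximum would favour short windows whose apparent
    straightness is measurement noise, which makes the slope estimate
    needlessly variable.  The blank defaults to the first reading.  On a
    noiseless exponential every window is colinear, so the estimate is
    exact regardless of the tolerance.

    Raises
    ------
    BelowDetectionError
        if the trace never rises above the blank.
    NoGrowthError
        if no increasing log-linear segment exists.
    """
    od = series.readings
    t = series.times
    b = float(od[0]) if blank is None else float(blank)
    if float(np.ptp(od)) <= detection_eps:
        raise BelowDetectionError(
            f"well {series.well}: all readings at blank level ({b:.3g})"
        )
    lo = 2.0 * b  # zero blank: any positive OD is above background
    hi = float(od.max()) / 2.0
    eligible = (od >= lo) & (od <= hi) & (od > 0)

    # contiguous eligible stretches
    stretches: list[tuple[int, int]] = []
    i = 0
    n = len(od)
    while i < n:
        if eligible[i]:
            j = i
            while j + 1 < n and eligible[j + 1]:
                j += 1
            stretches.append((i, j))
            i = j + 1
        else:
            i += 1

    low_quality = False
    want = min_points
    lengths = [j - i + 1 for i, j in stretches]
    if lengths and max(lengths) < min_points and max(lengths) >= 3:
        want = max(lengths)  # degraded trace: use the longest stretch
        low_quality = True
    windows: list[tuple[float, int, int]] = []  # (r2, len, start)
    for i0, j0 in stretches:
        m = j0 - i0 + 1
        for w in range(want, m + 1):
            for s in range(i0, j0 - w + 2):
                slope, r2 = _linfit(t[s : s + w], np.log(od[s : s + w]))
                if slope > 0:
                    windows.append((r2, w, s))
    if not windows:
        raise NoGrowthError(f"well {series.well}: no increasing exponential segment")
    r2_best = max(r2 for r2, _, _ in windows)
    r2, w, s = max(
        (c for c in windows if c[0] >= r2_best - r2_tolerance),
        key=lambda c: (c[1], -c[2]),
    )
    e = s + w - 1
    slope, _ = _linfit(t[s : e + 1], np.log(od[s : e + 1]))
    return DoublingTimeFit(
        doubling_time=math.log(2.0) / slope,
        window=(float(t[s]), float(t[e])),
        n_points=w,
        r_squared=r2,
        low_quality=low_quality,
    )


def compute_augc(
    series: ODTimeSeries,
    *,
    window_hours: float = 24.0,
    baseline: float | None = None,
) -> float:
    """Area under the growth curve in OD·hours over exactly the window.

    The trapezoidal integral of (OD − baseline) clipped at zero is taken
    from the first timepoint to first timepoint + ``window_hours``; the
    trace must span the window.  Baseline defaults to the first reading.
    """
    t = series.times
    od = series.readings
    b = float(od[0]) if baseline is None else float(baseline)
    t_end = t[0] + window_hours * 60.0
    if t[-1] < t_end - 1e-9:
        raise ValueError(
            f"trace spans {(t[-1]-t[0])/60:.2f} h < requested {window_hours} h window"
        )
    y = np.clip(od - b, 0.0, None)
    # truncate at the window end, interpolating the final value
    inside = t <= t_end + 1e-9
    tt = t[inside]
    yy = y[inside]
    if tt[-1] < t_end - 1e-9:
        y_end = float(np.interp(t_end, t, y))
        tt = np.append(tt, t_end)
        yy = np.append(yy, y_end)
    return float(np.trapezoid(yy, tt) / 60.0)


def relative_fitness_doubling(d_mutant: float, d_wildtype: float) -> float:
    """Fitness as wild-type doubling time over mutant doubling time."""
    if d_mutant <= 0 or d_wildtype <= 0:
        raise ValueError("doubling times must be positive")
    return d_wildtype / d_mutant


def relative_fitness_augc(augc_treated: float, augc_untreated: float) -> float:
    """Fitness as AUGC under treatment normalised to untreated AUGC."""
    if augc_untreated <= 0:
        raise ValueError("untreated AUGC must be positive")
    return augc_treated / augc_untreated


def relative_fitness(
    test: Sequence[ODTimeSeries],
    reference: Sequence[ODTimeSeries],
    *,
    method: str = "auto",
    window_hours: float = 24.0,
    inhibition_threshold: float = 0.5,
) -> FitnessRecord:
    """Replicate-averaged fitness of test wells relative to reference wells.

    ``method`` is ``"doubling"``, ``"augc"`` or ``"auto"``.  Auto uses the
    AUGC ratio when it indicates more than ``inhibition_threshold`` growth
    inhibition (where the doubling time is poorly defined) and the doubling
    time ratio otherwise.
    """
    if not test or not reference:
        raise ValueError("need at least one test and one reference trace")
    augc_ref = float(np.mean([compute_augc(s, window_hours=window_hours) for s in reference]))
    augc_test = np.array([compute_augc(s, window_hours=window_hours) for s in test])
    w_augc = augc_test / augc_ref
    use = method
    if method == "auto":
        use = "augc" if float(np.mean(w_augc)) < inhibition_threshold else "doubling"
    if use == "augc":
        w = w_augc
        rec_d, rec_a = None, float(np.mean(augc_test))
    elif use == "doubling":
        d_ref = float(np.mean([fit_doubling_time(s).doubling_time for s in reference]))
        d_test = np.array([fit_doubling_time(s).doubling_time for s in test])
        w = d_ref / d_test
        rec_d, rec_a = float(np.mean(d_test)), None
    else:
        raise ValueError(f"unknown method {method!r}")
    s0 = test[0]
    return FitnessRecord(
        strain=s0.strain,
        condition=s0.condition,
        W=float(np.mean(w)),
        method="augc" if use == "augc" else "doubling_time",
        D=rec_d,
        AUGC=rec_a,
        n_replicates=len(test),
        sd=float(np.std(w, ddof=1)) if len(test) > 1 else float("nan"),
    )


@dataclass
class DoseResponse:
    """Hill-model summary of fitness versus compound dose.

    Model: f(d) = floor + (1 − floor) / (1 + (d / IC50)^h); the fitted
    curve is monotonically non-increasing in dose.  When the measured
    response never falls to half the uninhibited level the IC50 is flagged
    undetermined and no extrapolated value is reported.
    """

    strain: str | None
    doses: np.ndarray
    fitness: np.ndarray
    ic50: float | None
    hill: float | None
    floor: float | None
    residual: float | None
    undetermined: bool = False
    message: str = ""
    dose_unit: str = "mM"

    def predict(self, doses: np.ndarray) -> np.ndarray:
        if self.undetermined:
            raise ValueError("IC50 undetermined; no fitted curve")
        d = np.asarray(doses, dtype=float)
        return _hill(d, self.ic50, self.hill, self.floor)


def _hill(d: np.ndarray, ic50: float, h: float, floor: float) -> np.ndarray:
    with np.errstate(divide="ignore"):
        ratio = np.where(d > 0, d / ic50, 0.0)
        return floor + (1.0 - floor) / (1.0 + ratio**h)


def fit_dose_response(
    doses: Sequence[float],
    fitness: Sequence[float],
    *,
    strain: str | None = None,
    dose_unit: str = "mM",
) -> DoseResponse:
    """Least-squares Hill fit of fitness against dose.

    Requires at least four distinct dose levels including zero.  Doses are
    internally rescaled by the largest dose so the fit is exactly
    equivariant under a change of dose units.  If the mean response at the
    highest doses never drops below half of the uninhibited (zero-dose)
    level, the result carries ``undetermined=True`` rather than an
    extrapolated IC50.
    """
    d = np.asarray(doses, dtype=float)
    f = np.asarray(fitness, dtype=float)
    if d.shape != f.shape:
        raise ValueError("doses and fitness must have the same length")
    if np.any(f < 0):
        raise ValueError("fitness values must be non-negative")
    levels = np.unique(d)
    if len(levels) < 4 or 0.0 not in levels:
        raise ValueError("need >= 4 dose levels including a zero dose")

    means = np.array([f[d == lv].mean() for lv in levels])
    top = means[levels == 0.0][0]
    if means.min() > 0.5 * top:
        return DoseResponse(
            strain, d, f, None, None, None, None,
            undetermined=True,
            message="response never crosses half the uninhibited level",
            dose_unit=dose_unit,
        )

    dscale = float(levels.max())
    u = d / dscale
    # initial IC50: dose level whose mean response is closest to half-span
    half = 0.5 * (top + means.min())
    i0 = int(np.argmin(np.abs(means - half)))
    u50_0 = max(levels[i0] / dscale, 1e-3)
    p0 = [u50_0, 2.0, max(0.0, min(0.9, float(means.min()) * 0.8))]
    popt, _ = curve_fit(
        _hill, u, f, p0=p0,
        bounds=([1e-6, 0.05, 0.0], [1e6, 50.0, 0.99]),
        maxfev=20000,
    )
    resid = f - _hill(u, *popt)
    return DoseResponse(
        strain=strain,
        doses=d,
        fitness=f,
        ic50=float(popt[0] * dscale),
        hill=float(popt[1]),
        floor=float(popt[2]),
        residual=float(np.sqrt(np.mean(resid**2))),
        dose_unit=dose_unit,
    )
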