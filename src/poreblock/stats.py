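"""Windowed summaries, Cohen's d, and single-channel electrophysiology fits.

The MD-side statistics summarise per-frame metric series over a contiguous
fraction of frames (typically the final 25%, once the system has settled) and
compare conditions with Cohen's d — the difference of window means divided by
a pooled standard deviation — classified by the conventional 0.2 / 0.5 / 0.8
thresholds on |d|.

The electrophysiology side fits the Hill concentration–response curve

    inhibited fraction = Imax · c^nH / (IC50^nH + c^nH),

single-exponential dwell-time constants (maximum likelihood: τ̂ is the sample
mean), the open probability NPo (open-level-weighted fraction of record
time), and the single-channel conductance as the least-squares slope of the
current–voltage relation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats as sps

from .metrics import FrameSeries


class DegenerateStatisticError(ValueError):
    """The requested statistic is undefined on this input."""


# ---------------------------------------------------------------------------
# windowed summaries and effect sizes


@dataclass
class WindowSummary:
    """Mean and sample SD of a metric over a contiguous fraction-of-frames window."""

    window: tuple[float, float]
    n_frames_used: int
    mean: float
    sd: float


@dataclass
class EffectSize:
    d: float
    sd_pooled: float
    label: str


def last_fraction(fraction: float) -> tuple[float, float]:
    """The window covering the final ``fraction`` of frames, e.g. last 25%."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    return (1.0 - fraction, 1.0)


def window_summary(series: FrameSeries, window: tuple[float, float] = (0.75, 1.0)) -> WindowSummary:
    """μ and σ (sample SD, n−1) over a contiguous fraction-of-frames window.

    ``window`` is an interval of frame fractions — ``(0.75, 1.0)`` is the
    final 25% of frames (500 of a 2000-frame series).  Undefined (NaN) frames
    are excluded from the moments but still occupy window positions.
    """
    lo, hi = window
    if not (0 <= lo < hi <= 1):
        raise ValueError(f"window must satisfy 0 <= lo < hi <= 1, got {window}")
    n = len(series)
    if n < 8:
        raise ValueError(f"series too short for a window summary ({n} frames)")
    start, stop = round(lo * n), round(hi * n)
    values = series.values[start:stop]
    values = values[np.isfinite(values)]
    if values.size < 2:
        raise DegenerateStatisticError("window contains fewer than 2 defined frames")
    return WindowSummary(
        window=(lo, hi),
        n_frames_used=stop - start,
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)),
    )


def classify_effect(d: float) -> str:
    """Conventional |d| thresholds: 0.2 (small), 0.5 (medium), 0.8 (large)."""
    if not math.isfinite(d):
        raise ValueError("d must be finite")
    a = abs(d)
    if a < 0.2:
        return "negligible"
    if a < 0.5:
        return "small"
    if a < 0.8:
        return "medium"
    return "large"


def cohens_d(a: WindowSummary, b: WindowSummary, *, pooled: str = "rms") -> EffectSize:
    """Standardised mean difference between two window summaries.

    ``pooled="rms"`` (default) uses sqrt((SD1² + SD2²)/2), the equal-n pooled
    SD; ``pooled="quadrature"`` uses sqrt(SD1² + SD2²) for the quadrature-sum
    convention.  Both summaries having zero SD leaves d undefined.
    """
    if pooled == "rms":
        sp = math.sqrt((a.sd**2 + b.sd**2) / 2.0)
    elif pooled == "quadrature":
        sp = math.sqrt(a.sd**2 + b.sd**2)
    else:
        raise ValueError(f"unknown pooled-SD convention {pooled!r}")
    if sp == 0:
        raise DegenerateStatisticError("both window SDs are zero; effect size undefined")
    d = (a.mean - b.mean) / sp
    return EffectSize(d=d, sd_pooled=sp, label=classify_effect(d))


# ---------------------------------------------------------------------------
# Hill concentration–response fit


@dataclass
class HillFitResult:
    imax: float  # maximal inhibited fraction, in (0, 1]
    ic50: float  # μM
    n_h: float  # Hill coefficient
    rss: float
    converged: bool


def hill_curve(c: np.ndarray, imax: float, ic50: float, n_h: float) -> np.ndarray:
    """Inhibited fraction at concentration ``c`` (same units as ``ic50``)."""
    c = np.asarray(c, dtype=float)
    return imax * c**n_h / (ic50**n_h + c**n_h)


_IC50_BOUNDS = (1e-6, 1e6)
_NH_BOUNDS = (1e-2, 20.0)


def fit_hill(concentrations: Sequence[float], inhibited_fractions: Sequence[float]) -> HillFitResult:
    """Least-squares Hill fit with bounds Imax ∈ (0, 1], IC50 > 0, nH > 0.

    Multi-start initialisation (a grid of nH guesses crossed with
    concentration-quantile IC50 guesses) guards against the local minima this
    sigmoid is prone to.  The convergence flag is false when the response
    range is below 0.1 (the curve is essentially flat and IC50 is not
    identified) or when IC50/nH are pinned at the box bounds.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(inhibited_fractions, dtype=float)
    if np.unique(c).size < 4:
        raise ValueError("need at least 4 distinct concentrations")
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    if np.any((y < -1e-9) | (y > 1 + 1e-9)):
        raise ValueError("inhibited fractions must lie in [0, 1]")

    lower = np.array([1e-6, _IC50_BOUNDS[0], _NH_BOUNDS[0]])
    upper = np.array([1.0, _IC50_BOUNDS[1], _NH_BOUNDS[1]])
    imax0 = float(np.clip(y.max(), 0.05, 1.0))
    ic50_guesses = np.quantile(np.unique(c), [0.25, 0.5, 0.75])
    best = None
    for n_h0 in (0.5, 1.0, 2.0, 4.0):
        for ic500 in ic50_guesses:
            try:
                popt, _ = optimize.curve_fit(
                    hill_curve, c, y, p0=[imax0, ic500, n_h0],
                    bounds=(lower, upper), maxfev=20000,
                )
            except RuntimeError:
                continue
            rss = float(np.sum((hill_curve(c, *popt) - y) ** 2))
            if best is None or rss < best[1]:
                best = (popt, rss)
    if best is None:
        raise RuntimeError("Hill fit failed to converge from any start")
    (imax, ic50, n_h), rss = best
    at_bounds = (
        ic50 <= _IC50_BOUNDS[0] * 1.01
        or ic50 >= _IC50_BOUNDS[1] * 0.99
        or n_h <= _NH_BOUNDS[0] * 1.01
        or n_h >= _NH_BOUNDS[1] * 0.99
    )
    converged = (float(y.max() - y.min()) >= 0.1) and not at_bounds
    return HillFitResult(
        imax=float(imax), ic50=float(ic50), n_h=float(n_h), rss=rss, converged=converged
    )


# ---------------------------------------------------------------------------
# dwell times, NPo, conductance


@dataclass
class DwellFit:
    tau: float  # ms
    n_events: int
    method: str = "exponential MLE"


def fit_dwell_exponential(dwells: Sequence[float], min_events: int = 10) -> DwellFit:
    """Single-exponential time constant by maximum likelihood (the sample mean)."""
    d = np.asarray(dwells, dtype=float)
    if d.size < min_events:
        raise ValueError(f"need at least {min_events} dwell times, got {d.size}")
    if np.any(d <= 0):
        raise ValueError("dwell times must be positive")
    return DwellFit(tau=float(d.mean()), n_events=int(d.size))


@dataclass
class NPoResult:
    npo: float
    total_open_time: float  # ms, open-level weighted
    record_duration: float  # ms


_STATE_LEVELS = {"closed": 0, "c": 0, "open": 1, "o": 1}


def compute_npo(
    idealized_events: Iterable[tuple[object, float]], record_duration: float
) -> NPoResult:
    """NPo from an idealised event list.

    Events are (state, duration ms) with the state either an open-level
    integer (0 = closed; stacked openings of k channels are level k) or the
    strings "open"/"closed".  NPo = Σ level·duration / record duration, left
    unnormalised by channel count.
    """
    if record_duration <= 0:
        raise ValueError("record duration must be positive")
    total = 0.0
    used = 0.0
    for state, dur in idealized_events:
        if dur < 0:
            raise ValueError(f"negative event duration: {dur}")
        if isinstance(state, str):
            level = _STATE_LEVELS.get(state.lower())
            if level is None:
                raise ValueError(f"unknown state {state!r}")
        else:
            level = int(state)
            if level < 0:
                raise ValueError("open level must be >= 0")
        total += level * dur
        used += dur
    if used > record_duration * (1 + 1e-9):
        raise ValueError(
            f"event durations sum to {used} ms, exceeding the record ({record_duration} ms)"
        )
    return NPoResult(npo=total / record_duration, total_open_time=total, record_duration=record_duration)


@dataclass
class ConductanceFit:
    conductance: float  # pS
    intercept: float  # pA
    r_squared: float


def fit_iv_conductance(voltages: Sequence[float], currents: Sequence[float]) -> ConductanceFit:
    """Single-channel conductance as the OLS slope of current (pA) vs voltage (mV).

    The slope in pA/mV is converted to pS (× 1000).
    """
    v = np.asarray(voltages, dtype=float)
    i = np.asarray(currents, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 I–V points")
    if np.unique(v).size < 2:
        raise ValueError("all voltages are equal; slope undefined")
    res = sps.linregress(v, i)
    return ConductanceFit(
        conductance=float(res.slope * 1000.0),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2) if np.isfinite(res.rvalue) else 0.0,
    )
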