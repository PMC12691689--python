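"""Reduction of NADH-coupled plate-reader traces to synthesis velocities.

The coupled assay converts the AMP released by each pyrophosphoryl transfer
into NADH oxidation (myokinase -> pyruvate kinase -> lactate dehydrogenase),
read as a decrease in absorbance at 340 nm.  A parallel reaction omitting
myokinase reports only ADP-producing background activities (phosphatases,
ATPases); its slope is subtracted before converting to a rate.  The signed
A340 slope maps to a velocity through an empirical extinction coefficient of
3.88 per mM of product — treated here as an opaque calibration constant,
overridable everywhere it appears.

Sign convention: synthesis consumes NADH, so a valid corrected signal has a
negative slope.  A positive net slope is floored to velocity zero and flagged
rather than reported as a negative rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ratelaw import InvalidParameterError

#: A340 change per mM of pyrophosphorylated product (2 NADH per AMP, plate path)
EPSILON_PER_MM = 3.88

#: minimum fit quality for the automatic initial-window search
AUTO_R2_MIN = 0.99


class InsufficientDataError(ValueError):
    """Fewer points than the slope fit requires."""


class NoSignalWarning(UserWarning):
    """Net slope positive after background correction — no synthesis signal."""


@dataclass(frozen=True)
class AssayTrace:
    """One well's A340 time series.

    times are minutes, strictly increasing; ``has_myokinase=False`` marks the
    paired background reaction.  ``dilution_factor`` is the fold-dilution of
    the enzyme sample into the well (>= 1); velocities are scaled back up by it.
    """

    times: Sequence[float]
    a340: Sequence[float]
    has_myokinase: bool = True
    dilution_factor: float = 1.0
    well_id: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.a340, dtype=float)
        if t.ndim != 1 or t.shape != a.shape:
            raise ValueError("times and a340 must be 1-D sequences of equal length")
        if len(t) < 3:
            raise InsufficientDataError(
                f"trace {self.well_id!r} has {len(t)} points; >= 3 required"
            )
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if self.dilution_factor < 1:
            raise ValueError(f"dilution_factor must be >= 1, got {self.dilution_factor}")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "a340", a)


@dataclass(frozen=True)
class RateResult:
    """Outcome of reducing one full/background trace pair."""

    slope_a340_per_min: float
    velocity_uM_per_min: float
    r_squared: float
    window: tuple[int, int]
    background_slope: float = 0.0
    no_signal: bool = False


def _ols_slope(t: np.ndarray, a: np.ndarray) -> tuple[float, float]:
    if np.ptp(a) == 0.0:
        # flat trace: slope 0, perfect fit by convention (linregress yields nan r)
        return 0.0, 1.0
    fit = stats.linregress(t, a)
    return float(fit.slope), float(fit.rvalue**2)


def fit_initial_slope(
    trace: AssayTrace, window: tuple[int, int] | str = "auto"
) -> tuple[float, float, tuple[int, int]]:
    """Least-squares slope of A340 vs time over an initial-rate window.

    ``window="auto"`` selects the longest initial window (starting at the first
    point) whose linear fit keeps r² >= 0.99, with a 3-point minimum; an explicit
    ``(start, stop)`` index range (stop exclusive) is used verbatim.

    Returns (slope in A340/min, r², window used).
    """
    t = np.asarray(trace.times, dtype=float)
    a = np.asarray(trace.a340, dtype=float)
    if window == "auto":
        best = None
        for stop in range(3, len(t) + 1):
            slope, r2 = _ols_slope(t[:stop], a[:stop])
            if r2 >= AUTO_R2_MIN:
                best = (slope, r2, (0, stop))
        if best is None:
            # no acceptable prefix: report the minimal 3-point window
            slope, r2 = _ols_slope(t[:3], a[:3])
            best = (slope, r2, (0, 3))
        return best
    start, stop = window
    if stop - start < 3:
        raise InsufficientDataError(
            f"window {window} has {stop - start} points; >= 3 required"
        )
    slope, r2 = _ols_slope(t[start:stop], a[start:stop])
    return slope, r2, (start, stop)


def subtract_background(slope_full: float, slope_minus_myokinase: float) -> float:
    """Net A340 slope after removing ADP-producing background activity."""
    net = slope_full - slope_minus_myokinase
    if net > 0:
        warnings.warn(
            f"net slope {net:+.4g} A340/min is positive after background "
            "correction: no synthesis signal",
            NoSignalWarning,
            stacklevel=2,
        )
    return net


def slope_to_velocity(
    net_slope: float,
    epsilon_per_mM: float = EPSILON_PER_MM,
    dilution_factor: float = 1.0,
) -> float:
    """Convert a net A340 slope to a synthesis velocity in µM/min.

    velocity = max(0, -net_slope) / epsilon * 1000 * dilution_factor.
    """
    if not epsilon_per_mM > 0:
        raise InvalidParameterError(
            f"epsilon_per_mM must be > 0, got {epsilon_per_mM}"
        )
    return max(0.0, -net_slope) / epsilon_per_mM * 1000.0 * dilution_factor


def reduce_pair(
    full: AssayTrace,
    background: AssayTrace | None = None,
    window: tuple[int, int] | str = "auto",
    epsilon_per_mM: float = EPSILON_PER_MM,
) -> RateResult:
    """Reduce a full trace (and optional minus-myokinase pair) to a velocity."""
    slope, r2, win = fit_initial_slope(full, window)
    bg_slope = 0.0
    if background is not None:
        bg_slope, _, _ = fit_initial_slope(background, window)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", NoSignalWarning)
        net = subtract_background(slope, bg_slope)
        no_signal = any(issubclass(w.category, NoSignalWarning) for w in caught)
    v = slope_to_velocity(net, epsilon_per_mM, full.dilution_factor)
    return RateResult(
        slope_a340_per_min=slope,
        velocity_uM_per_min=v,
        r_squared=r2,
        window=win,
        background_slope=bg_slope,
        no_signal=no_signal,
    )


TRACE_COLUMNS = ["well_id", "time_min", "a340", "has_myokinase", "dilution_factor", "condition_id"]


def traces_from_frame(df: pd.DataFrame) -> dict[str, dict[bool, AssayTrace]]:
    """Group a long-format trace table into per-condition full/background pairs.

    Pairing is by explicit ``condition_id`` declaration, never by well position.
    """
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace table lacks required columns: {sorted(missing)}")
    out: dict[str, dict[bool, AssayTrace]] = {}
    for (cond, wid, myo), grp in df.groupby(
        ["condition_id", "well_id", "has_myokinase"], sort=False
    ):
        grp = grp.sort_values("time_min")
        dil = grp["dilution_factor"].iloc[0]
        trace = AssayTrace(
            times=grp["time_min"].to_numpy(),
            a340=grp["a340"].to_numpy(),
            has_myokinase=bool(myo),
            dilution_factor=float(dil),
            well_id=str(wid),
        )
        slot = out.setdefault(str(cond), {})
        if bool(myo) in slot:
            raise ValueError(
                f"condition {cond!r} declares more than one "
                f"{'full' if myo else 'background'} well"
            )
        slot[bool(myo)] = trace
    return out


def reduce_traces(
    df: pd.DataFrame,
    window: tuple[int, int] | str = "auto",
    epsilon_per_mM: float = EPSILON_PER_MM,
) -> pd.DataFrame:
    """Reduce a long-format trace table to one velocity row per condition.

    Output columns: condition_id, well_id, slope_a340_per_min,
    background_slope_a340_per_min, r_squared, window_start, window_stop,
    dilution_factor, velocity_uM_per_min, no_signal.
    """
    rows = []
    for cond, pair in traces_from_frame(df).items():
        if True not in pair:
            raise ValueError(f"condition {cond!r} has no full (+myokinase) trace")
        full = pair[True]
        res = reduce_pair(full, pair.get(False), window, epsilon_per_mM)
        rows.append(
            {
                "condition_id": cond,
                "well_id": full.well_id,
                "slope_a340_per_min": res.slope_a340_per_min,
                "background_slope_a340_per_min": res.background_slope,
                "r_squared": res.r_squared,
                "window_start": res.window[0],
                "window_stop": res.window[1],
                "dilution_factor": full.dilution_factor,
                "velocity_uM_per_min": res.velocity_uM_per_min,
                "no_signal": res.no_signal,
            }
        )
    return pd.DataFrame(rows)
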