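"""Bioreactor physiology: growth rate, specific rates, yields, RQ.

Interval-wise quantities between sampling points T(i) and T(i+1):

* specific growth rate mu (1/h): slope of an OLS fit of ln(biomass) vs time
  over >= 3 points (exponential regression);
* specific rate q (g / g CDW / h): volumetric rate divided by the
  time-averaged biomass. During exponential growth the time average of
  X(t) = X1 * exp(mu t) over the interval is (X2 - X1) / ln(X2 / X1); during
  linear growth (oxygen-limited/anaerobic) the arithmetic mean (X1 + X2)/2
  is used;
* yield (g/g): product formed per glucose consumed between the two points;
* respiratory quotient RQ: molar CO2 evolution rate over molar O2 uptake
  rate from the inlet/outlet off-gas balance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "growth_rate",
    "exp_average_biomass",
    "specific_rate",
    "product_yield",
    "respiratory_quotient",
    "interval_kinetics",
    "IntervalKinetics",
]


def growth_rate(times, biomass) -> float:
    """Specific growth rate mu (1/h) by exponential regression.

    OLS slope of ln(biomass) against time; requires >= 3 points, all biomass
    strictly positive. Exact (to machine precision) on exactly exponential
    data for any mu and sampling grid.
    """
    t = np.asarray(times, dtype=float)
    x = np.asarray(biomass, dtype=float)
    if len(t) < 3:
        raise ValueError(f"growth rate needs >= 3 points, got {len(t)}")
    if (x <= 0).any():
        raise ValueError("biomass values must be positive for log regression")
    return float(stats.linregress(t, np.log(x)).slope)


def exp_average_biomass(x1: float, x2: float) -> float:
    """Time-average biomass over an exponential-growth interval.

    For X(t) growing exponentially from x1 to x2, the time average is the
    logarithmic mean (x2 - x1) / ln(x2 / x1); equal endpoints return the
    common value (the continuous limit).
    """
    if x1 <= 0 or x2 <= 0:
        raise ValueError("biomass endpoints must be positive")
    if x1 == x2:
        return float(x1)
    return float((x2 - x1) / np.log(x2 / x1))


def specific_rate(
    delta_conc: float,
    delta_t: float,
    x1: float,
    x2: float,
    mode: str = "exponential",
) -> float:
    """Specific production/uptake rate q (g / g CDW / h).

    q = (delta_conc / delta_t) / <X>, with <X> the exponential time-average
    of the biomass endpoints during exponential growth, or their arithmetic
    mean during linear growth.
    """
    if delta_t <= 0:
        raise ValueError("delta_t must be positive")
    if mode == "exponential":
        x_avg = exp_average_biomass(x1, x2)
    elif mode == "arithmetic":
        x_avg = (x1 + x2) / 2.0
    else:
        raise ValueError(f"unknown biomass-averaging mode {mode!r}")
    if x_avg <= 0:
        raise ValueError("average biomass must be positive")
    return float((delta_conc / delta_t) / x_avg)


def product_yield(delta_product: float, delta_glucose_consumed: float) -> tuple[float, bool]:
    """Yield (g product per g glucose consumed) between two sampling points.

    Returns (yield, flagged). A decreasing product is reported as yield 0
    with the flag set; zero glucose consumption raises.
    """
    if delta_glucose_consumed <= 0:
        raise ValueError("glucose consumed must be positive for a defined yield")
    if delta_product < 0:
        return 0.0, True
    return float(delta_product / delta_glucose_consumed), False


def respiratory_quotient(
    o2_in: float,
    o2_out: float,
    co2_in: float,
    co2_out: float,
    balance: str = "equal_flow",
) -> float:
    """RQ = CO2 evolution rate / O2 uptake rate from off-gas fractions.

    ``equal_flow`` assumes equal dry molar in/out flow, so rates reduce to
    fraction differences. ``inert_balance`` corrects the outlet flow by the
    N2 (inert) balance, appropriate when RQ deviates notably from 1.
    Raises when O2 uptake is not positive (e.g. the N2-sparged anaerobic
    phase, where RQ is undefined).
    """
    if balance == "equal_flow":
        our = o2_in - o2_out
        cer = co2_out - co2_in
    elif balance == "inert_balance":
        n2_in = 1.0 - o2_in - co2_in
        n2_out = 1.0 - o2_out - co2_out
        if n2_out <= 0:
            raise ValueError("outlet inert fraction must be positive")
        ratio = n2_in / n2_out  # outlet flow / inlet flow
        our = o2_in - o2_out * ratio
        cer = co2_out * ratio - co2_in
    else:
        raise ValueError(f"unknown balance mode {balance!r}")
    if our <= 0:
        raise ValueError("O2 uptake <= 0: RQ undefined (anaerobic phase?)")
    return float(cer / our)


@dataclass(frozen=True)
class IntervalKinetics:
    """Rates and yields over one sampling interval (Table-3-shaped row set)."""

    interval: str
    mu: float | None
    q_s: float | None  # g glucose / g CDW / h
    q_p: dict  # product -> g / g CDW / h
    yields: dict  # product -> g / g glucose
    rq: float | None


def interval_kinetics(
    timeseries: pd.DataFrame,
    boundaries: list[float],
    labels: list[str] | None = None,
    products: list[str] | None = None,
    exponential_intervals: int = 1,
) -> list[IntervalKinetics]:
    """Interval-wise kinetics from a dense culture time series.

    Parameters
    ----------
    timeseries : frame with columns ``time_h``, ``cdw_g_per_l``,
        ``glucose_g_per_l``, product columns (g/L), and optionally off-gas
        fractions ``o2_in``, ``o2_out``, ``co2_in``, ``co2_out``.
    boundaries : sampling times delimiting the intervals (e.g. T0..T5).
    exponential_intervals : number of leading intervals treated as
        exponential growth (exponential biomass averaging); later intervals
        use arithmetic averaging (linear growth under oxygen limitation).
    """
    ts = timeseries.sort_values("time_h").reset_index(drop=True)
    if products is None:
        reserved = {"time_h", "cdw_g_per_l", "od600", "glucose_g_per_l",
                    "o2_in", "o2_out", "co2_in", "co2_out", "phase"}
        products = [c for c in ts.columns if c not in reserved]
    if labels is None:
        labels = [f"T{i}-T{i + 1}" for i in range(len(boundaries) - 1)]

    def _at(col, t):
        return float(np.interp(t, ts["time_h"], ts[col]))

    out = []
    for i, (t1, t2) in enumerate(zip(boundaries[:-1], boundaries[1:])):
        mode = "exponential" if i < exponential_intervals else "arithmetic"
        window = ts[(ts["time_h"] >= t1) & (ts["time_h"] <= t2)]
        x1, x2 = _at("cdw_g_per_l", t1), _at("cdw_g_per_l", t2)
        dt = t2 - t1
        mu = growth_rate(window["time_h"], window["cdw_g_per_l"]) if len(window) >= 3 else None
        dglc = _at("glucose_g_per_l", t1) - _at("glucose_g_per_l", t2)
        q_s = specific_rate(dglc, dt, x1, x2, mode=mode) if dglc > 0 else None
        q_p, yields = {}, {}
        for p in products:
            dp = _at(p, t2) - _at(p, t1)
            q_p[p] = specific_rate(max(dp, 0.0), dt, x1, x2, mode=mode)
            if dglc > 0:
                yields[p], _ = product_yield(max(dp, 0.0), dglc)
        rq = None
        if {"o2_in", "o2_out", "co2_in", "co2_out"} <= set(ts.columns) and len(window):
            mid = window.iloc[len(window) // 2]
            try:
                rq = respiratory_quotient(
                    mid["o2_in"], mid["o2_out"], mid["co2_in"], mid["co2_out"]
                )
            except ValueError:
                rq = None
        out.append(IntervalKinetics(labels[i], mu, q_s, q_p, yields, rq))
    return out
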