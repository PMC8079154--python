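"""Small physiology statistics: oxygen-rate regression, gross photosynthesis,
and Welch's two-sample t-test (the shared utility of several screens).

The oxygen computation mirrors closed-chamber respirometry: the slope of
dissolved-oxygen concentration over time under darkness measures
respiration, the slope under light measures net photosynthesis, and the
gross photosynthetic rate is their sum, oG = oL + oD, with oD stored as a
positive consumption magnitude so the additive formula holds literally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass
class OxygenRates:
    """Oxygen exchange rates in mg O2 l^-1 min^-1."""
    oL: float  #: net O2 rate under light
    oD: float  #: O2 consumption magnitude in dark (>= 0)
    oG: float  #: gross photosynthetic rate, oL + oD


@dataclass
class WelchResult:
    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int


def fit_oxygen_rate(times_s: Sequence[float], conc_mg_l: Sequence[float]):
    """Ordinary least-squares fit of oxygen concentration against time.

    Parameters
    ----------
    times_s
        Strictly increasing times in seconds.
    conc_mg_l
        Dissolved-oxygen concentrations in mg O2 / l.

    Returns
    -------
    (slope, intercept, r_squared)
        Slope in mg O2 l^-1 **min^-1** (times converted from seconds);
        intercept in mg/l at t=0.
    """
    t = np.asarray(times_s, dtype=float)
    y = np.asarray(conc_mg_l, dtype=float)
    if t.size != y.size:
        raise ValueError("times and concentrations differ in length")
    if t.size < 3:
        raise ValueError("need at least 3 points for a rate fit")
    if not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")
    res = stats.linregress(t / 60.0, y)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


def gross_photosynthesis(light_slope: float, dark_slope: float) -> OxygenRates:
    """Combine light and dark oxygen slopes into a gross photosynthesis rate.

    ``dark_slope`` is expected to be negative (net consumption by
    respiration); a positive dark slope is biologically unexpected, raises
    a warning, and is clamped to zero consumption.
    """
    oL = float(light_slope)
    if dark_slope > 0:
        warnings.warn(
            "positive oxygen slope in darkness (net production without light?); "
            "clamping dark consumption to 0", stacklevel=2)
        oD = 0.0
    else:
        oD = -float(dark_slope)
    return OxygenRates(oL=oL, oD=oD, oG=oL + oD)


def welch_t_test(group_a: Sequence[float], group_b: Sequence[float]) -> WelchResult:
    """Welch's two-sample t-test (unequal variances), two-sided.

    t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2), with the Welch-Satterthwaite
    degrees of freedom.  Degenerate zero-variance inputs: equal means give
    t = 0, p = 1; unequal means give a p -> 0 sentinel with a warning.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite observation")
    m1, m2 = a.mean(), b.mean()
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    n1, n2 = a.size, b.size
    se2 = v1 / n1 + v2 / n2
    common = dict(mean_a=float(m1), mean_b=float(m2),
                  sd_a=float(np.sqrt(v1)), sd_b=float(np.sqrt(v2)),
                  n_a=int(n1), n_b=int(n2))
    if se2 == 0.0:
        if m1 == m2:
            return WelchResult(t=0.0, df=float(n1 + n2 - 2), p=1.0, **common)
        warnings.warn("zero variance in both groups with unequal means; "
                      "p reported as 0", stacklevel=2)
        t = np.inf if m1 > m2 else -np.inf
        return WelchResult(t=float(t), df=float(n1 + n2 - 2), p=0.0, **common)
    t = (m1 - m2) / np.sqrt(se2)
    df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(t=float(t), df=float(df), p=float(min(p, 1.0)), **common)
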