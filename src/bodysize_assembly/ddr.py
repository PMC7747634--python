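"""Distance-decay relationship (DDR) of community similarity.

Community similarity S = 1 − Bray-Curtis is regressed on geographic
distance D on log10–log10 axes,

    log10 S = a + b · log10 D        (D in km),

so the slope b is the spatial turnover rate.  From the fit we derive the
initial similarity S0 at the 1 km floor distance, S0 = 10^a, and the
halving-distance — the distance at which similarity drops to S0/2:

    d_H = 10^((log10(S0/2) − a) / b).

With S0 = 10^a this reduces to d_H = 10^(−log10 2 / b).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .metrics import DistanceMatrix

logger = logging.getLogger(__name__)

__all__ = ["DDRFit", "fit_ddr", "halving_distance"]

MIN_DISTANCE_KM = 1.0  # floor below which log-distance pairs are excluded


@dataclass
class DDRFit:
    """Ordinary least-squares fit of log10 similarity on log10 distance."""

    a: float          # intercept (log10 similarity at D = 1 km)
    b: float          # slope, dimensionless
    r_squared: float
    p_value: float    # two-sided t test on the slope
    s0: float         # initial similarity at D = 1 km, 10**a
    d_h: float        # halving-distance, km (nan when b >= 0)
    n_pairs: int
    n_excluded: int = 0


def halving_distance(a: float, b: float, s0: float) -> float:
    """Distance (km) at which similarity falls to half the initial value.

    Exact evaluation of d_H = 10^((log10(s0/2) − a)/b), log base 10.
    """
    if b >= 0:
        raise ValueError(f"halving-distance undefined for non-negative slope b={b}")
    if not 0 < s0 <= 1:
        raise ValueError(f"initial similarity must be in (0, 1], got {s0}")
    return float(10.0 ** ((np.log10(s0 / 2.0) - a) / b))


def fit_ddr(community: DistanceMatrix, geo: DistanceMatrix) -> DDRFit:
    """Fit the distance-decay regression over all unordered sample pairs.

    ``community`` holds Bray-Curtis dissimilarities (converted to
    similarity S = 1 − BC); ``geo`` holds distances in km.  Pairs with
    S ≤ 0 or D < 1 km are excluded (log undefined / below the S0 floor
    convention) and counted in ``n_excluded``.
    """
    if community.ids != geo.ids:
        raise ValueError("community and geographic matrices have mismatched ids")
    s = 1.0 - community.condensed()
    d = geo.condensed()
    usable = (s > 0) & (d >= MIN_DISTANCE_KM)
    n_excluded = int((~usable).sum())
    if n_excluded:
        logger.info("fit_ddr: excluded %d pairs (S<=0 or D<1 km)", n_excluded)
    if usable.sum() < 3:
        raise ValueError(f"only {int(usable.sum())} usable pairs; need at least 3")
    x = np.log10(d[usable])
    y = np.log10(s[usable])
    res = stats.linregress(x, y)
    a, b = float(res.intercept), float(res.slope)
    s0 = float(10.0 ** a)
    if s0 > 1.0:
        # extrapolating the fit back to 1 km can exceed the similarity
        # ceiling when all pairs lie far beyond it; cap at 1
        logger.info("fit_ddr: extrapolated S0=%.3g > 1; reporting 1.0", s0)
        s0 = 1.0
    if b < 0:
        d_h = halving_distance(a, b, s0)
    else:
        logger.warning("fit_ddr: non-negative slope b=%.4g; halving-distance undefined", b)
        d_h = float("nan")
    return DDRFit(
        a=a,
        b=b,
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        s0=s0,
        d_h=d_h,
        n_pairs=int(usable.sum()),
        n_excluded=n_excluded,
    )
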