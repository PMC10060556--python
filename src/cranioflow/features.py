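"""Waveform features of one cardiac cycle.

Eight features are extracted from a uniformly sampled signal over a single
cycle of length ``T``: maximum, minimum, mean, amplitude, min-to-max time
(the rising-limb duration, called rising time in the finger-PPG literature),
pulsatility index PI = (max-min)/mean, resistive index RI = (max-min)/max,
and max-to-mean ratio MMR = max/mean.  The identity PI = RI * MMR holds by
construction.

The cycle mean is the trapezoidal integral over the cycle divided by T.
Extrema are taken on the half-open window [t_start, t_start + T) with ties
broken toward the first sample attaining the extremum.  When the sampled
cycle's maximum precedes its minimum, the min-to-max time wraps modulo T so
it always measures the rising limb.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from cranioflow.circuit import TimeSeries

__all__ = ["CycleFeatures", "FeatureError", "extract_cycle",
           "relative_difference_table", "SHAPE_FEATURES", "VALUE_FEATURES"]

#: features expected to be insensitive to intracranial-capacitance changes
SHAPE_FEATURES = ("min_to_max_time", "PI", "RI", "MMR")
#: features expected to track the ICP operating point
VALUE_FEATURES = ("maximum", "minimum", "mean", "amplitude")


class FeatureError(ValueError):
    """Raised when a feature is undefined for the given cycle."""


@dataclass(frozen=True)
class CycleFeatures:
    maximum: float
    minimum: float
    mean: float
    amplitude: float
    min_to_max_time: float
    PI: float
    RI: float
    MMR: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def extract_cycle(ts: TimeSeries, t_start: float, T: float) -> CycleFeatures:
    """Extract the eight waveform features of the cycle starting at ``t_start``.

    Parameters
    ----------
    ts:
        Uniformly sampled signal covering at least ``[t_start, t_start + T]``.
    t_start:
        Cycle onset in seconds.
    T:
        Cardiac period in seconds (> 0).
    """
    if not T > 0:
        raise FeatureError("cycle length T must be positive")
    t, v = ts.t, ts.v
    if t.size < 3:
        raise FeatureError("signal too short")
    dt = ts.dt
    i0 = int(np.searchsorted(t, t_start - 1e-9))
    n_cycle = int(round(T / dt))
    i1 = i0 + n_cycle
    if i0 >= t.size or t[i0] > t_start + dt + 1e-9 or i1 >= t.size:
        raise FeatureError(
            f"signal [{t[0]:.4g}, {t[-1]:.4g}] s does not cover the requested "
            f"cycle [{t_start:.4g}, {t_start + T:.4g}] s")
    win = v[i0:i1]            # extrema on [t_start, t_start+T)
    imax = int(np.argmax(win))
    imin = int(np.argmin(win))
    maximum = float(win[imax])
    minimum = float(win[imin])
    # trapezoidal mean over the closed cycle [t_start, t_start+T]
    mean = float(np.trapezoid(v[i0:i1 + 1], dx=dt) / (t[i1] - t[i0]))
    amplitude = maximum - minimum
    if imax == imin:
        min_to_max = 0.0
    else:
        min_to_max = ((imax - imin) % n_cycle) * dt
    if mean <= 0:
        raise FeatureError(
            f"cycle mean {mean:.6g} is non-positive; PI and MMR are undefined")
    if maximum <= 0:
        raise FeatureError(f"cycle maximum {maximum:.6g} is non-positive; RI undefined")
    return CycleFeatures(
        maximum=maximum,
        minimum=minimum,
        mean=mean,
        amplitude=amplitude,
        min_to_max_time=min_to_max,
        PI=amplitude / mean,
        RI=amplitude / maximum,
        MMR=maximum / mean,
    )


def relative_difference_table(features_by_condition: pd.DataFrame,
                              feature_names: tuple[str, ...] = SHAPE_FEATURES,
                              condition_col: str = "ratio_cd") -> pd.DataFrame:
    """Per-feature relative spread (max-min)/min across conditions, in percent.

    ``features_by_condition`` holds one row per condition (plus arbitrary
    grouping columns such as age/territory already fixed by the caller) and
    one column per feature.  At least two conditions are required.
    """
    if len(features_by_condition) < 2:
        raise ValueError("need at least two conditions to compare")
    rows = []
    for name in feature_names:
        vals = features_by_condition[name].to_numpy(dtype=float)
        lo, hi = float(np.min(vals)), float(np.max(vals))
        if lo <= 0:
            rel = np.nan if hi > 0 else 0.0
        else:
            rel = 100.0 * (hi - lo) / lo
        rows.append({"feature": name, "relative_difference_pct": rel})
    out = pd.DataFrame(rows)
    out.attrs["conditions"] = list(features_by_condition[condition_col]) \
        if condition_col in features_by_condition else None
    return out
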