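"""Sensor figures of merit: entropy range, sensitivity and error.

Any window -> entropy estimator (direct FuzzyEn, a trained perceptron,
or the perceptron with trailing averaging) is characterized against ten
reference HR series at I_ex = 3.25: five chaotic (r = 0.0056, 0.0076,
0.0082, 0.0119, 0.0141) and five regular (r = 0.0068, 0.0070, 0.0099,
0.0105, 0.0108).  Per series, the estimator is evaluated on 100 windows
and averaged; the per-series means are then averaged across the five
series of each group.  The derived quantities are

    EnR     = En_av(chaos) - En_av(order)          (output range)
    EnSens  = EnR / Std_En(chaos)                  (sensitivity)
    EnErr   = 100 * Std_En(chaos) / EnR  [%]       (relative error)

where Std_En is the population standard deviation POOLED over all 500
individual window estimates of the group (5 series x 100 windows,
after any output smoothing).  The pooled reading — rather than the
deviation of the five per-series means — is what makes the
characteristics behave as observed: Std_En falls rapidly with window
length (per-window estimator noise shrinks), chaotic windows scatter
far more than regular ones, and trailing output averaging reduces
Std_En and hence EnErr roughly by the square root of the averaging
window.  EnSens * EnErr = 100 identically whenever EnR > 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .datasets import sliding_windows
from .fuzzyen import DEFAULT_PARAMS, FuzzyEnParams, fuzzy_entropy
from .hr import HRParams, generate_isi_series
from .sensor import SensorWeights, smooth_predictions

__all__ = [
    "CHAOTIC_R", "REGULAR_R", "CharacteristicsReport",
    "characterize", "fuzzyen_estimator", "sensor_estimator", "length_sweep",
]

#: r values of the five chaotic reference series (I_ex = 3.25)
CHAOTIC_R: tuple[float, ...] = (0.0056, 0.0076, 0.0082, 0.0119, 0.0141)
#: r values of the five regular reference series (I_ex = 3.25)
REGULAR_R: tuple[float, ...] = (0.0068, 0.0070, 0.0099, 0.0105, 0.0108)


@dataclass(frozen=True)
class CharacteristicsReport:
    """Sensor characteristics at one window length.

    ``defined`` is False when EnR <= 0 (degenerate estimator), in which
    case ensens/enerr are NaN.
    """

    estimator: str
    nl: int
    en_av_chaos: float
    en_av_order: float
    enr: float
    std_en_chaos: float
    std_en_order: float
    ensens: float
    enerr: float
    defined: bool

    def as_row(self) -> dict:
        return {
            "estimator": self.estimator, "nl": self.nl,
            "en_av_order": self.en_av_order, "en_av_chaos": self.en_av_chaos,
            "std_en_chaos": self.std_en_chaos, "ensens": self.ensens,
            "enerr_pct": self.enerr,
        }


def fuzzyen_estimator(params: FuzzyEnParams = DEFAULT_PARAMS) -> Callable:
    """Direct FuzzyEn estimator (the SFU sensor)."""
    return lambda window: fuzzy_entropy(window, params)


def sensor_estimator(weights: SensorWeights) -> Callable:
    """Trained-perceptron estimator (the SPE sensor)."""
    return lambda window: float(weights.predict(window)[0])


def _series_entropies(
    estimator: Callable,
    r: float,
    i_ex: float,
    nl: int,
    s: int,
    windows_per_series: int,
    long_len: int,
    smooth: int | None,
) -> np.ndarray:
    """Per-window estimates for one reference series (smoothed in-series)."""
    series = generate_isi_series(HRParams(r=r, i_ex=i_ex), long_len)
    win = sliding_windows(series.values, nl, s, windows_per_series)
    try:
        values = np.array([estimator(w) for w in win], dtype=float)
    except Exception as exc:
        raise RuntimeError(f"estimator failed at r={r}: {exc}") from exc
    if smooth is not None:
        values = smooth_predictions(values, smooth)
    return values


def characterize(
    estimator: Callable,
    nl: int = 50,
    s: int = 4,
    windows_per_series: int = 100,
    long_len: int = 500,
    i_ex: float = 3.25,
    smooth: int | None = None,
    label: str = "estimator",
) -> CharacteristicsReport:
    """Characterize a window -> entropy estimator at window length nl.

    ``smooth`` applies a trailing moving average of that many points to
    the per-window estimates within each series before averaging --
    the "averaging over 20" operating mode of the perceptron sensor.
    """
    chaos = [_series_entropies(estimator, r, i_ex, nl, s,
                               windows_per_series, long_len, smooth)
             for r in CHAOTIC_R]
    order = [_series_entropies(estimator, r, i_ex, nl, s,
                               windows_per_series, long_len, smooth)
             for r in REGULAR_R]
    # average within each series first, then across series
    en_av_chaos = float(np.mean([v.mean() for v in chaos]))
    en_av_order = float(np.mean([v.mean() for v in order]))
    enr = en_av_chaos - en_av_order
    # deviation pooled over all window estimates of the group
    std_chaos = float(np.concatenate(chaos).std())
    std_order = float(np.concatenate(order).std())
    defined = enr > 0 and std_chaos > 0
    ensens = enr / std_chaos if defined else math.nan
    enerr = 100.0 * std_chaos / enr if defined else math.nan
    return CharacteristicsReport(
        estimator=label, nl=nl,
        en_av_chaos=en_av_chaos, en_av_order=en_av_order, enr=enr,
        std_en_chaos=std_chaos, std_en_order=std_order,
        ensens=ensens, enerr=enerr, defined=defined,
    )


def length_sweep(
    estimator_factory: Callable[[int], Callable],
    nl_grid: Sequence[int] = tuple(range(10, 101, 10)),
    s: int = 4,
    windows_per_series: int = 100,
    long_len: int = 500,
    i_ex: float = 3.25,
    smooth: int | None = None,
    label: str = "estimator",
) -> list[CharacteristicsReport]:
    """Characteristics as a function of the window length.

    ``estimator_factory(nl)`` must return an estimator accepting
    nl-length windows; windows are re-cut from the same long series for
    every nl.
    """
    nl_grid = list(nl_grid)
    if not nl_grid:
        raise ValueError("nl_grid must be non-empty")
    return [
        characterize(estimator_factory(nl), nl=nl, s=s,
                     windows_per_series=windows_per_series,
                     long_len=long_len, i_ex=i_ex, smooth=smooth,
                     label=label)
        for nl in nl_grid
    ]
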