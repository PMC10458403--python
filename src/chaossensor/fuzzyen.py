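"""Fuzzy entropy (FuzzyEn) of short time series.

FuzzyEn measures the conditional probability that segments of a series
which are similar at embedding length m remain similar at length m+1,
with "similar" graded by an exponential fuzzy membership of the
Chebyshev distance between baseline-removed segments:

    D_ij = exp(-(d_ij)^r2 / r1).

The entropy is  FuzzyEn = ln(phi^m) - ln(phi^(m+1))  where phi^m is the
average pairwise similarity over all ordered template pairs (i != j).
Smaller FuzzyEn means a more regular series; chaotic ISI series score
several times higher than periodic ones.

Conventions (the defining equations leave two details open):

* N - m template vectors are used at BOTH lengths m and m+1, so the two
  phi averages run over comparable pair sets.
* The exponent groups as exp(-(d^r2)/r1) (Chen-style membership).
* ``std`` in the relative-tolerance mode is the population standard
  deviation of the window itself, recomputed per window.
* A constant series has sigma = 0, which would zero the tolerance; by
  convention its FuzzyEn is 0 (a constant series is maximally regular).

The tuned operating point used throughout the package is m=1, r2=1,
r1 = 0.01 * std: it maximizes sensor sensitivity on ISI windows of
10..100 elements.  Note that at m=1 the length-1 templates are
identically zero after baseline removal, so phi^1 = 1 and the entropy is
driven entirely by the first differences of the series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "FuzzyEnParams", "template_vectors", "pair_distance",
    "fuzzy_similarity", "phi", "fuzzy_entropy", "optimize_params",
]


@dataclass(frozen=True)
class FuzzyEnParams:
    """FuzzyEn parameterization.

    m : embedding dimension (>= 1).
    r2 : fuzzy exponent (> 0).
    r1_mode : "std_relative" (tolerance = r1_value * window std) or
        "absolute" (tolerance = r1_value).
    r1_value : tolerance coefficient or absolute tolerance (> 0).
    """

    m: int = 1
    r2: float = 1.0
    r1_mode: Literal["std_relative", "absolute"] = "std_relative"
    r1_value: float = 0.01

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not self.r2 > 0:
            raise ValueError("r2 must be > 0")
        if not self.r1_value > 0:
            raise ValueError("r1_value must be > 0")
        if self.r1_mode not in ("std_relative", "absolute"):
            raise ValueError(f"unknown r1_mode {self.r1_mode!r}")

    def resolve_r1(self, series: np.ndarray) -> float:
        """Absolute tolerance for a concrete series (0 if std is 0)."""
        if self.r1_mode == "absolute":
            return float(self.r1_value)
        return float(self.r1_value * np.asarray(series, dtype=float).std())


DEFAULT_PARAMS = FuzzyEnParams()


def _templates(x: np.ndarray, length: int, count: int) -> np.ndarray:
    t = np.lib.stride_tricks.sliding_window_view(x, length)[:count]
    return t - t.mean(axis=1, keepdims=True)


def template_vectors(series: Sequence[float], m: int) -> np.ndarray:
    """The first N-m consecutive length-m segments, each minus its own mean.

    Returns an (N-m, m) array.  Using N-m vectors (not N-m+1) keeps the
    template count identical between the length-m and length-(m+1) sets
    compared by :func:`fuzzy_entropy`.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n <= m:
        raise ValueError(f"series too short for embedding: N={n} <= m={m}")
    return _templates(x, m, n - m)


def pair_distance(a: Sequence[float], b: Sequence[float]) -> float:
    """Chebyshev distance max_k |a_k - b_k| between two template vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.max(np.abs(a - b)))


def fuzzy_similarity(d, r1: float, r2: float):
    """Fuzzy membership exp(-(d^r2)/r1); 1 at d=0, decreasing in d."""
    if not r1 > 0:
        raise ValueError("r1 must be > 0")
    return np.exp(-(np.asarray(d, dtype=float) ** r2) / r1)


def phi(templates: np.ndarray, r1: float, r2: float) -> float:
    """Mean over i of the mean similarity of template i to all j != i."""
    t = np.asarray(templates, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2:
        raise ValueError("need at least 2 templates")
    d = np.abs(t[:, None, :] - t[None, :, :]).max(axis=2)
    sim = fuzzy_similarity(d, r1, r2)
    n = t.shape[0]
    return float(((sim.sum(axis=1) - 1.0) / (n - 1)).mean())


def fuzzy_entropy(series: Sequence[float], params: FuzzyEnParams = DEFAULT_PARAMS) -> float:
    """FuzzyEn = ln(phi^m) - ln(phi^(m+1)) of a finite series.

    A constant series returns 0 by convention in std-relative mode.
    """
    x = np.asarray(series, dtype=float)
    m = params.m
    if x.size <= m + 1:
        raise ValueError(
            f"series too short: N={x.size} must exceed m+1={m + 1}"
        )
    r1 = params.resolve_r1(x)
    if r1 == 0.0:
        return 0.0  # constant series, std-relative tolerance
    # N - m template pairs at BOTH scales: the length-(m+1) set keeps all
    # N - m windows so the two phi averages run over comparable pairs
    count = x.size - m
    return float(
        np.log(phi(_templates(x, m, count), r1, params.r2))
        - np.log(phi(_templates(x, m + 1, count), r1, params.r2))
    )


def optimize_params(
    windows: np.ndarray,
    chaos_mask: np.ndarray,
    m_grid: Sequence[int] = (1, 2, 3),
    r2_grid: Sequence[float] = (1, 2, 3, 4, 5),
    r1_grid: Sequence[float] = (0.005, 0.01, 0.05, 0.1, 0.2, 0.4),
) -> tuple[FuzzyEnParams, float]:
    """Grid-search FuzzyEn parameters maximizing sensor sensitivity.

    ``windows`` is a (n, NL) matrix of ISI windows and ``chaos_mask`` a
    boolean row label (True = from a chaotic series).  Sensitivity is
    (mean chaos entropy - mean order entropy) / std of chaotic window
    entropies, a pooled-window analogue of the sensor's EnSens.  Returns
    the best parameter set and its sensitivity.
    """
    windows = np.asarray(windows, dtype=float)
    chaos_mask = np.asarray(chaos_mask, dtype=bool)
    if windows.shape[0] != chaos_mask.size:
        raise ValueError("windows and chaos_mask disagree in length")
    best: tuple[FuzzyEnParams, float] | None = None
    for m in m_grid:
        for r2 in r2_grid:
            for r1 in r1_grid:
                p = FuzzyEnParams(m=m, r2=float(r2), r1_value=float(r1))
                en = np.array([fuzzy_entropy(w, p) for w in windows])
                spread = en[chaos_mask].std()
                if spread == 0:
                    continue
                sens = (en[chaos_mask].mean() - en[~chaos_mask].mean()) / spread
                if best is None or sens > best[1]:
                    best = (p, float(sens))
    if best is None:
        raise ValueError("no parameter combination produced a defined sensitivity")
    return best
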