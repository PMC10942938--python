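"""Quadrant categorization and period comparison of vessel-noise conditions.

A station-month is placed in a two-dimensional dominance × exceedance
framework: high/low dominance (percent of hours with vessel noise) crossed
with high/low exceedance (dB added when vessels are present).  Thresholds are
management choices, so they are always caller-supplied; values exactly at a
threshold classify as "high".

Period comparisons use empirical cumulative distributions of 1-min samples:
the lower empirical quantile (smallest sample value whose cumulative fraction
reaches q, no interpolation) lets statements like "75% of the time exceedance
was at or below 2 dB" read directly off the curve.  Between-period change in
(dominance, sound level) is classified by delta sign pattern: reduction in
both (green), dominance down / level up (purple), dominance up / level down
(red), no change within tolerance (black), plus an explicit "increase-both"
class for increases on both axes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import UndefinedMetricError

__all__ = [
    "QuadrantLabel",
    "EcdfCurve",
    "ChangeClassification",
    "categorize",
    "ecdf",
    "ecdf_quantile",
    "compare_periods",
    "classify_change",
]


@dataclass(frozen=True)
class QuadrantLabel:
    """Dominance/exceedance quadrant with the thresholds that produced it."""

    label: str  # "HD-HE" | "HD-LE" | "LD-HE" | "LD-LE"
    dominance_threshold: float
    exceedance_threshold: float


@dataclass
class EcdfCurve:
    """Sorted sample values with cumulative fractions in (0, 1]."""

    values: np.ndarray
    fractions: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"value_db": self.values, "fraction": self.fractions})


@dataclass(frozen=True)
class ChangeClassification:
    """Between-period change class with the two deltas that produced it."""

    label: str  # green | purple | red | black | increase-both
    delta_dominance: float
    delta_level_db: float


def categorize(
    dominance_percent: float,
    exceedance_db: float,
    thresholds: tuple[float, float],
) -> QuadrantLabel:
    """Assign a dominance/exceedance quadrant.

    ``thresholds`` is (dominance %, exceedance dB); values at or above a
    threshold are "high" (deterministic tie rule).
    """
    td, te = thresholds
    dom = "HD" if dominance_percent >= td else "LD"
    exc = "HE" if exceedance_db >= te else "LE"
    return QuadrantLabel(f"{dom}-{exc}", float(td), float(te))


def ecdf(values: Sequence[float]) -> EcdfCurve:
    """Empirical cumulative distribution of a sample."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise UndefinedMetricError("ECDF of an empty sample is undefined")
    return EcdfCurve(values=v, fractions=np.arange(1, v.size + 1) / v.size)


def ecdf_quantile(values: Sequence[float], q: float) -> float:
    """Lower empirical quantile: smallest v with fraction(<= v) >= q."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise UndefinedMetricError("quantile of an empty sample is undefined")
    if not 0 < q <= 1:
        raise UndefinedMetricError(f"quantile order {q} outside (0, 1]")
    idx = int(np.ceil(q * v.size)) - 1
    return float(v[idx])


def compare_periods(
    values_a: Sequence[float],
    values_b: Sequence[float],
    quantiles: Sequence[float] = (0.25, 0.5, 0.75),
) -> tuple[pd.DataFrame, EcdfCurve, EcdfCurve]:
    """Quantile shift table between two periods plus both ECDF curves.

    Returns a tidy frame with columns ``quantile, value_a, value_b, shift``
    (shift = B − A) and the two curves for plotting or export.
    """
    rows = []
    for q in quantiles:
        qa = ecdf_quantile(values_a, q)
        qb = ecdf_quantile(values_b, q)
        rows.append({"quantile": q, "value_a": qa, "value_b": qb, "shift": qb - qa})
    return pd.DataFrame(rows), ecdf(values_a), ecdf(values_b)


def classify_change(
    dominance_before: float,
    dominance_after: float,
    level_before: float,
    level_after: float,
    tolerance: tuple[float, float] = (0.0, 0.0),
) -> ChangeClassification:
    """Classify the between-period change in (dominance, sound level).

    ``tolerance`` is (dominance %, level dB): a delta within tolerance in
    magnitude counts as no change on that axis.  Both axes unchanged → black.
    Otherwise the sign pattern maps to green (both down), purple (dominance
    down, level up), red (dominance up, level down), or the explicit
    "increase-both" class.  When exactly one axis is within tolerance, its
    raw delta sign is used as the tie-break (a zero raw delta counts as a
    reduction), keeping the mapping total and deterministic.
    """
    dd = dominance_after - dominance_before
    dl = level_after - level_before
    td, tl = tolerance

    def thresholded_sign(delta: float, tol: float) -> int:
        return 0 if abs(delta) <= tol else (1 if delta > 0 else -1)

    sd, sl = thresholded_sign(dd, td), thresholded_sign(dl, tl)
    if sd == 0 and sl == 0:
        label = "black"
    else:
        # tie-break a single null axis by its raw sign (0 -> reduction)
        sd = sd if sd != 0 else (1 if dd > 0 else -1)
        sl = sl if sl != 0 else (1 if dl > 0 else -1)
        label = {
            (-1, -1): "green",
            (-1, 1): "purple",
            (1, -1): "red",
            (1, 1): "increase-both",
        }[(sd, sl)]
    return ChangeClassification(label=label, delta_dominance=dd, delta_level_db=dl)
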