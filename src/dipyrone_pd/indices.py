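"""Composite hemorheological indices and metabolite correlation analysis.

Two bespoke indices summarise the coagulation/red-cell state so that it can
be regressed against plasma metabolite concentration:

* composite: ``PT + (Hb + Hct) / RBC**APTT_ratio`` with each input in its
  standard unit (PT %, Hb g/dL, Hct %, RBC x10^12/L, APTT_ratio
  dimensionless). The exponent couples red-cell mass to the intrinsic
  coagulation pathway; the index is monotone increasing in PT, Hb and Hct
  and, for RBC > 1 and positive exponent, decreasing in RBC.
* mcv_pt: the simple sum ``MCV + PT`` (fL + %), linear in both inputs.

Index-vs-metabolite association is the ordinary squared Pearson correlation
with its two-sided p-value. By default the index is evaluated on cohort-mean
parameter values per time point, pairing one index curve with one
concentration curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import StudyDataset

__all__ = [
    "CompositeIndexPoint",
    "CorrelationResult",
    "composite_index",
    "mcv_pt_index",
    "index_series",
    "pearson_r2",
]

COMPOSITE_PARAMETERS = ("PT", "Hb", "Hct", "RBC", "APTT_ratio")
MCV_PT_PARAMETERS = ("MCV", "PT")


@dataclass(frozen=True)
class CompositeIndexPoint:
    time_h: float
    value: float
    n_animals: int
    animal_id: str | None = None  # None for cohort-mean aggregation


@dataclass(frozen=True)
class CorrelationResult:
    r_squared: float
    p_value: float
    n: int


def composite_index(pt: float, hb: float, hct: float, rbc: float, aptt_ratio: float) -> float:
    """``PT + (Hb + Hct) / RBC**APTT_ratio``; requires RBC > 0."""
    if rbc <= 0:
        raise ValueError("RBC must be > 0")
    denom = rbc**aptt_ratio
    value = pt + (hb + hct) / denom
    if not math.isfinite(value):
        raise ValueError("composite index is non-finite for these inputs")
    return value


def mcv_pt_index(mcv: float, pt: float) -> float:
    """``MCV + PT``, the linear red-cell-size / clotting-time composite."""
    return mcv + pt


_INDEX_FUNCS = {
    "composite": (COMPOSITE_PARAMETERS, lambda row: composite_index(*row)),
    "mcv_pt": (MCV_PT_PARAMETERS, lambda row: mcv_pt_index(*row)),
}


def index_series(
    dataset: StudyDataset,
    index: str = "composite",
    aggregation: str = "cohort_mean",
    time_window: tuple[float, float] = (0.0, 72.0),
) -> list[CompositeIndexPoint]:
    """Evaluate an index at every scheduled time inside ``time_window``.

    ``cohort_mean`` averages each constituent parameter across animals per
    time point before evaluating the (generally nonlinear) index;
    ``per_animal`` evaluates one series per animal.
    """
    if index not in _INDEX_FUNCS:
        raise ValueError(f"unknown index {index!r}")
    if aggregation not in ("cohort_mean", "per_animal"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    params, func = _INDEX_FUNCS[index]
    t0, t1 = time_window
    times = [t for t in dataset.schedule.all_times if t0 <= t <= t1]
    animals = dataset.animals

    values: dict[tuple[str, str], dict[float, float]] = {}
    for animal in animals:
        for p in params:
            s = dataset.get_series(animal, p)  # KeyError if a constituent is missing
            values[(animal, p)] = dict(s.samples)

    points: list[CompositeIndexPoint] = []
    for t in times:
        for animal in animals:
            for p in params:
                if t not in values[(animal, p)]:
                    raise ValueError(f"{animal}/{p} missing a sample at t={t}")
        if aggregation == "cohort_mean":
            row = [float(np.mean([values[(a, p)][t] for a in animals])) for p in params]
            points.append(CompositeIndexPoint(t, func(row), n_animals=len(animals)))
        else:
            for animal in animals:
                row = [values[(animal, p)][t] for p in params]
                points.append(
                    CompositeIndexPoint(t, func(row), n_animals=1, animal_id=animal)
                )
    return points


def index_frame(points: list[CompositeIndexPoint]) -> pd.DataFrame:
    rows = [
        {"time_h": p.time_h, "index_value": p.value, "n_animals": p.n_animals,
         **({"animal_id": p.animal_id} if p.animal_id is not None else {})}
        for p in points
    ]
    return pd.DataFrame(rows)


def pearson_r2(x, y) -> CorrelationResult:
    """Squared Pearson correlation with the two-sided zero-correlation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("correlation needs n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r_squared=float(r**2), p_value=float(p), n=int(x.size))
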