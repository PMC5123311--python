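"""Pharmacodynamic effect analysis: AUEC, A/B change ratio, paired test, RSD%.

For each blood parameter and animal the area under the effect curve (AUEC)
is computed by the linear trapezoidal rule over the baseline window
B = [-36, 0] h and the post-dose window A = [0, 72] h. The cohort-level
change ratio normalises the time-averaged post-dose level by the
time-averaged baseline level::

    ratio = (B/36 - A/72) / (B/36)

so the ratio is positive when the parameter fell after dosing, negative when
it rose, and 0 when unchanged. Baseline-vs-effect significance uses the
two-sided paired Student t test on the per-animal differences A/72 - B/36,
and between-animal variability is summarised as RSD% = 100 * SD / |mean|,
pooled separately over baseline (t <= 0) and post-dose (t > 0) observations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import StudyDataset

__all__ = [
    "DegenerateVarianceError",
    "AUECPair",
    "EffectSummary",
    "trapezoid_auec",
    "ab_ratio",
    "paired_baseline_effect_test",
    "rsd_percent",
    "make_effect_table",
    "effect_table_frame",
]

BASELINE_HOURS = 36.0
EFFECT_HOURS = 72.0


class DegenerateVarianceError(ValueError):
    """Paired differences (or pooled values) have zero variance."""


@dataclass(frozen=True)
class AUECPair:
    """Per-animal AUEC over the post-dose (A) and baseline (B) windows."""

    parameter: str
    a: float
    b: float
    t_a: float = EFFECT_HOURS
    t_b: float = BASELINE_HOURS


@dataclass(frozen=True)
class EffectSummary:
    """One row of the per-parameter effect table."""

    parameter: str
    a_mean: float
    a_sd: float
    b_mean: float
    b_sd: float
    ab_ratio: float
    p_value: float              # NaN when the paired differences are degenerate
    rsd_baseline_pct: float
    rsd_effect_pct: float
    dynamic_max_mean: float
    dynamic_max_sd: float
    dynamic_min_mean: float
    dynamic_min_sd: float
    n_animals: int
    degenerate: bool = False


def trapezoid_auec(samples, window) -> float:
    """Area under the piecewise-linear interpolant restricted to ``window``.

    ``samples`` is an ordered list of (time_h, value); window edges that fall
    between samples are handled by linear interpolation to the edge.
    """
    t0, t1 = float(window[0]), float(window[1])
    if not t0 < t1:
        raise ValueError(f"empty or inverted window [{t0}, {t1}]")
    pts = sorted(samples)
    t = np.array([p[0] for p in pts], dtype=float)
    v = np.array([p[1] for p in pts], dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("sample times must be strictly increasing")
    if t0 < t[0] or t1 > t[-1]:
        raise ValueError(
            f"window [{t0}, {t1}] outside sampled range [{t[0]}, {t[-1]}]"
        )
    inner = (t > t0) & (t < t1)
    grid = np.concatenate(([t0], t[inner], [t1]))
    vals = np.concatenate(([np.interp(t0, t, v)], v[inner], [np.interp(t1, t, v)]))
    return float(np.trapezoid(vals, grid))


def ab_ratio(a: float, b: float, t_a: float = EFFECT_HOURS, t_b: float = BASELINE_HOURS) -> float:
    """Baseline-normalised change ratio (B/T_B - A/T_A) / (B/T_B)."""
    if t_a <= 0 or t_b <= 0:
        raise ValueError("window durations must be > 0")
    if b == 0:
        raise ZeroDivisionError("baseline AUEC B must be nonzero")
    b_avg = b / t_b
    return (b_avg - a / t_a) / b_avg


def paired_baseline_effect_test(per_animal_a_means, per_animal_b_means) -> float:
    """Two-sided paired t probability on per-animal differences A/T_A - B/T_B.

    Inputs are the per-animal time-averaged levels, paired by animal.
    Raises :class:`DegenerateVarianceError` when the differences have zero
    variance (the t statistic is undefined there).
    """
    a = np.asarray(per_animal_a_means, dtype=float)
    b = np.asarray(per_animal_b_means, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired lists must have equal length")
    if a.size < 2:
        raise ValueError("paired test needs n >= 2 animals")
    d = a - b
    if np.std(d, ddof=1) == 0:
        if np.all(d == 0):
            return 1.0  # identical pairs: t = 0 exactly
        raise DegenerateVarianceError("paired differences have zero variance")
    res = stats.ttest_rel(a, b)
    return float(res.pvalue)


def rsd_percent(values) -> float:
    """Relative standard deviation, 100 * sample SD / |mean|."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("RSD% needs n >= 2")
    mean = v.mean()
    if mean == 0:
        raise ZeroDivisionError("RSD% undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / abs(mean))


def _auec_pair(series, parameter: str) -> AUECPair:
    a = trapezoid_auec(series.samples, (0.0, EFFECT_HOURS))
    b = trapezoid_auec(series.samples, (-BASELINE_HOURS, 0.0))
    return AUECPair(parameter, a=a, b=b)


def make_effect_table(dataset: StudyDataset, parameters=None) -> list[EffectSummary]:
    """Per-parameter effect summaries over the whole cohort.

    Cohort ratio is computed from the cohort-mean A and B; the p-value from
    the paired t test on per-animal A/72 vs B/36; RSD% pools baseline
    (t <= 0, the t = 0 control sample counts as baseline) and post-dose
    (t > 0) observations separately; dynamic extrema are the cohort mean and
    SD of the per-animal post-dose maxima and minima.
    """
    if parameters is None:
        parameters = dataset.parameters
    animals = dataset.animals
    out = []
    for parameter in parameters:
        series = [dataset.get_series(a, parameter) for a in animals]
        pairs = [_auec_pair(s, parameter) for s in series]
        a_vals = np.array([p.a for p in pairs])
        b_vals = np.array([p.b for p in pairs])
        diffs = a_vals / EFFECT_HOURS - b_vals / BASELINE_HOURS
        degenerate = bool(np.std(diffs, ddof=1) == 0) if len(diffs) > 1 else True
        try:
            p_value = paired_baseline_effect_test(a_vals / EFFECT_HOURS, b_vals / BASELINE_HOURS)
        except DegenerateVarianceError:
            p_value = math.nan

        base_pool, post_pool, post_max, post_min = [], [], [], []
        for s in series:
            t = np.array(s.times)
            v = np.array(s.values)
            base_pool.extend(v[t <= 0].tolist())
            post = v[t > 0]
            post_pool.extend(post.tolist())
            post_max.append(post.max())
            post_min.append(post.min())

        out.append(
            EffectSummary(
                parameter=parameter,
                a_mean=float(a_vals.mean()),
                a_sd=float(a_vals.std(ddof=1)) if len(animals) > 1 else 0.0,
                b_mean=float(b_vals.mean()),
                b_sd=float(b_vals.std(ddof=1)) if len(animals) > 1 else 0.0,
                ab_ratio=ab_ratio(float(a_vals.mean()), float(b_vals.mean())),
                p_value=p_value,
                rsd_baseline_pct=rsd_percent(base_pool),
                rsd_effect_pct=rsd_percent(post_pool),
                dynamic_max_mean=float(np.mean(post_max)),
                dynamic_max_sd=float(np.std(post_max, ddof=1)) if len(animals) > 1 else 0.0,
                dynamic_min_mean=float(np.mean(post_min)),
                dynamic_min_sd=float(np.std(post_min, ddof=1)) if len(animals) > 1 else 0.0,
                n_animals=len(animals),
                degenerate=degenerate,
            )
        )
    return out


def effect_table_frame(summaries: list[EffectSummary]) -> pd.DataFrame:
    """Tabular view mirroring the reported summary-table column layout."""
    cols = [
        "parameter", "dynamic_max_mean", "dynamic_max_sd", "dynamic_min_mean",
        "dynamic_min_sd", "a_mean", "a_sd", "b_mean", "b_sd", "ab_ratio",
        "p_value", "rsd_baseline_pct", "rsd_effect_pct", "n_animals",
    ]
    return pd.DataFrame([{c: getattr(s, c) for c in cols} for s in summaries])
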