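"""Leave-one-out (LOO) validation of the metabolite <-> index relationship.

A univariate ordinary-least-squares model y = b0 + b1*x is validated by the
leave-one-out procedure: PRESS is the sum of squared prediction errors with
each point predicted from a refit that excludes it, SS is the total sum of
squares of y about its mean, and Q^2 = 1 - PRESS/SS is the cross-validated
coefficient of determination. For OLS the LOO residual has the exact
hat-matrix form e_i / (1 - h_ii), so no explicit refits are needed; because
0 < h_ii < 1, PRESS >= SSE and hence Q^2 <= R^2 always.

The asymptotic Q^2 approximates the cross-validated coefficient from the
fitted R^2 and the sample size alone. No single published form exists, so
the variant is always recorded in the report; the default is

    Q2_asym = 1 - (1 - R^2) * ((n - 1) / (n - p - 1))^2

with an unsquared "adjusted" variant selectable by name.

A model is accepted ("fully predictive") when all four gate criteria hold:
0 < Q2_asym - Q2 < 1, Q2 >= 0.65, R2 >= 0.85 and Q2 - R2 < 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LinearModelFit",
    "LOOValidationReport",
    "Q2_ASYM_VARIANTS",
    "fit_univariate",
    "loo_press_q2",
    "q2_asymptotic",
    "apply_gate",
    "validate_relationship",
]

Q2_THRESHOLD = 0.65
R2_THRESHOLD = 0.85


@dataclass(frozen=True)
class LinearModelFit:
    slope: float
    intercept: float
    r_squared: float
    ss_total: float
    sse: float
    n: int
    p: int = 1
    degenerate: bool = False  # ss_total == 0 (constant response)


@dataclass(frozen=True)
class LOOValidationReport:
    q2: float
    r2: float
    q2_asym: float
    ss: float
    press: float
    sse: float
    n: int
    variant: str
    q2_minus_r2: float
    q2asym_minus_q2: float
    crit_q2asym_gap: bool   # 0 < Q2_asym - Q2 < 1
    crit_q2: bool           # Q2 >= 0.65
    crit_r2: bool           # R2 >= 0.85
    crit_q2_lt_r2: bool     # Q2 - R2 < 0 (strict)
    passed: bool

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _check_xy(x, y, min_n: int = 4):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < min_n:
        raise ValueError(f"need n >= {min_n} observations, got {x.size}")
    if np.all(x == x[0]):
        raise ValueError("x is constant; the slope is unidentifiable")
    return x, y


def fit_univariate(x, y) -> LinearModelFit:
    """OLS fit of y on x with R^2 = 1 - SSE/SS_total."""
    x, y = _check_xy(x, y)
    design = np.column_stack([np.ones_like(x), x])
    (b0, b1), *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - (b0 + b1 * x)
    sse = float(resid @ resid)
    ss_total = float(np.sum((y - y.mean()) ** 2))
    if ss_total == 0:
        return LinearModelFit(float(b1), float(b0), 0.0, 0.0, sse, int(x.size),
                              degenerate=True)
    return LinearModelFit(
        slope=float(b1),
        intercept=float(b0),
        r_squared=1.0 - sse / ss_total,
        ss_total=ss_total,
        sse=sse,
        n=int(x.size),
    )


def loo_press_q2(x, y) -> tuple[float, float, float]:
    """(PRESS, Q^2, SS) for the univariate OLS model, via the hat matrix.

    h_ii = 1/n + (x_i - x_bar)^2 / Sxx; LOO residual e_i / (1 - h_ii).
    """
    x, y = _check_xy(x, y)
    n = x.size
    for i in range(n):
        rest = np.delete(x, i)
        if np.all(rest == rest[0]):
            raise ValueError(f"leave-one-out subset {i} has constant x")
    fit = fit_univariate(x, y)
    ss = float(np.sum((y - y.mean()) ** 2))
    if ss == 0:
        raise ValueError("SS = 0 (constant y); Q^2 is undefined")
    resid = y - (fit.intercept + fit.slope * x)
    sxx = float(np.sum((x - x.mean()) ** 2))
    h = 1.0 / n + (x - x.mean()) ** 2 / sxx
    press = float(np.sum((resid / (1.0 - h)) ** 2))
    return press, 1.0 - press / ss, ss


Q2_ASYM_VARIANTS = {
    "squared_ratio": lambda r2, n, p: 1.0 - (1.0 - r2) * ((n - 1) / (n - p - 1)) ** 2,
    "adjusted": lambda r2, n, p: 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1),
}


def q2_asymptotic(r_squared: float, n: int, p: int = 1, variant: str = "squared_ratio") -> float:
    """Asymptotic cross-validated coefficient from R^2 and the sample size."""
    if not 0.0 <= r_squared <= 1.0:
        raise ValueError("r_squared must lie in [0, 1]")
    if n <= p + 1:
        raise ValueError("need n > p + 1")
    try:
        f = Q2_ASYM_VARIANTS[variant]
    except KeyError:
        raise ValueError(f"unknown Q2_asym variant {variant!r}") from None
    return float(f(r_squared, n, p))


def apply_gate(q2: float, r2: float, q2_asym: float) -> dict:
    """The four acceptance criteria and their conjunction.

    0 < Q2_asym - Q2 < 1; Q2 >= 0.65; R2 >= 0.85; Q2 - R2 < 0 (strict).
    """
    gap = q2_asym - q2
    flags = {
        "crit_q2asym_gap": bool(0.0 < gap < 1.0),
        "crit_q2": bool(q2 >= Q2_THRESHOLD),
        "crit_r2": bool(r2 >= R2_THRESHOLD),
        "crit_q2_lt_r2": bool(q2 - r2 < 0.0),
    }
    flags["passed"] = all(flags.values())
    return flags


def validate_relationship(x, y, variant: str = "squared_ratio") -> LOOValidationReport:
    """Full LOO validation of the univariate metabolite -> index model."""
    fit = fit_univariate(x, y)
    if fit.degenerate:
        raise ValueError("constant y; validation statistics are undefined")
    press, q2, ss = loo_press_q2(x, y)
    q2_asym = q2_asymptotic(fit.r_squared, fit.n, fit.p, variant)
    flags = apply_gate(q2, fit.r_squared, q2_asym)
    return LOOValidationReport(
        q2=q2,
        r2=fit.r_squared,
        q2_asym=q2_asym,
        ss=ss,
        press=press,
        sse=fit.sse,
        n=fit.n,
        variant=variant,
        q2_minus_r2=q2 - fit.r_squared,
        q2asym_minus_q2=q2_asym - q2,
        **flags,
    )
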