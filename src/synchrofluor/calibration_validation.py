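"""Calibration regression and ICH-style validation statistics.

Implements the statistics layer of a univariate spectrofluorimetric method
validation: ordinary least-squares calibration with regression diagnostics
(Sy/x, Sa, Sb), detection and quantitation limits (LOD = 3.3*Sa/b,
LOQ = 10*Sa/b, with sigma taken as the standard deviation of the intercept),
recovery summaries, intra-/inter-day precision cells, and the two-sample
method-comparison tests (pooled-variance Student's t and the variance-ratio
F test) customarily used to compare a proposed method against a
pharmacopoeial reference at p = 0.05.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .eem_core import ValidationError

__all__ = [
    "CalibrationCurve",
    "SensitivityLimits",
    "RecoveryRecord",
    "MethodComparison",
    "PrecisionCell",
    "SingularDesignError",
    "fit_calibration",
    "sensitivity_limits",
    "recovery_stats",
    "recoveries_from_pairs",
    "student_t",
    "f_test",
    "compare_methods",
    "precision_study",
]

#: Two-sided significance level of the bundled critical values.
ALPHA = 0.05


class SingularDesignError(ValidationError):
    """All calibration concentrations coincide; the slope is undefined."""


@dataclass
class CalibrationCurve:
    """Linear calibration 1D = a + b*C with OLS diagnostics.

    ``s_yx`` is the standard deviation of residuals, ``s_a``/``s_b`` the
    standard deviations of intercept and slope; ``range`` is the validated
    linearity range in ug/ml.
    """

    analyte: str
    wavelength: float
    a: float
    b: float
    r: float
    s_yx: float
    s_a: float
    s_b: float
    n: int
    range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError("calibration needs n >= 2 points")
        if not (-1.0 - 1e-12 <= self.r <= 1.0 + 1e-12):
            raise ValidationError(f"correlation coefficient out of range: {self.r}")
        if min(self.s_yx, self.s_a, self.s_b) < 0:
            raise ValidationError("regression standard deviations must be >= 0")

    def predict(self, conc: float) -> float:
        return self.a + self.b * conc


@dataclass(frozen=True)
class SensitivityLimits:
    """ICH detection/quantitation limits in ug/ml; LOQ/LOD = 10/3.3 exactly."""

    lod: float
    loq: float


@dataclass(frozen=True)
class RecoveryRecord:
    """One accuracy determination: recovery = 100 * found / taken (percent)."""

    taken: float
    found: float

    @property
    def recovery(self) -> float:
        if self.taken == 0:
            raise ValidationError("recovery undefined for taken = 0")
        return 100.0 * self.found / self.taken


@dataclass(frozen=True)
class MethodComparison:
    """Two-sample comparison: pooled-variance t and variance-ratio F at p=0.05."""

    t: float
    f: float
    df_t: int
    df_f: tuple[int, int]
    t_critical: float
    f_critical: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int

    @property
    def significant(self) -> bool:
        return self.t > self.t_critical or self.f > self.f_critical


@dataclass(frozen=True)
class PrecisionCell:
    """Per-cell precision summary: %RSD = 100*sd/mean, %error = %RSD/sqrt(n)."""

    mode: str  # "intra-day" or "inter-day"
    concentration: float
    mean_recovery: float
    sd: float
    rsd: float
    error: float
    n: int
    day: object = None


def fit_calibration(
    concs: Sequence[float],
    amplitudes: Sequence[float],
    analyte: str = "",
    wavelength: float = float("nan"),
    conc_range: tuple[float, float] | None = None,
) -> CalibrationCurve:
    """Ordinary least-squares fit of derivative amplitude against concentration.

    Diagnostics follow the standard calibration formulas:
    s_yx = sqrt(SS_res / (n-2)), s_b = s_yx / sqrt(Sxx),
    s_a = s_yx * sqrt(sum(x^2) / (n * Sxx)).  With exactly two points the fit
    is saturated: r = +/-1 and the residual diagnostics are reported as 0
    with a warning.
    """
    x = np.asarray(concs, dtype=float)
    y = np.asarray(amplitudes, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("concentrations and amplitudes must be equal-length 1-D")
    n = x.size
    if n < 2:
        raise ValidationError("calibration needs at least 2 points")
    if np.unique(x).size < 2:
        raise SingularDesignError("all calibration concentrations are identical")

    xbar = x.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    b = float(np.sum((x - xbar) * (y - y.mean())) / sxx)
    a = float(y.mean() - b * xbar)
    resid = y - (a + b * x)

    if n == 2:
        warnings.warn(
            "two-point calibration: zero residual degrees of freedom, "
            "s_yx/s_a/s_b reported as 0",
            UserWarning,
            stacklevel=2,
        )
        s_yx = s_a = s_b = 0.0
        r = 1.0 if b > 0 else (-1.0 if b < 0 else 0.0)
    else:
        s_yx = math.sqrt(float(np.sum(resid**2)) / (n - 2))
        s_b = s_yx / math.sqrt(sxx)
        s_a = s_yx * math.sqrt(float(np.sum(x**2)) / (n * sxx))
        sy = float(np.std(y, ddof=1))
        r = 0.0 if sy == 0 else float(np.corrcoef(x, y)[0, 1])

    if conc_range is None:
        conc_range = (float(x.min()), float(x.max()))
    return CalibrationCurve(
        analyte=analyte,
        wavelength=wavelength,
        a=a,
        b=b,
        r=r,
        s_yx=s_yx,
        s_a=s_a,
        s_b=s_b,
        n=n,
        range=conc_range,
    )


def sensitivity_limits(curve: CalibrationCurve) -> SensitivityLimits:
    """LOD = 3.3 * s_a / b and LOQ = 10 * s_a / b (ICH, sigma = s.d. of intercept)."""
    if curve.b <= 0:
        raise ValidationError(
            "sensitivity limits require a positive calibration slope"
        )
    return SensitivityLimits(
        lod=3.3 * curve.s_a / curve.b, loq=10.0 * curve.s_a / curve.b
    )


def _as_recoveries(records) -> np.ndarray:
    vals = [
        r.recovery if isinstance(r, RecoveryRecord) else float(r) for r in records
    ]
    return np.asarray(vals, dtype=float)


def recoveries_from_pairs(
    taken: Sequence[float], found: Sequence[float]
) -> list[RecoveryRecord]:
    if len(taken) != len(found):
        raise ValidationError("taken and found must have equal length")
    return [RecoveryRecord(t, f) for t, f in zip(taken, found)]


def recovery_stats(records) -> tuple[float, float, float, float]:
    """(mean, sd, %RSD, %error) of a recovery set, sd with n-1 denominator."""
    vals = _as_recoveries(records)
    if vals.size < 2:
        raise ValidationError("recovery statistics need >= 2 records")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    rsd = 100.0 * sd / mean
    error = rsd / math.sqrt(vals.size)
    return mean, sd, rsd, error


def _group(values) -> np.ndarray:
    vals = _as_recoveries(values)
    if vals.size < 2:
        raise ValidationError("each comparison group needs >= 2 values")
    return vals


def student_t(group_a, group_b) -> MethodComparison:
    """Pooled-variance two-sample Student's t (absolute value), df = n1+n2-2."""
    return compare_methods(group_a, group_b)


def f_test(group_a, group_b) -> MethodComparison:
    """Variance-ratio F with the larger sample variance in the numerator."""
    return compare_methods(group_a, group_b)


def compare_methods(group_a, group_b) -> MethodComparison:
    a = _group(group_a)
    b = _group(group_b)
    na, nb = a.size, b.size
    va, vb = float(a.var(ddof=1)), float(b.var(ddof=1))

    df_t = na + nb - 2
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df_t
    if sp2 == 0.0:
        t = 0.0 if a.mean() == b.mean() else math.inf
    else:
        t = abs(a.mean() - b.mean()) / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))

    if va == 0.0 and vb == 0.0:
        f = 1.0
        df_f = (na - 1, nb - 1)
    elif va >= vb:
        f = math.inf if vb == 0.0 else va / vb
        df_f = (na - 1, nb - 1)
    else:
        f = math.inf if va == 0.0 else vb / va
        df_f = (nb - 1, na - 1)

    return MethodComparison(
        t=float(t),
        f=float(f),
        df_t=df_t,
        df_f=df_f,
        t_critical=float(stats.t.ppf(1.0 - ALPHA / 2.0, df_t)),
        f_critical=float(stats.f.ppf(1.0 - ALPHA, *df_f)),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=math.sqrt(va),
        sd_b=math.sqrt(vb),
        n_a=na,
        n_b=nb,
    )


def precision_study(
    replicate_sets: Mapping[tuple[object, float], Sequence[float]]
) -> list[PrecisionCell]:
    """Intra-/inter-day precision from recoveries keyed by (day, concentration).

    Intra-day cells summarize each (day, concentration) replicate set;
    inter-day cells pool all days at a given concentration.  Every cell needs
    at least two replicates.
    """
    if not replicate_sets:
        raise ValidationError("precision study needs at least one replicate set")
    cells: list[PrecisionCell] = []
    by_conc: dict[float, list[float]] = {}
    days_per_conc: dict[float, set] = {}
    for (day, conc), reps in sorted(replicate_sets.items(), key=lambda kv: (str(kv[0][0]), kv[0][1])):
        vals = _as_recoveries(reps)
        if vals.size < 2:
            raise ValidationError(
                f"precision cell (day={day}, conc={conc}) needs >= 2 replicates"
            )
        mean, sd, rsd, error = recovery_stats(vals)
        cells.append(
            PrecisionCell(
                mode="intra-day",
                concentration=float(conc),
                mean_recovery=mean,
                sd=sd,
                rsd=rsd,
                error=error,
                n=int(vals.size),
                day=day,
            )
        )
        by_conc.setdefault(float(conc), []).extend(vals.tolist())
        days_per_conc.setdefault(float(conc), set()).add(day)
    for conc, pooled in sorted(by_conc.items()):
        if len(days_per_conc[conc]) < 2:
            continue
        mean, sd, rsd, error = recovery_stats(pooled)
        cells.append(
            PrecisionCell(
                mode="inter-day",
                concentration=conc,
                mean_recovery=mean,
                sd=sd,
                rsd=rsd,
                error=error,
                n=len(pooled),
                day=None,
            )
        )
    return cells
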