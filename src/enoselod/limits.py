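"""Zeroth-order (univariate) limit-of-detection and quantification machinery.

The detection decision follows Currie's hypothesis-testing framework. For a
blank signal with mean ``x̄_b`` and sample standard deviation ``s_b``
(N−1 divisor), the signal threshold is

    y_LOD = x̄_b + k_LOD · s_b                                     (threshold)

and, through the calibration line with analytical sensitivity *m* (slope),

    c_LOD = k_LOD · s / |m|                                        (slope form)
    c_LOD = k_LOD · s · (1 + h0) / |m|,  h0 = 1/n + c̄²/Σ(c_i−c̄)²  (leverage)

where *s* is either ``s_b`` or the calibration line's residual standard
deviation (RMSE with N−2 divisor). The multiplier ``k_LOD`` encodes the
false-positive (α) and false-negative (β) error probabilities: under
normality and homoscedasticity ``k = z(1−α) + z(1−β)`` (3.29 for
α = β = 0.05, commonly printed 3.3); for few blank replicates the Student-t
form ``k = 2·t(1−α, N_b−1)`` is recommended (3.72 for 9 blanks). The limit
of quantification uses the same formulas with k = 10 (reciprocal of a 10%
acceptable relative SD).

The leverage factor is implemented both as the linear ``(1 + h0)`` factor
and as ``sqrt(1 + h0)`` (``variant="sqrt"``); the linear form is the
default. An "adjusted" LOD replaces the implicit assumption that the
calibration intercept equals the blank mean:
``c_LOD,adj = (x̄_b + k·s − b0)/m``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .errors import DesignError, InsufficientBlanksError

__all__ = [
    "KFactorSpec",
    "k_factor",
    "loq_factor",
    "error_probability",
    "BlankStatistics",
    "blank_statistics",
    "signal_threshold",
    "CalibrationCurve",
    "fit_calibration",
    "LimitEstimate",
    "lod_from_slope",
    "lod_with_leverage",
    "adjusted_lod",
    "ThresholdScan",
    "lowest_exceeding_concentration",
]


# ---------------------------------------------------------------------------
# k factors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KFactorSpec:
    """A resolved detection/quantification multiplier with its provenance.

    ``value`` is kept unrounded; use :meth:`display` for the conventional
    two-decimal rendering (3.29 → "3.29", 3.7190 → "3.72").
    """

    value: float
    purpose: str = "LOD"  # "LOD" | "LOQ"
    alpha: float | None = None
    beta: float | None = None
    distribution: str = "normal"  # "normal" | "student_t" | "fixed"
    n_blanks: int | None = None

    def display(self) -> str:
        return f"{self.value:.2f}"


def k_factor(
    alpha: float = 0.05,
    beta: float = 0.05,
    distribution: str = "normal",
    n_blanks: int | None = None,
) -> KFactorSpec:
    """Resolve the detection multiplier k_LOD from error probabilities.

    ``normal``: k = z(1−α) + z(1−β). ``student_t`` (recommended for few
    blank replicates): k = 2·t(1−α, ν) with ν = N_b − 1; only the symmetric
    α = β form is defined, asymmetric requests raise with a pointer to
    normal mode.
    """
    if not (0 < alpha < 0.5 and 0 < beta < 0.5):
        raise ValueError("alpha and beta must lie in (0, 0.5)")
    if distribution == "normal":
        value = float(stats.norm.ppf(1 - alpha) + stats.norm.ppf(1 - beta))
    elif distribution == "student_t":
        if alpha != beta:
            raise ValueError(
                "student_t k-factor is defined only for symmetric alpha == beta; "
                "use distribution='normal' for asymmetric error probabilities"
            )
        if n_blanks is None or n_blanks < 2:
            raise ValueError("student_t k-factor needs n_blanks >= 2")
        value = float(2.0 * stats.t.ppf(1 - alpha, df=n_blanks - 1))
    else:
        raise ValueError(f"unknown distribution {distribution!r}")
    return KFactorSpec(
        value=value, purpose="LOD", alpha=alpha, beta=beta,
        distribution=distribution, n_blanks=n_blanks,
    )


def loq_factor(value: float = 10.0) -> KFactorSpec:
    """The quantification multiplier: k = 10 by convention (10% relative SD)."""
    return KFactorSpec(value=float(value), purpose="LOQ", distribution="fixed")


def error_probability(k: float, distribution: str = "normal", n_blanks: int | None = None) -> float:
    """Symmetric error probability α = β implied by a multiplier k.

    Inverse of the symmetric k-factor: α = P(Z > k/2) (normal) or
    P(T_ν > k/2) (Student t). k = 3 gives ≈ 0.067, commonly quoted as 0.07.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if distribution == "normal":
        return float(stats.norm.sf(k / 2.0))
    if distribution == "student_t":
        if n_blanks is None or n_blanks < 2:
            raise ValueError("student_t needs n_blanks >= 2")
        return float(stats.t.sf(k / 2.0, df=n_blanks - 1))
    raise ValueError(f"unknown distribution {distribution!r}")


# ---------------------------------------------------------------------------
# Blank statistics and the signal threshold
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlankStatistics:
    """Mean and sample SD of the analyte-free (blank) signal."""

    mean: float
    sd: float
    count: int
    per_sensor_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


def blank_statistics(values: Sequence[float]) -> BlankStatistics:
    """Sample mean and SD (N−1 divisor) of the blank signals."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise InsufficientBlanksError(
            f"need at least 2 blank values for a standard deviation, got {arr.size}"
        )
    return BlankStatistics(mean=float(arr.mean()), sd=float(arr.std(ddof=1)), count=int(arr.size))


def signal_threshold(blanks: BlankStatistics, k: KFactorSpec) -> float:
    """y_LOD = x̄_b + k · s_b, in signal units."""
    return blanks.mean + k.value * blanks.sd


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationCurve:
    """A fitted univariate calibration line and its LOD ingredients."""

    slope: float
    intercept: float
    residual_sd: float
    concentrations: np.ndarray
    n: int
    weighting: str = "ols"

    @property
    def conc_mean(self) -> float:
        return float(np.mean(self.concentrations))

    @property
    def ssx(self) -> float:
        c = self.concentrations
        return float(np.sum((c - c.mean()) ** 2))

    @property
    def leverage(self) -> float:
        """h0 = 1/n + c̄² / Σ(c_i − c̄)², always ≥ 1/n."""
        return 1.0 / self.n + self.conc_mean**2 / self.ssx

    def predict(self, conc: np.ndarray | float) -> np.ndarray | float:
        return self.intercept + self.slope * np.asarray(conc, dtype=float)


def _replicate_weights(conc: np.ndarray, signal: np.ndarray) -> np.ndarray:
    """Reciprocal per-level replicate variances; pooled for levels with < 3 replicates."""
    levels = np.unique(conc)
    level_var: dict[float, float] = {}
    pool_num, pool_df = 0.0, 0
    for level in levels:
        y = signal[conc == level]
        if y.size >= 2:
            v = float(np.var(y, ddof=1))
            pool_num += v * (y.size - 1)
            pool_df += y.size - 1
            if y.size >= 3:
                level_var[level] = v
    if pool_df == 0:
        raise DesignError("WLS weighting needs at least one level with replicate measurements")
    pooled = pool_num / pool_df
    if pooled == 0:
        raise DesignError("all replicate variances are zero; WLS weights undefined")
    weights = np.empty_like(conc, dtype=float)
    for level in levels:
        v = level_var.get(level, pooled)
        if v == 0:
            raise DesignError(
                f"concentration level {level} has zero replicate variance; "
                "supply explicit weights or use the pooled variance"
            )
        weights[conc == level] = 1.0 / v
    return weights


def fit_calibration(
    conc: Sequence[float],
    signal: Sequence[float],
    weighting: str = "ols",
    weights: Sequence[float] | None = None,
) -> CalibrationCurve:
    """Least-squares calibration line, OLS or WLS.

    WLS weights default to reciprocal per-level replicate variances (pooled
    variance for levels with fewer than 3 replicates). The residual SD uses
    the N−2 divisor on unweighted residuals in both cases.
    """
    c = np.asarray(conc, dtype=float)
    y = np.asarray(signal, dtype=float)
    if c.size != y.size:
        raise DesignError("concentration and signal must have equal length")
    if c.size < 3:
        raise DesignError(f"need at least 3 samples to fit a calibration line, got {c.size}")
    if np.unique(c).size < 2:
        raise DesignError("all concentrations are equal; calibration design is degenerate")
    if weighting == "ols":
        w = np.ones_like(c)
    elif weighting == "wls":
        w = np.asarray(weights, dtype=float) if weights is not None else _replicate_weights(c, y)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    res = sm.WLS(y, sm.add_constant(c), weights=w).fit()
    intercept, slope = (float(v) for v in res.params)
    resid = y - (intercept + slope * c)
    residual_sd = float(np.sqrt(np.sum(resid**2) / (c.size - 2)))
    return CalibrationCurve(
        slope=slope, intercept=intercept, residual_sd=residual_sd,
        concentrations=c, n=int(c.size), weighting=weighting,
    )


# ---------------------------------------------------------------------------
# Limit estimates
# ---------------------------------------------------------------------------

@dataclass
class LimitEstimate:
    """One LOD or LOQ value with full provenance.

    ``qualifier`` is ``"<"`` when only an upper bound is known (the lowest
    measured level already exceeds the threshold, reported "< c_min").
    ``valid`` is False for degenerate or negative results, with ``reason``.
    """

    kind: str  # "LOD" | "LOQ"
    value: float
    method: str
    deviation: str  # "s_blank" | "rmse" | method-specific
    k: KFactorSpec | None = None
    leverage_applied: bool = False
    leverage_variant: str | None = None
    adjusted: bool = False
    valid: bool = True
    reason: str = ""
    qualifier: str = ""
    info: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        rec = {
            "kind": self.kind,
            "value": float(self.value) if np.isfinite(self.value) else None,
            "method": self.method,
            "deviation": self.deviation,
            "k": None if self.k is None else self.k.value,
            "k_distribution": None if self.k is None else self.k.distribution,
            "leverage_applied": self.leverage_applied,
            "leverage_variant": self.leverage_variant,
            "adjusted": self.adjusted,
            "valid": self.valid,
            "reason": self.reason,
            "qualifier": self.qualifier,
        }
        rec.update({k: v for k, v in self.info.items() if np.isscalar(v) or v is None})
        return rec

    def formatted(self, sig: int = 2) -> str:
        """Table rendering, rounded to ``sig`` significant digits."""
        if not np.isfinite(self.value):
            return "n.d."
        if self.value == 0:
            text = "0"
        else:
            from decimal import Decimal

            d = Decimal(f"{self.value:.{sig}g}")
            text = format(d.normalize(), "f")
        return f"{self.qualifier}{text}"


def _is_degenerate(s: float, curve: CalibrationCurve) -> bool:
    """Deviation numerically zero relative to the calibration's signal scale."""
    scale = abs(curve.slope) * float(np.std(curve.concentrations))
    return s == 0.0 or s <= 1e-10 * scale


def _check_slope(curve: CalibrationCurve) -> float:
    if curve.slope == 0:
        raise DesignError("calibration slope is zero: no analytical sensitivity")
    if curve.slope < 0:
        warnings.warn(
            "negative calibration slope; |m| used (LOD is a magnitude)", stacklevel=3
        )
    return abs(curve.slope)


def lod_from_slope(
    k: KFactorSpec,
    s: float,
    curve: CalibrationCurve,
    method: str = "single_sensor",
    deviation: str = "s_blank",
) -> LimitEstimate:
    """c = k · s / |m| (slope form, no leverage)."""
    if s < 0:
        raise ValueError("deviation estimate s must be non-negative")
    m = _check_slope(curve)
    value = k.value * s / m
    est = LimitEstimate(kind=k.purpose, value=value, method=method, deviation=deviation, k=k)
    if _is_degenerate(s, curve):
        est.valid = False
        est.reason = "zero deviation estimate (degenerate)"
    return est


def lod_with_leverage(
    k: KFactorSpec,
    s: float,
    curve: CalibrationCurve,
    variant: str = "as_printed",
    method: str = "single_sensor",
    deviation: str = "rmse",
) -> LimitEstimate:
    """c = k · s · (1 + h0) / |m| with the calibration-design leverage h0.

    ``variant="sqrt"`` uses sqrt(1 + h0) instead of the linear factor.
    """
    if s < 0:
        raise ValueError("deviation estimate s must be non-negative")
    if curve.ssx <= 0:
        raise DesignError("degenerate design: zero concentration spread")
    m = _check_slope(curve)
    h0 = curve.leverage
    if variant == "as_printed":
        factor = 1.0 + h0
    elif variant == "sqrt":
        factor = float(np.sqrt(1.0 + h0))
    else:
        raise ValueError(f"unknown leverage variant {variant!r}")
    value = k.value * s * factor / m
    est = LimitEstimate(
        kind=k.purpose, value=value, method=method, deviation=deviation, k=k,
        leverage_applied=True, leverage_variant=variant, info={"h0": h0},
    )
    if _is_degenerate(s, curve):
        est.valid = False
        est.reason = "zero deviation estimate (degenerate)"
    return est


def adjusted_lod(
    k: KFactorSpec,
    s: float,
    curve: CalibrationCurve,
    blanks: BlankStatistics,
    method: str = "single_sensor",
    deviation: str = "s_blank",
) -> LimitEstimate:
    """LOD corrected for intercept ≠ blank mean: c = (x̄_b + k·s − b0)/m.

    Equals the slope-form LOD minus (b0 − x̄_b)/m. When the intercept sits
    far above the blank threshold the correction turns negative and the
    estimate is flagged invalid.
    """
    _check_slope(curve)
    value = (blanks.mean + k.value * s - curve.intercept) / curve.slope
    est = LimitEstimate(
        kind=k.purpose, value=value, method=method, deviation=deviation, k=k, adjusted=True,
        info={"intercept_minus_blank_mean": curve.intercept - blanks.mean},
    )
    if value <= 0:
        est.valid = False
        est.reason = "adjusted LOD non-positive (intercept far above blank threshold)"
    return est


# ---------------------------------------------------------------------------
# Threshold scan (measured-concentration decision)
# ---------------------------------------------------------------------------

@dataclass
class ThresholdScan:
    """Outcome of comparing per-level mean signals against y_LOD."""

    y_lod: float
    level_means: dict[float, float]
    detected_level: float | None
    qualifier: str  # "<" when the lowest nonzero level already exceeds
    detected: bool


def lowest_exceeding_concentration(
    values: Sequence[float],
    concentrations: Sequence[float],
    y_lod: float,
) -> ThresholdScan:
    """Smallest measured nonzero level whose replicate mean exceeds y_LOD.

    Because only measured concentrations can be declared, the result is an
    upper bound ("< c_min") when the lowest nonzero level already exceeds,
    and a not-detected sentinel when no level does.
    """
    v = np.asarray(values, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    levels = np.unique(c[c > 0])
    if levels.size == 0:
        raise DesignError("no nonzero concentration levels")
    means = {float(lv): float(v[c == lv].mean()) for lv in levels}
    exceeding = [lv for lv in levels if means[float(lv)] > y_lod]
    if not exceeding:
        return ThresholdScan(y_lod=y_lod, level_means=means, detected_level=None,
                             qualifier="", detected=False)
    lowest = float(min(exceeding))
    qualifier = "<" if lowest == float(levels[0]) else ""
    return ThresholdScan(y_lod=y_lod, level_means=means, detected_level=lowest,
                         qualifier=qualifier, detected=True)
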