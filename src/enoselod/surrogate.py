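"""Surrogate-signal LOD estimation for multisensor (first-order) data.

Classical detection-limit formulas need one signal per sample, but a sensor
array yields a response vector. The strategy implemented here reduces the
samples × sensors feature matrix to a univariate *surrogate* and feeds it to
the zeroth-order machinery in :mod:`enoselod.limits`:

``PCA I``
    The first principal component score is the surrogate; the LOD is the
    lowest measured concentration whose mean PC1 score exceeds the blank
    threshold ``x̄_b + k·s_b`` computed on the blanks' scores. No
    calibration line — only measured levels can be declared.

``PCA II``
    An OLS line of PC1 score on concentration; slope and residual SD (or
    blank-score SD) enter the leverage-corrected LOD formula.

``PCR`` / ``PLSR``
    The model's predicted concentration is the surrogate. An OLS line of
    predicted vs actual concentration (slope ≈ 1 for a good model) supplies
    the sensitivity, and either its residual SD or the SD of the blanks'
    predictions supplies the deviation. The number of components is chosen
    by repeated stratified cross-validation with a one-standard-error rule.

Because the LOD of a surrogate is invariant under affine transformations of
the response (Ortiz et al.), these estimates do not depend on score scaling
or eigenvector sign conventions; PC1 is nevertheless oriented so that it
correlates non-negatively with concentration.

Two alternative methods from the literature are included for comparison:
the coefficient-vector method ``ĉ_LOD = 3 · s_blank(1×J) · b(J×1)`` (a dot
product of per-sensor blank SDs with regression coefficients, which can go
negative), and the mean-relative-error (MRE) change-point heuristic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.linear_model import LinearRegression

from .errors import DesignError, InsufficientBlanksError
from .features import FeatureMatrix
from . import limits
from .limits import KFactorSpec, LimitEstimate

__all__ = [
    "SurrogateSeries",
    "pc1_surrogate",
    "pca_threshold_lod",
    "pca_calibration_lod",
    "CVSelectionReport",
    "select_n_components",
    "regression_surrogate",
    "regression_surrogate_lod",
    "plsr_coefficients",
    "coefficient_vector_lod",
    "MREProfile",
    "mre_lod",
]


@dataclass
class SurrogateSeries:
    """A univariate surrogate aligned to the true concentrations."""

    values: np.ndarray
    concentrations: np.ndarray
    is_blank: np.ndarray
    provenance: str  # "PCA" | "PCR(k)" | "PLSR(k)"
    explained_variance_pc1: float | None = None
    orientation_flipped: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.is_blank = np.asarray(self.is_blank, dtype=bool)
        if not (len(self.values) == len(self.concentrations) == len(self.is_blank)):
            raise ValueError("surrogate fields must have equal length")

    @property
    def blank_values(self) -> np.ndarray:
        return self.values[self.is_blank]


def _require_normalized(fm: FeatureMatrix) -> None:
    if fm.normalization is None:
        warnings.warn(
            "feature matrix is not z-score normalized; surrogate methods assume "
            "standardized sensors", stacklevel=3,
        )


def pc1_surrogate(fm: FeatureMatrix, variance_floor: float = 0.80) -> SurrogateSeries:
    """First-principal-component scores as the univariate surrogate.

    Scores are oriented to correlate non-negatively with concentration so
    the result is independent of the eigensolver's sign convention. A
    warning is emitted when PC1 explains less than ``variance_floor`` of the
    total variance (the surrogate is then a poor one-dimensional summary;
    well-behaved arrays sit in the 0.92–0.98 range).
    """
    if fm.n_samples < 3:
        raise DesignError("PCA surrogate needs at least 3 samples")
    if len(fm.sensor_ids) < 2:
        raise DesignError("PCA surrogate needs at least 2 sensors")
    _require_normalized(fm)
    pca = PCA(n_components=1)
    scores = pca.fit_transform(fm.values.to_numpy()).ravel()
    evr = float(pca.explained_variance_ratio_[0])
    conc = fm.concentrations
    flipped = False
    r = np.corrcoef(scores, conc)[0, 1] if np.std(scores) > 0 and np.std(conc) > 0 else 0.0
    if r < 0:
        scores = -scores
        flipped = True
    if evr < variance_floor:
        warnings.warn(
            f"PC1 explains only {evr:.1%} of variance (< {variance_floor:.0%}); "
            "a univariate surrogate may be unreliable", stacklevel=2,
        )
    return SurrogateSeries(
        values=scores, concentrations=conc, is_blank=fm.is_blank,
        provenance="PCA", explained_variance_pc1=evr, orientation_flipped=flipped,
    )


def pca_threshold_lod(series: SurrogateSeries, k: KFactorSpec) -> LimitEstimate:
    """PCA I: lowest measured level whose mean PC1 score exceeds the blank threshold."""
    blanks = series.blank_values
    if blanks.size < 2:
        raise InsufficientBlanksError("PCA I needs at least 2 blank samples")
    bstats = limits.blank_statistics(blanks)
    y_lod = limits.signal_threshold(bstats, k)
    scan = limits.lowest_exceeding_concentration(series.values, series.concentrations, y_lod)
    info = {
        "y_lod": y_lod,
        "explained_variance_pc1": series.explained_variance_pc1,
        "level_means": scan.level_means,
    }
    if not scan.detected:
        return LimitEstimate(
            kind=k.purpose, value=float("nan"), method="PCA_I", deviation="s_blank", k=k,
            valid=False, reason="no measured level exceeds the blank threshold", info=info,
        )
    return LimitEstimate(
        kind=k.purpose, value=scan.detected_level, method="PCA_I", deviation="s_blank",
        k=k, qualifier=scan.qualifier, info=info,
    )


def _deviation(series: SurrogateSeries, curve: limits.CalibrationCurve, deviation: str) -> float:
    if deviation == "rmse":
        return curve.residual_sd
    if deviation == "s_blank":
        blanks = series.blank_values
        if blanks.size < 2:
            raise InsufficientBlanksError("s_blank deviation needs at least 2 blanks")
        return limits.blank_statistics(blanks).sd
    raise ValueError(f"unknown deviation {deviation!r}")


def pca_calibration_lod(
    series: SurrogateSeries,
    k: KFactorSpec,
    deviation: str = "rmse",
    leverage_variant: str = "as_printed",
) -> LimitEstimate:
    """PCA II: OLS line of PC1 score on concentration, leverage-corrected LOD."""
    curve = limits.fit_calibration(series.concentrations, series.values)
    s = _deviation(series, curve, deviation)
    est = limits.lod_with_leverage(
        k, s, curve, variant=leverage_variant, method="PCA_II", deviation=deviation
    )
    est.info["explained_variance_pc1"] = series.explained_variance_pc1
    est.info["slope"] = curve.slope
    return est


# ---------------------------------------------------------------------------
# Component-count selection by repeated stratified cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVSelectionReport:
    """Outcome of repeated stratified k-fold component selection."""

    model: str
    candidate_components: list[int]
    mean_rmse: dict[int, float]
    mean_q2: dict[int, float]
    chosen_per_repeat: list[int]
    chosen: int
    folds: int
    repeats: int
    seed: int


def _make_model(model: str, n_components: int):
    if model == "PLSR":
        return PLSRegression(n_components=n_components, scale=False)
    if model == "PCR":
        return None  # handled explicitly (PCA + OLS) below
    raise ValueError(f"unknown model {model!r}; expected 'PCR' or 'PLSR'")


def _fit_predict(model: str, n_components: int, X_train, y_train, X_test) -> np.ndarray:
    if model == "PLSR":
        pls = PLSRegression(n_components=n_components, scale=False)
        pls.fit(X_train, y_train)
        return pls.predict(X_test).ravel()
    pca = PCA(n_components=n_components)
    t_train = pca.fit_transform(X_train)
    reg = LinearRegression().fit(t_train, y_train)
    return reg.predict(pca.transform(X_test)).ravel()


def _standardize_fold(X_train: np.ndarray, X_test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score with training-fold statistics only (no test-fold leakage)."""
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (X_train - mu) / sd, (X_test - mu) / sd


def _stratified_folds(conc: np.ndarray, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Deal each concentration level's shuffled members round-robin to folds.

    Levels with fewer members than folds contribute to as many folds as
    they have members (graceful degradation).
    """
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for level in np.unique(conc):
        idx = np.flatnonzero(conc == level)
        rng.shuffle(idx)
        start = int(rng.integers(n_folds))
        for j, i in enumerate(idx):
            folds[(start + j) % n_folds].append(int(i))
    return [np.array(sorted(f), dtype=int) for f in folds if len(f) > 0]


def select_n_components(
    fm: FeatureMatrix,
    model: str = "PLSR",
    folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
    candidates: Sequence[int] | None = None,
) -> CVSelectionReport:
    """Choose the component count by repeated stratified k-fold CV.

    Per repeat, folds are stratified by concentration level (equal level
    representation). For each candidate count the held-out RMSE and Q²
    (1 − SS_res/SS_tot on the held-out fold) are recorded. "The minimum
    number of components giving a low RMSE and high Q²" is operationalized
    as the one-standard-error rule: the smallest count whose mean RMSE lies
    within one SE of the minimizer's fold RMSEs. The final choice is the
    median over repeats, with fractional medians floored (parsimony).
    """
    X = fm.values.to_numpy()
    y = fm.concentrations
    n, p = X.shape
    if n < folds:
        raise DesignError(f"{n} samples cannot fill {folds} folds; reduce the fold count")
    if candidates is None:
        candidates = list(range(1, min(10, p, n - 2) + 1))
    candidates = sorted(int(c) for c in candidates)
    _make_model(model, candidates[0])  # validate model name early
    rng = np.random.default_rng(seed)

    all_rmse: dict[int, list[float]] = {c: [] for c in candidates}
    all_q2: dict[int, list[float]] = {c: [] for c in candidates}
    chosen_per_repeat: list[int] = []
    for _ in range(repeats):
        fold_sets = _stratified_folds(y, folds, rng)
        repeat_rmse: dict[int, list[float]] = {c: [] for c in candidates}
        for test_idx in fold_sets:
            train_mask = np.ones(n, dtype=bool)
            train_mask[test_idx] = False
            Xtr, Xte = _standardize_fold(X[train_mask], X[test_idx])
            ytr, yte = y[train_mask], y[test_idx]
            ss_tot = float(np.sum((yte - yte.mean()) ** 2))
            for c in candidates:
                if c > min(Xtr.shape):
                    continue
                pred = _fit_predict(model, c, Xtr, ytr, Xte)
                ss_res = float(np.sum((yte - pred) ** 2))
                repeat_rmse[c].append(np.sqrt(ss_res / len(yte)))
                all_rmse[c].append(repeat_rmse[c][-1])
                all_q2[c].append(1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan"))
        means = {c: float(np.mean(v)) for c, v in repeat_rmse.items() if v}
        best = min(means, key=means.get)
        fold_vals = np.asarray(repeat_rmse[best])
        se = float(fold_vals.std(ddof=1) / np.sqrt(len(fold_vals))) if len(fold_vals) > 1 else 0.0
        chosen_per_repeat.append(min(c for c in means if means[c] <= means[best] + se))

    chosen = int(np.floor(np.median(chosen_per_repeat)))
    return CVSelectionReport(
        model=model,
        candidate_components=list(candidates),
        mean_rmse={c: float(np.mean(v)) for c, v in all_rmse.items() if v},
        mean_q2={c: float(np.nanmean(v)) for c, v in all_q2.items() if v},
        chosen_per_repeat=chosen_per_repeat,
        chosen=chosen,
        folds=folds,
        repeats=repeats,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Regression surrogates (PCR / PLSR)
# ---------------------------------------------------------------------------

def regression_surrogate(fm: FeatureMatrix, model: str, n_components: int) -> SurrogateSeries:
    """Predicted concentrations from a PCR or PLSR fit on the entire dataset."""
    _require_normalized(fm)
    X = fm.values.to_numpy()
    y = fm.concentrations
    if n_components < 1:
        raise DesignError("n_components must be >= 1")
    if n_components > min(X.shape):
        raise DesignError(
            f"n_components={n_components} exceeds the data rank bound {min(X.shape)}"
        )
    pred = _fit_predict(model, n_components, X, y, X)
    return SurrogateSeries(
        values=pred, concentrations=y, is_blank=fm.is_blank,
        provenance=f"{model}({n_components})",
    )


def regression_surrogate_lod(
    fm: FeatureMatrix,
    model: str,
    n_components: int,
    k: KFactorSpec,
    deviation: str = "rmse",
    leverage_variant: str = "as_printed",
) -> LimitEstimate:
    """PCR/PLSR LOD: leverage-corrected formula on the predicted-vs-actual line.

    The model is fit on the entire dataset; an OLS line of predicted on
    actual concentration supplies the slope, and the chosen deviation is
    either that line's residual SD (RMSE) or the SD of the blanks'
    predicted concentrations.
    """
    series = regression_surrogate(fm, model, n_components)
    curve = limits.fit_calibration(series.concentrations, series.values)
    s = _deviation(series, curve, deviation)
    est = limits.lod_with_leverage(
        k, s, curve, variant=leverage_variant, method=model, deviation=deviation
    )
    est.info["n_components"] = n_components
    est.info["slope"] = curve.slope
    return est


def plsr_coefficients(fm: FeatureMatrix, n_components: int) -> np.ndarray:
    """Regression coefficient vector b (J×1) of a PLSR fit on the full data."""
    _require_normalized(fm)
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(fm.values.to_numpy(), fm.concentrations)
    return np.asarray(pls.coef_).reshape(-1)


def per_sensor_blank_sd(fm: FeatureMatrix) -> np.ndarray:
    """Sample SD of each sensor's blank features, 1×J."""
    blanks = fm.blank_rows()
    if len(blanks) < 2:
        raise InsufficientBlanksError("per-sensor blank SD needs at least 2 blanks")
    return blanks.std(axis=0, ddof=1).to_numpy()


def coefficient_vector_lod(
    blank_sds: Sequence[float], coefficients: Sequence[float]
) -> LimitEstimate:
    """Coefficient-vector method: ĉ_LOD = 3 · s_blank(1×J) · b(J×1).

    The dot product of per-sensor blank SDs with the regression coefficient
    vector, times 3. Sensors with negative coefficients and large blank SDs
    can drive the sum negative — the estimate is then flagged invalid, the
    method's known failure mode.
    """
    s = np.asarray(blank_sds, dtype=float)
    b = np.asarray(coefficients, dtype=float)
    if s.shape != b.shape:
        raise ValueError(f"vector length mismatch: {s.shape} vs {b.shape}")
    value = float(3.0 * s @ b)
    est = LimitEstimate(
        kind="LOD", value=value, method="coefficient_vector", deviation="s_blank_vector",
        k=KFactorSpec(value=3.0, distribution="fixed"),
    )
    if value < 0:
        est.valid = False
        est.reason = "negative LOD (negative-coefficient sensors dominate)"
    elif value == 0:
        est.valid = False
        est.reason = "zero blank variation (degenerate)"
    return est


# ---------------------------------------------------------------------------
# Mean-relative-error change-point method
# ---------------------------------------------------------------------------

@dataclass
class MREProfile:
    """Mean relative prediction error (%) per ascending nonzero level."""

    levels: np.ndarray
    mre: np.ndarray
    deltas: np.ndarray  # |mre[i+1] − mre[i]|, percent points
    threshold: float = 1.0


def mre_lod(
    series: SurrogateSeries,
    threshold: float = 1.0,
    min_levels: int = 6,
) -> tuple[MREProfile, LimitEstimate]:
    """MRE change-point LOD on regression predictions.

    The mean relative error |ŷ − c|/c (in %) is computed per nonzero level;
    the LOD is the smallest level from which onward all consecutive changes
    are ≤ ``threshold`` percent points. Blank rows are rejected (relative
    error is undefined at c = 0). With few, widely spaced levels the rule is
    unreliable and the estimate is flagged accordingly.
    """
    if np.any(series.concentrations[~series.is_blank] == 0):
        raise DesignError("zero-concentration rows must be flagged as blanks")
    mask = ~series.is_blank
    if not mask.any():
        raise DesignError("MRE method needs nonzero-concentration samples")
    conc = series.concentrations[mask]
    pred = series.values[mask]
    levels = np.unique(conc)
    if levels.size < 3:
        raise DesignError(f"MRE method needs >= 3 nonzero levels, got {levels.size}")
    mre = np.array(
        [float(np.mean(np.abs(pred[conc == lv] - lv) / lv) * 100.0) for lv in levels]
    )
    deltas = np.abs(np.diff(mre))
    profile = MREProfile(levels=levels, mre=mre, deltas=deltas, threshold=threshold)

    suffix_ok = [bool(np.all(deltas[j:] <= threshold)) for j in range(deltas.size)]
    if suffix_ok and suffix_ok[0]:
        value, detected = float(levels[0]), True
    else:
        detected = False
        value = float("nan")
        for j, ok in enumerate(suffix_ok):
            if ok:  # stable from the transition into level j+1 onward
                value, detected = float(levels[j + 1]), True
                break
    est = LimitEstimate(
        kind="LOD", value=value, method="MRE", deviation="mre_profile", k=None,
        info={"n_levels": int(levels.size), "max_delta": float(deltas.max())},
    )
    if not detected:
        est.valid = False
        est.reason = f"MRE changes never stabilize below {threshold}% "
    elif levels.size < min_levels:
        est.valid = False
        est.reason = (
            f"only {levels.size} nonzero levels; the MRE rule needs many closely "
            "spaced concentrations and is unsuitable for few, widely spaced levels"
        )
    return profile, est
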