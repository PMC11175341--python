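"""Synthetic eNose dilution-series studies with known ground truth.

Emulates the measurement design used to characterize a 62-sensor MOS array:
for one substance, a dilution series of five concentration levels (blank
included) is measured in three replicates on each of three days, giving 45
samples and 9 blanks. Each sensor's mean response to concentration *c* is a
saturating, quasi-linear-at-low-c curve

    f(c) = c / (1 + c/κ)        (slope 1 at c = 0, scale κ in ppm)

scaled by a per-sensor sensitivity. Sensitivities share one latent channel
(``common_factor_weight``) so that PC1 of the standardized features captures
most of the variance, as observed on real arrays (92–98%). Additive noise
is Gaussian with SD ``σ0 + λ·c`` (λ = 0: homoscedastic); additive
per-(day, sensor) offsets model between-day drift, and an optional second
latent "interferent" channel adds variance uncorrelated with concentration.

Two output levels are provided: feature-level matrices
(:func:`simulate_features`, the raw per-sensor responses before the ethanol
reference correction and normalization) and trace-level day recordings
(:func:`simulate_traces`) whose phase plateaus are constructed so that the
extraction pipeline recovers exactly the simulated features after day-blank
correction. :func:`oracle_lod` supplies the ground-truth detectability of
the latent channel — closed form plus a Monte-Carlo cross-check — against
which estimated LODs can be judged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DesignError
from .features import FeatureMatrix
from .io import DayRecording, SensorTrace, DEFAULT_SCHEDULE

__all__ = [
    "SensorModelSpec",
    "StudyDesign",
    "OracleResult",
    "simulate_features",
    "simulate_traces",
    "oracle_lod",
    "diacetyl_like",
    "ethyl_acetate_like",
]


@dataclass(frozen=True)
class SensorModelSpec:
    """Response and noise model of the simulated sensor array.

    Parameters
    ----------
    n_sensors : sensor count of the array (62 in the reference instrument).
    sensitivity : overall signal change per ppm at c → 0 (arbitrary signal units).
    sensitivity_cv : relative spread of per-sensor sensitivities around 1.
    kappa : saturation scale in ppm; response is quasi-linear for c ≪ κ.
    sigma0 : additive noise SD at c = 0, per sensor.
    hetero_lambda : noise SD growth per ppm (0 = homoscedastic).
    day_drift_sd : SD of additive per-(day, sensor) offsets.
    common_factor_weight : fraction of each sensor's sensitivity carried by
        the shared latent channel; 1 gives an exactly rank-one mean response.
    interferent_strength : scale of a second latent channel uncorrelated
        with concentration (0 = single-latent).
    interferent_sd : SD of the interferent latent variable per sample.
    sensor_seed : seed fixing the array's loading pattern, so that every
        study drawn from the same spec shares one "instrument".
    """

    n_sensors: int = 62
    sensitivity: float = 1.0
    sensitivity_cv: float = 0.15
    kappa: float = 10.0
    sigma0: float = 0.25
    hetero_lambda: float = 0.0
    day_drift_sd: float = 0.0
    common_factor_weight: float = 1.0
    interferent_strength: float = 0.0
    interferent_sd: float = 1.0
    sensor_seed: int = 20240530

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.sigma0 < 0 or self.day_drift_sd < 0 or self.hetero_lambda < 0:
            raise ValueError("noise scales must be non-negative")
        if not 0.0 <= self.common_factor_weight <= 1.0:
            raise ValueError("common_factor_weight must lie in [0, 1]")

    def loadings(self) -> np.ndarray:
        """Per-sensor sensitivities a_s (deterministic given sensor_seed)."""
        rng = np.random.default_rng(self.sensor_seed)
        u = 1.0 + self.sensitivity_cv * rng.standard_normal(self.n_sensors)
        return self.sensitivity * u

    def idiosyncratic_kappas(self) -> np.ndarray:
        """Per-sensor saturation scales for the non-shared sensitivity part."""
        rng = np.random.default_rng(self.sensor_seed + 1)
        jitter = np.exp(0.3 * rng.standard_normal(self.n_sensors))
        return self.kappa * jitter

    def interferent_loadings(self) -> np.ndarray:
        """Interferent channel loadings b_s, deliberately non-orthogonal to a_s."""
        rng = np.random.default_rng(self.sensor_seed + 2)
        g = rng.standard_normal(self.n_sensors)
        a = self.loadings()
        return self.interferent_strength * (0.5 * a + self.sensitivity * g)

    def response(self, c: float | np.ndarray) -> np.ndarray:
        """Noise-free mean response of every sensor to concentration c (ppm)."""
        c = np.asarray(c, dtype=float)
        a = self.loadings()
        w = self.common_factor_weight
        shared = np.outer(c / (1.0 + c / self.kappa), a * w)
        if w < 1.0:
            ks = self.idiosyncratic_kappas()
            own = (c[..., None] / (1.0 + c[..., None] / ks)) * (a * (1.0 - w))
            shared = shared + own
        return shared


@dataclass(frozen=True)
class StudyDesign:
    """Dilution-series layout: levels × days × replicates, blank included."""

    levels: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0)
    days: int = 3
    replicates_per_day: int = 3
    seed: int = 0
    substance: str = "analyte"

    def __post_init__(self) -> None:
        if 0.0 not in self.levels:
            raise DesignError("the design must include the blank level 0")
        if self.days < 1 or self.replicates_per_day < 1:
            raise DesignError("days and replicates must be >= 1")
        if any(l < 0 for l in self.levels):
            raise DesignError("concentrations must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.days * len(self.levels) * self.replicates_per_day

    @property
    def n_blanks(self) -> int:
        return self.days * self.replicates_per_day


def diacetyl_like(seed: int = 0) -> StudyDesign:
    """A design spanning the sub-ppm range relevant for a VDK off-flavor.

    Illustrative preset for tutorials; the level grid brackets the odor
    threshold band (0.10–0.17 ppm in lager beer).
    """
    return StudyDesign(levels=(0.0, 0.05, 0.1, 0.25, 0.5), seed=seed, substance="diacetyl")


def ethyl_acetate_like(seed: int = 0) -> StudyDesign:
    """A design in the hundreds-of-ppm range typical for ester calibration."""
    return StudyDesign(levels=(0.0, 500.0, 1000.0, 2500.0, 5000.0), seed=seed,
                       substance="ethyl acetate")


def _sample_table(design: StudyDesign) -> pd.DataFrame:
    rows = []
    for day in range(1, design.days + 1):
        counter = 0
        for level in sorted(design.levels):  # measured in ascending concentrations
            for rep in range(1, design.replicates_per_day + 1):
                rows.append(
                    {
                        "cycle_id": f"d{day}c{counter:03d}",
                        "day": day,
                        "substance": design.substance,
                        "concentration_ppm": float(level),
                        "replicate": rep,
                        "is_blank": level == 0.0,
                    }
                )
                counter += 1
    return pd.DataFrame(rows).set_index("cycle_id")


def simulate_features(model: SensorModelSpec, design: StudyDesign) -> FeatureMatrix:
    """Raw (pre-correction, pre-normalization) feature matrix of one study.

    Per sample i at level c on day d and sensor s:

        R = a_s · c/(1 + c/κ) + b_s·z_i + δ_{d,s} + ε_{i,s}

    with δ ~ N(0, day_drift_sd²), z ~ N(0, interferent_sd²) and
    ε ~ N(0, (σ0 + λ·c)²). Deterministic given ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    ann = _sample_table(design)
    conc = ann["concentration_ppm"].to_numpy()
    mean = model.response(conc)
    deltas = rng.normal(0.0, model.day_drift_sd, size=(design.days, model.n_sensors))
    day_idx = ann["day"].to_numpy() - 1
    noise_sd = model.sigma0 + model.hetero_lambda * conc
    eps = rng.standard_normal(mean.shape) * noise_sd[:, None]
    values = mean + deltas[day_idx] + eps
    if model.interferent_strength > 0:
        z = rng.normal(0.0, model.interferent_sd, size=len(conc))
        values = values + np.outer(z, model.interferent_loadings())
    sensor_ids = [f"s{j:02d}" for j in range(1, model.n_sensors + 1)]
    return FeatureMatrix(
        values=pd.DataFrame(values, index=ann.index, columns=sensor_ids),
        annotations=ann,
    )


def simulate_traces(
    model: SensorModelSpec,
    design: StudyDesign,
    schedule: Sequence[tuple[str, float]] = DEFAULT_SCHEDULE,
    dt: float = 1.0,
    baseline_resistance: float = 1.0e5,
) -> tuple[list[DayRecording], pd.DataFrame]:
    """Day-level resistance recordings whose plateaus encode the features.

    Phases A and B sit at a per-(day, sensor) baseline resistance; phase C
    plateaus at baseline + raw feature + an ethanol-matrix offset shared by
    all cycles of a day. Plateaus are stationary (the trailing-window mean
    is exact), so segmenting and extracting features from these recordings
    reproduces :func:`simulate_features` for the same model/design minus
    each day's blank mean — i.e. exactly the reference-corrected features.
    Returns the recordings and the annotation table (in measurement order).
    """
    fm = simulate_features(model, design)
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 7]))
    ann = fm.annotations
    cycle_len = sum(d for _, d in schedule)
    n_per_phase = {label: int(round(d / dt)) for label, d in schedule}
    cycles_per_day = len(design.levels) * design.replicates_per_day

    recordings: list[DayRecording] = []
    for day in range(1, design.days + 1):
        day_rows = ann.index[ann["day"] == day]
        base = baseline_resistance * (1.0 + 0.02 * rng.standard_normal(model.n_sensors))
        ethanol_offset = rng.normal(0.0, 1.0, size=model.n_sensors)
        n_points = int(round(cycles_per_day * cycle_len / dt))
        t = np.arange(n_points) * dt
        traces = np.empty((model.n_sensors, n_points))
        pos = 0
        for cycle_id in day_rows:
            feat = fm.values.loc[cycle_id].to_numpy()
            for label, _ in schedule:
                n = n_per_phase[label]
                block = base if label != "C" else base + feat + ethanol_offset
                traces[:, pos : pos + n] = block[:, None]
                pos += n
        recordings.append(
            DayRecording(
                day=day,
                traces=[
                    SensorTrace(sid, t, traces[j])
                    for j, sid in enumerate(fm.values.columns)
                ],
            )
        )
    return recordings, ann.reset_index()


@dataclass(frozen=True)
class OracleResult:
    """Ground-truth LOD of a simulation model, closed form + Monte Carlo."""

    true_lod: float
    mc_lod: float
    k_used: float
    replicates: int
    se: float


def _invert_response(g: float, kappa: float) -> float:
    """Solve f(c) = c/(1+c/κ) = g for c."""
    if g >= kappa:
        raise DesignError("threshold exceeds the saturation asymptote; no finite LOD")
    return g / (1.0 - g / kappa)


def oracle_lod(
    model: SensorModelSpec,
    design: StudyDesign,
    k: float = 3.0,
    target: str | int = "latent",
    n_mc: int = 10_000,
    seed: int = 0,
) -> OracleResult:
    """True detectability of the latent channel (or one sensor).

    For the latent channel the array is read out along the sensitivity
    direction â: the projected signal is |a|·f(c) and the projected blank
    noise SD is σ_eff = sqrt(Σ a_s² σ_s²)/|a| (plus day-drift variance,
    which projects isotropically). The closed form solves
    f(c_LOD) = k·σ_eff/|a| and is cross-checked by Monte-Carlo simulation
    of the blank distribution: ``n_mc`` blank readouts give an empirical
    SD, threshold and the concentration whose mean readout meets it.
    """
    if model.sigma0 <= 0:
        raise DesignError("oracle requires sigma0 > 0")
    a = model.loadings()
    if target == "latent":
        if np.allclose(a, 0):
            raise DesignError("zero sensitivity: no latent channel")
        sigma_s = np.full(model.n_sensors, model.sigma0)
        var_proj = float(np.sum(a**2 * sigma_s**2) / np.sum(a**2))
        var_proj += model.day_drift_sd**2  # drift projects isotropically
        slope = float(np.sqrt(np.sum(a**2)))  # |a| · f'(0), f'(0) = 1
    else:
        j = int(target)
        if a[j] == 0:
            raise DesignError(f"sensor {j} has zero sensitivity")
        var_proj = model.sigma0**2 + model.day_drift_sd**2
        slope = abs(float(a[j]))
    sigma_eff = float(np.sqrt(var_proj))
    g = k * sigma_eff / slope
    true_lod = _invert_response(g, model.kappa)

    rng = np.random.default_rng(seed)
    if target == "latent":
        a_hat = a / np.linalg.norm(a)
        eps = rng.standard_normal((n_mc, model.n_sensors)) * model.sigma0
        if model.day_drift_sd > 0:
            eps += rng.standard_normal((n_mc, model.n_sensors)) * model.day_drift_sd
        proj = eps @ a_hat
    else:
        proj = rng.normal(0.0, sigma_eff, size=n_mc)
    sd_emp = float(proj.std(ddof=1))
    g_mc = k * sd_emp / slope
    mc_lod = _invert_response(g_mc, model.kappa)
    se_g = g_mc / np.sqrt(2.0 * (n_mc - 1))
    se = float(se_g / (1.0 - g_mc / model.kappa) ** 2)
    return OracleResult(true_lod=true_lod, mc_lod=mc_lod, k_used=float(k),
                        replicates=n_mc, se=se)
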