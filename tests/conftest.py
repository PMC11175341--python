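import numpy as np
import pandas as pd
import pytest

import enoselod as el


@pytest.fixture
def default_model() -> el.SensorModelSpec:
    return el.SensorModelSpec()


@pytest.fixture
def default_design() -> el.StudyDesign:
    return el.StudyDesign(seed=0)


@pytest.fixture
def study_features(default_model, default_design) -> el.FeatureMatrix:
    """Reference-corrected, z-scored features of the default simulated study."""
    raw = el.simulate_features(default_model, default_design)
    return el.zscore_normalize(el.subtract_ethanol_reference(raw))


def make_constant_cycle(
    cycle_id: str,
    sample_values: dict[str, float],
    baseline_values: dict[str, float],
    day: int = 1,
    concentration: float = 1.0,
    replicate: int = 1,
) -> el.MeasurementCycle:
    """A cycle whose A and C phases are flat plateaus at the given levels."""
    t = np.arange(10.0)
    phases = {
        "A": [el.SensorTrace(s, t, np.full(10, v)) for s, v in baseline_values.items()],
        "C": [el.SensorTrace(s, t, np.full(10, v)) for s, v in sample_values.items()],
    }
    ann = el.SampleAnnotation(
        day=day,
        substance="test",
        concentration=concentration,
        replicate=replicate,
        is_blank=concentration == 0.0,
    )
    return el.MeasurementCycle(cycle_id=cycle_id, phase_traces=phases, annotation=ann)


@pytest.fixture
def constant_cycle_factory():
    return make_constant_cycle


def feature_matrix_from_values(
    values: np.ndarray, conc: np.ndarray, days: np.ndarray | None = None
) -> el.FeatureMatrix:
    """Wrap a plain array + concentrations into a FeatureMatrix."""
    n, p = values.shape
    conc = np.asarray(conc, dtype=float)
    days = np.ones(n, dtype=int) if days is None else np.asarray(days)
    index = [f"c{i:03d}" for i in range(n)]
    ann = pd.DataFrame(
        {
            "day": days,
            "substance": "test",
            "concentration_ppm": conc,
            "replicate": 1,
            "is_blank": conc == 0,
        },
        index=index,
    )
    vals = pd.DataFrame(values, index=index, columns=[f"s{j:02d}" for j in range(p)])
    return el.FeatureMatrix(values=vals, annotations=ann)


@pytest.fixture
def fm_factory():
    return feature_matrix_from_values
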