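import numpy as np
import pytest

from osmech import (
    StretchProtocol,
    generate_cohort,
    clinical_cohort_config,
)
from osmech.synthetic import ClassParams, SynthConfig


@pytest.fixture(scope="session")
def default_protocol() -> StretchProtocol:
    """Mid-power clinical protocol: 800 mW, 1 s baseline + 10 s + 2 s at 30 Hz."""
    from osmech import clinical_protocols

    return clinical_protocols()[1]


@pytest.fixture(scope="session")
def cheap_protocols() -> list[StretchProtocol]:
    """Low-frame-rate protocols for tests where per-frame cost dominates."""
    from osmech.rheology import force_from_power, stress_from_power

    return [
        StretchProtocol(
            laser_power=p,
            step_stress=stress_from_power(p),
            peak_force=force_from_power(p),
            frame_rate=5.0,
        )
        for p in (400.0, 800.0, 1200.0)
    ]


@pytest.fixture(scope="session")
def small_cohort():
    """30 cells per class from the clinical-cohort preset (seeded)."""
    cfg = clinical_cohort_config(n_per_class=30, seed=11)
    traces, truths = generate_cohort(cfg, seed=11)
    return cfg, traces, truths


@pytest.fixture(scope="session")
def noise_free_passive_trace(default_protocol):
    """A single noise-free, non-contractile cell for closed-form checks."""
    from osmech import CellGroundTruth, simulate_trace

    truth = CellGroundTruth(
        cell_id="passive",
        class_label="PBMC",
        elastic_modulus=30.0,
        viscosity=75.0,
        activity=0.0,
        radius=5.0,
        initial_ellipticity=1.0,
        brightness=1.0,
        rotation_rate=0.0,
        poisson_ratio=0.45,
    )
    trace = simulate_trace(truth, default_protocol, axis_noise_sd=0.0, seed=0)
    return truth, trace
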