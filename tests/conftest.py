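import numpy as np
import pytest

from pvloop.sim import (CircuitParams, VentricleParams, simulate_occlusion,
                        simulate_stage)
from pvloop.trace import PVTrace


@pytest.fixture(scope="session")
def bench_params():
    """A well-conditioned chamber/circuit pair for analysis validation."""
    from pvloop.sim import recovery_benchmark_params

    return recovery_benchmark_params(1.15, 0.7)


@pytest.fixture(scope="session")
def steady_sim(bench_params):
    vp, cp = bench_params
    return simulate_stage(vp, cp, n_beats=10, ventricle="LV")


@pytest.fixture(scope="session")
def occlusion_sim(bench_params):
    vp, cp = bench_params
    return simulate_occlusion(vp, cp, n_beats=22, ramp_rate=0.30,
                              ventricle="LV")


@pytest.fixture(scope="session")
def small_study():
    """A reduced crossover study shared by the slower integration tests."""
    from pvloop.study import CrossoverStudySpec, generate_study

    spec = CrossoverStudySpec(n_control=2, n_pab=2, n_beats_stage=6,
                              n_beats_occlusion=18, seed=11)
    return generate_study(spec)


def make_trace(pressure, volume=None, fs=2000.0, ventricle="LV"):
    p = np.asarray(pressure, dtype=float)
    v = np.full_like(p, 50.0) if volume is None else np.asarray(volume, float)
    t = np.arange(p.size) / fs
    return PVTrace(t, p, v, sampling_rate=fs, ventricle=ventricle)
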