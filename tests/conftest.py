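import numpy as np
import pytest

import vitalguard as vg


@pytest.fixture(scope="session")
def default_benchmark():
    """The packaged synthetic benchmark: default generator, 5 medical
    events + 10 sensor faults at magnitude 0.50, fixed seed."""
    return vg.make_benchmark(vg.GeneratorConfig(n_samples=1000, seed=0))


@pytest.fixture(scope="session")
def benchmark_decisions(default_benchmark):
    return vg.run_pipeline(default_benchmark.series)


@pytest.fixture()
def clean_series():
    """A short anomaly-free stream with default physiology."""
    return vg.generate_vitals(vg.GeneratorConfig(n_samples=200, seed=11))


@pytest.fixture()
def constant_series():
    values = np.tile([85.0, 80.0, 80.0, 16.0, 97.5], (60, 1))
    return vg.VitalSeries(
        parameter_names=["ABPmean", "HR", "Pulse", "Respiration", "SpO2"],
        values=values,
    )
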