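import numpy as np
import pandas as pd
import pytest

from tcresponse import de, kinetics, normalize
from tcresponse.containers import CountExperiment
from tcresponse.simulate import SimulationConfig, simulate_counts


def run_time_course(cfg: SimulationConfig):
    """Simulate and run the full statistical chain; shared by several tests.

    Returns (truth, filtered experiment, contrast tables, per-gene calls).
    """
    exp, truth = simulate_counts(cfg)
    filt = normalize.filter_low_counts(exp)
    norm = normalize.normalize_experiment(filt)
    X = de.design_matrix(filt.design)
    w = normalize.voom_weights(norm.log_cpm, X, lib_sizes=norm.effective_lib_sizes)
    mfit = de.moderate(de.fit_models(norm.log_cpm, w.weights, X))
    tabs = de.test_contrasts(mfit)
    calls = kinetics.classify_genes(tabs)
    return truth, filt, tabs, calls


@pytest.fixture
def toy_experiment() -> CountExperiment:
    """Six genes, nine samples (three replicates per time point)."""
    rng = np.random.default_rng(42)
    counts = pd.DataFrame(
        rng.poisson(200, size=(6, 9)),
        index=[f"g{i}" for i in range(6)],
        columns=[f"s{i}" for i in range(9)],
    )
    design = pd.DataFrame(
        {"time": ["0"] * 3 + ["0.5h"] * 3 + ["3h"] * 3, "replicate": [1, 2, 3] * 3},
        index=counts.columns.rename("sample_id"),
    )
    return CountExperiment(counts, design)
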