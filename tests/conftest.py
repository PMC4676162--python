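import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as hyp_settings

from schurdle import DesignSpec, SimScenario, apply_threshold, simulate

hyp_settings.register_profile("deterministic", derandomize=True)
hyp_settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_sim():
    """Modest two-arm simulation with CDR structure and mixed effects."""
    sc = SimScenario(
        n_cells=120,
        n_genes=60,
        disc_effect=1.0,
        cont_effect=1.0,
        frac_affected=0.3,
        seed=42,
    )
    assay, cov, truth = simulate(sc)
    return assay, cov, truth


@pytest.fixture(scope="session")
def null_sim():
    """No-effect simulation used by calibration-style tests."""
    sc = SimScenario(n_cells=150, n_genes=80, seed=7)
    assay, cov, truth = simulate(sc)
    return assay, cov, truth


@pytest.fixture()
def tiny_assay():
    """Hand-sized assay: 6 cells x 4 genes, deterministic values."""
    rng = np.random.default_rng(0)
    vals = np.round(rng.uniform(0, 8, size=(6, 4)), 2)
    vals[vals < 2.0] = 0.0
    return apply_threshold(vals, 0.0)


@pytest.fixture()
def binary_design():
    """Covariates + spec for a 2-arm design without CDR."""

    def make(n_cells: int, include_cdr: bool = False) -> DesignSpec:
        treat = np.array(["ctrl", "stim"])[(np.arange(n_cells) >= n_cells // 2).astype(int)]
        cov = pd.DataFrame({"treatment": treat})
        return DesignSpec(cov, ["treatment"], include_cdr=include_cdr)

    return make
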