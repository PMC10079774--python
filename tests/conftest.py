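import numpy as np
import pytest

from sfdikit import BoundaryParams, McConfig, OpticalProperties, PhaseFunction, run_pencil_beam


@pytest.fixture(scope="session")
def boundary():
    """Tissue-air boundary (n_in=1.33, n_out=1.00, A ~ 2.515)."""
    return BoundaryParams.from_indices(1.33, 1.00)


@pytest.fixture(scope="session")
def small_profile():
    """A quick pencil-beam profile shared by transform/I-O tests."""
    cfg = McConfig(
        props=OpticalProperties(0.01, 5.0),
        phase=PhaseFunction.hg(0.9),
        n_photons=5_000,
        bin_width=0.01,
        n_bins=10_000,
        seed=42,
    )
    return run_pencil_beam(cfg)
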