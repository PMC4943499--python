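import numpy as np
import pytest

from ppisite import pipeline, synthetic

# Reduced quadrature keeps structure-level tests fast; convergence of the
# quadrature itself is tested separately.
FAST_N_POINTS = 240


@pytest.fixture(scope="session")
def toy_complex():
    spec = synthetic.ToyComplexSpec(
        n_res_per_chain=30, contact_patch_size=10, inter_chain_gap=4.0, seed=1
    )
    return synthetic.make_toy_complex(spec)


@pytest.fixture(scope="session")
def toy_profiles(toy_complex):
    structure, truth = toy_complex
    signal = synthetic.SignalSpec(effect_size=2.0, seed=2)
    return {
        chain.chain_id: synthetic.make_synthetic_profiles(
            chain.length, truth[chain.chain_id], signal
        )
        for chain in structure.chains
    }


@pytest.fixture(scope="session")
def toy_extraction(toy_complex, toy_profiles):
    structure, _ = toy_complex
    config = pipeline.RunConfig(sasa_n_points=FAST_N_POINTS)
    return pipeline.extract_from_structure(structure, toy_profiles, config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
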