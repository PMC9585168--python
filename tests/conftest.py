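import pytest

from zfcardio import (HeartSimParams, extract_geometry_trace,
                      phenotype_sequence, render_sequence)


@pytest.fixture(scope="session")
def default_params():
    """Healthy control fish: 150 bpm, 100 x 60 um ventricle, 30 fps, 3 s."""
    return HeartSimParams()


@pytest.fixture(scope="session")
def noiseless_fish(default_params):
    """One rendered noiseless control fish plus its analytic ground truth."""
    return render_sequence(default_params, seed=11, fish_id="ctrl_fixture")


@pytest.fixture(scope="session")
def noiseless_trace(noiseless_fish):
    seq, _ = noiseless_fish
    return extract_geometry_trace(seq)


@pytest.fixture(scope="session")
def noiseless_result(noiseless_fish):
    """Full phenotyping result of the noiseless control fish."""
    seq, _ = noiseless_fish
    return phenotype_sequence(seq)
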