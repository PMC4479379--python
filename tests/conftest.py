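import numpy as np
import pytest

from generich import FrequencySpectrum, default_complete_reference, default_population

# One master seed for the whole suite; heavy fixtures are session-scoped so
# the selection-harness and extra-sample studies share the same reference.
SEED = 1


@pytest.fixture(scope="session")
def reference_population():
    return default_population(seed=SEED)


@pytest.fixture(scope="session")
def complete_reference():
    """Complete sample (f1 = 0, g = G) from the default synthetic scenario."""
    return default_complete_reference(seed=SEED)


@pytest.fixture()
def worked_spectrum():
    """The near-complete human-transcriptome spectrum used as a worked example."""
    return FrequencySpectrum({1: 3, 2: 9, 3: 27, 4: 15, 5: 23, 6: 439})


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture()
def write_table(tmp_path):
    """Factory writing a small delimited count table and returning its path."""

    def _write(text, name="counts.tsv"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write
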