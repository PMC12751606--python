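import numpy as np
import pytest

from ppinet.io import STANDARD_AMINO_ACIDS, PropensityTable, load_default_propensity_table


@pytest.fixture(scope="session")
def bundled_table():
    return load_default_propensity_table()


@pytest.fixture
def toy_table():
    """Single constant scale: every residue maps to 1.0 on scale T."""
    return PropensityTable(
        scales=("T",), values={("T", aa): 1.0 for aa in STANDARD_AMINO_ACIDS}
    )


@pytest.fixture
def write_fasta(tmp_path):
    def _write(name, records):
        path = tmp_path / name
        path.write_text("".join(f">{h}\n{s}\n" for h, s in records))
        return path

    return _write


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
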