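import numpy as np
import pytest

from polyprobe.proteome_io import Proteome, ProteinEntry
from polyprobe.synthetic_data import SyntheticStudyConfig, generate_study


@pytest.fixture(scope="session")
def default_study():
    """One full synthetic study at the default (2000-protein) conditions."""
    return generate_study(SyntheticStudyConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture()
def tiny_proteome():
    return Proteome([
        ProteinEntry("P1", "P1 acidic-rich", "M" + "E" * 25 + "GGKR"),
        ProteinEntry("P2", "P2 plain", "MGGAVLIKRS" * 5),
        ProteinEntry("P3", "P3 short", "MKR"),
    ])


def random_proteome(rng, n, min_len=1, max_len=200, letters="ACDEFGHIKLMNPQRSTVWYBZXUO"):
    alphabet = np.array(list(letters))
    entries = []
    for i in range(n):
        L = int(rng.integers(min_len, max_len + 1))
        entries.append(ProteinEntry(f"R{i:05d}", f"R{i:05d} random",
                                    "".join(rng.choice(alphabet, size=L))))
    return Proteome(entries)
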