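import numpy as np
import pytest

from gofuse.simulate import SimConfig, generate_cohort


FIVE_TERM_OBO = """format-version: 1.2

[Term]
id: GO:0000001
name: root process
namespace: biological_process
def: "The root process." [TEST:1]

[Term]
id: GO:0000002
name: child process
namespace: biological_process
def: "A child process." [TEST:2]
is_a: GO:0000001

[Term]
id: GO:0000003
name: part process
namespace: biological_process
def: "A part." [TEST:3]
relationship: part_of GO:0000001

[Term]
id: GO:0000004
name: regulator
namespace: biological_process
def: "A regulator." [TEST:4]
relationship: regulates GO:0000002
is_a: GO:0000001

[Term]
id: GO:0000005
name: binding
namespace: molecular_function
def: "Binds something." [TEST:5]

[Term]
id: GO:0000006
name: gone
namespace: biological_process
def: "Obsolete term." [TEST:6]
is_obsolete: true
"""


@pytest.fixture
def five_term_obo(tmp_path):
    path = tmp_path / "five.obo"
    path.write_text(FIVE_TERM_OBO)
    return path


@pytest.fixture(scope="session")
def small_cohort():
    """60 proteins, 10 terms per aspect: fast enough for training tests."""
    return generate_cohort(SimConfig(n_proteins=60, gamma_per_aspect=10, seed=0))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
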