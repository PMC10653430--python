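import pytest

from optenvelope import save_json
from optenvelope.toys import make_coupling_toy, make_reversible_toy

BIOMASS = "R3"
PRODUCT = "EX_P"


@pytest.fixture
def toy():
    """Irreversible 5-metabolite / 8-reaction coupling toy (maintenance 1)."""
    return make_coupling_toy()


@pytest.fixture
def toy_no_maintenance():
    return make_coupling_toy(maintenance_lb=0.0)


@pytest.fixture
def rev_toy():
    """Coupling toy with R5 reversible, before irreversible conversion."""
    return make_reversible_toy()


@pytest.fixture
def toy_json(toy, tmp_path):
    path = tmp_path / "toy.json"
    save_json(toy, str(path))
    return str(path)
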