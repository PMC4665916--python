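import pytest

from pseudokit.model import Namespace
from pseudokit.protocols import Client
from pseudokit.synth import GeneratorSpec, example_three_subjects, generate_registry
from pseudokit.system import deploy

NS_A = Namespace("ns-a")
NS_B = Namespace("ns-b")


@pytest.fixture(scope="session")
def three_record_dataset():
    return example_three_subjects()


@pytest.fixture(scope="session")
def registry10():
    return generate_registry(GeneratorSpec(n_subjects=10, n_sites=3, seed=42))


@pytest.fixture()
def indirect_system(registry10):
    return deploy(registry10, mode="indirect", seed=7)


@pytest.fixture()
def direct_system(registry10):
    return deploy(registry10, mode="direct", seed=7)


def user_of_role(registry, role, site=None):
    for u in registry.users:
        if u.role == role and (site is None or u.site == site):
            return u
    raise LookupError(role)


@pytest.fixture()
def make_client():
    def _make(system, registry, role, site=None):
        u = user_of_role(registry, role, site)
        return Client(system, u.username, u.secret)

    return _make
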