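import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def uniform_genome():
    """One shared 300 kb i.i.d. uniform sequence (seeded)."""
    from qword.synthetic import random_genome

    return random_genome(300_000, seed=424242, id="iid")
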