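import pytest
from hypothesis import HealthCheck, settings

from lnadrop import simulate as sim
from lnadrop.thermo import BufferConditions

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cond():
    """Assay buffer: 50 mM monovalent, 3.0 mM Mg2+, 0.8 mM dNTP, 250 nM strand."""
    return BufferConditions()


@pytest.fixture(scope="session")
def locus():
    """Deterministic synthetic target locus (reference, cut_site, HdrTemplate)."""
    return sim.make_default_locus()
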