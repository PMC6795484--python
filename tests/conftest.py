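import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def table1_certificate():
    """The worked-example certificate: cocaine overdose with cardiac SCC."""
    from odcert import DeathCertificate

    return DeathCertificate(
        id="example",
        cause_a="ACUTE COCAINE TOXICITY",
        scc="HYPERTENSIVE CARDIOVASCULAR DISEASE, OBESITY",
        injury_desc="ACCIDENTAL OVERDOSE",
    )
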