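import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(20210318)


@pytest.fixture(scope="session")
def planted_triple():
    """A medium synthetic triple with 20 ingroup + 2 outgroup planted events."""
    from svlegacy.synthdata import EventSpec, gen_ancestor, plant_events

    r = np.random.default_rng(7)
    anc = gen_ancestor(120_000, 0.43, r)
    mechs = ["tandem_dup", "ectopic_ins", "deletion", "mixed"]
    spec = [
        EventSpec("A" if i % 2 else "B", mechs[i % 4], int(r.integers(60, 400)),
                  insertion_fraction=0.75)
        for i in range(20)
    ]
    spec.append(EventSpec("outgroup", "deletion", 200))
    spec.append(EventSpec("outgroup", "ectopic_ins", 150))
    return plant_events(anc, spec, r)
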