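import pytest
from hypothesis import HealthCheck, settings

import mitocomp as mc

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ancestral_genome():
    """One simulated genome in the unrearranged lepidopteran order."""
    record, truth = mc.simulate_mitogenome(mc.ancestral_config(seed=7))
    return record, truth


@pytest.fixture(scope="session")
def variant_genome():
    """The rearranged preset: trnA/trnR swap + three planted AT tracts."""
    record, truth = mc.simulate_mitogenome(mc.conopomorpha_config(seed=1))
    return record, truth


@pytest.fixture(scope="session")
def ancestral_order():
    return mc.GeneOrder.from_signed_labels(
        [("-" if s == "-" else "") + n
         for n, _c, _l, s in mc.gene_plan("ancestral")]).normalized("trnM")
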