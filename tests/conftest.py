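import pytest

from ccslib.pipeline import curate
from ccslib.synthetic import SimConfig, simulate_campaign


@pytest.fixture(scope="session")
def campaign2000():
    """Reference synthetic campaign: 2,000 chemicals, duplicate injections,
    0.3% replicate CV, 2% multimer rate at +40% CCS inflation, seed 7."""
    cfg = SimConfig(n_chemicals=2000, seed=7)
    registry, truth, features, manifest, cal = simulate_campaign(cfg)
    return {
        "cfg": cfg,
        "registry": registry,
        "truth": truth,
        "features": features,
        "manifest": manifest,
        "cal": cal,
    }


@pytest.fixture(scope="session")
def curated2000(campaign2000):
    """Curation result for the reference campaign."""
    return curate(
        campaign2000["registry"], campaign2000["features"], campaign2000["cal"]
    )


@pytest.fixture(scope="session")
def small_campaign():
    """Small campaign for fast structural tests."""
    cfg = SimConfig(n_chemicals=300, seed=11)
    registry, truth, features, manifest, cal = simulate_campaign(cfg)
    result = curate(registry, features, cal)
    return {
        "cfg": cfg,
        "registry": registry,
        "truth": truth,
        "features": features,
        "manifest": manifest,
        "cal": cal,
        "result": result,
    }
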