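import pytest

from ventflux.pipeline import run_pipeline
from ventflux.synthetic import generate_scenario


@pytest.fixture(scope="session")
def sulfide_variation_run(tmp_path_factory):
    """A generated sulfide variation experiment plus its pipeline outputs."""
    data = tmp_path_factory.mktemp("sv_data")
    out = tmp_path_factory.mktemp("sv_out")
    config, truth, scans, tissue = generate_scenario(
        "sulfide_variation", seed=11, out_dir=data
    )
    manifest = run_pipeline(data, out)
    return {
        "config": config,
        "truth": truth,
        "data": data,
        "out": out,
        "manifest": manifest,
    }


@pytest.fixture(scope="session")
def sulfur_free_run(tmp_path_factory):
    data = tmp_path_factory.mktemp("sf_data")
    out = tmp_path_factory.mktemp("sf_out")
    config, truth, scans, tissue = generate_scenario("sulfur_free", seed=7, out_dir=data)
    manifest = run_pipeline(data, out)
    return {
        "config": config,
        "truth": truth,
        "data": data,
        "out": out,
        "manifest": manifest,
    }
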