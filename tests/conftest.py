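import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

import ssn_divergence as sd


@pytest.fixture(scope="session")
def scheme():
    return sd.ScoringScheme()


@pytest.fixture(scope="session")
def blosum62(scheme):
    return scheme.matrix()


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """Full pipeline run on the default 15-family synthetic dataset (seed 1)."""
    out = tmp_path_factory.mktemp("default_run")
    config = sd.PipelineConfig(
        simulate=sd.default_configs(1), seed=1, out_dir=str(out)
    )
    report = sd.run_pipeline(config)
    return report


@pytest.fixture()
def toy_records():
    """Three hand-made records in one family across the three habitats."""
    return [
        sd.ProteinRecord("a", "fam1", "mat", "MKVLINGKTLKGEITVDGAKNAVLPIL"),
        sd.ProteinRecord("b", "fam1", "sediment", "MKVLINGKTLKGEITVDGAKNAVLPIM"),
        sd.ProteinRecord("c", "fam1", "water", "MKWLINGHTLKGEITREGAKNAVLPIL"),
    ]
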