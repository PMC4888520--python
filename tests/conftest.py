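import pytest

from screenval import default_preset, expected_confusion


@pytest.fixture(scope="session")
def preset():
    return default_preset()


@pytest.fixture(scope="session")
def preset_counts(preset):
    return {
        g.name: expected_confusion(g, preset.platform, preset.population)
        for g in preset.genes
    }
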