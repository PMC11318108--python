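import pytest

from xdosage import AUTOSOMAL, SimMarker, SynthConfig, X_LINKED


def make_config(
    amplification=2.0,
    rep_noise_sd=0.0,
    sample_offset_sd=0.0,
    outlier_prob=0.0,
    seed=0,
    **kwargs,
):
    """SynthConfig with a uniform amplification factor (noise-free default)."""
    markers = (
        SimMarker("VSSC", X_LINKED, amplification, 24.0),
        SimMarker("SL4108", X_LINKED, amplification, 24.4),
        SimMarker("SL3442", X_LINKED, amplification, 23.8),
        SimMarker("AL40057", AUTOSOMAL, amplification, 23.5),
    )
    return SynthConfig(
        markers=markers,
        rep_noise_sd=rep_noise_sd,
        sample_offset_sd=sample_offset_sd,
        outlier_prob=outlier_prob,
        seed=seed,
        **kwargs,
    )


@pytest.fixture
def doubling_config():
    """Noise-free generator with perfect doubling at every marker."""
    return make_config()


@pytest.fixture
def panel(doubling_config):
    return doubling_config.panel()
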