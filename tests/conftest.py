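import pytest

from topoqc.layout import build_layout
from topoqc.synth import SyntheticScreenConfig, generate_screen


@pytest.fixture(scope="session")
def default_screen():
    """Full-scale screen at the study defaults (9 chips, 66x66, ~1.2M
    cells); generated once per session for the calibration checks."""
    return generate_screen(SyntheticScreenConfig(seed=42))


@pytest.fixture(scope="session")
def small_screen_config():
    """Reduced geometry (3 chips, 16x16 grid, 126 designs) that keeps the
    full statistical structure but runs in seconds."""
    return SyntheticScreenConfig(
        n_chips=3, high_density_chips=2, n_designs=126,
        n_rows=16, n_cols=16, seed=7)


@pytest.fixture(scope="session")
def small_screen(small_screen_config):
    return generate_screen(small_screen_config)


@pytest.fixture()
def small_layout():
    return build_layout(6, 4, 4, 4, seed=7)
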