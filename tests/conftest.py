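import numpy as np
import pytest

from sc2wb import ArrayLayout, TargetSpec
from sc2wb.layout import LaneProfile


@pytest.fixture
def layout_2x2():
    return ArrayLayout(n_rows=2, n_cols=2)


@pytest.fixture
def cyt_target():
    """Single purely cytoplasmic target (all signal east)."""
    return TargetSpec(
        name="TurboGFP",
        nuclear_fraction_mean=0.0,
        nuclear_fraction_sd=0.0,
        expected_compartment="cytoplasmic",
    )


@pytest.fixture
def make_profile():
    """Build a LaneProfile with given Gaussian bands and noise.

    bands: list of (amplitude, center_um, sigma_um); the default grid spans
    +/-500 um at 5 um spacing with a 32 um well at the origin.
    """

    def _make(bands=(), noise_sd=0.0, seed=0, spacing=5.0, half_len=500.0,
              background_sd=None):
        positions = np.arange(-half_len, half_len, spacing)
        intensities = np.zeros_like(positions)
        for A, x0, sig in bands:
            intensities += A * np.exp(-0.5 * ((positions - x0) / sig) ** 2)
        if noise_sd > 0:
            rng = np.random.default_rng(seed)
            intensities = intensities + rng.normal(0, noise_sd, positions.size)
        return LaneProfile(
            cell_id=0,
            channel="AF647",
            positions=positions,
            intensities=intensities,
            background_sd=noise_sd if background_sd is None else background_sd,
            well_mask=(-16.0, 16.0),
        )

    return _make
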