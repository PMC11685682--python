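import numpy as np
import pytest

import nbisim as nb
from nbisim import fixtures as fx


@pytest.fixture(scope="session")
def grid():
    return nb.DEFAULT_GRID


@pytest.fixture(scope="session")
def cmf(grid):
    return nb.cie_1931_cmf(grid)


@pytest.fixture(scope="session")
def fixture_config(grid):
    return fx.FixtureConfig(seed=0, grid=grid)


@pytest.fixture(scope="session")
def checker_reflectances(fixture_config):
    return fx.generate_checker_reflectances(fixture_config)


@pytest.fixture(scope="session")
def wli_illuminant(grid):
    return fx.generate_wli_illuminant(grid)


@pytest.fixture(scope="session")
def fitted_pipeline(grid, cmf, fixture_config, checker_reflectances, wli_illuminant):
    """The full planted chain fit on the zero-noise synthetic checker."""
    refl = checker_reflectances
    rgbs, _ = fx.render_camera_rgb(refl, wli_illuminant, cmf=cmf)
    camera_xyz = nb.srgb_to_xyz(nb.srgb_decode(rgbs.astype(float) / 255.0))
    spectrum_xyz = nb.spectrum_to_xyz(refl, wli_illuminant, cmf)
    correction = nb.fit_correction(camera_xyz, spectrum_xyz)
    corrected = nb.apply_correction(correction, camera_xyz)
    basis = nb.fit_pca(refl, 12, grid)
    conversion = nb.fit_conversion_matrix(nb.project_scores(basis, refl), corrected)
    return {
        "reflectances": refl,
        "rgbs": rgbs,
        "camera_xyz": camera_xyz,
        "spectrum_xyz": spectrum_xyz,
        "correction": correction,
        "corrected": corrected,
        "basis": basis,
        "conversion": conversion,
    }
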