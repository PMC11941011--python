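import numpy as np
import pytest

import savehsi as sh


@pytest.fixture(scope="session")
def grid():
    return sh.SpectralGrid()


@pytest.fixture(scope="session")
def d65(grid):
    return sh.d65_illuminant(grid)


@pytest.fixture(scope="session")
def cmfs(grid):
    return sh.cie_1931_cmfs(grid)


@pytest.fixture(scope="session")
def checker(grid):
    return sh.make_reference_checker(grid)


def build_rig(grid, camera_noise=0.002, spectrometer_noise=0.002, seed=20240714):
    """Synthetic calibration experiment: virtual camera + virtual spectrometer
    on the reference checker, full calibration fit."""
    checker = sh.make_reference_checker(grid)
    cam = sh.default_virtual_camera(grid, noise_sigma=camera_noise, seed=seed)
    rgb = sh.simulate_camera_capture(checker, cam)
    measured = sh.simulate_spectrometer(
        checker.reflectances, spectrometer_noise, seed=seed + 1
    )
    model = sh.SpectralCalibration(rgb, measured, grid)
    results = model.fit(order=3, n_components=6)
    recon = results.reconstruct(rgb)
    true_rmse = np.array(
        [sh.patch_rmse(r, t, grid=grid) for r, t in zip(recon, checker.reflectances)]
    )
    return {
        "checker": checker,
        "camera_rgb": rgb,
        "measured": measured,
        "model": model,
        "results": results,
        "recon": recon,
        "rmse_vs_truth": true_rmse,
    }


@pytest.fixture(scope="session")
def rig(grid):
    """The default synthetic rig (noise sigma 0.002, fixed seed)."""
    return build_rig(grid)
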