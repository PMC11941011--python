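"""Synthetic study inputs with known ground truth.

Everything the calibration and synthesis stages consume can be generated
here: a 24-patch reference colour checker with smooth natural-surface-like
reflectances, a virtual camera with known spectral sensitivities, mild gamma
nonlinearity, dark offset and seeded readout noise, a virtual spectrometer
with additive noise, and circular skin-lesion scenes whose chromophore
absorption peaks at the narrow-band wavelengths (415/540 nm) so the enhanced
rendering carries diagnostic contrast.

The chromophore curves are smooth parametric stand-ins (Gaussian absorption
bands for hemoglobin, an exponentially decaying band for melanin), not
literature extinction tables: they exercise the band-contrast mechanism and
are clearly synthetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import ColorCheckerSet, SpectralCube
from .colorimetry import (
    CMFSet,
    ContractError,
    Illuminant,
    SpectralGrid,
    cie_1931_cmfs,
    d65_illuminant,
    spectra_to_xyz,
)

__all__ = [
    "make_reference_checker",
    "VirtualCamera",
    "default_virtual_camera",
    "simulate_camera_capture",
    "simulate_spectrometer",
    "LesionSceneParams",
    "make_lesion_scene",
]


def _sig(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    """Smooth cut-on edge (0 below center, 1 above)."""
    return 1.0 / (1.0 + np.exp(-(wl - center) / width))


def _bump(wl: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - mu) / sigma) ** 2)


# name -> (base, [("sig"|"bump", amplitude, p1, p2), ...])
# Synthetic analogues of the classic 24-patch chart: 18 chromatic patches
# built from broad cut-on edges and absorption/reflection bands, 6 flat
# neutrals from white to black.
_PATCH_RECIPES: list[tuple[str, float, list[tuple[str, float, float, float]]]] = [
    ("dark skin", 0.06, [("sig", 0.22, 610, 28), ("bump", 0.04, 540, 50)]),
    ("light skin", 0.22, [("sig", 0.38, 585, 30), ("bump", 0.08, 450, 55)]),
    ("blue sky", 0.10, [("bump", 0.26, 450, 55), ("sig", 0.10, 660, 40)]),
    ("foliage", 0.05, [("bump", 0.12, 545, 35), ("sig", 0.18, 680, 35)]),
    ("blue flower", 0.18, [("bump", 0.28, 445, 50), ("sig", 0.25, 640, 45)]),
    ("bluish green", 0.16, [("bump", 0.36, 500, 60), ("sig", 0.10, 660, 50)]),
    ("orange", 0.06, [("sig", 0.55, 585, 22)]),
    ("purplish blue", 0.08, [("bump", 0.34, 450, 45), ("sig", 0.12, 680, 40)]),
    ("moderate red", 0.08, [("sig", 0.45, 600, 22), ("bump", 0.06, 440, 50)]),
    ("purple", 0.05, [("bump", 0.20, 430, 40), ("sig", 0.25, 660, 35)]),
    ("yellow green", 0.08, [("sig", 0.45, 525, 25)]),
    ("orange yellow", 0.07, [("sig", 0.55, 560, 22)]),
    ("blue", 0.05, [("bump", 0.30, 455, 35), ("sig", 0.05, 700, 40)]),
    ("green", 0.06, [("bump", 0.30, 535, 40), ("sig", 0.04, 700, 40)]),
    ("red", 0.05, [("sig", 0.55, 615, 20)]),
    ("yellow", 0.07, [("sig", 0.65, 545, 22)]),
    ("magenta", 0.10, [("sig", 0.45, 600, 25), ("bump", 0.25, 440, 45)]),
    ("cyan", 0.08, [("bump", 0.35, 490, 55)]),
    ("white 9.5", 0.92, []),
    ("neutral 8", 0.59, []),
    ("neutral 6.5", 0.36, []),
    ("neutral 5", 0.19, []),
    ("neutral 3.5", 0.09, []),
    ("black 2", 0.031, []),
]


def make_reference_checker(
    grid: SpectralGrid | None = None,
    illuminant: Illuminant | None = None,
    cmfs: CMFSet | None = None,
) -> ColorCheckerSet:
    """Synthetic 24-patch reference chart.

    Reflectances are smooth analytic curves emulating the classic chart's
    patch set (primaries, secondaries, skin/foliage tones and six flat
    neutral steps); reference XYZ is computed under D65 with the CIE 1931
    2-degree observer.
    """
    grid = grid or SpectralGrid()
    illuminant = illuminant or d65_illuminant(grid)
    cmfs = cmfs or cie_1931_cmfs(grid)
    wl = grid.wavelengths
    names, rows = [], []
    for name, base, parts in _PATCH_RECIPES:
        r = np.full(wl.shape, base)
        for kind, amp, p1, p2 in parts:
            r = r + amp * (_sig(wl, p1, p2) if kind == "sig" else _bump(wl, p1, p2))
        rows.append(np.clip(r, 0.0, 1.0))
        names.append(name)
    refl = np.vstack(rows)
    xyz = spectra_to_xyz(refl, illuminant, cmfs)
    return ColorCheckerSet(names, grid, refl, xyz)


@dataclass
class VirtualCamera:
    """Forward model of an RGB camera with known spectral response.

    Per channel: ``out = (integral(R * S * sens) / integral(S * ybar)
    + dark_level) ** gamma + noise``.  With CMF sensitivities, identity
    gamma and zero dark/noise the output equals XYZ/100.
    """

    grid: SpectralGrid
    sensitivities: np.ndarray  # (3, n_bands), non-negative
    gamma: float = 1.0
    dark_level: float = 0.0
    noise_sigma: float = 0.0
    seed: int = 20240714
    illuminant: Illuminant | None = None

    def __post_init__(self) -> None:
        self.sensitivities = np.asarray(self.sensitivities, dtype=float)
        if self.sensitivities.shape != (3, self.grid.n_bands):
            raise ContractError("sensitivities must be (3, n_bands)")
        if np.any(self.sensitivities < 0):
            raise ContractError("sensitivities must be non-negative")
        if self.noise_sigma < 0:
            raise ContractError("noise_sigma must be >= 0")
        if self.illuminant is None:
            self.illuminant = d65_illuminant(self.grid)


def default_virtual_camera(
    grid: SpectralGrid | None = None,
    noise_sigma: float = 0.002,
    seed: int = 20240714,
) -> VirtualCamera:
    """Smooth Gaussian sensitivities peaking at 600/550/460 nm (R/G/B), mild
    gamma 1.05 and dark level 0.002, so the third-order expansion has real
    nonlinearity to absorb."""
    grid = grid or SpectralGrid()
    wl = grid.wavelengths
    sens = np.vstack(
        [
            1.00 * _bump(wl, 600.0, 45.0),
            0.95 * _bump(wl, 550.0, 40.0),
            0.90 * _bump(wl, 460.0, 35.0),
        ]
    )
    return VirtualCamera(
        grid, sens, gamma=1.05, dark_level=0.002, noise_sigma=noise_sigma, seed=seed
    )


def simulate_camera_capture(
    scene: SpectralCube | ColorCheckerSet | np.ndarray, cam: VirtualCamera
) -> np.ndarray:
    """Render a spectral scene through the virtual camera.

    Returns (24, 3) patch readings for a checker, (H, W, 3) for a cube.
    Deterministic for a given (camera params, seed).
    """
    if isinstance(scene, ColorCheckerSet):
        refl = scene.reflectances
        shape = (24, 3)
        if scene.grid != cam.grid:
            raise ContractError("scene and camera grids differ")
    elif isinstance(scene, SpectralCube):
        if scene.grid != cam.grid:
            raise ContractError("scene and camera grids differ")
        refl = scene.values.reshape(-1, scene.grid.n_bands)
        shape = (scene.height, scene.width, 3)
    else:
        refl = np.atleast_2d(np.asarray(scene, dtype=float))
        shape = (refl.shape[0], 3)
    # integrate over the 400-700 nm tristimulus window with luminance
    # normalisation, so CMF sensitivities reproduce XYZ/100 exactly
    mask = cam.grid.window_mask(400.0, 700.0)
    wl = cam.grid.wavelengths[mask]
    S = cam.illuminant.values[mask]
    ybar = cie_1931_cmfs(cam.grid).ybar[mask]
    norm = np.trapezoid(S * ybar, wl)
    signal = np.trapezoid(
        refl[:, None, mask] * (S * cam.sensitivities[:, mask])[None, :, :], wl, axis=2
    )
    signal = signal / norm + cam.dark_level
    signal = np.sign(signal) * np.abs(signal) ** cam.gamma
    rng = np.random.default_rng(cam.seed)
    signal = signal + rng.normal(0.0, cam.noise_sigma, size=signal.shape)
    return signal.reshape(shape)


def simulate_spectrometer(
    spectra: np.ndarray, noise_sigma: float = 0.0, seed: int = 20240714
) -> np.ndarray:
    """Spectrometer measurement: additive seeded Gaussian noise, clipped >= 0."""
    if noise_sigma < 0:
        raise ContractError("noise_sigma must be >= 0")
    X = np.asarray(spectra, dtype=float)
    if noise_sigma == 0:
        return X.copy()
    rng = np.random.default_rng(seed)
    return np.clip(X + rng.normal(0.0, noise_sigma, size=X.shape), 0.0, None)


def default_skin_spectrum(grid: SpectralGrid) -> np.ndarray:
    """Smooth fair-skin-like base reflectance rising toward the red."""
    wl = grid.wavelengths
    return np.clip(0.25 + 0.35 * _sig(wl, 580.0, 45.0), 0.0, 1.0)


def hemoglobin_absorbance(grid: SpectralGrid) -> np.ndarray:
    """Synthetic hemoglobin-like absorbance: strong band at 415 nm, weaker
    double-hump structure around 540/575 nm, unit peak."""
    wl = grid.wavelengths
    a = 1.0 * _bump(wl, 415.0, 20.0) + 0.35 * _bump(wl, 542.0, 18.0) + 0.30 * _bump(wl, 577.0, 16.0)
    return a


def melanin_absorbance(grid: SpectralGrid) -> np.ndarray:
    """Synthetic melanin-like absorbance: monotone exponential decay with
    wavelength, normalised to 1 at 400 nm."""
    wl = grid.wavelengths
    return np.exp(-(wl - 400.0) / 150.0)


@dataclass
class LesionSceneParams:
    """Parameters of the circular-lesion phantom."""

    size: int = 32
    lesion_radius: int = 8
    melanin_od: float = 0.8
    hemoglobin_od: float = 0.3
    grid: SpectralGrid = field(default_factory=SpectralGrid)
    base_skin: np.ndarray | None = None
    texture_sigma: float = 0.01
    seed: int = 20240714

    def __post_init__(self) -> None:
        if self.melanin_od < 0 or self.hemoglobin_od < 0:
            raise ContractError("optical densities must be >= 0")
        if self.lesion_radius >= self.size / 2:
            raise ContractError("lesion must fit inside the scene")


def make_lesion_scene(params: LesionSceneParams) -> tuple[SpectralCube, np.ndarray]:
    """Skin phantom: hemoglobin-attenuated background, melanin-darkened disk.

    Returns the reflectance cube and the boolean lesion mask.  Reflectance
    follows a Beer-Lambert-style attenuation ``R = R_skin * 10**(-OD * A)``
    with smooth synthetic absorbance curves; a small seeded log-normal
    texture keeps the scene from being piecewise constant.
    """
    grid = params.grid
    base = params.base_skin if params.base_skin is not None else default_skin_spectrum(grid)
    hb = hemoglobin_absorbance(grid)
    mel = melanin_absorbance(grid)
    background = base * 10.0 ** (-params.hemoglobin_od * hb)
    lesion = background * 10.0 ** (-params.melanin_od * mel)
    yy, xx = np.mgrid[0 : params.size, 0 : params.size]
    c = (params.size - 1) / 2.0
    mask = (yy - c) ** 2 + (xx - c) ** 2 <= params.lesion_radius**2
    cube = np.where(mask[:, :, None], lesion[None, None, :], background[None, None, :])
    rng = np.random.default_rng(params.seed)
    texture = np.exp(rng.normal(0.0, params.texture_sigma, size=(params.size, params.size)))
    cube = np.clip(cube * texture[:, :, None], 0.0, 1.0)
    return SpectralCube(grid, cube), mask
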