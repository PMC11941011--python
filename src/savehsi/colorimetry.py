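"""CIE 1931 colorimetry: spectral grids, tristimulus integration, sRGB and
CIELAB conversions, and the CIEDE2000 color-difference formula.

All spectral quantities live on a :class:`SpectralGrid` (default 380-780 nm at
1 nm).  Tristimulus integration follows the reflective-sample convention: the
normalisation constant ``k = 100 / integral(S * ybar)`` is computed over the
400-700 nm window so that a perfect diffuse reflector has Y = 100 under any
illuminant.  XYZ values throughout the package are on this 0-100 scale.

The colour-matching functions use the multi-lobe piecewise-Gaussian analytic
fit to the CIE 1931 2-degree observer; the D65 spectral power distribution is
packaged as a 10 nm table and interpolated onto the working grid.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpectralGrid",
    "Spectrum",
    "Illuminant",
    "CMFSet",
    "TristimulusXYZ",
    "LabColor",
    "cie_1931_cmfs",
    "d65_illuminant",
    "equal_energy_illuminant",
    "spectrum_to_xyz",
    "spectra_to_xyz",
    "srgb_to_linear",
    "linear_to_srgb",
    "srgb_to_xyz",
    "xyz_to_srgb",
    "xyz_to_lab",
    "ciede2000",
    "mean_color_difference",
    "D65_WHITE_XYZ",
]

_DATA_DIR = os.path.join(os.path.dirname(__file__), "data")

#: sRGB (IEC 61966-2-1) linear-RGB -> XYZ matrix, D65 white, Y in [0, 1].
SRGB_TO_XYZ_MATRIX = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
XYZ_TO_SRGB_MATRIX = np.linalg.inv(SRGB_TO_XYZ_MATRIX)

#: D65 white point on the 0-100 scale (sRGB matrix row sums, Y forced to 100).
_rowsum = SRGB_TO_XYZ_MATRIX.sum(axis=1)
D65_WHITE_XYZ = tuple(100.0 * _rowsum / _rowsum[1])


class ContractError(ValueError):
    """Raised when an operation's input contract is violated."""


@dataclass(frozen=True)
class SpectralGrid:
    """Uniform wavelength axis in nanometres.

    Must cover at least the 400-700 nm tristimulus integration window.
    """

    start_nm: float = 380.0
    stop_nm: float = 780.0
    step_nm: float = 1.0

    def __post_init__(self) -> None:
        if self.step_nm <= 0:
            raise ContractError("step_nm must be positive")
        if self.stop_nm <= self.start_nm:
            raise ContractError("stop_nm must exceed start_nm")
        if self.start_nm > 400.0 or self.stop_nm < 700.0:
            raise ContractError("grid must cover the 400-700 nm window")

    @property
    def wavelengths(self) -> np.ndarray:
        n = int(round((self.stop_nm - self.start_nm) / self.step_nm)) + 1
        return self.start_nm + self.step_nm * np.arange(n)

    @property
    def n_bands(self) -> int:
        return int(round((self.stop_nm - self.start_nm) / self.step_nm)) + 1

    def window_mask(self, lo_nm: float = 400.0, hi_nm: float = 700.0) -> np.ndarray:
        wl = self.wavelengths
        return (wl >= lo_nm - 1e-9) & (wl <= hi_nm + 1e-9)

    def to_dict(self) -> dict:
        return {"start_nm": self.start_nm, "stop_nm": self.stop_nm, "step_nm": self.step_nm}

    @classmethod
    def from_dict(cls, d: dict) -> "SpectralGrid":
        return cls(d["start_nm"], d["stop_nm"], d["step_nm"])


@dataclass
class Spectrum:
    """Reflectance (or relative radiance) sampled on a grid.

    Reflectance is dimensionless; values above 1 up to 1.2 are tolerated
    (fluorescent overshoot) and flagged, values above 1.2 are clipped.
    Negative values are rejected.
    """

    grid: SpectralGrid
    values: np.ndarray
    name: str = ""
    overshoot: bool = field(default=False, init=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size != self.grid.n_bands:
            raise ContractError("spectrum length must match grid")
        if np.any(v < -1e-12):
            raise ContractError("negative reflectance")
        self.overshoot = bool(np.any(v > 1.0))
        self.values = np.clip(v, 0.0, 1.2)


@dataclass
class Illuminant:
    """Relative spectral power S(lambda), normalised to 100 at 560 nm."""

    grid: SpectralGrid
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size != self.grid.n_bands:
            raise ContractError("illuminant length must match grid")
        if np.any(v < 0):
            raise ContractError("illuminant power must be non-negative")
        at560 = float(np.interp(560.0, self.grid.wavelengths, v))
        if at560 <= 0:
            raise ContractError("illuminant must be positive at 560 nm")
        self.values = v * (100.0 / at560)


@dataclass
class CMFSet:
    """CIE 1931 2-degree colour-matching functions on a grid."""

    grid: SpectralGrid
    xbar: np.ndarray
    ybar: np.ndarray
    zbar: np.ndarray

    def __post_init__(self) -> None:
        for a in (self.xbar, self.ybar, self.zbar):
            if np.asarray(a).size != self.grid.n_bands:
                raise ContractError("CMF length must match grid")
            if np.any(np.asarray(a) < 0):
                raise ContractError("CMFs must be non-negative")


@dataclass(frozen=True)
class TristimulusXYZ:
    X: float
    Y: float
    Z: float

    def as_array(self) -> np.ndarray:
        return np.array([self.X, self.Y, self.Z])


@dataclass(frozen=True)
class LabColor:
    L: float
    a: float
    b: float

    def as_array(self) -> np.ndarray:
        return np.array([self.L, self.a, self.b])


def _lobe(wl: np.ndarray, mu: float, s1: float, s2: float) -> np.ndarray:
    # piecewise Gaussian: left/right standard deviations differ
    s = np.where(wl < mu, s1, s2)
    return np.exp(-0.5 * ((wl - mu) / s) ** 2)


def cie_1931_cmfs(grid: SpectralGrid | None = None) -> CMFSet:
    """Analytic multi-lobe fit to the CIE 1931 2-degree observer."""
    grid = grid or SpectralGrid()
    wl = grid.wavelengths
    xbar = (
        1.056 * _lobe(wl, 599.8, 37.9, 31.0)
        + 0.362 * _lobe(wl, 442.0, 16.0, 26.7)
        - 0.065 * _lobe(wl, 501.1, 20.4, 26.2)
    )
    ybar = 0.821 * _lobe(wl, 568.8, 46.9, 40.5) + 0.286 * _lobe(wl, 530.9, 16.3, 31.1)
    zbar = 1.217 * _lobe(wl, 437.0, 11.8, 36.0) + 0.681 * _lobe(wl, 459.0, 26.0, 13.8)
    return CMFSet(grid, np.clip(xbar, 0, None), np.clip(ybar, 0, None), np.clip(zbar, 0, None))


def d65_illuminant(grid: SpectralGrid | None = None) -> Illuminant:
    """CIE standard illuminant D65, interpolated from the packaged 10 nm table."""
    grid = grid or SpectralGrid()
    table = np.loadtxt(
        os.path.join(_DATA_DIR, "illuminant_d65_10nm.csv"), delimiter=",", skiprows=1
    )
    values = np.interp(grid.wavelengths, table[:, 0], table[:, 1])
    return Illuminant(grid, values, name="D65")


def equal_energy_illuminant(grid: SpectralGrid | None = None) -> Illuminant:
    grid = grid or SpectralGrid()
    return Illuminant(grid, np.full(grid.n_bands, 100.0), name="E")


def _check_common_grid(*objs) -> SpectralGrid:
    g0 = objs[0].grid
    for o in objs[1:]:
        if o.grid != g0:
            raise ContractError("inputs must share a common spectral grid")
    return g0


def spectra_to_xyz(
    reflectances: np.ndarray,
    illuminant: Illuminant,
    cmfs: CMFSet,
    window: tuple[float, float] = (400.0, 700.0),
) -> np.ndarray:
    """Vectorised tristimulus integration.

    Parameters
    ----------
    reflectances : (n, n_bands) array of reflectance factors in [0, 1.2].

    Returns
    -------
    (n, 3) array of XYZ on the 0-100 scale (perfect reflector -> Y = 100).
    """
    _check_common_grid(illuminant, cmfs)
    R = np.atleast_2d(np.asarray(reflectances, dtype=float))
    if R.shape[1] != illuminant.grid.n_bands:
        raise ContractError("reflectance length must match grid")
    if np.any(R < -1e-12):
        raise ContractError("negative reflectance")
    mask = illuminant.grid.window_mask(*window)
    wl = illuminant.grid.wavelengths[mask]
    S = illuminant.values[mask]
    bars = np.stack([cmfs.xbar[mask], cmfs.ybar[mask], cmfs.zbar[mask]])
    k = 100.0 / np.trapezoid(S * bars[1], wl)
    # integrand: (n, 3, n_wl)
    integrand = R[:, None, mask] * (S * bars)[None, :, :]
    return k * np.trapezoid(integrand, wl, axis=2)


def spectrum_to_xyz(
    reflectance: Spectrum, illuminant: Illuminant, cmfs: CMFSet
) -> TristimulusXYZ:
    """Tristimulus values of a single reflectance spectrum (Y=100 for R=1)."""
    _check_common_grid(reflectance, illuminant, cmfs)
    xyz = spectra_to_xyz(reflectance.values[None, :], illuminant, cmfs)[0]
    return TristimulusXYZ(*xyz)


def srgb_to_linear(rgb8: np.ndarray | float) -> np.ndarray:
    """Decode 8-bit-scale sRGB values ([0, 255]) to linear light in [0, 1]."""
    v = np.asarray(rgb8, dtype=float)
    if np.any(v < 0) or np.any(v > 255):
        raise ContractError("sRGB values must lie in [0, 255]")
    c = v / 255.0
    return np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)


def linear_to_srgb(linear: np.ndarray | float) -> np.ndarray:
    """Encode linear light in [0, 1] to sRGB on the [0, 255] scale."""
    c = np.clip(np.asarray(linear, dtype=float), 0.0, 1.0)
    enc = np.where(c <= 0.0031308, 12.92 * c, 1.055 * c ** (1 / 2.4) - 0.055)
    return 255.0 * enc


def srgb_to_xyz(rgb_linear: np.ndarray) -> np.ndarray:
    """Linear sRGB -> XYZ (0-100 scale). Out-of-gamut inputs pass through."""
    rgb = np.asarray(rgb_linear, dtype=float)
    return 100.0 * rgb @ SRGB_TO_XYZ_MATRIX.T


def xyz_to_srgb(xyz: np.ndarray, return_gamut_flag: bool = False):
    """XYZ (0-100 scale) -> linear sRGB, unclipped.

    Out-of-gamut results are preserved; ``return_gamut_flag`` additionally
    returns a boolean mask of samples outside [0, 1].
    """
    rgb = np.asarray(xyz, dtype=float) / 100.0 @ XYZ_TO_SRGB_MATRIX.T
    if return_gamut_flag:
        flat = np.atleast_2d(rgb)
        flag = np.any((flat < 0) | (flat > 1), axis=-1)
        return rgb, flag
    return rgb


_LAB_DELTA = 6.0 / 29.0


def _lab_f(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return np.where(t > _LAB_DELTA**3, np.cbrt(t), t / (3 * _LAB_DELTA**2) + 4.0 / 29.0)


def xyz_to_lab(xyz: np.ndarray, white: np.ndarray | None = None) -> np.ndarray:
    """CIE 1976 L*a*b* relative to a white point with Y = 100 (default D65)."""
    white = np.asarray(D65_WHITE_XYZ if white is None else white, dtype=float)
    if np.any(white <= 0):
        raise ContractError("white point must be positive")
    if abs(white[1] - 100.0) > 1e-6:
        raise ContractError("white point must have Y = 100")
    xyz = np.asarray(xyz, dtype=float)
    fx, fy, fz = (_lab_f(xyz[..., i] / white[i]) for i in range(3))
    return np.stack([116.0 * fy - 16.0, 500.0 * (fx - fy), 200.0 * (fy - fz)], axis=-1)


def ciede2000(lab1: np.ndarray, lab2: np.ndarray) -> np.ndarray | float:
    """CIEDE2000 colour difference with kL = kC = kH = 1.

    Accepts (..., 3) Lab arrays; broadcasts elementwise over leading axes.
    """
    lab1 = np.asarray(lab1, dtype=float)
    lab2 = np.asarray(lab2, dtype=float)
    scalar = lab1.ndim == 1 and lab2.ndim == 1
    L1, a1, b1 = np.moveaxis(np.atleast_2d(lab1), -1, 0)
    L2, a2, b2 = np.moveaxis(np.atleast_2d(lab2), -1, 0)

    C1 = np.hypot(a1, b1)
    C2 = np.hypot(a2, b2)
    Cbar = 0.5 * (C1 + C2)
    G = 0.5 * (1.0 - np.sqrt(Cbar**7 / (Cbar**7 + 25.0**7)))
    a1p = (1.0 + G) * a1
    a2p = (1.0 + G) * a2
    C1p = np.hypot(a1p, b1)
    C2p = np.hypot(a2p, b2)

    h1p = np.degrees(np.arctan2(b1, a1p)) % 360.0
    h2p = np.degrees(np.arctan2(b2, a2p)) % 360.0
    h1p = np.where((np.abs(a1p) < 1e-14) & (np.abs(b1) < 1e-14), 0.0, h1p)
    h2p = np.where((np.abs(a2p) < 1e-14) & (np.abs(b2) < 1e-14), 0.0, h2p)

    dLp = L2 - L1
    dCp = C2p - C1p
    dh = h2p - h1p
    dh = np.where(dh > 180.0, dh - 360.0, dh)
    dh = np.where(dh < -180.0, dh + 360.0, dh)
    dh = np.where(C1p * C2p == 0.0, 0.0, dh)
    dHp = 2.0 * np.sqrt(C1p * C2p) * np.sin(np.radians(dh) / 2.0)

    Lbp = 0.5 * (L1 + L2)
    Cbp = 0.5 * (C1p + C2p)
    hsum = h1p + h2p
    habs = np.abs(h1p - h2p)
    hbp = np.where(habs <= 180.0, 0.5 * hsum, np.where(hsum < 360.0, 0.5 * (hsum + 360.0), 0.5 * (hsum - 360.0)))
    hbp = np.where(C1p * C2p == 0.0, hsum, hbp)

    T = (
        1.0
        - 0.17 * np.cos(np.radians(hbp - 30.0))
        + 0.24 * np.cos(np.radians(2.0 * hbp))
        + 0.32 * np.cos(np.radians(3.0 * hbp + 6.0))
        - 0.20 * np.cos(np.radians(4.0 * hbp - 63.0))
    )
    dtheta = 30.0 * np.exp(-(((hbp - 275.0) / 25.0) ** 2))
    RC = 2.0 * np.sqrt(Cbp**7 / (Cbp**7 + 25.0**7))
    SL = 1.0 + 0.015 * (Lbp - 50.0) ** 2 / np.sqrt(20.0 + (Lbp - 50.0) ** 2)
    SC = 1.0 + 0.045 * Cbp
    SH = 1.0 + 0.015 * Cbp * T
    RT = -np.sin(np.radians(2.0 * dtheta)) * RC

    dE = np.sqrt(
        (dLp / SL) ** 2 + (dCp / SC) ** 2 + (dHp / SH) ** 2 + RT * (dCp / SC) * (dHp / SH)
    )
    return float(dE[0]) if scalar else dE


def mean_color_difference(
    xyz_a: np.ndarray, xyz_b: np.ndarray, white: np.ndarray | None = None
) -> float:
    """Mean pairwise CIEDE2000 between two aligned sets of XYZ colours."""
    A = np.atleast_2d(np.asarray(xyz_a, dtype=float))
    B = np.atleast_2d(np.asarray(xyz_b, dtype=float))
    if A.shape != B.shape:
        raise ContractError("colour sets must have equal length")
    return float(np.mean(ciede2000(xyz_to_lab(A, white), xyz_to_lab(B, white))))
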