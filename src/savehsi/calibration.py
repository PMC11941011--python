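"""Colour-checker calibration and RGB-to-spectral reconstruction.

The calibration is fitted from a 24-patch colour checker photographed by the
camera being calibrated and measured by a spectrometer:

1. A *variable matrix* V expands each linear camera RGB triple into all
   monomials of degree <= 3 plus a constant dark term (20 terms).  The
   polynomial terms absorb mild sensor nonlinearity and channel cross-talk;
   the expansion is capped at third order to avoid over-correction.
2. The *correction matrix* ``C = XYZ_ref @ pinv(V)`` maps V to the
   spectrometer-referenced XYZ of the patches (least squares via the
   Moore-Penrose pseudoinverse).
3. The measured patch reflectances are decomposed by PCA into six principal
   components; the *transformation matrix* ``M = Score @ pinv(V)`` maps V to
   the six component scores, so any camera RGB can be expanded into a full
   reflectance spectrum: ``R = mean + components.T @ (M @ v)``.

The statsmodels-style entry point is :class:`SpectralCalibration`, whose
``fit()`` returns a :class:`CalibrationResults` carrying the fitted matrices,
per-patch diagnostics and reconstruction methods.  The module-level functions
implement the individual steps and are what the model object delegates to.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .colorimetry import (
    CMFSet,
    ContractError,
    Illuminant,
    SpectralGrid,
    Spectrum,
    TristimulusXYZ,
    cie_1931_cmfs,
    d65_illuminant,
    mean_color_difference,
    spectra_to_xyz,
    srgb_to_xyz,
)

__all__ = [
    "ColorCheckerSet",
    "VariableMatrix",
    "CorrectionMatrix",
    "PCABasis",
    "TransformMatrix",
    "SpectralCube",
    "build_variable_matrix",
    "fit_correction_matrix",
    "apply_correction",
    "fit_pca_basis",
    "fit_transform_matrix",
    "reconstruct_spectrum",
    "rgb_image_to_spectral_cube",
    "patch_rmse",
    "SpectralCalibration",
    "CalibrationResults",
]

PINV_RCOND = 1e-10

#: Monomial labels of the third-order variable matrix, in fixed order.
TERM_LABELS_ORDER3 = [
    "R", "G", "B",
    "R2", "G2", "B2", "RG", "GB", "RB",
    "R3", "G3", "B3", "R2G", "R2B", "G2R", "G2B", "B2R", "B2G", "RGB",
    "1",
]


@dataclass
class ColorCheckerSet:
    """A 24-patch calibration chart: names, reflectances, reference XYZ and
    (optionally) the camera's linear-RGB readings of each patch."""

    names: list[str]
    grid: SpectralGrid
    reflectances: np.ndarray  # (24, n_bands)
    reference_xyz: np.ndarray  # (24, 3), 0-100 scale
    camera_rgb: np.ndarray | None = None  # (24, 3) linear RGB

    def __post_init__(self) -> None:
        self.reflectances = np.asarray(self.reflectances, dtype=float)
        self.reference_xyz = np.asarray(self.reference_xyz, dtype=float)
        if len(self.names) != 24 or self.reflectances.shape[0] != 24:
            raise ContractError("a colour checker has exactly 24 patches")
        if self.reflectances.shape[1] != self.grid.n_bands:
            raise ContractError("reflectance length must match grid")
        if np.any(self.reflectances < 0) or np.any(self.reflectances > 1 + 1e-9):
            raise ContractError("checker reflectance must lie in [0, 1]")
        if self.camera_rgb is not None:
            self.camera_rgb = np.asarray(self.camera_rgb, dtype=float)

    @property
    def neutral_indices(self) -> list[int]:
        """Patches whose reflectance is spectrally flat (max-min < 0.05)."""
        span = self.reflectances.max(axis=1) - self.reflectances.min(axis=1)
        return [i for i in range(24) if span[i] < 0.05]

    def with_camera_rgb(self, rgb: np.ndarray) -> "ColorCheckerSet":
        return ColorCheckerSet(self.names, self.grid, self.reflectances, self.reference_xyz, rgb)

    def spectra(self) -> list[Spectrum]:
        return [Spectrum(self.grid, r, name=n) for n, r in zip(self.names, self.reflectances)]


@dataclass
class VariableMatrix:
    """Polynomial design matrix: one column per sample, one row per monomial."""

    terms: list[str]
    matrix: np.ndarray  # (n_terms, n_samples)

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]


@dataclass
class CorrectionMatrix:
    """(3 x n_terms) map from variable-matrix columns to corrected XYZ."""

    matrix: np.ndarray
    residuals: np.ndarray | None = None  # (3, n_samples) training residuals


@dataclass
class PCABasis:
    """Mean spectrum plus orthonormal principal loadings of patch reflectance."""

    grid: SpectralGrid
    mean_spectrum: np.ndarray  # (n_bands,)
    components: np.ndarray  # (n_components, n_bands), orthonormal rows
    eigenvalues: np.ndarray  # (n_components,) descending
    explained_fraction: float  # cumulative variance ratio of kept components

    def scores(self, reflectances: np.ndarray) -> np.ndarray:
        """Project (n, n_bands) reflectances onto the basis -> (n_components, n)."""
        centered = np.atleast_2d(reflectances) - self.mean_spectrum
        return self.components @ centered.T

    def reconstruct(self, scores: np.ndarray) -> np.ndarray:
        """Scores (n_components, n) -> reflectances (n, n_bands)."""
        return (self.components.T @ np.atleast_2d(scores)).T + self.mean_spectrum


@dataclass
class TransformMatrix:
    """(n_components x n_terms) map from variable-matrix columns to PCA scores."""

    matrix: np.ndarray
    rmse_per_sample: np.ndarray | None = None


@dataclass
class SpectralCube:
    """H x W x B reconstructed reflectance cube.

    Reconstruction overshoot in [-0.1, 1.3] is tolerated in memory and
    clipped to [0, 1] on export.
    """

    grid: SpectralGrid
    values: np.ndarray  # (H, W, B)
    saturation_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[2] != self.grid.n_bands:
            raise ContractError("cube must be (H, W, n_bands)")
        self.values = np.clip(self.values, -0.1, 1.3)

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def clipped(self) -> np.ndarray:
        return np.clip(self.values, 0.0, 1.0)


def build_variable_matrix(rgb_linear: np.ndarray, order: int = 3) -> VariableMatrix:
    """Expand linear RGB triples into the polynomial design matrix.

    Term order (order 3): R,G,B | R2,G2,B2,RG,GB,RB |
    R3,G3,B3,R2G,R2B,G2R,G2B,B2R,B2G,RGB | constant.
    Lower orders keep the corresponding prefix plus the constant term.
    """
    if order not in (1, 2, 3):
        raise ContractError("order must be 1, 2 or 3")
    rgb = np.atleast_2d(np.asarray(rgb_linear, dtype=float))
    if rgb.shape[1] != 3:
        raise ContractError("expected RGB triples")
    R, G, B = rgb[:, 0], rgb[:, 1], rgb[:, 2]
    ones = np.ones_like(R)
    cols = [R, G, B]
    labels = ["R", "G", "B"]
    if order >= 2:
        cols += [R * R, G * G, B * B, R * G, G * B, R * B]
        labels += ["R2", "G2", "B2", "RG", "GB", "RB"]
    if order >= 3:
        cols += [
            R**3, G**3, B**3,
            R * R * G, R * R * B, G * G * R, G * G * B, B * B * R, B * B * G,
            R * G * B,
        ]
        labels += ["R3", "G3", "B3", "R2G", "R2B", "G2R", "G2B", "B2R", "B2G", "RGB"]
    cols.append(ones)
    labels.append("1")
    return VariableMatrix(labels, np.vstack(cols))


def _pinv(v: np.ndarray) -> np.ndarray:
    s = np.linalg.svd(v, compute_uv=False)
    if s[-1] < PINV_RCOND * s[0] * 10:
        warnings.warn("variable matrix is nearly rank-deficient; pseudoinverse truncates")
    return np.linalg.pinv(v, rcond=PINV_RCOND)


def fit_correction_matrix(xyz_reference: np.ndarray, v: VariableMatrix) -> CorrectionMatrix:
    """Least-squares correction matrix ``C = XYZ_ref @ pinv(V)``."""
    xyz = np.asarray(xyz_reference, dtype=float)
    if xyz.ndim == 1:
        xyz = xyz[None, :]
    if xyz.shape[0] != v.n_samples:
        raise ContractError("reference XYZ count must match design columns")
    C = xyz.T @ _pinv(v.matrix)
    residuals = C @ v.matrix - xyz.T
    return CorrectionMatrix(C, residuals)


def apply_correction(c: CorrectionMatrix, v: VariableMatrix) -> np.ndarray:
    """Corrected XYZ per sample: ``[C] @ [V]`` -> (n_samples, 3)."""
    if c.matrix.shape[1] != v.matrix.shape[0]:
        raise ContractError("correction matrix and design dimensions disagree")
    return (c.matrix @ v.matrix).T


def fit_pca_basis(
    reflectances: np.ndarray | list[Spectrum],
    grid: SpectralGrid | None = None,
    n_components: int = 6,
) -> PCABasis:
    """Mean-centred PCA of patch reflectance spectra.

    ``explained_fraction`` is the ratio of the top-``n_components``
    eigenvalues to the total variance.
    """
    if isinstance(reflectances, (list, tuple)) and isinstance(reflectances[0], Spectrum):
        grid = reflectances[0].grid
        reflectances = np.vstack([s.values for s in reflectances])
    X = np.atleast_2d(np.asarray(reflectances, dtype=float))
    if grid is None:
        raise ContractError("grid required when passing a raw array")
    if X.shape[0] < n_components + 1:
        raise ContractError("need at least n_components + 1 spectra")
    from sklearn.decomposition import PCA

    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(X)
    return PCABasis(
        grid=grid,
        mean_spectrum=pca.mean_,
        components=pca.components_,
        eigenvalues=pca.explained_variance_,
        explained_fraction=float(pca.explained_variance_ratio_.sum()),
    )


def fit_transform_matrix(scores: np.ndarray, v_color: VariableMatrix) -> TransformMatrix:
    """Least-squares transformation matrix ``M = Score @ pinv(V_color)``."""
    S = np.atleast_2d(np.asarray(scores, dtype=float))
    if S.shape[1] != v_color.n_samples:
        raise ContractError("score columns must match design columns")
    M = S @ _pinv(v_color.matrix)
    resid = M @ v_color.matrix - S
    rmse = np.sqrt(np.mean(resid**2, axis=0))
    return TransformMatrix(M, rmse)


def reconstruct_spectrum(
    m: TransformMatrix, basis: PCABasis, v_sample: np.ndarray
) -> Spectrum:
    """Reconstruct one reflectance spectrum from a variable-matrix column."""
    v = np.asarray(v_sample, dtype=float).reshape(-1)
    scores = m.matrix @ v
    values = basis.mean_spectrum + basis.components.T @ scores
    return Spectrum(basis.grid, np.clip(values, 0.0, 1.2))


def reconstruct_spectra(
    m: TransformMatrix, basis: PCABasis, v: VariableMatrix
) -> np.ndarray:
    """Vectorised reconstruction -> (n_samples, n_bands), unclipped."""
    scores = m.matrix @ v.matrix
    return basis.reconstruct(scores)


def rgb_image_to_spectral_cube(
    image: np.ndarray,
    results: "CalibrationResults",
    saturation_threshold: float = 0.999,
) -> SpectralCube:
    """Convert a linear-RGB image (H, W, 3) to a reflectance cube.

    Saturated pixels (any channel >= threshold) are flagged in the cube's
    mask but still converted.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ContractError("expected an (H, W, 3) linear RGB image")
    h, w, _ = img.shape
    flat = img.reshape(-1, 3)
    v = build_variable_matrix(flat, order=results.order)
    spectra = reconstruct_spectra(results.transform, results.basis, v)
    cube = spectra.reshape(h, w, -1)
    mask = np.any(flat >= saturation_threshold, axis=1).reshape(h, w)
    return SpectralCube(results.basis.grid, cube, saturation_mask=mask)


def patch_rmse(
    reconstructed: Spectrum | np.ndarray,
    reference: Spectrum | np.ndarray,
    grid: SpectralGrid | None = None,
    window: tuple[float, float] = (400.0, 700.0),
) -> float:
    """Root-mean-square reflectance difference over the evaluation window."""
    if isinstance(reconstructed, Spectrum):
        grid = reconstructed.grid
        reconstructed = reconstructed.values
    if isinstance(reference, Spectrum):
        if grid is not None and reference.grid != grid:
            raise ContractError("spectra must share a grid")
        grid = reference.grid
        reference = reference.values
    if grid is None:
        raise ContractError("grid required for raw arrays")
    a = np.asarray(reconstructed, dtype=float)
    b = np.asarray(reference, dtype=float)
    if a.shape != b.shape:
        raise ContractError("spectra must share a grid")
    mask = grid.window_mask(*window)
    return float(np.sqrt(np.mean((a[mask] - b[mask]) ** 2)))


class SpectralCalibration:
    """Model object: fit the RGB-to-spectrum calibration from a colour checker.

    Parameters
    ----------
    camera_rgb : (24, 3) linear camera readings of the patches.
    reference_spectra : (24, n_bands) spectrometer reflectance measurements.
    grid : wavelength axis of the reference spectra.
    reference_xyz : optional (24, 3); computed from the reference spectra
        under the given illuminant when omitted.
    illuminant, cmfs : colorimetric context (default D65, CIE 1931 2-deg).
    """

    def __init__(
        self,
        camera_rgb: np.ndarray,
        reference_spectra: np.ndarray,
        grid: SpectralGrid,
        reference_xyz: np.ndarray | None = None,
        illuminant: Illuminant | None = None,
        cmfs: CMFSet | None = None,
    ) -> None:
        self.camera_rgb = np.atleast_2d(np.asarray(camera_rgb, dtype=float))
        self.reference_spectra = np.atleast_2d(np.asarray(reference_spectra, dtype=float))
        self.grid = grid
        self.illuminant = illuminant or d65_illuminant(grid)
        self.cmfs = cmfs or cie_1931_cmfs(grid)
        if reference_xyz is None:
            reference_xyz = spectra_to_xyz(self.reference_spectra, self.illuminant, self.cmfs)
        self.reference_xyz = np.asarray(reference_xyz, dtype=float)
        if self.camera_rgb.shape[0] != self.reference_spectra.shape[0]:
            raise ContractError("camera readings and reference spectra must align")

    @classmethod
    def from_checker(
        cls,
        checker: ColorCheckerSet,
        illuminant: Illuminant | None = None,
        cmfs: CMFSet | None = None,
    ) -> "SpectralCalibration":
        if checker.camera_rgb is None:
            raise ContractError("checker carries no camera readings")
        return cls(
            checker.camera_rgb,
            checker.reflectances,
            checker.grid,
            reference_xyz=checker.reference_xyz,
            illuminant=illuminant,
            cmfs=cmfs,
        )

    def fit(
        self,
        order: int = 3,
        n_components: int = 6,
        evaluation_window: tuple[float, float] = (400.0, 700.0),
    ) -> "CalibrationResults":
        v = build_variable_matrix(self.camera_rgb, order=order)
        correction = fit_correction_matrix(self.reference_xyz, v)
        basis = fit_pca_basis(self.reference_spectra, self.grid, n_components=n_components)
        scores = basis.scores(self.reference_spectra)
        transform = fit_transform_matrix(scores, v)
        results = CalibrationResults(
            model=self,
            order=order,
            correction=correction,
            transform=transform,
            basis=basis,
            evaluation_window=evaluation_window,
        )
        results._build_fit_report(v)
        return results


@dataclass
class CalibrationResults:
    """Fitted calibration bundle with diagnostics.

    Attributes
    ----------
    correction : CorrectionMatrix mapping V -> corrected XYZ.
    transform : TransformMatrix mapping V -> PCA scores.
    basis : PCABasis of the reference reflectances.
    fit_report : per-patch spectral RMSE and colour-difference diagnostics.
    """

    model: SpectralCalibration | None
    order: int
    correction: CorrectionMatrix
    transform: TransformMatrix
    basis: PCABasis
    evaluation_window: tuple[float, float] = (400.0, 700.0)
    fit_report: dict = field(default_factory=dict)

    @property
    def grid(self) -> SpectralGrid:
        return self.basis.grid

    def _build_fit_report(self, v: VariableMatrix) -> None:
        m = self.model
        recon = reconstruct_spectra(self.transform, self.basis, v)
        rmse = np.array(
            [
                patch_rmse(r, t, grid=self.grid, window=self.evaluation_window)
                for r, t in zip(recon, m.reference_spectra)
            ]
        )
        recon_xyz = spectra_to_xyz(np.clip(recon, 0, 1.2), m.illuminant, m.cmfs)
        corrected_xyz = apply_correction(self.correction, v)
        raw_xyz = srgb_to_xyz(m.camera_rgb)  # naive sRGB interpretation, pre-correction
        self.fit_report = {
            "patch_rmse": rmse,
            "mean_rmse": float(rmse.mean()),
            "mean_de00_reconstruction": mean_color_difference(recon_xyz, m.reference_xyz),
            "mean_de00_corrected_xyz": mean_color_difference(corrected_xyz, m.reference_xyz),
            "mean_de00_precorrection": mean_color_difference(raw_xyz, m.reference_xyz),
            "explained_fraction": self.basis.explained_fraction,
        }

    # -- prediction -------------------------------------------------------

    def correct_xyz(self, rgb_linear: np.ndarray) -> np.ndarray:
        v = build_variable_matrix(rgb_linear, order=self.order)
        return apply_correction(self.correction, v)

    def reconstruct(self, rgb_linear: np.ndarray) -> np.ndarray:
        """Reconstruct (n, n_bands) reflectance spectra from linear RGB."""
        v = build_variable_matrix(rgb_linear, order=self.order)
        return reconstruct_spectra(self.transform, self.basis, v)

    def convert_image(self, image: np.ndarray) -> SpectralCube:
        return rgb_image_to_spectral_cube(image, self)

    # -- reporting --------------------------------------------------------

    def summary(self) -> str:
        rep = self.fit_report
        lines = [
            "Spectral calibration results",
            "=" * 60,
            f"polynomial order:            {self.order}"
            f"   (terms: {len(self.transform.matrix[0])})",
            f"principal components:        {self.basis.components.shape[0]}",
            f"explained variance:          {100 * rep['explained_fraction']:.2f} %",
            f"mean patch spectral RMSE:    {rep['mean_rmse']:.4f}",
            f"mean dE00 (reconstruction):  {rep['mean_de00_reconstruction']:.3f}",
            f"mean dE00 (corrected XYZ):   {rep['mean_de00_corrected_xyz']:.3f}",
            f"mean dE00 (pre-correction):  {rep['mean_de00_precorrection']:.3f}",
            "-" * 60,
        ]
        if self.model is not None:
            lines.append(f"{'patch':>6}  {'RMSE':>8}")
            for i, r in enumerate(rep["patch_rmse"]):
                lines.append(f"{i:>6}  {r:>8.4f}")
        return "\n".join(lines)

    def plot_patch_fits(self, ax=None):
        """Overlay reference and reconstructed patch spectra (needs matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 5))
        wl = self.grid.wavelengths
        recon = self.reconstruct(self.model.camera_rgb)
        for ref, rec in zip(self.model.reference_spectra, recon):
            ax.plot(wl, ref, color="0.6", lw=0.8)
            ax.plot(wl, rec, color="C3", lw=0.8, ls="--")
        ax.set_xlabel("wavelength (nm)")
        ax.set_ylabel("reflectance")
        return ax

    # -- persistence ------------------------------------------------------

    def to_dict(self) -> dict:
        rep = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in self.fit_report.items()
        }
        return {
            "format": "savehsi-calibration-bundle",
            "version": 1,
            "grid": self.grid.to_dict(),
            "order": self.order,
            "term_labels": build_variable_matrix(np.zeros((1, 3)), self.order).terms,
            "correction_matrix": self.correction.matrix.tolist(),
            "transform_matrix": self.transform.matrix.tolist(),
            "mean_spectrum": self.basis.mean_spectrum.tolist(),
            "components": self.basis.components.tolist(),
            "eigenvalues": self.basis.eigenvalues.tolist(),
            "explained_fraction": self.basis.explained_fraction,
            "evaluation_window": list(self.evaluation_window),
            "fit_report": rep,
        }

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationResults":
        if d.get("format") != "savehsi-calibration-bundle":
            raise ContractError("not a calibration bundle")
        grid = SpectralGrid.from_dict(d["grid"])
        basis = PCABasis(
            grid=grid,
            mean_spectrum=np.array(d["mean_spectrum"]),
            components=np.array(d["components"]),
            eigenvalues=np.array(d["eigenvalues"]),
            explained_fraction=d["explained_fraction"],
        )
        rep = {
            k: (np.array(v) if isinstance(v, list) else v)
            for k, v in d.get("fit_report", {}).items()
        }
        return cls(
            model=None,
            order=d["order"],
            correction=CorrectionMatrix(np.array(d["correction_matrix"])),
            transform=TransformMatrix(np.array(d["transform_matrix"])),
            basis=basis,
            evaluation_window=tuple(d.get("evaluation_window", (400.0, 700.0))),
            fit_report=rep,
        )

    @classmethod
    def load(cls, path: str) -> "CalibrationResults":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
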