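"""End-to-end pipeline driver: simulate -> calibrate -> convert -> render ->
evaluate, with cached stage artifacts and a run manifest.

The demo configuration is fully synthetic: a reference colour checker is
photographed by the virtual camera and measured by the virtual spectrometer,
the calibration is fitted, a lesion scene is converted to a reflectance cube
and composited into the narrow-band enhanced image, and the result is scored
against the enhanced rendering of the ground-truth cube.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np

from . import io as hio
from .calibration import SpectralCalibration
from .colorimetry import SpectralGrid, linear_to_srgb, xyz_to_srgb
from .metrics import compute_report
from .synthesis import (
    AnnealingParams,
    BandSet,
    BandWeightCalibration,
    band_values,
    default_save_bands,
    synthesize_save_image,
)
from .synthetic import (
    LesionSceneParams,
    default_virtual_camera,
    make_lesion_scene,
    make_reference_checker,
    simulate_camera_capture,
    simulate_spectrometer,
)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]

log = logging.getLogger("savehsi.pipeline")

VERSION = "0.1.0"


@dataclass
class PipelineConfig:
    """Validated configuration of a full synthetic run."""

    out_dir: str = "savehsi_run"
    grid: dict = field(default_factory=lambda: {"start_nm": 380.0, "stop_nm": 780.0, "step_nm": 1.0})
    order: int = 3
    n_components: int = 6
    camera_noise_sigma: float = 0.002
    spectrometer_noise_sigma: float = 0.002
    scene_size: int = 32
    lesion_radius: int = 8
    melanin_od: float = 0.8
    hemoglobin_od: float = 0.3
    bands: dict | None = None
    annealing: dict = field(default_factory=lambda: asdict(AnnealingParams()))
    evaluation_window: tuple[float, float] = (400.0, 700.0)
    seed: int = 20240714

    def __post_init__(self) -> None:
        SpectralGrid.from_dict(self.grid)  # validates
        if self.order not in (1, 2, 3):
            raise ValueError("order must be 1, 2 or 3")
        if self.camera_noise_sigma < 0 or self.spectrometer_noise_sigma < 0:
            raise ValueError("noise sigmas must be >= 0")
        AnnealingParams(**self.annealing)
        if self.bands is not None:
            BandSet.from_dict(self.bands)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(canon).hexdigest()


@dataclass
class RunManifest:
    version: str
    config_hash: str
    artifact_hashes: dict
    timings_s: dict
    metrics: dict

    def write(self, path: str) -> None:
        tmp = path + ".tmp"
        with open(tmp, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
        os.replace(tmp, path)  # atomic

    @classmethod
    def read(cls, path: str) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def _timed(timings: dict, name: str):
    class _T:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, *exc):
            timings[name] = round(time.perf_counter() - self.t0, 4)
            log.info("stage %s: done in %.3fs", name, timings[name])

    return _T()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages, reusing cached artifacts that already exist."""
    out = hio.ensure_dir(config.out_dir)
    grid = SpectralGrid.from_dict(config.grid)
    bandset = BandSet.from_dict(config.bands) if config.bands else default_save_bands()
    timings: dict = {}
    metrics: dict = {}
    paths = {
        "checker_spectra": os.path.join(out, "checker_spectra.csv"),
        "checker_rgb": os.path.join(out, "checker_rgb.csv"),
        "bundle": os.path.join(out, "bundle.json"),
        "scene_cube": os.path.join(out, "scene_truth.npz"),
        "scene_rgb": os.path.join(out, "scene_camera.tiff"),
        "recon_cube": os.path.join(out, "scene_recon.npz"),
        "save_image": os.path.join(out, "save_render.png"),
        "reference_image": os.path.join(out, "save_reference.png"),
        "wli_image": os.path.join(out, "wli_render.png"),
        "manifest": os.path.join(out, "manifest.json"),
    }

    # -- simulate ----------------------------------------------------------
    with _timed(timings, "simulate"):
        checker = make_reference_checker(grid)
        cam = default_virtual_camera(grid, noise_sigma=config.camera_noise_sigma, seed=config.seed)
        camera_rgb = simulate_camera_capture(checker, cam)
        measured = simulate_spectrometer(
            checker.reflectances, config.spectrometer_noise_sigma, seed=config.seed + 1
        )
        scene_params = LesionSceneParams(
            size=config.scene_size,
            lesion_radius=config.lesion_radius,
            melanin_od=config.melanin_od,
            hemoglobin_od=config.hemoglobin_od,
            grid=grid,
            seed=config.seed + 2,
        )
        truth_cube, _mask = make_lesion_scene(scene_params)
        if not os.path.exists(paths["checker_spectra"]):
            hio.write_spectra_csv(paths["checker_spectra"], grid, measured, checker.names)
        if not os.path.exists(paths["checker_rgb"]):
            import pandas as pd

            pd.DataFrame(camera_rgb, columns=["R", "G", "B"]).assign(name=checker.names).to_csv(
                paths["checker_rgb"], index=False
            )
        if not os.path.exists(paths["scene_cube"]):
            hio.write_cube(paths["scene_cube"], truth_cube)
        if not os.path.exists(paths["scene_rgb"]):
            scene_cam = default_virtual_camera(
                grid, noise_sigma=config.camera_noise_sigma, seed=config.seed + 3
            )
            scene_rgb = np.clip(simulate_camera_capture(truth_cube, scene_cam), 0.0, 1.0)
            hio.write_image(paths["scene_rgb"], scene_rgb, bit_depth=16, encode_srgb=True)

    # -- calibrate ---------------------------------------------------------
    with _timed(timings, "calibrate"):
        if os.path.exists(paths["bundle"]):
            results = hio.read_bundle(paths["bundle"])
        else:
            sgrid, spectra, _names = hio.read_spectra_csv(paths["checker_spectra"])
            model = SpectralCalibration(camera_rgb, spectra, sgrid)
            results = model.fit(order=config.order, n_components=config.n_components,
                                evaluation_window=tuple(config.evaluation_window))
            results.save(paths["bundle"])
        metrics["calibration"] = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in results.fit_report.items()
        }

    # -- convert -----------------------------------------------------------
    with _timed(timings, "convert"):
        if not os.path.exists(paths["recon_cube"]):
            scene_rgb = hio.read_image(paths["scene_rgb"])
            hio.write_cube(paths["recon_cube"], results.convert_image(scene_rgb))
        # always read back so downstream metrics are independent of cache state
        recon_cube = hio.read_cube(paths["recon_cube"])

    # -- render ------------------------------------------------------------
    with _timed(timings, "render"):
        truth_cube = hio.read_cube(paths["scene_cube"])
        save_img = synthesize_save_image(recon_cube, bandset)
        ref_img = synthesize_save_image(truth_cube, bandset)
        hio.write_image(paths["save_image"], save_img.channels, encode_srgb=False)
        hio.write_image(paths["reference_image"], ref_img.channels, encode_srgb=False)
        from .colorimetry import cie_1931_cmfs, d65_illuminant, spectra_to_xyz

        xyz = spectra_to_xyz(
            truth_cube.values.reshape(-1, grid.n_bands), d65_illuminant(grid), cie_1931_cmfs(grid)
        )
        wli = np.clip(xyz_to_srgb(xyz), 0, 1).reshape(truth_cube.height, truth_cube.width, 3)
        hio.write_image(paths["wli_image"], wli, encode_srgb=True)

        # band-weight calibration against the ground-truth rendering
        bvals = band_values(
            recon_cube.values.reshape(-1, grid.n_bands), grid, bandset
        )
        from .colorimetry import srgb_to_xyz

        target_xyz = srgb_to_xyz(ref_img.channels.reshape(-1, 3))
        sub = np.linspace(0, bvals.shape[0] - 1, min(64, bvals.shape[0]), dtype=int)
        bw = BandWeightCalibration(bvals[sub], target_xyz[sub], bandset)
        linear_stage = bw.fit_linear()
        fsa_stage = bw.fit(params=AnnealingParams(**{**config.annealing, "seed": config.seed + 4}))
        metrics["band_calibration"] = {
            "mean_de00_linear_stage": linear_stage.mean_de00,
            "mean_de00_fsa_stage": fsa_stage.mean_de00,
        }

    # -- evaluate ----------------------------------------------------------
    with _timed(timings, "evaluate"):
        report = compute_report(ref_img.channels, save_img.channels)
        metrics["image_quality"] = report.to_dict()

    hashes = {
        k: hio.sha256_of(p) for k, p in paths.items() if k != "manifest" and os.path.exists(p)
    }
    manifest = RunManifest(
        version=VERSION,
        config_hash=config.config_hash(),
        artifact_hashes=hashes,
        timings_s=timings,
        metrics=metrics,
    )
    manifest.write(paths["manifest"])
    return manifest
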