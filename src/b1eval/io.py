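"""NIfTI volume I/O and the YAML run configuration.

Volumes are exchanged as NIfTI-1/2 files on an isotropic grid; complex
fields are persisted as magnitude/phase pairs (complex NIfTI support is
inconsistent across toolchains).  The reader rejects anisotropic spacing
beyond 1% unless overridden, because the FD method assumes a single
isotropic h.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from b1eval.domain import ComplexField, VoxelGrid


class AnisotropicSpacingError(ValueError):
    pass


def read_volume(path: str | Path, allow_anisotropic: bool = False):
    """Read a NIfTI volume; returns (data, spacing_h [m], affine).

    Raises :class:`AnisotropicSpacingError` if the voxel spacing deviates
    from isotropy by more than 1% and ``allow_anisotropic`` is not set
    (the mean spacing is then returned as h).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    mean_zoom = float(np.mean(zooms))
    if mean_zoom <= 0:
        raise ValueError(f"non-positive voxel spacing in {path}")
    aniso = max(abs(z - mean_zoom) for z in zooms) / mean_zoom
    if aniso > 0.01 and not allow_anisotropic:
        raise AnisotropicSpacingError(
            f"{path} has anisotropic spacing {tuple(float(z) for z in zooms)} mm; "
            "the method assumes isotropic voxels (pass allow_anisotropic to override)"
        )
    # NIfTI zooms are in mm by convention
    return data, mean_zoom * 1e-3, img.affine


def write_volume(path: str | Path, data: np.ndarray, spacing_h: float,
                 affine: np.ndarray | None = None) -> None:
    """Write a real volume as NIfTI with isotropic spacing (h in meters)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    h_mm = spacing_h * 1e3
    if affine is None:
        affine = np.diag([h_mm, h_mm, h_mm, 1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    img.header.set_zooms((h_mm, h_mm, h_mm))
    nib.save(img, str(path))


def write_complex_field(
    stem: str | Path, field_: ComplexField, spacing_h: float
) -> tuple[Path, Path]:
    """Persist a complex field as <stem>_mag.nii.gz / <stem>_phase.nii.gz."""
    stem = Path(stem)
    mag_path = stem.with_name(stem.name + "_mag.nii.gz")
    phase_path = stem.with_name(stem.name + "_phase.nii.gz")
    write_volume(mag_path, field_.magnitude, spacing_h)
    write_volume(phase_path, field_.phase, spacing_h)
    return mag_path, phase_path


def read_complex_field(
    mag_path: str | Path, phase_path: str | Path, role: str = "b1_plus_measured"
):
    """Reassemble a complex field from a magnitude/phase NIfTI pair."""
    mag, h1, _ = read_volume(mag_path)
    phase, h2, _ = read_volume(phase_path)
    if abs(h1 - h2) > 1e-9:
        raise ValueError("magnitude and phase volumes have different spacing")
    return ComplexField.from_polar(mag, phase, role=role), h1


@dataclass
class RunConfig:
    """Flat run configuration mirroring the YAML file.

    Defaults reproduce the reference settings: convergence limit 1e-6,
    Gaussian smoothing std 4 in an 11-voxel kernel, spherical mean filter
    diameter 11, Larmor frequency 128 MHz, display thresholds 0.1 and
    0.2 S/m.
    """

    frequency: float = 128e6
    spacing_h: float = 1e-3
    grid_shape: tuple[int, int, int] = (48, 48, 48)

    convergence_limit_C: float = 1e-6
    max_iterations: int = 200_000
    init_mode: str = "uniform"
    convergence_statistic: str = "max"
    stop_rule: str = "fixed_point_error"
    with_bz: bool = False

    recon_method: str = "helmholtz_complex"
    denoise_diameter: int = 11
    boundary_erosion: int = 0

    smoothing_std: float = 4.0
    smoothing_kernel: int = 11
    display_threshold: float = 0.1
    display_threshold_invivo: float = 0.2

    phantom: dict = field(default_factory=dict)
    anomaly: dict | None = None
    noise: dict | None = None
    drive: dict = field(default_factory=dict)

    seed: int = 0
    output_dir: str = "b1eval_out"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "grid_shape" in raw:
            raw["grid_shape"] = tuple(int(n) for n in raw["grid_shape"])
        # YAML 1.1 reads exponents without a sign ("128.0e6") as strings
        for f_ in cls.__dataclass_fields__.values():  # type: ignore[attr-defined]
            if f_.name in raw and f_.type in ("float", "int"):
                raw[f_.name] = float(raw[f_.name]) if f_.type == "float" \
                    else int(raw[f_.name])
        return cls(**raw)

    def to_dict(self) -> dict:
        out = {}
        for name in self.__dataclass_fields__:  # type: ignore[attr-defined]
            value = getattr(self, name)
            out[name] = list(value) if isinstance(value, tuple) else value
        return out

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    def grid(self) -> VoxelGrid:
        return VoxelGrid(
            shape=self.grid_shape, spacing_h=self.spacing_h, frequency=self.frequency
        )
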