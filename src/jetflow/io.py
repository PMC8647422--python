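"""Containers and file I/O for 4D flow velocity fields and cardiac curves.

A 4D flow CMR acquisition encodes, per voxel and timeframe, a
three-directional velocity vector. The in-memory container
(:class:`VelocityField4D`) holds a single 5-axis array with axes
``(time, x, y, z, component)`` in cm/s, together with the acquisition
metadata needed for quantification: voxel spacing (mm), mid-frame times
(ms) and the velocity-encoding limit VENC (cm/s) beyond which measured
velocities wrap.

On disk a field is one NIfTI volume series per velocity component
(``<prefix>_vx.nii.gz`` etc., each of shape ``(x, y, z, t)``) plus a JSON
sidecar with ``spacing_mm``, ``frame_times_ms`` and ``venc_cms``. This
mirrors common research 4D flow exports without committing to any
scanner-specific DICOM layout. Flow-rate and volume curves are two-column
CSV files with times in ms.

Internal unit conventions, used everywhere in the package:
velocity cm/s, length mm, volume mL, flow rate mL/s
(1 cm/s through 1 mm² = 10 mm³/s = 0.01 mL/s).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VelocityField4D",
    "FlowCurve",
    "VolumeCurve",
    "read_velocity_field",
    "write_velocity_field",
    "read_flow_curve",
    "write_flow_curve",
    "read_volume_curve",
    "write_volume_curve",
]

_COMPONENT_SUFFIXES = ("vx", "vy", "vz")


@dataclass
class VelocityField4D:
    """Time-resolved three-directional velocity field.

    Parameters
    ----------
    velocities
        Array of shape ``(n_frames, nx, ny, nz, 3)`` in cm/s. Components
        are expressed along the physical axes of the affine.
    spacing
        Per-axis voxel size in mm, length 3, strictly positive.
    frame_times
        Mid-frame times in ms, strictly increasing, length ``n_frames``.
    venc
        Velocity-encoding limit in cm/s (> 0). A freshly acquired
        (wrapped) field has every component in ``[-venc, +venc]``.
    alias_flags
        Optional boolean array of shape ``(n_frames, nx, ny, nz)`` marking
        voxels whose velocity was corrected for aliasing.
    affine
        4x4 voxel-index -> physical-mm mapping. Defaults to a diagonal of
        the spacing with origin at 0.
    """

    velocities: np.ndarray
    spacing: np.ndarray
    frame_times: np.ndarray
    venc: float
    alias_flags: np.ndarray | None = None
    affine: np.ndarray = dc_field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.velocities = np.asarray(self.velocities, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.venc = float(self.venc)
        if self.velocities.ndim != 5 or self.velocities.shape[-1] != 3:
            raise ValueError(
                "velocities must have shape (t, x, y, z, 3); got "
                f"{self.velocities.shape}"
            )
        if self.velocities.shape[0] == 0:
            raise ValueError("velocity field must contain at least one frame")
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError("spacing must be 3 strictly positive values (mm)")
        if len(self.frame_times) != self.velocities.shape[0]:
            raise ValueError(
                f"{len(self.frame_times)} frame times for "
                f"{self.velocities.shape[0]} frames"
            )
        if len(self.frame_times) > 1 and np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")
        if not np.isfinite(self.venc) or self.venc <= 0:
            raise ValueError(f"venc must be a positive velocity in cm/s, got {self.venc}")
        if self.alias_flags is not None:
            self.alias_flags = np.asarray(self.alias_flags, dtype=bool)
            if self.alias_flags.shape != self.velocities.shape[:4]:
                raise ValueError("alias_flags shape must match (t, x, y, z)")
        if self.affine is None:
            self.affine = np.diag(np.append(self.spacing, 1.0))
        else:
            self.affine = np.asarray(self.affine, dtype=float)
            if self.affine.shape != (4, 4):
                raise ValueError("affine must be 4x4")

    @property
    def n_frames(self) -> int:
        return self.velocities.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.velocities.shape[1:4]

    def speed(self, frame: int) -> np.ndarray:
        """Euclidean velocity magnitude (cm/s) of one frame, shape (x, y, z)."""
        return np.linalg.norm(self.velocities[frame], axis=-1)

    def voxel_to_mm(self, idx: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices to physical mm via the affine."""
        idx = np.asarray(idx, dtype=float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def mm_to_voxel(self, pts: np.ndarray) -> np.ndarray:
        """Map (..., 3) physical-mm points to (fractional) voxel indices."""
        pts = np.asarray(pts, dtype=float)
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def copy(self) -> "VelocityField4D":
        return VelocityField4D(
            velocities=self.velocities.copy(),
            spacing=self.spacing.copy(),
            frame_times=self.frame_times.copy(),
            venc=self.venc,
            alias_flags=None if self.alias_flags is None else self.alias_flags.copy(),
            affine=self.affine.copy(),
        )


@dataclass
class FlowCurve:
    """A signed flow-rate curve: times in ms, rates in mL/s.

    Positive rates are forward/antegrade in the curve's declared
    direction convention (for an aortic curve: toward the aorta; for a
    regurgitant curve: into the atrium).
    """

    times: np.ndarray
    rates: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.rates.shape:
            raise ValueError("times and rates must be 1-D and equal length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class VolumeCurve:
    """Left-ventricular cavity volume over the cycle: times ms, volumes mL."""

    times: np.ndarray
    volumes: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.volumes.shape:
            raise ValueError("times and volumes must be 1-D and equal length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.volumes < 0):
            raise ValueError("volumes must be nonnegative")


def _component_paths(prefix: Path) -> list[Path]:
    return [prefix.parent / f"{prefix.name}_{s}.nii.gz" for s in _COMPONENT_SUFFIXES]


def write_velocity_field(field: VelocityField4D, out_prefix: str | Path) -> dict:
    """Write a field as three NIfTI series plus a JSON sidecar.

    Returns a dict of the written paths. ``read_velocity_field`` inverts
    this within floating-point round-trip tolerance.
    """
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for c, p in enumerate(_component_paths(prefix)):
        # component series stored (x, y, z, t) as is conventional for NIfTI
        vol = np.moveaxis(field.velocities[..., c], 0, -1)
        nib.save(nib.Nifti1Image(vol.astype(np.float32), field.affine), p)
        paths[_COMPONENT_SUFFIXES[c]] = p
    sidecar = prefix.parent / f"{prefix.name}_meta.json"
    meta = {
        "spacing_mm": field.spacing.tolist(),
        "frame_times_ms": field.frame_times.tolist(),
        "venc_cms": field.venc,
        "affine": field.affine.tolist(),
    }
    if field.alias_flags is not None:
        flag_path = prefix.parent / f"{prefix.name}_aliasflags.nii.gz"
        flags = np.moveaxis(field.alias_flags, 0, -1).astype(np.uint8)
        nib.save(nib.Nifti1Image(flags, field.affine), flag_path)
        meta["alias_flags"] = flag_path.name
        paths["alias_flags"] = flag_path
    sidecar.write_text(json.dumps(meta, indent=1))
    paths["meta"] = sidecar
    return paths


def read_velocity_field(
    component_paths: list[str | Path] | str | Path,
    metadata_path: str | Path | None = None,
) -> VelocityField4D:
    """Read a field from three component NIfTI series plus a JSON sidecar.

    ``component_paths`` may also be a single prefix path, in which case the
    ``<prefix>_vx/_vy/_vz.nii.gz`` and ``<prefix>_meta.json`` naming of
    :func:`write_velocity_field` is assumed.
    """
    if isinstance(component_paths, (str, Path)):
        prefix = Path(component_paths)
        component_paths = _component_paths(prefix)
        if metadata_path is None:
            metadata_path = prefix.parent / f"{prefix.name}_meta.json"
    if metadata_path is None:
        raise ValueError("metadata_path is required when explicit component paths are given")
    meta = json.loads(Path(metadata_path).read_text())
    for key in ("spacing_mm", "frame_times_ms", "venc_cms"):
        if key not in meta:
            raise ValueError(f"metadata sidecar is missing required key {key!r}")

    comps = []
    for p in component_paths:
        img = nib.load(str(p))
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim == 3:
            data = data[..., None]
        comps.append(np.moveaxis(data, -1, 0))  # -> (t, x, y, z)
    shapes = {c.shape for c in comps}
    if len(shapes) != 1:
        raise ValueError(f"component series disagree on grid/frame shape: {sorted(shapes)}")

    alias = None
    if meta.get("alias_flags"):
        flag_path = Path(metadata_path).parent / meta["alias_flags"]
        flags = np.asarray(nib.load(str(flag_path)).dataobj)
        alias = np.moveaxis(flags, -1, 0).astype(bool)

    return VelocityField4D(
        velocities=np.stack(comps, axis=-1),
        spacing=np.asarray(meta["spacing_mm"], dtype=float),
        frame_times=np.asarray(meta["frame_times_ms"], dtype=float),
        venc=float(meta["venc_cms"]),
        alias_flags=alias,
        affine=np.asarray(meta["affine"], dtype=float) if "affine" in meta else None,
    )


def write_flow_curve(curve: FlowCurve, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_ms": curve.times, "rate_mls": curve.rates}).to_csv(path, index=False)
    return path


def read_flow_curve(path: str | Path) -> FlowCurve:
    df = pd.read_csv(path)
    return FlowCurve(times=df["time_ms"].to_numpy(), rates=df["rate_mls"].to_numpy())


def write_volume_curve(curve: VolumeCurve, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_ms": curve.times, "volume_ml": curve.volumes}).to_csv(path, index=False)
    return path


def read_volume_curve(path: str | Path) -> VolumeCurve:
    df = pd.read_csv(path)
    return VolumeCurve(times=df["time_ms"].to_numpy(), volumes=df["volume_ml"].to_numpy())
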