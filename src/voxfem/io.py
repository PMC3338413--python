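"""Image readers/writers, run reports and configuration plumbing.

Supported volume formats: NIfTI (via nibabel), MetaImage (via SimpleITK)
and raw binary with a JSON sidecar describing dims, dtype, voxel size and
an optional linear intensity-to-BVF map.  Voxel spacing must be isotropic;
the element kernel derivation assumes cubic voxels, so anisotropic images
are rejected rather than silently resampled.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk

from .mechanics import SolveResult
from .model import VoxelModel

__all__ = [
    "read_bvf_image",
    "write_bvf_image",
    "write_energy_map",
    "write_report",
    "parse_report",
]

logger = logging.getLogger(__name__)

_ISO_RTOL = 1e-4


def _detect_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".mha", ".mhd")):
        return "metaimage"
    if name.endswith(".raw"):
        return "raw"
    raise ValueError(f"cannot infer image format from {path.name!r}")


def _check_isotropic(spacing) -> float:
    spacing = np.asarray(spacing, dtype=float)
    if not np.allclose(spacing, spacing[0], rtol=_ISO_RTOL):
        raise ValueError(f"anisotropic voxel spacing {tuple(spacing)} is not supported")
    return float(spacing[0])


def _to_bvf(data: np.ndarray, slope: float, intercept: float) -> np.ndarray:
    bvf = slope * data.astype(np.float64) + intercept
    out_of_range = (bvf < -1e-6) | (bvf > 1.0 + 1e-6)
    if out_of_range.any():
        warnings.warn(
            f"{int(out_of_range.sum())} voxel(s) outside [0, 1] after intensity map; clipping",
            stacklevel=3,
        )
    return np.clip(bvf, 0.0, 1.0)


def read_bvf_image(
    path: str | Path,
    fmt: str | None = None,
    slope: float = 1.0,
    intercept: float = 0.0,
) -> VoxelModel:
    """Read a 3D bone-volume-fraction image.

    ``slope`` / ``intercept`` apply a linear intensity-to-BVF calibration
    (for raw files the sidecar's values take precedence); the result is
    clipped to [0, 1] with a warning if the declared map overshoots.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or _detect_format(path)

    if fmt == "nifti":
        img = nib.load(path)
        voxel_size = _check_isotropic(img.header.get_zooms()[:3])
        data = np.asarray(img.dataobj)
    elif fmt == "metaimage":
        img = sitk.ReadImage(str(path))
        voxel_size = _check_isotropic(img.GetSpacing())
        # SimpleITK arrays are (z, y, x); store as (x, y, z)
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    elif fmt == "raw":
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise FileNotFoundError(f"raw image requires sidecar {sidecar.name}")
        meta = json.loads(sidecar.read_text())
        for key in ("dims", "dtype", "voxel_size"):
            if key not in meta:
                raise ValueError(f"sidecar missing required field {key!r}")
        dims = tuple(int(d) for d in meta["dims"])
        data = np.fromfile(path, dtype=np.dtype(meta["dtype"]))
        if data.size != int(np.prod(dims)):
            raise ValueError("raw file size does not match sidecar dims")
        data = data.reshape(dims, order=meta.get("order", "C"))
        voxel_size = float(meta["voxel_size"])
        slope = float(meta.get("slope", slope))
        intercept = float(meta.get("intercept", intercept))
    else:
        raise ValueError(f"unsupported format {fmt!r}")

    if data.ndim != 3:
        raise ValueError("expected a 3D volume")
    return VoxelModel(bvf=_to_bvf(data, slope, intercept), voxel_size=voxel_size)


def _write_volume(data: np.ndarray, voxel_size: float, path: Path) -> None:
    fmt = _detect_format(path)
    if fmt == "nifti":
        affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
        nib.save(nib.Nifti1Image(data.astype(np.float32), affine), path)
    elif fmt == "metaimage":
        img = sitk.GetImageFromArray(data.transpose(2, 1, 0).astype(np.float32))
        img.SetSpacing((voxel_size,) * 3)
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unsupported output format for {path.name!r}")


def write_bvf_image(model: VoxelModel, path: str | Path) -> None:
    """Write a model's BVF grid as NIfTI or MetaImage."""
    _write_volume(model.bvf, model.voxel_size, Path(path))


def write_energy_map(emap: np.ndarray, model: VoxelModel, path: str | Path) -> None:
    """Write a strain-energy map with the model's geometry/header."""
    if emap.shape != model.dims:
        raise ValueError("energy map shape does not match model dims")
    _write_volume(emap, model.voxel_size, Path(path))


def write_report(result: SolveResult, path: str | Path, extra: dict | None = None) -> None:
    """Key-value run report (text, one ``key = value`` per line)."""
    from . import __version__

    fields: dict[str, object] = {
        "voxfem_version": __version__,
        "stiffness_mpa": repr(result.stiffness),
        "total_stress_mpa": repr(result.stress),
        "applied_strain": repr(result.strain),
        "iterations_per_level": ",".join(str(i) for i in result.iterations_per_level),
        "total_iterations": result.total_iterations,
        "converged": result.converged,
    }
    if result.trace is not None and result.trace.estimated_errors:
        ests = [e for e in result.trace.estimated_errors if e is not None]
        fields["estimated_relative_error"] = repr(ests[-1]) if ests else "unavailable"
    if extra:
        fields.update(extra)
    lines = [f"{k} = {v}" for k, v in fields.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def parse_report(path: str | Path) -> dict[str, str]:
    """Parse a run report back into a string-valued dict."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if " = " in line:
            k, v = line.split(" = ", 1)
            out[k.strip()] = v.strip()
    return out
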