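"""Standard-format I/O: CSV spectra, NIfTI volume stacks, HDF5 datasets.

Single spectra travel as two-column CSV (offset_ppm, value); volumetric
studies as one 3D NIfTI volume per offset plus R1obs/fm maps; training
datasets and simulation sets as HDF5.  Every CLI run writes a JSON
reproducibility manifest (config, seeds, package versions, input hashes).
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .partial_synth import TrainingDataset, TrainingSample
from .physics import RexSpectrum, ZSpectrum

__all__ = [
    "StudyBundle",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_nifti_stack",
    "write_maps",
    "save_dataset_h5",
    "load_dataset_h5",
    "save_samples_h5",
    "load_samples_h5",
    "load_config",
    "write_manifest",
]


@dataclass
class StudyBundle:
    """A volumetric CEST study: per-offset volumes plus parameter maps."""

    volumes: np.ndarray  # (nx, ny, nz, n_offsets)
    offsets_ppm: np.ndarray
    r1obs: np.ndarray | None = None
    fm: np.ndarray | None = None
    mask: np.ndarray | None = None
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.offsets_ppm = np.asarray(self.offsets_ppm, dtype=float)
        if self.volumes.shape[-1] != self.offsets_ppm.size:
            raise ValueError(
                f"offset count ({self.offsets_ppm.size}) does not match volume count ({self.volumes.shape[-1]})"
            )
        for name in ("r1obs", "fm", "mask"):
            m = getattr(self, name)
            if m is not None and np.asarray(m).shape != self.volumes.shape[:-1]:
                raise ValueError(f"{name} map shape does not match the volume grid")

    def voxel_spectrum(self, i: int, j: int, k: int) -> ZSpectrum:
        return ZSpectrum(
            self.offsets_ppm,
            self.volumes[i, j, k],
            r1obs=float(self.r1obs[i, j, k]) if self.r1obs is not None else np.nan,
            fm=float(self.fm[i, j, k]) if self.fm is not None else np.nan,
        )


# ---------------------------------------------------------------------------
# CSV spectra


def read_spectrum_csv(path, r1obs: float = np.nan, fm: float = np.nan) -> ZSpectrum:
    """Two-column CSV (offset_ppm, value) → ZSpectrum, offsets sorted."""
    df = pd.read_csv(path)
    if not {"offset_ppm", "value"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns offset_ppm, value")
    order = np.argsort(df["offset_ppm"].to_numpy())
    return ZSpectrum(
        df["offset_ppm"].to_numpy()[order], df["value"].to_numpy()[order], r1obs=r1obs, fm=fm
    )


def write_spectrum_csv(path, offsets_ppm, values) -> None:
    pd.DataFrame({"offset_ppm": np.asarray(offsets_ppm), "value": np.asarray(values)}).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# NIfTI


def read_nifti_stack(z_paths, offsets_ppm, r1obs_path=None, fm_path=None, mask_path=None) -> StudyBundle:
    """Load one 3D NIfTI per offset (order must match ``offsets_ppm``)."""
    offsets_ppm = np.asarray(offsets_ppm, dtype=float)
    imgs = [nib.load(str(p)) for p in z_paths]
    if len(imgs) != offsets_ppm.size:
        raise ValueError(f"{len(imgs)} volumes but {offsets_ppm.size} offsets")
    shapes = {im.shape for im in imgs}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent volume shapes: {shapes}")
    vol = np.stack([np.asarray(im.dataobj, dtype=float) for im in imgs], axis=-1)
    order = np.argsort(offsets_ppm)
    load_map = lambda p: None if p is None else np.asarray(nib.load(str(p)).dataobj, dtype=float)
    return StudyBundle(
        vol[..., order],
        offsets_ppm[order],
        r1obs=load_map(r1obs_path),
        fm=load_map(fm_path),
        mask=load_map(mask_path),
        affine=imgs[0].affine,
    )


def write_maps(maps: dict[str, np.ndarray], affine: np.ndarray, out_dir, units: str = "%s^-1") -> list[Path]:
    """Write method-tagged NIfTI maps (NaN voxels preserved)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, data in maps.items():
        img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
        img.header["descrip"] = f"units={units}".encode()[:80]
        p = out_dir / f"{name}.nii.gz"
        nib.save(img, str(p))
        written.append(p)
    return written


# ---------------------------------------------------------------------------
# HDF5 datasets


def save_dataset_h5(dataset: TrainingDataset, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=dataset.X, compression="gzip")
        f.create_dataset("y", data=dataset.y, compression="gzip")
        f.create_dataset("offsets_ppm", data=dataset.offsets_ppm)
        f.attrs["normalization"] = dataset.normalization


def load_dataset_h5(path) -> TrainingDataset:
    with h5py.File(path, "r") as f:
        return TrainingDataset(
            f["X"][()], f["y"][()], f["offsets_ppm"][()], f.attrs["normalization"]
        )


def save_samples_h5(samples: list[TrainingSample], path) -> None:
    """Raw sample bundle: Z matrix, targets, per-sample metadata."""
    with h5py.File(path, "w") as f:
        f.create_dataset("offsets_ppm", data=samples[0].offsets_ppm)
        f.create_dataset("Z", data=np.stack([s.z for s in samples]), compression="gzip")
        f.create_dataset("r1obs", data=np.array([s.r1obs for s in samples]))
        f.create_dataset("fm", data=np.array([s.fm for s in samples]))
        f.create_dataset("target_a", data=np.array([s.target_a for s in samples]))
        f.create_dataset("target_w", data=np.array([s.target_w for s in samples]))
        f.create_dataset(
            "provenance", data=np.array([json.dumps(s.provenance) for s in samples], dtype=h5py.string_dtype())
        )


def load_samples_h5(path) -> list[TrainingSample]:
    with h5py.File(path, "r") as f:
        offs = f["offsets_ppm"][()]
        Z = f["Z"][()]
        r1 = f["r1obs"][()]
        fm = f["fm"][()]
        a = f["target_a"][()]
        w = f["target_w"][()]
        prov = [json.loads(p) for p in f["provenance"].asstr()[()]]
    return [
        TrainingSample(offs, Z[i], float(r1[i]), float(fm[i]), float(a[i]), float(w[i]), prov[i])
        for i in range(Z.shape[0])
    ]


# ---------------------------------------------------------------------------
# config and manifests


def load_config(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f) or {}


def _file_hash(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_manifest(out_dir, command: str, config: dict, seeds: dict, inputs: list = ()) -> Path:
    """JSON reproducibility manifest for a CLI run."""
    import guancest

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config": config,
        "seeds": seeds,
        "versions": {
            "guancest": guancest.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
        "input_hashes": {str(p): _file_hash(p) for p in inputs},
    }
    path = out_dir / f"manifest_{command}.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
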