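"""NIfTI / FSL-dialect readers and writers, and the pipeline configuration.

Conventions: voxel indices are 0-based; world coordinates follow the NIfTI
affine; gradient directions are interpreted in the image coordinate frame
(FSL dialect).  Scalar maps are written as float32 with missing values
encoded as NaN, each with a sidecar TSV recording the units.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .gradients import GradientTable, read_bvals_bvecs, write_bvals_bvecs

__all__ = [
    "DWIDataset",
    "ParameterMap",
    "read_dwi",
    "write_map",
    "load_map",
    "write_phantom",
    "PipelineConfig",
]

#: Units of every scalar map the pipeline produces.
MAP_UNITS = {
    "md": "um^2/ms",
    "fa": "dimensionless",
    "lambda_par": "um^2/ms",
    "lambda_perp": "um^2/ms",
    "mk": "dimensionless",
    "rk": "dimensionless",
    "ak": "dimensionless",
    "icvf": "fraction",
    "odi": "dimensionless",
    "iso": "fraction",
    "mwf": "fraction",
    "mtr": "percent",
    "r2star": "1/s",
}


@dataclass(frozen=True)
class DWIDataset:
    """4D diffusion-weighted volume paired with its gradient table."""

    data: np.ndarray
    gtab: GradientTable
    affine: np.ndarray


@dataclass(frozen=True)
class ParameterMap:
    """Voxel-wise scalar map with units metadata."""

    name: str
    data: np.ndarray
    units: str
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))


def read_dwi(
    nifti_path: str | Path, bval_path: str | Path, bvec_path: str | Path
) -> DWIDataset:
    """Load a 4D DWI NIfTI with FSL ``bvals``/``bvecs``.

    The 4th-axis length must equal the gradient count; slightly off-unit
    bvecs (|norm - 1| < 1e-3) are renormalised.
    """
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D volume, got shape {data.shape}")
    gtab = read_bvals_bvecs(bval_path, bvec_path)
    if data.shape[3] != len(gtab):
        raise ValueError(
            f"volume has {data.shape[3]} frames but gradient table has "
            f"{len(gtab)} entries"
        )
    return DWIDataset(data, gtab, img.affine)


def write_map(
    data: np.ndarray,
    path: str | Path,
    affine: np.ndarray | None = None,
    units: str | None = None,
    name: str | None = None,
) -> Path:
    """Write a scalar map as float32 NIfTI plus a units sidecar TSV."""
    path = Path(path)
    affine = np.eye(4) if affine is None else affine
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    nib.save(img, str(path))
    stem = path.name.removesuffix(".gz").removesuffix(".nii")
    if units is None:
        units = MAP_UNITS.get(name or stem, "unknown")
    sidecar = path.with_name(stem + "_units.tsv")
    sidecar.write_text(f"map\tunits\n{name or stem}\t{units}\n")
    return path


def load_map(path: str | Path) -> ParameterMap:
    path = Path(path)
    img = nib.load(str(path))
    stem = path.name.removesuffix(".gz").removesuffix(".nii")
    units = "unknown"
    sidecar = path.with_name(stem + "_units.tsv")
    if sidecar.exists():
        line = sidecar.read_text().splitlines()[-1].split("\t")
        if len(line) == 2:
            units = line[1]
    return ParameterMap(stem, np.asarray(img.dataobj, dtype=float), units, img.affine)


def write_phantom(phantom, out_dir: str | Path) -> Path:
    """Write a phantom to disk as standard volumes.

    Emits 4D DWI NIfTIs (one per forward-model channel) with shared FSL
    ``bvals``/``bvecs``, the CPMG 4D series (echo axis last), B1, MT and
    non-MT volumes, the 4D gradient-echo series, the integer ROI label
    mask and a ground-truth TSV.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = phantom.affine

    def save(arr, fname, dtype=np.float32):
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=dtype), aff), str(out / fname))

    save(phantom.dwi_tensor, "dwi_tensor.nii.gz")
    save(phantom.dwi_kurtosis, "dwi_kurtosis.nii.gz")
    save(phantom.dwi_noddi, "dwi_noddi.nii.gz")
    save(phantom.cpmg, "cpmg.nii.gz")
    save(phantom.b1, "b1.nii.gz")
    save(phantom.non_mt, "non_mt.nii.gz")
    save(phantom.mt, "mt.nii.gz")
    save(phantom.gre, "gre.nii.gz")
    save(phantom.labels, "labels.nii.gz", dtype=np.int16)
    write_bvals_bvecs(phantom.gtab, out / "bvals", out / "bvecs")
    phantom.truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    np.savetxt(out / "cpmg_echo_times_ms.txt", phantom.cpmg_echo_times, fmt="%.3f")
    np.savetxt(out / "gre_echo_times_ms.txt", phantom.gre_echo_times, fmt="%.3f")
    return out


@dataclass
class PipelineConfig:
    """Flat, YAML-serialisable configuration of the end-to-end run."""

    out_dir: str = "wmquant_out"
    seed: int = 0
    n_subjects: int = 3
    voxels_per_region: int = 5
    noise_sigma: float = 0.0
    # acquisition
    b_low: float = 700.0
    n_low: int = 30
    b_high: float = 2000.0
    n_high: int = 64
    n_b0: int = 1
    n_echoes: int = 32
    echo_spacing_ms: float = 10.0
    gre_echo_times_ms: tuple = (4.5, 10.0, 15.0, 21.0, 27.0, 33.0, 39.0, 46.0)
    # fitting
    t2_grid_n: int = 32
    t2_grid_min_ms: float = 10.0
    t2_grid_max_ms: float = 2000.0
    mwf_cutoff_ms: float = 30.0
    chi2_factor: float = 1.01
    t1_ms: float = 1000.0
    noddi_d_par: float = 1.7
    noddi_d_iso: float = 3.0
    # stage switches
    fit_dti: bool = True
    fit_dki: bool = True
    fit_noddi: bool = True
    fit_mwf: bool = True
    fit_mtr: bool = True
    fit_r2star: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "gre_echo_times_ms" in raw:
            raw["gre_echo_times_ms"] = tuple(raw["gre_echo_times_ms"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["gre_echo_times_ms"] = list(d["gre_echo_times_ms"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
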