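"""Standard-format readers and writers.

NIfTI-1 volumes via nibabel (maps written float32, affines passed through);
FSL-dialect bval/bvec text b-tables (bvec columns correspond to volumes,
vectors in the image frame); TRK/TCK tractograms via nibabel.streamlines;
JSON sidecars for peak maps and run manifests.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
from nibabel import streamlines as nibsl

from .peaks import PeakMap
from .recon import ConfigurationError, DWIDataset
from .sphere import build_tessellation
from .tracking import Streamline, Tractogram

__all__ = [
    "read_dwi",
    "write_dwi",
    "read_btable",
    "save_map",
    "write_tractogram",
    "read_tractogram",
    "save_peakmap",
    "load_peakmap",
    "write_manifest",
]


def read_btable(bval_path, bvec_path, n_volumes: int) -> tuple[np.ndarray, np.ndarray]:
    """Load FSL bval/bvec files and validate against the volume count."""
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.ndim != 2:
        raise ConfigurationError("bvec file must be a 2-D table")
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T  # FSL writes 3 rows x N columns
    if len(bvals) != n_volumes or bvecs.shape[0] != n_volumes:
        raise ConfigurationError(
            f"b-table does not match image: {n_volumes} volumes, "
            f"{len(bvals)} b-values, {bvecs.shape[0]} b-vectors"
        )
    norms = np.linalg.norm(bvecs, axis=1)
    nz = norms > 0
    bvecs = bvecs.copy()
    bvecs[nz] /= norms[nz, None]  # normalize; zero vectors kept for b=0
    return bvals, bvecs


def read_dwi(nifti_path, bval_path, bvec_path, mask_path=None) -> DWIDataset:
    """Load a 4-D DWI NIfTI with its b-table into a validated dataset."""
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ConfigurationError(f"expected 4-D DWI, got shape {data.shape}")
    bvals, bvecs = read_btable(bval_path, bvec_path, data.shape[3])
    mask = None
    if mask_path is not None:
        mimg = nib.load(str(mask_path))
        mask = np.asarray(mimg.dataobj) > 0
    voxel_size = np.asarray(img.header.get_zooms()[:3], dtype=float)
    return DWIDataset(
        signal=data,
        bvals=bvals,
        bvecs=bvecs,
        voxel_size=voxel_size,
        mask=mask,
        affine=np.asarray(img.affine),
    )


def write_dwi(dwi: DWIDataset, nifti_path, bval_path, bvec_path) -> None:
    img = nib.Nifti1Image(dwi.signal.astype(np.float32), dwi.affine)
    img.header.set_zooms(tuple(dwi.voxel_size) + (1.0,))
    nib.save(img, str(nifti_path))
    np.savetxt(bval_path, dwi.bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, dwi.bvecs.T, fmt="%.9f")


def save_map(volume: np.ndarray, path, affine: np.ndarray | None = None) -> None:
    """Write a scalar map as float32 NIfTI."""
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine), str(path))


def _tractogram_format(path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix not in (".trk", ".tck"):
        raise ConfigurationError(f"unknown tractogram extension {suffix!r}")
    return suffix[1:]


def write_tractogram(tractogram: Tractogram, path, format: str | None = None) -> None:
    """Write streamlines as TRK or TCK (chosen from the extension).

    Streamline points are already in mm (RAS); the TRK header carries the
    voxel size and grid dimensions.
    """
    fmt = format or _tractogram_format(path)
    sl = [s.points.astype(np.float32) for s in tractogram.streamlines]
    t = nibsl.Tractogram(sl, affine_to_rasmm=np.eye(4))
    if fmt == "trk":
        header = {
            "voxel_sizes": np.asarray(tractogram.voxel_size, np.float32),
            "voxel_to_rasmm": np.asarray(tractogram.affine, np.float32),
            "voxel_order": "RAS",
        }
        nibsl.save(t, str(path), header=header)
    elif fmt == "tck":
        nibsl.save(nibsl.tck.TckFile(t), str(path))
    else:
        raise ConfigurationError(f"unknown tractogram format {fmt!r}")


def read_tractogram(path) -> Tractogram:
    f = nibsl.load(str(path))
    t = f.tractogram.to_world()
    sls = [Streamline(points=np.asarray(p, dtype=np.float64)) for p in t.streamlines]
    if hasattr(f.header, "get"):
        vs = np.asarray(f.header.get("voxel_sizes", (1.0, 1.0, 1.0)), float)
    else:  # pragma: no cover
        vs = np.ones(3)
    return Tractogram(streamlines=sls, voxel_size=vs, affine=np.eye(4))


def save_peakmap(peaks: PeakMap, stem) -> None:
    """Persist a PeakMap as a NIfTI pair plus a JSON sidecar.

    ``<stem>_index.nii.gz`` holds hemisphere vertex ids (-1 = empty slot),
    ``<stem>_qa.nii.gz`` the QA values, and ``<stem>.json`` the scalars
    needed to rebuild it (z0, sampling ratio, tessellation level, max_peaks).
    """
    stem = str(stem)
    aff = peaks.affine
    nib.save(nib.Nifti1Image(peaks.peak_vertex.astype(np.int32), aff), stem + "_index.nii.gz")
    nib.save(nib.Nifti1Image(peaks.peak_qa.astype(np.float32), aff), stem + "_qa.nii.gz")
    sidecar = {
        "z0": peaks.z0,
        "tessellation_level": peaks.tessellation.level,
        "max_peaks": peaks.max_peaks,
        "voxel_size": list(map(float, peaks.voxel_size)),
        "sampling_length_ratio": peaks.meta.get("sampling_length_ratio"),
    }
    Path(stem + ".json").write_text(json.dumps(sidecar, indent=2))


def load_peakmap(stem) -> PeakMap:
    stem = str(stem)
    sidecar = json.loads(Path(stem + ".json").read_text())
    vert_img = nib.load(stem + "_index.nii.gz")
    qa_img = nib.load(stem + "_qa.nii.gz")
    tess = build_tessellation(sidecar["tessellation_level"])
    return PeakMap(
        peak_vertex=np.asarray(vert_img.dataobj, dtype=np.int64),
        peak_qa=np.asarray(qa_img.dataobj, dtype=np.float64),
        tessellation=tess,
        z0=sidecar["z0"],
        voxel_size=np.asarray(sidecar["voxel_size"], float),
        affine=np.asarray(vert_img.affine),
        meta={"sampling_length_ratio": sidecar.get("sampling_length_ratio")},
    )


def write_manifest(path, **entries) -> None:
    """Record every parameter of a run (thresholds, seeds, version) as JSON,
    sufficient to reproduce the run bitwise."""
    from . import __version__

    payload = {"qatract_version": __version__}
    for k, v in entries.items():
        if isinstance(v, np.ndarray):
            v = v.tolist()
        payload[k] = v
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
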