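"""Peak extraction and quantitative anisotropy (QA).

A fiber orientation is a strict local maximum of the voxel's SDF over the
tessellation's 1-ring adjacency (hemisphere-symmetrized).  Each peak carries

    QA(a) = Z0 * (psi(a) - iso(psi)),

where iso(psi) is the voxel's minimum SDF sample and Z0 is a global constant
scaling free-water diffusion to 1, making QA comparable across datasets.
Because QA belongs to an orientation rather than to the voxel, thresholding
on QA can remove a single noisy fiber while keeping the others — unlike FA,
GFA, or an anatomy label, which every fiber in the voxel shares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .recon import ConfigurationError, SDFVolume
from .sphere import SphereTessellation

__all__ = ["PeakMap", "extract_peaks", "compute_z0", "attach_scalar_indices"]

VOXEL_LEVEL_INDICES = ("fa", "gfa", "anatomy")


@dataclass
class PeakMap:
    """Per-voxel fiber orientations with per-orientation QA.

    ``peak_vertex`` holds hemisphere vertex ids into
    ``tessellation.hemisphere_vertices`` (-1 pads empty slots); ``peak_qa``
    the matching QA values, non-increasing within each voxel.  Optional
    voxel-level maps (``fa``, ``gfa``, ``anatomy``) support swapping the
    tracker's termination index.
    """

    peak_vertex: np.ndarray  # (X, Y, Z, max_peaks) int
    peak_qa: np.ndarray  # (X, Y, Z, max_peaks) float
    tessellation: SphereTessellation
    z0: float
    voxel_size: np.ndarray
    affine: np.ndarray | None = None
    fa: np.ndarray | None = None
    gfa: np.ndarray | None = None
    anatomy: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.affine is None:
            self.affine = np.diag(np.r_[np.asarray(self.voxel_size, float), 1.0])
        # cache unit vectors of peaks for the tracker
        self._hemi = self.tessellation.hemisphere_vertices
        self._dirs = np.where(
            (self.peak_vertex >= 0)[..., None],
            self._hemi[np.clip(self.peak_vertex, 0, None)],
            0.0,
        )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.peak_vertex.shape[:3]

    @property
    def max_peaks(self) -> int:
        return self.peak_vertex.shape[3]

    @property
    def peak_dirs(self) -> np.ndarray:
        """Unit orientation per peak slot, (X, Y, Z, max_peaks, 3); zero rows
        pad empty slots."""
        return self._dirs

    def n_peaks(self) -> np.ndarray:
        return (self.peak_vertex >= 0).sum(axis=-1)

    def index_map(self, index_name: str) -> np.ndarray:
        """Voxel-level scalar map for a named index (qa -> largest peak QA)."""
        if index_name == "qa":
            return self.peak_qa[..., 0]
        m = getattr(self, index_name, None)
        if m is None:
            raise ConfigurationError(f"index map {index_name!r} not attached")
        return np.asarray(m, dtype=float)

    def voxel_peaks(self, voxel: tuple[int, int, int]) -> list[tuple[np.ndarray, float]]:
        """(orientation, qa) pairs at an integer voxel, descending qa."""
        out = []
        for s in range(self.max_peaks):
            v = self.peak_vertex[voxel][s]
            if v < 0:
                break
            out.append((self._hemi[v], float(self.peak_qa[voxel][s])))
        return out


def _neighbor_table(tess: SphereTessellation) -> np.ndarray:
    """Hemisphere adjacency padded to a rectangular int array (-1 pads)."""
    adj = tess.hemisphere_adjacency()
    width = max(len(a) for a in adj)
    table = np.full((len(adj), width), -1, dtype=np.int64)
    for i, a in enumerate(adj):
        table[i, : len(a)] = a
    return table


def extract_peaks(
    sdf: SDFVolume,
    tess: SphereTessellation | None = None,
    max_peaks: int = 3,
    z0: float | None = None,
) -> PeakMap:
    """Find strict local maxima of each voxel's SDF and score them with QA.

    A vertex is a peak iff its psi strictly exceeds psi at every 1-ring
    neighbor (plateaus therefore yield no peak; a constant, e.g. isotropic,
    voxel has none).  The ``max_peaks`` largest peaks are kept, sorted by
    descending QA.  ``z0`` defaults to the value stored on ``sdf`` (1.0 if
    unset); compute it with :func:`compute_z0`.
    """
    if max_peaks < 1:
        raise ConfigurationError("max_peaks must be a positive integer")
    tess = tess or sdf.tessellation
    if z0 is None:
        z0 = sdf.z0 if sdf.z0 is not None else 1.0

    psi = sdf.psi
    shape = psi.shape[:3]
    flat = psi.reshape(-1, psi.shape[-1])

    table = _neighbor_table(tess)
    pad = table < 0
    nb = np.clip(table, 0, None)
    # (V, H, deg): psi at each vertex's neighbors; padded slots never veto
    nb_psi = flat[:, nb]
    is_peak = np.all(flat[:, :, None] > np.where(pad, -np.inf, nb_psi), axis=-1)

    qa_all = np.where(is_peak, z0 * (flat - flat.min(axis=1, keepdims=True)), -np.inf)
    order = np.argsort(-qa_all, axis=1, kind="stable")[:, :max_peaks]
    top_qa = np.take_along_axis(qa_all, order, axis=1)
    vert = np.where(np.isfinite(top_qa), order, -1)
    top_qa = np.where(np.isfinite(top_qa), top_qa, 0.0)

    return PeakMap(
        peak_vertex=vert.reshape(shape + (max_peaks,)),
        peak_qa=top_qa.reshape(shape + (max_peaks,)),
        tessellation=tess,
        z0=float(z0),
        voxel_size=np.ones(3) if sdf.voxel_size is None else sdf.voxel_size,
        affine=sdf.affine,
        meta={"sampling_length_ratio": sdf.sampling_length_ratio,
              "tessellation_level": tess.level, "max_peaks": int(max_peaks)},
    )


def compute_z0(
    sdf: SDFVolume,
    free_water_region: np.ndarray | str = "auto",
    auto_fraction: float = 0.001,
) -> float:
    """Scaling constant Z0 that normalizes free-water diffusion to 1.

    Z0 = 1 / mean over the free-water region of each voxel's maximum SDF
    sample.  With ``free_water_region='auto'`` the region is the voxels with
    the largest isotropic background (top ``auto_fraction`` of iso, at least
    one voxel) — free water has the flattest, tallest SDF baseline.  Phantoms
    should pass their known water mask explicitly.
    """
    max_psi = sdf.psi.max(axis=-1)
    if isinstance(free_water_region, str):
        if free_water_region != "auto":
            raise ConfigurationError("free_water_region must be a mask or 'auto'")
        valid = sdf.mask if sdf.mask is not None else np.ones(sdf.iso.shape, bool)
        iso = np.where(valid, sdf.iso, -np.inf)
        n = max(1, int(round(auto_fraction * valid.sum())))
        thresh = np.partition(iso.ravel(), -n)[-n]
        region = iso >= thresh
    else:
        region = np.asarray(free_water_region, dtype=bool)
        if region.shape != sdf.iso.shape:
            raise ConfigurationError("free_water_region shape mismatch")
    if not region.any():
        raise ConfigurationError("free-water region is empty")
    mean_max = float(max_psi[region].mean())
    if mean_max <= 0:
        raise ConfigurationError("free-water region has zero SDF amplitude")
    return 1.0 / mean_max


def attach_scalar_indices(
    peaks: PeakMap,
    fa_map: np.ndarray | None = None,
    gfa_map: np.ndarray | None = None,
    anatomy_mask: np.ndarray | None = None,
) -> PeakMap:
    """Attach voxel-level index maps for termination-index swapping.

    Every fiber in a voxel shares these values; thresholding on them is
    all-or-nothing per voxel, whereas QA thresholds act per orientation.
    """
    for name, m in (("fa", fa_map), ("gfa", gfa_map), ("anatomy", anatomy_mask)):
        if m is None:
            continue
        m = np.asarray(m, dtype=float)
        if m.shape != peaks.shape:
            raise ConfigurationError(
                f"{name} map shape {m.shape} does not match peak grid {peaks.shape}"
            )
        setattr(peaks, name, m)
    return peaks
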