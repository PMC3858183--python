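"""Generalized deterministic fiber tracking.

The tracker propagates a trajectory r(s) by Euler integration,

    r(s + ds) = r(s) + ds * u(r(s)),

where the propagation direction u(r) is a trilinear-weighted sum of fiber
orientations selected, per lattice voxel R of the cell containing r, by a
filtering-selection rule: a fiber qualifies if its termination index exceeds
the index threshold and its turning angle relative to the incoming direction
is below the angular threshold; among qualifiers the one with the smallest
turning angle wins, sign-flipped so it points along the trajectory.  The
track terminates when the summed trilinear weight of contributing voxels
falls below the termination weight (default 0.5) — i.e. when fewer than
"half a voxel" of qualifying fibers surrounds the point.

The termination index is pluggable: per-orientation QA, or any voxel-level
scalar (FA, GFA, anatomy label), which makes the algorithm a generalization
of classic streamline tracking; with nearest-neighbor weighting and an
infinitesimal step it reduces to FACT.

Coordinates: continuous voxel coordinates with integer values at voxel
centers; output streamlines are stored in mm (voxel coords * voxel size).
Direction vectors live in the image frame; the affine is assumed axis
aligned (scaling + translation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .peaks import VOXEL_LEVEL_INDICES, PeakMap
from .recon import ConfigurationError

__all__ = [
    "TrackingParams",
    "Streamline",
    "Tractogram",
    "RoiFilter",
    "trilinear_neighborhood",
    "select_fiber",
    "propagation_direction",
    "track_from_seed",
    "generate_tractography",
]


@dataclass(frozen=True)
class TrackingParams:
    """Parameters of the generalized deterministic tracker.

    angular_threshold : max turning angle between consecutive steps, degrees.
    index_threshold : termination-index threshold (no default — comparable
        values are scheme-dependent and must be calibrated).
    index_name : which index filters fibers: 'qa' (per-orientation) or the
        voxel-level 'fa' / 'gfa' / 'anatomy'.
    step_size : Euler step, mm (in-vivo protocol: half a voxel, 1.25 mm).
    min_length / max_length : accepted track length range, mm.
    termination_weight : minimum summed trilinear weight to continue (0.5).
    target_track_count : accepted streamlines to generate.
    seed_budget : max seeds tried before giving up (default 200x target).
    rng_seed : seed of the named generator (numpy PCG64) placing seeds.
    interpolation : 'trilinear' or 'nearest' (the FACT limit).
    init_direction : 'best' (highest qualifying index at seed) or 'random'.
    """

    index_threshold: float
    angular_threshold: float = 60.0
    index_name: str = "qa"
    step_size: float = 1.25
    min_length: float = 40.0
    max_length: float = 300.0
    termination_weight: float = 0.5
    target_track_count: int = 2000
    seed_budget: int | None = None
    rng_seed: int = 0
    interpolation: str = "trilinear"
    init_direction: str = "best"

    def __post_init__(self) -> None:
        if not 0 < self.angular_threshold <= 90:
            raise ConfigurationError("angular_threshold must be in (0, 90] degrees")
        if self.step_size <= 0:
            raise ConfigurationError("step_size must be positive")
        if not 0 < self.termination_weight <= 1:
            raise ConfigurationError("termination_weight must be in (0, 1]")
        if self.index_name not in ("qa",) + VOXEL_LEVEL_INDICES:
            raise ConfigurationError(f"unknown index_name {self.index_name!r}")
        if self.interpolation not in ("trilinear", "nearest"):
            raise ConfigurationError("interpolation must be 'trilinear' or 'nearest'")
        if self.min_length < 0 or self.max_length <= 0:
            raise ConfigurationError("track length bounds must be positive")

    @property
    def cos_angular(self) -> float:
        return float(np.cos(np.radians(self.angular_threshold)))


@dataclass
class Streamline:
    """An ordered polyline in mm coordinates with seed provenance."""

    points: np.ndarray  # (n, 3) mm
    seed_id: int = -1
    seed_point: np.ndarray | None = None  # voxel coords

    @property
    def length(self) -> float:
        if len(self.points) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class Tractogram:
    """A collection of streamlines with their spatial reference."""

    streamlines: list[Streamline]
    voxel_size: np.ndarray
    affine: np.ndarray
    params: TrackingParams | None = None
    warnings: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.streamlines)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([s.length for s in self.streamlines])


def trilinear_neighborhood(r: np.ndarray) -> np.ndarray:
    """The lattice voxels N(r) of the trilinear cell containing r.

    Returns the 8 corners {floor(c), floor(c)+1} per axis as an (8, 3) int
    array; e.g. r = (32.3, 12.4, 16.9) -> {32,33} x {12,13} x {16,17}.
    Corners lying on the zero-weight far planes (integer coordinates) are
    still listed; their trilinear weight is 0.
    """
    c0 = np.floor(np.asarray(r, dtype=float)).astype(np.int64)
    offs = np.array(
        [[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)], dtype=np.int64
    )
    return c0 + offs


def _trilinear_weights(r: np.ndarray, corners: np.ndarray) -> np.ndarray:
    """f(dr) = prod_c (1 - |dr_c|) for each corner."""
    d = np.abs(np.asarray(r, dtype=float) - corners)
    return np.prod(1.0 - d, axis=-1)


class _PeakGrid:
    """Flat, padded views of a PeakMap for fast gather during tracking."""

    def __init__(self, peaks: PeakMap, params: TrackingParams):
        self.shape = np.asarray(peaks.shape, dtype=np.int64)
        self.dirs = peaks.peak_dirs  # (X,Y,Z,P,3)
        self.qa = peaks.peak_qa
        self.has_peak = peaks.peak_vertex >= 0
        if params.index_name == "qa":
            self.index = self.qa
        else:
            vox = peaks.index_map(params.index_name)
            self.index = np.broadcast_to(
                np.nan_to_num(vox, nan=-np.inf)[..., None], self.qa.shape
            )
        self.cos_thr = params.cos_angular
        self.thr = params.index_threshold

    def in_bounds(self, voxels: np.ndarray) -> np.ndarray:
        return np.all((voxels >= 0) & (voxels < self.shape), axis=-1)

    def best_fibers(
        self, voxels: np.ndarray, u: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per voxel row: the sign-corrected qualifying fiber closest in
        angle to u (ties -> larger QA), plus a validity mask."""
        inb = self.in_bounds(voxels)
        vi = np.clip(voxels, 0, self.shape - 1)
        ix, iy, iz = vi[:, 0], vi[:, 1], vi[:, 2]
        dirs = self.dirs[ix, iy, iz]  # (n, P, 3)
        dots = dirs @ u  # (n, P)
        adots = np.abs(dots)
        ok = (
            inb[:, None]
            & self.has_peak[ix, iy, iz]
            & (self.index[ix, iy, iz] > self.thr)
            & (adots > self.cos_thr)
        )
        cand = np.where(ok, adots, -1.0)
        best = cand.max(axis=1, keepdims=True)
        tie = ok & (cand >= best) & (best >= 0)
        qa_tie = np.where(tie, self.qa[ix, iy, iz], -1.0)
        j = np.argmax(qa_tie, axis=1)
        rows = np.arange(len(vi))
        valid = ok[rows, j]
        chosen = dirs[rows, j] * np.where(dots[rows, j] >= 0, 1.0, -1.0)[:, None]
        return np.where(valid[:, None], chosen, 0.0), valid


def select_fiber(
    voxel: np.ndarray, u: np.ndarray, peaks: PeakMap, params: TrackingParams
) -> np.ndarray | None:
    """Filtering-selection at one voxel.

    Among the voxel's fibers a with index > threshold and |<u, a>| >
    cos(angular threshold), return delta(u, a) * a for the fiber maximizing
    |<u, a>| (delta = +1 if <u, a> >= 0 else -1, so the result points along
    the trajectory).  Ties in angle break toward larger QA.  Returns None if
    no fiber qualifies — a valid outcome marking termination territory.
    """
    grid = _PeakGrid(peaks, params)
    v = np.asarray(voxel, dtype=np.int64).reshape(1, 3)
    chosen, valid = grid.best_fibers(v, np.asarray(u, dtype=float))
    return chosen[0] if valid[0] else None


def propagation_direction(
    r: np.ndarray, u: np.ndarray, peaks: PeakMap, params: TrackingParams
) -> tuple[np.ndarray | None, float]:
    """Estimate u(r) = Z * sum_{R in N(r)} w(r - R) v(R) and its total weight.

    Returns (direction, w).  The direction is None when w falls below the
    termination weight (the track must stop), including when r is outside
    the grid (w = 0).  With 'nearest' interpolation N(r) collapses to the
    nearest voxel with weight 1 — the FACT limit of the algorithm.
    """
    grid = _PeakGrid(peaks, params)
    return _propagate(grid, np.asarray(r, float), np.asarray(u, float), params)


def _propagate(
    grid: _PeakGrid, r: np.ndarray, u: np.ndarray, params: TrackingParams
) -> tuple[np.ndarray | None, float]:
    if params.interpolation == "nearest":
        vox = np.round(r).astype(np.int64).reshape(1, 3)
        chosen, valid = grid.best_fibers(vox, u)
        w = 1.0 if valid[0] else 0.0
        if w < params.termination_weight:
            return None, w
        return chosen[0], w

    corners = trilinear_neighborhood(r)
    weights = _trilinear_weights(r, corners)
    chosen, valid = grid.best_fibers(corners, u)
    w = float(weights[valid].sum())
    if w < params.termination_weight:
        return None, w
    vsum = (weights[:, None] * chosen).sum(axis=0)
    norm = np.linalg.norm(vsum)
    if norm == 0.0:  # opposing fibers cancelled exactly
        return None, w
    return vsum / norm, w


def _half_track(
    grid: _PeakGrid,
    seed: np.ndarray,
    u0: np.ndarray,
    params: TrackingParams,
    voxel_size: np.ndarray,
) -> list[np.ndarray]:
    """Euler propagation from seed along u0 until termination; returns the
    visited voxel-coordinate list (seed included)."""
    step_vox = params.step_size / voxel_size
    max_steps = int(np.ceil(params.max_length / params.step_size)) + 1
    pts = [np.asarray(seed, dtype=float)]
    u = np.asarray(u0, dtype=float)
    r = pts[0]
    for _ in range(max_steps):
        u_new, _ = _propagate(grid, r, u, params)
        if u_new is None:
            break
        r = r + step_vox * u_new
        pts.append(r)
        u = u_new
    return pts


def track_from_seed(
    seed: np.ndarray,
    init_dir: np.ndarray,
    peaks: PeakMap,
    params: TrackingParams,
    _grid: _PeakGrid | None = None,
) -> Streamline | None:
    """Bidirectional tracking from one seed.

    Propagates along ``init_dir``, then again along ``-init_dir``, and
    concatenates the two half-tracks sharing the seed point once.  Returns
    None when the combined length is below ``min_length``.
    """
    grid = _grid if _grid is not None else _PeakGrid(peaks, params)
    voxel_size = np.asarray(peaks.voxel_size, dtype=float)
    fwd = _half_track(grid, seed, init_dir, params, voxel_size)
    bwd = _half_track(grid, seed, -np.asarray(init_dir, float), params, voxel_size)
    pts = bwd[::-1] + fwd[1:]
    length = params.step_size * (len(pts) - 1)
    if length < params.min_length:
        return None
    mm = np.asarray(pts) * voxel_size
    if peaks.affine is not None:
        mm = mm + peaks.affine[:3, 3]
    return Streamline(points=mm, seed_point=np.asarray(seed, float))


@dataclass(frozen=True)
class RoiFilter:
    """Spherical region-of-interest filter in mm coordinates.

    mode 'pass': the track must have at least one point inside the sphere;
    mode 'select-endpoints': at least one endpoint must lie inside.
    """

    center: np.ndarray
    radius: float
    mode: str = "pass"

    def accepts(self, streamline: Streamline) -> bool:
        pts = streamline.points
        if self.mode == "select-endpoints":
            pts = pts[[0, -1]]
        elif self.mode != "pass":
            raise ConfigurationError(f"unknown ROI mode {self.mode!r}")
        d = np.linalg.norm(pts - np.asarray(self.center, float), axis=1)
        return bool((d <= self.radius).any())


def _initial_direction(
    grid: _PeakGrid,
    voxel: np.ndarray,
    params: TrackingParams,
    rng: np.random.Generator,
) -> np.ndarray | None:
    vi = voxel.reshape(1, 3)
    if not grid.in_bounds(vi)[0]:
        return None
    ix, iy, iz = voxel
    qualifying = grid.has_peak[ix, iy, iz] & (grid.index[ix, iy, iz] > grid.thr)
    if not qualifying.any():
        return None
    if params.init_direction == "random":
        j = rng.choice(np.flatnonzero(qualifying))
    else:
        idx = np.where(qualifying, grid.index[ix, iy, iz], -np.inf)
        # voxel-level indices tie across fibers; break by QA
        j = np.argmax(np.where(idx >= idx.max(), grid.qa[ix, iy, iz], -np.inf))
    return grid.dirs[ix, iy, iz, j]


def generate_tractography(
    peaks: PeakMap,
    params: TrackingParams,
    seed_region: np.ndarray | None = None,
    roi_filters: tuple[RoiFilter, ...] = (),
) -> Tractogram:
    """Seed-and-track until the target count of accepted streamlines.

    Seeds are drawn by a seeded generator: a uniformly random voxel of the
    seed region (whole grid if None) plus a uniform sub-voxel offset — a
    deterministically random sequence, so identical seeds give bitwise
    identical tractograms.  The initial direction is the seed voxel's
    qualifying peak with the highest index value (configurable to a random
    qualifying peak).  Tracks shorter than ``min_length`` or failing an ROI
    filter are rejected.  If the seed budget runs out first, the partial
    tractogram carries a warning record.
    """
    grid = _PeakGrid(peaks, params)
    if seed_region is None:
        seed_voxels = np.argwhere(grid.has_peak.any(axis=-1))
    else:
        seed_region = np.asarray(seed_region, dtype=bool)
        if seed_region.shape != peaks.shape:
            raise ConfigurationError("seed_region shape does not match peak grid")
        seed_voxels = np.argwhere(seed_region)
    if len(seed_voxels) == 0:
        raise ConfigurationError("seed region contains no voxels")

    rng = np.random.default_rng(params.rng_seed)
    budget = params.seed_budget or 200 * params.target_track_count
    accepted: list[Streamline] = []
    tried = 0
    while len(accepted) < params.target_track_count and tried < budget:
        tried += 1
        voxel = seed_voxels[rng.integers(len(seed_voxels))]
        offset = rng.uniform(-0.5, 0.5, 3)
        u0 = _initial_direction(grid, voxel, params, rng)
        if u0 is None:
            continue
        seed = voxel + offset
        sl = track_from_seed(seed, u0, peaks, params, _grid=grid)
        if sl is None:
            continue
        if not all(f.accepts(sl) for f in roi_filters):
            continue
        sl.seed_id = len(accepted)
        accepted.append(sl)

    warn: list[str] = []
    if len(accepted) < params.target_track_count:
        warn.append(
            f"seed budget ({budget}) exhausted after {len(accepted)} of "
            f"{params.target_track_count} requested tracks"
        )
    return Tractogram(
        streamlines=accepted,
        voxel_size=np.asarray(peaks.voxel_size, float),
        affine=np.asarray(peaks.affine, float),
        params=params,
        warnings=warn,
        meta={"rng_seed": params.rng_seed, "seeds_tried": tried},
    )
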