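"""Synthetic multi-compartment DWI phantoms.

Two layouts emulate the physical phantoms used to characterize QA:

* a 90-degree two-bundle crossing immersed in free water with non-diffusive
  inserts, exposing three partial-volume conditions per voxel label —
  (a) fiber/free-water, (b) fiber crossing, (c) fiber/non-diffusive;
* a "spindle" of concentric ring strands of decreasing fiber volume
  fraction embedded in an isotropic gel, which probes the spatial
  resolution of index-aided tracking.

Each fiber compartment is an axially symmetric Gaussian tensor; free water
is isotropic; non-diffusive material contributes no signal at any b-value
(capillary walls / plastic).  Rician noise is applied as the magnitude of a
complex Gaussian perturbation, with SNR defined on the b=0 signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .recon import FREE_WATER_DIFFUSIVITY, ConfigurationError, DWIDataset

__all__ = [
    "PhantomSpec",
    "simulate_signal",
    "make_crossing_phantom",
    "make_spindle_phantom",
    "fibonacci_directions",
    "shell_btable",
    "grid_btable",
]

#: Default fiber compartment diffusivities, mm^2/s (typical packed-axon values).
AXIAL_DIFFUSIVITY = 1.7e-3
RADIAL_DIFFUSIVITY = 0.2e-3


def fibonacci_directions(n: int) -> np.ndarray:
    """n roughly uniform unit vectors on the hemisphere (spherical Fibonacci).

    Deterministic; used as a stand-in for the scanners' gradient tables.
    """
    i = np.arange(n) + 0.5
    z = i / n  # hemisphere: z in (0, 1)
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    r = np.sqrt(1.0 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shell_btable(
    n_directions: int = 160, bvalue: float = 4000.0, n_b0: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Single-shell b-table: ``n_b0`` unweighted volumes then the shell."""
    dirs = fibonacci_directions(n_directions)
    bvals = np.r_[np.zeros(n_b0), np.full(n_directions, float(bvalue))]
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    return bvals, bvecs


def grid_btable(bmax: float = 4000.0, radius2: int = 13) -> tuple[np.ndarray, np.ndarray]:
    """Cartesian q-space grid (DSI-style), b_i = bmax * |q|^2 / radius2.

    The default ``radius2`` = 13 yields 203 sampling points (202 grid points
    plus the b=0 origin), mirroring the common 203-point grid scheme.
    """
    rng = int(np.floor(np.sqrt(radius2)))
    pts = [
        (x, y, z, x * x + y * y + z * z)
        for x in range(-rng, rng + 1)
        for y in range(-rng, rng + 1)
        for z in range(-rng, rng + 1)
        if 0 < x * x + y * y + z * z <= radius2
    ]
    q = np.array([(x, y, z) for x, y, z, _ in pts], dtype=float)
    n2 = np.array([p[3] for p in pts], dtype=float)
    bvals = np.r_[0.0, bmax * n2 / radius2]
    bvecs = np.vstack([[0.0, 0.0, 0.0], q / np.linalg.norm(q, axis=1, keepdims=True)])
    return bvals, bvecs


@dataclass
class PhantomSpec:
    """Ground-truth description of a synthetic phantom.

    Per-voxel compartments: up to ``n_comp`` fiber populations with unit
    orientations and volume fractions, plus free-water and non-diffusive
    fractions.  Fractions may sum to less than 1 (the remainder is signal
    void).  ``labels`` maps region names to boolean voxel masks; ``meta``
    carries construction details (strand centerlines, radii...).
    """

    shape: tuple[int, int, int]
    voxel_size: np.ndarray
    fiber_dirs: np.ndarray  # (X, Y, Z, n_comp, 3)
    fiber_fracs: np.ndarray  # (X, Y, Z, n_comp)
    water_frac: np.ndarray  # (X, Y, Z)
    solid_frac: np.ndarray  # (X, Y, Z)
    bvals: np.ndarray
    bvecs: np.ndarray
    s0: float = 1.0
    snr: float = 30.0
    rng_seed: int = 0
    axial_diffusivity: float = AXIAL_DIFFUSIVITY
    radial_diffusivity: float = RADIAL_DIFFUSIVITY
    water_diffusivity: float = FREE_WATER_DIFFUSIVITY
    labels: dict[str, np.ndarray] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        fr = self.fiber_fracs
        total = fr.sum(axis=-1) + self.water_frac + self.solid_frac
        if np.any(fr < 0) or np.any(self.water_frac < 0) or np.any(self.solid_frac < 0):
            raise ConfigurationError("volume fractions must be non-negative")
        if np.any(total > 1.0 + 1e-9):
            raise ConfigurationError("per-voxel volume fractions must sum to <= 1")
        if self.snr <= 0:
            raise ConfigurationError("snr must be positive")

    def region(self, name: str) -> np.ndarray:
        return self.labels[name]


def simulate_signal(spec: PhantomSpec, noiseless: bool = False) -> DWIDataset:
    """Simulate the DWI signal of a phantom.

    Noiseless per-voxel signal:

        S(b, g) = S0 * [ sum_k f_k exp(-b g' D_k g)
                         + f_water exp(-b D_water) ]         (solid adds 0)

    Rician noise (two seeded Gaussian channels of sigma = S0 / SNR) is then
    applied unless ``noiseless``.
    """
    b = spec.bvals
    g = spec.bvecs
    dirs = spec.fiber_dirs.reshape(-1, spec.fiber_dirs.shape[-2], 3)
    fracs = spec.fiber_fracs.reshape(-1, spec.fiber_fracs.shape[-1])

    # g' D g = lambda_perp + (lambda_par - lambda_perp) <g, e>^2
    dot2 = np.einsum("nj,vkj->vnk", g, dirs) ** 2  # (V, N, K)
    adc = spec.radial_diffusivity + (
        spec.axial_diffusivity - spec.radial_diffusivity
    ) * dot2
    fiber_sig = np.einsum("vk,vnk->vn", fracs, np.exp(-b[None, :, None] * adc))
    water_sig = spec.water_frac.reshape(-1, 1) * np.exp(-b * spec.water_diffusivity)

    signal = spec.s0 * (fiber_sig + water_sig)
    if not noiseless:
        rng = np.random.default_rng(spec.rng_seed)
        sigma = spec.s0 / spec.snr
        n1 = rng.normal(0.0, sigma, signal.shape)
        n2 = rng.normal(0.0, sigma, signal.shape)
        signal = np.sqrt((signal + n1) ** 2 + n2**2)

    signal = signal.reshape(spec.shape + (len(b),))
    return DWIDataset(
        signal=signal,
        bvals=b,
        bvecs=g,
        voxel_size=spec.voxel_size,
        mask=np.ones(spec.shape, dtype=bool),
    )


def _empty_geometry(shape: tuple[int, int, int], n_comp: int):
    dirs = np.zeros(shape + (n_comp, 3))
    fracs = np.zeros(shape + (n_comp,))
    water = np.zeros(shape)
    solid = np.zeros(shape)
    return dirs, fracs, water, solid


def make_crossing_phantom(
    crossing_angle: float = 90.0,
    shape: tuple[int, int, int] = (20, 20, 3),
    voxel_size: float = 2.5,
    bundle_fraction: float = 0.5,
    snr: float = 30.0,
    rng_seed: int = 0,
    bvalue: float = 4000.0,
    n_directions: int = 160,
) -> PhantomSpec:
    """Two crossing capillary bundles in a water bath with solid inserts.

    A horizontal bundle (along +x) and a second bundle rotated in-plane by
    ``crossing_angle`` (default 90 degrees, along +y) intersect at the grid
    center.  Outside the crossing, bundle voxels mix fiber with non-diffusive
    capillary-wall material (condition c); where a bundle meets the bath its
    edge voxels mix fiber with free water (condition a); the intersection
    mixes the two fiber populations (condition b).  Solid insert blocks sit
    in the bath corners.  Labels: ``fiber_water`` (a), ``crossing`` (b),
    ``fiber_solid`` (c), ``water``, ``solid``; the three fiber-bearing labels
    partition the bundle voxels.
    """
    if not 0 < crossing_angle <= 90:
        raise ConfigurationError("crossing_angle must be in (0, 90] degrees")
    nx, ny, nz = shape
    dirs, fracs, water, solid = _empty_geometry(shape, 2)

    th = np.radians(crossing_angle)
    e1 = np.array([1.0, 0.0, 0.0])
    e2 = np.array([np.cos(th), np.sin(th), 0.0])

    bw = 4  # bundle width in voxels
    lo, hi = ny // 2 - bw // 2, ny // 2 + bw // 2  # rows/cols of the bundles
    h_band = np.zeros(shape, dtype=bool)
    v_band = np.zeros(shape, dtype=bool)
    h_band[:, lo:hi, :] = True
    v_band[lo:hi, :, :] = True

    cross = h_band & v_band
    h_only = h_band & ~v_band
    v_only = v_band & ~h_band

    # condition (a): bundle end voxels facing the water bath
    edge = np.zeros(shape, dtype=bool)
    edge[[0, -1], lo:hi, :] = True  # horizontal bundle ends
    edge[lo:hi, [0, -1], :] = True  # second bundle ends
    edge &= h_band | v_band

    f = bundle_fraction
    # horizontal fibers
    sel = h_only | cross
    dirs[sel, 0] = e1
    fracs[sel, 0] = f
    # second bundle
    sel = v_only | cross
    dirs[sel, 1] = e2
    fracs[sel, 1] = f

    single = (h_only | v_only) & ~edge
    solid[single] = 1.0 - f  # capillary walls (condition c)
    water[(h_only | v_only) & edge] = 1.0 - f  # condition a
    bath = ~(h_band | v_band)
    water[bath] = 1.0

    # pure non-diffusive inserts in two bath corners
    ins = np.zeros(shape, dtype=bool)
    ins[1:4, 1:4, :] = True
    ins[-4:-1, -4:-1, :] = True
    ins &= bath
    water[ins] = 0.0
    solid[ins] = 1.0

    labels = {
        "fiber_water": (h_only | v_only) & edge,
        "crossing": cross,
        "fiber_solid": single,
        "water": bath & ~ins,
        "solid": ins,
    }
    bvals, bvecs = shell_btable(n_directions, bvalue, n_b0=1)
    return PhantomSpec(
        shape=shape,
        voxel_size=np.full(3, float(voxel_size)),
        fiber_dirs=dirs,
        fiber_fracs=fracs,
        water_frac=water,
        solid_frac=solid,
        bvals=bvals,
        bvecs=bvecs,
        snr=snr,
        rng_seed=rng_seed,
        labels=labels,
        meta={"crossing_angle": crossing_angle, "bundle_fraction": bundle_fraction},
    )


def make_spindle_phantom(
    n_strands: int = 6,
    fraction_ladder: tuple[float, ...] = (0.9, 0.75, 0.6, 0.45, 0.3, 0.15),
    shape: tuple[int, int, int] = (44, 44, 5),
    voxel_size: float = 2.5,
    snr: float = 20.0,
    rng_seed: int = 0,
    bvalue: float = 1000.0,
    n_directions: int = 180,
    n_b0: int = 20,
) -> PhantomSpec:
    """Concentric ring strands of decreasing fiber fraction in a gel bath.

    Strand k (k = 0 outermost/largest) is an annulus of in-plane radius
    ``R_k`` and ~2-voxel thickness spanning the middle z slices, with fiber
    orientation tangent to the ring and fiber fraction ``fraction_ladder[k]``
    (the remainder of the voxel is gel that seeps into the groove).
    Decreasing fraction emulates the physical spindle's decreasing groove
    sizes.  The spindle body between and inside the strands is non-diffusive
    plastic — a signal void where ratio-based indices like FA reduce to pure
    noise while spin-density-scaled QA stays near zero; the bath outside the
    body is isotropic gel.  Adjacent strands are separated by at least one
    non-strand voxel.  Labels: ``strand_0`` ... and their union ``strands``,
    plus ``body`` (plastic) and ``gel``; ``meta['centerlines']`` holds each
    ring's polyline in voxel coordinates, ``meta['radii']`` the ring radii
    in voxels.
    """
    ladder = tuple(float(x) for x in fraction_ladder)
    if len(ladder) != n_strands:
        raise ConfigurationError("fraction_ladder length must equal n_strands")
    if any(not 0 < x <= 1 for x in ladder) or any(
        a <= b for a, b in zip(ladder, ladder[1:])
    ):
        raise ConfigurationError("fraction_ladder must be strictly decreasing in (0, 1]")

    nx, ny, nz = shape
    dirs, fracs, water, solid = _empty_geometry(shape, 1)
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0

    r_out = min(cx, cy) - 2.0
    radii = np.linspace(r_out, 5.0, n_strands)
    half_thick = 0.9  # annulus half-thickness in voxels
    z_lo, z_hi = 1, nz - 1  # strands span the middle slices

    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    rho = np.sqrt((ix - cx) ** 2 + (iy - cy) ** 2)

    labels: dict[str, np.ndarray] = {}
    centerlines = []
    for k, (rk, frac) in enumerate(zip(radii, ladder)):
        ring2d = np.abs(rho - rk) <= half_thick
        mask = np.zeros(shape, dtype=bool)
        mask[:, :, z_lo:z_hi] = ring2d[:, :, None]
        # tangent orientation: (-sin, cos, 0) of the polar angle
        ang = np.arctan2(iy - cy, ix - cx)
        tangent = np.stack([-np.sin(ang), np.cos(ang), np.zeros_like(ang)], axis=-1)
        dirs[mask, 0] = np.broadcast_to(tangent[:, :, None, :], shape + (3,))[mask]
        fracs[mask, 0] = frac
        water[mask] = 1.0 - frac
        labels[f"strand_{k}"] = mask
        t = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        centerlines.append(
            np.column_stack(
                [cx + rk * np.cos(t), cy + rk * np.sin(t), np.full_like(t, (nz - 1) / 2)]
            )
        )

    strands = np.zeros(shape, dtype=bool)
    for k in range(n_strands):
        strands |= labels[f"strand_{k}"]

    # plastic spindle body: everything inside the outer strand radius that is
    # not a groove, over the strand z-span
    body = np.zeros(shape, dtype=bool)
    body[:, :, z_lo:z_hi] = (rho <= r_out + half_thick)[:, :, None]
    body &= ~strands
    solid[body] = 1.0
    gel = ~strands & ~body
    water[gel] = 1.0  # gel background modeled as free water
    labels["strands"] = strands
    labels["body"] = body
    labels["gel"] = gel

    bvals, bvecs = shell_btable(n_directions, bvalue, n_b0=n_b0)
    return PhantomSpec(
        shape=shape,
        voxel_size=np.full(3, float(voxel_size)),
        fiber_dirs=dirs,
        fiber_fracs=fracs,
        water_frac=water,
        solid_frac=solid,
        bvals=bvals,
        bvecs=bvecs,
        snr=snr,
        rng_seed=rng_seed,
        labels=labels,
        meta={"radii": radii, "centerlines": centerlines, "ladder": ladder},
    )
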