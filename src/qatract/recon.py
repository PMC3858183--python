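"""Per-voxel diffusion model reconstruction.

Three reconstructions feed the tracker's termination indices:

* diffusion tensor fit -> fractional anisotropy (FA), a voxel-level ratio;
* generalized q-sampling imaging (GQI) -> spin distribution functions (SDFs),
  whose per-peak amplitudes yield quantitative anisotropy (QA);
* analytic q-ball imaging -> ODFs -> generalized fractional anisotropy (GFA).

The SDF at unit direction u is the sinc-kernel transform of the signal,

    psi(u) = sum_i S_i * sinc(sigma * sqrt(6 * D * b_i) * <g_i, u>),

with sinc(x) = sin(x)/x, sigma the diffusion sampling length ratio
(default 1.25) and D a fixed free-water diffusivity.  Unlike min-max scaled
ODFs, psi scales with spin density, which is what makes QA robust to partial
volume effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import eval_legendre, sph_harm_y

from .sphere import SphereTessellation

__all__ = [
    "ConfigurationError",
    "DWIDataset",
    "TensorVolume",
    "SDFVolume",
    "ODFVolume",
    "FREE_WATER_DIFFUSIVITY",
    "fa_from_eigenvalues",
    "gfa_from_samples",
    "fit_dti",
    "gqi_sdf",
    "qball_gfa",
]

#: Free-water diffusivity at body temperature, mm^2/s. Used both by the GQI
#: kernel and as the default water compartment in phantoms; its absolute value
#: is largely absorbed by the Z0 normalization of QA.
FREE_WATER_DIFFUSIVITY = 2.5e-3

_B0_THRESHOLD = 50.0  # s/mm^2; acquisitions below this count as b=0


class ConfigurationError(ValueError):
    """Invalid input data or parameters (b-table mismatches, missing b0...)."""


@dataclass
class DWIDataset:
    """A diffusion-weighted acquisition: 4-D signal grid plus b-table.

    ``signal`` has shape (X, Y, Z, N) with one volume per b-table entry;
    ``bvecs`` are unit vectors in the image frame (zero vectors for b=0).
    """

    signal: np.ndarray
    bvals: np.ndarray
    bvecs: np.ndarray
    voxel_size: np.ndarray
    mask: np.ndarray | None = None
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        self.bvals = np.asarray(self.bvals, dtype=np.float64).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=np.float64)
        self.voxel_size = np.asarray(self.voxel_size, dtype=np.float64).ravel()
        if self.signal.ndim != 4:
            raise ConfigurationError("signal must be 4-D (x, y, z, acquisition)")
        n = self.signal.shape[3]
        if len(self.bvals) != n or self.bvecs.shape != (n, 3):
            raise ConfigurationError(
                f"b-table length mismatch: {n} volumes, "
                f"{len(self.bvals)} b-values, {self.bvecs.shape[0]} b-vectors"
            )
        if not np.all(np.isfinite(self.signal)):
            raise ConfigurationError("signal contains non-finite values")
        if not np.any(self.b0_mask):
            raise ConfigurationError("at least one b=0 acquisition is required")
        if self.voxel_size.shape != (3,) or np.any(self.voxel_size <= 0):
            raise ConfigurationError("voxel_size must be three positive lengths")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.signal.shape[:3]:
                raise ConfigurationError("mask shape does not match signal grid")
        if self.affine is None:
            self.affine = np.diag(np.r_[self.voxel_size, 1.0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals < _B0_THRESHOLD

    def mean_b0(self) -> np.ndarray:
        """Average of all b=0 volumes, shape (X, Y, Z)."""
        return self.signal[..., self.b0_mask].mean(axis=-1)

    def grid_mask(self) -> np.ndarray:
        """The analysis mask (all-true if none was supplied)."""
        if self.mask is not None:
            return self.mask
        return np.ones(self.shape, dtype=bool)


@dataclass
class TensorVolume:
    """Per-voxel diffusion tensor with eigen-decomposition and FA map.

    ``evals`` are sorted descending; FA is NaN where the fit is undefined
    (outside the mask or non-positive b0 signal).
    """

    tensor: np.ndarray  # (X, Y, Z, 3, 3)
    evals: np.ndarray  # (X, Y, Z, 3)
    evecs: np.ndarray  # (X, Y, Z, 3, 3), columns match evals
    fa: np.ndarray  # (X, Y, Z)

    @property
    def principal_direction(self) -> np.ndarray:
        return self.evecs[..., :, 0]


@dataclass
class SDFVolume:
    """Spin distribution functions sampled on a tessellation hemisphere."""

    psi: np.ndarray  # (X, Y, Z, n_hemisphere)
    iso: np.ndarray  # (X, Y, Z): per-voxel min of psi
    sampling_length_ratio: float
    tessellation: SphereTessellation
    z0: float | None = None
    mask: np.ndarray | None = None
    voxel_size: np.ndarray | None = None
    affine: np.ndarray | None = None


@dataclass
class ODFVolume:
    """q-ball ODF samples and the derived GFA map."""

    odf: np.ndarray  # (X, Y, Z, n_hemisphere)
    gfa: np.ndarray  # (X, Y, Z)
    sh_order: int
    tessellation: SphereTessellation
    warnings: list[str] = field(default_factory=list)


def fa_from_eigenvalues(evals: np.ndarray) -> np.ndarray:
    """FA = sqrt(3/2 * sum((l_i - lbar)^2) / sum(l_i^2)) over the last axis.

    Zero tensors give FA = 0.
    """
    evals = np.asarray(evals, dtype=np.float64)
    mean = evals.mean(axis=-1, keepdims=True)
    num = ((evals - mean) ** 2).sum(axis=-1)
    den = (evals**2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)
    return np.where(den > 0, fa, 0.0)


def gfa_from_samples(samples: np.ndarray) -> np.ndarray:
    """GFA = sqrt(n * sum((p_i - pbar)^2) / ((n - 1) * sum(p_i^2))).

    ``samples`` are ODF values over the hemisphere directions (last axis).
    Constant ODFs give 0; an all-zero ODF gives 0 by convention.
    """
    samples = np.asarray(samples, dtype=np.float64)
    n = samples.shape[-1]
    mean = samples.mean(axis=-1, keepdims=True)
    num = n * ((samples - mean) ** 2).sum(axis=-1)
    den = (n - 1) * (samples**2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        gfa = np.sqrt(num / den)
    return np.where(den > 0, gfa, 0.0)


def _dti_design(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    g = bvecs
    b = bvals
    return np.column_stack(
        [
            np.ones_like(b),
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
        ]
    )


def fit_dti(dwi: DWIDataset) -> TensorVolume:
    """Weighted least-squares log-linear tensor fit.

    An ordinary LS fit of log(S) seeds one weighted refinement with the
    squared predicted signals as weights (the standard WLS scheme).  Negative
    eigenvalues are clipped to zero before FA so FA stays in [0, 1].
    """
    nonzero = ~dwi.b0_mask
    if nonzero.sum() < 6 or dwi.signal.shape[3] < 7:
        raise ConfigurationError(
            "tensor fit needs at least 6 diffusion-weighted directions "
            "plus one b=0 volume"
        )
    X = _dti_design(dwi.bvals, dwi.bvecs)  # (N, 7)
    shape = dwi.shape
    mask = dwi.grid_mask() & (dwi.mean_b0() > 0)

    s = dwi.signal[mask]  # (V, N)
    logs = np.log(np.clip(s, 1e-10, None))

    # OLS seed (shared design -> one solve), then one WLS pass per voxel
    # batched through einsum normal equations.
    beta = np.linalg.lstsq(X, logs.T, rcond=None)[0].T  # (V, 7)
    w = np.exp(X @ beta.T).T ** 2  # (V, N) predicted-signal^2 weights
    xtwx = np.einsum("ni,vn,nj->vij", X, w, X)
    xtwy = np.einsum("ni,vn,vn->vi", X, w, logs)
    beta = np.linalg.solve(xtwx, xtwy[..., None])[..., 0]

    dt = np.zeros(beta.shape[:1] + (3, 3))
    dt[:, 0, 0] = beta[:, 1]
    dt[:, 1, 1] = beta[:, 2]
    dt[:, 2, 2] = beta[:, 3]
    dt[:, 0, 1] = dt[:, 1, 0] = beta[:, 4]
    dt[:, 0, 2] = dt[:, 2, 0] = beta[:, 5]
    dt[:, 1, 2] = dt[:, 2, 1] = beta[:, 6]

    evals, evecs = np.linalg.eigh(dt)  # ascending
    evals = evals[:, ::-1]
    evecs = evecs[:, :, ::-1]
    fa = fa_from_eigenvalues(np.clip(evals, 0.0, None))

    full = lambda last, fill: np.full(shape + last, fill)  # noqa: E731
    tensor_v = full((3, 3), np.nan)
    evals_v = full((3,), np.nan)
    evecs_v = full((3, 3), np.nan)
    fa_v = full((), np.nan)
    tensor_v[mask] = dt
    evals_v[mask] = evals
    evecs_v[mask] = evecs
    fa_v[mask] = fa
    return TensorVolume(tensor=tensor_v, evals=evals_v, evecs=evecs_v, fa=fa_v)


def gqi_kernel(
    bvals: np.ndarray,
    bvecs: np.ndarray,
    directions: np.ndarray,
    sampling_length_ratio: float = 1.25,
    diffusivity: float = FREE_WATER_DIFFUSIVITY,
) -> np.ndarray:
    """GQI sinc kernel, shape (n_acquisitions, n_directions)."""
    q = sampling_length_ratio * np.sqrt(6.0 * diffusivity * np.asarray(bvals))
    x = q[:, None] * (np.asarray(bvecs) @ np.asarray(directions).T)
    return np.sinc(x / np.pi)  # numpy sinc is sin(pi x)/(pi x)


def gqi_sdf(
    dwi: DWIDataset,
    tess: SphereTessellation,
    sampling_length_ratio: float = 1.25,
    diffusivity: float = FREE_WATER_DIFFUSIVITY,
) -> SDFVolume:
    """Reconstruct spin distribution functions by generalized q-sampling.

    psi is evaluated on the tessellation's hemisphere representatives (SDFs
    are antipodally symmetric).  The transform is linear in the signal, so
    psi scales with spin density; negative ringing is clipped at zero.  The
    isotropic background iso(psi) is the per-voxel minimum sample.
    """
    if sampling_length_ratio <= 0:
        raise ConfigurationError("sampling_length_ratio must be positive")
    K = gqi_kernel(
        dwi.bvals, dwi.bvecs, tess.hemisphere_vertices,
        sampling_length_ratio, diffusivity,
    )
    mask = dwi.grid_mask()
    psi = np.zeros(dwi.shape + (K.shape[1],))
    psi[mask] = np.clip(dwi.signal[mask] @ K, 0.0, None)
    iso = psi.min(axis=-1)
    return SDFVolume(
        psi=psi,
        iso=iso,
        sampling_length_ratio=float(sampling_length_ratio),
        tessellation=tess,
        mask=mask,
        voxel_size=dwi.voxel_size,
        affine=dwi.affine,
    )


def _sph_coords(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    v = np.asarray(v, dtype=float)
    theta = np.arccos(np.clip(v[:, 2], -1.0, 1.0))  # polar
    phi = np.arctan2(v[:, 1], v[:, 0])  # azimuth
    return theta, phi


def real_sh_basis(order: int, directions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Real, symmetric (even-degree) spherical-harmonic basis.

    Returns (B, degrees): B has shape (n_dirs, n_coef) with columns ordered
    (l, m) = (0,0), (2,-2)...(2,2), (4,-4)... ; ``degrees`` lists l per
    column.  Convention: m < 0 -> sqrt(2) * (-1)^m * Im(Y_l^|m|), m = 0 ->
    Y_l^0, m > 0 -> sqrt(2) * (-1)^m * Re(Y_l^m).
    """
    theta, phi = _sph_coords(directions)
    cols, degs = [], []
    for l in range(0, order + 1, 2):
        for m in range(-l, l + 1):
            y = sph_harm_y(l, abs(m), theta, phi)
            if m < 0:
                c = np.sqrt(2.0) * (-1) ** m * y.imag
            elif m == 0:
                c = y.real
            else:
                c = np.sqrt(2.0) * (-1) ** m * y.real
            cols.append(c)
            degs.append(l)
    return np.column_stack(cols), np.asarray(degs)


def _find_shell(bvals: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Indices of the (outermost) non-zero shell; warns on grid data."""
    notes: list[str] = []
    nz = bvals[bvals >= _B0_THRESHOLD]
    if nz.size == 0:
        raise ConfigurationError("no diffusion-weighted shell found in b-table")
    bmax = nz.max()
    # shell = acquisitions within 10% of a common b-value
    shells = []
    remaining = np.unique(np.round(nz, 1))
    used = np.zeros_like(remaining, dtype=bool)
    for b in remaining:
        if not used[remaining == b].any():
            grp = np.abs(remaining - b) <= 0.1 * max(b, 1.0)
            used |= grp
            shells.append(b)
    if len(shells) > 1:
        notes.append(
            f"b-table contains {len(shells)} distinct b-values (grid scheme); "
            f"using the outermost shell at b={bmax:.0f}"
        )
    sel = np.abs(bvals - bmax) <= 0.1 * bmax
    if sel.sum() < 6:
        raise ConfigurationError("outermost shell has fewer than 6 directions")
    return np.flatnonzero(sel), notes


def qball_gfa(
    dwi: DWIDataset,
    tess: SphereTessellation,
    sh_order: int = 8,
    smooth: float = 0.006,
) -> ODFVolume:
    """Analytic q-ball ODFs via the spherical-harmonic Funk-Radon transform.

    The single-shell signal is fit with an even real SH basis under
    Laplace-Beltrami regularization (lambda = ``smooth``); the Funk-Radon
    transform multiplies degree-l coefficients by 2*pi*P_l(0).  GFA is the
    normalized standard deviation of the ODF samples and lies in [0, 1].
    """
    if sh_order % 2 != 0 or sh_order < 0:
        raise ConfigurationError("sh_order must be a non-negative even integer")
    shell_idx, notes = _find_shell(dwi.bvals)
    for msg in notes:
        warnings.warn(msg, stacklevel=2)

    bvecs = dwi.bvecs[shell_idx]
    B, degs = real_sh_basis(sh_order, bvecs)
    L = np.diag((degs * (degs + 1.0)) ** 2)
    fit = np.linalg.solve(B.T @ B + smooth * L, B.T)  # (n_coef, n_dirs)
    frt = 2.0 * np.pi * eval_legendre(degs, 0.0)  # Funk-Radon per degree

    Bv, _ = real_sh_basis(sh_order, tess.hemisphere_vertices)

    mask = dwi.grid_mask()
    b0 = dwi.mean_b0()
    valid = mask & (b0 > 0)
    s = dwi.signal[valid][:, shell_idx] / b0[valid][:, None]
    coef = s @ fit.T * frt
    odf_flat = coef @ Bv.T

    odf = np.zeros(dwi.shape + (Bv.shape[0],))
    odf[valid] = odf_flat
    gfa = np.full(dwi.shape, np.nan)
    gfa[valid] = np.clip(gfa_from_samples(odf_flat), 0.0, 1.0)
    return ODFVolume(
        odf=odf, gfa=gfa, sh_order=sh_order, tessellation=tess, warnings=notes
    )
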