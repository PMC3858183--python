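"""Shared fixtures: tessellations, phantom pipelines, synthetic peak fields."""

from types import SimpleNamespace

import numpy as np
import pytest

import qatract as qt
from qatract import evaluation as ev


@pytest.fixture(scope="session")
def tess3():
    return qt.build_tessellation(3)


def make_field_peakmap(tess, dirs, qa, voxel_size=1.0):
    """PeakMap from a per-voxel single-direction field (zero rows = no peak).

    Directions snap to the nearest tessellation hemisphere vertex, as real
    peak maps do.
    """
    dirs = np.asarray(dirs, dtype=float)
    qa = np.asarray(qa, dtype=float)
    shape = dirs.shape[:3]
    hemi = tess.hemisphere_vertices
    vert = np.full(shape + (1,), -1, dtype=np.int64)
    qav = np.zeros(shape + (1,))
    d = dirs.reshape(-1, 3)
    n = np.linalg.norm(d, axis=1)
    ok = n > 0
    idx = np.argmax(np.abs((d[ok] / n[ok, None]) @ hemi.T), axis=1)
    vert.reshape(-1)[ok] = idx
    qav.reshape(-1)[ok] = qa.reshape(-1)[ok]
    return qt.PeakMap(
        peak_vertex=vert,
        peak_qa=qav,
        tessellation=tess,
        z0=1.0,
        voxel_size=np.full(3, float(voxel_size)),
    )


def make_two_peak_voxel(tess, qa1=0.8, qa2=0.3, fa=0.5):
    """A 1-voxel PeakMap with two orthogonal peaks (x and y) and an FA map."""
    hemi = tess.hemisphere_vertices
    ix = int(np.argmax(np.abs(hemi @ np.array([1.0, 0, 0]))))
    iy = int(np.argmax(np.abs(hemi @ np.array([0, 1.0, 0]))))
    vert = np.full((1, 1, 1, 3), -1, dtype=np.int64)
    qav = np.zeros((1, 1, 1, 3))
    vert[0, 0, 0, :2] = [ix, iy]
    qav[0, 0, 0, :2] = [qa1, qa2]
    pk = qt.PeakMap(
        peak_vertex=vert, peak_qa=qav, tessellation=tess, z0=1.0,
        voxel_size=np.ones(3),
    )
    qt.attach_scalar_indices(pk, fa_map=np.full((1, 1, 1), fa))
    return pk


@pytest.fixture(scope="session")
def crossing(tess3):
    """Full pipeline on the 90-degree crossing phantom at SNR 30."""
    spec = qt.make_crossing_phantom(snr=30.0, rng_seed=1)
    dwi = qt.simulate_signal(spec)
    ten = qt.fit_dti(dwi)
    sdf = qt.gqi_sdf(dwi, tess3)
    odf = qt.qball_gfa(dwi, tess3)
    z0 = qt.compute_z0(sdf, spec.region("water"))
    pk = qt.extract_peaks(sdf, tess3, z0=z0)
    qt.attach_scalar_indices(pk, fa_map=ten.fa, gfa_map=odf.gfa)
    return SimpleNamespace(
        spec=spec, dwi=dwi, tensor=ten, sdf=sdf, odf=odf, z0=z0, peaks=pk
    )


@pytest.fixture(scope="session")
def spindle_factory(tess3):
    """Cached spindle-phantom pipelines keyed by RNG seed.

    Each run reconstructs FA and QA maps, calibrates both thresholds against
    the strand mask by Dice sweep, and returns everything tracking needs.
    """
    cache = {}

    def run(seed: int):
        if seed in cache:
            return cache[seed]
        spec = qt.make_spindle_phantom(rng_seed=seed)
        dwi = qt.simulate_signal(spec)
        ten = qt.fit_dti(dwi)
        sdf = qt.gqi_sdf(dwi, tess3)
        z0 = qt.compute_z0(sdf, spec.region("gel"))
        pk = qt.extract_peaks(sdf, tess3, z0=z0)
        qt.attach_scalar_indices(pk, fa_map=ten.fa)
        strands = spec.region("strands")
        qa_map = pk.peak_qa[..., 0]
        fa_thr, _ = ev.calibrate_threshold(
            ten.fa, strands, np.linspace(0.01, 0.6, 60)
        )
        qa_thr, _ = ev.calibrate_threshold(
            qa_map, strands, np.linspace(0.001, float(qa_map.max()), 60)
        )
        strand_masks = {
            f"strand_{k}": spec.region(f"strand_{k}") for k in range(6)
        }
        out = SimpleNamespace(
            spec=spec, tensor=ten, sdf=sdf, z0=z0, peaks=pk,
            strands=strands, strand_masks=strand_masks,
            fa_threshold=fa_thr, qa_threshold=qa_thr,
        )
        cache[seed] = out
        return out

    return run


def track_spindle(run, index_name: str, rng_seed: int, count: int = 200):
    """Track a spindle pipeline with the calibrated threshold of an index."""
    thr = run.qa_threshold if index_name == "qa" else run.fa_threshold
    params = qt.TrackingParams(
        index_threshold=thr,
        index_name=index_name,
        target_track_count=count,
        rng_seed=rng_seed,
    )
    return qt.generate_tractography(run.peaks, params, seed_region=run.strands)
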