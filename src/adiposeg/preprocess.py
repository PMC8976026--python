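"""Preprocessing chain: station registration and merging, supersampling to
isotropic voxels, median filtering, and body-mask extraction.

Station registration is a 3-degree-of-freedom translational fit per
junction: the superior station of each junction is shifted so that the
mean squared intensity difference over the overlap slices is minimised.
The optimiser is a coarse integer-voxel grid search followed by
Nelder–Mead simplex refinement with restarts; intensities are
interpolated trilinearly at fractional shifts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .core import LabelMap, VolumeImage
from .phantom import StationSeries

__all__ = [
    "RegistrationResult",
    "register_stations",
    "merge_stations",
    "supersample",
    "supersample_labels",
    "median_filter_volume",
    "body_mask",
]


@dataclass
class RegistrationResult:
    """Estimated per-junction displacement of the superior station (voxels)."""

    shifts: list[tuple[float, float, float]]
    cost: float
    converged: bool
    n_iterations: int


def _junction_cost(ref_block: np.ndarray, mov_block: np.ndarray,
                   overlap: int, shift) -> float:
    """MSE over the overlap after undoing ``shift`` on the moving block."""
    corrected = ndimage.shift(mov_block, [-s for s in shift], order=1,
                              mode="nearest")
    diff = corrected[:, :, :overlap] - ref_block
    return float(np.mean(diff * diff))


def register_stations(s: StationSeries, search_bound: float = 3.0,
                      seed: int = 0, max_iter: int = 200,
                      ) -> RegistrationResult:
    """Recover per-junction translational shifts of a station series.

    For each junction the inferior station's top ``overlap_slices`` slices
    are the fixed reference; the superior station is translated.  Returns
    the estimated displacement that was applied to the superior station
    (so on phantoms it should match ``StationSeries.true_shifts``).
    """
    o = s.overlap_slices
    if o < 1:
        raise ValueError("junctions need at least one overlap slice")
    rng = np.random.default_rng(seed)
    b = int(np.ceil(search_bound))
    shifts: list[tuple[float, float, float]] = []
    total_cost = 0.0
    total_iter = 0
    all_converged = True

    for j in range(len(s.stations) - 1):
        ref = s.stations[j].data
        mov = s.stations[j + 1].data
        if ref.shape[2] < o or mov.shape[2] < o:
            raise ValueError("station shorter than the overlap")
        ref_block = np.asarray(ref[:, :, -o:], dtype=np.float64)
        # enough superior slices to slide ±b in z with margin
        mov_block = np.asarray(mov[:, :, :min(mov.shape[2], o + b + 2)],
                               dtype=np.float64)

        cost = lambda p: _junction_cost(ref_block, mov_block, o, p)  # noqa: E731

        # stage 1: integer grid search, robust to local minima; exact cost
        # ties (flat plateaus on noiseless data) break toward the smallest
        # displacement
        best_p, best_key = (0.0, 0.0, 0.0), (np.inf, np.inf)
        grid = range(-b, b + 1)
        for dx in grid:
            for dy in grid:
                for dz in grid:
                    key = (cost((dx, dy, dz)), abs(dx) + abs(dy) + abs(dz))
                    if key < best_key:
                        best_key, best_p = key, (float(dx), float(dy), float(dz))
        best_c = best_key[0]

        # stage 2: simplex refinement with 2 restarts from perturbed starts
        starts = [np.array(best_p)]
        for _ in range(2):
            starts.append(np.array(best_p) + rng.uniform(-0.5, 0.5, 3))
        best_res = None
        for x0 in starts:
            res = optimize.minimize(cost, x0, method="Nelder-Mead",
                                    options={"maxiter": max_iter,
                                             "xatol": 1e-3, "fatol": 1e-10})
            total_iter += res.nit
            if best_res is None or res.fun < best_res.fun:
                best_res = res
        p = np.clip(best_res.x, -search_bound, search_bound)
        c = float(best_res.fun)
        if c >= best_c:  # refinement must strictly beat the grid optimum
            p, c = np.array(best_p), best_c
        else:
            all_converged &= bool(best_res.success)
        shifts.append(tuple(float(v) for v in p))
        total_cost += c

    return RegistrationResult(shifts=shifts, cost=total_cost,
                              converged=all_converged, n_iterations=total_iter)


def merge_stations(s: StationSeries, r: RegistrationResult) -> VolumeImage:
    """Merge registered stations into one contiguous volume.

    Each superior station is shifted back by its estimated displacement;
    in the overlap the superior station wins (no blending).  Output
    z-extent is the sum of station extents minus the overlaps.
    """
    if len(r.shifts) != len(s.stations) - 1:
        raise ValueError("registration result does not cover every junction")
    o = s.overlap_slices
    nx, ny = s.stations[0].shape[:2]
    lengths = [st.shape[2] for st in s.stations]
    nz = sum(lengths) - o * (len(s.stations) - 1)
    out = np.empty((nx, ny, nz), dtype=np.float64)

    z = 0
    for i, st in enumerate(s.stations):
        block = np.asarray(st.data, dtype=np.float64)
        if i > 0:
            sh = r.shifts[i - 1]
            if any(abs(c) > 1e-12 for c in sh):
                block = ndimage.shift(block, [-c for c in sh], order=1,
                                      mode="nearest")
            z -= o  # superior station overwrites the overlap
        out[:, :, z:z + block.shape[2]] = block
        z += block.shape[2]
    if not np.all(np.isfinite(out)):
        raise ValueError("merged volume contains non-finite intensities")
    return VolumeImage(out, spacing=s.stations[0].spacing,
                       origin_z=s.stations[0].origin_z,
                       subject_id=s.stations[0].subject_id)


def _zoom_factors(spacing, target):
    return tuple(si / ti for si, ti in zip(spacing, target))


def supersample(v: VolumeImage,
                target_spacing: tuple[float, float, float] = (1.2, 1.2, 1.2),
                ) -> VolumeImage:
    """Trilinear resampling onto an isotropic grid (default 1.2 mm).

    Output dims are ``round(dim × spacing / target)``; e.g. 36 slices at
    6 mm become 180 slices at 1.2 mm.
    """
    if any(t <= 0 for t in target_spacing):
        raise ValueError("target spacing must be positive")
    factors = _zoom_factors(v.spacing, target_spacing)
    if all(abs(f - 1.0) < 1e-12 for f in factors):
        return v.copy()
    out = ndimage.zoom(np.asarray(v.data, dtype=np.float64), factors,
                       order=1, mode="nearest", grid_mode=True)
    return VolumeImage(out, spacing=tuple(target_spacing), origin_z=v.origin_z,
                       subject_id=v.subject_id)


def supersample_labels(m: LabelMap,
                       target_spacing: tuple[float, float, float] = (1.2, 1.2, 1.2),
                       ) -> LabelMap:
    """Nearest-neighbour resampling for label maps (classes stay in {0,1,2})."""
    factors = _zoom_factors(m.spacing, target_spacing)
    if all(abs(f - 1.0) < 1e-12 for f in factors):
        return m.copy()
    out = ndimage.zoom(m.classes, factors, order=0, mode="nearest",
                       grid_mode=True)
    return LabelMap(out, spacing=tuple(target_spacing), subject_id=m.subject_id)


def median_filter_volume(v: VolumeImage,
                         kernel: tuple[int, int, int] = (3, 3, 3),
                         ) -> VolumeImage:
    """Voxelwise median within an odd-sided kernel, reflecting at edges."""
    if any(k % 2 == 0 or k < 1 for k in kernel):
        raise ValueError(f"kernel sides must be odd and positive, got {kernel}")
    out = ndimage.median_filter(np.asarray(v.data, dtype=np.float64),
                                size=kernel, mode="reflect")
    return VolumeImage(out, spacing=v.spacing, origin_z=v.origin_z,
                       subject_id=v.subject_id)


def body_mask(v: VolumeImage, threshold_quantile: float = 0.5) -> np.ndarray:
    """Binary body mask: intensity threshold, per-slice largest connected
    component, holes filled.

    Disconnected lateral structures (arm remnants, phantom distractor
    blobs) are discarded by the largest-component rule — the automated
    stand-in for interactive arm deletion.
    """
    data = np.asarray(v.data, dtype=np.float64)
    thr = float(np.quantile(data, threshold_quantile))
    fg = data > thr
    if not fg.any():
        raise ValueError("empty foreground: no voxel above the threshold")
    out = np.zeros(data.shape, dtype=bool)
    structure = np.ones((3, 3), dtype=bool)  # 8-connectivity in-plane
    for k in range(data.shape[2]):
        sl = ndimage.binary_fill_holes(fg[:, :, k])
        lab, n = ndimage.label(sl, structure=structure)
        if n == 0:
            continue
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=range(1, n + 1))
        keep = 1 + int(np.argmax(sizes))
        out[:, :, k] = ndimage.binary_fill_holes(lab == keep)
    if not out.any():
        warnings.warn("body mask is empty on every slice")
    return out
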