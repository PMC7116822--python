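"""Voxel-wise MRSI fitting with a parallel/serial equivalence contract.

Every voxel is fitted independently.  Per-voxel MH seeds are derived
deterministically from the global seed and the voxel index, so results are
identical no matter how many workers run the voxels or in which order.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .core import BasisSet, MRSData, ParameterError
from .fitting import FitResult, fit_spectrum
from .model import FitConfig

__all__ = ["fit_mrsi", "MRSIResult", "voxel_seed"]


def voxel_seed(global_seed: int | None, ix: int, iy: int, iz: int) -> int:
    """Deterministic per-voxel seed below 2**31."""
    base = 0 if global_seed is None else int(global_seed)
    return int((base * 1_000_003 + ix * 73_856_093 + iy * 19_349_663
                + iz * 83_492_791) % (2 ** 31 - 1))


class MRSIResult:
    """Per-voxel fit results plus concentration map assembly."""

    def __init__(self, results: dict, shape, metab_names, affine,
                 failures: dict):
        self.results = results          # {(ix,iy,iz): FitResult}
        self.shape = shape
        self.metab_names = metab_names
        self.affine = affine
        self.failures = failures        # {(ix,iy,iz): message}

    def concentration_map(self, name: str) -> np.ndarray:
        out = np.full(self.shape, np.nan)
        for (ix, iy, iz), res in self.results.items():
            out[ix, iy, iz] = res.concentration(name)
        return out

    def as_dataframe(self) -> pd.DataFrame:
        rows = []
        for (ix, iy, iz), res in sorted(self.results.items()):
            for i, name in enumerate(res.metab_names):
                row = {"x": ix, "y": iy, "z": iz, "metabolite": name,
                       "conc": float(res.point_estimate.conc[i])}
                if res.has_samples:
                    row["sd"] = float(res.samples[:, i].std())
                rows.append(row)
        return pd.DataFrame(rows)


def _fit_one(index, spec, basis, config):
    try:
        res = fit_spectrum(spec, basis, config)
        # drop heavy per-voxel references before returning across processes
        res.basis = None
        return index, res, None
    except Exception as exc:  # per-voxel failure: mask voxel, keep going
        return index, None, f"{type(exc).__name__}: {exc}"


def fit_mrsi(data: MRSData, basis: BasisSet, config: FitConfig | None = None,
             mask: np.ndarray | None = None, n_workers: int = 1) -> MRSIResult:
    """Fit every (masked) voxel of an MRSI grid independently.

    ``mask`` is a boolean array over the spatial shape (default: voxels with
    any signal energy).  Failed voxels are recorded and excluded from maps.
    """
    config = config or FitConfig()
    if data.n_coils != 1 or data.n_averages != 1:
        raise ParameterError("reduce coil/average dimensions before MRSI fitting")
    spatial = data.spatial_shape
    if mask is None:
        mask = np.abs(data.signal[:, :, :, :, 0, 0]).sum(axis=3) > 0
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != spatial:
        raise ParameterError("mask shape does not match the spatial grid")
    voxels = [tuple(v) for v in np.argwhere(mask)]
    if not voxels:
        raise ParameterError("mask selects no voxels")

    from .core import to_spectrum

    tasks = []
    for (ix, iy, iz) in voxels:
        cfg = replace(config, seed=voxel_seed(config.seed, ix, iy, iz))
        spec = to_spectrum(data.signal[ix, iy, iz, :, 0, 0])
        tasks.append(((ix, iy, iz), spec, cfg))
    if n_workers == 1:
        outputs = [_fit_one(i, s, basis, c) for i, s, c in tasks]
    else:
        outputs = Parallel(n_jobs=n_workers)(
            delayed(_fit_one)(i, s, basis, c) for i, s, c in tasks)
    results, failures = {}, {}
    for index, res, err in outputs:
        if err is None:
            results[index] = res
        else:
            failures[index] = err
    return MRSIResult(results, spatial, list(basis.names), data.affine,
                      failures)
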