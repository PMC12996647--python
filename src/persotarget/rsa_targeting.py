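"""Refined seed-based target derivation (RSA).

The algorithm correlates every DLPFC voxel with an sgACC "representative
signal": the mean, over all brain voxels outside the DLPFC, of each
voxel's time series multiplied by a population-level sgACC connectivity
weight.  DLPFC voxels are ranked ascending by that correlation (most
anticorrelated first), a fraction is retained (default the top 50 %),
and the centroid of the largest contiguous retained cluster is the
target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from persotarget.targets import Target
from persotarget.volumetric_io import BinaryMask, BoldRun, VolumeGeometry, WeightMap


class RsaError(ValueError):
    pass


@dataclass
class SeedFcMap:
    """Per-voxel Pearson correlation with a seed's mean time series."""

    data: np.ndarray  # 3D; NaN outside the brain mask
    geometry: VolumeGeometry
    seed_name: str = "sgacc"


@dataclass
class RetainedSet:
    """The retained (most anticorrelated) fraction of DLPFC voxels."""

    mask: BinaryMask
    fraction: float
    source_correlations: np.ndarray  # per-DLPFC-voxel, in voxel_indices order


def _corr_with_series(ts: np.ndarray, seed: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of ``ts`` with ``seed``."""
    seed = seed - seed.mean()
    seed_ss = float(seed @ seed)
    if seed_ss == 0:
        raise RsaError("seed series has zero variance")
    centered = ts - ts.mean(axis=1, keepdims=True)
    num = centered @ seed
    denom = np.sqrt(np.einsum("ij,ij->i", centered, centered) * seed_ss)
    out = np.full(len(ts), np.nan)
    ok = denom > 0
    out[ok] = num[ok] / denom[ok]
    return np.clip(out, -1.0, 1.0)


def sgacc_fc_map(run: BoldRun, sgacc_mask: BinaryMask, brain_mask: BinaryMask) -> SeedFcMap:
    """Seed-to-whole-brain connectivity map: mean sgACC series correlated
    with every brain-mask voxel."""
    sgacc_mask.require_nonempty()
    brain_mask.require_nonempty()
    seed = run.data[sgacc_mask.data].mean(axis=0)
    if np.var(seed) == 0:
        raise RsaError("zero-variance sgACC seed series")
    vol = np.full(run.geometry.dims, np.nan)
    vol[brain_mask.data] = _corr_with_series(run.data[brain_mask.data], seed)
    return SeedFcMap(data=vol, geometry=run.geometry, seed_name=sgacc_mask.name or "sgacc")


def group_weight_map(maps: list[SeedFcMap], fisher_z: bool = False) -> WeightMap:
    """Voxelwise mean of individual seed maps (the population weighting
    mask).  NaN-aware: a voxel is NaN only where NaN in every map.
    Optionally averages Fisher-z transformed values (back-transformed)."""
    if not maps:
        raise RsaError("need at least one map")
    geom = maps[0].geometry
    for m in maps[1:]:
        if m.geometry != geom:
            raise RsaError("seed maps have mismatched geometry")
    stack = np.stack([m.data for m in maps])
    with warnings.catch_warnings():
        # voxels NaN in every map (outside the brain) stay NaN by design
        warnings.simplefilter("ignore", category=RuntimeWarning)
        if fisher_z:
            clipped = np.clip(stack, -1 + 1e-7, 1 - 1e-7)
            mean = np.tanh(np.nanmean(np.arctanh(clipped), axis=0))
        else:
            mean = np.nanmean(stack, axis=0)
    return WeightMap(data=mean, geometry=geom)


def weighted_representative_signal(
    run: BoldRun,
    weights: WeightMap,
    dlpfc_mask: BinaryMask,
    brain_mask: BinaryMask,
) -> np.ndarray:
    """sgACC representative signal: mean over brain voxels outside the
    DLPFC of weight * time series.  Signed weights are used as-is."""
    outside = brain_mask.data & ~dlpfc_mask.data
    if not outside.any():
        raise RsaError("no brain voxels outside the DLPFC mask")
    w = np.nan_to_num(weights.data[outside], nan=0.0)
    ts = run.data[outside]
    signal = (w[:, None] * ts).mean(axis=0)
    if np.allclose(signal, signal[0]):
        warnings.warn("degenerate (constant) representative signal; check weights")
    return signal


def retain_top_fraction(correlations: np.ndarray, fraction: float,
                        voxels: np.ndarray, geom, ascending: bool = True) -> RetainedSet:
    """Retain round(fraction * N) voxels ranked by correlation.

    Ascending order (the default) keeps the most anticorrelated voxels
    first.  Ties are broken by linearized voxel index, so the retained
    set is deterministic.
    """
    correlations = np.asarray(correlations, dtype=float)
    n = len(correlations)
    if n == 0:
        raise RsaError("no DLPFC voxels to rank")
    if not 0 < fraction <= 1:
        raise RsaError(f"fraction must be in (0, 1], got {fraction}")
    n_keep = max(1, int(np.floor(fraction * n + 0.5)))
    lin = np.ravel_multi_index(np.asarray(voxels, dtype=int).T, geom.dims)
    key = correlations if ascending else -correlations
    order = np.lexsort((lin, key))
    keep = order[:n_keep]
    mask_vol = np.zeros(geom.dims, dtype=bool)
    kept_vox = np.asarray(voxels)[keep]
    mask_vol[kept_vox[:, 0], kept_vox[:, 1], kept_vox[:, 2]] = True
    return RetainedSet(
        mask=BinaryMask(data=mask_vol, geometry=geom, name="retained"),
        fraction=fraction,
        source_correlations=correlations,
    )


_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def largest_connected_cluster(mask: BinaryMask, connectivity: int = 26) -> BinaryMask:
    """The connected component with the most voxels (ties broken by the
    component containing the lowest linearized voxel index)."""
    mask.require_nonempty()
    if connectivity not in _STRUCTS:
        raise RsaError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    labeled, n = ndimage.label(mask.data, structure=_STRUCTS[connectivity])
    sizes = np.bincount(labeled.ravel())[1:]  # drop background
    best = sizes.max()
    tied = np.flatnonzero(sizes == best) + 1
    if len(tied) > 1:
        # component whose minimum linear index is smallest wins
        flat = labeled.ravel()
        first_idx = {lab: np.flatnonzero(flat == lab)[0] for lab in tied}
        winner = min(tied, key=lambda lab: first_idx[lab])
    else:
        winner = tied[0]
    return BinaryMask(data=labeled == winner, geometry=mask.geometry, name="largest_cluster")


def cluster_centroid(cluster: BinaryMask) -> np.ndarray:
    """Unweighted mean of member-voxel world-mm coordinates."""
    cluster.require_nonempty()
    return cluster.world_coords_mm().mean(axis=0)


def rsa_target(
    run: BoldRun,
    weights: WeightMap,
    dlpfc_mask: BinaryMask,
    brain_mask: BinaryMask,
    fraction: float = 0.5,
    connectivity: int = 26,
    ascending: bool = True,
    gsr: bool | None = None,
) -> Target:
    """Full RSA pipeline on a preprocessed run."""
    dlpfc_mask.require_nonempty()
    signal = weighted_representative_signal(run, weights, dlpfc_mask, brain_mask)
    voxels = dlpfc_mask.voxel_indices()
    corr = _corr_with_series(run.data[dlpfc_mask.data], signal)
    retained = retain_top_fraction(corr, fraction, voxels, run.geometry, ascending)
    cluster = largest_connected_cluster(retained.mask, connectivity)
    xyz = cluster_centroid(cluster)
    params = {"fraction": fraction, "connectivity": connectivity, "ascending": ascending}
    if gsr is not None:
        params["gsr"] = gsr
    return Target(
        world_mm=tuple(xyz),
        algorithm="RSA",
        subject_id=run.subject_id,
        day=run.day,
        phase=run.phase,
        params=params,
    )
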