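"""Hierarchical-clustering target derivation (HCA).

The DLPFC (and sgACC) are partitioned into functional subunits by
spatially constrained agglomerative clustering of voxel time series:
every voxel starts as its own cluster and the spatially adjacent pair
with the smallest average Spearman-distance linkage is merged until the
minimum adjacent-pair linkage exceeds a stop threshold (default 0.5).
Each subunit is summarized by a median time course and a representative
voxel, and DLPFC subunits are ranked by a composite of three z-scored
parameters: the size-weighted sum of correlations with sgACC subunits,
spatial concentration, and voxel count.  The representative voxel of the
top-composite subunit is the target.

All tie-breaks use the lowest linearized voxel index, so the result is
invariant to voxel enumeration order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from persotarget.targets import Target
from persotarget.volumetric_io import BinaryMask, BoldRun, VolumeGeometry


class HcaError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Distance matrix and spatial adjacency


def spearman_distance_matrix(ts: np.ndarray) -> np.ndarray:
    """1 - Spearman rank correlation between the rows of a voxel x time
    matrix.  Symmetric, zero diagonal, entries in [0, 2]."""
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2 or ts.shape[0] < 2:
        raise HcaError("need a (n_voxels >= 2) x time matrix")
    if ts.shape[1] < 3:
        raise HcaError("need at least 3 time points for a rank correlation")
    if np.any(np.ptp(ts, axis=1) == 0):
        raise HcaError("constant voxel time series: rank correlation undefined")
    ranks = np.apply_along_axis(stats.rankdata, 1, ts)
    rho = np.corrcoef(ranks)
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def voxel_adjacency(voxels: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """Boolean adjacency matrix for an (n, 3) voxel index array.

    connectivity 6 = faces, 18 = faces+edges, 26 = faces+edges+corners.
    """
    if connectivity not in (6, 18, 26):
        raise HcaError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    voxels = np.asarray(voxels, dtype=int)
    diff = np.abs(voxels[:, None, :] - voxels[None, :, :])
    cheb = diff.max(axis=2)
    manh = diff.sum(axis=2)
    if connectivity == 6:
        adj = manh == 1
    elif connectivity == 18:
        adj = (cheb == 1) & (manh <= 2)
    else:
        adj = cheb == 1
    np.fill_diagonal(adj, False)
    return adj


def constrained_agglomerative_cluster(
    dist: np.ndarray,
    adjacency: np.ndarray,
    stop: float = 0.5,
) -> np.ndarray:
    """Spatially constrained average-linkage agglomerative clustering.

    Starting from singletons, repeatedly merge the spatially adjacent
    cluster pair with the smallest average linkage (mean of the original
    pairwise distances between members, maintained via the Lance-Williams
    update).  Two clusters are adjacent iff any cross-pair of member
    voxels is adjacent.  Stops when the minimum adjacent-pair linkage
    exceeds ``stop`` or one cluster per connected component remains.

    Ties are broken by the smallest (id_i, id_j) pair, where a cluster's
    id is the minimum member index; this makes the labeling independent
    of voxel enumeration order.

    Returns integer labels (0..k-1) ordered by each cluster's minimum
    member index.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if n == 0:
        raise HcaError("empty mask: nothing to cluster")
    if dist.shape != (n, n) or adjacency.shape != (n, n):
        raise HcaError("distance and adjacency matrices must be square and congruent")
    if not 0 < stop < 2:
        raise HcaError(f"stop threshold must lie in (0, 2), got {stop}")

    link = dist.copy().astype(float)
    adj = adjacency.copy().astype(bool)
    sizes = np.ones(n, dtype=int)
    active = np.ones(n, dtype=bool)
    members: list[list[int]] = [[i] for i in range(n)]
    big = np.inf

    while active.sum() > 1:
        cand = np.where(adj, link, big)
        np.fill_diagonal(cand, big)
        mval = cand.min()
        if not np.isfinite(mval) or mval > stop:
            break
        # smallest (i, j) among all tied minima; row/col indices are
        # cluster ids == minimum member index by construction below
        ti, tj = np.nonzero(cand == mval)
        order = np.lexsort((tj, ti))
        i, j = int(ti[order[0]]), int(tj[order[0]])
        if i > j:
            i, j = j, i
        # Lance-Williams update for unweighted average linkage
        ni, nj = sizes[i], sizes[j]
        link[i, :] = (ni * link[i, :] + nj * link[j, :]) / (ni + nj)
        link[:, i] = link[i, :]
        adj[i, :] |= adj[j, :]
        adj[:, i] = adj[i, :]
        adj[i, i] = False
        sizes[i] = ni + nj
        members[i] = sorted(members[i] + members[j])
        active[j] = False
        adj[j, :] = False
        adj[:, j] = False
        link[j, :] = big
        link[:, j] = big

    labels = np.empty(n, dtype=int)
    cluster_ids = sorted(int(i) for i in np.nonzero(active)[0])
    for lab, cid in enumerate(cluster_ids):
        labels[members[cid]] = lab
    return labels


# ---------------------------------------------------------------------------
# Subunit summaries


@dataclass
class Subunit:
    """A spatially connected cluster of voxels with its summaries."""

    voxel_indices: np.ndarray  # (k, 3) int
    median_timecourse: np.ndarray
    representative_voxel: tuple[int, int, int]
    representative_series: np.ndarray
    size: int
    concentration: float  # voxels per mm; 0 for singletons


@dataclass
class SubunitSet:
    subunits: list[Subunit]
    region_mask: BinaryMask
    stop_threshold: float = 0.5

    def __len__(self):
        return len(self.subunits)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return 0.0
    return float(a @ b / denom)


def subunit_summary(
    ts: np.ndarray,
    labels: np.ndarray,
    voxels: np.ndarray,
    geom: VolumeGeometry,
    region_mask: BinaryMask | None = None,
    stop_threshold: float = 0.5,
) -> SubunitSet:
    """Summarize each labeled cluster.

    median time course: elementwise median across member voxels;
    representative voxel: the member whose series has the highest Pearson
    correlation with the median course (lowest linearized index on ties);
    concentration: size / mean pairwise world-mm distance (0 for
    singletons, where no pair exists).
    """
    ts = np.asarray(ts, dtype=float)
    labels = np.asarray(labels, dtype=int)
    voxels = np.asarray(voxels, dtype=int)
    lin = np.ravel_multi_index(voxels.T, geom.dims)
    subunits = []
    for lab in np.unique(labels):
        sel = labels == lab
        member_ts = ts[sel]
        member_vox = voxels[sel]
        member_lin = lin[sel]
        median_tc = np.median(member_ts, axis=0)
        corrs = np.array([_pearson(row, median_tc) for row in member_ts])
        best = np.flatnonzero(corrs == corrs.max())
        rep_i = best[np.argmin(member_lin[best])]
        size = int(sel.sum())
        if size > 1:
            coords = geom.voxel_centers_mm(member_vox)
            dists = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
            iu = np.triu_indices(size, k=1)
            concentration = size / float(dists[iu].mean())
        else:
            concentration = 0.0
        subunits.append(
            Subunit(
                voxel_indices=member_vox,
                median_timecourse=median_tc,
                representative_voxel=tuple(int(v) for v in member_vox[rep_i]),
                representative_series=member_ts[rep_i].copy(),
                size=size,
                concentration=concentration,
            )
        )
    return SubunitSet(subunits=subunits, region_mask=region_mask, stop_threshold=stop_threshold)


def cluster_region(
    run: BoldRun,
    mask: BinaryMask,
    stop: float = 0.5,
    connectivity: int = 26,
) -> tuple[SubunitSet, np.ndarray, np.ndarray]:
    """Cluster a masked region of a run into subunits.

    Returns (subunit set, labels, voxel indices).
    """
    mask.require_nonempty()
    voxels = mask.voxel_indices()
    ts = run.data[mask.data]
    if len(voxels) == 1:
        labels = np.zeros(1, dtype=int)
    else:
        dist = spearman_distance_matrix(ts)
        adj = voxel_adjacency(voxels, connectivity)
        labels = constrained_agglomerative_cluster(dist, adj, stop)
    subs = subunit_summary(ts, labels, voxels, run.geometry,
                           region_mask=mask, stop_threshold=stop)
    return subs, labels, voxels


# ---------------------------------------------------------------------------
# Composite scoring


@dataclass
class HcaScoreRow:
    subunit_id: int
    weighted_corr_sum: float
    concentration: float
    size: int
    z_weighted: float = 0.0
    z_conc: float = 0.0
    z_size: float = 0.0
    composite: float = 0.0


def _zscore(x: np.ndarray) -> np.ndarray:
    """Sample z-score (ddof=1); all-zero when the column has no variance."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def score_subunits(dlpfc: SubunitSet, sgacc: SubunitSet) -> list[HcaScoreRow]:
    """Three-parameter composite score for every DLPFC subunit.

    For DLPFC subunit i: weighted_corr_sum_i = sum_j r_ij * n_j where
    r_ij is the Pearson correlation between representative-voxel series
    of DLPFC subunit i and sgACC subunit j and n_j is the sgACC subunit's
    voxel count.  The three parameters are z-scored across DLPFC
    subunits and summed into the composite.  Because the therapeutic
    premise is sgACC *anticorrelation*, the correlation parameter enters
    the composite with its sign flipped: z_weighted is the z-score of
    -weighted_corr_sum, so more strongly anticorrelated subunits score
    higher.  (``weighted_corr_sum`` itself is reported unnegated.)
    """
    if len(dlpfc) < 2:
        raise HcaError(
            "composite z-scores need >= 2 DLPFC subunits; "
            "check the mask or stop threshold"
        )
    dl_reps = [su.representative_series for su in dlpfc.subunits]
    sg_reps = [su.representative_series for su in sgacc.subunits]
    sg_sizes = np.array([s.size for s in sgacc.subunits], dtype=float)
    rows = []
    for i, su in enumerate(dlpfc.subunits):
        r = np.array([_pearson(dl_reps[i], sg) for sg in sg_reps])
        rows.append(
            HcaScoreRow(
                subunit_id=i,
                weighted_corr_sum=float(r @ sg_sizes),
                concentration=su.concentration,
                size=su.size,
            )
        )
    zw = _zscore([-row.weighted_corr_sum for row in rows])
    zc = _zscore([row.concentration for row in rows])
    zs = _zscore([float(row.size) for row in rows])
    for row, a, b, c in zip(rows, zw, zc, zs):
        row.z_weighted, row.z_conc, row.z_size = float(a), float(b), float(c)
        row.composite = float(a + b + c)
    return rows


def hca_target(
    run: BoldRun,
    dlpfc_mask: BinaryMask,
    sgacc_mask: BinaryMask,
    stop: float = 0.5,
    connectivity: int = 26,
    gsr: bool | None = None,
) -> Target:
    """Full HCA pipeline on a preprocessed run: cluster both regions,
    score DLPFC subunits, and return the representative voxel of the
    highest-composite subunit (lowest subunit id on exact ties)."""
    dl_subs, dl_labels, dl_vox = cluster_region(run, dlpfc_mask, stop, connectivity)
    sg_subs, _, _ = cluster_region(run, sgacc_mask, stop, connectivity)
    rows = score_subunits(dl_subs, sg_subs)
    composites = np.array([r.composite for r in rows])
    winner = int(np.flatnonzero(composites == composites.max()).min())
    rep = dl_subs.subunits[winner].representative_voxel
    from persotarget.volumetric_io import voxel_to_world

    xyz = voxel_to_world(rep, run.geometry)
    params = {"stop": stop, "connectivity": connectivity}
    if gsr is not None:
        params["gsr"] = gsr
    return Target(
        world_mm=tuple(xyz),
        algorithm="HCA",
        subject_id=run.subject_id,
        day=run.day,
        phase=run.phase,
        params=params,
    )
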