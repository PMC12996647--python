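"""Target-to-sgACC connectivity vs. symptom severity.

For each subject, functional connectivity is computed between an 8-mm
spherical ROI around the derived target and every sgACC voxel.  Across
the cohort, a voxel-wise multiple linear regression models symptom score
as intercept + FC + age + sex; the FC coefficient's t statistic is
thresholded voxel-wise (p < 0.001) and cluster-extent corrected (k >= 4
within the sgACC small volume, k > 18 whole-brain), with an optional
permutation-based max-cluster-size null as an alternative to the fixed
extents.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from persotarget.rsa_targeting import _corr_with_series
from persotarget.targets import Target
from persotarget.volumetric_io import BinaryMask, BoldRun, VolumeGeometry, make_sphere_mask

#: |Fisher z| cap applied when r is numerically +-1.
FISHER_Z_CAP = np.arctanh(1 - 1e-7)

_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


class AssociationError(ValueError):
    pass


@dataclass
class SubjectFcVector:
    """One subject's per-sgACC-voxel connectivity plus covariates."""

    subject_id: str
    fc: np.ndarray  # length = number of sgACC voxels
    age: float
    sex: int  # coded 0/1
    score: float

    def __post_init__(self):
        self.fc = np.asarray(self.fc, dtype=float)
        if np.any(~np.isfinite(self.fc)):
            raise AssociationError(f"subject {self.subject_id}: NaN in fc vector")


@dataclass
class ClusterResult:
    voxels: np.ndarray  # (k, 3) indices into the analysis volume
    peak_voxel: tuple[int, int, int]
    peak_t: float
    size: int
    direction: str  # "positive" | "negative"


def target_roi_mask(target: Target, geom: VolumeGeometry, radius_mm: float = 8.0) -> BinaryMask:
    """Spherical ROI of ``radius_mm`` around the target coordinate."""
    return make_sphere_mask(target.world_mm, radius_mm, geom, name="target_roi")


def roi_sgacc_fc(
    run: BoldRun,
    roi: BinaryMask,
    sgacc: BinaryMask,
    fisher_z: bool = True,
) -> np.ndarray:
    """ROI-mean series correlated with every sgACC voxel, optionally
    Fisher-z transformed (|z| capped for |r| at machine 1)."""
    roi.require_nonempty()
    sgacc.require_nonempty()
    seed = run.data[roi.data].mean(axis=0)
    if np.var(seed) == 0:
        raise AssociationError("zero-variance ROI mean series")
    r = _corr_with_series(run.data[sgacc.data], seed)
    r = np.nan_to_num(r, nan=0.0)
    if fisher_z:
        return np.clip(np.arctanh(np.clip(r, -1 + 1e-7, 1 - 1e-7)), -FISHER_Z_CAP, FISHER_Z_CAP)
    return r


def voxelwise_regression(cohort: list[SubjectFcVector]) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel OLS of score ~ intercept + fc + age + sex.

    Returns (t-map, p-map) for the FC coefficient: one value per sgACC
    voxel, two-sided p from the t distribution with n - 4 df.
    """
    n = len(cohort)
    if n <= 4:
        raise AssociationError(f"need more subjects than regressors (4), got {n}")
    fc = np.stack([s.fc for s in cohort])  # (n, n_vox)
    ages = np.array([s.age for s in cohort], dtype=float)
    sexes = np.array([s.sex for s in cohort], dtype=float)
    scores = np.array([s.score for s in cohort], dtype=float)
    base = np.column_stack([np.ones(n), ages, sexes])
    if np.linalg.matrix_rank(base) < base.shape[1]:
        raise AssociationError("rank-deficient covariate design (age/sex constant?)")
    n_vox = fc.shape[1]
    tvals = np.empty(n_vox)
    df = n - 4
    for v in range(n_vox):
        x = np.column_stack([base, fc[:, v]])
        if np.linalg.matrix_rank(x) < 4:
            raise AssociationError(f"fc column {v} is collinear with covariates (constant?)")
        beta, _, _, _ = np.linalg.lstsq(x, scores, rcond=None)
        resid = scores - x @ beta
        sigma2 = resid @ resid / df
        xtx_inv = np.linalg.inv(x.T @ x)
        se = np.sqrt(sigma2 * xtx_inv[3, 3])
        tvals[v] = beta[3] / se if se > 0 else 0.0
    pvals = 2 * stats.t.sf(np.abs(tvals), df)
    return tvals, pvals


def fc_coefficient(cohort: list[SubjectFcVector], voxel: int) -> float:
    """The fitted FC slope at one voxel (same model as the t-map)."""
    n = len(cohort)
    x = np.column_stack(
        [
            np.ones(n),
            [s.age for s in cohort],
            [s.sex for s in cohort],
            [s.fc[voxel] for s in cohort],
        ]
    )
    scores = np.array([s.score for s in cohort], dtype=float)
    beta, *_ = np.linalg.lstsq(x, scores, rcond=None)
    return float(beta[3])


def cluster_threshold(
    p_map: np.ndarray,
    t_map: np.ndarray,
    mask_voxels: np.ndarray,
    geom: VolumeGeometry,
    voxel_p: float = 0.001,
    min_size: int = 4,
    connectivity: int = 26,
    strict_greater: bool = False,
) -> list[ClusterResult]:
    """Cluster-extent thresholding of a voxel-wise map.

    Suprathreshold voxels (p < voxel_p) are split by t sign, connected-
    component labeled within the analysis mask, and clusters with size
    >= min_size (small-volume mode) or > min_size (whole-brain mode,
    ``strict_greater=True``) are reported.
    """
    p_map = np.asarray(p_map, dtype=float)
    t_map = np.asarray(t_map, dtype=float)
    if p_map.shape != t_map.shape:
        raise AssociationError("p-map and t-map shapes differ")
    mask_voxels = np.asarray(mask_voxels, dtype=int)
    results: list[ClusterResult] = []
    for direction, sign in (("positive", 1), ("negative", -1)):
        vol = np.zeros(geom.dims, dtype=bool)
        keep = (p_map < voxel_p) & (sign * t_map > 0)
        sel = mask_voxels[keep]
        if len(sel) == 0:
            continue
        vol[sel[:, 0], sel[:, 1], sel[:, 2]] = True
        labeled, n_lab = ndimage.label(vol, structure=_STRUCTS[connectivity])
        tvol = np.zeros(geom.dims)
        tvol[mask_voxels[:, 0], mask_voxels[:, 1], mask_voxels[:, 2]] = t_map
        for lab in range(1, n_lab + 1):
            comp = np.argwhere(labeled == lab)
            size = len(comp)
            passes = size > min_size if strict_greater else size >= min_size
            if not passes:
                continue
            comp_t = tvol[comp[:, 0], comp[:, 1], comp[:, 2]]
            peak_i = int(np.argmax(np.abs(comp_t)))
            results.append(
                ClusterResult(
                    voxels=comp,
                    peak_voxel=tuple(int(v) for v in comp[peak_i]),
                    peak_t=float(comp_t[peak_i]),
                    size=size,
                    direction=direction,
                )
            )
    results.sort(key=lambda c: -c.size)
    return results


def cluster_size_null(
    cohort: list[SubjectFcVector],
    mask_voxels: np.ndarray,
    geom: VolumeGeometry,
    voxel_p: float = 0.001,
    connectivity: int = 26,
    n_perm: int = 500,
    seed: int = 0,
) -> int:
    """Permutation-based cluster-extent recommendation.

    Scores are permuted across subjects (breaking any score-FC link while
    preserving the FC covariance structure), the regression and voxel
    threshold are re-applied, and the 95th percentile of the maximum null
    cluster size is returned as the recommended minimum extent.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} < 100: cluster-size null will be coarse")
    rng = np.random.default_rng(seed)
    scores = np.array([s.score for s in cohort])
    max_sizes = np.zeros(n_perm, dtype=int)
    for it in range(n_perm):
        perm = rng.permutation(len(cohort))
        shuffled = [
            SubjectFcVector(
                subject_id=s.subject_id, fc=s.fc, age=s.age, sex=s.sex,
                score=float(scores[perm[i]]),
            )
            for i, s in enumerate(cohort)
        ]
        t_map, p_map = voxelwise_regression(shuffled)
        clusters = cluster_threshold(
            p_map, t_map, mask_voxels, geom, voxel_p=voxel_p, min_size=1,
            connectivity=connectivity,
        )
        max_sizes[it] = clusters[0].size if clusters else 0
    return int(np.percentile(max_sizes, 95))
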