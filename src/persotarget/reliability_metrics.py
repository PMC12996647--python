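"""Spatial test-retest reliability and discriminability statistics.

Each subject contributes four targets, one per (day, phase-encoding)
run: (1, LR), (1, RL), (2, LR), (2, RL).  From those quads we derive

* distance indices: IntraDD, InterDD, IntraPD, InterPD — mean Euclidean
  distances between targets from same-day, different-day, same-phase and
  different-phase runs — plus the mean over all six run pairs;
* a variability report: the centroid of the four targets, the SD of the
  four run-to-centroid distances, and per-axis coordinate SDs;
* inter/intra discriminability ratios across a cohort.

InterDD and InterPD are defined over the same two run pairs
((1,LR)-(2,RL) and (1,RL)-(2,LR)) and are therefore always identical;
both names are kept because the two factorial decompositions (day x
algorithm, phase x algorithm) use them in different roles.

Sample standard deviations (n-1 denominator) are used throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from persotarget.targets import Target

RUN_KEYS = ((1, "LR"), (1, "RL"), (2, "LR"), (2, "RL"))

#: Config constant for "reliable subject" summaries: six-pair mean below
#: this (mm) counts as a small intra-individual distance.
SMALL_DISTANCE_MM = 10.0


class ReliabilityError(ValueError):
    pass


@dataclass
class TargetQuad:
    """A subject's four run-specific targets from one algorithm."""

    subject_id: str
    targets: dict  # {(day, phase): Target}

    def __post_init__(self):
        missing = [k for k in RUN_KEYS if k not in self.targets]
        if missing:
            raise ReliabilityError(f"subject {self.subject_id}: missing runs {missing}")
        algs = {t.algorithm for t in self.targets.values()}
        if len(algs) > 1:
            raise ReliabilityError(f"mixed algorithms in one quad: {algs}")

    @classmethod
    def from_targets(cls, targets: list[Target]) -> "TargetQuad":
        by_key = {(t.day, t.phase): t for t in targets}
        sid = targets[0].subject_id if targets else ""
        return cls(subject_id=sid, targets=by_key)

    def coords(self) -> np.ndarray:
        """(4, 3) array in canonical run order."""
        return np.array([self.targets[k].xyz for k in RUN_KEYS])


@dataclass
class DistanceIndices:
    intra_dd: float
    inter_dd: float
    intra_pd: float
    inter_pd: float
    six_pair_mean: float


@dataclass
class VariabilityReport:
    sd_distance: float
    sd_x: float
    sd_y: float
    sd_z: float
    centroid: np.ndarray


@dataclass
class DiscriminabilityRatio:
    subject_id: str
    intra_mean: float
    inter_mean: float
    ratio: float


def euclidean_distance(a, b) -> float:
    return float(np.linalg.norm(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)))


def distance_indices(quad: TargetQuad) -> DistanceIndices:
    """IntraDD / InterDD / IntraPD / InterPD and the six-pair mean.

    IntraDD = (d(D1LR, D1RL) + d(D2LR, D2RL)) / 2
    InterDD = (d(D1LR, D2RL) + d(D1RL, D2LR)) / 2 = InterPD
    IntraPD = (d(D1LR, D2LR) + d(D1RL, D2RL)) / 2
    """
    t = {k: quad.targets[k].xyz for k in RUN_KEYS}
    d = euclidean_distance
    intra_dd = (d(t[(1, "LR")], t[(1, "RL")]) + d(t[(2, "LR")], t[(2, "RL")])) / 2
    inter = (d(t[(1, "LR")], t[(2, "RL")]) + d(t[(1, "RL")], t[(2, "LR")])) / 2
    intra_pd = (d(t[(1, "LR")], t[(2, "LR")]) + d(t[(1, "RL")], t[(2, "RL")])) / 2
    pairs = list(combinations(RUN_KEYS, 2))
    six = float(np.mean([d(t[a], t[b]) for a, b in pairs]))
    return DistanceIndices(
        intra_dd=intra_dd, inter_dd=inter, intra_pd=intra_pd, inter_pd=inter,
        six_pair_mean=six,
    )


def variability_report(quad: TargetQuad) -> VariabilityReport:
    """Centroid of the four targets, SD of run-to-centroid distances, and
    per-axis coordinate SDs (sample SD, n-1)."""
    coords = quad.coords()
    centroid = coords.mean(axis=0)
    dists = np.linalg.norm(coords - centroid, axis=1)
    sds = coords.std(axis=0, ddof=1)
    return VariabilityReport(
        sd_distance=float(dists.std(ddof=1)),
        sd_x=float(sds[0]),
        sd_y=float(sds[1]),
        sd_z=float(sds[2]),
        centroid=centroid,
    )


def discriminability_ratios(quads: list[TargetQuad]) -> list[DiscriminabilityRatio]:
    """Per subject: mean of the 6 within-subject pair distances (intra),
    mean distance to every other subject's same-(day, phase) targets
    (inter), and their ratio.  A subject with zero intra-individual
    distance gets an infinite ratio (flagged with a warning)."""
    if len(quads) < 2:
        raise ReliabilityError("need at least two subjects for discriminability")
    coords = {q.subject_id: q.coords() for q in quads}
    out = []
    for q in quads:
        own = coords[q.subject_id]
        intra = float(np.mean([euclidean_distance(a, b) for a, b in combinations(own, 2)]))
        inter_d = [
            euclidean_distance(own[r], coords[other.subject_id][r])
            for other in quads
            if other.subject_id != q.subject_id
            for r in range(4)
        ]
        inter = float(np.mean(inter_d))
        if intra == 0:
            warnings.warn(f"subject {q.subject_id}: zero intra-individual distance")
            ratio = float("inf")
        else:
            ratio = inter / intra
        out.append(DiscriminabilityRatio(q.subject_id, intra, inter, ratio))
    return out


def proportion_small_distance(quads: list[TargetQuad],
                              threshold_mm: float = SMALL_DISTANCE_MM) -> float:
    """Share of subjects whose six-pair mean distance is below the
    threshold (default 10 mm)."""
    sixes = [distance_indices(q).six_pair_mean for q in quads]
    return float(np.mean([s < threshold_mm for s in sixes]))


def tsnr(run, mask) -> float:
    """Mean temporal signal-to-noise ratio (temporal mean / temporal SD)
    over mask voxels; zero-variance voxels are excluded with a warning."""
    ts = run.data[mask.data]
    if ts.shape[1] < 2:
        raise ReliabilityError("tSNR needs at least 2 time points")
    sd = ts.std(axis=1, ddof=1)
    ok = sd > 0
    if not np.all(ok):
        warnings.warn(f"excluding {int((~ok).sum())} zero-variance voxels from tSNR")
    if not ok.any():
        raise ReliabilityError("all voxels have zero temporal variance")
    return float(np.mean(ts.mean(axis=1)[ok] / sd[ok]))
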