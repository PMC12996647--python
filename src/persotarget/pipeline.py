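"""End-to-end orchestration: preprocess a cohort, derive targets with
both algorithms, and summarize reliability.

This is the library-level engine behind the command-line interface and
the reproduction scripts.  Every stage takes and returns the package's
domain objects, so any step can be swapped or run in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from persotarget import hca_targeting, preprocessing, rsa_targeting
from persotarget.reliability_metrics import (
    TargetQuad,
    distance_indices,
    discriminability_ratios,
    proportion_small_distance,
    variability_report,
)
from persotarget.synthetic_data import SyntheticMasks
from persotarget.targets import Target
from persotarget.volumetric_io import BoldRun


@dataclass
class PipelineConfig:
    """Defaults follow the printed analysis parameters: 5-mm FWHM
    smoothing, 0.01-0.1 Hz band-pass, clustering stop 0.5, retention
    fraction 0.5, 8-mm association ROI, 10,000 permutation iterations."""

    fwhm_mm: float = 5.0
    low_hz: float = 0.01
    high_hz: float = 0.1
    gsr: bool = False
    compcor_k: int = 5
    stop: float = 0.5
    fraction: float = 0.5
    connectivity: int = 26
    roi_radius_mm: float = 8.0
    n_iter: int = 10_000
    smooth: bool = True
    truncate_nt: int | None = None


def preprocess_cohort(
    runs: dict[str, list[BoldRun]],
    masks: SyntheticMasks,
    config: PipelineConfig,
) -> dict[str, list[BoldRun]]:
    """Denoise every run: smoothing, WM+CSF aCompCor nuisance regression
    (plus global signal when configured), band-pass.

    aCompCor components are extracted from the *unsmoothed* data, as in
    standard pipelines: smoothing first would smear gray-matter signal
    into the tissue masks and the components would silently absorb it.
    """
    out: dict[str, list[BoldRun]] = {}
    for sid, subject_runs in runs.items():
        cleaned = []
        for run in subject_runs:
            if config.truncate_nt is not None:
                run = run.truncated(config.truncate_nt)
            wm = preprocessing.compcor_components(run, masks.wm, config.compcor_k)
            csf = preprocessing.compcor_components(run, masks.csf, config.compcor_k)
            confounds = wm.hstack(csf)
            smoothed = (
                preprocessing.smooth_gaussian(run, config.fwhm_mm) if config.smooth else run
            )
            cleaned.append(
                preprocessing.preprocess_run(
                    smoothed,
                    confounds=confounds,
                    brain_mask=masks.brain,
                    gsr=config.gsr,
                    low_hz=config.low_hz,
                    high_hz=config.high_hz,
                    smooth=False,  # already smoothed above
                )
            )
        out[sid] = cleaned
    return out


def build_weight_map(
    runs: dict[str, list[BoldRun]],
    masks: SyntheticMasks,
) -> rsa_targeting.WeightMap:
    """Population weighting mask: per-run sgACC connectivity maps are
    averaged within subject, then across subjects."""
    subject_maps = []
    for sid, subject_runs in runs.items():
        maps = [
            rsa_targeting.sgacc_fc_map(r, masks.sgacc, masks.brain) for r in subject_runs
        ]
        subject_maps.append(rsa_targeting.group_weight_map(maps))
    wrapped = [
        rsa_targeting.SeedFcMap(data=w.data, geometry=w.geometry) for w in subject_maps
    ]
    return rsa_targeting.group_weight_map(wrapped)


def derive_targets(
    runs: dict[str, list[BoldRun]],
    masks: SyntheticMasks,
    config: PipelineConfig,
    weight_map: rsa_targeting.WeightMap | None = None,
    algorithms: tuple[str, ...] = ("RSA", "HCA"),
) -> dict[str, dict[str, TargetQuad]]:
    """Per-subject target quads for the requested algorithms."""
    if "RSA" in algorithms and weight_map is None:
        weight_map = build_weight_map(runs, masks)
    out: dict[str, dict[str, TargetQuad]] = {}
    for sid, subject_runs in runs.items():
        quads: dict[str, TargetQuad] = {}
        if "RSA" in algorithms:
            targets = [
                rsa_targeting.rsa_target(
                    r, weight_map, masks.dlpfc, masks.brain,
                    fraction=config.fraction, connectivity=config.connectivity,
                    gsr=config.gsr,
                )
                for r in subject_runs
            ]
            quads["RSA"] = TargetQuad.from_targets(targets)
        if "HCA" in algorithms:
            targets = [
                hca_targeting.hca_target(
                    r, masks.dlpfc, masks.sgacc,
                    stop=config.stop, connectivity=config.connectivity, gsr=config.gsr,
                )
                for r in subject_runs
            ]
            quads["HCA"] = TargetQuad.from_targets(targets)
        out[sid] = quads
    return out


def reliability_table(quads_by_subject: dict[str, dict[str, TargetQuad]]) -> pd.DataFrame:
    """Long table of distance indices and variability SDs, one row per
    (subject, algorithm)."""
    rows = []
    for sid, quads in quads_by_subject.items():
        for alg, quad in quads.items():
            di = distance_indices(quad)
            vr = variability_report(quad)
            rows.append(
                {
                    "subject": sid,
                    "algorithm": alg,
                    "intra_dd": di.intra_dd,
                    "inter_dd": di.inter_dd,
                    "intra_pd": di.intra_pd,
                    "inter_pd": di.inter_pd,
                    "six_pair_mean": di.six_pair_mean,
                    "sd_distance": vr.sd_distance,
                    "sd_x": vr.sd_x,
                    "sd_y": vr.sd_y,
                    "sd_z": vr.sd_z,
                }
            )
    return pd.DataFrame(rows)


def run_reliability_study(
    runs: dict[str, list[BoldRun]],
    masks: SyntheticMasks,
    config: PipelineConfig,
) -> tuple[pd.DataFrame, dict[str, dict[str, TargetQuad]]]:
    """Preprocess, target, and tabulate reliability for a cohort."""
    cleaned = preprocess_cohort(runs, masks, config)
    quads = derive_targets(cleaned, masks, config)
    return reliability_table(quads), quads
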