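"""Synthetic resting-state cohorts with planted sgACC-DLPFC coupling.

The latent sgACC signal is drawn once per subject; with run noise, the
global component, and day jitter all switched off, a subject's four
runs are exactly identical (the determinism limit of the generator).

The generator emulates the acquisition structure the targeting
algorithms expect — per subject, four runs crossing acquisition day
{1, 2} with phase-encoding direction {LR, RL} — on a small 3D grid with
geometric-primitive masks (brain, gray matter, DLPFC, sgACC, WM, CSF).

Signal model, per subject and run:

* a band-limited (0.01-0.1 Hz) unit-variance latent sgACC signal s(t);
* sgACC voxels follow s(t) plus voxel noise;
* a planted spherical DLPFC blob couples to s(t) at a fixed negative
  strength (default -0.8) — the anticorrelated stimulation site both
  algorithms should find;
* all remaining brain voxels receive heterogeneous iid background
  couplings; the ~5-mm spatial correlation length of real connectivity
  maps then arises from the smoothing step of the preprocessing
  pipeline, exactly as it does for real EPI data (an optional
  ``coupling_background_fwhm_mm`` adds larger-scale structure);
* every brain voxel receives a run-specific global signal component
  through a spatially smooth per-voxel loading field (mean 1) redrawn
  each run, emulating the heterogeneous, session-varying expression of
  the global signal in real BOLD data.  All three properties matter: a
  spatially uniform component would merely offset every seed correlation
  equally; a loading pattern fixed across runs would bias targets
  without making them unstable; and a spatially white pattern would be
  averaged away by cluster-centroid extraction — in each of those cases
  global signal regression would have nothing to repair.  The component
  is expressed in gray matter only: were it present identically in WM
  and CSF, the aCompCor nuisance step would already remove it and GSR
  would again be moot — mirroring the real-data fact that WM/CSF
  components do not capture the gray-matter global signal;
* couplings are perturbed per acquisition day (day_effect_sd), so
  same-day runs are more alike than different-day runs;
* voxel noise is itself band-limited so the denoising pipeline does not
  strip the planted structure.

Symptom cohorts add a per-subject symptom score that depends linearly
on the subject's true (noiseless) target-sgACC coupling plus age, sex
and residual noise.

All randomness derives from the mandatory integer seed; the same seed
reproduces a cohort bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from persotarget.symptom_association import SubjectFcVector
from persotarget.volumetric_io import (
    BinaryMask,
    BoldRun,
    VolumeGeometry,
    make_sphere_mask,
)

RUN_KEYS = ((1, "LR"), (1, "RL"), (2, "LR"), (2, "RL"))


@dataclass(frozen=True)
class CohortSpec:
    """Generator parameters.  Defaults give a 24^3 grid of 2-mm voxels
    (world span about +-23 mm), 300 time points at TR = 0.72 s, and a
    -0.8 peak coupling between the planted DLPFC blob and the sgACC."""

    n_subjects: int = 5
    grid: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = 2.0
    tr: float = 0.72
    nt: int = 300
    target_center_mm: tuple[float, float, float] = (-5.0, 2.0, 8.5)
    target_radius_mm: float = 4.0
    coupling_target: float = -0.8
    coupling_background_sd: float = 0.15
    coupling_background_fwhm_mm: float = 0.0  # 0 = spatially white
    coupling_subject_sd: float = 0.1
    # 5-mm smoothing shrinks unit white voxel noise to ~0.019 variance
    # while leaving the spatially smooth global component intact, so
    # amp 0.06 (variance 0.0036) leaves the global signal carrying
    # ~15 % of post-smoothing gray-matter variance and voxel-to-global
    # correlations around 0.4 — the residual level typical of real data
    # after nuisance regression.  Global-heavy cohorts override this.
    global_amp: float = 0.06
    global_loading_sd: float = 0.5
    global_loading_fwhm_mm: float = 12.0
    run_noise_sd: float = 1.0
    day_effect_sd: float = 0.05
    baseline: float = 1000.0
    bold_amp: float = 20.0
    band_hz: tuple[float, float] = (0.01, 0.1)
    # symptom-cohort parameters
    symptom_slope: float = 2.0
    symptom_noise_sd: float = 1.0
    symptom_intercept: float = 15.0
    age_coef: float = 0.1
    sex_coef: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.nt < 64:
            raise ValueError(f"nt must be >= 64, got {self.nt}")
        if self.seed is None:
            raise ValueError("a seed is mandatory")


@dataclass
class SyntheticMasks:
    brain: BinaryMask
    gray_matter: BinaryMask
    dlpfc: BinaryMask
    sgacc: BinaryMask
    wm: BinaryMask
    csf: BinaryMask
    target_blob: BinaryMask


def make_geometry(spec: CohortSpec) -> VolumeGeometry:
    """Axis-aligned RAS+ grid centered on the world origin."""
    vs = spec.voxel_size_mm
    origin = [-(d - 1) * vs / 2.0 for d in spec.grid]
    affine = np.diag([vs, vs, vs, 1.0])
    affine[:3, 3] = origin
    return VolumeGeometry(dims=spec.grid, affine=affine)


# Geometric-primitive mask layout (world mm) on the default grid; every
# region lies strictly inside the brain sphere, and WM/CSF/sgACC do not
# overlap the DLPFC.  The DLPFC is an elongated capsule (all points
# within a radius of a line segment) — an extended search region like
# the multi-sphere union masks used for real seed-based targeting —
# so a shallow connectivity landscape leaves room for the target to
# wander along the long axis while the planted blob sits at its middle.
_BRAIN_R = 21.0
_DLPFC_AXIS = ((-12.0, 6.0, 6.0), (2.0, -2.0, 11.0))
_DLPFC_R = 6.0
_SGACC_CENTER, _SGACC_R = (7.0, -7.0, -7.0), 6.0
_WM_CENTER, _WM_R = (10.0, 6.0, 2.0), 5.0
_CSF_CENTER, _CSF_R = (-6.0, -10.0, 2.0), 4.0


def _capsule_mask(a_mm, b_mm, radius_mm: float, geom: VolumeGeometry,
                  name: str = "capsule") -> BinaryMask:
    """Voxels whose centers lie within ``radius_mm`` of segment a-b."""
    a = np.asarray(a_mm, dtype=float)
    b = np.asarray(b_mm, dtype=float)
    nx, ny, nz = geom.dims
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    pts = geom.voxel_centers_mm(np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1))
    ab = b - a
    t = np.clip((pts - a) @ ab / (ab @ ab), 0.0, 1.0)
    nearest = a + t[:, None] * ab
    d = np.linalg.norm(pts - nearest, axis=1)
    return BinaryMask(data=(d <= radius_mm).reshape(geom.dims), geometry=geom, name=name)


def make_masks(spec: CohortSpec) -> SyntheticMasks:
    """Brain, gray-matter, DLPFC, sgACC, WM, CSF and planted-blob masks
    as spheres on the synthetic grid."""
    geom = make_geometry(spec)
    brain = make_sphere_mask((0.0, 0.0, 0.0), _BRAIN_R, geom, name="brain")
    dlpfc = _capsule_mask(_DLPFC_AXIS[0], _DLPFC_AXIS[1], _DLPFC_R, geom, name="dlpfc")
    sgacc = make_sphere_mask(_SGACC_CENTER, _SGACC_R, geom, name="sgacc")
    wm = make_sphere_mask(_WM_CENTER, _WM_R, geom, name="wm")
    csf = make_sphere_mask(_CSF_CENTER, _CSF_R, geom, name="csf")
    blob = make_sphere_mask(spec.target_center_mm, spec.target_radius_mm, geom, name="blob")
    if not np.all(dlpfc.data[blob.data]):
        raise ValueError("planted target blob extends outside the synthetic DLPFC mask")
    for region in (dlpfc, sgacc, wm, csf):
        if not np.all(brain.data[region.data]):
            raise ValueError(f"synthetic region {region.name} extends outside the brain")
    gray = BinaryMask(
        data=brain.data & ~wm.data & ~csf.data, geometry=geom, name="gray_matter"
    )
    return SyntheticMasks(
        brain=brain, gray_matter=gray, dlpfc=dlpfc, sgacc=sgacc, wm=wm, csf=csf,
        target_blob=blob,
    )


def band_limited_noise(
    rng: np.random.Generator,
    n_series: int,
    nt: int,
    tr: float,
    band: tuple[float, float] = (0.01, 0.1),
) -> np.ndarray:
    """Unit-variance noise whose spectrum is confined to ``band`` Hz."""
    freqs = np.fft.rfftfreq(nt, d=tr)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    if not keep.any():
        raise ValueError(f"band {band} Hz contains no Fourier bin at nt={nt}, tr={tr}")
    white = rng.standard_normal((n_series, nt))
    spec = np.fft.rfft(white, axis=1)
    spec[:, ~keep] = 0
    out = np.fft.irfft(spec, n=nt, axis=1)
    sd = out.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


@dataclass
class SubjectGroundTruth:
    subject_id: str
    blob_centroid_mm: np.ndarray
    blob_voxels: np.ndarray  # (k, 3)
    coupling_target: float  # subject-level peak coupling
    true_target_fc: float  # mean noiseless blob coupling
    couplings: dict = field(default_factory=dict)  # day -> per-brain-voxel field


def _coupling_field(
    spec: CohortSpec,
    masks: SyntheticMasks,
    subject_coupling: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-brain-voxel coupling to the latent sgACC signal.

    Planted-blob voxels couple at the subject's (negative) target
    strength; all other voxels — inside and outside the DLPFC — get
    heterogeneous background couplings (iid by default, optionally
    spatially smoothed); sgACC voxels carry the latent signal itself.
    """
    from scipy import ndimage

    geom = masks.brain.geometry
    brain_vox = masks.brain.voxel_indices()
    field = rng.standard_normal(geom.dims)
    if spec.coupling_background_fwhm_mm > 0:
        sigma_vox = [
            spec.coupling_background_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / vs
            for vs in geom.voxel_size
        ]
        field = ndimage.gaussian_filter(field, sigma=sigma_vox, mode="wrap")
    sd = field.std()
    if sd > 0:
        field = field / sd * spec.coupling_background_sd
    c = field[brain_vox[:, 0], brain_vox[:, 1], brain_vox[:, 2]]
    in_blob = masks.target_blob.data[brain_vox[:, 0], brain_vox[:, 1], brain_vox[:, 2]]
    c[in_blob] = subject_coupling
    in_sgacc = masks.sgacc.data[brain_vox[:, 0], brain_vox[:, 1], brain_vox[:, 2]]
    c[in_sgacc] = 1.0  # sgACC voxels carry the latent signal itself
    return np.clip(c, -0.95, 0.95)


def _smooth_loading_field(
    spec: CohortSpec,
    geom: VolumeGeometry,
    brain_vox: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Spatially smooth global-signal loading field (mean 1, SD
    ``global_loading_sd``, correlation length ``global_loading_fwhm_mm``),
    sampled at the brain voxels."""
    from scipy import ndimage

    sigma_vox = [
        spec.global_loading_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / vs
        for vs in geom.voxel_size
    ]
    white = rng.standard_normal(geom.dims)
    smooth = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="wrap")
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd * spec.global_loading_sd
    return 1.0 + smooth[brain_vox[:, 0], brain_vox[:, 1], brain_vox[:, 2]]


def simulate_subject(
    spec: CohortSpec,
    subject_index: int,
    masks: SyntheticMasks | None = None,
) -> tuple[list[BoldRun], SubjectGroundTruth]:
    """Four runs ((day, phase) in {1,2} x {LR, RL}) for one subject, plus
    the ground-truth record of the planted structure."""
    if masks is None:
        masks = make_masks(spec)
    geom = masks.brain.geometry
    rng = np.random.default_rng([spec.seed, subject_index])
    sid = f"sub-{subject_index:02d}"

    subject_coupling = spec.coupling_target + rng.normal(0.0, spec.coupling_subject_sd)
    base_field = _coupling_field(spec, masks, subject_coupling, rng)
    brain_vox = masks.brain.voxel_indices()
    sgacc_sel = masks.sgacc.data[brain_vox[:, 0], brain_vox[:, 1], brain_vox[:, 2]]
    gray_sel = masks.gray_matter.data[brain_vox[:, 0], brain_vox[:, 1], brain_vox[:, 2]]

    day_fields = {}
    for day in (1, 2):
        jitter = rng.normal(0.0, spec.day_effect_sd, size=len(base_field))
        jitter[sgacc_sel] = 0.0
        day_fields[day] = np.clip(base_field + jitter, -0.95, 0.95)

    # one latent sgACC signal per subject; runs differ through noise,
    # global-signal draws, and day-level coupling jitter
    latent = band_limited_noise(rng, 1, spec.nt, spec.tr, spec.band_hz)[0]

    runs = []
    for day, phase in RUN_KEYS:
        c = day_fields[day]
        noise = band_limited_noise(rng, len(brain_vox), spec.nt, spec.tr, spec.band_hz)
        g = band_limited_noise(rng, 1, spec.nt, spec.tr, spec.band_hz)[0]
        global_loading = _smooth_loading_field(spec, geom, brain_vox, rng)
        global_loading[~gray_sel] = 0.0  # global artifact lives in gray matter
        amp_noise = spec.run_noise_sd * np.sqrt(np.clip(1.0 - c**2, 0.0, None))
        series = c[:, None] * latent + amp_noise[:, None] * noise
        series = series + spec.global_amp * global_loading[:, None] * g[None, :]
        vol = np.zeros(geom.dims + (spec.nt,))
        vol[brain_vox[:, 0], brain_vox[:, 1], brain_vox[:, 2], :] = (
            spec.baseline + spec.bold_amp * series
        )
        runs.append(
            BoldRun(data=vol, geometry=geom, tr=spec.tr, subject_id=sid, day=day, phase=phase)
        )

    blob_vox = masks.target_blob.voxel_indices()
    blob_sel = masks.target_blob.data[brain_vox[:, 0], brain_vox[:, 1], brain_vox[:, 2]]
    truth = SubjectGroundTruth(
        subject_id=sid,
        blob_centroid_mm=masks.target_blob.world_coords_mm().mean(axis=0),
        blob_voxels=blob_vox,
        coupling_target=float(subject_coupling),
        true_target_fc=float(base_field[blob_sel].mean()),
        couplings={day: day_fields[day] for day in (1, 2)},
    )
    return runs, truth


def simulate_cohort(
    spec: CohortSpec,
) -> tuple[dict[str, list[BoldRun]], dict[str, SubjectGroundTruth], SyntheticMasks]:
    """All subjects' runs keyed by subject id, with ground truth."""
    masks = make_masks(spec)
    runs, truths = {}, {}
    for i in range(spec.n_subjects):
        r, t = simulate_subject(spec, i, masks)
        runs[t.subject_id] = r
        truths[t.subject_id] = t
    return runs, truths, masks


def simulate_cohort_with_scores(
    spec: CohortSpec,
) -> tuple[dict[str, list[BoldRun]], dict[str, SubjectGroundTruth], SyntheticMasks, pd.DataFrame]:
    """Cohort plus a symptom-score table.

    score = intercept + slope * trueFC + age and sex effects + noise,
    where trueFC is the subject's mean noiseless blob coupling.  Ages are
    drawn uniformly from 18-60 years; sex is Bernoulli(0.5) coded {0,1}.
    """
    runs, truths, masks = simulate_cohort(spec)
    rng = np.random.default_rng([spec.seed, 10_007])
    rows = []
    for sid, truth in truths.items():
        age = float(rng.uniform(18, 60))
        sex = int(rng.integers(0, 2))
        score = (
            spec.symptom_intercept
            + spec.symptom_slope * truth.true_target_fc
            + spec.age_coef * (age - 39.0)
            + spec.sex_coef * sex
            + rng.normal(0.0, spec.symptom_noise_sd)
        )
        rows.append({"subject": sid, "score": score, "age": age, "sex": sex,
                     "true_fc": truth.true_target_fc})
    return runs, truths, masks, pd.DataFrame(rows)


def global_heavy_spec(n_subjects: int = 10, seed: int = 0) -> CohortSpec:
    """The global-signal-heavy study condition.

    Two deliberate departures from the defaults define it: the global
    component dominates gray-matter variance (amp 2.0 instead of the
    post-cleanup residual 0.15), and the planted anticorrelation is
    weak (-0.25, the realistic magnitude of sgACC-DLPFC coupling in
    individual data) rather than the idealized -0.8 used for planted-
    recovery checks.  Seed-based targeting breaks down here without
    global signal regression because session-varying global structure
    perturbs a shallow correlation ranking; a dominant planted blob
    would anchor the retained cluster and mask the effect entirely.
    """
    return CohortSpec(
        n_subjects=n_subjects, seed=seed, global_amp=2.0, coupling_target=-0.25
    )


# ---------------------------------------------------------------------------
# Connectivity-level symptom cohorts (no volumes)


@dataclass
class FcCohortTruth:
    planted_voxels: np.ndarray  # indices into the sgACC voxel list
    slope: float
    sgacc_voxels: np.ndarray  # (n_vox, 3)


def simulate_fc_cohort(
    n_subjects: int = 60,
    slope: float = 2.0,
    noise_sd: float = 0.1,
    fc_subject_sd: float = 0.15,
    fc_voxel_sd: float = 0.02,
    planted_radius_mm: float = 4.0,
    seed: int = 0,
    spec: CohortSpec | None = None,
) -> tuple[list[SubjectFcVector], FcCohortTruth]:
    """Cohort of per-sgACC-voxel connectivity vectors with a planted
    score-FC association.

    Within a compact cluster of sgACC voxels (radius ``planted_radius_mm``
    around the sgACC center) every subject's FC is a shared subject-level
    value plus small voxel noise; elsewhere FC is independent noise.  The
    symptom score is ``slope`` times the subject-level FC plus age, sex
    and residual noise, so a voxel-wise regression should recover
    ``slope`` at planted voxels and nothing elsewhere.  ``slope=0`` gives
    a null cohort.

    The default noise levels are deliberately small: residual score
    noise 0.1 keeps the slope standard error near 0.09 at n = 60, and
    per-voxel FC noise 0.02 keeps measurement-error attenuation of the
    slope below 2 % — a high-signal regime for recovery checks rather
    than a realistic clinical effect size.
    """
    spec = spec or CohortSpec(seed=seed)
    masks = make_masks(spec)
    geom = masks.sgacc.geometry
    sg_vox = masks.sgacc.voxel_indices()
    coords = geom.voxel_centers_mm(sg_vox)
    d = np.linalg.norm(coords - np.asarray(_SGACC_CENTER), axis=1)
    planted = np.flatnonzero(d <= planted_radius_mm)
    rng = np.random.default_rng([seed, 20_011])
    cohort = []
    for i in range(n_subjects):
        u = rng.normal(0.2, fc_subject_sd)
        fc = rng.normal(0.1, fc_subject_sd, size=len(sg_vox))
        fc[planted] = u + rng.normal(0.0, fc_voxel_sd, size=len(planted))
        age = float(rng.uniform(18, 60))
        sex = int(rng.integers(0, 2))
        score = (
            15.0 + slope * u + 0.1 * (age - 39.0) + 1.0 * sex
            + rng.normal(0.0, noise_sd)
        )
        cohort.append(
            SubjectFcVector(subject_id=f"sub-{i:02d}", fc=fc, age=age, sex=sex, score=score)
        )
    return cohort, FcCohortTruth(planted_voxels=planted, slope=slope, sgacc_voxels=sg_vox)
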