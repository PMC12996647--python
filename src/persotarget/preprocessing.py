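"""Post-minimal-pipeline denoising of BOLD runs.

The pipeline order is fixed: spatial smoothing, then nuisance regression
(with the global signal optionally added as an extra column of the same
regression), then band-pass filtering.  All steps are deterministic.

Defaults mirror common practice for multiband resting-state data: 5-mm
FWHM smoothing, 6 motion parameters plus backward-difference derivatives,
5 white-matter/CSF principal components (aCompCor), and an ideal
0.01–0.1 Hz band-pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from persotarget.volumetric_io import BinaryMask, BoldRun

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class PreprocessingError(ValueError):
    pass


@dataclass
class ConfoundMatrix:
    """Named nuisance regressors, one row per time point."""

    values: np.ndarray
    column_names: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise PreprocessingError("confound matrix must be 2D (nt x k)")
        if self.values.shape[1] != len(self.column_names):
            raise PreprocessingError("column_names length does not match matrix width")
        if not np.all(np.isfinite(self.values)):
            raise PreprocessingError("confound matrix contains NaN/inf")

    @property
    def nt(self) -> int:
        return self.values.shape[0]

    def hstack(self, other: "ConfoundMatrix") -> "ConfoundMatrix":
        if other.nt != self.nt:
            raise PreprocessingError("confound matrices have different nt")
        return ConfoundMatrix(
            values=np.hstack([self.values, other.values]),
            column_names=self.column_names + other.column_names,
        )


def motion_with_derivatives(motion: np.ndarray) -> ConfoundMatrix:
    """Six motion parameters plus their backward-difference temporal
    derivatives (first row of each derivative set to zero, preserving nt)."""
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise PreprocessingError(f"expected nt x 6 motion parameters, got {motion.shape}")
    deriv = np.vstack([np.zeros((1, 6)), np.diff(motion, axis=0)])
    names = [f"mot{i}" for i in range(6)] + [f"mot{i}_deriv" for i in range(6)]
    return ConfoundMatrix(values=np.hstack([motion, deriv]), column_names=names)


def smooth_gaussian(run: BoldRun, fwhm_mm: float = 5.0) -> BoldRun:
    """Isotropic Gaussian smoothing of each volume.

    sigma = FWHM / (2 * sqrt(2 ln 2)) in mm, converted per-axis to voxel
    units via the voxel size.  Reflective boundaries, so a constant
    volume is exactly invariant.
    """
    if fwhm_mm <= 0:
        raise PreprocessingError(f"fwhm must be positive, got {fwhm_mm}")
    sigma_vox = [fwhm_mm * _FWHM_TO_SIGMA / vs for vs in run.geometry.voxel_size]
    out = ndimage.gaussian_filter(run.data, sigma=sigma_vox + [0.0], mode="reflect")
    return run.with_data(out)


def compcor_components(run: BoldRun, tissue_mask: BinaryMask, k: int = 5) -> ConfoundMatrix:
    """Top-k principal-component time series of the demeaned voxel x time
    matrix within a tissue (WM/CSF) mask, ordered by explained variance."""
    tissue_mask.require_nonempty()
    ts = run.data[tissue_mask.data]  # (n_vox, nt)
    if ts.shape[0] < k:
        raise PreprocessingError(f"tissue mask has {ts.shape[0]} voxels < k={k}")
    if run.nt <= k:
        raise PreprocessingError(f"nt={run.nt} must exceed k={k}")
    centered = ts - ts.mean(axis=1, keepdims=True)
    if np.allclose(centered, 0):
        raise PreprocessingError("tissue signals have zero variance")
    # PCA over time: right singular vectors are the component time series.
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    comps = vt[:k].T  # (nt, k)
    return ConfoundMatrix(values=comps, column_names=[f"compcor{i}" for i in range(k)])


def _design_matrix(confounds: ConfoundMatrix) -> np.ndarray:
    design = np.column_stack([np.ones(confounds.nt), confounds.values])
    demeaned = design[:, 1:] - design[:, 1:].mean(axis=0)
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(confounds.nt), demeaned]))
    if rank < design.shape[1]:
        # name the columns that add no rank, for the error message
        bad = []
        cols = [np.ones(confounds.nt)]
        for j, name in enumerate(confounds.column_names):
            trial = np.column_stack(cols + [confounds.values[:, j]])
            if np.linalg.matrix_rank(trial) == len(cols):
                bad.append(name)
            else:
                cols.append(confounds.values[:, j])
        raise PreprocessingError(f"collinear confound columns: {bad}")
    return design


def regress_nuisance(run: BoldRun, confounds: ConfoundMatrix) -> BoldRun:
    """Per-voxel OLS residuals after regressing intercept + confounds."""
    if confounds.nt != run.nt:
        raise PreprocessingError(f"confound nt={confounds.nt} != run nt={run.nt}")
    design = _design_matrix(confounds)
    flat = run.data.reshape(-1, run.nt).T  # (nt, n_vox)
    beta, *_ = np.linalg.lstsq(design, flat, rcond=None)
    resid = flat - design @ beta
    return run.with_data(resid.T.reshape(run.data.shape))


def bandpass(run: BoldRun, low_hz: float = 0.01, high_hz: float = 0.1) -> BoldRun:
    """Ideal (hard-cutoff) FFT band-pass: Fourier coefficients outside
    [low, high] Hz are zeroed; the mean (0 Hz) is removed."""
    nyquist = 0.5 / run.tr
    if not 0 < low_hz < high_hz:
        raise PreprocessingError(f"need 0 < low < high, got {low_hz}, {high_hz}")
    if high_hz >= nyquist:
        raise PreprocessingError(f"high={high_hz} Hz >= Nyquist {nyquist:.4f} Hz")
    freqs = np.fft.rfftfreq(run.nt, d=run.tr)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    spectrum = np.fft.rfft(run.data, axis=-1)
    spectrum[..., ~keep] = 0
    return run.with_data(np.fft.irfft(spectrum, n=run.nt, axis=-1))


def global_signal(run: BoldRun, brain_mask: BinaryMask) -> np.ndarray:
    """Mean time series over brain-mask voxels."""
    brain_mask.require_nonempty()
    return run.data[brain_mask.data].mean(axis=0)


def global_signal_regress(run: BoldRun, brain_mask: BinaryMask) -> BoldRun:
    """Regress the brain-wide mean time series (plus intercept) out of every
    voxel.  Residuals are exactly orthogonal to the global signal."""
    gs = global_signal(run, brain_mask)
    if np.var(gs) < 1e-30:
        raise PreprocessingError("global signal has zero variance")
    return regress_nuisance(run, ConfoundMatrix(values=gs[:, None], column_names=["global"]))


def preprocess_run(
    run: BoldRun,
    confounds: ConfoundMatrix | None = None,
    brain_mask: BinaryMask | None = None,
    fwhm_mm: float = 5.0,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
    gsr: bool = False,
    smooth: bool = True,
) -> BoldRun:
    """Full denoising pipeline: smooth -> nuisance regression (global
    signal appended as a column when ``gsr``) -> band-pass."""
    out = smooth_gaussian(run, fwhm_mm) if smooth else run
    cols = confounds
    if gsr:
        if brain_mask is None:
            raise PreprocessingError("GSR requires a brain mask")
        gs = ConfoundMatrix(values=global_signal(out, brain_mask)[:, None],
                            column_names=["global"])
        cols = gs if cols is None else cols.hstack(gs)
    if cols is not None:
        out = regress_nuisance(out, cols)
    return bandpass(out, low_hz, high_hz)
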