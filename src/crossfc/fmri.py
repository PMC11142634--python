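"""fMRI functional connectivity pipeline.

Region-averaged BOLD time series are cleaned with nuisance regression
(CSF, white matter, six motion parameters and global gray matter), band-pass
filtered at 0.009-0.08 Hz, motion-scrubbed at a framewise-displacement
threshold of 0.5 mm, and summarized as the unthresholded pairwise Pearson
correlation matrix.

The stage order is fixed: regress -> band-pass -> scrub -> correlate.
Filtering needs contiguous samples, so censoring happens last.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import Connectome

logger = logging.getLogger("crossfc")

FD_ROTATION_RADIUS_MM = 50.0
DEFAULT_FD_THRESHOLD_MM = 0.5
DEFAULT_BAND_HZ = (0.009, 0.08)
MIN_VOLUMES = 10


class FmriPipelineError(ValueError):
    pass


@dataclass
class BoldRegionSeries:
    """Region x time BOLD data with its confound table.

    ``confounds`` is volumes x K (CSF, WM, global gray matter, ...);
    the six motion parameters are kept separately because they feed both
    the regression and the framewise-displacement computation.
    """

    data: np.ndarray
    tr_s: float
    confounds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[1] < MIN_VOLUMES:
            raise FmriPipelineError(
                f"need at least {MIN_VOLUMES} volumes, got {self.data.shape[1]}"
            )
        if not np.all(np.isfinite(self.data)):
            raise FmriPipelineError("BOLD series contains non-finite values")
        if self.confounds is not None:
            self.confounds = np.atleast_2d(np.asarray(self.confounds, dtype=float))
            if self.confounds.shape[0] != self.data.shape[1]:
                raise FmriPipelineError(
                    "confound rows must align with volumes: "
                    f"{self.confounds.shape[0]} vs {self.data.shape[1]}"
                )


@dataclass
class ScrubMask:
    keep: np.ndarray
    fd: np.ndarray
    threshold_mm: float

    @property
    def n_removed(self) -> int:
        return int((~self.keep).sum())


def framewise_displacement(motion_params: np.ndarray) -> np.ndarray:
    """Power-style framewise displacement from a volumes x 6 motion table.

    Columns are three translations (mm) followed by three rotations (rad);
    rotations are converted to arc length on a 50 mm sphere.  ``fd[0] = 0``
    by convention.
    """
    mp = np.atleast_2d(np.asarray(motion_params, dtype=float))
    if mp.shape[1] != 6:
        raise FmriPipelineError(f"motion table must have 6 columns, got {mp.shape[1]}")
    delta = np.abs(np.diff(mp, axis=0))
    fd = np.zeros(mp.shape[0])
    fd[1:] = delta[:, :3].sum(axis=1) + FD_ROTATION_RADIUS_MM * delta[:, 3:].sum(axis=1)
    return fd


def scrub(
    series: np.ndarray,
    fd: np.ndarray,
    threshold_mm: float = DEFAULT_FD_THRESHOLD_MM,
) -> tuple[np.ndarray, ScrubMask]:
    """Censor volumes whose framewise displacement exceeds the threshold."""
    series = np.atleast_2d(np.asarray(series, dtype=float))
    fd = np.asarray(fd, dtype=float)
    if fd.shape[0] != series.shape[1]:
        raise FmriPipelineError("fd length must match number of volumes")
    keep = fd <= threshold_mm
    mask = ScrubMask(keep=keep, fd=fd, threshold_mm=threshold_mm)
    # the survivor minimum only applies to recordings long enough to meet it
    if keep.sum() < MIN_VOLUMES <= fd.size:
        raise FmriPipelineError(
            f"only {int(keep.sum())} volumes survive scrubbing (< {MIN_VOLUMES}); "
            "subject should be excluded"
        )
    if mask.n_removed:
        logger.info("scrubbed %d/%d volumes (FD > %.2f mm)",
                    mask.n_removed, fd.size, threshold_mm)
    return series[:, keep], mask


def nuisance_regress(series: np.ndarray, confounds: np.ndarray) -> np.ndarray:
    """Per-region OLS residuals against [intercept | confounds].

    Raises on a rank-deficient design, naming the first collinear column.
    """
    y = np.atleast_2d(np.asarray(series, dtype=float)).T  # volumes x regions
    c = np.atleast_2d(np.asarray(confounds, dtype=float))
    if c.shape[0] != y.shape[0]:
        raise FmriPipelineError("confound rows must align with volumes")
    x = np.column_stack([np.ones(y.shape[0]), c])
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify the first column that adds no rank
        bad = None
        for k in range(1, x.shape[1]):
            if np.linalg.matrix_rank(x[:, : k + 1]) < k + 1:
                bad = k - 1  # confound index (0-based, intercept excluded)
                break
        raise FmriPipelineError(
            f"rank-deficient nuisance design (confound column {bad} is collinear)"
        )
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return (y - x @ beta).T


def bandpass(
    series: np.ndarray,
    tr_s: float,
    low_hz: float = DEFAULT_BAND_HZ[0],
    high_hz: float = DEFAULT_BAND_HZ[1],
    order: int = 2,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the time axis.

    ``order`` is the per-pass filter order; forward-backward filtering
    doubles the effective roll-off and cancels the phase response.
    """
    fs = 1.0 / tr_s
    nyq = fs / 2.0
    if high_hz >= nyq:
        raise FmriPipelineError(
            f"upper edge {high_hz} Hz is not below Nyquist {nyq:.4f} Hz at TR {tr_s}s"
        )
    if low_hz <= 0 or low_hz >= high_hz:
        raise FmriPipelineError("band edges must satisfy 0 < low < high")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.atleast_2d(np.asarray(series, dtype=float)), axis=1)


def fmri_connectome(
    cleaned: np.ndarray,
    subject_id: str = "",
    n_samples_used: int | None = None,
) -> Connectome:
    """Unthresholded pairwise Pearson correlation of cleaned region series.

    Zero-variance regions get all their edges set to 0 (with a warning)
    rather than producing NaNs.
    """
    x = np.atleast_2d(np.asarray(cleaned, dtype=float))
    if x.shape[1] < MIN_VOLUMES:
        raise FmriPipelineError(f"need >= {MIN_VOLUMES} volumes to correlate")
    sd = x.std(axis=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance region(s); their edges set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r[flat, :] = 0.0
    r[:, flat] = 0.0
    r = np.nan_to_num(r, nan=0.0)
    np.fill_diagonal(r, 0.0)
    r = np.clip(0.5 * (r + r.T), -1.0, 1.0)
    return Connectome(
        values=r,
        modality="fmri",
        band="none",
        subject_id=subject_id,
        n_samples_used=x.shape[1] if n_samples_used is None else n_samples_used,
    )


def fmri_pipeline(
    bold: BoldRegionSeries,
    motion_params: np.ndarray,
    fd_threshold_mm: float = DEFAULT_FD_THRESHOLD_MM,
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
    subject_id: str = "",
) -> tuple[Connectome, ScrubMask]:
    """Full chain: nuisance regression, band-pass, scrubbing, correlation."""
    confounds = bold.confounds
    mp = np.atleast_2d(np.asarray(motion_params, dtype=float))
    if mp.shape[1] != 6:
        raise FmriPipelineError("motion table must have 6 columns")
    design = mp if confounds is None else np.column_stack([confounds, mp])
    cleaned = nuisance_regress(bold.data, design)
    filtered = bandpass(cleaned, bold.tr_s, *band_hz)
    fd = framewise_displacement(mp)
    censored, mask = scrub(filtered, fd, fd_threshold_mm)
    conn = fmri_connectome(censored, subject_id=subject_id,
                           n_samples_used=censored.shape[1])
    return conn, mask
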