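"""Band-wise EEG source connectivity via corrected imaginary coherency.

Region-averaged source time series are cut into non-overlapping segments of
one fMRI TR.  Per segment, cross-spectra are estimated with Hann-windowed
sub-windows of ``fs/2`` samples (2-Hz resolution, bin centers at
1, 3, ..., 59 Hz), the coherency ``C = S_xy / sqrt(S_xx S_yy)`` is formed,
and the corrected imaginary coherency

    ciCoh = sqrt( Im(C)^2 / (1 - Re(C)^2) )

(also called lagged coherence) is computed per 2-Hz bin.  Bins whose
coherence magnitude is not significant under the analytic null

    p = (1 - |C|^2) ** ((dof - 2) / 2)

at alpha = 0.05 are zeroed.  Bins are averaged into the five canonical
bands and segments are averaged over time (zeros included) into one FC_EEG
matrix per band; no threshold is applied to the final matrix.

Sub-windows do not overlap by default: under a white-noise null the
windowed DFT coefficients of disjoint windows are independent complex
Gaussians, which makes the analytic p exactly calibrated at
``dof = 2 * n_windows``.  Overlapping estimation is available through the
``overlap`` argument at the cost of that exactness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import windows

from .core import Connectome

logger = logging.getLogger("crossfc")

#: Canonical band edges in Hz (lower inclusive, upper exclusive except gamma).
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.3, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 60.0),
}

#: 2-Hz analysis bins: centers 1, 3, ..., 59 Hz.
BIN_CENTERS_HZ = np.arange(1.0, 60.0, 2.0)

MIN_SEGMENT_SAMPLES = 64
REJECTION_POLICIES = ("sd4", "amp300", "none")

_POWER_FLOOR = 1e-20


class EegPipelineError(ValueError):
    pass


@dataclass
class EegRegionSeries:
    """Region x sample EEG source series with sampling metadata."""

    data: np.ndarray
    fs: float
    segment_len_s: float
    units: str | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs < 100:
            raise EegPipelineError(f"sampling rate must be >= 100 Hz, got {self.fs}")
        if not np.all(np.isfinite(self.data)):
            raise EegPipelineError("EEG series contains non-finite values")


@dataclass
class SegmentSpectra:
    """Per-segment coherency spectrum.

    ``coherency`` is ``(R, R, B)`` complex, Hermitian in the region axes per
    bin; ``dof`` is twice the number of averaged sub-windows.
    """

    coherency: np.ndarray
    freqs_hz: np.ndarray
    dof: int

    def __post_init__(self) -> None:
        if self.dof < 4:
            raise EegPipelineError(f"dof must be >= 4, got {self.dof}")


def band_of_bin(center_hz: float) -> str | None:
    """Map a 2-Hz bin center to its band (None outside 0.3-60 Hz)."""
    for name, (lo, hi) in BANDS.items():
        if lo <= center_hz < hi or (name == "gamma" and center_hz == hi):
            return name
    return None


def band_bin_indices() -> dict[str, np.ndarray]:
    out: dict[str, list[int]] = {name: [] for name in BANDS}
    for k, c in enumerate(BIN_CENTERS_HZ):
        name = band_of_bin(c)
        if name is not None:
            out[name].append(k)
    return {name: np.asarray(idx, dtype=int) for name, idx in out.items()}


def segment(series: EegRegionSeries) -> list[np.ndarray]:
    """Cut into non-overlapping TR-length segments; drop the trailing rest."""
    L = int(round(series.fs * series.segment_len_s))
    if L < MIN_SEGMENT_SAMPLES:
        raise EegPipelineError(
            f"segment length {L} samples < {MIN_SEGMENT_SAMPLES}"
        )
    n = series.data.shape[1] // L
    if n == 0:
        raise EegPipelineError(
            f"recording shorter than one segment ({series.data.shape[1]} < {L})"
        )
    return [series.data[:, k * L : (k + 1) * L] for k in range(n)]


def reject_segments(
    segments: list[np.ndarray],
    policy: str = "none",
    units: str | None = None,
) -> tuple[list[np.ndarray], dict]:
    """Apply a segment-rejection rule.

    ``sd4`` drops segments in which any region exceeds its whole-recording
    mean by more than 4 whole-recording standard deviations; ``amp300``
    drops segments whose minimum/maximum crosses -300/+300 (requires the
    data to be in microvolts, declared via ``units="uV"``).
    """
    if policy not in REJECTION_POLICIES:
        raise EegPipelineError(f"unknown rejection policy {policy!r}")
    if policy == "none":
        return list(segments), {"policy": policy, "rejected": []}
    rejected = []
    if policy == "sd4":
        whole = np.concatenate(segments, axis=1)
        mean = whole.mean(axis=1, keepdims=True)
        sd = whole.std(axis=1, keepdims=True)
        sd[sd == 0] = np.inf  # flat region can never trip the rule
        for k, seg in enumerate(segments):
            if np.any(np.abs(seg - mean) > 4.0 * sd):
                rejected.append(k)
    else:  # amp300
        if units != "uV":
            raise EegPipelineError(
                "amp300 rejection needs amplitudes in microvolts (units='uV')"
            )
        for k, seg in enumerate(segments):
            if seg.min() < -300.0 or seg.max() > 300.0:
                rejected.append(k)
    kept = [seg for k, seg in enumerate(segments) if k not in set(rejected)]
    log = {"policy": policy, "rejected": rejected, "n_in": len(segments)}
    if rejected:
        logger.info("rejected %d/%d segments (%s)", len(rejected), len(segments), policy)
    return kept, log


def segment_coherency(
    seg: np.ndarray,
    fs: float,
    overlap: float = 0.0,
) -> SegmentSpectra:
    """Welch cross-spectral estimate of one segment at the 2-Hz bin centers.

    Hann sub-windows of ``fs/2`` samples; the FFT is zero-padded to one
    second so the spectrum is evaluated exactly at the odd-Hz bin centers.
    """
    seg = np.atleast_2d(np.asarray(seg, dtype=float))
    L = seg.shape[1]
    nper = int(round(fs / 2.0))
    step = max(1, int(round(nper * (1.0 - overlap))))
    starts = range(0, L - nper + 1, step)
    n_win = len(starts)
    if n_win < 2:
        raise EegPipelineError(
            f"segment of {L} samples yields {n_win} sub-window(s); need >= 2"
        )
    win = windows.hann(nper, sym=False)
    nfft = int(round(fs))
    # (n_win, R, nper) -> windowed FFT at 1-Hz spacing
    chunks = np.stack([seg[:, s : s + nper] for s in starts])
    spec = np.fft.rfft(chunks * win, n=nfft, axis=-1)
    centers = BIN_CENTERS_HZ[BIN_CENTERS_HZ < fs / 2.0]
    spec = spec[:, :, centers.astype(int)]  # 1-Hz spacing -> index == Hz
    s_full = np.einsum("wrf,wsf->rsf", spec, np.conj(spec)) / n_win
    auto = np.real(np.einsum("rrf->rf", s_full))
    denom = np.sqrt(auto[:, None, :] * auto[None, :, :])
    # bins carrying no genuine signal (absolute or relative to the region's
    # strongest bin) are treated as incoherent rather than 0/0
    floor = np.maximum(_POWER_FLOOR, 1e-12 * auto.max(axis=1, keepdims=True))
    low_power = (auto[:, None, :] < floor[:, None, :]) | (auto[None, :, :] < floor[None, :, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.where(low_power, 0.0, s_full / np.where(denom == 0, 1.0, denom))
    # enforce exact Hermitian symmetry and a unit-magnitude bound
    coh = 0.5 * (coh + np.conj(np.transpose(coh, (1, 0, 2))))
    mag = np.abs(coh)
    over = mag > 1.0
    if np.any(over):
        coh = np.where(over, coh / mag, coh)
    return SegmentSpectra(coherency=coh, freqs_hz=centers, dof=2 * n_win)


def cicoh(spectra: SegmentSpectra | np.ndarray) -> np.ndarray:
    """Corrected imaginary coherency (lagged coherence), clipped to [0, 1].

    ``ciCoh = sqrt(Im(C)^2 / (1 - Re(C)^2))``; where ``Re(C)^2 = 1`` the
    value is defined as 0 (a purely instantaneous, fully coherent pair has
    no lagged component).
    """
    c = spectra.coherency if isinstance(spectra, SegmentSpectra) else np.asarray(spectra)
    re2 = np.real(c) ** 2
    im2 = np.imag(c) ** 2
    denom = 1.0 - re2
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.sqrt(np.where(denom <= 0, 0.0, im2 / np.where(denom <= 0, 1.0, denom)))
    return np.clip(out, 0.0, 1.0)


def significance_mask(spectra: SegmentSpectra, alpha: float = 0.05) -> np.ndarray:
    """Analytic coherence significance: keep bins with ``p <= alpha``.

    ``p(|C|^2) = (1 - |C|^2) ** ((dof - 2) / 2)`` with ``dof`` the recorded
    degrees of freedom of the segment estimate.
    """
    if spectra.dof <= 2:
        raise EegPipelineError(f"significance test needs dof > 2, got {spectra.dof}")
    coh2 = np.clip(np.abs(spectra.coherency) ** 2, 0.0, 1.0)
    p = (1.0 - coh2) ** ((spectra.dof - 2) / 2.0)
    return p <= alpha


def coherence_pvalue(coh2: np.ndarray, dof: int) -> np.ndarray:
    """Analytic null p-value of a squared coherence estimate."""
    if dof <= 2:
        raise EegPipelineError(f"dof must exceed 2, got {dof}")
    return (1.0 - np.clip(np.asarray(coh2, dtype=float), 0.0, 1.0)) ** ((dof - 2) / 2.0)


def eeg_connectome(
    series: EegRegionSeries,
    policy: str = "none",
    alpha: float = 0.05,
    overlap: float = 0.0,
    subject_id: str = "",
) -> dict[str, Connectome]:
    """Full EEG stage: segment, reject, estimate, mask, band- and time-average."""
    segs = segment(series)
    kept, _ = reject_segments(segs, policy=policy, units=series.units)
    if not kept:
        raise EegPipelineError("no segments survive rejection")
    bins = band_bin_indices()
    r = series.data.shape[0]
    sums = {name: np.zeros((r, r)) for name in BANDS}
    for seg_data in kept:
        spectra = segment_coherency(seg_data, series.fs, overlap=overlap)
        values = cicoh(spectra)
        values = np.where(significance_mask(spectra, alpha=alpha), values, 0.0)
        present = {c: k for k, c in enumerate(spectra.freqs_hz)}
        for name, idx in bins.items():
            cols = [present[BIN_CENTERS_HZ[k]] for k in idx if BIN_CENTERS_HZ[k] in present]
            if cols:
                sums[name] += values[:, :, cols].mean(axis=2)
    out = {}
    for name in BANDS:
        m = sums[name] / len(kept)
        m = 0.5 * (m + m.T)
        np.fill_diagonal(m, 0.0)
        out[name] = Connectome(
            values=np.clip(m, 0.0, 1.0),
            modality="eeg",
            band=name,
            subject_id=subject_id,
            n_samples_used=len(kept),
        )
    return out
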