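"""Synthetic two-site, three-group multimodal cohort generator.

The generator emulates the study design the statistics are built for: two
acquisition sites (a fast-TR site with 1 kHz EEG and a slow-TR site with
250 Hz EEG), three groups (controls, left and right temporal lobe
epilepsy), 68 cortical regions and five EEG bands, with a controlled
ground-truth *cross-modal spatial coupling* between each group's mean EEG
and fMRI connectomes.

Coupling is induced at the edge-vector level: a shared latent edge
topology (distance-decaying, mimicking the strong empirical relationship
between connectivity strength and inter-centroid Euclidean distance) feeds
both modalities, and each EEG band mixes that latent with an independent
band-specific latent.  The mixture weight is calibrated numerically so
that the *realized* correlation between group-mean connectomes matches the
requested target despite the value-range squashing (tanh for Pearson fMRI
values, logistic for ciCoh EEG values) and finite group size.

A separate time-series mode emits region-level BOLD (+motion/confounds)
and EEG recordings that exercise the full connectivity pipelines:
narrow-band oscillations with quarter-cycle-lagged common drivers (so the
lagged coherence is non-zero), an instantaneous mixing component that the
corrected imaginary coherency must suppress, motion spikes that trigger
scrubbing, and amplitude artifacts that trigger segment rejection.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import signal as sp_signal
from scipy.special import expit

from .atlas import AtlasModel, default_atlas
from .core import CohortStack, Connectome, SubjectRecord, devectorize, n_edges
from .eeg import BANDS
from .io import write_connectome, write_metadata, write_timeseries_tsv

EEG_BAND_NAMES = tuple(BANDS)

# pre-squash value maps: fMRI = tanh(B_F + S_F * x), EEG = expit(B_E + S_E * x)
B_F, S_F = 0.3, 0.35
B_E, S_E = -1.6, 0.8

_CAL_REPS = 10  # internal Monte-Carlo repetitions used by the calibration
_MASK_CAL_REPS = 48  # repetitions for small-mask (intra-DMN) calibrations


class SimulationError(ValueError):
    pass


class CalibrationError(SimulationError):
    """The requested coupling target cannot be realized."""


@dataclass
class SiteParams:
    tr_s: float
    n_volumes: int
    eeg_fs: float
    n_segments: int

    def __post_init__(self) -> None:
        if self.tr_s <= 0:
            raise SimulationError("TR must be positive")


def _default_group_sizes() -> dict:
    # the study's per-site group sizes
    return {
        "control": {"site256": 21, "site64": 14},
        "lTLE": {"site256": 13, "site64": 3},
        "rTLE": {"site256": 10, "site64": 9},
    }


def _default_targets() -> dict:
    # controls/lTLE 0.40 everywhere; rTLE raised to 0.55 in delta-beta
    targets = {g: {b: 0.40 for b in EEG_BAND_NAMES} for g in ("control", "lTLE", "rTLE")}
    for b in ("delta", "theta", "alpha", "beta"):
        targets["rTLE"][b] = 0.55
    return targets


def _default_sites() -> dict:
    return {
        "site256": SiteParams(tr_s=2.0, n_volumes=150, eeg_fs=1000.0, n_segments=150),
        "site64": SiteParams(tr_s=3.6, n_volumes=350, eeg_fs=250.0, n_segments=350),
    }


@dataclass
class SimulationDesign:
    """Complete specification of a synthetic cohort.

    ``coupling_target[group][band]`` is the cross-modal spatial correlation
    the group-mean connectomes should realize; ``dmn_decoupling``
    multiplies the coupling of intra-default-mode-network edges for the
    ``dmn_flag`` (group, band) combination (default: beta-band decoupling
    in left TLE).
    """

    group_sizes: dict = field(default_factory=_default_group_sizes)
    coupling_target: dict = field(default_factory=_default_targets)
    dmn_decoupling: float = 0.75
    dmn_flag: tuple = ("lTLE", "beta")
    noise_sd: float = 1.0
    distance_decay_rate: float = 0.012  # 1/mm
    site_effect: float = 0.1
    eeg_mixing_strength: float = 0.3
    eeg_background_scale: float = 1.0
    eeg_artifact_rate: float = 0.02
    eeg_drivers: list | None = None
    motion_spike_rate: float = 0.02
    site_params: dict = field(default_factory=_default_sites)
    seed: int = 0

    def __post_init__(self) -> None:
        for g, per_band in self.coupling_target.items():
            for b, rho in per_band.items():
                if not -1.0 <= rho <= 1.0:
                    raise SimulationError(f"coupling target {rho} for {g}/{b} not in [-1, 1]")
        for g, per_site in self.group_sizes.items():
            for s, n in per_site.items():
                if n < 1:
                    raise SimulationError(f"group size must be >= 1 ({g}/{s}: {n})")
                if s not in self.site_params:
                    raise SimulationError(f"unknown site {s!r}")
        if self.distance_decay_rate < 0:
            raise SimulationError("distance decay rate must be >= 0")

    def group_n(self, group: str) -> int:
        return sum(self.group_sizes[group].values())

    def subject_plan(self) -> list[tuple[str, str]]:
        """Deterministic (group, site) sequence for the whole cohort."""
        plan = []
        for group in self.group_sizes:
            for site, n in self.group_sizes[group].items():
                plan.extend([(group, site)] * n)
        return plan

    def to_dict(self) -> dict:
        d = asdict(self)
        d["site_params"] = {k: asdict(v) if isinstance(v, SiteParams) else v
                            for k, v in self.site_params.items()}
        d["dmn_flag"] = list(self.dmn_flag)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationDesign":
        d = dict(d)
        if "site_params" in d:
            d["site_params"] = {k: SiteParams(**v) if isinstance(v, dict) else v
                                for k, v in d["site_params"].items()}
        if "dmn_flag" in d and d["dmn_flag"] is not None:
            d["dmn_flag"] = tuple(d["dmn_flag"])
        return cls(**d)


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *[int(s) for s in stream]])


def latent_topology(
    atlas: AtlasModel,
    decay_rate: float,
    seed: int,
    jitter_sd: float = 0.05,
) -> np.ndarray:
    """Distance-decaying base edge pattern, rescaled to [0, 1].

    ``w_ij = exp(-lambda * d_ij) + eps`` with ``d_ij`` the Euclidean
    centroid distance; lambda = 0 gives a flat pattern before the random
    perturbation.
    """
    if decay_rate < 0:
        raise SimulationError("decay rate must be >= 0")
    d = atlas.edge_distances()
    w = np.exp(-decay_rate * d)
    w = w + jitter_sd * _rng(seed, 1).standard_normal(w.size)
    lo, hi = w.min(), w.max()
    if hi - lo < 1e-12:
        return np.full_like(w, 0.5)
    return (w - lo) / (hi - lo)


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


@dataclass
class GroundTruth:
    """Everything needed to regenerate and audit a synthetic cohort."""

    seed: int
    latent01: np.ndarray
    band_latents: dict  # band -> standardized E-vector
    weights: dict  # (group, band) -> {"base": w, "dmn": w or None}
    realized_targets: dict  # (group, band) -> calibrated realized coupling
    dmn_mask: np.ndarray | None
    per_subject_coupling: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "weights": {f"{g}/{b}": w for (g, b), w in self.weights.items()},
            "realized_targets": {f"{g}/{b}": v for (g, b), v in self.realized_targets.items()},
            "per_subject_coupling": self.per_subject_coupling,
        }


def _site_shift_vector(design: SimulationDesign, group: str) -> np.ndarray:
    shifts = []
    for site, n in design.group_sizes[group].items():
        shift = design.site_effect if site == "site64" else 0.0
        shifts.extend([shift] * n)
    return np.asarray(shifts)


def _group_mean_fmri(u, eps, shifts, noise_sd):
    scale = np.sqrt(1.0 + noise_sd**2)
    pre = (u[None, :] + noise_sd * eps) / scale
    return np.tanh(B_F + shifts[:, None] + S_F * pre).mean(axis=0)


def _group_mean_eeg(shared, eta, shifts, noise_sd):
    scale = np.sqrt(1.0 + noise_sd**2)
    pre = (shared[None, :] + noise_sd * eta) / scale
    return expit(B_E + shifts[:, None] + S_E * pre).mean(axis=0)


def _realized_at(w, u, v, f_means, etas, shifts, noise_sd, mask=None) -> float:
    """Expected realized group-mean coupling at mixture weight ``w``.

    With a mask, everything is evaluated on the masked columns only; small
    masks therefore afford many more Monte-Carlo repetitions at equal cost.
    """
    if mask is not None:
        u, v = u[mask], v[mask]
        f_means = [f[mask] for f in f_means]
        etas = [eta[:, mask] for eta in etas]
    shared = w * u + np.sqrt(max(0.0, 1.0 - w * w)) * v
    vals = [
        _corr(f, _group_mean_eeg(shared, eta, shifts, noise_sd))
        for f, eta in zip(f_means, etas)
    ]
    return float(np.mean(vals))


def _calibrate_weight(
    target: float,
    u: np.ndarray,
    v: np.ndarray,
    f_means: list[np.ndarray],
    etas: list[np.ndarray],
    shifts: np.ndarray,
    noise_sd: float,
    mask: np.ndarray | None,
    tol: float = 5e-4,
) -> tuple[float, float]:
    """Bisect the latent mixture weight until the realized group-mean
    coupling matches ``target``.  Returns (weight, realized)."""

    def realized(w):
        return _realized_at(w, u, v, f_means, etas, shifts, noise_sd, mask)

    lo, hi = -0.9999, 0.9999
    r_lo, r_hi = realized(lo), realized(hi)
    if target > r_hi + tol:
        if noise_sd == 0 and target >= 0.95:
            return 1.0, realized(0.9999)  # degenerate rank-identical limit
        raise CalibrationError(
            f"coupling target {target:.3f} unreachable (max realizable {r_hi:.3f})"
        )
    if target < r_lo - tol:
        raise CalibrationError(
            f"coupling target {target:.3f} unreachable (min realizable {r_lo:.3f})"
        )
    for _ in range(45):
        mid = 0.5 * (lo + hi)
        r_mid = realized(mid)
        if abs(r_mid - target) < tol:
            return mid, r_mid
        if r_mid < target:
            lo = mid
        else:
            hi = mid
    mid = 0.5 * (lo + hi)
    return mid, realized(mid)


def _balance_over_blocks(v: np.ndarray, u: np.ndarray, blocks: list) -> np.ndarray:
    """Decorrelate ``v`` from ``u`` within each edge block and match spreads.

    The intra-ICN edge masks partition a small part of the edge set; without
    balancing, the empirical correlation of the two latents inside a given
    mask fluctuates like 1/sqrt(mask size), so the realized coupling of a
    subnetwork would drift far from the whole-brain target from one latent
    draw to the next.  Block-wise Gram-Schmidt plus spread matching makes
    the planted coupling hold uniformly across subnetwork masks.
    """
    v = v.copy()
    for block in blocks:
        if block.sum() < 3:
            continue
        ub, vb = u[block], v[block]
        uc = ub - ub.mean()
        resid = (vb - vb.mean()) - (vb - vb.mean()) @ uc / (uc @ uc) * uc
        sd = resid.std()
        if sd > 0:
            v[block] = vb.mean() + resid * (uc.std() / sd)
    return _standardize(v)


def build_ground_truth(design: SimulationDesign, atlas: AtlasModel) -> GroundTruth:
    """Latent topology plus calibrated per-(group, band) mixture weights."""
    e = n_edges(atlas.n_regions)
    latent01 = latent_topology(atlas, design.distance_decay_rate, design.seed)
    u = _standardize(latent01)
    blocks = [atlas.intra_network_mask(net) for net in atlas.networks]
    if blocks:
        blocks.append(~np.logical_or.reduce(blocks))  # inter-network remainder
    band_latents = {
        b: _balance_over_blocks(
            _standardize(_rng(design.seed, 2, k).standard_normal(e)), u, blocks
        )
        for k, b in enumerate(EEG_BAND_NAMES)
    }
    dmn_mask = None
    if design.dmn_flag is not None:
        dmn_mask = atlas.intra_network_mask("default-mode")
        if dmn_mask.sum() < 3:
            warnings.warn("atlas has <2 default-mode regions; DMN decoupling disabled")
            dmn_mask = None

    weights, realized_targets = {}, {}
    # common random numbers across groups: groups sharing a target calibrate
    # to (nearly) identical weights, so unflagged group contrasts are null
    cal_rng = _rng(design.seed, 3)
    n_max = max(design.group_n(g) for g in design.group_sizes)
    eps_f_all = [cal_rng.standard_normal((n_max, e)) for _ in range(_CAL_REPS)]
    etas_all = {
        band: [cal_rng.standard_normal((n_max, e)) for _ in range(_CAL_REPS)]
        for band in EEG_BAND_NAMES
    }
    for gi, group in enumerate(design.group_sizes):
        n = design.group_n(group)
        shifts = _site_shift_vector(design, group)
        f_means = [
            _group_mean_fmri(u, eps[:n], shifts, design.noise_sd) for eps in eps_f_all
        ]
        for bi, band in enumerate(EEG_BAND_NAMES):
            target = design.coupling_target[group][band]
            etas = [eta[:n] for eta in etas_all[band]]
            v = band_latents[band]
            flagged = (
                dmn_mask is not None
                and design.dmn_flag is not None
                and (group, band) == tuple(design.dmn_flag)
            )
            w_base, r_base = _calibrate_weight(
                target, u, v, f_means, etas, shifts, design.noise_sd, None
            )
            entry = {"base": w_base, "dmn": None}
            realized = {"base": r_base}
            if flagged:
                # decoupling is multiplicative on the coupling these edges
                # would otherwise realize (which fluctuates with the latent
                # draw on the small intra-DMN mask), so attenuate relative
                # to the base weight's own realized value on that mask; the
                # small mask affords many calibration repetitions at low cost
                m = int(dmn_mask.sum())
                u_m, v_m = u[dmn_mask], v[dmn_mask]
                mask_rng = _rng(design.seed, 7, gi, bi)
                eps_m = [mask_rng.standard_normal((n, m)) for _ in range(_MASK_CAL_REPS)]
                eta_m = [mask_rng.standard_normal((n, m)) for _ in range(_MASK_CAL_REPS)]
                f_means_m = [
                    _group_mean_fmri(u_m, eps, shifts, design.noise_sd) for eps in eps_m
                ]
                r_base_dmn = _realized_at(
                    w_base, u_m, v_m, f_means_m, eta_m, shifts, design.noise_sd
                )
                w_dmn, r_dmn = _calibrate_weight(
                    r_base_dmn * design.dmn_decoupling,
                    u_m, v_m, f_means_m, eta_m, shifts, design.noise_sd, None,
                )
                entry["dmn"] = w_dmn
                realized["dmn"] = r_dmn
            weights[(group, band)] = entry
            realized_targets[(group, band)] = realized
    return GroundTruth(
        seed=design.seed,
        latent01=latent01,
        band_latents=band_latents,
        weights=weights,
        realized_targets=realized_targets,
        dmn_mask=dmn_mask,
    )


def _edge_weight_vector(gt: GroundTruth, group: str, band: str, e: int) -> np.ndarray:
    entry = gt.weights[(group, band)]
    w = np.full(e, entry["base"])
    if entry["dmn"] is not None and gt.dmn_mask is not None:
        w[gt.dmn_mask] = entry["dmn"]
    return w


def sample_subject_connectomes(
    design: SimulationDesign,
    ground_truth: GroundTruth,
    group: str,
    site: str,
    subject_index: int,
    subject_id: str = "",
    bands: tuple = EEG_BAND_NAMES,
) -> dict:
    """Draw one subject's fMRI and band-wise EEG connectomes."""
    u = _standardize(ground_truth.latent01)
    e = u.size
    r = int(round((1 + np.sqrt(1 + 8 * e)) / 2))
    rng = _rng(design.seed, 4, subject_index)
    tau = design.noise_sd
    scale = np.sqrt(1.0 + tau**2)
    shift = design.site_effect if site == "site64" else 0.0
    site_p = design.site_params[site]

    pre_f = (u + tau * rng.standard_normal(e)) / scale
    fmri_vals = np.tanh(B_F + shift + S_F * pre_f)
    out = {
        ("fmri", "none"): Connectome(
            values=devectorize(fmri_vals, r),
            modality="fmri",
            band="none",
            subject_id=subject_id,
            n_samples_used=site_p.n_volumes,
        )
    }
    for band in bands:
        w = _edge_weight_vector(ground_truth, group, band, e)
        shared = w * u + np.sqrt(np.clip(1.0 - w * w, 0.0, 1.0)) * ground_truth.band_latents[band]
        pre_e = (shared + tau * rng.standard_normal(e)) / scale
        eeg_vals = expit(B_E + shift + S_E * pre_e)
        out[("eeg", band)] = Connectome(
            values=devectorize(eeg_vals, r),
            modality="eeg",
            band=band,
            subject_id=subject_id,
            n_samples_used=site_p.n_segments,
        )
    return out


# -- time-series mode ------------------------------------------------------


@dataclass
class SubjectTimeseries:
    """Raw synthetic recordings for one subject (time-series mode)."""

    bold: np.ndarray  # R x T
    motion: np.ndarray  # T x 6
    confounds: np.ndarray  # T x 3 (CSF, WM, global gray)
    eeg: np.ndarray  # R x N, microvolts
    tr_s: float
    eeg_fs: float


def _narrowband(rng, n, fs, lo, hi, order=3):
    nyq = fs / 2.0
    hi = min(hi, 0.95 * nyq)
    sos = sp_signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sp_signal.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def sample_region_timeseries(
    design: SimulationDesign,
    subject_connectomes: dict,
    site: str,
    subject_index: int,
) -> SubjectTimeseries:
    """Region-level BOLD + motion + confounds + EEG for one subject.

    BOLD is multivariate Gaussian with covariance matching the subject's
    target fMRI connectome, plus drift, a 0.15 Hz physiological component,
    confound leakage and motion-spike glitches.  EEG superposes per-band
    narrow-band background, quarter-cycle-lagged common drivers on the
    strongest target edges, an instantaneous mixing component, and
    occasional high-amplitude artifact segments.
    """
    site_p = design.site_params[site]
    t = site_p.n_volumes
    if t < 10:
        raise SimulationError(f"n_volumes must be >= 10, got {t}")
    rng = _rng(design.seed, 5, subject_index)

    fmri_target = subject_connectomes[("fmri", "none")].values
    r = fmri_target.shape[0]
    cov = fmri_target + np.eye(r)
    vals, vecs = np.linalg.eigh(cov)
    vals = np.clip(vals, 1e-4, None)
    root = vecs * np.sqrt(vals)
    bold = root @ rng.standard_normal((r, t))

    # drift + physiological component (both removed by the 0.009-0.08 Hz band-pass)
    time = np.arange(t) * site_p.tr_s
    drift = np.outer(rng.normal(0, 0.5, r), np.linspace(-1, 1, t))
    physio = np.outer(rng.normal(0, 0.4, r), np.sin(2 * np.pi * 0.15 * time + rng.uniform(0, 2 * np.pi)))
    # confounds: CSF/WM AR(1) processes leaking into regions; global gray = mean signal
    def ar1(n_):
        x = rng.standard_normal(n_)
        for k in range(1, n_):
            x[k] = 0.9 * x[k - 1] + 0.44 * x[k]
        return x / x.std()
    csf, wm = ar1(t), ar1(t)
    bold = bold + drift + physio
    bold += np.outer(rng.normal(0, 0.3, r), csf) + np.outer(rng.normal(0, 0.3, r), wm)
    gray = bold.mean(axis=0) + 0.05 * rng.standard_normal(t)
    confounds = np.column_stack([csf, wm, gray])

    # motion: smooth random walk with occasional spikes
    motion = np.cumsum(
        rng.normal(0, [0.02] * 3 + [4e-4] * 3, size=(t, 6)), axis=0
    )
    n_spikes = rng.binomial(t - 1, design.motion_spike_rate)
    spike_at = rng.choice(np.arange(1, t), size=n_spikes, replace=False) if n_spikes else []
    for s in spike_at:
        motion[s, :3] += rng.uniform(0.4, 1.2, 3) * rng.choice([-1, 1], 3)
        bold[:, s] += rng.normal(0, 3.0, r)  # glitch removed by scrubbing

    # -- EEG ---------------------------------------------------------------
    fs = site_p.eeg_fs
    seg_len = int(round(fs * site_p.tr_s))
    n = seg_len * site_p.n_segments
    base_amp = {"delta": 4.0, "theta": 3.0, "alpha": 3.0, "beta": 2.0, "gamma": 1.0}
    eeg = np.zeros((r, n))
    bg = design.eeg_background_scale
    if bg > 0:
        for band, (lo, hi) in BANDS.items():
            amp = bg * base_amp[band]
            for i in range(r):
                eeg[i] += amp * _narrowband(rng, n, fs, lo, hi)

    drivers = design.eeg_drivers
    if drivers is None:
        drivers = []
        for band in EEG_BAND_NAMES:
            key = ("eeg", band)
            if key not in subject_connectomes:
                continue
            edges = subject_connectomes[key].values
            iu, ju = np.triu_indices(r, k=1)
            vals_e = edges[iu, ju]
            if vals_e.size == 0:
                continue
            cut = np.quantile(vals_e, 0.99)
            for i, j, v in zip(iu, ju, vals_e):
                if v >= cut:
                    drivers.append((int(i), int(j), band, float(2.0 + 4.0 * v)))
    for (i, j, band, strength) in drivers:
        lo, hi = BANDS[band]
        carrier = _narrowband(rng, n, fs, lo, min(hi, 0.95 * fs / 2))
        analytic = sp_signal.hilbert(carrier)
        eeg[i] += strength * np.real(analytic)
        eeg[j] += strength * np.imag(analytic)  # exact quarter-cycle lag

    gamma = design.eeg_mixing_strength
    if gamma > 0 and r > 1:
        g = rng.standard_normal((r, r))
        g = 0.5 * (g + g.T)
        np.fill_diagonal(g, 0.0)
        g /= np.sqrt((g**2).sum(axis=1, keepdims=True)).clip(1e-12)
        eeg = eeg + gamma * (g @ eeg)

    eeg *= 6.0  # microvolt scale (background sd ~ 37 uV)
    if design.eeg_artifact_rate > 0:
        for k in range(site_p.n_segments):
            if rng.random() < design.eeg_artifact_rate:
                region = rng.integers(0, r)
                sl = slice(k * seg_len, (k + 1) * seg_len)
                eeg[region, sl] += rng.choice([-1, 1]) * rng.uniform(350, 500)

    return SubjectTimeseries(
        bold=bold, motion=motion, confounds=confounds, eeg=eeg,
        tr_s=site_p.tr_s, eeg_fs=fs,
    )


# -- cohort assembly -------------------------------------------------------


def _sample_covariates(design: SimulationDesign, group: str, idx: int):
    rng = _rng(design.seed, 6, idx)
    age = float(rng.uniform(18, 60))
    sex = "F" if rng.random() < 0.5 else "M"
    if group == "control":
        return age, sex, None, None, None
    duration = float(rng.uniform(1, 30))
    is_hs = bool(rng.random() < 0.5)
    ied = float(rng.exponential(0.3))
    return age, sex, duration, is_hs, ied


def generate_cohort(
    design: SimulationDesign,
    atlas: AtlasModel | None = None,
    out_dir=None,
    mode: str = "connectomes",
) -> tuple[CohortStack, GroundTruth]:
    """Generate a full synthetic cohort; optionally write it to disk.

    ``mode="timeseries"`` additionally emits per-subject BOLD, motion,
    confound and EEG recordings (requires ``out_dir``).
    """
    if mode not in ("connectomes", "timeseries"):
        raise SimulationError(f"unknown mode {mode!r}")
    if mode == "timeseries" and out_dir is None:
        raise SimulationError("timeseries mode writes to disk; out_dir is required")
    if atlas is None:
        atlas = default_atlas()
    gt = build_ground_truth(design, atlas)

    subjects = []
    per_subject = {b: [] for b in EEG_BAND_NAMES}
    for idx, (group, site) in enumerate(design.subject_plan()):
        sid = f"sub-{idx:03d}-{group}"
        age, sex, duration, is_hs, ied = _sample_covariates(design, group, idx)
        rec = SubjectRecord(
            subject_id=sid, group=group, age=age, sex=sex, site=site,
            epilepsy_duration=duration, is_hs=is_hs, ied_per_min=ied,
        )
        rec.connectomes = sample_subject_connectomes(
            design, gt, group, site, idx, subject_id=sid
        )
        fmri_edges = rec.connectome("fmri").edge_vector()
        for band in EEG_BAND_NAMES:
            per_subject[band].append(
                _corr(rec.connectome("eeg", band).edge_vector(), fmri_edges)
            )
        subjects.append(rec)
    gt.per_subject_coupling = {b: list(map(float, v)) for b, v in per_subject.items()}
    stack = CohortStack(subjects=subjects, atlas=atlas)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_metadata(subjects, out_dir / "metadata.tsv")
        (out_dir / "design.json").write_text(json.dumps(design.to_dict(), indent=1))
        (out_dir / "ground_truth.json").write_text(json.dumps(gt.to_dict(), indent=1))
        for idx, rec in enumerate(subjects):
            sub_dir = out_dir / rec.subject_id
            sub_dir.mkdir(exist_ok=True)
            write_connectome(rec.connectome("fmri"), sub_dir / "fc_fmri.tsv")
            for band in EEG_BAND_NAMES:
                write_connectome(rec.connectome("eeg", band), sub_dir / f"fc_eeg_{band}.tsv")
            if mode == "timeseries":
                ts = sample_region_timeseries(design, rec.connectomes, rec.site, idx)
                write_timeseries_tsv(ts.bold, sub_dir / "bold.tsv")
                write_timeseries_tsv(ts.motion, sub_dir / "motion.tsv")
                write_timeseries_tsv(ts.confounds, sub_dir / "confounds.tsv")
                write_timeseries_tsv(ts.eeg, sub_dir / "eeg.tsv")
    return stack, gt
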