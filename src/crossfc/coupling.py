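"""Group-level cross-modal coupling statistics.

The central quantity is the *cross-modal spatial correlation*: the Pearson
correlation, across upper-triangle edges, between a group-averaged EEG
connectome (one band) and the group-averaged fMRI connectome.  Group
differences in this coupling are tested by permuting group labels and
rebuilding the averaged matrices (one-sided, direction fixed a priori).

Also provided: split-half reliability of monomodal group averages, the
exact additive contribution decomposition of a Pearson correlation,
subnetwork (intrinsic-connectivity-network) restricted tests, hemisphere-
and distance-based exploratory analyses, and clinical sensitivity filters.

All permutation p-values use the add-one estimator ``(1 + b) / (1 + m)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .core import CohortStack, Connectome, group_average, vectorize_upper
from .eeg import BANDS
from .thresholds import bonferroni

EEG_BAND_NAMES = tuple(BANDS)

#: one-sided contrasts fixed a priori: (reference group, test group, direction)
DEFAULT_CONTRASTS = (
    ("control", "rTLE", "greater"),
    ("control", "lTLE", "less"),
)

SENSITIVITY_RULES = ("ied_le_1", "hs_only", "non_hs_only")


class CouplingError(ValueError):
    pass


# -- elementary statistics -------------------------------------------------


def _masked_edges(connectome_or_edges, edge_mask=None) -> np.ndarray:
    x = connectome_or_edges
    if isinstance(x, Connectome):
        x = x.edge_vector()
    x = np.asarray(x, dtype=float).ravel()
    if edge_mask is not None:
        x = x[np.asarray(edge_mask, dtype=bool)]
    return x


def crossmodal_correlation(group_mean_eeg, group_mean_fmri, edge_mask=None) -> float:
    """Pearson correlation of two group-mean edge vectors over a mask."""
    x = _masked_edges(group_mean_eeg, edge_mask)
    y = _masked_edges(group_mean_fmri, edge_mask)
    if x.size != y.size:
        raise CouplingError(f"edge vectors disagree: {x.size} vs {y.size}")
    if x.size < 3:
        raise CouplingError("need at least 3 edges")
    if x.std() == 0 or y.std() == 0:
        raise CouplingError("constant edge vector; correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class ContributionMap:
    """Exact additive decomposition of a Pearson correlation.

    ``c_i = z_x[i] * z_y[i] / r`` with the z-vectors normalized to unit sum
    of squares, so that ``sum(c) == 1`` and ``sum(z_x * z_y) == r``.
    """

    c: np.ndarray
    r: float
    z_x: np.ndarray
    z_y: np.ndarray
    band: str = ""
    group: str = ""


def spatial_contribution(x_edges, y_edges, band: str = "", group: str = "") -> ContributionMap:
    """Per-edge relative contribution to the Pearson correlation of x and y."""
    x = _masked_edges(x_edges)
    y = _masked_edges(y_edges)
    if x.size < 3:
        raise CouplingError("need at least 3 edges")
    xc, yc = x - x.mean(), y - y.mean()
    nx, ny = np.sqrt(xc @ xc), np.sqrt(yc @ yc)
    if nx == 0 or ny == 0:
        raise CouplingError("constant vector; contributions undefined")
    z_x, z_y = xc / nx, yc / ny
    r = float(z_x @ z_y)
    if abs(r) < 1e-12:
        raise CouplingError("r = 0; relative contributions undefined")
    return ContributionMap(c=z_x * z_y / r, r=r, z_x=z_x, z_y=z_y, band=band, group=group)


# -- vectorized permutation machinery -------------------------------------


def _rowwise_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    num = np.einsum("ij,ij->i", a, b)
    den = np.sqrt(np.einsum("ij,ij->i", a, a) * np.einsum("ij,ij->i", b, b))
    return num / den


def _rowwise_z(a: np.ndarray) -> np.ndarray:
    a = a - a.mean(axis=1, keepdims=True)
    return a / np.sqrt(np.einsum("ij,ij->i", a, a))[:, None]


def _random_indicators(n, n_b, n_perm, rng) -> np.ndarray:
    """(n_perm, n) 0/1 rows with exactly n_b ones each."""
    r = rng.random((n_perm, n))
    kth = np.partition(r, n_b - 1, axis=1)[:, n_b - 1 : n_b]
    return (r <= kth).astype(float)


def _permutation_engine(
    x_e: np.ndarray,
    x_f: np.ndarray,
    is_b: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    masks: dict,
    want_contribution: bool = False,
    chunk: int = 1000,
) -> dict:
    """Observed and label-permuted coupling statistics for a set of edge masks.

    Returns per mask name a dict with observed ``r_b``/``r_a`` and the null
    array of ``r_b - r_a``; with ``want_contribution`` also the observed and
    null intra-mask sums of the whole-brain contribution decomposition.
    """
    is_b = np.asarray(is_b, dtype=float)
    n = is_b.size
    n_b = int(is_b.sum())
    n_a = n - n_b
    if n_b == 0 or n_a == 0:
        raise CouplingError("both groups must be non-empty")
    col_e, col_f = x_e.sum(axis=0), x_f.sum(axis=0)
    mask_arrays = {
        name: (np.ones(x_e.shape[1], dtype=bool) if m is None else np.asarray(m, dtype=bool))
        for name, m in masks.items()
    }
    for name, m in mask_arrays.items():
        if m.sum() < 3:
            raise CouplingError(f"mask {name!r} selects fewer than 3 edges")

    def batch_stats(ind):
        sb_e, sb_f = ind @ x_e, ind @ x_f
        mb_e, mb_f = sb_e / n_b, sb_f / n_b
        ma_e, ma_f = (col_e - sb_e) / n_a, (col_f - sb_f) / n_a
        out = {}
        if want_contribution:
            prod_b = _rowwise_z(mb_e) * _rowwise_z(mb_f)
            prod_a = _rowwise_z(ma_e) * _rowwise_z(ma_f)
            r_b_all, r_a_all = prod_b.sum(axis=1), prod_a.sum(axis=1)
        for name, m in mask_arrays.items():
            r_b = _rowwise_corr(mb_e[:, m], mb_f[:, m])
            r_a = _rowwise_corr(ma_e[:, m], ma_f[:, m])
            entry = {"r_b": r_b, "r_a": r_a}
            if want_contribution:
                entry["c_b"] = prod_b[:, m].sum(axis=1) / r_b_all
                entry["c_a"] = prod_a[:, m].sum(axis=1) / r_a_all
            out[name] = entry
        return out

    observed = batch_stats(is_b[None, :])
    nulls = {name: {k: [] for k in observed[name]} for name in observed}
    done = 0
    while done < n_perm:
        take = min(chunk, n_perm - done)
        ind = _random_indicators(n, n_b, take, rng)
        stats = batch_stats(ind)
        for name in stats:
            for k, v in stats[name].items():
                nulls[name][k].append(v)
        done += take
    result = {}
    for name in observed:
        obs = {k: float(v[0]) for k, v in observed[name].items()}
        nul = {k: np.concatenate(v) for k, v in nulls[name].items()}
        result[name] = {
            "r_a": obs["r_a"],
            "r_b": obs["r_b"],
            "null_diff": nul["r_b"] - nul["r_a"],
        }
        if want_contribution:
            result[name]["c_a"] = obs["c_a"]
            result[name]["c_b"] = obs["c_b"]
            result[name]["null_c_diff"] = nul["c_b"] - nul["c_a"]
    return result


def _perm_pvalue(observed: float, null: np.ndarray, direction: str) -> float:
    if direction == "greater":
        b = int(np.sum(null >= observed))
    elif direction == "less":
        b = int(np.sum(null <= observed))
    else:
        raise CouplingError(f"direction must be 'greater' or 'less', got {direction!r}")
    return (1 + b) / (1 + null.size)


@dataclass
class CouplingResult:
    """Cross-modal coupling contrast with its permutation inference."""

    band: str
    group_a: str
    group_b: str
    r_a: float
    r_b: float
    statistic: float
    n_perm: int
    p_perm: float
    direction: str
    edge_mask: str = "whole-brain"
    seed: int | None = None


def _band_edges(stack: CohortStack, subjects, modality: str, band: str) -> np.ndarray:
    b = "none" if modality == "fmri" else band
    return np.stack([s.connectome(modality, b).edge_vector() for s in subjects])


def group_permutation_test(
    stack: CohortStack,
    group_a: str,
    group_b: str,
    band: str,
    modality_pair: tuple = ("eeg", "fmri"),
    direction: str = "greater",
    n_perm: int = 5000,
    seed: int | None = None,
    edge_mask=None,
    mask_name: str = "whole-brain",
) -> CouplingResult:
    """One-sided label-permutation test of the coupling difference
    ``r(group_b) - r(group_a)``.

    The null rebuilds both group-averaged matrices after randomly switching
    group labels (group sizes preserved).
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives a coarse p-value resolution", stacklevel=2)
    subs_a = stack.select(group=group_a).subjects
    subs_b = stack.select(group=group_b).subjects
    if not subs_a or not subs_b:
        raise CouplingError("both groups must be non-empty")
    subjects = subs_a + subs_b
    is_b = np.array([0.0] * len(subs_a) + [1.0] * len(subs_b))
    x_e = _band_edges(stack, subjects, modality_pair[0], band)
    x_f = _band_edges(stack, subjects, modality_pair[1], band)
    rng = np.random.default_rng(seed)
    res = _permutation_engine(x_e, x_f, is_b, n_perm, rng, {mask_name: edge_mask})[mask_name]
    stat = res["r_b"] - res["r_a"]
    return CouplingResult(
        band=band, group_a=group_a, group_b=group_b,
        r_a=res["r_a"], r_b=res["r_b"], statistic=stat,
        n_perm=n_perm, p_perm=_perm_pvalue(stat, res["null_diff"], direction),
        direction=direction, edge_mask=mask_name, seed=seed,
    )


# -- split-half reliability ------------------------------------------------


@dataclass
class SplitHalfResult:
    mean_r: float
    n_splits: int
    exhaustive: bool
    r_values: np.ndarray = field(repr=False, default=None)


def split_half_consistency(
    stack: CohortStack,
    group: str,
    modality: str,
    band: str = "none",
    n_iter: int = 5000,
    seed: int | None = None,
) -> SplitHalfResult:
    """Mean correlation between the averaged connectomes of two random
    half-cohorts.

    For even group sizes below 16 all distinct balanced splits are
    enumerated exactly once (complementary splits deduplicated by pinning
    the first subject to side A); otherwise ``n_iter`` random balanced
    splits are drawn, dropping one random subject per iteration when the
    group size is odd.
    """
    subs = stack.select(group=group).subjects
    n = len(subs)
    if n < 2:
        raise CouplingError(f"group {group!r} has {n} subject(s); need >= 2")
    edges = np.stack([s.connectome(modality, "none" if modality == "fmri" else band).edge_vector() for s in subs])
    rng = np.random.default_rng(seed)
    half = n // 2
    exhaustive = n < 16 and n % 2 == 0
    if exhaustive:
        others = list(range(1, n))
        rows = []
        for combo in combinations(others, half - 1):
            ind = np.zeros(n)
            ind[[0, *combo]] = 1.0
            rows.append(ind)
        ind_a = np.stack(rows)
    else:
        rows = []
        for _ in range(n_iter):
            order = rng.permutation(n)
            use = order[: 2 * half]  # odd n: one random subject left out
            ind = np.zeros(n)
            ind[use[:half]] = 1.0
            ind[use[half:]] = np.nan  # mark side B (others excluded entirely)
            rows.append(ind)
        ind_a = np.stack(rows)
    # side A mean vs side B mean per split
    a_mask = ind_a == 1.0
    b_mask = np.isnan(ind_a) if not exhaustive else (ind_a == 0.0)
    mean_a = (a_mask @ edges) / half
    mean_b = (b_mask @ edges) / (b_mask.sum(axis=1, keepdims=True))
    r = _rowwise_corr(mean_a, mean_b)
    return SplitHalfResult(
        mean_r=float(r.mean()), n_splits=r.size, exhaustive=exhaustive, r_values=r
    )


# -- subnetwork / hemisphere / distance analyses ---------------------------


def _network_masks(atlas, min_regions: int = 2) -> dict:
    masks = {}
    for net in atlas.networks:
        n_regions = sum(tag == net for tag in atlas.icn_assignment)
        if n_regions < min_regions:
            warnings.warn(f"network {net!r} has {n_regions} region(s); skipped", stacklevel=3)
            continue
        masks[net] = atlas.intra_network_mask(net)
    return masks


def subnetwork_coupling_tests(
    stack: CohortStack,
    atlas=None,
    bands: tuple = EEG_BAND_NAMES,
    contrasts: tuple = DEFAULT_CONTRASTS,
    n_perm: int = 5000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-(network, band) coupling contrasts plus contribution comparison.

    Each intrinsic connectivity network contributes its intra-network edge
    mask; coupling and the network-summed share of the whole-brain
    contribution decomposition are both compared between groups by label
    permutation.  The Bonferroni threshold is ``alpha / (n_bands * n_networks)``.
    """
    atlas = atlas or stack.atlas
    if atlas is None:
        raise CouplingError("an atlas with ICN assignments is required")
    masks = _network_masks(atlas)
    bonf = bonferroni(alpha, len(bands) * len(masks))
    rng = np.random.default_rng(seed)
    rows = []
    for group_a, group_b, direction in contrasts:
        subs_a = stack.select(group=group_a).subjects
        subs_b = stack.select(group=group_b).subjects
        subjects = subs_a + subs_b
        is_b = np.array([0.0] * len(subs_a) + [1.0] * len(subs_b))
        x_f = _band_edges(stack, subjects, "fmri", "none")
        for band in bands:
            x_e = _band_edges(stack, subjects, "eeg", band)
            res = _permutation_engine(
                x_e, x_f, is_b, n_perm, rng, masks, want_contribution=True
            )
            for net, r in res.items():
                stat = r["r_b"] - r["r_a"]
                c_stat = r["c_b"] - r["c_a"]
                rows.append(
                    {
                        "contrast": f"{group_b} vs {group_a}", "direction": direction,
                        "band": band, "network": net, "test": "coupling",
                        "value_a": r["r_a"], "value_b": r["r_b"], "statistic": stat,
                        "p_perm": _perm_pvalue(stat, r["null_diff"], direction),
                        "bonferroni_alpha": bonf,
                    }
                )
                rows.append(
                    {
                        "contrast": f"{group_b} vs {group_a}", "direction": direction,
                        "band": band, "network": net, "test": "contribution",
                        "value_a": r["c_a"], "value_b": r["c_b"], "statistic": c_stat,
                        "p_perm": _perm_pvalue(c_stat, r["null_c_diff"], direction),
                        "bonferroni_alpha": bonf,
                    }
                )
    df = pd.DataFrame(rows)
    df["significant"] = df["p_perm"] < df["bonferroni_alpha"]
    return df


def distance_fc_correlation(atlas, group_mean: Connectome | np.ndarray) -> float:
    """Correlation between edge-wise centroid distance and edge weight."""
    d = atlas.edge_distances()
    if d.std() == 0:
        raise CouplingError("degenerate centroids: all inter-region distances equal")
    w = _masked_edges(group_mean)
    if w.size != d.size:
        raise CouplingError("connectome does not match the atlas")
    return float(np.corrcoef(d, w)[0, 1])


def hemisphere_restricted_analysis(
    stack: CohortStack,
    hemisphere: str,
    atlas=None,
    bands: tuple = EEG_BAND_NAMES,
    contrasts: tuple = DEFAULT_CONTRASTS,
    n_perm: int = 5000,
    seed: int | None = None,
) -> list[CouplingResult]:
    """The main coupling battery restricted to intra-hemispheric edges."""
    atlas = atlas or stack.atlas
    if atlas is None:
        raise CouplingError("an atlas with hemisphere tags is required")
    mask = atlas.hemisphere_mask(hemisphere)
    rng = np.random.default_rng(seed)
    out = []
    for group_a, group_b, direction in contrasts:
        for band in bands:
            out.append(
                group_permutation_test(
                    stack, group_a, group_b, band,
                    direction=direction, n_perm=n_perm,
                    seed=int(rng.integers(2**31 - 1)),
                    edge_mask=mask, mask_name=f"intra-{hemisphere}",
                )
            )
    return out


# -- sensitivity analyses --------------------------------------------------


def apply_sensitivity_filter(stack: CohortStack, rule: str) -> CohortStack:
    """Clinical sensitivity filters on the patient population.

    ``ied_le_1`` removes patients with more than 1 interictal discharge per
    minute; ``hs_only``/``non_hs_only`` stratify by hippocampal sclerosis.
    Controls always pass.  A filter that empties a previously non-empty
    patient group raises.
    """
    if rule not in SENSITIVITY_RULES:
        raise CouplingError(f"unknown sensitivity rule {rule!r}")

    def keep(s):
        if not s.is_patient:
            return True
        if rule == "ied_le_1":
            return s.ied_per_min is None or s.ied_per_min <= 1.0
        if rule == "hs_only":
            return s.is_hs is True
        return s.is_hs is False  # non_hs_only

    kept = [s for s in stack.subjects if keep(s)]
    before = {g for g in stack.groups if g != "control"}
    after = {s.group for s in kept if s.is_patient}
    emptied = before - after
    if emptied:
        raise CouplingError(f"filter {rule!r} empties group(s) {sorted(emptied)}")
    return CohortStack(subjects=kept, atlas=stack.atlas)


def individual_level_coupling(
    stack: CohortStack,
    bands: tuple = EEG_BAND_NAMES,
    contrasts: tuple = DEFAULT_CONTRASTS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-subject coupling compared between groups by one-sided t tests.

    Individual coupling is the correlation between a subject's own EEG and
    fMRI edge vectors (much lower than the group-average coupling since
    subject noise does not average out).  Bonferroni threshold alpha/n_bands.
    """
    from scipy import stats as sp_stats

    per = {
        s.subject_id: {
            band: crossmodal_correlation(
                s.connectome("eeg", band), s.connectome("fmri")
            )
            for band in bands
        }
        for s in stack.subjects
    }
    bonf = bonferroni(alpha, len(bands))
    rows = []
    for group_a, group_b, direction in contrasts:
        a_ids = [s.subject_id for s in stack.select(group=group_a).subjects]
        b_ids = [s.subject_id for s in stack.select(group=group_b).subjects]
        for band in bands:
            a_vals = np.array([per[i][band] for i in a_ids])
            b_vals = np.array([per[i][band] for i in b_ids])
            t, p = sp_stats.ttest_ind(b_vals, a_vals, alternative=direction)
            rows.append(
                {
                    "contrast": f"{group_b} vs {group_a}", "direction": direction,
                    "band": band, "mean_a": a_vals.mean(), "mean_b": b_vals.mean(),
                    "t": float(t), "p": float(p), "bonferroni_alpha": bonf,
                    "significant": p < bonf,
                }
            )
    return pd.DataFrame(rows)


# -- statsmodels-style model facade ----------------------------------------


class CrossModalCoupling:
    """Cross-modal connectome coupling model for a multi-group cohort.

    Parameters
    ----------
    stack
        Cohort with fMRI and band-wise EEG connectomes per subject.
    bands
        EEG bands to analyze (default: the five canonical bands).
    edge_mask, mask_name
        Optional boolean edge restriction applied to every statistic.

    ``fit`` runs the group-coupling battery and returns a
    :class:`CrossModalCouplingResults`.
    """

    def __init__(self, stack: CohortStack, bands: tuple = EEG_BAND_NAMES,
                 edge_mask=None, mask_name: str = "whole-brain"):
        self.stack = stack
        self.bands = tuple(bands)
        self.edge_mask = edge_mask
        self.mask_name = mask_name

    def fit(self, contrasts: tuple = DEFAULT_CONTRASTS, n_perm: int = 5000,
            seed: int | None = None, alpha: float = 0.05) -> "CrossModalCouplingResults":
        rng = np.random.default_rng(seed)
        coupling = {}
        for group in self.stack.groups:
            for band in self.bands:
                eeg_mean = group_average(self.stack, group, "eeg", band)
                fmri_mean = group_average(self.stack, group, "fmri", "none")
                coupling[(group, band)] = crossmodal_correlation(
                    eeg_mean, fmri_mean, self.edge_mask
                )
        tests = [
            group_permutation_test(
                self.stack, a, b, band, direction=direction, n_perm=n_perm,
                seed=int(rng.integers(2**31 - 1)),
                edge_mask=self.edge_mask, mask_name=self.mask_name,
            )
            for (a, b, direction) in contrasts
            for band in self.bands
        ]
        return CrossModalCouplingResults(
            model=self, coupling=coupling, tests=tests,
            bonferroni_alpha=bonferroni(alpha, len(self.bands)),
            n_perm=n_perm, seed=seed,
        )

    def fit_subnetworks(self, n_perm: int = 5000, seed: int | None = None,
                        contrasts: tuple = DEFAULT_CONTRASTS, alpha: float = 0.05) -> pd.DataFrame:
        return subnetwork_coupling_tests(
            self.stack, bands=self.bands, contrasts=contrasts,
            n_perm=n_perm, seed=seed, alpha=alpha,
        )

    def fit_hemisphere(self, hemisphere: str, n_perm: int = 5000,
                       seed: int | None = None,
                       contrasts: tuple = DEFAULT_CONTRASTS) -> list[CouplingResult]:
        return hemisphere_restricted_analysis(
            self.stack, hemisphere, bands=self.bands, contrasts=contrasts,
            n_perm=n_perm, seed=seed,
        )


@dataclass
class CrossModalCouplingResults:
    """Fitted coupling battery: group couplings plus permutation contrasts."""

    model: CrossModalCoupling
    coupling: dict
    tests: list
    bonferroni_alpha: float
    n_perm: int
    seed: int | None

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "band": t.band, "contrast": f"{t.group_b} vs {t.group_a}",
                "direction": t.direction, "r_a": t.r_a, "r_b": t.r_b,
                "statistic": t.statistic, "p_perm": t.p_perm,
                "bonferroni_alpha": self.bonferroni_alpha,
                "significant": t.p_perm < self.bonferroni_alpha,
            }
            for t in self.tests
        ]
        return pd.DataFrame(rows)

    def group_coupling_table(self) -> pd.DataFrame:
        rows = [
            {"group": g, "band": b, "r": r} for (g, b), r in self.coupling.items()
        ]
        return pd.DataFrame(rows).pivot(index="group", columns="band", values="r")

    def plot(self, ax=None):
        """Bar plot of group-mean coupling per band."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        table = self.group_coupling_table()
        table.T.plot.bar(ax=ax, rot=0)
        ax.set_ylabel("cross-modal spatial correlation r")
        ax.set_xlabel("EEG band")
        ax.legend(title="group")
        return ax
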