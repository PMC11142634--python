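"""Monomodal edge-wise GLM with network-based-statistics correction.

Mass-univariate OLS is fitted per edge with the group indicator as the
regressor of interest and age, sex and site as nuisance covariates.  The
family-wise error of the resulting edge-wise t-map is controlled by the
network-based statistic: edges with ``t > T`` (one-sided, default T = 2)
form a graph over regions, and the size (edge count) of each connected
component is compared with the permutation null of the *maximum* component
size obtained by shuffling group labels (nuisance columns held fixed).

When run as the six-model battery (fMRI plus five EEG bands), the
component-level threshold is Bonferroni-adapted to ``alpha / 6``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .core import CohortStack, fisher_z, triu_indices_from_r
from .thresholds import bonferroni

DEFAULT_T_THRESHOLD = 2.0
N_BATTERY_MODELS = 6  # fMRI + five EEG bands


class NbsError(ValueError):
    pass


@dataclass
class EdgeGlmDesign:
    """Subjects x edges response with its subject-level design matrix."""

    response: np.ndarray  # n_subjects x E
    group: np.ndarray  # group indicator (1 = test group)
    nuisance: np.ndarray | None = None  # n_subjects x K

    def matrix(self) -> np.ndarray:
        n = self.response.shape[0]
        cols = [np.ones(n), np.asarray(self.group, dtype=float)]
        if self.nuisance is not None:
            nuis = np.atleast_2d(np.asarray(self.nuisance, dtype=float))
            if nuis.shape[0] != n:
                raise NbsError("nuisance rows must align with subjects")
            cols.extend(nuis.T)
        return np.column_stack(cols)


def edgewise_glm(design: EdgeGlmDesign, sign: int = 1) -> np.ndarray:
    """Per-edge t-statistic of the group coefficient.

    ``sign=+1`` tests group > reference; ``sign=-1`` flips the contrast.
    Raises on rank deficiency or when residual degrees of freedom vanish.
    """
    y = np.asarray(design.response, dtype=float)
    x = design.matrix()
    n, k = x.shape
    if n <= k + 1:
        raise NbsError(f"need n_subjects > n_covariates + 2 ({n} vs {k})")
    if np.linalg.matrix_rank(x) < k:
        raise NbsError("rank-deficient design (collinear covariates)")
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ (x.T @ y)
    resid = y - x @ beta
    sigma2 = np.einsum("ij,ij->j", resid, resid) / (n - k)
    se = np.sqrt(np.clip(sigma2 * xtx_inv[1, 1], 1e-300, None))
    return sign * beta[1] / se


def suprathreshold_components(
    t_map: np.ndarray, threshold: float, n_regions: int
) -> list[np.ndarray]:
    """Connected components of the graph of edges with ``t > threshold``.

    Returns per component the array of edge indices (into the canonical
    upper-triangle ordering), sorted by decreasing size.
    """
    if threshold <= 0:
        raise NbsError("first-level threshold must be positive")
    t_map = np.asarray(t_map, dtype=float)
    i, j = triu_indices_from_r(n_regions)
    keep = t_map > threshold
    if not keep.any():
        return []
    ik, jk = i[keep], j[keep]
    adj = sparse.coo_matrix(
        (np.ones(ik.size), (ik, jk)), shape=(n_regions, n_regions)
    )
    _, labels = connected_components(adj, directed=False)
    edge_idx = np.flatnonzero(keep)
    comp_of_edge = labels[ik]  # both endpoints share the component label
    comps = [edge_idx[comp_of_edge == c] for c in np.unique(comp_of_edge)]
    comps.sort(key=len, reverse=True)
    return comps


@dataclass
class NbsResult:
    """Edge-wise t-map plus NBS component-level inference."""

    t_map: np.ndarray
    components: list
    component_sizes: list
    corrected_p: list
    null_max_sizes: np.ndarray = field(repr=False)
    n_perm: int = 0
    threshold: float = DEFAULT_T_THRESHOLD
    alpha: float = bonferroni(0.05, N_BATTERY_MODELS)
    contrast: str = ""

    @property
    def max_component_size(self) -> int:
        return self.component_sizes[0] if self.component_sizes else 0

    @property
    def significant(self) -> list:
        return [
            comp for comp, p in zip(self.components, self.corrected_p) if p < self.alpha
        ]

    def summary(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "component": range(len(self.components)),
                "size_edges": self.component_sizes,
                "corrected_p": self.corrected_p,
                "significant": [p < self.alpha for p in self.corrected_p],
            }
        )


def nbs(
    stack: CohortStack,
    modality: str,
    band: str = "none",
    contrast: tuple = ("control", "rTLE", "greater"),
    threshold: float = DEFAULT_T_THRESHOLD,
    n_perm: int = 5000,
    alpha: float = bonferroni(0.05, N_BATTERY_MODELS),
    seed: int | None = None,
) -> NbsResult:
    """Network-based statistic for one monomodal group contrast.

    fMRI responses are Fisher z-transformed before the GLM; EEG band
    responses enter raw.  Only group labels are permuted; age, sex and
    site stay attached to their subjects.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives a coarse p-value resolution", stacklevel=2)
    group_a, group_b, direction = contrast
    subs = stack.select(group=group_a).subjects + stack.select(group=group_b).subjects
    if not subs:
        raise NbsError("empty contrast groups")
    n_regions = subs[0].connectome(modality, band if modality == "eeg" else "none").n_regions
    rows = []
    for s in subs:
        c = s.connectome(modality, band if modality == "eeg" else "none")
        if modality == "fmri" and c.transform == "none":
            c = fisher_z(c)
        rows.append(c.edge_vector())
    response = np.stack(rows)
    group = np.array([1.0 if s.group == group_b else 0.0 for s in subs])
    sites = sorted({s.site for s in subs})
    nuisance_cols = [
        [s.age for s in subs],
        [1.0 if s.sex == "F" else 0.0 for s in subs],
    ]
    if len(sites) > 1:
        nuisance_cols.append([float(sites.index(s.site)) for s in subs])
    nuisance = np.column_stack(nuisance_cols)
    sign = 1 if direction == "greater" else -1

    design = EdgeGlmDesign(response=response, group=group, nuisance=nuisance)
    t_obs = edgewise_glm(design, sign=sign)
    comps = suprathreshold_components(t_obs, threshold, n_regions)
    sizes = [len(c) for c in comps]

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    for p in range(n_perm):
        perm_design = EdgeGlmDesign(
            response=response, group=rng.permutation(group), nuisance=nuisance
        )
        t_null = edgewise_glm(perm_design, sign=sign)
        null_comps = suprathreshold_components(t_null, threshold, n_regions)
        null_max[p] = len(null_comps[0]) if null_comps else 0
    corrected = [
        float((1 + np.sum(null_max >= s)) / (1 + n_perm)) for s in sizes
    ]
    return NbsResult(
        t_map=t_obs, components=comps, component_sizes=sizes,
        corrected_p=corrected, null_max_sizes=null_max, n_perm=n_perm,
        threshold=threshold, alpha=alpha,
        contrast=f"{group_b} {'>' if sign == 1 else '<'} {group_a}",
    )


class NetworkBasedStatistic:
    """Model facade: NBS for one modality/band/contrast on a cohort."""

    def __init__(self, stack: CohortStack, modality: str, band: str = "none",
                 contrast: tuple = ("control", "rTLE", "greater"),
                 threshold: float = DEFAULT_T_THRESHOLD):
        self.stack = stack
        self.modality = modality
        self.band = band
        self.contrast = contrast
        self.threshold = threshold

    def fit(self, n_perm: int = 5000, alpha: float = bonferroni(0.05, N_BATTERY_MODELS),
            seed: int | None = None) -> NbsResult:
        return nbs(
            self.stack, self.modality, self.band, self.contrast,
            threshold=self.threshold, n_perm=n_perm, alpha=alpha, seed=seed,
        )
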