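"""Bootstrap-of-group-averages linear models for the cross-modal coupling.

Each bootstrap iteration resamples subjects with replacement from the
pooled model population, averages their connectomes, and records the
resulting cross-modal coupling ``r`` together with the iteration-averaged
covariates (mean age, sex ratio, group fraction, site fraction; the
patients-only model adds epilepsy duration, hippocampal-sclerosis fraction
and interictal-discharge rate).  An ordinary least squares fit of ``r`` on
the averaged covariates across iterations quantifies how each subject
characteristic moves the group-average coupling.

Coefficient significance is assessed against a permuted-covariate null:
the bootstrap distribution is rebuilt with the target covariate shuffled
across subjects, the model refitted, and the observed t-value compared to
the null t distribution (add-one permutation p, one-sided where a
direction is stated a priori).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import CohortStack

logger = logging.getLogger("crossfc")

MODEL_GROUPS = {
    "I": ("control", "lTLE"),
    "II": ("control", "rTLE"),
    "III": ("lTLE", "rTLE"),
}

#: a-priori one-sided directions for the group coefficient; other
#: covariates are tested two-sided.
MODEL_GROUP_DIRECTION = {"I": "less", "II": "greater", "III": "greater"}

MAX_CONSECUTIVE_REDRAWS = 50


class BootstrapModelError(ValueError):
    pass


@dataclass
class BootstrapModelResult:
    """Fitted bootstrap coupling model with permutation inference."""

    model_id: str
    band: str
    params: pd.Series
    tvalues: pd.Series
    p_perm: pd.Series
    directions: dict
    n_boot: int
    n_perm_null: int
    dropped: list
    ols_results: object = None

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.params,
                "t": self.tvalues,
                "direction": pd.Series(self.directions),
                "p_perm": self.p_perm,
            }
        )


def _rowwise_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    num = np.einsum("ij,ij->i", a, b)
    den = np.sqrt(np.einsum("ij,ij->i", a, a) * np.einsum("ij,ij->i", b, b))
    return num / den


def _ols_t(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """t-values of all coefficients of y ~ [1 | x]."""
    design = np.column_stack([np.ones(x.shape[0]), x])
    xtx_inv = np.linalg.inv(design.T @ design)
    beta = xtx_inv @ (design.T @ y)
    resid = y - design @ beta
    dof = design.shape[0] - design.shape[1]
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(np.diag(xtx_inv) * sigma2)
    return beta / se


class BootstrapCouplingModel:
    """Bootstrap linear model of the group-average EEG-fMRI coupling.

    Parameters
    ----------
    stack
        Cohort containing the two groups of the selected model.
    model_id
        ``"I"`` (controls vs lTLE), ``"II"`` (controls vs rTLE) or
        ``"III"`` (patients only, with clinical covariates).
    band
        EEG band whose coupling is modelled.
    """

    def __init__(self, stack: CohortStack, model_id: str, band: str):
        if model_id not in MODEL_GROUPS:
            raise BootstrapModelError(f"model_id must be one of {sorted(MODEL_GROUPS)}")
        self.model_id = model_id
        self.band = band
        group_a, group_b = MODEL_GROUPS[model_id]
        subs = (
            stack.select(group=group_a).subjects
            + stack.select(group=group_b).subjects
        )
        if not subs:
            raise BootstrapModelError("no subjects for the selected model")
        self.group_b = group_b
        cov, names, kept = self._build_covariates(subs, group_b)
        self.subjects = kept
        self.covariates = cov
        self.covariate_names = names
        self.x_eeg = np.stack([s.connectome("eeg", band).edge_vector() for s in kept])
        self.x_fmri = np.stack([s.connectome("fmri").edge_vector() for s in kept])

    def _build_covariates(self, subs, group_b):
        if self.model_id == "III":
            usable = [
                s for s in subs
                if s.epilepsy_duration is not None and s.is_hs is not None
                and s.ied_per_min is not None
            ]
            if len(usable) < len(subs):
                warnings.warn(
                    f"dropped {len(subs) - len(usable)} patient(s) with missing "
                    "clinical covariates", stacklevel=3,
                )
            subs = usable
        cols = {
            "age": [s.age for s in subs],
            "sex": [1.0 if s.sex == "F" else 0.0 for s in subs],
            "group": [1.0 if s.group == group_b else 0.0 for s in subs],
            "site": [1.0 if s.site == "site64" else 0.0 for s in subs],
        }
        if self.model_id == "III":
            cols["duration"] = [s.epilepsy_duration for s in subs]
            cols["is_hs"] = [1.0 if s.is_hs else 0.0 for s in subs]
            cols["ied_per_min"] = [s.ied_per_min for s in subs]
        self.dropped_covariates = []
        names = []
        keep_cols = []
        for name, vals in cols.items():
            v = np.asarray(vals, dtype=float)
            if np.ptp(v) == 0:
                warnings.warn(
                    f"covariate {name!r} is constant across subjects; excluded",
                    stacklevel=3,
                )
                self.dropped_covariates.append(name)
                continue
            names.append(name)
            keep_cols.append(v)
        if "group" not in names:
            raise BootstrapModelError("group indicator is constant; nothing to test")
        return np.column_stack(keep_cols), names, subs

    # -- fitting -----------------------------------------------------------

    def _bootstrap_distribution(self, rng, n_boot):
        """Bootstrap weights plus coupling r and covariate means per iteration."""
        n = len(self.subjects)
        for attempt in range(MAX_CONSECUTIVE_REDRAWS):
            w = rng.multinomial(n, np.full(n, 1.0 / n), size=n_boot) / n
            r = _rowwise_corr(w @ self.x_eeg, w @ self.x_fmri)
            cov_means = w @ self.covariates
            design = np.column_stack([np.ones(n_boot), cov_means])
            if np.linalg.matrix_rank(design) == design.shape[1]:
                return w, r, cov_means
            logger.warning("rank-deficient bootstrap design; redrawing (%d)", attempt + 1)
        raise BootstrapModelError(
            f"{MAX_CONSECUTIVE_REDRAWS} consecutive rank-deficient bootstrap draws"
        )

    def fit(
        self,
        n_boot: int = 1000,
        n_perm_null: int = 1000,
        seed: int | None = None,
        directions: dict | None = None,
    ) -> BootstrapModelResult:
        """Fit the bootstrap linear model and its permuted-covariate nulls."""
        rng = np.random.default_rng(seed)
        _, r, cov_means = self._bootstrap_distribution(rng, n_boot)
        exog = sm.add_constant(pd.DataFrame(cov_means, columns=self.covariate_names))
        ols = sm.OLS(r, exog).fit()
        t_obs = ols.tvalues.drop("const")

        if directions is None:
            directions = {name: "two-sided" for name in self.covariate_names}
            directions["group"] = MODEL_GROUP_DIRECTION[self.model_id]

        n = len(self.subjects)
        null_t = {name: np.empty(n_perm_null) for name in self.covariate_names}
        for it in range(n_perm_null):
            w, r_null, base_means = self._bootstrap_distribution(rng, n_boot)
            for k, name in enumerate(self.covariate_names):
                perm_col = rng.permutation(self.covariates[:, k])
                means = base_means.copy()
                means[:, k] = w @ perm_col
                t_all = _ols_t(means, r_null)
                null_t[name][it] = t_all[k + 1]  # +1 skips the intercept

        p_perm = {}
        for name in self.covariate_names:
            obs = t_obs[name]
            nt = null_t[name]
            direction = directions.get(name, "two-sided")
            if direction == "greater":
                b = int(np.sum(nt >= obs))
            elif direction == "less":
                b = int(np.sum(nt <= obs))
            else:
                b = int(np.sum(np.abs(nt) >= abs(obs)))
            p_perm[name] = (1 + b) / (1 + n_perm_null)

        return BootstrapModelResult(
            model_id=self.model_id, band=self.band,
            params=ols.params.drop("const"), tvalues=t_obs,
            p_perm=pd.Series(p_perm), directions=directions,
            n_boot=n_boot, n_perm_null=n_perm_null,
            dropped=self.dropped_covariates, ols_results=ols,
        )
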