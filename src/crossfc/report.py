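"""Behavioral/QC report: head-motion and data-retention group comparisons.

Mirrors the standard sanity check that group differences in coupling are
not driven by differential head motion or data loss: two-sided t tests of
mean framewise displacement, scrubbed fMRI volume counts and rejected EEG
segment counts between each patient group and controls, per site and
pooled.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

QC_METRICS = ("mean_fd", "n_scrubbed_volumes", "n_rejected_segments")


def subject_qc_row(subject_id, group, site, fd, scrub_mask=None, rejection_log=None) -> dict:
    """Assemble one subject's QC metrics from pipeline outputs."""
    fd = np.asarray(fd, dtype=float)
    n_scrubbed = int((~scrub_mask.keep).sum()) if scrub_mask is not None else 0
    n_rejected = len(rejection_log["rejected"]) if rejection_log else 0
    return {
        "subject_id": subject_id, "group": group, "site": site,
        "mean_fd": float(fd.mean()), "n_scrubbed_volumes": n_scrubbed,
        "n_rejected_segments": n_rejected,
    }


def qc_group_comparison(
    qc_table: pd.DataFrame,
    patient_groups: tuple = ("rTLE", "lTLE"),
    control_group: str = "control",
    per_site: bool = True,
) -> pd.DataFrame:
    """Two-sided Welch t tests of QC metrics, patients vs controls."""
    scopes = [("pooled", qc_table)]
    if per_site:
        scopes += [(site, df) for site, df in qc_table.groupby("site")]
    rows = []
    for scope, df in scopes:
        controls = df[df["group"] == control_group]
        for group in patient_groups:
            patients = df[df["group"] == group]
            if len(patients) < 2 or len(controls) < 2:
                continue
            for metric in QC_METRICS:
                if metric not in df.columns:
                    continue
                t, p = sp_stats.ttest_ind(
                    patients[metric], controls[metric], equal_var=False
                )
                rows.append(
                    {
                        "scope": scope, "contrast": f"{group} vs {control_group}",
                        "metric": metric,
                        "mean_patients": patients[metric].mean(),
                        "mean_controls": controls[metric].mean(),
                        "t": float(t), "p": float(p),
                    }
                )
    return pd.DataFrame(rows)
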