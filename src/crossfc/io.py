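"""File dialects: connectome TSVs, subject metadata tables, YAML configs.

Connectomes are stored as headerless TSVs of floats (diagonal written as 0)
with a JSON sidecar (``<path>.json``) carrying modality/band/subject_id and
the number of samples that survived scrubbing/rejection.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    CohortStack,
    Connectome,
    ConnectomeFormatError,
    ConnectomeValidationError,
    SubjectRecord,
    triu_indices_from_r,
)

logger = logging.getLogger("crossfc")

METADATA_COLUMNS = [
    "subject_id",
    "group",
    "age",
    "sex",
    "site",
    "duration_years",
    "is_hs",
    "ied_per_min",
]


def write_connectome(connectome: Connectome, path) -> Path:
    """Write a connectome matrix TSV plus its JSON metadata sidecar."""
    path = Path(path)
    np.savetxt(path, connectome.values, delimiter="\t", fmt="%.17g")
    sidecar = {
        "modality": connectome.modality,
        "band": connectome.band,
        "subject_id": connectome.subject_id,
        "n_samples_used": int(connectome.n_samples_used),
        "transform": connectome.transform,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_connectome(path, modality: str | None = None, band: str | None = None) -> Connectome:
    """Read a connectome TSV, symmetrizing mild asymmetry with a warning.

    Modality/band default to the sidecar values when a sidecar exists.
    Non-square input raises :class:`ConnectomeFormatError`; NaN off the
    diagonal raises :class:`ConnectomeValidationError`.
    """
    path = Path(path)
    m = np.loadtxt(path, delimiter="\t", ndmin=2)
    if m.shape[0] != m.shape[1]:
        raise ConnectomeFormatError(
            f"{path.name}: connectome must be square, got {m.shape}"
        )
    i, j = triu_indices_from_r(m.shape[0])
    if np.any(np.isnan(m[i, j])) or np.any(np.isnan(m[j, i])):
        raise ConnectomeValidationError(f"{path.name}: NaN off-diagonal entries")
    asym = np.max(np.abs(m - m.T), initial=0.0)
    if asym > 1e-12:
        logger.warning(
            "%s: asymmetric by %.3g; symmetrizing as (M + M.T)/2", path.name, asym
        )
        m = 0.5 * (m + m.T)
    meta = {}
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return Connectome(
        values=m,
        modality=modality or meta.get("modality", "fmri"),
        band=band or meta.get("band", "none"),
        subject_id=meta.get("subject_id", path.stem),
        n_samples_used=meta.get("n_samples_used", 0),
        transform=meta.get("transform", "none"),
    )


# -- subject metadata -----------------------------------------------------


def _opt(value):
    return None if pd.isna(value) else value


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ConnectomeFormatError(f"metadata table missing columns {sorted(missing)}")
    return df


def write_metadata(subjects, path) -> Path:
    rows = []
    for s in subjects:
        rows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "age": s.age,
                "sex": s.sex,
                "site": s.site,
                "duration_years": s.epilepsy_duration,
                "is_hs": s.is_hs,
                "ied_per_min": s.ied_per_min,
            }
        )
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(path, sep="\t", index=False)
    return Path(path)


def record_from_row(row) -> SubjectRecord:
    is_hs = _opt(row["is_hs"])
    if is_hs is not None:
        is_hs = bool(is_hs)
    return SubjectRecord(
        subject_id=str(row["subject_id"]),
        group=str(row["group"]),
        age=float(row["age"]),
        sex=str(row["sex"]),
        site=str(row["site"]),
        epilepsy_duration=_opt(row["duration_years"]),
        is_hs=is_hs,
        ied_per_min=_opt(row["ied_per_min"]),
    )


def load_cohort(cohort_dir, atlas=None, bands=("delta", "theta", "alpha", "beta", "gamma")) -> CohortStack:
    """Load a cohort directory written by the simulator or the CLI stages.

    Layout: ``metadata.tsv`` plus one subdirectory per subject containing
    ``fc_fmri.tsv`` and ``fc_eeg_<band>.tsv`` (each with JSON sidecars).
    """
    cohort_dir = Path(cohort_dir)
    meta = read_metadata(cohort_dir / "metadata.tsv")
    subjects = []
    for _, row in meta.iterrows():
        rec = record_from_row(row)
        sub_dir = cohort_dir / rec.subject_id
        fmri_path = sub_dir / "fc_fmri.tsv"
        if fmri_path.exists():
            rec.connectomes[("fmri", "none")] = read_connectome(fmri_path, "fmri", "none")
        for band in bands:
            p = sub_dir / f"fc_eeg_{band}.tsv"
            if p.exists():
                rec.connectomes[("eeg", band)] = read_connectome(p, "eeg", band)
        subjects.append(rec)
    return CohortStack(subjects=subjects, atlas=atlas)


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def read_timeseries_tsv(path) -> np.ndarray:
    """Region x time (or time x column) numeric TSV without header."""
    return np.loadtxt(path, delimiter="\t", ndmin=2)


def write_timeseries_tsv(array, path) -> Path:
    np.savetxt(path, np.asarray(array, dtype=float), delimiter="\t", fmt="%.10g")
    return Path(path)
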