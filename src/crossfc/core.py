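"""Core data model: connectomes, edge vectorization, group averaging.

Conventions used throughout the package
---------------------------------------
* A connectome is a symmetric ``R x R`` matrix with a zero diagonal; the
  diagonal never enters any statistic.
* The canonical edge vector is the row-major upper triangle with 0-based
  index pairs ``(0,1), (0,2), ..., (R-2, R-1)``, length ``E = R(R-1)/2``.
* fMRI connectomes hold Pearson correlations in ``[-1, 1]``; EEG connectomes
  hold corrected imaginary coherency (lagged coherence) values in ``[0, 1]``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger("crossfc")

MODALITIES = ("fmri", "eeg")
BAND_NAMES = ("none", "delta", "theta", "alpha", "beta", "gamma")
GROUPS = ("control", "lTLE", "rTLE")

_SYMMETRY_TOL = 1e-12


class ConnectomeFormatError(ValueError):
    pass


class ConnectomeValidationError(ValueError):
    pass


def triu_indices_from_r(r: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the canonical upper-triangle edge ordering."""
    return np.triu_indices(r, k=1)


def n_edges(r: int) -> int:
    return r * (r - 1) // 2


def r_from_n_edges(e: int) -> int:
    """Invert E = R(R-1)/2; raise if ``e`` is not a triangular number."""
    r = int(round((1 + np.sqrt(1 + 8 * e)) / 2))
    if n_edges(r) != e:
        raise ConnectomeFormatError(f"{e} is not a triangular number R(R-1)/2")
    return r


def vectorize_upper(matrix: np.ndarray) -> np.ndarray:
    """Extract the canonical upper-triangle edge vector of a square matrix."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ConnectomeFormatError(f"expected a square matrix, got {m.shape}")
    i, j = triu_indices_from_r(m.shape[0])
    return m[i, j].copy()


def devectorize(vector: np.ndarray, r: int | None = None) -> np.ndarray:
    """Rebuild a symmetric zero-diagonal matrix from an edge vector."""
    v = np.asarray(vector, dtype=float).ravel()
    if r is None:
        r = r_from_n_edges(v.size)
    elif n_edges(r) != v.size:
        raise ConnectomeFormatError(
            f"edge vector of length {v.size} does not match R={r}"
        )
    out = np.zeros((r, r), dtype=float)
    i, j = triu_indices_from_r(r)
    out[i, j] = v
    out[j, i] = v
    return out


@dataclass
class Connectome:
    """One subject's symmetric functional connectivity matrix.

    ``transform`` records value-domain transforms (``"fisher_z"``) so that
    range validation only applies to raw matrices.
    """

    values: np.ndarray
    modality: str
    band: str = "none"
    subject_id: str = ""
    n_samples_used: int = 0
    transform: str = "none"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ConnectomeFormatError(f"connectome must be square, got {v.shape}")
        if self.modality not in MODALITIES:
            raise ConnectomeValidationError(f"unknown modality {self.modality!r}")
        if self.band not in BAND_NAMES:
            raise ConnectomeValidationError(f"unknown band {self.band!r}")
        i, j = triu_indices_from_r(v.shape[0])
        if not np.all(np.isfinite(v[i, j])):
            raise ConnectomeValidationError("off-diagonal entries must be finite")
        if np.max(np.abs(v - v.T), initial=0.0) > _SYMMETRY_TOL:
            raise ConnectomeValidationError(
                "connectome not symmetric within 1e-12; symmetrize on read"
            )
        v = v.copy()
        np.fill_diagonal(v, 0.0)
        if self.transform == "none":
            off = v[i, j]
            if self.modality == "fmri" and (off.min(initial=0) < -1 or off.max(initial=0) > 1):
                raise ConnectomeValidationError("fMRI values must lie in [-1, 1]")
            if self.modality == "eeg" and (off.min(initial=0) < 0 or off.max(initial=0) > 1):
                raise ConnectomeValidationError("EEG ciCoh values must lie in [0, 1]")
        self.values = v

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def edge_vector(self) -> np.ndarray:
        return vectorize_upper(self.values)

    def key(self) -> tuple[str, str]:
        return (self.modality, self.band)


@dataclass
class SubjectRecord:
    """Metadata plus the connectomes of one subject.

    Clinical fields are ``None`` for controls (explicit missing, never 0).
    """

    subject_id: str
    group: str
    age: float
    sex: str
    site: str
    epilepsy_duration: float | None = None
    is_hs: bool | None = None
    ied_per_min: float | None = None
    connectomes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ConnectomeValidationError(f"unknown group {self.group!r}")
        if self.sex not in ("F", "M"):
            raise ConnectomeValidationError(f"sex must be F or M, got {self.sex!r}")
        if self.ied_per_min is not None and self.ied_per_min < 0:
            raise ConnectomeValidationError("ied_per_min must be non-negative")

    @property
    def is_patient(self) -> bool:
        return self.group != "control"

    def connectome(self, modality: str, band: str = "none") -> Connectome:
        return self.connectomes[(modality, band)]


@dataclass
class CohortStack:
    """Aligned collection of subjects sharing one atlas."""

    subjects: list
    atlas: object = None

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ConnectomeValidationError("subject_ids must be unique")
        sizes = {
            c.n_regions for s in self.subjects for c in s.connectomes.values()
        }
        if len(sizes) > 1:
            raise ConnectomeValidationError(
                f"connectomes disagree on region count: {sorted(sizes)}"
            )

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def groups(self) -> tuple[str, ...]:
        seen = []
        for s in self.subjects:
            if s.group not in seen:
                seen.append(s.group)
        return tuple(seen)

    def select(self, group: str | None = None, subject_ids=None) -> "CohortStack":
        subs = self.subjects
        if group is not None:
            subs = [s for s in subs if s.group == group]
        if subject_ids is not None:
            wanted = set(subject_ids)
            subs = [s for s in subs if s.subject_id in wanted]
        return CohortStack(subjects=list(subs), atlas=self.atlas)

    def edge_matrix(self, modality: str, band: str = "none") -> np.ndarray:
        """Stack subject edge vectors into an ``(n_subjects, E)`` array."""
        if not self.subjects:
            raise ConnectomeValidationError("empty cohort")
        return np.stack(
            [s.connectome(modality, band).edge_vector() for s in self.subjects]
        )

    def group_labels(self) -> np.ndarray:
        return np.array([s.group for s in self.subjects])


def group_average(
    stack: CohortStack,
    group: str | None,
    modality: str,
    band: str = "none",
) -> Connectome:
    """Element-wise mean connectome over the subjects matching ``group``.

    ``group=None`` averages the whole stack.  The number of averaged
    subjects is recorded in ``n_samples_used``.
    """
    sub = stack.select(group=group)
    if len(sub) == 0:
        raise ConnectomeValidationError(f"no subjects match group {group!r}")
    edges = sub.edge_matrix(modality, band)
    mean = edges.mean(axis=0)
    any_c = sub.subjects[0].connectome(modality, band)
    return Connectome(
        values=devectorize(mean, any_c.n_regions),
        modality=modality,
        band=band,
        subject_id=f"mean:{group or 'all'}",
        n_samples_used=len(sub),
        transform=any_c.transform,
    )


def fisher_z(connectome: Connectome, force: bool = False) -> Connectome:
    """Fisher z-transform (atanh) of an fMRI correlation connectome.

    Values at exactly +/-1 are clipped to +/-(1 - 1e-7) with a warning so
    that the transform stays finite.  Applying the transform to a non-fMRI
    connectome emits a warning (and requires ``force=True``): atanh of a
    coherence magnitude has no variance-stabilizing interpretation.
    """
    if connectome.modality != "fmri":
        warnings.warn(
            "fisher_z is intended for fMRI Pearson connectomes",
            stacklevel=2,
        )
        if not force:
            raise ConnectomeValidationError(
                "refusing fisher_z on non-fMRI connectome (pass force=True)"
            )
    v = connectome.values.copy()
    clip = 1.0 - 1e-7
    if np.any(np.abs(v) >= 1.0):
        warnings.warn("values at +/-1 clipped before atanh", stacklevel=2)
        v = np.clip(v, -clip, clip)
    z = np.arctanh(v)
    np.fill_diagonal(z, 0.0)
    return replace(connectome, values=z, transform="fisher_z")
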