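"""Cortical parcellation metadata.

An :class:`AtlasModel` carries everything the group statistics need to know
about the parcellation: region labels, hemisphere tags, centroid coordinates
(mm) and the assignment of each region to one of the seven canonical
intrinsic connectivity networks (ICNs).  The reference parcellation is the
68-region Desikan-Killiany cortical atlas.

The bundled file ``data/desikan68_synthetic_atlas.tsv`` uses the standard
Desikan region labels but *synthetic* centroid coordinates and a hand-built
Yeo-7 style network assignment: true centroids are subject-specific
FreeSurfer output and cannot be shipped.  The approximation preserves the
properties the analyses probe (hemispheric mirror symmetry, realistic
inter-centroid distances, a large default-mode network).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .core import triu_indices_from_r

ICN_TAGS = frozenset(
    {
        "visual",
        "somato-motor",
        "dorsal-attention",
        "ventral-attention",
        "limbic",
        "fronto-parietal",
        "default-mode",
        "unassigned",
    }
)

HEMISPHERES = ("L", "R")


class AtlasFormatError(ValueError):
    """Malformed or mutually inconsistent atlas files."""


class AtlasValidationError(ValueError):
    """Atlas content violating the domain invariants."""


@dataclass(frozen=True)
class AtlasModel:
    """Parcellation metadata for ``R`` cortical regions.

    Parameters
    ----------
    region_labels
        Unique region names, length ``R``.
    hemisphere
        Per-region tag in ``{"L", "R"}``.
    centroid_mm
        ``(R, 3)`` array of centroid coordinates in mm.
    icn_assignment
        Per-region intrinsic-connectivity-network tag drawn from
        :data:`ICN_TAGS`.
    """

    region_labels: tuple[str, ...]
    hemisphere: tuple[str, ...]
    centroid_mm: np.ndarray
    icn_assignment: tuple[str, ...]
    _edge_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        r = len(self.region_labels)
        if len(set(self.region_labels)) != r:
            raise AtlasValidationError("region labels must be unique")
        if len(self.hemisphere) != r or len(self.icn_assignment) != r:
            raise AtlasFormatError("atlas field lengths disagree")
        object.__setattr__(
            self, "centroid_mm", np.asarray(self.centroid_mm, dtype=float)
        )
        if self.centroid_mm.shape != (r, 3):
            raise AtlasFormatError(
                f"centroids must be (R, 3); got {self.centroid_mm.shape}"
            )
        if not np.all(np.isfinite(self.centroid_mm)):
            raise AtlasValidationError("centroids must be finite")
        bad_hemi = set(self.hemisphere) - set(HEMISPHERES)
        if bad_hemi:
            raise AtlasValidationError(f"unknown hemisphere tags: {sorted(bad_hemi)}")
        bad_icn = set(self.icn_assignment) - ICN_TAGS
        if bad_icn:
            raise AtlasValidationError(f"unknown ICN tags: {sorted(bad_icn)}")

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)

    @property
    def n_edges(self) -> int:
        r = self.n_regions
        return r * (r - 1) // 2

    @property
    def networks(self) -> tuple[str, ...]:
        """ICN names present in the atlas, excluding ``unassigned``."""
        seen = []
        for tag in self.icn_assignment:
            if tag != "unassigned" and tag not in seen:
                seen.append(tag)
        return tuple(seen)

    # -- edge-level geometry ------------------------------------------------

    def edge_distances(self) -> np.ndarray:
        """Euclidean centroid distance (mm) for each upper-triangle edge."""
        if "dist" not in self._edge_cache:
            i, j = triu_indices_from_r(self.n_regions)
            d = np.linalg.norm(self.centroid_mm[i] - self.centroid_mm[j], axis=1)
            self._edge_cache["dist"] = d
        return self._edge_cache["dist"]

    def intra_network_mask(self, network: str) -> np.ndarray:
        """Boolean edge mask selecting edges with both endpoints in ``network``."""
        if network not in ICN_TAGS:
            raise AtlasValidationError(f"unknown ICN tag: {network!r}")
        member = np.array([tag == network for tag in self.icn_assignment])
        i, j = triu_indices_from_r(self.n_regions)
        return member[i] & member[j]

    def hemisphere_mask(self, hemisphere: str) -> np.ndarray:
        """Boolean edge mask selecting intra-hemispheric edges."""
        if hemisphere not in HEMISPHERES:
            raise AtlasValidationError(f"hemisphere must be L or R, got {hemisphere!r}")
        member = np.array([h == hemisphere for h in self.hemisphere])
        i, j = triu_indices_from_r(self.n_regions)
        return member[i] & member[j]


def _frame_to_atlas(df: pd.DataFrame) -> AtlasModel:
    return AtlasModel(
        region_labels=tuple(df["label"].astype(str)),
        hemisphere=tuple(df["hemisphere"].astype(str)),
        centroid_mm=df[["x", "y", "z"]].to_numpy(dtype=float),
        icn_assignment=tuple(df["icn"].astype(str)),
    )


def load_atlas(labels_path, centroids_path=None, icn_path=None) -> AtlasModel:
    """Load an atlas from one combined TSV or from three aligned files.

    The combined dialect is a TSV with header
    ``label  hemisphere  x  y  z  icn``.  Alternatively three row-aligned
    files can be given: labels (``label``, ``hemisphere``), centroids
    (``x``, ``y``, ``z``) and ICN tags (single ``icn`` column).
    """
    if centroids_path is None and icn_path is None:
        df = pd.read_csv(labels_path, sep="\t")
        required = {"label", "hemisphere", "x", "y", "z", "icn"}
        if not required.issubset(df.columns):
            raise AtlasFormatError(
                f"combined atlas TSV must have columns {sorted(required)}"
            )
        return _frame_to_atlas(df)
    if centroids_path is None or icn_path is None:
        raise AtlasFormatError("provide either one combined TSV or all three files")
    labels = pd.read_csv(labels_path, sep="\t")
    centroids = pd.read_csv(centroids_path, sep="\t")
    icn = pd.read_csv(icn_path, sep="\t")
    if not (len(labels) == len(centroids) == len(icn)):
        raise AtlasFormatError(
            "atlas files have mismatched row counts: "
            f"{len(labels)}/{len(centroids)}/{len(icn)}"
        )
    df = pd.concat(
        [labels.reset_index(drop=True), centroids.reset_index(drop=True),
         icn.reset_index(drop=True)],
        axis=1,
    )
    return _frame_to_atlas(df)


def default_atlas() -> AtlasModel:
    """The bundled 68-region Desikan atlas (synthetic centroids/ICN tags)."""
    path = resources.files("crossfc.data") / "desikan68_synthetic_atlas.tsv"
    with resources.as_file(path) as p:
        return load_atlas(p)
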