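"""Core containers for landmark-based mandible morphometrics.

A specimen is a configuration of k homologous 2-D landmarks digitized in
buccal view (x increases anteriorly, y dorsally). Datasets carry the raw
coordinates in mm; after generalized Procrustes alignment they additionally
carry tangent-space coordinates and the consensus shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

#: Closed vocabulary of dietary groups (seven analysis groups + ungrouped).
DIET_GROUPS = (
    "fruits",
    "nuts",
    "seeds",
    "leaves",
    "herbivore_ss",
    "bark_gleaner",
    "insects",
    "ungrouped",
)

#: Closed vocabulary of locomotor groups.
LOCOMOTION_GROUPS = (
    "terrestrial",
    "arboreal_scansorial",
    "gliding",
    "ungrouped",
)


class DatasetInconsistencyError(ValueError):
    """Raised when specimens in one dataset disagree (e.g. mixed landmark counts)."""


class VocabularyError(ValueError):
    """Raised when a group label is outside the closed vocabulary."""


def centroid_size(coords: np.ndarray) -> float:
    """Centroid size: root summed squared landmark distances from the centroid.

    The standard geometric-morphometric size measure; homogeneous of degree 1
    in the coordinates and invariant to translation and rotation.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError(f"expected k x 2 coordinates, got shape {coords.shape}")
    centered = coords - coords.mean(axis=0)
    return float(np.sqrt(np.sum(centered**2)))


@dataclass(frozen=True)
class LandmarkConfiguration:
    """One specimen's raw k x 2 landmark coordinates (mm)."""

    specimen_id: str
    coords: np.ndarray  # (k, 2)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError(
                f"{self.specimen_id}: expected k x 2 coordinates, got {coords.shape}"
            )
        if coords.shape[0] < 3:
            raise ValueError(f"{self.specimen_id}: need at least 3 landmarks")
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"{self.specimen_id}: non-finite coordinate")
        object.__setattr__(self, "coords", coords)

    @property
    def k(self) -> int:
        return self.coords.shape[0]

    @property
    def centroid_size(self) -> float:
        return centroid_size(self.coords)


@dataclass(frozen=True)
class SpecimenRecord:
    """A landmark configuration plus its taxon and ecological labels."""

    configuration: LandmarkConfiguration
    taxon: str = ""
    diet: str = "ungrouped"
    locomotion: str = "ungrouped"

    def __post_init__(self) -> None:
        if self.diet not in DIET_GROUPS:
            raise VocabularyError(
                f"unknown diet {self.diet!r}; allowed: {DIET_GROUPS}"
            )
        if self.locomotion not in LOCOMOTION_GROUPS:
            raise VocabularyError(
                f"unknown locomotion {self.locomotion!r}; allowed: {LOCOMOTION_GROUPS}"
            )

    @property
    def specimen_id(self) -> str:
        return self.configuration.specimen_id

    @property
    def centroid_size(self) -> float:
        return self.configuration.centroid_size


@dataclass
class ShapeDataset:
    """Specimens with labels; optionally carries GPA results.

    After alignment, ``tangent_coords`` holds one length-2k row per specimen
    (orthogonal tangent projection at the consensus, expressed as full
    coordinates near the consensus so that averages remain shapes) and
    ``consensus`` the k x 2 mean configuration of unit centroid size.
    """

    specimens: list[SpecimenRecord]
    consensus: Optional[np.ndarray] = None  # (k, 2), unit CS
    tangent_coords: Optional[np.ndarray] = None  # (n, 2k)
    gpa_converged: bool = True
    mean_centroid_sizes: Optional[np.ndarray] = None  # per-record mean CS (taxon means)

    def __post_init__(self) -> None:
        if not self.specimens:
            raise DatasetInconsistencyError("dataset must contain at least one specimen")
        ks = {s.configuration.k for s in self.specimens}
        if len(ks) != 1:
            bad = next(
                s.specimen_id
                for s in self.specimens
                if s.configuration.k != self.specimens[0].configuration.k
            )
            raise DatasetInconsistencyError(
                f"mixed landmark counts {sorted(ks)}; first offending record: {bad}"
            )
        for s in self.specimens:
            if not s.taxon and s.taxon != "":
                raise DatasetInconsistencyError("empty taxon label")

    @property
    def k(self) -> int:
        return self.specimens[0].configuration.k

    @property
    def n(self) -> int:
        return len(self.specimens)

    @property
    def aligned(self) -> bool:
        return self.tangent_coords is not None

    @property
    def specimen_ids(self) -> list[str]:
        return [s.specimen_id for s in self.specimens]

    @property
    def taxa(self) -> list[str]:
        return [s.taxon for s in self.specimens]

    @property
    def diets(self) -> list[str]:
        return [s.diet for s in self.specimens]

    @property
    def locomotions(self) -> list[str]:
        return [s.locomotion for s in self.specimens]

    @property
    def centroid_sizes(self) -> np.ndarray:
        if self.mean_centroid_sizes is not None:
            return np.asarray(self.mean_centroid_sizes, dtype=float)
        return np.array([s.centroid_size for s in self.specimens])

    def require_aligned(self) -> np.ndarray:
        if self.tangent_coords is None:
            raise ValueError("dataset is not aligned; run gpa_align first")
        return self.tangent_coords

    def with_labels(
        self, diets: Sequence[str], locomotions: Sequence[str]
    ) -> "ShapeDataset":
        """Return a copy with per-specimen diet/locomotion labels replaced."""
        if len(diets) != self.n or len(locomotions) != self.n:
            raise ValueError("label sequences must match specimen count")
        new = [
            replace(s, diet=d, locomotion=l)
            for s, d, l in zip(self.specimens, diets, locomotions)
        ]
        return ShapeDataset(
            specimens=new,
            consensus=self.consensus,
            tangent_coords=self.tangent_coords,
            gpa_converged=self.gpa_converged,
            mean_centroid_sizes=self.mean_centroid_sizes,
        )


def shapes_to_matrix(shapes: Sequence[np.ndarray]) -> np.ndarray:
    """Stack k x 2 configurations into an (n, 2k) row matrix (x1 y1 x2 y2 ...)."""
    return np.stack([np.asarray(s, dtype=float).reshape(-1) for s in shapes])


def vector_to_shape(vec: np.ndarray) -> np.ndarray:
    """Fold a length-2k vector back to k x 2 landmark form."""
    vec = np.asarray(vec, dtype=float)
    if vec.size % 2:
        raise ValueError("tangent vector length must be even")
    return vec.reshape(-1, 2)
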