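"""Input data shapes: cross-sectional whole-bone sets and longitudinal LAG series."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


class ValidationError(ValueError):
    """Raised when a data set violates its structural invariants."""


@dataclass
class WholeBoneDataset:
    """Cross-sectional growth data: one (estimated age, bone dimension) per row.

    Ages are in years (from LAG counts, possibly retrocalculated upstream);
    dimensions in the unit given by ``units`` (cm for lengths, mm for
    circumferences in the source literature).
    """

    ages: np.ndarray
    dimensions: np.ndarray
    specimen_ids: Optional[Sequence[str]] = None
    dimension_type: str = "length"        # length | circumference | radial | mass
    bone: str = ""
    units: str = "cm"
    name: str = ""

    def __post_init__(self):
        self.ages = np.asarray(self.ages, float)
        self.dimensions = np.asarray(self.dimensions, float)
        if self.ages.ndim != 1 or self.ages.shape != self.dimensions.shape:
            raise ValidationError("ages and dimensions must be equal-length 1-d arrays")
        if self.n < 2:
            raise ValidationError("a whole-bone data set needs at least 2 points")
        if np.any(~np.isfinite(self.ages)) or np.any(~np.isfinite(self.dimensions)):
            raise ValidationError("non-finite age or dimension")
        if np.any(self.ages < 0):
            raise ValidationError("negative age")
        if np.any(self.dimensions <= 0):
            raise ValidationError("non-positive dimension")
        if self.specimen_ids is None:
            self.specimen_ids = [f"sp{i}" for i in range(self.n)]
        elif len(self.specimen_ids) != self.n:
            raise ValidationError("specimen_ids length mismatch")

    @property
    def n(self) -> int:
        return len(self.ages)

    def subset(self, idx) -> "WholeBoneDataset":
        idx = np.asarray(idx)
        return WholeBoneDataset(
            ages=self.ages[idx], dimensions=self.dimensions[idx],
            specimen_ids=[self.specimen_ids[i] for i in idx],
            dimension_type=self.dimension_type, bone=self.bone,
            units=self.units, name=self.name)


@dataclass
class LAGSeries:
    """Longitudinal growth history of one specimen.

    ``year_indices`` count years within the specimen (0, 1, 2, ...); the true
    hatching offset is unknown and recovered by alignment.  Dimensions must be
    strictly increasing — bone does not shrink between annual marks.
    """

    specimen_id: str
    year_indices: np.ndarray
    dimensions: np.ndarray
    bone: str = ""
    dimension_type: str = "circumference"
    units: str = "mm"

    def __post_init__(self):
        self.year_indices = np.asarray(self.year_indices, float)
        self.dimensions = np.asarray(self.dimensions, float)
        if self.year_indices.shape != self.dimensions.shape or self.year_indices.ndim != 1:
            raise ValidationError("year_indices and dimensions must match")
        if len(self.year_indices) == 0:
            raise ValidationError("empty LAG series")
        order = np.argsort(self.year_indices)
        self.year_indices = self.year_indices[order]
        self.dimensions = self.dimensions[order]
        if np.any(np.diff(self.year_indices) <= 0):
            raise ValidationError(f"{self.specimen_id}: duplicate year indices")
        if np.any(np.diff(self.dimensions) <= 0):
            raise ValidationError(
                f"{self.specimen_id}: dimensions must increase with year index")
        if np.any(self.dimensions <= 0):
            raise ValidationError(f"{self.specimen_id}: non-positive dimension")

    @property
    def n(self) -> int:
        return len(self.year_indices)
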