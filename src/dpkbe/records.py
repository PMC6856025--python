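"""In-memory containers for tape-stripping study data."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .design import StudyDesign

__all__ = [
    "UPTAKE",
    "CLEARANCE",
    "PHASES",
    "TapeGroupRecord",
    "SiteRecord",
    "SubjectProductSummary",
    "ValidationError",
    "SchemaError",
    "IntegrityError",
]

UPTAKE = "uptake"
CLEARANCE = "clearance"
PHASES = (UPTAKE, CLEARANCE)


class ValidationError(ValueError):
    """A field value violates a domain invariant."""


class SchemaError(ValueError):
    """The input table is missing required structure (e.g. a column)."""


class IntegrityError(ValueError):
    """The input table contains contradictory rows (e.g. duplicates)."""


@dataclass(frozen=True)
class TapeGroupRecord:
    """One group of pooled tape-strips from a single site.

    ``group_index`` orders groups from the skin surface inward; ``sc_mass_mg``
    is the SC mass removed by the group and ``extract_concentration_ug_ml``
    the drug concentration assayed in the pooled extract.
    """

    subject_id: str
    product_code: str
    phase: str
    replicate_index: int
    group_index: int
    sc_mass_mg: float
    extract_concentration_ug_ml: float
    n_tapes_in_group: int = 1

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValidationError(
                f"phase must be one of {PHASES}, got {self.phase!r}"
            )
        if self.sc_mass_mg < 0:
            raise ValidationError("sc_mass_mg must be >= 0")
        if self.extract_concentration_ug_ml < 0:
            raise ValidationError("extract_concentration_ug_ml must be >= 0")
        if self.n_tapes_in_group < 1:
            raise ValidationError("n_tapes_in_group must be >= 1")


@dataclass
class SiteRecord:
    """All tape groups from one application site, surface to depth.

    Optionally carries the TEWL record for the site: the pre-stripping
    baseline plus one reading per tape (g m^-2 h^-1), used by the
    stopping-rule check.
    """

    design: StudyDesign
    groups: Sequence[TapeGroupRecord]
    tewl_baseline: Optional[float] = None
    tewl_series: Optional[Sequence[float]] = None

    def __post_init__(self) -> None:
        if len(self.groups) == 0:
            raise ValidationError("SiteRecord needs at least one tape group")
        first = self.groups[0]
        key = (first.subject_id, first.product_code, first.phase, first.replicate_index)
        for g in self.groups:
            if (g.subject_id, g.product_code, g.phase, g.replicate_index) != key:
                raise IntegrityError(
                    "all tape groups in a SiteRecord must share "
                    "subject/product/phase/replicate"
                )
        idx = [g.group_index for g in self.groups]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise IntegrityError(
                "group_index must be strictly increasing within a site"
            )

    @property
    def subject_id(self) -> str:
        return self.groups[0].subject_id

    @property
    def product_code(self) -> str:
        return self.groups[0].product_code

    @property
    def phase(self) -> str:
        return self.groups[0].phase

    @property
    def replicate_index(self) -> int:
        return self.groups[0].replicate_index

    @property
    def n_tapes(self) -> int:
        return sum(g.n_tapes_in_group for g in self.groups)

    @property
    def key(self) -> tuple:
        return (self.subject_id, self.product_code, self.phase, self.replicate_index)


@dataclass(frozen=True)
class SubjectProductSummary:
    """Per-subject geometric-mean drug amounts for one product.

    ``q_up`` and ``q_cl`` (ug/cm^2) are geometric means over the replicate
    sites of the uptake and clearance phases; positivity is guaranteed
    upstream by the LOQ substitution rule.
    """

    subject_id: str
    product_code: str
    q_up: float
    q_cl: float
    n_replicates_used: int = field(default=1)

    def __post_init__(self) -> None:
        if not (self.q_up > 0 and self.q_cl > 0):
            raise ValidationError("q_up and q_cl must be positive")
        if self.n_replicates_used < 1:
            raise ValidationError("n_replicates_used must be >= 1")


def geometric_mean(values: Sequence[float]) -> float:
    """Geometric mean of strictly positive values."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("geometric mean of empty sequence")
    if np.any(arr <= 0):
        raise ValueError("geometric mean requires positive values")
    return float(np.exp(np.mean(np.log(arr))))
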