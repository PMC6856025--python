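"""Study design parameters and the tape-stripping stopping rule.

A two-time-point stratum-corneum sampling study applies each product for a
fixed uptake period (``t_up_h``), removes it, and samples a second set of
sites after a further clearance interval (``delta_t_h``).  The design object
carries every protocol constant the downstream calculations need: sampled
area, extraction volume, assay limit of quantification, SC density, and the
replication structure (``n_subjects`` subjects x ``n_replicates`` sites per
product per phase).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

__all__ = ["StudyDesign", "StoppingRule", "load_design"]


@dataclass(frozen=True)
class StudyDesign:
    """Protocol constants for one tape-stripping study.

    Parameters
    ----------
    t_up_h : float
        Duration of the uptake (application) period, hours.
    delta_t_h : float
        Interval between product removal and clearance sampling, hours.
    area_cm2 : float
        Skin area sampled through the template, cm^2.
    extract_volume_ml : float
        Solvent volume used to extract each tape group, mL.
    loq_ug_per_ml : float
        Assay limit of quantification for the extract, ug/mL.
    sc_density_g_per_cm3 : float
        Stratum-corneum density used to convert mass/area to thickness
        (1 g/cm^3 by convention).
    n_subjects : int
        Number of subjects enrolled.
    n_replicates : int
        Replicate application sites per product per phase (2 in a
        duplicate-site design).
    """

    t_up_h: float = 6.0
    delta_t_h: float = 17.0
    area_cm2: float = 5.0
    extract_volume_ml: float = 3.6
    loq_ug_per_ml: float = 0.038
    sc_density_g_per_cm3: float = 1.0
    n_subjects: int = 10
    n_replicates: int = 2

    def __post_init__(self) -> None:
        for name in (
            "t_up_h",
            "delta_t_h",
            "area_cm2",
            "extract_volume_ml",
            "loq_ug_per_ml",
            "sc_density_g_per_cm3",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"StudyDesign.{name} must be positive")
        if self.n_subjects < 1:
            raise ValueError("StudyDesign.n_subjects must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("StudyDesign.n_replicates must be >= 1")

    @property
    def loq_areal_ug_per_cm2(self) -> float:
        """Areal LOQ: the drug amount/area corresponding to one extract
        exactly at the assay LOQ."""
        return self.loq_ug_per_ml * self.extract_volume_ml / self.area_cm2

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyDesign":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown design keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyDesign":
        """Read a design from a plain-text key/value (YAML) file."""
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"design file {path} did not parse to a mapping")
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def load_design(path: str | Path | None) -> StudyDesign:
    """Load a design file, or return the default duplicate-site design."""
    if path is None:
        return StudyDesign()
    return StudyDesign.from_file(path)


@dataclass(frozen=True)
class StoppingRule:
    """Criteria that end tape-stripping at a site.

    Stripping stops when TEWL (transepidermal water loss) reaches an
    absolute ceiling, exceeds a multiple of the pre-stripping baseline, or a
    maximum tape count has been removed.
    """

    tewl_absolute_limit: float = 60.0  # g m^-2 h^-1
    tewl_baseline_multiplier: float = 6.0
    max_tapes: int = 30

    def __post_init__(self) -> None:
        if self.tewl_absolute_limit <= 0:
            raise ValueError("tewl_absolute_limit must be positive")
        if self.tewl_baseline_multiplier <= 0:
            raise ValueError("tewl_baseline_multiplier must be positive")
        if self.max_tapes <= 0:
            raise ValueError("max_tapes must be positive")
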