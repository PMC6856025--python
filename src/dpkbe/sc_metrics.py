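"""Per-site quality control and primary stratum-corneum measurements.

This module turns raw tape-group records into the quantities the study
analysis consumes: the stopping-rule audit, total SC mass and thickness
removed, the per-site drug amount Q (with the limit-of-quantification
substitution), and mass-normalised depth-concentration profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .design import StoppingRule
from .records import SiteRecord

__all__ = [
    "StoppingDecision",
    "DepthProfile",
    "check_stopping_rule",
    "sc_mass_and_thickness",
    "site_amount_q",
    "depth_profile",
    "qc_table",
    "amounts_table",
]


@dataclass(frozen=True)
class StoppingDecision:
    stop: bool
    criterion: Optional[str]  # "absolute_tewl" | "baseline_multiple" | "max_tapes"
    warning: Optional[str] = None


def check_stopping_rule(
    tewl_baseline: float,
    tewl_series: Sequence[float],
    n_tapes: int,
    rule: StoppingRule = StoppingRule(),
) -> StoppingDecision:
    """Decide whether tape-stripping must stop at this point.

    Stop if the latest TEWL reading reaches the absolute ceiling, exceeds
    the allowed multiple of the baseline, or the tape budget is exhausted.
    The triggered criterion is reported in that order of precedence; the
    stop/continue decision itself is order-independent.
    """
    if tewl_baseline <= 0:
        raise ValueError("tewl_baseline must be positive")
    warning = None
    latest = None
    if len(tewl_series) == 0:
        if n_tapes < rule.max_tapes:
            warning = "no TEWL readings available; continuing on tape count only"
    else:
        latest = float(tewl_series[-1])

    if latest is not None and latest >= rule.tewl_absolute_limit:
        return StoppingDecision(True, "absolute_tewl")
    if latest is not None and latest > rule.tewl_baseline_multiplier * tewl_baseline:
        return StoppingDecision(True, "baseline_multiple")
    if n_tapes >= rule.max_tapes:
        return StoppingDecision(True, "max_tapes")
    return StoppingDecision(False, None, warning)


def sc_mass_and_thickness(site: SiteRecord) -> tuple[float, float]:
    """Total SC mass per area (mg/cm^2) and the equivalent thickness (um).

    Thickness follows from mass/area divided by the SC density; with the
    conventional density of 1 g/cm^3, 1 mg/cm^2 corresponds to 10 um.
    """
    area = site.design.area_cm2
    if area <= 0:
        raise ValueError("sampled area must be positive")
    mass_per_area = sum(g.sc_mass_mg for g in site.groups) / area
    # mg/cm^2 / (g/cm^3) = 1e-3 g/cm^2 / (g/cm^3) = 1e-3 cm = 10 um
    thickness_um = mass_per_area / site.design.sc_density_g_per_cm3 * 10.0
    return mass_per_area, thickness_um


def site_amount_q(site: SiteRecord) -> float:
    """Drug amount per unit area Q (ug/cm^2) for one site.

    Each tape group contributes concentration x extract volume when the
    extract concentration is at or above the LOQ, and zero otherwise.  A
    site in which every group falls below the LOQ is assigned half the
    areal LOQ so that Q stays positive for log-transformation.
    """
    d = site.design
    total_ug = 0.0
    for g in site.groups:
        if g.extract_concentration_ug_ml >= d.loq_ug_per_ml:
            total_ug += g.extract_concentration_ug_ml * d.extract_volume_ml
    q = total_ug / d.area_cm2
    if q == 0.0:
        q = d.loq_areal_ug_per_cm2 / 2.0
    return q


@dataclass(frozen=True)
class DepthProfile:
    """Drug concentration versus normalised depth in the collected SC.

    Depth is expressed as a fraction of the SC actually removed (the total
    thickness at a site is unknown); interval widths are proportional to
    the SC mass of each tape group.  ``concentrations`` are local drug
    concentrations in ug per cm^3 of SC; groups with zero SC mass produce
    zero-width segments with undefined (NaN) concentration, flagged in
    ``undefined``.
    """

    depth_lower: np.ndarray  # fraction of collected SC, starts at 0
    depth_upper: np.ndarray
    concentrations_ug_cm3: np.ndarray
    undefined: np.ndarray  # bool mask of zero-mass segments

    @property
    def widths(self) -> np.ndarray:
        return self.depth_upper - self.depth_lower


def depth_profile(site: SiteRecord) -> DepthProfile:
    """Mass-normalised depth-concentration profile for one site."""
    d = site.design
    masses = np.array([g.sc_mass_mg for g in site.groups], dtype=float)
    total_mass = masses.sum()
    if total_mass <= 0:
        raise ValueError("depth profile undefined for a site with zero SC mass")
    drug_ug = np.array(
        [g.extract_concentration_ug_ml * d.extract_volume_ml for g in site.groups],
        dtype=float,
    )
    widths = masses / total_mass
    upper = np.cumsum(widths)
    lower = np.concatenate([[0.0], upper[:-1]])
    # SC volume of group i in cm^3: mass[mg] -> g / density
    volume_cm3 = masses * 1e-3 / d.sc_density_g_per_cm3
    undefined = masses == 0
    conc = np.full_like(drug_ug, np.nan)
    np.divide(drug_ug, volume_cm3, out=conc, where=~undefined)
    return DepthProfile(lower, upper, conc, undefined)


def qc_table(sites: Sequence[SiteRecord], rule: StoppingRule = StoppingRule()) -> pd.DataFrame:
    """Per-site QC summary: tape count, SC mass/area, thickness and the
    stopping criterion that fired (if TEWL data are available)."""
    rows = []
    for site in sites:
        mass_per_area, thickness = sc_mass_and_thickness(site)
        criterion = None
        if site.tewl_baseline is not None:
            decision = check_stopping_rule(
                site.tewl_baseline, site.tewl_series or [], site.n_tapes, rule
            )
            criterion = decision.criterion if decision.stop else "none"
        rows.append(
            {
                "subject_id": site.subject_id,
                "product_code": site.product_code,
                "phase": site.phase,
                "replicate_index": site.replicate_index,
                "n_tapes": site.n_tapes,
                "sc_mass_mg_cm2": mass_per_area,
                "sc_thickness_um": thickness,
                "stop_criterion": criterion,
            }
        )
    return pd.DataFrame(rows)


def amounts_table(sites: Sequence[SiteRecord]) -> pd.DataFrame:
    """Per-site drug amounts Q (ug/cm^2), one row per site."""
    rows = [
        {
            "subject_id": site.subject_id,
            "product_code": site.product_code,
            "phase": site.phase,
            "replicate_index": site.replicate_index,
            "q_ug_cm2": site_amount_q(site),
        }
        for site in sites
    ]
    return pd.DataFrame(rows)
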