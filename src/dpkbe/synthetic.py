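"""Synthetic tape-stripping studies with the statistical structure the
analysis assumes.

Two levels of realism are provided:

* :func:`generate_site_amounts` draws per-site drug amounts Q from the
  log-normal variance-component model (shared subject effect, independent
  site noise, product geometric-mean-ratio effects).  Clearance amounts
  follow the slab-diffusion retained fraction W(t_up/t_lag, dt/t_lag) so
  the kinetic and diffusion stages have a recoverable ground truth; a pure
  two-log-normal mode (explicit W) is available for statistics-only tests.

* :func:`generate_tape_records` additionally expands each site into tape
  groups: declining per-tape SC masses, drug distributed over depth
  according to the diffusion concentration profile at the appropriate
  time, extract concentrations derived through the design's volume and
  area (possibly below the LOQ, exercising the censoring path).

Defaults mimic the magnitudes of a duplicate-site acyclovir cream study:
reference uptake amount ~0.65 ug/cm^2, within-subject log SD ~0.6,
between-subject log SD ~0.4, lag time ~18.9 h against a 6 h uptake /
17 h clearance protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .design import StudyDesign
from .diffusion import clearance_fraction, clearance_profile, uptake_profile
from .records import CLEARANCE, UPTAKE

__all__ = [
    "ProductSpec",
    "SyntheticStudyConfig",
    "true_retained_fraction",
    "generate_site_amounts",
    "generate_tape_records",
    "generate_tewl_series",
    "write_synthetic_study",
]


@dataclass(frozen=True)
class ProductSpec:
    """One product arm: its code, analysis role and true effect size."""

    code: str
    role: str  # "reference" | "positive_control" | "test"
    true_gmr: float = 1.0

    def __post_init__(self) -> None:
        if self.true_gmr <= 0:
            raise ValueError("true_gmr must be positive")


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Ground truth and design dimensions for a simulated study."""

    design: StudyDesign = field(default_factory=StudyDesign)
    products: tuple[ProductSpec, ...] = (
        ProductSpec("REF", "reference", 1.0),
        ProductSpec("CPLUS", "positive_control", 1.0),
        ProductSpec("TEST", "test", 0.6),
    )
    q_up_ref_ug_cm2: float = 0.65
    sigma_s: float = 0.4  # between-subject log SD
    sigma_w: float = 0.6  # within-subject (site) log SD
    clearance_model: str = "diffusion"  # "diffusion" | "lognormal"
    true_t_lag_h: float = 18.9
    true_w: Optional[float] = None  # used by the "lognormal" clearance model
    # tape-level expansion
    mean_tapes_per_site: float = 22.0
    sc_mass_mg_cm2: float = 0.88
    collected_depth_fraction: float = 0.85
    tape_mass_decline: float = 0.06  # exponential decline per tape
    tape_mass_cv: float = 0.25

    def __post_init__(self) -> None:
        if self.sigma_s < 0 or self.sigma_w < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.q_up_ref_ug_cm2 <= 0:
            raise ValueError("q_up_ref_ug_cm2 must be positive")
        if self.clearance_model not in ("diffusion", "lognormal"):
            raise ValueError("clearance_model must be 'diffusion' or 'lognormal'")
        if self.clearance_model == "lognormal" and self.true_w is None:
            raise ValueError("the lognormal clearance model needs an explicit true_w")
        if self.true_t_lag_h <= 0:
            raise ValueError("true_t_lag_h must be positive")
        if not 0 < self.collected_depth_fraction <= 1:
            raise ValueError("collected_depth_fraction must be in (0, 1]")

    @property
    def tau_up(self) -> float:
        return self.design.t_up_h / self.true_t_lag_h

    @property
    def tau_cl(self) -> float:
        return self.design.delta_t_h / self.true_t_lag_h


def true_retained_fraction(config: SyntheticStudyConfig) -> float:
    """The ground-truth W = Q_cl/Q_up implied by the configuration."""
    if config.clearance_model == "lognormal":
        return float(config.true_w)
    return float(clearance_fraction(config.tau_up, config.tau_cl))


def generate_site_amounts(config: SyntheticStudyConfig, seed: int) -> pd.DataFrame:
    """Tidy per-site amount table (subject x product x phase x replicate).

    ln Q_up,jk = ln(q_ref GMR_p) + S_j + eps_jk; clearance sites share the
    subject effect and multiply by the ground-truth retained fraction with
    independent site noise.  Deterministic under the seed.
    """
    rng = np.random.default_rng(seed)
    d = config.design
    w = true_retained_fraction(config)
    rows = []
    subjects = [f"S{i + 1:02d}" for i in range(d.n_subjects)]
    for j, subject in enumerate(subjects):
        s_j = rng.normal(0.0, config.sigma_s)
        for product in config.products:
            base = np.log(config.q_up_ref_ug_cm2 * product.true_gmr) + s_j
            for phase, offset in ((UPTAKE, 0.0), (CLEARANCE, np.log(w))):
                eps = rng.normal(0.0, config.sigma_w, d.n_replicates)
                for k in range(d.n_replicates):
                    rows.append(
                        {
                            "subject_id": subject,
                            "product_code": product.code,
                            "phase": phase,
                            "replicate_index": k + 1,
                            "q_ug_cm2": float(np.exp(base + offset + eps[k])),
                        }
                    )
    return pd.DataFrame(rows)


def _tape_masses(config: SyntheticStudyConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-tape SC masses (mg) for one site: declining with depth, noisy,
    capped at 30 tapes, scaled to the site's total SC mass."""
    n_tapes = int(np.clip(round(rng.normal(config.mean_tapes_per_site, 3.0)), 6, 30))
    weights = np.exp(-config.tape_mass_decline * np.arange(n_tapes))
    noise = rng.lognormal(0.0, config.tape_mass_cv, n_tapes)
    weights = weights * noise
    total_mg = config.sc_mass_mg_cm2 * config.design.area_cm2
    return weights / weights.sum() * total_mg


def _group_tapes(masses: np.ndarray, rng: np.random.Generator) -> list[np.ndarray]:
    """Indices of tape groups: the first two tapes singly, the rest pooled
    in groups of 2-8 chosen to roughly equalise SC mass per group."""
    groups = [np.array([0]), np.array([1])]
    i = 2
    n = len(masses)
    target = masses[2:].mean() * 4 if n > 2 else 0.0
    while i < n:
        size = 2
        acc = masses[i : i + size].sum()
        while size < 8 and i + size < n and acc < target:
            acc += masses[i + size]
            size += 1
        groups.append(np.arange(i, min(i + size, n)))
        i += size
    return groups


def _depth_drug_fractions(
    config: SyntheticStudyConfig, phase: str, depth_edges: np.ndarray
) -> np.ndarray:
    """Fraction of the site's drug between consecutive collected-depth
    edges, from the diffusion concentration profile at the phase time."""
    x_edges = depth_edges * config.collected_depth_fraction
    # fine grid for the cumulative drug integral over depth
    x = np.linspace(0.0, config.collected_depth_fraction, 801)
    if phase == UPTAKE:
        c = uptake_profile(x, config.tau_up)
    else:
        c = clearance_profile(x, config.tau_up, config.tau_cl)
    cum = np.concatenate([[0.0], np.cumsum((c[1:] + c[:-1]) / 2 * np.diff(x))])
    total = cum[-1]
    if total <= 0:
        # degenerate profile: spread the drug uniformly
        return np.diff(depth_edges)
    cum_at = np.interp(x_edges, x, cum) / total
    return np.diff(cum_at)


def generate_tape_records(config: SyntheticStudyConfig, seed: int) -> pd.DataFrame:
    """Full tape-group study in the tidy CSV schema.

    Site amounts come from :func:`generate_site_amounts` under a
    seed-derived stream; each site's drug is then distributed over its
    tape groups according to the depth profile, and converted to extract
    concentrations.  Summing group drug masses over a site reproduces the
    site amount exactly (censoring happens at analysis, not generation).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    amounts = generate_site_amounts(config, seed)
    d = config.design
    rows = []
    for site in amounts.itertuples(index=False):
        masses = _tape_masses(config, rng)
        groups = _group_tapes(masses, rng)
        group_masses = np.array([masses[g].sum() for g in groups])
        depth_edges = np.concatenate([[0.0], np.cumsum(group_masses)]) / group_masses.sum()
        fractions = _depth_drug_fractions(config, site.phase, depth_edges)
        site_drug_ug = site.q_ug_cm2 * d.area_cm2
        for gi, (g, frac) in enumerate(zip(groups, fractions)):
            conc = site_drug_ug * frac / d.extract_volume_ml
            rows.append(
                {
                    "subject_id": site.subject_id,
                    "product_code": site.product_code,
                    "phase": site.phase,
                    "replicate_index": site.replicate_index,
                    "group_index": gi + 1,
                    "sc_mass_mg": float(group_masses[gi]),
                    "extract_concentration_ug_ml": float(conc),
                    "n_tapes_in_group": int(len(g)),
                }
            )
    return pd.DataFrame(rows)


def generate_tewl_series(
    n_tapes: int, baseline: float = 8.0, rise_per_tape: float = 1.2, seed: int = 0
) -> tuple[float, list[float]]:
    """A simple increasing TEWL sequence for stopping-rule exercises (not a
    physiological model)."""
    rng = np.random.default_rng(seed)
    readings = baseline + rise_per_tape * np.arange(1, n_tapes + 1)
    readings = readings * rng.lognormal(0.0, 0.05, n_tapes)
    return baseline, [float(v) for v in readings]


def write_synthetic_study(
    config: SyntheticStudyConfig,
    seed: int,
    path: str | Path,
    tapes: bool = True,
) -> pd.DataFrame:
    """Generate a study and write it as CSV; returns the frame written."""
    df = generate_tape_records(config, seed) if tapes else generate_site_amounts(config, seed)
    df.to_csv(path, index=False)
    return df
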