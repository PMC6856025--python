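"""Slab-diffusion model of drug transport through the stratum corneum and
the C*-concept estimate of concentration at the site of action.

The SC is modelled as a homogeneous membrane of thickness L and diffusivity
D; the governing time scale is the diffusional lag time

    t_lag = L^2 / (6 D),

and all solutions below are written in the reduced time tau = t / t_lag.

**Uptake** (product on the skin): constant drug concentration at the outer
surface, perfect sink at the SC/viable-tissue boundary.  The drug amount in
the membrane relative to its steady-state value is the classic series

    u(tau) = 1 - (8/pi^2) * sum_{n odd} n^-2 exp(-n^2 pi^2 tau / 6).

**Clearance** (product removed): the uptake profile at t_up becomes the
initial condition; the outer surface switches to zero flux while the inner
sink is maintained.  Expanding on the eigenfunctions cos((m+1/2) pi x/L)
gives the retained fraction W = Q(t_up + dt) / Q(t_up) in closed series
form.

At steady state the concentration profile is linear, the membrane holds
Q_ss = C0 L / 2 and the flux into the tissue is J_ss = Q_ss / (3 t_lag) —
the identity used to extrapolate a measured two-time-point experiment to
steady state.  The C* concept then converts a flux J into the free drug
concentration at the target site via J = P_D * C*, with P_D = D_D / h_D the
lumped dermal clearance rate constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "uptake_fraction",
    "uptake_profile",
    "clearance_fraction",
    "clearance_profile",
    "DiffusionFit",
    "fit_lag_time",
    "SlabClearanceModel",
    "SlabDiffusionResults",
    "DermisParams",
    "dermal_diffusivity",
    "permeability_p_d",
    "c_star",
    "dofm_flux",
]

_TERM_TOL = 1e-12
_MAX_TERMS = 10_000
_SHORT_TIME_TAU = 1e-4


def _n_terms(tau: float) -> int:
    """Series length so the smallest retained exponential is below tol."""
    if tau <= 0:
        return _MAX_TERMS
    n = int(np.ceil(np.sqrt(6.0 * -np.log(_TERM_TOL) / (np.pi**2 * tau)))) + 1
    return min(max(n, 4), _MAX_TERMS)


def uptake_fraction(tau) -> np.ndarray | float:
    """Membrane drug amount relative to steady state during uptake, u(tau).

    Vectorised over ``tau >= 0``; switches to the short-time semi-infinite
    law (4/sqrt(pi)) sqrt(tau/6) below tau = 1e-4 for numerical stability.
    """
    tau_arr = np.atleast_1d(np.asarray(tau, dtype=float))
    if np.any(tau_arr < 0):
        raise ValueError("tau must be non-negative")
    out = np.empty_like(tau_arr)
    small = tau_arr < _SHORT_TIME_TAU
    out[small] = (4.0 / np.sqrt(np.pi)) * np.sqrt(tau_arr[small] / 6.0)
    big = ~small
    if np.any(big):
        nmax = _n_terms(float(tau_arr[big].min()))
        n = np.arange(1, 2 * nmax, 2, dtype=float)  # odd harmonics
        e = np.exp(-np.outer(tau_arr[big], n**2) * np.pi**2 / 6.0)
        out[big] = 1.0 - (8.0 / np.pi**2) * (e / n**2).sum(axis=1)
    return out if np.ndim(tau) else float(out[0])


def uptake_profile(x, tau: float) -> np.ndarray:
    """Concentration profile c(x, tau)/C0 during uptake.

    ``x`` is depth as a fraction of the membrane (0 = surface, 1 = inner
    boundary).  The profile is (1 - x) at steady state.
    """
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    if tau < 0:
        raise ValueError("tau must be non-negative")
    nmax = _n_terms(max(tau, _SHORT_TIME_TAU))
    n = np.arange(1, nmax + 1, dtype=float)
    e = np.exp(-(n**2) * np.pi**2 * tau / 6.0)
    series = np.sin(np.outer(x_arr, n) * np.pi) @ (e / n)
    c = (1.0 - x_arr) - (2.0 / np.pi) * series
    return np.clip(c, 0.0, None)


def _clearance_coefficients(tau_up: float, n_modes: int) -> np.ndarray:
    """Eigen-expansion coefficients b_m of the clearance initial condition
    (the uptake profile at tau_up) on cos(mu_m x), mu_m = (m + 1/2) pi."""
    m = np.arange(n_modes, dtype=float)
    mu = (m + 0.5) * np.pi
    nmax = _n_terms(max(tau_up, _SHORT_TIME_TAU))
    n = np.arange(1, nmax + 1, dtype=float)
    e_n = np.exp(-(n**2) * np.pi**2 * tau_up / 6.0)
    denom = (n[None, :] * np.pi) ** 2 - mu[:, None] ** 2  # never zero
    return 2.0 * (1.0 / mu**2 - 2.0 * (e_n[None, :] / denom).sum(axis=1))


def _clearance_modes(tau_cl: float) -> int:
    if tau_cl <= 0:
        # prefactor decay alone (~mu^-3) must reach the tolerance
        return min(int((4.0 / _TERM_TOL) ** (1.0 / 3.0) / np.pi) + 1, _MAX_TERMS)
    mu_max = np.sqrt(6.0 * -np.log(_TERM_TOL) / tau_cl)
    return min(max(int(mu_max / np.pi) + 2, 8), _MAX_TERMS)


def clearance_fraction(tau_up: float, tau_cl) -> np.ndarray | float:
    """Retained fraction W = Q(t_up + dt)/Q(t_up) during clearance.

    ``tau_up = t_up/t_lag`` fixes the initial profile; ``tau_cl`` (scalar
    or array) is the reduced clearance time.  W = 1 at tau_cl = 0 and
    decreases strictly as drug drains through the inner sink.
    """
    if tau_up <= 0:
        raise ValueError("tau_up must be positive")
    tau_arr = np.atleast_1d(np.asarray(tau_cl, dtype=float))
    if np.any(tau_arr < 0):
        raise ValueError("tau_cl must be non-negative")
    n_modes = _clearance_modes(float(tau_arr.min()))
    b = _clearance_coefficients(tau_up, n_modes)
    m = np.arange(n_modes, dtype=float)
    mu = (m + 0.5) * np.pi
    weights = b * ((-1.0) ** m) / mu
    # normalise by the (fully converged) uptake amount at tau_up; the mode
    # sum of `weights` equals it only in the limit of infinitely many modes
    q0 = 0.5 * uptake_fraction(tau_up)
    decay = np.exp(-np.outer(tau_arr, mu**2) / 6.0)
    w = (decay * weights).sum(axis=1) / q0
    w[tau_arr == 0.0] = 1.0
    return w if np.ndim(tau_cl) else float(w[0])


def clearance_profile(x, tau_up: float, tau_cl: float) -> np.ndarray:
    """Concentration profile c(x)/C0 at reduced time tau_cl into clearance."""
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    if tau_cl < 0:
        raise ValueError("tau_cl must be non-negative")
    n_modes = _clearance_modes(tau_cl)
    b = _clearance_coefficients(tau_up, n_modes)
    mu = (np.arange(n_modes, dtype=float) + 0.5) * np.pi
    decay = np.exp(-(mu**2) * tau_cl / 6.0)
    c = np.cos(np.outer(x_arr, mu)) @ (b * decay)
    return np.clip(c, 0.0, None)


@dataclass(frozen=True)
class DiffusionFit:
    """Lag-time inversion of a two-time-point tape-stripping measurement.

    ``w`` is the measured retained fraction Q_cl/Q_up; ``t_lag_h`` the
    fitted diffusional lag time; ``f`` the steady-state correction factor
    Q_ss/Q_up; ``q_ss_ug_cm2`` and ``j_ss_ng_cm2_h`` the extrapolated
    steady-state amount and flux (identity: Q_ss = 3 J_ss t_lag).
    """

    w: float
    t_lag_h: Optional[float]
    tau_up: Optional[float]
    f: Optional[float]
    q_ss_ug_cm2: Optional[float]
    j_ss_ng_cm2_h: Optional[float]
    success: bool
    message: str = ""


def fit_lag_time(
    q_up: float,
    q_cl: float,
    t_up_h: float,
    delta_t_h: float,
    bracket: tuple[float, float] = (0.1, 1000.0),
) -> DiffusionFit:
    """Invert the clearance solution for the lag time.

    Solves W(t_up/t_lag, dt/t_lag) = Q_cl/Q_up for t_lag by bracketed
    root-finding, then evaluates the steady-state extrapolation:
    F = 1/u(t_up/t_lag), Q_ss = F Q_up, J_ss = Q_ss/(3 t_lag) (reported in
    ng/cm^2/h for amounts in ug/cm^2).

    A measurement with Q_cl >= Q_up carries no clearance signal and yields
    an unsuccessful fit with a diagnostic rather than an exception.
    """
    if q_up <= 0 or q_cl <= 0:
        raise ValueError("amounts must be positive")
    if t_up_h <= 0 or delta_t_h <= 0:
        raise ValueError("times must be positive")
    w = q_cl / q_up
    if w >= 1.0:
        return DiffusionFit(
            w, None, None, None, None, None, False,
            "clearance did not reduce the SC amount (W >= 1); lag time not identifiable",
        )

    def g(t_lag: float) -> float:
        return clearance_fraction(t_up_h / t_lag, delta_t_h / t_lag) - w

    lo, hi = bracket
    g_lo, g_hi = g(lo), g(hi)
    if g_lo * g_hi > 0:
        raise ValueError(
            f"lag time not bracketed in [{lo}, {hi}] h (g({lo})={g_lo:.3g}, "
            f"g({hi})={g_hi:.3g})"
        )
    t_lag = brentq(g, lo, hi, rtol=1e-9)
    tau_up = t_up_h / t_lag
    f = 1.0 / uptake_fraction(tau_up)
    q_ss = f * q_up
    j_ss = 1000.0 * q_ss / (3.0 * t_lag)
    return DiffusionFit(w, float(t_lag), float(tau_up), float(f), float(q_ss), float(j_ss), True)


# --- dermal clearance and the C* concept -------------------------------------

_DIFFUSIVITY_CORRELATIONS = ("logmw", "cube_root")


def dermal_diffusivity(mw: float, correlation: str = "logmw") -> float:
    """Empirical dermal diffusivity D_D (cm^2/s) from molecular weight (Da).

    Two literature correlations are available:
    ``logmw``      log10 D = -4.15 - 0.655 log10(MW)
    ``cube_root``  log10 D = -4.38 - 0.207 MW^(1/3)
    """
    if mw <= 0:
        raise ValueError("molecular weight must be positive")
    if correlation == "logmw":
        return float(10.0 ** (-4.15 - 0.655 * np.log10(mw)))
    if correlation == "cube_root":
        return float(10.0 ** (-4.38 - 0.207 * mw ** (1.0 / 3.0)))
    raise ValueError(f"correlation must be one of {_DIFFUSIVITY_CORRELATIONS}")


def permeability_p_d(d_d_cm2_s: float, h_d_cm: float) -> float:
    """Lumped dermal clearance rate constant P_D = D_D/h_D in cm/h.

    ``d_d_cm2_s`` in cm^2/s is converted to cm^2/h (x3600); ``h_d_cm`` is
    the diffusion path length from the basal epidermis to the
    microcirculation.
    """
    if d_d_cm2_s <= 0:
        raise ValueError("diffusivity must be positive")
    if h_d_cm <= 0:
        raise ValueError("path length must be positive")
    return 3600.0 * d_d_cm2_s / h_d_cm


def c_star(j_ng_cm2_h: float, p_d_cm_h: float) -> float:
    """Free drug concentration at the site of action, C* = J/P_D (ng/mL)."""
    if p_d_cm_h <= 0:
        raise ValueError("P_D must be positive")
    return j_ng_cm2_h / p_d_cm_h


@dataclass(frozen=True)
class DermisParams:
    """Dermal transport parameters behind the C* estimate."""

    mw: float
    d_d_cm2_s: float
    h_d_cm: float

    def __post_init__(self) -> None:
        if min(self.mw, self.d_d_cm2_s, self.h_d_cm) <= 0:
            raise ValueError("all dermis parameters must be positive")

    @property
    def p_d_cm_h(self) -> float:
        return permeability_p_d(self.d_d_cm2_s, self.h_d_cm)

    @classmethod
    def from_mw(
        cls, mw: float, h_d_cm: float = 0.01, correlation: str = "average"
    ) -> "DermisParams":
        """Build from molecular weight; ``correlation`` may name a single
        empirical correlation or ``"average"`` (arithmetic mean of both)."""
        if correlation == "average":
            d = 0.5 * (
                dermal_diffusivity(mw, "logmw") + dermal_diffusivity(mw, "cube_root")
            )
        else:
            d = dermal_diffusivity(mw, correlation)
        return cls(mw=mw, d_d_cm2_s=d, h_d_cm=h_d_cm)


def dofm_flux(
    flow_rate_ul_h: float,
    perfusate_conc_ng_ml: float,
    probe_length_mm: float = 15.0,
    probe_diameter_mm: float = 0.5,
) -> float:
    """Flux (ng/cm^2/h) implied by an open-flow microperfusion measurement.

    The drug mass rate collected by the probe is flow x concentration; the
    exchange area is the planar projection of the fibre (length x
    diameter).  Used as an independent cross-check of the tape-stripping
    flux estimates.
    """
    if min(flow_rate_ul_h, probe_length_mm, probe_diameter_mm) <= 0:
        raise ValueError("flow rate and probe dimensions must be positive")
    mass_rate_ng_h = flow_rate_ul_h * 1e-3 * perfusate_conc_ng_ml  # uL -> mL
    area_cm2 = (probe_length_mm / 10.0) * (probe_diameter_mm / 10.0)
    return mass_rate_ng_h / area_cm2


class SlabClearanceModel:
    """Two-time-point slab-diffusion model of SC uptake and clearance.

    A statsmodels-style mechanistic model: constructed from the measured
    amounts (Q_up, Q_cl) and the protocol times, ``fit`` inverts the
    clearance solution for the lag time and extrapolates to steady state.
    """

    def __init__(self, q_up: float, q_cl: float, t_up_h: float, delta_t_h: float):
        self.q_up = q_up
        self.q_cl = q_cl
        self.t_up_h = t_up_h
        self.delta_t_h = delta_t_h

    def fit(self) -> "SlabDiffusionResults":
        return SlabDiffusionResults(self, fit_lag_time(
            self.q_up, self.q_cl, self.t_up_h, self.delta_t_h
        ))


class SlabDiffusionResults:
    """Fitted lag time with steady-state extrapolation and C* estimates."""

    def __init__(self, model: SlabClearanceModel, fit: DiffusionFit):
        self.model = model
        self.fit_result = fit

    def __getattr__(self, name):
        return getattr(self.fit_result, name)

    def c_star_at(self, dermis: DermisParams, j_ng_cm2_h: Optional[float] = None) -> float:
        """C* for a supplied flux (default: the extrapolated steady-state
        flux of this fit)."""
        if j_ng_cm2_h is None:
            if not self.fit_result.success:
                raise ValueError("no steady-state flux available from a failed fit")
            j_ng_cm2_h = self.fit_result.j_ss_ng_cm2_h
        return c_star(j_ng_cm2_h, dermis.p_d_cm_h)

    def summary(self) -> str:
        m, r = self.model, self.fit_result
        lines = [
            "Slab-diffusion clearance fit",
            "-" * 46,
            f"{'Q_up (ug/cm^2)':<28}{m.q_up:>14.3g}",
            f"{'Q_cl (ug/cm^2)':<28}{m.q_cl:>14.3g}",
            f"{'t_up (h)':<28}{m.t_up_h:>14.3g}",
            f"{'delta_t (h)':<28}{m.delta_t_h:>14.3g}",
            f"{'W = Q_cl/Q_up':<28}{r.w:>14.3g}",
        ]
        if r.success:
            lines += [
                f"{'t_lag (h)':<28}{r.t_lag_h:>14.4g}",
                f"{'t_up/t_lag':<28}{r.tau_up:>14.3g}",
                f"{'F = Q_ss/Q_up':<28}{r.f:>14.4g}",
                f"{'Q_ss (ug/cm^2)':<28}{r.q_ss_ug_cm2:>14.4g}",
                f"{'J_ss (ng/cm^2/h)':<28}{r.j_ss_ng_cm2_h:>14.4g}",
            ]
        else:
            lines.append(f"fit failed: {r.message}")
        lines.append("-" * 46)
        return "\n".join(lines)
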