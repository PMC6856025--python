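"""Shared fixtures and the independent finite-difference diffusion oracle."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.sparse import diags
from scipy.sparse.linalg import splu

from dpkbe import StudyDesign, SyntheticStudyConfig, generate_tape_records, read_study


# --- finite-difference oracle -------------------------------------------------
#
# Crank-Nicolson solver for the dimensionless membrane problem (x in [0, 1],
# D = 1/6 so that time is measured in lag times).  Entirely independent of
# the eigenfunction-series implementation it is used to check.

_D = 1.0 / 6.0


def _cn_factors(nx: int, dt: float, left_bc: str):
    """LU factors of the Crank-Nicolson step matrices.

    ``left_bc`` is "dirichlet" (fixed value at x=0) or "neumann" (zero flux);
    the right boundary is always an absorbing sink (c=0).
    """
    dx = 1.0 / (nx - 1)
    r = _D * dt / dx**2
    main = np.full(nx, 1.0 + r)
    off_lo = np.full(nx - 1, -r / 2.0)
    off_hi = np.full(nx - 1, -r / 2.0)
    bmain = np.full(nx, 1.0 - r)
    boff_lo = np.full(nx - 1, r / 2.0)
    boff_hi = np.full(nx - 1, r / 2.0)
    if left_bc == "dirichlet":
        main[0] = 1.0
        off_hi[0] = 0.0
        bmain[0] = 1.0
        boff_hi[0] = 0.0
    else:  # zero flux: ghost-node reflection doubles the inner coupling
        off_hi[0] = -r
        boff_hi[0] = r
    # sink at the right boundary
    main[-1] = 1.0
    off_lo[-1] = 0.0
    bmain[-1] = 1.0
    boff_lo[-1] = 0.0
    a = diags([off_lo, main, off_hi], [-1, 0, 1], format="csc")
    b = diags([boff_lo, bmain, boff_hi], [-1, 0, 1], format="csr")
    return splu(a), b


def _march(c: np.ndarray, t_end: float, left_bc: str, dt: float, record_at=None):
    """March the CN scheme to t_end; optionally record ∫c dx at given times."""
    nx = len(c)
    lu, b = _cn_factors(nx, dt, left_bc)
    x = np.linspace(0.0, 1.0, nx)
    t = 0.0
    recorded = {}
    targets = sorted(record_at) if record_at is not None else []
    ti = 0
    n_steps = int(round(t_end / dt))
    for _ in range(n_steps):
        c = lu.solve(b @ c)
        if left_bc == "dirichlet":
            c[0] = 1.0
        c[-1] = 0.0
        t += dt
        while ti < len(targets) and t >= targets[ti] - dt / 2:
            recorded[targets[ti]] = np.trapezoid(c, x)
            ti += 1
    return c, recorded


def fd_uptake_fraction(taus, nx: int = 401, dt: float = 5e-5) -> np.ndarray:
    """Membrane amount relative to steady state at the requested reduced
    times, by finite differences."""
    taus = np.asarray(taus, dtype=float)
    c0 = np.zeros(nx)
    c0[0] = 1.0
    _, rec = _march(c0, float(taus.max()) + dt, "dirichlet", dt, record_at=list(taus))
    m_ss = 0.5
    return np.array([rec[t] for t in sorted(taus)])[np.argsort(np.argsort(taus))] / m_ss


def fd_clearance_fraction(tau_up: float, taus_cl, nx: int = 401, dt: float = 5e-5):
    """Retained fraction W by finite differences: uptake to tau_up, then
    zero-flux/sink clearance."""
    taus_cl = np.asarray(taus_cl, dtype=float)
    c0 = np.zeros(nx)
    c0[0] = 1.0
    c_up, _ = _march(c0, tau_up, "dirichlet", dt)
    x = np.linspace(0.0, 1.0, nx)
    m_up = np.trapezoid(c_up, x)
    _, rec = _march(c_up.copy(), float(taus_cl.max()) + dt, "neumann", dt,
                    record_at=list(taus_cl))
    w = np.array([rec[t] for t in sorted(taus_cl)])[np.argsort(np.argsort(taus_cl))]
    return w / m_up


# --- study fixtures -----------------------------------------------------------


@pytest.fixture(scope="session")
def design() -> StudyDesign:
    return StudyDesign()


@pytest.fixture(scope="session")
def synth_config() -> SyntheticStudyConfig:
    return SyntheticStudyConfig()


@pytest.fixture(scope="session")
def tape_study_csv(tmp_path_factory, synth_config):
    """A complete synthetic tape-level study written to CSV."""
    path = tmp_path_factory.mktemp("study") / "study.csv"
    df = generate_tape_records(synth_config, seed=42)
    df.to_csv(path, index=False)
    return path


@pytest.fixture(scope="session")
def sites(tape_study_csv, design):
    return read_study(tape_study_csv, design)
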