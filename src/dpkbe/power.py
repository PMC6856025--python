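"""Monte-Carlo power and type-I error for ABE and SABE deciders.

Each simulated trial draws a replicate-design crossover study from the
log-normal variance-component model

    ln Q_{P,jk} = mu + ln(GMR) 1[P = test] + S_j + eps_{P,jk}

with a shared subject effect S_j ~ N(0, sigma_S^2) and independent
site-level noise eps ~ N(0, sigma_W^2).  Power is the fraction of trials
the chosen decider passes; all streams derive deterministically from the
scenario seed so curves are reproducible and nested across the subject
grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PowerScenario",
    "PowerCurve",
    "simulate_trial",
    "pass_rate",
    "power",
    "subjects_needed",
    "boundary_log_gmr",
    "at_boundary",
    "plot_power_curve",
]


@dataclass(frozen=True)
class PowerScenario:
    """Inputs of the power function.

    ``sigma_wr`` is the within-subject log SD of the reference product
    (the test product uses ``sigma_wt``, defaulting to the same value);
    ``sigma_s`` the between-subject log SD; ``n_grid`` the subject counts
    to evaluate; ``nr`` replicates per product; ``true_gmr`` the simulated
    geometric mean ratio (1 under the assumption of bioequivalence).
    """

    true_gmr: float = 1.0
    sigma_wr: float = 0.6
    sigma_s: float = 0.4
    n_grid: tuple[int, ...] = (6, 8, 10, 12, 14, 16, 18, 20, 24, 30)
    nr: int = 2
    margin: float = 1.25
    method: str = "abe"  # "abe" | "sabe"
    n_trials: int = 10_000
    seed: int = 0
    sigma_wt: float | None = None

    def __post_init__(self) -> None:
        if self.true_gmr <= 0:
            raise ValueError("true_gmr must be positive")
        if self.sigma_wr < 0 or self.sigma_s < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.sigma_wt is not None and self.sigma_wt < 0:
            raise ValueError("sigma_wt must be non-negative")
        if min(self.n_grid) < 3:
            raise ValueError("n must be >= 3")
        if self.nr < 1:
            raise ValueError("nr must be >= 1")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.method not in ("abe", "sabe"):
            raise ValueError("method must be 'abe' or 'sabe'")
        if self.margin <= 1:
            raise ValueError("margin must exceed 1")

    @property
    def sigma_wt_effective(self) -> float:
        return self.sigma_wr if self.sigma_wt is None else self.sigma_wt


@dataclass(frozen=True)
class PowerCurve:
    """Estimated pass probability per subject count, with binomial MC SE."""

    n_grid: tuple[int, ...]
    estimates: np.ndarray
    mc_se: np.ndarray
    scenario: PowerScenario = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n_subjects": self.n_grid, "power": self.estimates, "mc_se": self.mc_se}
        )


def _rng_for(scenario: PowerScenario, n: int) -> np.random.Generator:
    # n-keyed substream: curves are reproducible and nested across the grid
    return np.random.default_rng(np.random.SeedSequence([scenario.seed, n]))


def simulate_trial(
    scenario: PowerScenario, n: int, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """One simulated study: (test, ref) log-amount arrays of shape (n, nr)."""
    if rng is None:
        rng = _rng_for(scenario, n)
    t, r = _simulate_batch(scenario, n, 1, rng)
    return t[0], r[0]


def _simulate_batch(
    scenario: PowerScenario, n: int, n_trials: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    s = rng.normal(0.0, scenario.sigma_s, (n_trials, n, 1))
    log_gmr = np.log(scenario.true_gmr)
    test = log_gmr + s + rng.normal(
        0.0, scenario.sigma_wt_effective, (n_trials, n, scenario.nr)
    )
    ref = s + rng.normal(0.0, scenario.sigma_wr, (n_trials, n, scenario.nr))
    return test, ref


def _decide(
    scenario: PowerScenario, test: np.ndarray, ref: np.ndarray, criterion: str = "full"
) -> np.ndarray:
    """Vectorised pass/fail over a batch of trials.

    ``criterion`` selects the full decision rule or, for SABE, the scaled
    upper-bound component alone (``"bound"``), which is the statistically
    calibrated part of the decision.
    """
    n_trials, n, nr = test.shape
    log_m = np.log(scenario.margin)
    d = test.mean(axis=2) - ref.mean(axis=2)  # per-subject log differences
    dbar = d.mean(axis=1)
    se = d.std(axis=1, ddof=1) / np.sqrt(n)
    if scenario.method == "abe":
        half = stats.t.ppf(0.95, n - 1) * se
        return (dbar - half >= -log_m) & (dbar + half <= log_m)
    # SABE with Howe's approximation
    if nr < 2:
        raise ValueError("SABE requires nr >= 2 replicates")
    theta = (log_m / 0.25) ** 2
    df = n * (nr - 1)
    dev = ref - ref.mean(axis=2, keepdims=True)
    s2_wr = (dev**2).sum(axis=(1, 2)) / df
    eta = dbar**2 - s2_wr * theta
    u = (np.abs(dbar) + stats.t.ppf(0.95, n - 1) * se) ** 2 - dbar**2
    v = s2_wr * theta * (df / stats.chi2.ppf(0.95, df) - 1.0)
    scl_ub = eta + np.sqrt(u**2 + v**2)
    bound_ok = scl_ub <= 0
    if criterion == "bound":
        return bound_ok
    return bound_ok & (np.abs(dbar) <= log_m)


def pass_rate(scenario: PowerScenario, n: int, criterion: str = "full") -> tuple[float, float]:
    """Monte-Carlo pass probability and its binomial SE at one subject count."""
    rng = _rng_for(scenario, n)
    # batch in chunks to bound memory at large n_trials
    chunk = max(1, min(scenario.n_trials, 200_000 // max(n * scenario.nr, 1)))
    passes = 0
    done = 0
    while done < scenario.n_trials:
        b = min(chunk, scenario.n_trials - done)
        test, ref = _simulate_batch(scenario, n, b, rng)
        passes += int(_decide(scenario, test, ref, criterion).sum())
        done += b
    p = passes / scenario.n_trials
    se = float(np.sqrt(p * (1 - p) / scenario.n_trials))
    return p, se


def power(scenario: PowerScenario) -> PowerCurve:
    """Pass probability across the scenario's subject grid."""
    est, ses = [], []
    for n in scenario.n_grid:
        p, se = pass_rate(scenario, n)
        est.append(p)
        ses.append(se)
    return PowerCurve(tuple(scenario.n_grid), np.array(est), np.array(ses), scenario)


def subjects_needed(scenario: PowerScenario, target_power: float = 0.8):
    """Smallest subject count on the grid reaching the target power.

    Returns ``None`` when the target is unattained anywhere on the grid.
    """
    curve = power(scenario)
    for n, p in zip(curve.n_grid, curve.estimates):
        if p >= target_power:
            return n
    return None


def boundary_log_gmr(scenario: PowerScenario) -> float:
    """|ln GMR| at the applicable bioequivalence boundary for type-I-error
    scenarios: ln m for ABE; for SABE, the scaled limit sigma_WR ln m/0.25
    when it exceeds ln m."""
    log_m = np.log(scenario.margin)
    if scenario.method == "abe":
        return float(log_m)
    return float(max(log_m, scenario.sigma_wr * log_m / 0.25))


def at_boundary(scenario: PowerScenario) -> PowerScenario:
    """The same scenario with the true GMR moved to the BE boundary."""
    return replace(scenario, true_gmr=float(np.exp(boundary_log_gmr(scenario))))


def plot_power_curve(curves: Sequence[PowerCurve], labels: Sequence[str] | None = None, ax=None):
    """Plot one or more power curves (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for i, curve in enumerate(curves):
        label = labels[i] if labels else f"curve {i}"
        ax.errorbar(curve.n_grid, curve.estimates, yerr=curve.mc_se, marker="o", label=label)
    ax.axhline(0.8, ls="--", color="grey", lw=0.8)
    ax.set_xlabel("number of subjects")
    ax.set_ylabel("power")
    ax.set_ylim(0, 1)
    ax.legend()
    return ax
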