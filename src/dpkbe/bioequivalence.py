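"""Average and reference-scaled average bioequivalence of SC drug amounts.

Drug amounts in the stratum corneum are treated as log-normal, so all
inference is on natural-log-transformed amounts.  Two deciders are
implemented:

* **ABE** (average bioequivalence): the 90% confidence interval of the
  geometric mean ratio (GMR) of test to reference, from the paired
  within-subject log differences, must lie inside [1/m, m] (classically
  m = 1.25, i.e. 80-125%).

* **SABE** (reference-scaled average bioequivalence), for highly variable
  endpoints (within-subject log SD of the reference, s_WR, above 0.294):
  the scaled criterion

      eta = (mu_T - mu_R)^2 - sigma_WR^2 (ln m / 0.25)^2

  must have a 95% upper confidence bound (SCl_UB) at or below zero, and
  the GMR point estimate must additionally lie inside [1/m, m].

The within-subject reference SD comes from the closed-form replicate-site
estimator

    s_WR = sqrt( 1/(n(nr-1)) * sum_j sum_k [ln Q_jk - ln Qbar_j]^2 )

with Qbar_j the geometric mean of subject j's nr replicates.  SCl_UB is
built with Howe's approximation, combining a t-based 95% upper limit on
the squared-mean component with a chi-square 95% lower limit on the scaled
variance component.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import UPTAKE, CLEARANCE

__all__ = [
    "HIGH_VARIABILITY_THRESHOLD",
    "BEResult",
    "HighVariabilityFlag",
    "s_wr",
    "abe",
    "sabe",
    "scaled_criterion_bound",
    "classify_variability",
    "BioequivalenceModel",
    "BioequivalenceResults",
]

HIGH_VARIABILITY_THRESHOLD = 0.294


@dataclass(frozen=True)
class BEResult:
    """Outcome of one test/reference comparison on one endpoint."""

    endpoint: str
    gmr: float
    ci_low: float
    ci_high: float
    margin: float
    n: int
    nr: int
    abe_pass: bool
    s_wr: Optional[float] = None
    scl_ub: Optional[float] = None
    sabe_pass: Optional[bool] = None
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.gmr <= self.ci_high):
            raise ValueError("CI must bracket the GMR")
        if self.gmr <= 0:
            raise ValueError("GMR must be positive")


@dataclass(frozen=True)
class HighVariabilityFlag:
    s_wr: float
    threshold: float
    is_highly_variable: bool


def classify_variability(
    s_wr_value: float, threshold: float = HIGH_VARIABILITY_THRESHOLD
) -> HighVariabilityFlag:
    """Flag an endpoint as highly variable when s_WR strictly exceeds the
    regulatory threshold (0.294 on the log scale)."""
    if s_wr_value < 0:
        raise ValueError("s_WR must be non-negative")
    return HighVariabilityFlag(s_wr_value, threshold, s_wr_value > threshold)


def _as_replicate_matrix(ref_replicates) -> np.ndarray:
    arr = np.asarray(ref_replicates, dtype=float)
    if arr.ndim != 2:
        raise ValueError("replicates must be a 2-D (n_subjects x nr) array")
    if np.any(arr <= 0):
        raise ValueError("replicate amounts must be positive")
    return arr


def s_wr(ref_replicates) -> float:
    """Within-subject log-scale SD of the reference product.

    ``ref_replicates`` is an (n_subjects x nr) array of positive amounts,
    one row per subject, nr >= 2 replicates each.
    """
    arr = _as_replicate_matrix(ref_replicates)
    n, nr = arr.shape
    if nr < 2:
        raise ValueError("s_WR is undefined for nr < 2 replicates")
    logs = np.log(arr)
    dev = logs - logs.mean(axis=1, keepdims=True)
    return float(np.sqrt((dev**2).sum() / (n * (nr - 1))))


def _paired_log_differences(test_q, ref_q) -> np.ndarray:
    x = np.asarray(test_q, dtype=float)
    y = np.asarray(ref_q, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("test and reference amounts must be equal-length 1-D arrays")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("amounts must be positive for log transformation")
    return np.log(x) - np.log(y)


def abe(test_q, ref_q, margin: float = 1.25, endpoint: str = "amount") -> BEResult:
    """Traditional average bioequivalence from paired per-subject amounts.

    ``test_q`` and ``ref_q`` are the per-subject geometric-mean amounts,
    paired by position.  Passes when the anti-logged 90% CI of the mean
    within-subject log difference lies inside [1/margin, margin].
    """
    if margin <= 1:
        raise ValueError("margin must exceed 1")
    d = _paired_log_differences(test_q, ref_q)
    n = len(d)
    if n < 3:
        raise ValueError("ABE requires n >= 3 paired subjects")
    mean = d.mean()
    sd = d.std(ddof=1)
    half = stats.t.ppf(0.95, n - 1) * sd / np.sqrt(n)
    lo, hi = np.exp(mean - half), np.exp(mean + half)
    return BEResult(
        endpoint=endpoint,
        gmr=float(np.exp(mean)),
        ci_low=float(lo),
        ci_high=float(hi),
        margin=margin,
        n=n,
        nr=1,
        abe_pass=bool(lo >= 1 / margin and hi <= margin),
    )


def scaled_criterion_bound(d: np.ndarray, s_wr_value: float, df_wr: int, margin: float) -> float:
    """Howe's-approximation 95% upper bound on the scaled ABE criterion.

    ``d`` holds the per-subject within-subject log differences, and
    ``s_wr_value`` the reference within-subject SD with ``df_wr`` degrees
    of freedom (n(nr-1) for the replicate-site estimator).
    """
    n = len(d)
    theta = (np.log(margin) / 0.25) ** 2
    delta = d.mean()
    se = d.std(ddof=1) / np.sqrt(n)
    eta = delta**2 - s_wr_value**2 * theta
    # squared-mean component: 95% upper limit via the t quantile
    cq = (abs(delta) + stats.t.ppf(0.95, n - 1) * se) ** 2
    u = cq - delta**2
    # scaled-variance component: chi-square 95% lower limit on sigma_WR^2
    v = s_wr_value**2 * theta * (df_wr / stats.chi2.ppf(0.95, df_wr) - 1.0)
    return float(eta + np.sqrt(u**2 + v**2))


def sabe(
    test_q,
    ref_q,
    ref_replicates,
    margin: float = 1.25,
    endpoint: str = "amount",
) -> BEResult:
    """Reference-scaled average bioequivalence.

    ``test_q``/``ref_q`` are per-subject geometric-mean amounts (paired by
    position); ``ref_replicates`` the (n x nr) reference replicate amounts
    feeding the s_WR estimator.  Passes when SCl_UB <= 0 **and** the GMR
    point estimate lies inside [1/margin, margin].
    """
    base = abe(test_q, ref_q, margin=margin, endpoint=endpoint)
    reps = _as_replicate_matrix(ref_replicates)
    n_wr, nr = reps.shape
    s = s_wr(reps)
    d = _paired_log_differences(test_q, ref_q)
    scl_ub = scaled_criterion_bound(d, s, n_wr * (nr - 1), margin)
    gmr_ok = 1 / margin <= base.gmr <= margin
    return BEResult(
        endpoint=endpoint,
        gmr=base.gmr,
        ci_low=base.ci_low,
        ci_high=base.ci_high,
        margin=margin,
        n=base.n,
        nr=nr,
        abe_pass=base.abe_pass,
        s_wr=s,
        scl_ub=scl_ub,
        sabe_pass=bool(scl_ub <= 0 and gmr_ok),
    )


class BioequivalenceModel:
    """Bioequivalence assessment of a test against a reference product.

    A statsmodels-style model over a tidy per-site amount table (columns
    ``subject_id``, ``product_code``, ``phase``, ``replicate_index``,
    ``q_ug_cm2``).  ``fit`` evaluates both study endpoints (uptake and
    clearance amounts) and returns a :class:`BioequivalenceResults`.

    Parameters
    ----------
    data : DataFrame
        Tidy per-site drug amounts.
    test, ref : str
        Product codes of the test and reference products.
    margin : float
        Bioequivalence margin m (1.25 standard; 1.33 supported for
        sensitivity analyses).
    method : {"abe", "sabe", "auto"}
        ``auto`` applies SABE when the endpoint is highly variable
        (s_WR > 0.294) and ABE otherwise.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        test: str,
        ref: str,
        margin: float = 1.25,
        method: str = "auto",
    ) -> None:
        if method not in ("abe", "sabe", "auto"):
            raise ValueError("method must be 'abe', 'sabe' or 'auto'")
        for col in ("subject_id", "product_code", "phase", "replicate_index", "q_ug_cm2"):
            if col not in data.columns:
                raise KeyError(f"data is missing column {col!r}")
        self.data = data
        self.test = test
        self.ref = ref
        self.margin = margin
        self.method = method

    @classmethod
    def from_sites(cls, sites, test: str, ref: str, **kwargs) -> "BioequivalenceModel":
        from .sc_metrics import amounts_table

        return cls(amounts_table(sites), test, ref, **kwargs)

    def _endpoint_arrays(self, phase: str):
        """Per-subject geometric means (paired, listwise-complete) and the
        reference replicate matrix for one phase."""
        from .records import geometric_mean

        block = self.data[self.data["phase"] == phase]
        test_means, ref_means, ref_rows = {}, {}, {}
        for (subject, product), cell in block.groupby(["subject_id", "product_code"]):
            qs = cell["q_ug_cm2"].to_numpy(dtype=float)
            if product == self.test:
                test_means[subject] = geometric_mean(qs)
            elif product == self.ref:
                ref_means[subject] = geometric_mean(qs)
                ref_rows[subject] = qs
        subjects = sorted(set(test_means) & set(ref_means))
        n_excluded = len(set(test_means) ^ set(ref_means))
        t = np.array([test_means[s] for s in subjects])
        r = np.array([ref_means[s] for s in subjects])
        nr_counts = {len(ref_rows[s]) for s in subjects}
        reps = (
            np.array([ref_rows[s] for s in subjects])
            if len(nr_counts) == 1 and nr_counts != {1}
            else None
        )
        return t, r, reps, n_excluded

    def fit(self) -> "BioequivalenceResults":
        results = {}
        for phase in (UPTAKE, CLEARANCE):
            t, r, reps, n_excluded = self._endpoint_arrays(phase)
            method = self.method
            s = s_wr(reps) if reps is not None else None
            if method == "auto":
                if s is not None and classify_variability(s).is_highly_variable:
                    method = "sabe"
                else:
                    method = "abe"
            if method == "sabe":
                if reps is None:
                    raise ValueError(
                        "SABE requires a constant number (>= 2) of reference "
                        "replicates per subject"
                    )
                res = sabe(t, r, reps, margin=self.margin, endpoint=phase)
            else:
                res = abe(t, r, margin=self.margin, endpoint=phase)
                if s is not None:
                    res = BEResult(
                        endpoint=res.endpoint,
                        gmr=res.gmr,
                        ci_low=res.ci_low,
                        ci_high=res.ci_high,
                        margin=res.margin,
                        n=res.n,
                        nr=reps.shape[1],
                        abe_pass=res.abe_pass,
                        s_wr=s,
                    )
            results[phase] = replace(res, n_excluded=n_excluded)
        return BioequivalenceResults(self, results)


class BioequivalenceResults:
    """Fitted bioequivalence comparison for both study endpoints."""

    def __init__(self, model: BioequivalenceModel, endpoints: dict[str, BEResult]):
        self.model = model
        self.endpoints = endpoints

    def __getitem__(self, endpoint: str) -> BEResult:
        return self.endpoints[endpoint]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for phase, r in self.endpoints.items():
            rows.append(
                {
                    "endpoint": phase,
                    "test": self.model.test,
                    "ref": self.model.ref,
                    "gmr": r.gmr,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "margin": r.margin,
                    "s_wr": r.s_wr,
                    "scl_ub": r.scl_ub,
                    "abe_pass": r.abe_pass,
                    "sabe_pass": r.sabe_pass,
                    "n": r.n,
                    "nr": r.nr,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"Bioequivalence assessment: {self.model.test} vs {self.model.ref} "
            f"(m = {self.model.margin}, method = {self.model.method})",
            "-" * 78,
            f"{'endpoint':<12}{'GMR':>8}{'90% CI':>18}{'s_WR':>8}"
            f"{'SCl_UB':>9}{'ABE':>6}{'SABE':>6}",
        ]
        for phase, r in self.endpoints.items():
            swr = f"{r.s_wr:.3f}" if r.s_wr is not None else "-"
            scl = f"{r.scl_ub:+.3f}" if r.scl_ub is not None else "-"
            sab = {True: "pass", False: "fail", None: "-"}[r.sabe_pass]
            lines.append(
                f"{phase:<12}{r.gmr:>8.2f}"
                f"{f'({r.ci_low:.2f}-{r.ci_high:.2f})':>18}"
                f"{swr:>8}{scl:>9}{'pass' if r.abe_pass else 'fail':>6}{sab:>6}"
            )
        lines.append("-" * 78)
        return "\n".join(lines)
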