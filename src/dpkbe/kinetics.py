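"""Per-subject clearance kinetics from uptake/clearance drug amounts.

With Q_up the drug amount/area in the SC at the end of application and Q_cl
the amount after a further clearance interval Δt, the average flux into the
viable tissue over that interval is

    J = (Q_up - Q_cl) / Δt

and, reading clearance as a first-order process,

    k = -ln(Q_cl / Q_up) / Δt.

Both metrics may legitimately come out negative when measurement
variability makes Q_cl exceed Q_up; negative values propagate unmodified.
Product comparisons of J and k use paired differences (not ratios), because
ratios are meaningless for sign-changing quantities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import CLEARANCE, UPTAKE, SubjectProductSummary, geometric_mean

__all__ = [
    "KineticEstimate",
    "PairedDifferenceResult",
    "summarize_subject",
    "summarize_study",
    "flux_in_vivo",
    "clearance_rate_constant",
    "kinetic_estimates",
    "paired_difference_test",
    "study_level_table",
]


@dataclass(frozen=True)
class KineticEstimate:
    subject_id: str
    product_code: str
    j_ng_cm2_h: float
    k_per_h: float


def summarize_subject(
    q_table: pd.DataFrame,
    subject_id: str,
    product_code: str,
    pool_products: Optional[Sequence[str]] = None,
) -> SubjectProductSummary:
    """Geometric-mean Q_up/Q_cl for one subject and product.

    ``q_table`` is the tidy per-site amount table (columns ``subject_id``,
    ``product_code``, ``phase``, ``replicate_index``, ``q_ug_cm2``).  When
    ``pool_products`` is given, replicates from all listed product codes
    are pooled (e.g. reference and positive control combined into a
    four-replicate "average" product) and the result is labelled with
    ``product_code``.
    """
    codes = list(pool_products) if pool_products is not None else [product_code]
    sub = q_table[
        (q_table["subject_id"] == subject_id)
        & (q_table["product_code"].isin(codes))
    ]
    values = {}
    for phase in (UPTAKE, CLEARANCE):
        qs = sub.loc[sub["phase"] == phase, "q_ug_cm2"]
        if len(qs) == 0:
            raise ValueError(
                f"no {phase} replicates for subject {subject_id!r}, "
                f"product(s) {codes}"
            )
        values[phase] = geometric_mean(qs.to_numpy())
    n_used = int((sub["phase"] == UPTAKE).sum())
    return SubjectProductSummary(
        subject_id=subject_id,
        product_code=product_code,
        q_up=values[UPTAKE],
        q_cl=values[CLEARANCE],
        n_replicates_used=n_used,
    )


def summarize_study(
    q_table: pd.DataFrame,
    pooled: Optional[dict[str, Sequence[str]]] = None,
) -> list[SubjectProductSummary]:
    """Per-subject summaries for every product (plus optional pooled labels).

    ``pooled`` maps a new label to the product codes whose replicates it
    combines, e.g. ``{"US-Ave": ["US-Ref", "US-C+"]}``.
    """
    out = []
    subjects = sorted(q_table["subject_id"].unique())
    products = sorted(q_table["product_code"].unique())
    for subject in subjects:
        for product in products:
            out.append(summarize_subject(q_table, subject, product))
        if pooled:
            for label, codes in pooled.items():
                out.append(summarize_subject(q_table, subject, label, pool_products=codes))
    return out


def flux_in_vivo(summary: SubjectProductSummary, delta_t_h: float) -> float:
    """Average SC-to-viable-tissue flux over the clearance interval,
    ng/cm^2/h (amounts in ug/cm^2; negative values returned as-is)."""
    if delta_t_h <= 0:
        raise ValueError("delta_t_h must be positive")
    return 1000.0 * (summary.q_up - summary.q_cl) / delta_t_h


def clearance_rate_constant(summary: SubjectProductSummary, delta_t_h: float) -> float:
    """First-order clearance rate constant k (1/h).

    Exact inverse of Q_cl = Q_up * exp(-k Δt); requires positive amounts.
    """
    if delta_t_h <= 0:
        raise ValueError("delta_t_h must be positive")
    if summary.q_up <= 0 or summary.q_cl <= 0:
        raise ValueError("amounts must be positive for the rate constant")
    return -float(np.log(summary.q_cl / summary.q_up)) / delta_t_h


def kinetic_estimates(
    summaries: Iterable[SubjectProductSummary], delta_t_h: float
) -> pd.DataFrame:
    """Per-subject J and k for each summary, as a tidy frame."""
    rows = [
        {
            "subject_id": s.subject_id,
            "product_code": s.product_code,
            "q_up_ug_cm2": s.q_up,
            "q_cl_ug_cm2": s.q_cl,
            "j_ng_cm2_h": flux_in_vivo(s, delta_t_h),
            "k_per_h": clearance_rate_constant(s, delta_t_h),
        }
        for s in summaries
    ]
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PairedDifferenceResult:
    mean_difference: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    n_excluded: int = 0
    degenerate: bool = False  # zero variance in the paired differences


def paired_difference_test(
    values_test: pd.Series | Sequence[float],
    values_ref: pd.Series | Sequence[float],
    confidence: float = 0.90,
) -> PairedDifferenceResult:
    """Paired comparison of a per-subject metric between two products.

    Accepts either two pandas Series indexed by subject (unpaired subjects
    are dropped, counted in ``n_excluded``) or two equal-length sequences
    already paired by position.  Returns the mean difference, the
    t-distribution confidence interval, and the two-sided paired t p-value.
    """
    n_excluded = 0
    if isinstance(values_test, pd.Series) and isinstance(values_ref, pd.Series):
        common = values_test.index.intersection(values_ref.index)
        n_excluded = (len(values_test) - len(common)) + (len(values_ref) - len(common))
        x = values_test.loc[common].to_numpy(dtype=float)
        y = values_ref.loc[common].to_numpy(dtype=float)
    else:
        x = np.asarray(values_test, dtype=float)
        y = np.asarray(values_ref, dtype=float)
        if x.shape != y.shape:
            raise ValueError("paired sequences must have equal length")
    n = len(x)
    if n < 2:
        raise ValueError("paired test requires n >= 2 pairs")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        # all differences identical: CI degenerates to the point
        p = 1.0 if mean == 0.0 else 0.0
        return PairedDifferenceResult(mean, mean, mean, p, n, n_excluded, degenerate=True)
    se = sd / np.sqrt(n)
    tq = stats.t.ppf(0.5 + confidence / 2.0, n - 1)
    t_stat = mean / se
    p = 2.0 * stats.t.sf(abs(t_stat), n - 1)
    return PairedDifferenceResult(
        mean, mean - tq * se, mean + tq * se, float(p), n, n_excluded
    )


def study_level_table(per_subject: pd.DataFrame, confidence: float = 0.90) -> pd.DataFrame:
    """Study-level summary per product: amounts as the anti-log of the mean
    log Q with a t-based CI; J and k as arithmetic means with t-based CIs."""
    rows = []
    for product, block in per_subject.groupby("product_code", sort=True):
        n = len(block)
        tq = stats.t.ppf(0.5 + confidence / 2.0, n - 1) if n > 1 else np.nan
        row = {"product_code": product, "n": n}
        for col, log_scale in (
            ("q_up_ug_cm2", True),
            ("q_cl_ug_cm2", True),
            ("j_ng_cm2_h", False),
            ("k_per_h", False),
        ):
            v = block[col].to_numpy(dtype=float)
            if log_scale:
                m, s = np.log(v).mean(), np.log(v).std(ddof=1)
                half = tq * s / np.sqrt(n)
                row[col] = float(np.exp(m))
                row[col + "_lo"] = float(np.exp(m - half))
                row[col + "_hi"] = float(np.exp(m + half))
            else:
                m, s = v.mean(), v.std(ddof=1)
                half = tq * s / np.sqrt(n)
                row[col] = float(m)
                row[col + "_lo"] = float(m - half)
                row[col + "_hi"] = float(m + half)
        rows.append(row)
    return pd.DataFrame(rows)
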