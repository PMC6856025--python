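"""Published-scale example data for worked examples and cross-checks.

These are study-level summary statistics (product-level geometric-mean drug
amounts) from a pair of duplicate-site tape-stripping studies of three
commercial 5% acyclovir creams: a US reference cream compared against a UK
product (study 1) and against an Austrian generic (study 2), each study
carrying the reference twice (once as a positive control).  Subject-level
data are not public; these product-level means support worked examples,
GMR point-estimate arithmetic and the steady-state diffusion extrapolation.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "acyclovir_study_summary",
    "combined_mean_amounts",
    "ACYCLOVIR_MW",
]

#: Molecular weight of acyclovir, Da (standard value).
ACYCLOVIR_MW = 225.2


def acyclovir_study_summary() -> pd.DataFrame:
    """Product-level geometric-mean SC amounts (ug/cm^2) per study.

    ``q_up``/``q_cl`` are uptake (end of 6 h application) and clearance
    (17 h post-removal) amounts; the ``*-Ave`` rows pool the reference and
    positive-control replicates (four sites per subject).
    """
    rows = [
        # study, product, role, q_up, q_cl
        (1, "US-Ref", "reference", 0.68, 0.45),
        (1, "US-C+", "positive_control", 0.59, 0.42),
        (1, "UK-Test", "test", 0.42, 0.26),
        (1, "US-Ave", "pooled_reference", 0.64, 0.43),
        (2, "AT-Ref", "reference", 1.54, 1.69),
        (2, "AT-C+", "positive_control", 1.74, 1.45),
        (2, "US-Test", "test", 0.96, 0.85),
        (2, "AT-Ave", "pooled_reference", 1.64, 1.50),
    ]
    return pd.DataFrame(rows, columns=["study", "product", "role", "q_up", "q_cl"])


def combined_mean_amounts() -> tuple[float, float]:
    """All-product mean amounts (Q_up, Q_cl) in ug/cm^2 over both studies
    combined (60 site pairs) — the inputs of the steady-state
    extrapolation worked example."""
    return 0.87, 0.69
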