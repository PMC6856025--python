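"""CSV readers/writers and design-balance validation.

The canonical on-disk layout is a tidy, comma-separated, UTF-8 table with
one row per tape group per site:

    subject_id, product_code, phase, replicate_index, group_index,
    sc_mass_mg, extract_concentration_ug_ml, n_tapes_in_group
    [, tewl_baseline, tewl_reading]

The two TEWL columns are optional; when present, ``tewl_baseline`` repeats
the site's pre-stripping baseline on every row and ``tewl_reading`` carries
the evaporimeter reading after that tape group.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .design import StudyDesign
from .records import (
    IntegrityError,
    SchemaError,
    SiteRecord,
    TapeGroupRecord,
    ValidationError,
)

__all__ = [
    "REQUIRED_COLUMNS",
    "read_study",
    "write_study",
    "sites_to_frame",
    "validate_design_balance",
]

REQUIRED_COLUMNS = (
    "subject_id",
    "product_code",
    "phase",
    "replicate_index",
    "group_index",
    "sc_mass_mg",
    "extract_concentration_ug_ml",
    "n_tapes_in_group",
)

_SITE_KEY = ["subject_id", "product_code", "phase", "replicate_index"]


def read_study(path: str | Path, design: StudyDesign) -> list[SiteRecord]:
    """Read a tidy tape-group CSV into one :class:`SiteRecord` per site.

    Raises
    ------
    SchemaError
        if a required column is absent.
    IntegrityError
        if a (subject, product, phase, replicate, group_index) key repeats.
    ValidationError
        if a mass or concentration is negative.
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "product_code": str, "phase": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    dup_key = _SITE_KEY + ["group_index"]
    dup = df.duplicated(subset=dup_key)
    if dup.any():
        first = df.loc[dup, dup_key].iloc[0].tolist()
        raise IntegrityError(f"duplicate tape-group row for key {first}")

    if (df["sc_mass_mg"] < 0).any() or (df["extract_concentration_ug_ml"] < 0).any():
        raise ValidationError("negative sc_mass_mg or extract_concentration_ug_ml")

    has_tewl = "tewl_baseline" in df.columns and "tewl_reading" in df.columns
    sites: list[SiteRecord] = []
    for _, block in df.groupby(_SITE_KEY, sort=True):
        block = block.sort_values("group_index")
        groups = [
            TapeGroupRecord(
                subject_id=row.subject_id,
                product_code=row.product_code,
                phase=row.phase,
                replicate_index=int(row.replicate_index),
                group_index=int(row.group_index),
                sc_mass_mg=float(row.sc_mass_mg),
                extract_concentration_ug_ml=float(row.extract_concentration_ug_ml),
                n_tapes_in_group=int(row.n_tapes_in_group),
            )
            for row in block.itertuples(index=False)
        ]
        tewl_baseline = None
        tewl_series = None
        if has_tewl and block["tewl_baseline"].notna().all():
            tewl_baseline = float(block["tewl_baseline"].iloc[0])
            tewl_series = [float(v) for v in block["tewl_reading"] if np.isfinite(v)]
        sites.append(
            SiteRecord(
                design=design,
                groups=groups,
                tewl_baseline=tewl_baseline,
                tewl_series=tewl_series,
            )
        )
    return sites


def sites_to_frame(sites: Sequence[SiteRecord]) -> pd.DataFrame:
    """Flatten SiteRecords back to the tidy tape-group table."""
    rows = []
    for site in sites:
        series = list(site.tewl_series) if site.tewl_series is not None else []
        for i, g in enumerate(site.groups):
            row = {
                "subject_id": g.subject_id,
                "product_code": g.product_code,
                "phase": g.phase,
                "replicate_index": g.replicate_index,
                "group_index": g.group_index,
                "sc_mass_mg": g.sc_mass_mg,
                "extract_concentration_ug_ml": g.extract_concentration_ug_ml,
                "n_tapes_in_group": g.n_tapes_in_group,
            }
            if site.tewl_baseline is not None:
                row["tewl_baseline"] = site.tewl_baseline
                row["tewl_reading"] = series[i] if i < len(series) else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def write_study(sites: Sequence[SiteRecord], path: str | Path) -> None:
    sites_to_frame(sites).to_csv(path, index=False)


def validate_design_balance(
    sites: Sequence[SiteRecord], design: StudyDesign
) -> pd.DataFrame:
    """Report every (subject, product, phase) cell whose replicate count
    differs from the design's ``n_replicates``.

    Returns an empty frame iff the study is fully balanced.  Cells that are
    entirely absent for a (subject, product) pair observed elsewhere are
    reported as missing.
    """
    counts: dict[tuple, int] = {}
    subjects, products = set(), set()
    for site in sites:
        cell = (site.subject_id, site.product_code, site.phase)
        counts[cell] = counts.get(cell, 0) + 1
        subjects.add(site.subject_id)
        products.add(site.product_code)

    rows = []
    from .records import PHASES

    for subject in sorted(subjects):
        for product in sorted(products):
            for phase in PHASES:
                n = counts.get((subject, product, phase), 0)
                if n != design.n_replicates:
                    rows.append(
                        {
                            "subject_id": subject,
                            "product_code": product,
                            "phase": phase,
                            "n_replicates_found": n,
                            "n_replicates_expected": design.n_replicates,
                            "status": "missing" if n < design.n_replicates else "extra",
                        }
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "product_code",
            "phase",
            "n_replicates_found",
            "n_replicates_expected",
            "status",
        ],
    )
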