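"""Exceedance classification and human-readable summaries.

Non-cancer results are flagged where the hazard index exceeds 1.  Cancer
risks are banded on the conventional scheme: below 1e-6 negligible, 1e-6 to
1e-4 "acceptable-concern" and above 1e-4 high — the study states only the
1e-6 lower bound; the 1e-4 upper band is the conventional extension used
throughout regulatory practice.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io_config import ValidationError

log = logging.getLogger(__name__)

__all__ = ["CR_BANDS", "classify", "pathway_order"]

#: (upper bound, label); bands partition [0, inf).
CR_BANDS: tuple[tuple[float, str], ...] = (
    (1e-6, "negligible"),
    (1e-4, "acceptable-concern"),
    (np.inf, "high"),
)


def cr_band(cr: float) -> str:
    if not cr >= 0:
        raise ValidationError(f"cancer risk must be >= 0, got {cr!r}")
    for upper, label in CR_BANDS:
        if cr < upper:
            return label
    return CR_BANDS[-1][1]


def classify(rows: pd.DataFrame) -> pd.DataFrame:
    """Exceedance report for a deterministic risk table.

    One row per station x compound (Mean rows excluded) with ``hi_flag``
    (HI > 1), ``cr_band`` (empty for compounds without a slope factor) and
    ``worst_pathway`` — the pathway with the largest cancer risk where one
    exists, otherwise the largest hazard quotient.
    """
    if len(rows) == 0:
        raise ValidationError("empty risk table")
    body = rows[rows["station"] != "Mean"].copy()
    out = body[["station", "compound"]].copy()
    out["hi"] = body["hi"]
    out["hi_flag"] = body["hi"] > 1.0

    has_cr = "cr_total" in body.columns
    crs = body[["cr_inh", "cr_ing", "cr_der"]] if has_cr else None

    def worst(row) -> str:
        lab = {"inh": "inhalation", "ing": "ingestion", "der": "dermal"}
        if has_cr and np.isfinite(row.get("cr_total", np.nan)):
            vals = {p: row[f"cr_{p}"] for p in lab}
        else:
            vals = {p: row[f"hq_{p}"] for p in lab}
        return lab[max(vals, key=vals.get)]

    out["worst_pathway"] = body.apply(worst, axis=1)
    if has_cr:
        out["cr_total"] = body["cr_total"]
        out["cr_band"] = [
            cr_band(c) if np.isfinite(c) else "" for c in body["cr_total"]
        ]
    else:
        out["cr_band"] = ""
    n_flag = int(out["hi_flag"].sum())
    log.info("classification: %d rows, %d HI exceedances, %d non-negligible CR",
             len(out), n_flag,
             int((out["cr_band"] != "negligible").sum() - (out["cr_band"] == "").sum())
             if has_cr else 0)
    return out.reset_index(drop=True)


def pathway_order(rows: pd.DataFrame, metric: str = "cr") -> list[str]:
    """Pathways sorted by decreasing mean risk (``cr`` or ``hq``) over the
    station rows — the study-level "ingestion > dermal > inhalation" type
    ordering."""
    body = rows[rows["station"] != "Mean"]
    lab = {"inh": "inhalation", "ing": "ingestion", "der": "dermal"}
    cols = {p: f"{metric}_{p}" for p in lab}
    missing = [c for c in cols.values() if c not in body.columns]
    if missing:
        raise ValidationError(f"risk table lacks columns {missing}")
    means = {lab[p]: float(body[c].mean(skipna=True)) for p, c in cols.items()}
    return sorted(means, key=means.get, reverse=True)
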