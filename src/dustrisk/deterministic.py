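"""Deterministic multi-pathway dose, hazard and cancer-risk engine.

Implements the conventional US-EPA-style dust exposure equations for the
three pathways.  With ``Cs`` the dust concentration (μg/g) and the exposure
factors of :class:`~dustrisk.io_config.ExposureFactors`:

    ADD_inh = Cs · IR_inh · EF · ED / (BW · AT · PEF)
    ADD_ing = Cs · IR_ing · EF · ED · 1e-6 / (BW · AT)
    ADD_der = Cs · SA · AF · ABS · EF · ED · 1e-6 / (BW · AT)

(μg/g equals mg/kg of dust, so the inhalation pathway converts through the
particulate emission factor without the 1e-6 μg→mg factor that the mass-based
ingestion and dermal pathways carry.)

Non-carcinogenic use divides by ``AT = at_noncarc`` and the pathway reference
dose to give hazard quotients; the hazard index is their sum.  Carcinogenic
use divides by ``AT = at_carc`` to give lifetime average daily doses (LADD),
summed over population groups — an inactive group (children in an
occupational scenario) contributes zero — and multiplies by the cancer slope
factor: ``CR = LADD · CSF``.

All dose operations are linear (homogeneous of degree 1) in ``Cs`` and
accept numpy arrays for the concentration or any exposure factor, which is
how the Monte Carlo engine reuses them unchanged.
"""
from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_config import (
    COMPOUNDS,
    ConcentrationTable,
    ExposureFactors,
    ParameterError,
    Scenario,
    ToxicityReference,
    _station_key,
)

log = logging.getLogger(__name__)

__all__ = [
    "PATHWAYS",
    "add_dermal",
    "add_ingestion",
    "add_inhalation",
    "cancer_risk",
    "concentration_from_ingestion_hq",
    "hazard_index",
    "hazard_quotient",
    "pathway_dose",
    "run_deterministic",
]

PATHWAYS: tuple[str, ...] = ("inhalation", "ingestion", "dermal")

UG_TO_MG = 1e-6


def _at(f: ExposureFactors, carcinogenic: bool):
    at = f.at_carc if carcinogenic else f.at_noncarc
    for name, v in (("bw", f.bw), ("at", at), ("pef", f.pef)):
        if v is None or (np.ndim(v) == 0 and not v > 0):
            raise ParameterError(f"non-positive {name} in group {f.group!r}")
    return at


def add_inhalation(cs, f: ExposureFactors, carcinogenic: bool = False):
    """Average daily inhalation dose, mg/kg/day."""
    if not f.active:
        return 0.0 * np.asarray(cs) if np.ndim(cs) else 0.0
    at = _at(f, carcinogenic)
    return cs * f.ir_inh * f.ef * f.ed / (f.bw * at * f.pef)


def add_ingestion(cs, f: ExposureFactors, carcinogenic: bool = False):
    """Average daily ingestion dose, mg/kg/day."""
    if not f.active:
        return 0.0 * np.asarray(cs) if np.ndim(cs) else 0.0
    at = _at(f, carcinogenic)
    return cs * f.ir_ing * f.ef * f.ed * UG_TO_MG / (f.bw * at)


def add_dermal(cs, f: ExposureFactors, carcinogenic: bool = False):
    """Average daily dermal-contact dose, mg/kg/day."""
    if not f.active:
        return 0.0 * np.asarray(cs) if np.ndim(cs) else 0.0
    at = _at(f, carcinogenic)
    return cs * f.sa * f.af * f.abs * f.ef * f.ed * UG_TO_MG / (f.bw * at)


_DOSE = {"inhalation": add_inhalation, "ingestion": add_ingestion, "dermal": add_dermal}


def pathway_dose(
    pathway: str,
    cs,
    groups: Iterable[ExposureFactors],
    carcinogenic: bool = False,
):
    """Dose for one pathway summed over population groups (the lifetime-dose
    group sum; inactive groups contribute zero)."""
    fn = _DOSE[pathway]
    return sum(fn(cs, f, carcinogenic) for f in groups)


def hazard_quotient(dose, tox: ToxicityReference, pathway: str):
    """dose / pathway reference dose (unified-RfD convention by default)."""
    rfd = tox.rfd_for(pathway)
    if rfd is None or (np.ndim(rfd) == 0 and not rfd > 0):
        raise ParameterError(
            f"no positive {pathway} reference dose for {tox.compound}"
        )
    return dose / rfd


def hazard_index(hqs: Sequence[float]):
    """Plain left-to-right sum of hazard quotients; empty input gives 0.

    Callers pass quotients in the fixed pathway order (inhalation, ingestion,
    dermal) so that floating-point summation order is reproducible.
    """
    total = 0.0
    for hq in hqs:
        total = total + hq
    return total


def cancer_risk(ladd, tox: ToxicityReference):
    """CR = LADD · CSF.  Requires a cancer slope factor; compounds without
    one carry no cancer entry at all (absent, never zero)."""
    if tox.csf is None:
        raise ParameterError(f"{tox.compound} has no cancer slope factor")
    return ladd * tox.csf


def concentration_from_ingestion_hq(hq: float, tox: ToxicityReference,
                                    f: ExposureFactors) -> float:
    """Invert the ingestion hazard quotient for the dust concentration
    (μg/g).  Used to recover the station-level concentrations underlying
    published hazard-quotient tables."""
    return hq * tox.rfd_oral * f.bw * f.at_noncarc / (f.ir_ing * f.ef * f.ed * UG_TO_MG)


def run_deterministic(
    conc: ConcentrationTable | pd.DataFrame,
    scenario: Scenario,
    aggregation: str = "mean",
) -> pd.DataFrame:
    """Evaluate the full deterministic risk table.

    Parameters
    ----------
    conc
        A :class:`ConcentrationTable`, or an already-aggregated DataFrame
        with columns ``station, compound, value`` (one concentration per
        station x compound).
    scenario
        Exposure scenario; compounds without a toxicity entry must appear in
        ``scenario.skip`` and are excluded with a logged warning.
    aggregation
        Statistic collapsing sampling steps into the per-station
        concentration (the survey does not state which step statistic feeds
        its risk tables; the default is the mean over steps, and callers that
        need a specific statistic pass it explicitly).

    Returns
    -------
    DataFrame with one row per station x compound, ordered by (station,
    compound), columns ``add_inh/add_ing/add_der`` (doses), ``hq_*``/``hi``,
    and for carcinogens ``ladd_*``/``cr_*``/``cr_total`` (NaN where no slope
    factor exists).  One ``Mean`` row per compound — the arithmetic mean of
    its station rows — is appended.
    """
    if isinstance(conc, ConcentrationTable):
        flat = conc.aggregate(aggregation)
    else:
        flat = conc.copy()
    if len(flat) == 0:
        log.warning("empty concentration table: empty result")
        return pd.DataFrame()

    flat = flat.sort_values(
        by=["station", "compound"],
        key=lambda s: (
            s.map(_station_key) if s.name == "station" else s.map(COMPOUNDS.index)
        ),
        kind="stable",
    )

    groups = list(scenario.exposure.values())
    rows = []
    for r in flat.itertuples(index=False):
        tox = scenario.toxicity_for(r.compound)
        if tox is None:
            continue
        cs = r.value
        doses = {p: pathway_dose(p, cs, groups, carcinogenic=False) for p in PATHWAYS}
        hqs = {p: hazard_quotient(doses[p], tox, p) for p in PATHWAYS}
        row = {
            "station": r.station,
            "compound": r.compound,
            "add_inh": doses["inhalation"],
            "add_ing": doses["ingestion"],
            "add_der": doses["dermal"],
            "hq_inh": hqs["inhalation"],
            "hq_ing": hqs["ingestion"],
            "hq_der": hqs["dermal"],
            "hi": hazard_index(
                [hqs["inhalation"], hqs["ingestion"], hqs["dermal"]]
            ),
        }
        if tox.csf is not None:
            ladds = {p: pathway_dose(p, cs, groups, carcinogenic=True)
                     for p in PATHWAYS}
            crs = {p: cancer_risk(ladds[p], tox) for p in PATHWAYS}
            row.update(
                ladd_inh=ladds["inhalation"],
                ladd_ing=ladds["ingestion"],
                ladd_der=ladds["dermal"],
                cr_inh=crs["inhalation"],
                cr_ing=crs["ingestion"],
                cr_der=crs["dermal"],
                cr_total=hazard_index(
                    [crs["inhalation"], crs["ingestion"], crs["dermal"]]
                ),
            )
        rows.append(row)

    if not rows:
        log.warning("no compound with toxicity data: empty result")
        return pd.DataFrame()
    out = pd.DataFrame(rows)

    means = (
        out.drop(columns="station")
        .groupby("compound", sort=False)
        .mean(numeric_only=True)
        .reset_index()
    )
    means.insert(0, "station", "Mean")
    out = pd.concat([out, means], ignore_index=True)
    log.info("deterministic risk: %d station rows, %d compounds",
             len(out) - len(means), len(means))
    return out
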