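"""Domain types, table/scenario I/O and packaged reference fixtures.

The package's canonical in-memory containers:

* :class:`ConcentrationTable` -- long-format station x compound x
  sampling-step dust concentrations (μg/g) with below-LOD censoring flags;
* :class:`ExposureFactors` / :class:`ToxicityReference` /
  :class:`DistributionSpec` bundled into a :class:`Scenario`.

Packaged fixtures transcribe the published station-level tables of the Yazd
industrial-park outdoor-dust survey (concentration summary, per-pathway
hazard quotients, hazard indices, BBP cancer risks); they are used as
reference oracles by the test-suite and the acceptance script.
"""
from __future__ import annotations

import dataclasses
import logging
import math
import tomllib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "COMPOUNDS",
    "COMPOUND_ALIASES",
    "ConcentrationRecord",
    "ConcentrationTable",
    "DistributionSpec",
    "DustRiskError",
    "ExposureFactors",
    "ParameterError",
    "Scenario",
    "ToxicityReference",
    "ValidationError",
    "load_fixture_table",
    "load_scenario",
    "normalize_compound",
    "packaged_scenario_path",
    "read_concentration_table",
    "read_results_table",
    "summary_to_table",
    "write_results_table",
]


class DustRiskError(Exception):
    """Base class for errors raised by this package."""


class ValidationError(DustRiskError, ValueError):
    """Raised when input data violate a documented invariant."""


class ParameterError(DustRiskError, ValueError):
    """Raised for non-physical exposure or toxicity parameters."""


# ---------------------------------------------------------------------------
# compound registry
# ---------------------------------------------------------------------------

#: Canonical phthalate-ester codes.  ``DOP`` and ``DiOP`` are distinct
#: registry entries: the survey's concentration table lists both a "DOP" row
#: (carrying a reference dose, hence included in risk) and a separate
#: "di-octyl phthalate" row with no reference dose (risk never computed).
COMPOUNDS: tuple[str, ...] = ("DMP", "DEP", "DBP", "IBP", "BBP", "BEHP", "DOP", "DiOP")

#: Published synonyms mapped onto the canonical codes.
COMPOUND_ALIASES: dict[str, str] = {
    "DIBP": "IBP",
    "DNBP": "DBP",
    "DBP": "DBP",
    "DEHP": "BEHP",
    "DNOP": "DOP",
    "DI-OCTYL PHTHALATE": "DiOP",
    "DI- OCTYL PHTHALATE": "DiOP",
    "DIOP": "DiOP",
}


def normalize_compound(name: str) -> str:
    """Map a compound label (canonical or published synonym) to its
    canonical registry code.

    Raises
    ------
    ValidationError
        If the label is not in the registry; the message lists the registry.
    """
    key = str(name).strip()
    if key in COMPOUNDS:
        return key
    upper = key.upper()
    if upper in COMPOUND_ALIASES:
        return COMPOUND_ALIASES[upper]
    if upper in (c.upper() for c in COMPOUNDS):
        return next(c for c in COMPOUNDS if c.upper() == upper)
    raise ValidationError(
        f"unknown compound {name!r}; registry: {', '.join(COMPOUNDS)}"
    )


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConcentrationRecord:
    """One dust-concentration measurement (μg/g).

    ``censored`` marks a value recorded as 0.00, i.e. below the analytical
    limit of detection.  Censored records keep ``value == 0``; any
    substitution (e.g. LOD/2) is a downstream option, never applied at read
    time.
    """

    station_id: str
    compound: str
    sampling_step: str
    value: float
    censored: bool = False
    allowable_threshold: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "compound", normalize_compound(self.compound))
        if not math.isfinite(self.value) or self.value < 0:
            raise ValidationError(
                f"concentration must be a non-negative real, got {self.value!r} "
                f"({self.station_id}/{self.compound}/{self.sampling_step})"
            )
        if self.censored and self.value != 0:
            raise ValidationError(
                f"censored record must have value 0, got {self.value!r} "
                f"({self.station_id}/{self.compound}/{self.sampling_step})"
            )


class ConcentrationTable:
    """Long-format collection of :class:`ConcentrationRecord`.

    Thin wrapper around a validated :class:`pandas.DataFrame` with columns
    ``station, compound, step, value, censored`` (and optionally
    ``allowable``).
    """

    REQUIRED = ("station", "compound", "step", "value")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"concentration table missing columns: {missing}")
        if len(df) == 0:
            raise ValidationError("concentration table has zero records")
        df = df.copy()
        df["station"] = df["station"].astype(str)
        df["step"] = df["step"].astype(str)
        df["compound"] = [normalize_compound(c) for c in df["compound"]]
        values = pd.to_numeric(df["value"], errors="coerce")
        bad = df.index[~np.isfinite(values) | (values < 0)]
        if len(bad):
            row = bad[0]
            raise ValidationError(
                f"non-negative numeric concentration required; offending row "
                f"{row}: {df.loc[row].to_dict()}"
            )
        df["value"] = values.astype(float)
        if "censored" not in df.columns:
            df["censored"] = df["value"] == 0.0
        df["censored"] = df["censored"].astype(bool)
        n_subst = int(((df["censored"]) & (df["value"] != 0)).sum())
        if n_subst:
            # below-LOD records are 0 as recorded; positive censored values
            # mean a substitution policy (e.g. LOD/2) was applied upstream
            log.info("%d censored records carry substituted (non-zero) values",
                     n_subst)
        self.df = df.reset_index(drop=True)

    # -- basic introspection -------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:  # value equality, used by round-trip tests
        if not isinstance(other, ConcentrationTable):
            return NotImplemented
        a = self.df[list(self.REQUIRED) + ["censored"]]
        b = other.df[list(self.REQUIRED) + ["censored"]]
        return a.equals(b)

    @property
    def stations(self) -> list[str]:
        return sorted(set(self.df["station"]), key=_station_key)

    @property
    def compounds(self) -> list[str]:
        present = set(self.df["compound"])
        return [c for c in COMPOUNDS if c in present]

    def records(self) -> Iterable[ConcentrationRecord]:
        for row in self.df.itertuples(index=False):
            yield ConcentrationRecord(
                row.station, row.compound, row.step, row.value, row.censored,
                getattr(row, "allowable", None),
            )

    # -- aggregation ---------------------------------------------------------
    def aggregate(self, statistic: str = "mean") -> pd.DataFrame:
        """Collapse sampling steps: one concentration per station x compound.

        ``statistic`` is any reduction understood by pandas ``agg`` ("mean",
        "median", "max", ...).  Censored zeros enter the reduction as zeros.
        """
        out = (
            self.df.groupby(["station", "compound"], sort=False)["value"]
            .agg(statistic)
            .reset_index()
        )
        return out

    # -- I/O -----------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        cols = ["station", "compound", "step", "value", "censored"]
        if "allowable" in self.df.columns:
            cols.append("allowable")
        # default float formatting is shortest-round-trip: read-back exact
        self.df[cols].to_csv(path, index=False)

    @classmethod
    def from_records(cls, records: Iterable[ConcentrationRecord]) -> "ConcentrationTable":
        rows = [
            {
                "station": r.station_id,
                "compound": r.compound,
                "step": r.sampling_step,
                "value": r.value,
                "censored": r.censored,
                "allowable": r.allowable_threshold,
            }
            for r in records
        ]
        if not rows:
            raise ValidationError("no records supplied")
        return cls(pd.DataFrame(rows))


def _station_key(s: str):
    try:
        return (0, float(s.lstrip("S")), s)
    except ValueError:
        return (1, 0.0, s)


@dataclass
class ExposureFactors:
    """Point exposure parameters for one population group.

    Units follow the conventional dust dose equations: ingestion rate
    ``ir_ing`` mg/day, inhalation rate ``ir_inh`` m³/day, exposure frequency
    ``ef`` days/year, exposure duration ``ed`` years, body weight ``bw`` kg,
    particulate emission factor ``pef`` m³/kg, skin surface area ``sa`` cm²,
    adherence factor ``af`` and dermal absorption fraction ``abs`` unitless.

    Averaging times (days): ``at_noncarc`` defaults to ``ed x 365`` and
    ``at_carc`` to ``70 x 365``.  A group may be marked ``active=False``
    (e.g. children in a purely occupational scenario); inactive groups
    contribute zero dose and skip field validation.
    """

    group: str = "adult"
    ir_ing: float | None = None
    ir_inh: float | None = None
    ef: float | None = None
    ed: float | None = None
    bw: float | None = None
    pef: float | None = None
    sa: float | None = None
    af: float | None = None
    abs: float | None = None
    at_noncarc: float | None = None
    at_carc: float | None = None
    active: bool = True

    def __post_init__(self) -> None:
        if not self.active:
            return
        if self.at_noncarc is None and self.ed is not None:
            self.at_noncarc = float(self.ed) * 365.0
        if self.at_carc is None:
            self.at_carc = 70.0 * 365.0
        for name in ("ir_ing", "ir_inh", "ef", "ed", "bw", "pef", "sa", "af",
                     "abs", "at_noncarc", "at_carc"):
            v = getattr(self, name)
            if v is None:
                raise ParameterError(f"exposure factor {name!r} missing for "
                                     f"active group {self.group!r}")
            if np.ndim(v) == 0 and not v > 0:
                raise ParameterError(f"exposure factor {name!r} must be > 0, "
                                     f"got {v!r}")
        if np.ndim(self.ef) == 0 and self.ef > 365:
            raise ParameterError(f"exposure frequency ef={self.ef} exceeds 365 d/y")
        for name in ("af", "abs"):
            v = getattr(self, name)
            if np.ndim(v) == 0 and not (0 < v <= 1):
                raise ParameterError(f"{name} must lie in (0, 1], got {v!r}")

    def replace(self, **updates) -> "ExposureFactors":
        """Return a copy with fields replaced (values may be numpy arrays,
        which is how the Monte Carlo engine threads factor draws through the
        deterministic dose equations)."""
        return dataclasses.replace(self, **updates)


@dataclass(frozen=True)
class ToxicityReference:
    """Per-compound toxicity values.

    One unified reference dose is used across pathways:
    ``rfd_dermal = rfd_oral x abs_gi`` (gastrointestinal absorption fraction,
    default 1) and ``rfd_inh = rfd_oral`` unless explicitly overridden.
    ``csf`` is the cancer slope factor, present only for carcinogens.
    """

    compound: str
    rfd_oral: float | None = None
    abs_gi: float = 1.0
    rfd_dermal: float | None = None
    rfd_inh: float | None = None
    csf: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "compound", normalize_compound(self.compound))
        if self.rfd_oral is not None and not self.rfd_oral > 0:
            raise ParameterError(f"rfd_oral must be > 0, got {self.rfd_oral!r}")
        if not (0 < self.abs_gi <= 1):
            raise ParameterError(f"abs_gi must lie in (0, 1], got {self.abs_gi!r}")
        if self.rfd_dermal is None and self.rfd_oral is not None:
            object.__setattr__(self, "rfd_dermal", self.rfd_oral * self.abs_gi)
        if self.rfd_inh is None and self.rfd_oral is not None:
            object.__setattr__(self, "rfd_inh", self.rfd_oral)
        if self.csf is not None and self.csf < 0:
            raise ParameterError(f"csf must be >= 0, got {self.csf!r}")

    def rfd_for(self, pathway: str) -> float | None:
        return {
            "ingestion": self.rfd_oral,
            "inhalation": self.rfd_inh,
            "dermal": self.rfd_dermal,
        }[pathway]


@dataclass(frozen=True)
class DistributionSpec:
    """Specification of one stochastic (or point) exposure factor.

    ``family`` is ``point``, ``lognormal`` or ``normal``.  For the stochastic
    families ``p1``/``p2`` are the ARITHMETIC mean and standard deviation;
    lognormal log-scale parameters are derived by moment matching at sampling
    time.  Normal factors are truncated below at ``max(lower, 0)`` because
    every factor is a physical, positive quantity.
    """

    factor: str
    family: str
    p1: float
    p2: float | None = None
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("point", "lognormal", "normal"):
            raise ValidationError(
                f"unknown distribution family {self.family!r} for factor "
                f"{self.factor!r}; expected point | lognormal | normal"
            )
        if self.family != "point":
            if self.p2 is None or not self.p2 > 0:
                raise ValidationError(
                    f"{self.family} factor {self.factor!r} needs sd p2 > 0"
                )
            if not self.p1 > 0:
                raise ValidationError(
                    f"{self.family} factor {self.factor!r} needs mean p1 > 0"
                )


#: Mapping of distribution factor labels onto :class:`ExposureFactors` fields.
FACTOR_FIELDS: dict[str, str] = {
    "IR_ing": "ir_ing",
    "IR_inh": "ir_inh",
    "EF": "ef",
    "ED": "ed",
    "BW": "bw",
    "PEF": "pef",
    "SA": "sa",
    "AF": "af",
    "ABS": "abs",
}


@dataclass
class Scenario:
    """A complete exposure scenario: per-group exposure factors, per-compound
    toxicity values, per-factor sampling distributions, and Monte Carlo
    settings."""

    exposure: dict[str, ExposureFactors]
    toxicity: dict[str, ToxicityReference]
    distributions: dict[str, DistributionSpec] = field(default_factory=dict)
    skip: tuple[str, ...] = ()
    mc_iterations: int = 10000
    seed: int = 42
    name: str = "scenario"

    def __post_init__(self) -> None:
        self.skip = tuple(normalize_compound(c) for c in self.skip)
        for fac in self.distributions:
            if fac not in FACTOR_FIELDS:
                raise ValidationError(
                    f"distribution declared for unknown factor {fac!r}; "
                    f"known factors: {sorted(FACTOR_FIELDS)}"
                )

    @property
    def adult(self) -> ExposureFactors:
        return self.exposure["adult"]

    def active_groups(self) -> list[ExposureFactors]:
        return [f for f in self.exposure.values() if f.active]

    def toxicity_for(self, compound: str) -> ToxicityReference | None:
        """Toxicity entry for a compound, or None when the compound is
        excluded.  A compound that is neither covered nor listed under
        ``skip`` raises; a skipped compound logs a warning and returns None
        (never a silent zero)."""
        compound = normalize_compound(compound)
        tox = self.toxicity.get(compound)
        if tox is not None and tox.rfd_oral is not None:
            return tox
        if compound in self.skip:
            log.warning("compound %s has no reference dose; excluded from risk",
                        compound)
            return None
        raise ValidationError(
            f"no toxicity entry for compound {compound!r}; add one under "
            f"[toxicity.{compound}] or list it under skip"
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_concentration_table(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> ConcentrationTable:
    """Read a long-format concentration CSV (UTF-8, header row, '.' decimal).

    Expected columns ``station, compound, step, value`` plus optional
    ``censored`` and ``allowable``; ``dialect`` maps these canonical names to
    the file's actual column names, e.g. ``{"station": "site"}``.  Zeros are
    flagged censored (below LOD).  The record count is logged.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"concentration file not found: {path}")
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValidationError(f"concentration file {path} is empty; zero records")
    if dialect:
        df = df.rename(columns={v: k for k, v in dialect.items()})
    table = ConcentrationTable(df)
    log.info("read %d concentration records (%d stations x %d compounds) from %s",
             len(table), len(table.stations), len(table.compounds), path)
    return table


def read_concentration_summary(path: str | Path) -> pd.DataFrame:
    """Read a summary-level concentration table (compound x sampling step
    rows with min/max/mean/sd columns), the layout of the published
    concentration summary."""
    df = pd.read_csv(path, comment="#")
    need = {"compound", "step", "min", "max", "mean", "sd"}
    missing = need - set(df.columns)
    if missing:
        raise ValidationError(f"summary table missing columns: {sorted(missing)}")
    df["compound"] = [normalize_compound(c) for c in df["compound"]]
    return df


def summary_to_table(summary: pd.DataFrame, statistic: str = "mean") -> ConcentrationTable:
    """Build a one-station concentration table from a summary table, using
    the chosen per-step statistic as the concentration.  Intended for
    survey-level (not station-resolved) risk screening."""
    if statistic not in summary.columns:
        raise ValidationError(f"summary has no column {statistic!r}")
    df = pd.DataFrame(
        {
            "station": "survey-" + statistic,
            "compound": summary["compound"],
            "step": summary["step"],
            "value": summary[statistic].astype(float),
        }
    )
    return ConcentrationTable(df)


def write_results_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a results table as CSV with 12 significant digits (so a
    write -> read round-trip is value-identical at that precision)."""
    df.to_csv(path, index=False, float_format="%.12g")


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", float_precision="round_trip")


# ---------------------------------------------------------------------------
# packaged fixtures and scenarios
# ---------------------------------------------------------------------------

_FIXTURES = {
    "table3": "concentration summary (min/max/mean/SD per compound x step, μg/g)",
    "table4": "inhalation hazard quotients per station x compound",
    "table5": "ingestion hazard quotients per station x compound",
    "table6": "dermal hazard quotients per station x compound",
    "table7": "hazard indices per station x compound",
    "table8": "BBP cancer risk per station x pathway",
}


def _data_path(fname: str) -> Path:
    return Path(resources.files("dustrisk.data") / fname)


def load_fixture_table(name: str) -> pd.DataFrame:
    """Load one of the packaged reference tables transcribed from the
    published survey (``table3`` ... ``table8``).

    Station-level tables keep the published values (including the Mean row);
    a handful of exponents that the publication's own internal identities
    prove wrong were restored, as itemised in each CSV's header comment.
    """
    if name not in _FIXTURES:
        raise ValidationError(
            f"unknown fixture {name!r}; available: "
            + ", ".join(f"{k} ({v})" for k, v in _FIXTURES.items())
        )
    df = pd.read_csv(_data_path(f"{name}.csv"), comment="#")
    if "station" in df.columns:
        df["station"] = df["station"].astype(str)
    return df


def load_fixture_concentrations(statistic: str = "mean") -> ConcentrationTable:
    """The packaged concentration summary as a one-station
    :class:`ConcentrationTable` (see :func:`summary_to_table`)."""
    summary = read_concentration_summary(_data_path("table3.csv"))
    return summary_to_table(summary, statistic)


def packaged_scenario_path(name: str = "yazd_adult") -> Path:
    """Path of a packaged scenario TOML (currently only ``yazd_adult``)."""
    p = _data_path(f"{name}.toml")
    if not p.exists():
        raise ValidationError(f"no packaged scenario named {name!r}")
    return p


def load_scenario(path: str | Path) -> Scenario:
    """Load an exposure scenario from TOML.

    Layout: ``[exposure.<group>]`` sections with the
    :class:`ExposureFactors` fields, ``[toxicity.<compound>]`` sections,
    ``[distributions.<FACTOR>]`` sections (``family`` plus ``value`` or
    ``mean``/``sd``), a top-level ``skip`` list, and ``[mc]`` with
    ``iterations`` and ``seed``.  Defaults live in the file as explicit
    values, never silently in code.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)

    exposure = {}
    for group, params in raw.get("exposure", {}).items():
        exposure[group] = ExposureFactors(group=group, **params)
    if not exposure:
        raise ValidationError(f"scenario {path} declares no [exposure.*] group")

    toxicity = {}
    for comp, params in raw.get("toxicity", {}).items():
        tox = ToxicityReference(compound=comp, **params)
        toxicity[tox.compound] = tox

    distributions = {}
    for fac, params in raw.get("distributions", {}).items():
        distributions[fac] = _parse_distribution(fac, params)

    mc = raw.get("mc", {})
    scenario = Scenario(
        exposure=exposure,
        toxicity=toxicity,
        distributions=distributions,
        skip=tuple(raw.get("skip", ())),
        mc_iterations=int(mc.get("iterations", 10000)),
        seed=int(mc.get("seed", 42)),
        name=path.stem,
    )
    log.info("loaded scenario %s: %d groups, %d toxicity entries, %d distributions",
             scenario.name, len(exposure), len(toxicity), len(distributions))
    return scenario


def _parse_distribution(factor: str, params: Mapping) -> DistributionSpec:
    family = params.get("family", "point")
    if family == "point":
        if "value" not in params:
            raise ValidationError(f"point factor {factor!r} needs 'value'")
        return DistributionSpec(factor, "point", float(params["value"]))
    return DistributionSpec(
        factor,
        family,
        float(params.get("mean", float("nan"))),
        float(params["sd"]) if "sd" in params else None,
        lower=params.get("lower"),
        upper=params.get("upper"),
    )
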