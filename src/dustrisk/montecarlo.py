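"""Probabilistic risk assessment by Monte Carlo propagation.

Each iteration draws one joint realisation of every exposure factor that
carries a :class:`~dustrisk.io_config.DistributionSpec` (factors are sampled
independently — no correlation structure is specified for them) and pushes it
through the deterministic dose engine unchanged.  Summaries (mean, sd,
min/max, P5/P50/P95) are reported per compound x pathway for hazard
quotients and, where a slope factor exists, cancer risks.

Reproducibility: one master seed; every factor draws from its own
deterministically derived substream (seed sequence keyed by the factor
name), so adding or removing a factor never perturbs the draws of the
others, and a fixed seed reproduces results bitwise.

Concentration is a fixed per-compound input by default (the study conditions
give no sampling distribution for it); ``conc_mode="bootstrap"`` optionally
resamples the observed station x step values, which makes concentration a
ranked input in the sensitivity analysis.
"""
from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .deterministic import PATHWAYS, cancer_risk, hazard_index, hazard_quotient, pathway_dose
from .io_config import (
    ConcentrationTable,
    DistributionSpec,
    FACTOR_FIELDS,
    Scenario,
    ValidationError,
)

log = logging.getLogger(__name__)

__all__ = [
    "MCRun",
    "MCSummary",
    "factor_rng",
    "run_mc",
    "sample_factor",
    "stochastic_ingestion_scenario",
]


def factor_rng(master_seed: int, factor: str) -> np.random.Generator:
    """Independent substream for one factor, derived from the master seed
    and the factor name (stable across runs and across factor-set changes)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed) % 2**31, zlib.crc32(factor.encode())])
    )


def sample_factor(spec: DistributionSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` positive values for one exposure factor.

    point      -> constant vector of the point value.
    lognormal  -> arithmetic-moment-matched draws: with mean m and sd s,
                  σ² = ln(1 + s²/m²), μ = ln m − σ²/2, so sample mean and sd
                  converge to (m, s).
    normal     -> truncated normal, lower bound max(lower, 0) (physical
                  quantities are positive), upper bound if given.
    """
    if n < 1:
        raise ValidationError("need n >= 1 draws")
    if spec.family == "point":
        return np.full(n, float(spec.p1))
    if spec.family == "lognormal":
        m, s = spec.p1, spec.p2
        sigma2 = np.log1p((s / m) ** 2)
        mu = np.log(m) - sigma2 / 2.0
        draws = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)
        if spec.lower is not None or spec.upper is not None:
            lo = spec.lower if spec.lower is not None else 0.0
            hi = spec.upper if spec.upper is not None else np.inf
            for _ in range(100):
                bad = (draws < lo) | (draws > hi)
                if not bad.any():
                    break
                draws[bad] = rng.lognormal(mu, np.sqrt(sigma2), int(bad.sum()))
            else:
                raise ValidationError(
                    f"truncation bounds for {spec.factor!r} reject nearly all mass"
                )
        return draws
    # normal, truncated at zero
    lo = max(spec.lower if spec.lower is not None else 0.0, 0.0)
    hi = spec.upper if spec.upper is not None else np.inf
    a, b = (lo - spec.p1) / spec.p2, (hi - spec.p1) / spec.p2
    return stats.truncnorm.rvs(a, b, loc=spec.p1, scale=spec.p2, size=n,
                               random_state=rng)


@dataclass(frozen=True)
class MCSummary:
    """Distribution summary of one simulated target (a hazard quotient or
    cancer risk for one compound x pathway, or their per-compound sums)."""

    target: str
    n_iter: int
    mean: float
    sd: float
    minimum: float
    maximum: float
    p5: float
    p50: float
    p95: float
    seed: int

    def __post_init__(self) -> None:
        if not (self.minimum <= self.p5 <= self.p50 <= self.p95 <= self.maximum):
            raise ValidationError(
                f"percentiles of {self.target} are not ordered"
            )

    @classmethod
    def from_draws(cls, target: str, x: np.ndarray, seed: int) -> "MCSummary":
        if np.ptp(x) == 0:  # degenerate (all-point) run: exact constants
            v = float(x[0])
            return cls(target, len(x), v, 0.0, v, v, v, v, v, seed)
        p5, p50, p95 = np.percentile(x, [5, 50, 95])
        return cls(target, len(x), float(np.mean(x)), float(np.std(x, ddof=1)),
                   float(np.min(x)), float(np.max(x)), float(p5), float(p50),
                   float(p95), seed)


@dataclass
class MCRun:
    """Result bundle of :func:`run_mc`: per-target summaries, the retained
    factor-draw matrix (needed by the sensitivity analysis) and the raw
    per-target output vectors."""

    summaries: dict[str, MCSummary]
    draws: pd.DataFrame
    outputs: dict[str, np.ndarray]
    cs: dict[str, float | np.ndarray]
    n_iter: int
    seed: int

    def summary_frame(self) -> pd.DataFrame:
        rows = [vars(s) for s in self.summaries.values()]
        return pd.DataFrame(rows)

    def draws_for(self, target: str) -> pd.DataFrame:
        """Draw matrix relevant to one target: all exposure-factor columns
        plus, in bootstrap mode, that compound's concentration column
        renamed ``Cs`` (other compounds' concentrations dropped)."""
        comp = target.split(":", 1)[0]
        cols = [c for c in self.draws.columns if not c.startswith("Cs[")]
        df = self.draws[cols].copy()
        cs_col = f"Cs[{comp}]"
        if cs_col in self.draws.columns:
            df["Cs"] = self.draws[cs_col]
        return df

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.summary_frame().to_csv(d / "mc_summary.csv", index=False,
                                    float_format="%.12g")
        self.draws.to_csv(d / "draws.csv", index=False, float_format="%.12g")
        pd.DataFrame(self.outputs).to_csv(d / "outputs.csv", index=False,
                                          float_format="%.12g")
        (d / "meta.json").write_text(
            json.dumps({"n_iter": self.n_iter, "seed": self.seed,
                        "cs": {k: (v if np.ndim(v) == 0 else "bootstrap")
                               for k, v in self.cs.items()}}, indent=2)
        )

    @classmethod
    def load(cls, directory: str | Path) -> "MCRun":
        d = Path(directory)
        meta = json.loads((d / "meta.json").read_text())
        draws = pd.read_csv(d / "draws.csv")
        outputs = {c: s.to_numpy() for c, s in pd.read_csv(d / "outputs.csv").items()}
        summary = pd.read_csv(d / "mc_summary.csv")
        summaries = {r["target"]: MCSummary(**r) for r in summary.to_dict("records")}
        return cls(summaries, draws, outputs, meta.get("cs", {}),
                   int(meta["n_iter"]), int(meta["seed"]))


def _aggregate_cs(conc: ConcentrationTable, station: str | None) -> dict[str, np.ndarray]:
    """Observed concentration values per compound (optionally one station)."""
    df = conc.df
    if station is not None:
        df = df[df["station"] == str(station)]
        if len(df) == 0:
            raise ValidationError(f"no records for station {station!r}")
    return {c: g["value"].to_numpy() for c, g in df.groupby("compound", sort=False)}


def run_mc(
    conc: ConcentrationTable,
    scenario: Scenario,
    n_iter: int | None = None,
    seed: int | None = None,
    station: str | None = None,
    conc_mode: str = "fixed",
) -> MCRun:
    """Monte Carlo risk simulation.

    Parameters
    ----------
    conc, scenario
        As in :func:`~dustrisk.deterministic.run_deterministic`.
    n_iter, seed
        Default to the scenario's ``[mc]`` settings; ``n_iter`` must be at
        least 100.
    station
        Restrict the concentration input to one station; default uses all
        station x step values.
    conc_mode
        ``"fixed"`` (default): the per-compound mean of the observed values
        is a constant input.  ``"bootstrap"``: each iteration resamples one
        observed value per compound (columns ``Cs[<compound>]`` appear in the
        retained draw matrix).
    """
    n = int(n_iter if n_iter is not None else scenario.mc_iterations)
    master = int(seed if seed is not None else scenario.seed)
    if n < 100:
        raise ValidationError(f"n_iter must be >= 100, got {n}")
    if conc_mode not in ("fixed", "bootstrap"):
        raise ValidationError(f"unknown conc_mode {conc_mode!r}")

    values = _aggregate_cs(conc, station)

    draws: dict[str, np.ndarray] = {}
    for fac in sorted(scenario.distributions):
        draws[fac] = sample_factor(scenario.distributions[fac], n,
                                   factor_rng(master, fac))

    cs: dict[str, float | np.ndarray] = {}
    for comp, vals in values.items():
        if conc_mode == "bootstrap":
            rng = factor_rng(master, f"Cs[{comp}]")
            cs[comp] = rng.choice(vals, size=n, replace=True)
            draws[f"Cs[{comp}]"] = cs[comp]
        else:
            cs[comp] = float(np.mean(vals))

    # thread the draws through the adult group's exposure factors
    adult = scenario.adult
    updates = {FACTOR_FIELDS[f]: draws[f] for f in scenario.distributions
               if f in FACTOR_FIELDS}
    adult_mc = adult.replace(**updates)
    ed_spec = scenario.distributions.get("ED")
    if ed_spec is not None and ed_spec.family != "point":
        # a stochastic exposure duration drags the non-carcinogenic
        # averaging time along (AT_noncarc = ED x 365); AT_carc stays fixed
        adult_mc = adult_mc.replace(at_noncarc=adult_mc.ed * 365.0)
    groups = [adult_mc] + [g for name, g in scenario.exposure.items()
                           if name != "adult"]

    outputs: dict[str, np.ndarray] = {}
    summaries: dict[str, MCSummary] = {}

    def record(target: str, x) -> None:
        x = np.broadcast_to(np.asarray(x, float), (n,)).copy()
        outputs[target] = x
        summaries[target] = MCSummary.from_draws(target, x, master)

    for comp in conc.compounds:
        tox = scenario.toxicity_for(comp)
        if tox is None:
            continue
        c = cs[comp]
        hqs = {}
        for p in PATHWAYS:
            hqs[p] = hazard_quotient(pathway_dose(p, c, groups, False), tox, p)
            record(f"{comp}:{p}:HQ", hqs[p])
        record(f"{comp}:HI",
               hazard_index([hqs["inhalation"], hqs["ingestion"], hqs["dermal"]]))
        if tox.csf is not None:
            crs = {}
            for p in PATHWAYS:
                crs[p] = cancer_risk(pathway_dose(p, c, groups, True), tox)
                record(f"{comp}:{p}:CR", crs[p])
            record(f"{comp}:CR_total",
                   hazard_index([crs["inhalation"], crs["ingestion"], crs["dermal"]]))

    log.info("monte carlo: %d iterations, %d factors, %d targets, seed=%d",
             n, len(draws), len(outputs), master)
    return MCRun(summaries, pd.DataFrame(draws), outputs, cs, n, master)


def stochastic_ingestion_scenario(scenario: Scenario, cv: float = 1.56 / 1.4) -> Scenario:
    """Variant of ``scenario`` whose dust ingestion rate is lognormal.

    The packaged probabilistic scenario keeps the ingestion rate at its
    deterministic 50 mg/day point value because the published stochastic
    entry (LN(1.4, 1.56) L/day) is a fluid-intake figure with units
    incoherent with the dust dose equation.  For sensitivity analyses of the
    ingestion pathway this helper re-applies that entry's *relative* spread
    (coefficient of variation 1.56/1.4 ≈ 1.11) to the unit-coherent mean.
    """
    spec = scenario.distributions.get("IR_ing")
    mean = spec.p1 if spec is not None else scenario.adult.ir_ing
    dists = dict(scenario.distributions)
    dists["IR_ing"] = DistributionSpec("IR_ing", "lognormal", mean, mean * cv)
    return Scenario(
        exposure=scenario.exposure,
        toxicity=scenario.toxicity,
        distributions=dists,
        skip=scenario.skip,
        mc_iterations=scenario.mc_iterations,
        seed=scenario.seed,
        name=scenario.name + "+stochastic-IR_ing",
    )
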