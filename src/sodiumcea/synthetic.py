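"""Synthetic stratified model inputs.

The real inputs behind this kind of analysis (linked administrative health
data, burden-of-disease YLD tables, costed health events) are not publicly
distributable, so this module generates internally consistent stand-ins with
the qualitative structure of the New Zealand adult population: 13 five-year
age bands (35-39 ... 95+) x 2 sexes x 2 ethnic groupings, log-linear age
gradients in disease rates, male- and Maori-excess coronary heart disease,
and plausible cost gradients.  All numbers here are documented synthetic
defaults, not the original administrative values.

Rates are stored as annual *rates* (events per person-year), never as
probabilities; the Markov engine performs all rate-to-probability
conversions.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import strata
from .strata import (
    BAND_LABELS,
    DISEASES,
    ETHNICITIES,
    N_BANDS,
    SEXES,
    SHAPE,
)

BASE_YEAR = 2011
DEFAULT_COHORT_SIZE = 2_300_000

#: Versioned synthetic parameter set ("NZ-like defaults").  These are
#: deliberately round, documented stand-ins chosen for epidemiological
#: plausibility: incidence doubles every `age_doubling_bands` five-year bands,
#: background mortality follows a Gompertz-like doubling time of ~7.7 years,
#: and Maori/male excess risk multipliers reflect the direction (not the
#: magnitude) of observed inequalities.
NZ_LIKE_DEFAULTS: dict = {
    "version": 1,
    # population structure
    "band_weights": [0.125, 0.125, 0.12, 0.115, 0.105, 0.09, 0.08,
                     0.065, 0.055, 0.045, 0.035, 0.025, 0.015],
    "maori_share_base": 0.14,       # declining 0.008 per band
    "maori_share_slope": -0.008,
    "female_share_base": 0.50,      # rising with age (female longevity)
    "female_share_slope": 0.012,
    # incidence (annual rate at band 35-39, non-Maori female)
    "incidence_base": {"chd": 0.0008, "stroke": 0.0004},
    "age_doubling_bands": {"chd": 2.0, "stroke": 2.0},
    "male_incidence_mult": {"chd": 1.8, "stroke": 1.25},
    "maori_incidence_mult": {"chd": 2.0, "stroke": 1.5},
    # case fatality among prevalent cases (annual rate)
    "case_fatality_base": {"chd": 0.020, "stroke": 0.035},
    "case_fatality_doubling_bands": 3.0,
    "maori_case_fatality_mult": 1.3,
    # prevalence = incidence x mean duration, capped
    "prevalence_duration_years": {"chd": 10.0, "stroke": 7.0},
    "prevalence_cap": {"chd": 0.35, "stroke": 0.25},
    # background (non-CVD) mortality, Gompertz-like in age
    "mortality_base": 0.001,
    "mortality_doubling_years": 7.7,
    "male_mortality_mult": 1.4,
    "maori_mortality_mult": 1.8,
    # morbidity (prevalent YLD per capita and per prevalent case)
    "background_pyld_base": 0.04,
    "background_pyld_slope": 0.012,   # per band
    "maori_pyld_excess": 0.03,
    "disease_yld_per_case": {"chd": 0.12, "stroke": 0.22},
    # costs, 2011 NZ$-like units
    "first_year_cost": {"chd": 15_000.0, "stroke": 22_000.0},
    "subsequent_year_cost": {"chd": 5_500.0, "stroke": 9_000.0},
    "healthy_background_cost_base": 1_800.0,
    "healthy_background_cost_slope": 180.0,  # per band
    "last6m_cost": 25_000.0,
    "public_share_scale": 1.2,   # 1/0.83: public share of total health spend
    # multiplicative lognormal jitter (per sex x ethnicity) so different
    # seeds give different but structurally identical worlds
    "jitter_sd": 0.05,
}


@dataclass
class PopulationTable:
    """Closed-cohort population counts per stratum at the base year."""

    counts: np.ndarray          # shape (2, 13, 2), people
    base_year: int = BASE_YEAR

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != SHAPE:
            raise ValueError(f"counts must have shape {SHAPE}")
        if (self.counts < 0).any():
            raise ValueError("population counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class EpiInputs:
    """Stratified annual rates for CHD and stroke plus background mortality.

    ``background_mortality`` has the CVD-attributable component removed, so
    disease case fatality can be added to it without double counting.
    """

    incidence: dict[str, np.ndarray]
    prevalence: dict[str, np.ndarray]
    case_fatality: dict[str, np.ndarray]
    background_mortality: np.ndarray

    def validate(self) -> None:
        for d in DISEASES:
            for name, table in (("incidence", self.incidence),
                                ("prevalence", self.prevalence),
                                ("case_fatality", self.case_fatality)):
                arr = np.asarray(table[d])
                if arr.shape != SHAPE:
                    raise ValueError(f"{name}[{d}] must have shape {SHAPE}")
                if (arr < 0).any():
                    raise ValueError(f"{name}[{d}] contains negative values")
            if (np.asarray(self.prevalence[d]) > 1).any():
                raise ValueError(f"prevalence[{d}] exceeds 1")
        prev_total = sum(np.asarray(self.prevalence[d]) for d in DISEASES)
        if (prev_total > 1).any():
            raise ValueError("total disease prevalence exceeds 1 in some stratum")
        if (np.asarray(self.background_mortality) < 0).any():
            raise ValueError("background mortality contains negative values")


@dataclass
class MorbidityInputs:
    """Per-capita background morbidity and per-case disease morbidity.

    Both are expressed as prevalent years lived with disability (YLD), i.e.
    disability-weighted fractions of a year on the 0 (full health) to 1
    (death) scale, so ``1 - background_pyld - disease_yld`` is a valid QALY
    weight.
    """

    background_pyld: np.ndarray
    disease_yld_per_case: dict[str, np.ndarray]

    def validate(self) -> None:
        bg = np.asarray(self.background_pyld)
        if bg.shape != SHAPE:
            raise ValueError(f"background_pyld must have shape {SHAPE}")
        if (bg < 0).any() or (bg >= 1).any():
            raise ValueError("background_pyld must lie in [0, 1)")
        for d in DISEASES:
            yld = np.asarray(self.disease_yld_per_case[d])
            if (yld < 0).any() or (yld >= 1).any():
                raise ValueError(f"disease_yld_per_case[{d}] must lie in [0, 1)")
            if (bg + yld >= 1).any():
                raise ValueError(
                    f"background_pyld + disease_yld_per_case[{d}] reaches 1; "
                    "QALY weight would be non-positive"
                )


@dataclass
class CostInputs:
    """Stratified health-system costs in 2011 NZ$-like units.

    ``healthy_background_cost`` excludes the CVD-attributable component
    (the disease states carry their own full annual costs).  The
    ``public_share_scale`` (default 1.2 = 1/0.83) and the old-age
    multipliers (1.1 / 1.2 / 1.3 for 65-74 / 75-84 / 85+) are applied once,
    at accrual time, to every cost item.
    """

    first_year_cost: dict[str, np.ndarray]
    subsequent_year_cost: dict[str, np.ndarray]
    healthy_background_cost: np.ndarray
    last6m_cost: np.ndarray
    public_share_scale: float = 1.2

    def validate(self) -> None:
        for d in DISEASES:
            for table in (self.first_year_cost, self.subsequent_year_cost):
                arr = np.asarray(table[d])
                if arr.shape != SHAPE:
                    raise ValueError(f"cost table for {d} must have shape {SHAPE}")
                if (arr < 0).any():
                    raise ValueError(f"cost table for {d} contains negative values")
        if (np.asarray(self.healthy_background_cost) < 0).any():
            raise ValueError("healthy background cost contains negative values")
        if (np.asarray(self.last6m_cost) < 0).any():
            raise ValueError("last-6-months cost contains negative values")
        if self.public_share_scale <= 0:
            raise ValueError("public_share_scale must be positive")


@dataclass
class ModelInputs:
    """Bundle of everything the engine needs for one simulated world."""

    population: PopulationTable
    epi: EpiInputs
    morbidity: MorbidityInputs
    costs: CostInputs

    def validate(self) -> "ModelInputs":
        self.epi.validate()
        self.morbidity.validate()
        self.costs.validate()
        return self


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _band_arange() -> np.ndarray:
    return np.arange(N_BANDS, dtype=float)


def _sex_eth_jitter(rng: np.random.Generator, sd: float) -> np.ndarray:
    """One multiplicative factor per (sex, ethnicity), broadcast over bands.

    Jitter is deliberately constant across age bands so that the constructed
    age gradients (and the monotonicity invariants that rely on them) are
    preserved exactly.
    """
    return np.exp(rng.normal(0.0, sd, size=(2, 1, 2)))


def generate_population(seed: int, total: int = DEFAULT_COHORT_SIZE,
                        params: dict | None = None) -> PopulationTable:
    """Deterministic synthetic population of ``total`` people over 52 strata."""
    if total <= 0:
        raise ValueError("cohort size must be positive")
    p = params or NZ_LIKE_DEFAULTS
    rng = np.random.default_rng(seed)

    band = _band_arange()
    band_w = np.asarray(p["band_weights"], dtype=float)
    maori_share = np.clip(p["maori_share_base"] + p["maori_share_slope"] * band, 0.01, 0.5)
    female_share = np.clip(p["female_share_base"] + p["female_share_slope"] * band, 0.0, 1.0)

    weights = np.empty(SHAPE)
    for si, sex in enumerate(SEXES):
        sex_w = female_share if sex == "female" else 1.0 - female_share
        for ei, eth in enumerate(ETHNICITIES):
            eth_w = maori_share if eth == "maori" else 1.0 - maori_share
            weights[si, :, ei] = band_w * sex_w * eth_w
    # small stratum-level jitter; renormalised, so the total is exact
    weights *= np.exp(rng.normal(0.0, 0.02, size=SHAPE))
    weights /= weights.sum()

    exact = weights * total
    counts = np.floor(exact)
    remainder = exact - counts
    deficit = int(round(total - counts.sum()))
    if deficit > 0:
        order = np.argsort(remainder, axis=None)[::-1][:deficit]
        flat = counts.ravel()
        flat[order] += 1
        counts = flat.reshape(SHAPE)
    return PopulationTable(counts=counts, base_year=BASE_YEAR)


def generate_epi_inputs(seed: int, params: dict | None = None) -> EpiInputs:
    """Synthetic incidence / prevalence / case-fatality / mortality tables.

    Incidence follows a log-linear age gradient (doubling every
    ``age_doubling_bands`` bands) with male- and Maori-excess multipliers;
    background mortality is Gompertz-like with the CVD share notionally
    removed.
    """
    p = params or NZ_LIKE_DEFAULTS
    rng = np.random.default_rng(seed)
    band = _band_arange().reshape(1, N_BANDS, 1)
    male = np.array([0.0, 1.0]).reshape(2, 1, 1)       # sex axis: female, male
    maori = np.array([1.0, 0.0]).reshape(1, 1, 2)      # ethnicity axis

    incidence, prevalence, case_fatality = {}, {}, {}
    for d in DISEASES:
        jit = _sex_eth_jitter(rng, p["jitter_sd"])
        base = p["incidence_base"][d]
        age_mult = 2.0 ** (band / p["age_doubling_bands"][d])
        sex_mult = np.where(male > 0, p["male_incidence_mult"][d], 1.0)
        eth_mult = np.where(maori > 0, p["maori_incidence_mult"][d], 1.0)
        inc = base * age_mult * sex_mult * eth_mult * jit
        incidence[d] = inc
        duration = p["prevalence_duration_years"][d]
        prevalence[d] = np.minimum(inc * duration, p["prevalence_cap"][d])
        cf_jit = _sex_eth_jitter(rng, p["jitter_sd"])
        cf = (p["case_fatality_base"][d]
              * 2.0 ** (band / p["case_fatality_doubling_bands"])
              * np.where(maori > 0, p["maori_case_fatality_mult"], 1.0)
              * cf_jit)
        case_fatality[d] = np.broadcast_to(cf, SHAPE).copy()

    mort_jit = _sex_eth_jitter(rng, p["jitter_sd"])
    doubling_bands = p["mortality_doubling_years"] / 5.0
    mort = (p["mortality_base"]
            * 2.0 ** (band / doubling_bands)
            * np.where(male > 0, p["male_mortality_mult"], 1.0)
            * np.where(maori > 0, p["maori_mortality_mult"], 1.0)
            * mort_jit)

    epi = EpiInputs(
        incidence={d: np.broadcast_to(incidence[d], SHAPE).copy() for d in DISEASES},
        prevalence={d: np.broadcast_to(prevalence[d], SHAPE).copy() for d in DISEASES},
        case_fatality=case_fatality,
        background_mortality=np.broadcast_to(mort, SHAPE).copy(),
    )
    epi.validate()
    return epi


def generate_morbidity_and_costs(
    seed: int, params: dict | None = None
) -> tuple[MorbidityInputs, CostInputs]:
    p = params or NZ_LIKE_DEFAULTS
    rng = np.random.default_rng(seed + 10_007)  # distinct stream from epi
    band = _band_arange().reshape(1, N_BANDS, 1)
    maori = np.array([1.0, 0.0]).reshape(1, 1, 2)

    pyld_jit = _sex_eth_jitter(rng, p["jitter_sd"])
    background_pyld = (
        (p["background_pyld_base"] + p["background_pyld_slope"] * band
         + p["maori_pyld_excess"] * maori) * pyld_jit
    )
    disease_yld = {}
    for d in DISEASES:
        jit = _sex_eth_jitter(rng, p["jitter_sd"] / 2)
        disease_yld[d] = np.broadcast_to(p["disease_yld_per_case"][d] * jit, SHAPE).copy()

    morbidity = MorbidityInputs(
        background_pyld=np.broadcast_to(background_pyld, SHAPE).copy(),
        disease_yld_per_case=disease_yld,
    )

    first_year, subsequent = {}, {}
    for d in DISEASES:
        # a single factor per (sex, ethnicity) scales both cost items, so
        # first-year > subsequent-year survives the jitter by construction
        jit = _sex_eth_jitter(rng, p["jitter_sd"])
        first_year[d] = np.broadcast_to(p["first_year_cost"][d] * jit, SHAPE).copy()
        subsequent[d] = np.broadcast_to(p["subsequent_year_cost"][d] * jit, SHAPE).copy()
    bg_jit = _sex_eth_jitter(rng, p["jitter_sd"])
    healthy_cost = (
        (p["healthy_background_cost_base"] + p["healthy_background_cost_slope"] * band)
        * bg_jit
    )
    costs = CostInputs(
        first_year_cost=first_year,
        subsequent_year_cost=subsequent,
        healthy_background_cost=np.broadcast_to(healthy_cost, SHAPE).copy(),
        last6m_cost=np.full(SHAPE, p["last6m_cost"]),
        public_share_scale=p["public_share_scale"],
    )
    morbidity.validate()
    costs.validate()
    return morbidity, costs


def generate_model_inputs(seed: int, total: int = DEFAULT_COHORT_SIZE,
                          params: dict | None = None) -> ModelInputs:
    """Convenience wrapper producing a fully validated input bundle."""
    morbidity, costs = generate_morbidity_and_costs(seed, params)
    return ModelInputs(
        population=generate_population(seed, total, params),
        epi=generate_epi_inputs(seed, params),
        morbidity=morbidity,
        costs=costs,
    ).validate()


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------

def _stratum_frame() -> pd.DataFrame:
    s, b, e = strata.flat_indices()
    return pd.DataFrame({
        "sex": [SEXES[i] for i in s],
        "age_band": [BAND_LABELS[i] for i in b],
        "ethnicity": [ETHNICITIES[i] for i in e],
    })


def _flat(arr: np.ndarray) -> np.ndarray:
    return np.asarray(arr).reshape(-1)


def _unflat(values: np.ndarray) -> np.ndarray:
    return np.asarray(values, dtype=float).reshape(SHAPE)


def write_inputs(inputs: ModelInputs, outdir: str | Path) -> None:
    """Serialize all input tables as UTF-8 CSVs with fixed headers."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base = _stratum_frame()

    pop = base.copy()
    pop["count"] = _flat(inputs.population.counts)
    pop.to_csv(outdir / "population.csv", index=False)

    rows = []
    for d in DISEASES:
        df = base.copy()
        df["disease"] = d
        df["incidence"] = _flat(inputs.epi.incidence[d])
        df["prevalence"] = _flat(inputs.epi.prevalence[d])
        df["case_fatality"] = _flat(inputs.epi.case_fatality[d])
        df["background_mortality"] = _flat(inputs.epi.background_mortality)
        rows.append(df)
    pd.concat(rows).to_csv(outdir / "epi.csv", index=False)

    morb = base.copy()
    morb["background_pyld"] = _flat(inputs.morbidity.background_pyld)
    for d in DISEASES:
        morb[f"{d}_yld_per_case"] = _flat(inputs.morbidity.disease_yld_per_case[d])
    morb.to_csv(outdir / "morbidity.csv", index=False)

    cost = base.copy()
    for d in DISEASES:
        cost[f"{d}_first_year_cost"] = _flat(inputs.costs.first_year_cost[d])
        cost[f"{d}_subsequent_year_cost"] = _flat(inputs.costs.subsequent_year_cost[d])
    cost["healthy_background_cost"] = _flat(inputs.costs.healthy_background_cost)
    cost["last6m_cost"] = _flat(inputs.costs.last6m_cost)
    cost["public_share_scale"] = inputs.costs.public_share_scale
    cost.to_csv(outdir / "costs.csv", index=False)


def read_inputs(indir: str | Path) -> ModelInputs:
    indir = Path(indir)
    read = lambda name: pd.read_csv(indir / name, float_precision="round_trip")
    pop = read("population.csv")
    epi = read("epi.csv")
    morb = read("morbidity.csv")
    cost = read("costs.csv")

    population = PopulationTable(counts=_unflat(pop["count"].to_numpy()))
    incidence, prevalence, case_fatality = {}, {}, {}
    for d in DISEASES:
        sub = epi[epi["disease"] == d]
        incidence[d] = _unflat(sub["incidence"].to_numpy())
        prevalence[d] = _unflat(sub["prevalence"].to_numpy())
        case_fatality[d] = _unflat(sub["case_fatality"].to_numpy())
    background_mortality = _unflat(
        epi[epi["disease"] == DISEASES[0]]["background_mortality"].to_numpy()
    )
    morbidity = MorbidityInputs(
        background_pyld=_unflat(morb["background_pyld"].to_numpy()),
        disease_yld_per_case={
            d: _unflat(morb[f"{d}_yld_per_case"].to_numpy()) for d in DISEASES
        },
    )
    costs = CostInputs(
        first_year_cost={
            d: _unflat(cost[f"{d}_first_year_cost"].to_numpy()) for d in DISEASES
        },
        subsequent_year_cost={
            d: _unflat(cost[f"{d}_subsequent_year_cost"].to_numpy()) for d in DISEASES
        },
        healthy_background_cost=_unflat(cost["healthy_background_cost"].to_numpy()),
        last6m_cost=_unflat(cost["last6m_cost"].to_numpy()),
        public_share_scale=float(cost["public_share_scale"].iloc[0]),
    )
    return ModelInputs(
        population=population,
        epi=EpiInputs(incidence, prevalence, case_fatality, background_mortality),
        morbidity=morbidity,
        costs=costs,
    ).validate()


def scaled_inputs(inputs: ModelInputs, **multipliers: float) -> ModelInputs:
    """Return a deep copy with named quantities scaled (used by the PSA).

    Recognised keys: ``chd_cost``, ``stroke_cost``, ``healthy_cost``,
    ``disease_yld``, ``chd_incidence``, ``stroke_incidence``.
    """
    epi = EpiInputs(
        incidence={d: inputs.epi.incidence[d].copy() for d in DISEASES},
        prevalence={d: inputs.epi.prevalence[d].copy() for d in DISEASES},
        case_fatality={d: inputs.epi.case_fatality[d].copy() for d in DISEASES},
        background_mortality=inputs.epi.background_mortality.copy(),
    )
    morbidity = MorbidityInputs(
        background_pyld=inputs.morbidity.background_pyld.copy(),
        disease_yld_per_case={
            d: inputs.morbidity.disease_yld_per_case[d].copy() for d in DISEASES
        },
    )
    costs = CostInputs(
        first_year_cost={d: inputs.costs.first_year_cost[d].copy() for d in DISEASES},
        subsequent_year_cost={
            d: inputs.costs.subsequent_year_cost[d].copy() for d in DISEASES
        },
        healthy_background_cost=inputs.costs.healthy_background_cost.copy(),
        last6m_cost=inputs.costs.last6m_cost.copy(),
        public_share_scale=inputs.costs.public_share_scale,
    )
    for key, m in multipliers.items():
        if key in ("chd_cost", "stroke_cost"):
            d = key.split("_")[0]
            costs.first_year_cost[d] *= m
            costs.subsequent_year_cost[d] *= m
        elif key == "healthy_cost":
            costs.healthy_background_cost *= m
        elif key == "disease_yld":
            for d in DISEASES:
                morbidity.disease_yld_per_case[d] *= m
        elif key in ("chd_incidence", "stroke_incidence"):
            d = key.split("_")[0]
            epi.incidence[d] *= m
        else:
            raise KeyError(f"unknown scalable quantity {key!r}")
    return ModelInputs(inputs.population, epi, morbidity, costs)
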