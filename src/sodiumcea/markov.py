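"""Annual-cycle four-state Markov cohort engine.

Each of the 52 strata is simulated as a closed cohort from the 2011 base
year until extinction or age 100, moving between four health states:
Healthy, CHD, Stroke and Dead (absorbing).  Annual transition
probabilities are assembled from trend-adjusted incidence, case-fatality
and background-mortality rates; an intervention enters only through
relative risks applied to the incidence of *first* events (Healthy ->
CHD / Stroke), ramped by the intervention's phase-in.

Modelling conventions:

* cohort age advances one year per cycle and rates are looked up in the
  five-year band containing the current age (no step artefacts at band
  edges);
* each destination rate is converted to a probability independently via
  ``1 - exp(-rate)``; the stay-probability is the residual, and a negative
  residual raises an error naming the stratum-year;
* background mortality applies in every alive state; in the disease states
  case fatality is added to the background rate before conversion;
* no recovery transitions and no combined CHD+stroke state: the first
  qualifying event assigns the state.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import strata
from .effect_chain import (
    EffectChainParams,
    PhaseIn,
    rr_profile,
    salt_g_to_sodium_mmol,
)
from .interventions import InterventionSpec, SaltBaseline, overall_reduction
from .strata import DISEASES, MAX_AGE, N_STRATA, StratumKey
from .synthetic import BASE_YEAR, ModelInputs

#: state indices
HEALTHY, CHD, STROKE, DEAD = 0, 1, 2, 3
STATE_NAMES = ("healthy", "chd", "stroke", "dead")


@dataclass(frozen=True)
class TrendParams:
    """Secular decline of rates out to a horizon year, then constant.

    Defaults: CHD/stroke incidence and case fatality decline 2.0 %/year;
    background mortality declines 1.75 %/year (non-Maori) and 2.25 %/year
    (Maori); all declines stop after 2026.
    """

    incidence_decline: float = 0.020
    case_fatality_decline: float = 0.020
    mortality_decline: dict = field(
        default_factory=lambda: {"maori": 0.0225, "non_maori": 0.0175}
    )
    trend_end_year: int = 2026

    def __post_init__(self) -> None:
        declines = [self.incidence_decline, self.case_fatality_decline,
                    *self.mortality_decline.values()]
        if any(not 0 <= d < 1 for d in declines):
            raise ValueError("annual declines must lie in [0, 1)")


def trend_adjust(rate, year: int, decline: float,
                 base_year: int = BASE_YEAR, end_year: int = 2026):
    """Rate after ``(1 - decline)`` compounding from base year to ``year``.

    The decline is held at zero after ``end_year`` (rates become constant).
    """
    if np.any(np.asarray(rate) < 0):
        raise ValueError("rate must be non-negative")
    if year < base_year:
        raise ValueError(f"year {year} precedes base year {base_year}")
    elapsed = min(year, end_year) - base_year
    return rate * (1.0 - decline) ** elapsed


def rate_to_prob(rate):
    """Annual event rate -> annual event probability, 1 - exp(-rate)."""
    if np.any(np.asarray(rate) < 0):
        raise ValueError("rate must be non-negative")
    return -np.expm1(-np.asarray(rate, dtype=float))


def _transition_probs(inc_chd, inc_stroke, mort, cf_chd, cf_stroke,
                      rr_chd=1.0, rr_stroke=1.0):
    """Per-destination annual probabilities from annual rates.

    Returns (p_hc, p_hs, p_hd, p_cd, p_sd); works on scalars or arrays.
    """
    p_hc = rate_to_prob(np.asarray(inc_chd) * rr_chd)
    p_hs = rate_to_prob(np.asarray(inc_stroke) * rr_stroke)
    p_hd = rate_to_prob(mort)
    p_cd = rate_to_prob(np.asarray(cf_chd) + np.asarray(mort))
    p_sd = rate_to_prob(np.asarray(cf_stroke) + np.asarray(mort))
    return p_hc, p_hs, p_hd, p_cd, p_sd


def build_transitions(stratum: StratumKey, year: int, epi,
                      trends: TrendParams | None = None,
                      rr: dict[str, float] | None = None,
                      base_year: int = BASE_YEAR) -> np.ndarray:
    """4x4 annual transition matrix for one stratum-year.

    ``rr`` maps disease name to the relative risk on first-event incidence
    (1.0 = comparator).  Rows sum to one; the Dead row is the identity.
    """
    trends = trends or TrendParams()
    rr = rr or {}
    for d, v in rr.items():
        if not 0 < v <= 1:
            raise ValueError(f"relative risk for {d} must lie in (0, 1]")
    s, b, e = stratum.indices
    end = trends.trend_end_year
    inc = {d: trend_adjust(epi.incidence[d][s, b, e], year,
                           trends.incidence_decline, base_year, end)
           for d in DISEASES}
    cf = {d: trend_adjust(epi.case_fatality[d][s, b, e], year,
                          trends.case_fatality_decline, base_year, end)
          for d in DISEASES}
    mort = trend_adjust(epi.background_mortality[s, b, e], year,
                        trends.mortality_decline[stratum.ethnicity],
                        base_year, end)
    p_hc, p_hs, p_hd, p_cd, p_sd = _transition_probs(
        inc["chd"], inc["stroke"], mort, cf["chd"], cf["stroke"],
        rr.get("chd", 1.0), rr.get("stroke", 1.0),
    )
    stay_h = 1.0 - p_hc - p_hs - p_hd
    if stay_h < 0:
        raise ValueError(
            f"transition probabilities exceed 1 for {stratum} in {year}"
        )
    m = np.zeros((4, 4))
    m[HEALTHY] = [stay_h, p_hc, p_hs, p_hd]
    m[CHD] = [0.0, 1.0 - p_cd, 0.0, p_cd]
    m[STROKE] = [0.0, 0.0, 1.0 - p_sd, p_sd]
    m[DEAD, DEAD] = 1.0
    return m


@dataclass
class CohortTrajectory:
    """Per-cycle state occupancy and event flows for all strata.

    ``occupancy`` has shape (T+1, 52, 4) (people; index 0 = base year),
    ``flows`` has shape (T, 52, 3): new CHD cases, new strokes, deaths
    during each cycle.  ``active[t, s]`` is False once the stratum's cohort
    age has reached the age-100 cap (its occupancy is frozen and it stops
    accruing anything).
    """

    base_year: int
    years: np.ndarray            # (T,) calendar year of each cycle
    ages: np.ndarray             # (T, 52) cohort age at cycle start
    active: np.ndarray           # (T, 52) bool
    occupancy: np.ndarray        # (T+1, 52, 4) people
    flows: np.ndarray            # (T, 52, 3) people: into CHD, into stroke, deaths
    counts: np.ndarray           # (52,) initial stratum counts

    @property
    def n_cycles(self) -> int:
        return len(self.years)

    def to_frame(self) -> pd.DataFrame:
        """Long-format occupancy table (stratum, year, state, occupancy)."""
        s_idx, b_idx, e_idx = strata.flat_indices()
        rows = []
        for t in range(self.n_cycles + 1):
            year = self.base_year + t
            for k, state in enumerate(STATE_NAMES):
                rows.append(pd.DataFrame({
                    "sex": [strata.SEXES[i] for i in s_idx],
                    "age_band": [strata.BAND_LABELS[i] for i in b_idx],
                    "ethnicity": [strata.ETHNICITIES[i] for i in e_idx],
                    "year": year,
                    "state": state,
                    "occupancy": self.occupancy[t, :, k],
                }))
        return pd.concat(rows, ignore_index=True)


class CycleModel:
    """Per-cycle transition probabilities for all 52 strata at once.

    This is the single place where stratum-year transition probabilities
    are assembled for a given intervention arm; the cohort engine and the
    individual-level microsimulation both consume it, so they share one
    transition model by construction.
    """

    def __init__(self, inputs: ModelInputs,
                 spec: InterventionSpec | None = None,
                 effect: EffectChainParams | None = None,
                 trends: TrendParams | None = None,
                 baseline: SaltBaseline = SaltBaseline(),
                 reduction_multiplier: float = 1.0):
        self.effect = effect or EffectChainParams()
        self.trends = trends or TrendParams()
        self.epi = inputs.epi
        self.base_year = inputs.population.base_year
        s_idx, b_idx, e_idx = strata.flat_indices()
        self.s_idx, self.b_idx, self.e_idx = s_idx, b_idx, e_idx
        self.start_ages = np.array([strata.start_age(b) for b in b_idx],
                                   dtype=float)
        self.mort_decline = np.array(
            [self.trends.mortality_decline[strata.ETHNICITIES[e]]
             for e in e_idx]
        )
        if spec is not None:
            delta_salt = baseline.baseline_salt_g * overall_reduction(spec)
            self.delta_na_full = (salt_g_to_sodium_mmol(delta_salt)
                                  * reduction_multiplier)
            self.phase = PhaseIn(spec.phase_in_years)
        else:
            self.delta_na_full, self.phase = 0.0, PhaseIn(0)
        self.n_cycles = MAX_AGE - int(self.start_ages.min())

    def cycle(self, t: int):
        """(ages, alive-mask, current band, p_hc, p_hs, p_hd, p_cd, p_sd)."""
        year = self.base_year + t
        age = self.start_ages + t
        alive_band = age < MAX_AGE
        cur_band = np.minimum(((age - strata.BAND_LOWER[0]) // 5).astype(int),
                              strata.N_BANDS - 1)

        elapsed = min(year, self.trends.trend_end_year) - self.base_year
        inc_f = (1.0 - self.trends.incidence_decline) ** elapsed
        cf_f = (1.0 - self.trends.case_fatality_decline) ** elapsed
        mort_f = (1.0 - self.mort_decline) ** elapsed

        s_idx, e_idx = self.s_idx, self.e_idx
        inc_chd = self.epi.incidence["chd"][s_idx, cur_band, e_idx] * inc_f
        inc_str = self.epi.incidence["stroke"][s_idx, cur_band, e_idx] * inc_f
        cf_chd = self.epi.case_fatality["chd"][s_idx, cur_band, e_idx] * cf_f
        cf_str = self.epi.case_fatality["stroke"][s_idx, cur_band, e_idx] * cf_f
        mort = self.epi.background_mortality[s_idx, cur_band, e_idx] * mort_f

        if self.delta_na_full > 0:
            # phase-in evaluated at mid-cycle
            rr_bands = rr_profile(self.delta_na_full, t + 0.5, self.phase,
                                  self.effect)
            rr_chd = rr_bands["chd"][cur_band]
            rr_str = rr_bands["stroke"][cur_band]
        else:
            rr_chd = rr_str = 1.0

        probs = _transition_probs(inc_chd, inc_str, mort, cf_chd, cf_str,
                                  rr_chd, rr_str)
        stay_h = 1.0 - probs[0] - probs[1] - probs[2]
        if (stay_h[alive_band] < 0).any():
            bad = int(np.argmax((stay_h < 0) & alive_band))
            key = StratumKey(strata.SEXES[s_idx[bad]], int(self.b_idx[bad]),
                             strata.ETHNICITIES[e_idx[bad]])
            raise ValueError(
                f"transition probabilities exceed 1 for {key} in {year}"
            )
        return age, alive_band, cur_band, probs


def run_cohort(inputs: ModelInputs,
               spec: InterventionSpec | None = None,
               effect: EffectChainParams | None = None,
               trends: TrendParams | None = None,
               baseline: SaltBaseline = SaltBaseline(),
               reduction_multiplier: float = 1.0) -> CohortTrajectory:
    """Simulate every stratum from the base year to extinction or age 100.

    ``spec=None`` is the "do nothing" comparator.  ``reduction_multiplier``
    scales the achieved sodium reduction (used by the sensitivity
    analyses); the run is fully deterministic.
    """
    inputs.validate()
    model = CycleModel(inputs, spec, effect, trends, baseline,
                       reduction_multiplier)
    epi = inputs.epi
    s_idx, b_idx, e_idx = model.s_idx, model.b_idx, model.e_idx
    counts = inputs.population.counts.reshape(-1)
    base_year = inputs.population.base_year

    T = model.n_cycles
    occupancy = np.zeros((T + 1, N_STRATA, 4))
    flows = np.zeros((T, N_STRATA, 3))
    ages = np.zeros((T, N_STRATA))
    active = np.zeros((T, N_STRATA), dtype=bool)

    prev_chd = epi.prevalence["chd"][s_idx, b_idx, e_idx]
    prev_str = epi.prevalence["stroke"][s_idx, b_idx, e_idx]
    occupancy[0, :, HEALTHY] = counts * (1.0 - prev_chd - prev_str)
    occupancy[0, :, CHD] = counts * prev_chd
    occupancy[0, :, STROKE] = counts * prev_str

    for t in range(T):
        age, alive_band, cur_band, probs = model.cycle(t)
        p_hc, p_hs, p_hd, p_cd, p_sd = probs
        stay_h = 1.0 - p_hc - p_hs - p_hd
        ages[t] = age
        active[t] = alive_band

        h, c, s, d = (occupancy[t, :, HEALTHY], occupancy[t, :, CHD],
                      occupancy[t, :, STROKE], occupancy[t, :, DEAD])
        new_chd = np.where(alive_band, h * p_hc, 0.0)
        new_str = np.where(alive_band, h * p_hs, 0.0)
        deaths = np.where(alive_band, h * p_hd + c * p_cd + s * p_sd, 0.0)

        occupancy[t + 1, :, HEALTHY] = np.where(alive_band, h * stay_h, h)
        occupancy[t + 1, :, CHD] = np.where(
            alive_band, c * (1.0 - p_cd) + new_chd, c)
        occupancy[t + 1, :, STROKE] = np.where(
            alive_band, s * (1.0 - p_sd) + new_str, s)
        occupancy[t + 1, :, DEAD] = d + deaths

        flows[t, :, 0] = new_chd
        flows[t, :, 1] = new_str
        flows[t, :, 2] = deaths

    return CohortTrajectory(
        base_year=base_year,
        years=base_year + np.arange(T),
        ages=ages,
        active=active,
        occupancy=occupancy,
        flows=flows,
        counts=counts,
    )
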