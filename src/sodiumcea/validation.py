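"""Independent validation oracles for the Markov cohort engine.

Two cross-checks, mirroring how population-health Markov models are
usually validated:

* a **multi-state life table** (MSLT): a proportion-based life table per
  stratum that consumes the same input files but shares no
  transition-assembly code with the engine.  It uses exact
  competing-exponential survival within each year and trapezoidal
  person-years, so agreement with the engine is evidence rather than
  tautology.
* an **individual-level microsimulation**: Monte Carlo individuals stepped
  through the engine's own annual transition probabilities, with common
  random numbers across the intervention and comparator arms, giving an
  unbiased stochastic estimate of the QALYs gained with a standard error.

The standard validation intervention is a uniform 22.8 mmol/day cut in
dietary sodium, applied with no phase-in.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import strata
from .economics import DiscountConfig, accrue_qalys, discount_factor
from .effect_chain import (
    EffectChainParams,
    PhaseIn,
    rr_profile,
    sodium_mmol_to_salt_g,
)
from .interventions import MANDATORY, InterventionSpec, SaltBaseline
from .markov import CHD, DEAD, HEALTHY, STROKE, CycleModel, TrendParams, run_cohort
from .strata import MAX_AGE
from .synthetic import ModelInputs

VALIDATION_SODIUM_CUT_MMOL = 22.8


def uniform_sodium_cut(delta_mmol: float = VALIDATION_SODIUM_CUT_MMOL,
                       baseline: SaltBaseline = SaltBaseline()
                       ) -> InterventionSpec:
    """Test intervention: a uniform sodium cut, no phase-in, no uncertainty."""
    reduction = sodium_mmol_to_salt_g(delta_mmol) / baseline.baseline_salt_g
    return InterventionSpec(
        id=0, name=f"uniform {delta_mmol} mmol/day sodium cut",
        mode=MANDATORY, phase_in_years=0, overall=reduction, effect_sd=0.0,
    )


# ---------------------------------------------------------------------------
# multi-state life table
# ---------------------------------------------------------------------------

def _mslt_stratum(inputs: ModelInputs, key: strata.StratumKey,
                  spec: InterventionSpec | None,
                  effect: EffectChainParams, trends: TrendParams,
                  discount: DiscountConfig,
                  baseline: SaltBaseline,
                  delta_na_full: float) -> float:
    """Discounted QALYs per initial member of one stratum, life-table style."""
    si, b0, ei = key.indices
    epi, morb = inputs.epi, inputs.morbidity
    base_year = inputs.population.base_year
    age0 = strata.start_age(b0)
    phase = PhaseIn(spec.phase_in_years) if spec is not None else PhaseIn(0)

    prev_c = epi.prevalence["chd"][si, b0, ei]
    prev_s = epi.prevalence["stroke"][si, b0, ei]
    h, c, s = 1.0 - prev_c - prev_s, prev_c, prev_s

    qalys = 0.0
    t = 0
    while age0 + t < MAX_AGE and h + c + s > 1e-12:
        year = base_year + t
        band = min((age0 + t - strata.BAND_LOWER[0]) // 5, strata.N_BANDS - 1)
        elapsed = min(year, trends.trend_end_year) - base_year
        i_c = (epi.incidence["chd"][si, band, ei]
               * (1.0 - trends.incidence_decline) ** elapsed)
        i_s = (epi.incidence["stroke"][si, band, ei]
               * (1.0 - trends.incidence_decline) ** elapsed)
        f_c = (epi.case_fatality["chd"][si, band, ei]
               * (1.0 - trends.case_fatality_decline) ** elapsed)
        f_s = (epi.case_fatality["stroke"][si, band, ei]
               * (1.0 - trends.case_fatality_decline) ** elapsed)
        m = (epi.background_mortality[si, band, ei]
             * (1.0 - trends.mortality_decline[key.ethnicity]) ** elapsed)
        if delta_na_full > 0:
            rr = rr_profile(delta_na_full, t + 0.5, phase, effect)
            i_c *= rr["chd"][band]
            i_s *= rr["stroke"][band]

        # exact competing-exponential survival within the year
        exit_h = i_c + i_s + m
        surv_h = math.exp(-exit_h)
        if exit_h > 0:
            leave = (1.0 - surv_h) / exit_h
            to_c, to_s = h * i_c * leave, h * i_s * leave
        else:
            to_c = to_s = 0.0
        h2 = h * surv_h
        c2 = c * math.exp(-(f_c + m)) + to_c
        s2 = s * math.exp(-(f_s + m)) + to_s

        # trapezoidal person-years by state, weighted and discounted
        w_bg = 1.0 - morb.background_pyld[si, band, ei]
        w_c = w_bg - morb.disease_yld_per_case["chd"][si, band, ei]
        w_s = w_bg - morb.disease_yld_per_case["stroke"][si, band, ei]
        py = (0.5 * (h + h2) * w_bg + 0.5 * (c + c2) * w_c
              + 0.5 * (s + s2) * w_s)
        qalys += py * discount_factor(year, discount)

        h, c, s = h2, c2, s2
        t += 1
    return qalys


def mslt_total_qalys(inputs: ModelInputs, spec: InterventionSpec | None,
                     effect: EffectChainParams | None = None,
                     trends: TrendParams | None = None,
                     discount: DiscountConfig = DiscountConfig(),
                     baseline: SaltBaseline = SaltBaseline()) -> float:
    """Population discounted QALYs from the life-table model."""
    inputs.validate()
    effect = effect or EffectChainParams()
    trends = trends or TrendParams()
    if spec is not None:
        from .effect_chain import salt_g_to_sodium_mmol
        from .interventions import overall_reduction
        delta_na = salt_g_to_sodium_mmol(
            baseline.baseline_salt_g * overall_reduction(spec))
    else:
        delta_na = 0.0
    total = 0.0
    for key in strata.iter_strata():
        count = inputs.population.counts[key.indices]
        if count == 0:
            continue
        total += count * _mslt_stratum(inputs, key, spec, effect, trends,
                                       discount, baseline, delta_na)
    return total


def mslt_qalys_gained(inputs: ModelInputs, spec: InterventionSpec,
                      effect: EffectChainParams | None = None,
                      trends: TrendParams | None = None,
                      discount: DiscountConfig = DiscountConfig()) -> float:
    """QALYs gained by ``spec`` according to the life-table oracle."""
    return (mslt_total_qalys(inputs, spec, effect, trends, discount)
            - mslt_total_qalys(inputs, None, effect, trends, discount))


def mslt_life_expectancy(inputs: ModelInputs,
                         trends: TrendParams | None = None) -> float:
    """Undiscounted, unweighted comparator life expectancy (years per adult).

    Computed as trapezoidal person-years per initial cohort member.
    """
    inputs.validate()
    trends = trends or TrendParams()
    effect = EffectChainParams()
    # reuse the life-table recursion with weight 1 by zeroing morbidity
    import dataclasses

    from .synthetic import MorbidityInputs
    zero_morb = MorbidityInputs(
        background_pyld=np.zeros(strata.SHAPE),
        disease_yld_per_case={d: np.zeros(strata.SHAPE)
                              for d in strata.DISEASES},
    )
    flat_inputs = dataclasses.replace(inputs, morbidity=zero_morb)
    py = mslt_total_qalys(flat_inputs, None, effect, trends,
                          DiscountConfig(rate=0.0))
    return py / inputs.population.total


def engine_life_expectancy(traj, half_cycle: bool = True) -> float:
    """Comparator life expectancy (years per adult) from an engine trajectory.

    With ``half_cycle`` person-years are the trapezoid of start- and
    end-of-cycle alive occupancy, the life-table convention, so the figure
    is directly comparable with :func:`mslt_life_expectancy`.
    """
    alive = traj.occupancy[:, :, :DEAD].sum(axis=2)
    per_cycle = 0.5 * (alive[:-1] + alive[1:]) if half_cycle else alive[:-1]
    return float((per_cycle * traj.active).sum() / traj.counts.sum())


# ---------------------------------------------------------------------------
# individual-level microsimulation
# ---------------------------------------------------------------------------

def _allocate_individuals(counts: np.ndarray, n: int) -> np.ndarray:
    """Stratum index for each of ``n`` individuals, proportional to counts."""
    share = counts / counts.sum()
    exact = share * n
    alloc = np.floor(exact).astype(int)
    deficit = n - alloc.sum()
    if deficit > 0:
        order = np.argsort(exact - alloc)[::-1][:deficit]
        alloc[order] += 1
    return np.repeat(np.arange(len(counts)), alloc)


def microsim_qalys_gained(inputs: ModelInputs, spec: InterventionSpec,
                          effect: EffectChainParams | None = None,
                          trends: TrendParams | None = None,
                          discount: DiscountConfig = DiscountConfig(),
                          n: int = 10_000, seed: int = 0
                          ) -> tuple[float, float]:
    """(mean, standard error) of population QALYs gained, by microsimulation.

    Individuals are allocated to strata proportional to population counts
    and stepped through both arms with common random numbers, so the
    difference estimator is unbiased for the cohort-model expectation with
    much less variance than independent arms would give.
    """
    if n < 1000:
        raise ValueError("microsimulation needs at least 1000 individuals")
    inputs.validate()
    rng = np.random.default_rng(seed)
    counts = inputs.population.counts.reshape(-1)
    si = _allocate_individuals(counts, n)

    arm_cmp = CycleModel(inputs, None, effect, trends)
    arm_int = CycleModel(inputs, spec, effect, trends)
    s_idx, b_idx, e_idx = arm_cmp.s_idx, arm_cmp.b_idx, arm_cmp.e_idx

    prev_c = inputs.epi.prevalence["chd"][s_idx, b_idx, e_idx][si]
    prev_s = inputs.epi.prevalence["stroke"][s_idx, b_idx, e_idx][si]
    u0 = rng.random(n)
    state0 = np.where(u0 < prev_c, CHD,
                      np.where(u0 < prev_c + prev_s, STROKE, HEALTHY))
    states = {"cmp": state0.copy(), "int": state0.copy()}
    qalys = {"cmp": np.zeros(n), "int": np.zeros(n)}

    morb = inputs.morbidity
    T = arm_cmp.n_cycles
    for t in range(T):
        u = rng.random(n)  # shared across arms: common random numbers
        for name, arm in (("cmp", arm_cmp), ("int", arm_int)):
            age, alive_band, cur_band, probs = arm.cycle(t)
            p_hc, p_hs, p_hd, p_cd, p_sd = (p[si] for p in probs)
            st = states[name]
            act = alive_band[si] & (st != DEAD)

            band_i = cur_band[si]
            w_bg = 1.0 - morb.background_pyld[s_idx[si], band_i, e_idx[si]]
            w = np.where(
                st == HEALTHY, w_bg,
                np.where(
                    st == CHD,
                    w_bg - morb.disease_yld_per_case["chd"][s_idx[si], band_i,
                                                            e_idx[si]],
                    w_bg - morb.disease_yld_per_case["stroke"][s_idx[si],
                                                               band_i,
                                                               e_idx[si]],
                ),
            )
            df = discount_factor(arm.base_year + t, discount)
            qalys[name] += np.where(act, w, 0.0) * df

            new = st.copy()
            healthy = act & (st == HEALTHY)
            new[healthy & (u < p_hc)] = CHD
            new[healthy & (u >= p_hc) & (u < p_hc + p_hs)] = STROKE
            new[healthy & (u >= p_hc + p_hs) & (u < p_hc + p_hs + p_hd)] = DEAD
            new[act & (st == CHD) & (u < p_cd)] = DEAD
            new[act & (st == STROKE) & (u < p_sd)] = DEAD
            states[name] = new

    gain = qalys["int"] - qalys["cmp"]
    pop = counts.sum()
    mean = float(gain.mean() * pop)
    se = float(gain.std(ddof=1) / math.sqrt(n) * pop)
    return mean, se


# ---------------------------------------------------------------------------
# cross-model comparison
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    markov_gain: float
    mslt_gain: float
    relative_difference: float      # |markov - mslt| / markov
    microsim_mean: float
    microsim_se: float
    z_score: float                  # (microsim - markov) / se
    mslt_tolerance: float = 0.07
    microsim_sigmas: float = 3.0

    @property
    def mslt_ok(self) -> bool:
        return self.relative_difference <= self.mslt_tolerance

    @property
    def microsim_ok(self) -> bool:
        return abs(self.z_score) <= self.microsim_sigmas

    @property
    def ok(self) -> bool:
        return self.mslt_ok and self.microsim_ok

    def summary(self) -> str:
        lines = [
            f"Markov engine QALYs gained:   {self.markov_gain:,.0f}",
            f"Multi-state life table:       {self.mslt_gain:,.0f}"
            f"  (diff {100 * self.relative_difference:.1f} %,"
            f" tol {100 * self.mslt_tolerance:.0f} %:"
            f" {'OK' if self.mslt_ok else 'FAIL'})",
            f"Microsimulation:              {self.microsim_mean:,.0f}"
            f" +/- {self.microsim_se:,.0f}"
            f"  (z = {self.z_score:+.2f},"
            f" |z| <= {self.microsim_sigmas:.0f}:"
            f" {'OK' if self.microsim_ok else 'FAIL'})",
        ]
        return "\n".join(lines)


def validate_engine(inputs: ModelInputs,
                    spec: InterventionSpec | None = None,
                    effect: EffectChainParams | None = None,
                    trends: TrendParams | None = None,
                    discount: DiscountConfig = DiscountConfig(),
                    n_individuals: int = 10_000,
                    seed: int = 0) -> ValidationReport:
    """Compare the engine against both oracles on the standard test cut."""
    spec = spec or uniform_sodium_cut()
    traj_cmp = run_cohort(inputs, None, effect, trends)
    traj_int = run_cohort(inputs, spec, effect, trends)
    markov_gain = float(
        accrue_qalys(traj_int, inputs.morbidity, discount).sum()
        - accrue_qalys(traj_cmp, inputs.morbidity, discount).sum()
    )
    mslt_gain = mslt_qalys_gained(inputs, spec, effect, trends, discount)
    micro_mean, micro_se = microsim_qalys_gained(
        inputs, spec, effect, trends, discount, n=n_individuals, seed=seed)
    return ValidationReport(
        markov_gain=markov_gain,
        mslt_gain=mslt_gain,
        relative_difference=abs(markov_gain - mslt_gain) / abs(markov_gain),
        microsim_mean=micro_mean,
        microsim_se=micro_se,
        z_score=(micro_mean - markov_gain) / micro_se,
    )
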