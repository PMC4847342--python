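"""Discounted QALY and health-system cost accounting.

QALYs weight each alive person-year by ``1 - background_pyld -
disease_yld_per_case`` (the morbidity decrements are prevalent-YLD
fractions on the 0-1 disability scale) and discount it back to the 2011
reference year.  Costs accrue annual background costs in the Healthy state
(with the CVD-attributable component already removed from the input),
first-year costs on new disease entrants, subsequent-year costs on
continuing prevalent cases, and a one-off last-six-months-of-life cost at
the cycle of death.  The public-share scale-up (1.2) and the old-age
multipliers (1.1/1.2/1.3 for 65-74/75-84/85+) are applied exactly once to
every cost item.

Incremental results are computed against the "do nothing" comparator and
reported both in total and per adult alive in 2011 by sex, ethnicity and
baseline age (<65 / 65+).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import strata
from .effect_chain import EffectChainParams
from .interventions import InterventionSpec, SaltBaseline
from .markov import CHD, DEAD, HEALTHY, STROKE, CohortTrajectory, TrendParams, run_cohort
from .synthetic import BASE_YEAR, CostInputs, ModelInputs, MorbidityInputs


@dataclass(frozen=True)
class DiscountConfig:
    rate: float = 0.03
    reference_year: int = BASE_YEAR

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("discount rate must be non-negative")


def discount_factor(year: int, cfg: DiscountConfig = DiscountConfig()) -> float:
    """Present-value factor (1 + rate)^-(year - reference_year)."""
    if year < cfg.reference_year:
        raise ValueError(f"year {year} precedes reference year {cfg.reference_year}")
    return float((1.0 + cfg.rate) ** -(year - cfg.reference_year))


@dataclass(frozen=True)
class InterventionCostConfig:
    """Programme costs (regulation / reformulation support), NZ$-like per year.

    These are order-of-magnitude placeholders (the underlying costings are
    not public); they are charged annually during the phase-in period only.
    """

    annual: dict = field(default_factory=lambda: {"mandatory": 2.0e6,
                                                  "voluntary": 1.5e6})


def intervention_cost(spec: InterventionSpec,
                      cfg: DiscountConfig = DiscountConfig(),
                      costs: InterventionCostConfig = InterventionCostConfig()
                      ) -> float:
    """Discounted programme cost over the phase-in years."""
    annual = costs.annual[spec.mode]
    return float(sum(
        annual * discount_factor(cfg.reference_year + t, cfg)
        for t in range(spec.phase_in_years)
    ))


def _band_lookup(ages: np.ndarray) -> np.ndarray:
    return np.minimum(((ages - strata.BAND_LOWER[0]) // 5).astype(int),
                      strata.N_BANDS - 1)


def accrue_qalys(traj: CohortTrajectory, morbidity: MorbidityInputs,
                 cfg: DiscountConfig = DiscountConfig(),
                 half_cycle: bool = False) -> np.ndarray:
    """Discounted QALYs per stratum (shape (52,)).

    By default each person alive at the start of a cycle accrues that full
    cycle-year; with ``half_cycle`` the average of start- and end-of-cycle
    occupancy is used instead.
    """
    morbidity.validate()
    s_idx, _, e_idx = strata.flat_indices()
    out = np.zeros(strata.N_STRATA)
    for t in range(traj.n_cycles):
        act = traj.active[t]
        if not act.any():
            break
        band = _band_lookup(traj.ages[t])
        bg = morbidity.background_pyld[s_idx, band, e_idx]
        w = np.stack([
            1.0 - bg,
            1.0 - bg - morbidity.disease_yld_per_case["chd"][s_idx, band, e_idx],
            1.0 - bg - morbidity.disease_yld_per_case["stroke"][s_idx, band, e_idx],
        ])
        occ = traj.occupancy[t, :, :DEAD].T
        if half_cycle:
            occ = 0.5 * (occ + traj.occupancy[t + 1, :, :DEAD].T)
        df = discount_factor(traj.base_year + t, cfg)
        out += np.where(act, (w * occ).sum(axis=0), 0.0) * df
    return out


#: cost components reported by accrue_costs
COST_COMPONENTS = ("healthy_background", "disease_first_year",
                   "disease_subsequent", "end_of_life")


def accrue_costs(traj: CohortTrajectory, costs: CostInputs,
                 cfg: DiscountConfig = DiscountConfig(),
                 half_cycle: bool = False) -> dict[str, np.ndarray]:
    """Discounted costs per stratum, broken down by component.

    Returns a dict with one (52,) array per component in
    ``COST_COMPONENTS`` plus their sum under ``"total"``.
    """
    costs.validate()
    s_idx, _, e_idx = strata.flat_indices()
    out = {k: np.zeros(strata.N_STRATA) for k in COST_COMPONENTS}
    for t in range(traj.n_cycles):
        act = traj.active[t]
        if not act.any():
            break
        band = _band_lookup(traj.ages[t])
        scale = costs.public_share_scale * strata.age_cost_multiplier(band)
        df = discount_factor(traj.base_year + t, cfg)
        occ = traj.occupancy[t]
        if half_cycle:
            occ = 0.5 * (occ + traj.occupancy[t + 1])
        w = np.where(act, scale * df, 0.0)

        out["healthy_background"] += (
            occ[:, HEALTHY] * costs.healthy_background_cost[s_idx, band, e_idx] * w
        )
        out["disease_subsequent"] += (
            occ[:, CHD] * costs.subsequent_year_cost["chd"][s_idx, band, e_idx]
            + occ[:, STROKE] * costs.subsequent_year_cost["stroke"][s_idx, band, e_idx]
        ) * w
        out["disease_first_year"] += (
            traj.flows[t, :, 0] * costs.first_year_cost["chd"][s_idx, band, e_idx]
            + traj.flows[t, :, 1] * costs.first_year_cost["stroke"][s_idx, band, e_idx]
        ) * w
        out["end_of_life"] += (
            traj.flows[t, :, 2] * costs.last6m_cost[s_idx, band, e_idx] * w
        )
    out["total"] = sum(out[k] for k in COST_COMPONENTS)
    return out


# ---------------------------------------------------------------------------
# incremental analysis
# ---------------------------------------------------------------------------

def _subgroup_masks() -> dict[str, np.ndarray]:
    s_idx, b_idx, e_idx = strata.flat_indices()
    lower = np.asarray(strata.BAND_LOWER)[b_idx]
    return {
        "age<65": lower < 65,
        "age65+": lower >= 65,
        "women": s_idx == 0,
        "men": s_idx == 1,
        "maori": e_idx == 0,
        "non_maori": e_idx == 1,
    }


@dataclass
class IncrementalResult:
    """Incremental QALYs and net cost of one intervention vs "do nothing"."""

    spec: InterventionSpec
    qalys_gained: float
    net_cost: float                      # negative = cost saving
    intervention_cost: float
    dqaly_by_stratum: np.ndarray         # (52,)
    dcost_by_stratum: np.ndarray         # (52,) health-system component only
    cost_components: dict[str, float]    # incremental, by component
    per_adult: pd.DataFrame              # group, dqaly_per_adult, dcost_per_adult
    counts: np.ndarray


def incremental(intervention_qalys: np.ndarray, comparator_qalys: np.ndarray,
                intervention_costs: dict[str, np.ndarray],
                comparator_costs: dict[str, np.ndarray],
                counts: np.ndarray, spec: InterventionSpec,
                programme_cost: float = 0.0) -> IncrementalResult:
    """Assemble an incremental result from per-stratum accruals.

    Per-adult figures divide the group's incremental totals by the group's
    base-year population; the programme cost is apportioned per capita.
    """
    if intervention_qalys.shape != comparator_qalys.shape:
        raise ValueError("mismatched accrual shapes")
    dq = intervention_qalys - comparator_qalys
    dc = intervention_costs["total"] - comparator_costs["total"]
    total = counts.sum()
    rows = []
    for group, mask in _subgroup_masks().items():
        n = counts[mask].sum()
        prog = programme_cost * n / total
        rows.append({
            "group": group,
            "population": n,
            "dqaly_per_adult": dq[mask].sum() / n,
            "dcost_per_adult": (dc[mask].sum() + prog) / n,
        })
    components = {
        k: float(intervention_costs[k].sum() - comparator_costs[k].sum())
        for k in COST_COMPONENTS
    }
    return IncrementalResult(
        spec=spec,
        qalys_gained=float(dq.sum()),
        net_cost=float(dc.sum() + programme_cost),
        intervention_cost=programme_cost,
        dqaly_by_stratum=dq,
        dcost_by_stratum=dc,
        cost_components=components,
        per_adult=pd.DataFrame(rows),
        counts=counts,
    )


def evaluate_intervention(inputs: ModelInputs, spec: InterventionSpec,
                          effect: EffectChainParams | None = None,
                          discount: DiscountConfig = DiscountConfig(),
                          trends: TrendParams | None = None,
                          baseline: SaltBaseline = SaltBaseline(),
                          prog_costs: InterventionCostConfig = InterventionCostConfig(),
                          comparator_traj: CohortTrajectory | None = None,
                          reduction_multiplier: float = 1.0,
                          half_cycle: bool = False) -> IncrementalResult:
    """Run intervention and comparator and return the incremental result.

    Pass ``comparator_traj`` to reuse an already-computed comparator run
    (valid only if inputs, effect parameters and trends are unchanged).
    """
    if comparator_traj is None:
        comparator_traj = run_cohort(inputs, None, effect, trends, baseline)
    traj = run_cohort(inputs, spec, effect, trends, baseline,
                      reduction_multiplier=reduction_multiplier)
    q_int = accrue_qalys(traj, inputs.morbidity, discount, half_cycle)
    q_cmp = accrue_qalys(comparator_traj, inputs.morbidity, discount, half_cycle)
    c_int = accrue_costs(traj, inputs.costs, discount, half_cycle)
    c_cmp = accrue_costs(comparator_traj, inputs.costs, discount, half_cycle)
    prog = intervention_cost(spec, discount, prog_costs)
    return incremental(q_int, q_cmp, c_int, c_cmp, traj.counts, spec, prog)
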