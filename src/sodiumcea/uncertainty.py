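"""Probabilistic sensitivity analysis, tornado diagrams and scenario grids.

The PSA re-evaluates the full model (intervention and comparator) for each
joint draw of the uncertain parameters — achieved sodium reduction, SBP
dose-response, SBP-risk halving constants, disease and background costs,
and disease morbidity — all sampled independently, and summarises the
incremental results as percentile 95 % uncertainty intervals.  The tornado
analysis sweeps one parameter at a time between its 2.5th and 97.5th
percentiles around the expected-value base case.  The scenario runner
covers the discount-rate grid (0 / 3 / 6 %) and the half-effect variant of
the voluntary interventions.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .economics import (
    DiscountConfig,
    InterventionCostConfig,
    accrue_costs,
    accrue_qalys,
    evaluate_intervention,
    intervention_cost,
)
from .effect_chain import DoseResponseParams, EffectChainParams, RiskTranslation
from .interventions import VOLUNTARY, InterventionSpec, half_effect
from .markov import TrendParams, run_cohort
from .strata import DISEASES
from .synthetic import ModelInputs, scaled_inputs

#: draw keys routed to synthetic.scaled_inputs
_INPUT_KEYS = ("chd_cost", "stroke_cost", "healthy_cost", "disease_yld")


@dataclass(frozen=True)
class ParamDistribution:
    """Sampling distribution of one uncertain multiplier.

    ``kind`` is one of normal / lognormal / beta / uniform.  For normal the
    (loc, scale) are mean and SD; for lognormal, the median and the SD of
    the log; for uniform, the lower and upper bounds; for beta, the two
    shape parameters.  Draws are clipped to the parameter's domain
    (multipliers are non-negative).
    """

    name: str
    kind: str
    loc: float
    scale: float

    @property
    def degenerate(self) -> bool:
        """True for a zero-variance (point-mass) parameter."""
        return self.kind in ("normal", "lognormal") and self.scale == 0.0

    def _frozen(self):
        if self.kind == "normal":
            return stats.norm(self.loc, self.scale)
        if self.kind == "lognormal":
            return stats.lognorm(s=self.scale, scale=self.loc)
        if self.kind == "uniform":
            return stats.uniform(self.loc, self.scale - self.loc)
        if self.kind == "beta":
            return stats.beta(self.loc, self.scale)
        raise ValueError(f"unknown distribution kind {self.kind!r}")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        u = rng.random(n)  # always consume the stream, even if degenerate
        if self.degenerate:
            return np.full(n, self.loc)
        return np.clip(self._frozen().ppf(u), 0.0, None)

    def percentile(self, q: float) -> float:
        if self.degenerate:
            return float(max(self.loc, 0.0))
        return float(max(self._frozen().ppf(q / 100.0), 0.0))


def default_psa_params(spec: InterventionSpec) -> list[ParamDistribution]:
    """Default uncertain-parameter set (multipliers around 1).

    The achieved-reduction SD comes from the intervention's mode (10 %
    mandatory, 20 % voluntary).
    """
    return [
        ParamDistribution("effect_size", "normal", 1.0, spec.effect_sd),
        ParamDistribution("sbp_coeff", "lognormal", 1.0, 0.25),
        ParamDistribution("chd_halving", "lognormal", 1.0, 0.15),
        ParamDistribution("stroke_halving", "lognormal", 1.0, 0.15),
        ParamDistribution("chd_cost", "lognormal", 1.0, 0.10),
        ParamDistribution("stroke_cost", "lognormal", 1.0, 0.10),
        ParamDistribution("disease_yld", "lognormal", 1.0, 0.10),
        ParamDistribution("healthy_cost", "lognormal", 1.0, 0.03),
    ]


def _apply_draw(inputs: ModelInputs, effect: EffectChainParams,
                draw: dict[str, float]
                ) -> tuple[ModelInputs, EffectChainParams, float]:
    mults = {k: v for k, v in draw.items() if k in _INPUT_KEYS and v != 1.0}
    if mults:
        inputs = scaled_inputs(inputs, **mults)
    dose = effect.dose_response
    risk = effect.risk
    if draw.get("sbp_coeff", 1.0) != 1.0:
        dose = DoseResponseParams(dose.sbp_fall_per_100mmol * draw["sbp_coeff"])
    halving = {d: risk.halving_mmHg[d] for d in DISEASES}
    for d in DISEASES:
        key = f"{d}_halving"
        if draw.get(key, 1.0) != 1.0:
            halving = {**halving, d: halving[d] * draw[key]}
    if halving is not risk.halving_mmHg:
        risk = RiskTranslation(dict(halving))
    return (inputs, EffectChainParams(dose, risk),
            max(draw.get("effect_size", 1.0), 0.0))


def _evaluate_draw(inputs, spec, effect, draw, discount, trends, prog_costs):
    inputs2, effect2, red_mult = _apply_draw(inputs, effect, draw)
    res = evaluate_intervention(inputs2, spec, effect2, discount, trends,
                                prog_costs=prog_costs,
                                reduction_multiplier=red_mult)
    return res.qalys_gained, res.net_cost


@dataclass
class PsaResult:
    spec: InterventionSpec
    draws: pd.DataFrame              # columns: draw, dqaly, dcost
    ui95: dict[str, tuple[float, float]]
    point: tuple[float, float]       # expected-value (dqaly, dcost)
    seed: int

    @property
    def correlation(self) -> float:
        """Pearson correlation between QALY and cost increments across draws."""
        return float(np.corrcoef(self.draws["dqaly"], self.draws["dcost"])[0, 1])

    @property
    def fraction_cost_saving(self) -> float:
        return float((self.draws["dcost"] < 0).mean())


def run_psa(inputs: ModelInputs, spec: InterventionSpec,
            effect: EffectChainParams | None = None,
            n_draws: int = 2000, seed: int = 0,
            params: list[ParamDistribution] | None = None,
            discount: DiscountConfig = DiscountConfig(),
            trends: TrendParams | None = None,
            prog_costs: InterventionCostConfig = InterventionCostConfig()
            ) -> PsaResult:
    """Monte Carlo uncertainty analysis with percentile 95 % intervals."""
    if n_draws < 100:
        raise ValueError("PSA needs at least 100 draws for stable percentiles")
    effect = effect or EffectChainParams()
    params = params if params is not None else default_psa_params(spec)
    rng = np.random.default_rng(seed)
    samples = {p.name: p.sample(rng, n_draws) for p in params}

    dqaly = np.empty(n_draws)
    dcost = np.empty(n_draws)
    for i in range(n_draws):
        draw = {name: float(vals[i]) for name, vals in samples.items()}
        dqaly[i], dcost[i] = _evaluate_draw(
            inputs, spec, effect, draw, discount, trends, prog_costs)

    base = evaluate_intervention(inputs, spec, effect, discount, trends,
                                 prog_costs=prog_costs)
    ui = {
        "dqaly": tuple(np.percentile(dqaly, [2.5, 97.5])),
        "dcost": tuple(np.percentile(dcost, [2.5, 97.5])),
    }
    draws = pd.DataFrame({"draw": np.arange(n_draws),
                          "dqaly": dqaly, "dcost": dcost})
    return PsaResult(spec=spec, draws=draws, ui95=ui,
                     point=(base.qalys_gained, base.net_cost), seed=seed)


@dataclass
class TornadoResult:
    spec: InterventionSpec
    table: pd.DataFrame   # param, qaly_low/high, cost_low/high, width; sorted
    output: str           # which output the bars were sorted on


def run_tornado(inputs: ModelInputs, spec: InterventionSpec,
                effect: EffectChainParams | None = None,
                params: list[ParamDistribution] | None = None,
                discount: DiscountConfig = DiscountConfig(),
                trends: TrendParams | None = None,
                output: str = "cost",
                prog_costs: InterventionCostConfig = InterventionCostConfig()
                ) -> TornadoResult:
    """One-way sensitivity bars, each parameter swept 2.5th -> 97.5th pct."""
    if output not in ("cost", "qaly"):
        raise ValueError("output must be 'cost' or 'qaly'")
    effect = effect or EffectChainParams()
    params = params if params is not None else default_psa_params(spec)
    rows = []
    for p in params:
        lo_q, lo_c = _evaluate_draw(inputs, spec, effect,
                                    {p.name: p.percentile(2.5)},
                                    discount, trends, prog_costs)
        hi_q, hi_c = _evaluate_draw(inputs, spec, effect,
                                    {p.name: p.percentile(97.5)},
                                    discount, trends, prog_costs)
        rows.append({
            "param": p.name,
            "qaly_low": lo_q, "qaly_high": hi_q,
            "cost_low": lo_c, "cost_high": hi_c,
            "qaly_width": abs(hi_q - lo_q),
            "cost_width": abs(hi_c - lo_c),
        })
    table = (pd.DataFrame(rows)
             .sort_values(f"{output}_width", ascending=False, kind="stable")
             .reset_index(drop=True))
    return TornadoResult(spec=spec, table=table, output=output)


def run_scenarios(inputs: ModelInputs, specs: list[InterventionSpec],
                  effect: EffectChainParams | None = None,
                  trends: TrendParams | None = None,
                  discount_rates: tuple[float, ...] = (0.0, 0.03, 0.06),
                  prog_costs: InterventionCostConfig = InterventionCostConfig()
                  ) -> pd.DataFrame:
    """Scenario grid: discount rates x (full / half-effect voluntary).

    Trajectories are discount-independent, so each spec is simulated once
    and accrued at every discount rate.
    """
    effect = effect or EffectChainParams()
    comparator = run_cohort(inputs, None, effect, trends)
    rows = []
    variants: list[tuple[InterventionSpec, bool]] = []
    for spec in specs:
        variants.append((spec, False))
        if spec.mode == VOLUNTARY:
            variants.append((half_effect(spec), True))
    trajs = {i: run_cohort(inputs, s, effect, trends)
             for i, (s, _) in enumerate(variants)}
    for rate in discount_rates:
        cfg = DiscountConfig(rate=rate)
        q_cmp = accrue_qalys(comparator, inputs.morbidity, cfg)
        c_cmp = accrue_costs(comparator, inputs.costs, cfg)
        for i, (spec, halved) in enumerate(variants):
            traj = trajs[i]
            dq = (accrue_qalys(traj, inputs.morbidity, cfg)
                  - q_cmp).sum()
            dc = (accrue_costs(traj, inputs.costs, cfg)["total"]
                  - c_cmp["total"]).sum()
            rows.append({
                "intervention": spec.id, "name": spec.name, "mode": spec.mode,
                "half_effect": halved, "discount_rate": rate,
                "dqaly": float(dq),
                "net_cost": float(dc + intervention_cost(spec, cfg, prog_costs)),
            })
    return pd.DataFrame(rows)
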