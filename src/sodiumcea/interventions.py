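"""Sodium-reduction intervention targets.

Ten targets are modelled, from a "full target" (an overall 35 % cut in
dietary salt, from 8.4 g/day to 5.5 g/day) down to single food-category
targets (bread, processed meats, sauces, snack foods, bakery, cheese).
Each can be achieved through mandatory maximum sodium limits (3-year
phase-in, lower uncertainty) or a voluntary industry programme (5-year
phase-in, higher uncertainty).

A target is expressed as a set of food categories, each with an intake
share (the fraction of total dietary sodium sourced from that category)
and a within-category fractional sodium reduction; the population-level
reduction is the share-weighted sum.  The intake-share table itself is not
publicly available, so the shipped default shares are synthetic values
calibrated so that the published category-level percentages (36 % across
all packaged foods; 35 % overall for the full target) are reproduced.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import yaml

MANDATORY = "mandatory"
VOLUNTARY = "voluntary"

#: Default phase-in durations (years) and relative effect uncertainty by mode.
PHASE_IN_YEARS = {MANDATORY: 3, VOLUNTARY: 5}
EFFECT_SD = {MANDATORY: 0.10, VOLUNTARY: 0.20}


@dataclass(frozen=True)
class FoodCategory:
    """A food category's share of total dietary sodium and its target cut."""

    name: str
    intake_share: float   # fraction of total dietary sodium, [0, 1]
    reduction: float      # fractional sodium cut within the category, [0, 1]

    def __post_init__(self) -> None:
        if not 0.0 <= self.intake_share <= 1.0:
            raise ValueError(f"intake share of {self.name!r} outside [0, 1]")
        if not 0.0 <= self.reduction <= 1.0:
            raise ValueError(f"reduction of {self.name!r} outside [0, 1]")


@dataclass(frozen=True)
class SaltBaseline:
    """Population mean dietary salt intake and the headline target."""

    baseline_salt_g: float = 8.4
    target_salt_g: float = 5.5

    def __post_init__(self) -> None:
        if not 0 < self.target_salt_g <= self.baseline_salt_g:
            raise ValueError("need 0 < target <= baseline salt intake")


@dataclass(frozen=True)
class InterventionSpec:
    id: int
    name: str
    mode: str = MANDATORY
    phase_in_years: int | None = None
    categories: tuple[FoodCategory, ...] | None = None
    overall: float | None = None       # direct overall reduction, if no categories
    effect_sd: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in (MANDATORY, VOLUNTARY):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.phase_in_years is None:
            object.__setattr__(self, "phase_in_years", PHASE_IN_YEARS[self.mode])
        if self.effect_sd is None:
            object.__setattr__(self, "effect_sd", EFFECT_SD[self.mode])
        if self.phase_in_years < 0:
            raise ValueError("phase-in must be non-negative")
        if (self.categories is None) == (self.overall is None):
            raise ValueError("specify exactly one of categories / overall")
        if self.overall is not None and not 0.0 <= self.overall <= 1.0:
            raise ValueError("overall reduction outside [0, 1]")

    @property
    def label(self) -> str:
        return f"{self.id}) {self.name} ({self.mode})"


def overall_reduction(spec: InterventionSpec) -> float:
    """Population-level fractional sodium reduction achieved by ``spec``.

    For category-based targets this is the intake-share-weighted sum of the
    within-category reductions; shares must not sum above 1.
    """
    if spec.categories is None:
        return float(spec.overall)
    shares = sum(c.intake_share for c in spec.categories)
    if shares > 1.0 + 1e-9:
        raise ValueError(
            f"intake shares of {spec.label} sum to {shares:.3f} > 1"
        )
    return float(sum(c.intake_share * c.reduction for c in spec.categories))


def salt_reduction_g(spec: InterventionSpec,
                     baseline: SaltBaseline = SaltBaseline()) -> float:
    """Absolute salt cut in g/day implied by ``spec`` at the given baseline."""
    return baseline.baseline_salt_g * overall_reduction(spec)


# ---------------------------------------------------------------------------
# default target set
# ---------------------------------------------------------------------------

# Synthetic intake shares (fractions of total dietary sodium).  Chosen so
# that (a) the seven packaged sub-categories sum to the packaged-foods share
# and reproduce a 36 % within-packaged reduction, and (b) packaged + fast
# food + discretionary reproduce the 35 % full-target reduction exactly.
_PACKAGED_SHARE = 0.625
_FAST_FOOD_SHARE = 0.1875
_DISCRETIONARY_SHARE = 0.125

# (share of total sodium, share-weighted within-category reduction)
_PACKAGED_COMPONENTS = {
    "bread": (0.110, 0.25),             # published range 12-37 %
    "processed_meats": (0.090, 0.45),   # 35-55 %
    "sauces": (0.080, 0.45),            # 30-63 %
    "snack_foods": (0.035, 0.41),       # 34-48 %
    "bakery_other": (0.045, 0.58),      # 54-63 %
    "cheese": (0.045, 0.33),            # 27-42 %
}
# residual packaged foods: reduction solved so packaged overall is exactly 36 %
_OTHER_SHARE = _PACKAGED_SHARE - sum(s for s, _ in _PACKAGED_COMPONENTS.values())
_OTHER_REDUCTION = (
    0.36 * _PACKAGED_SHARE
    - sum(s * r for s, r in _PACKAGED_COMPONENTS.values())
) / _OTHER_SHARE


def _cat(name: str) -> FoodCategory:
    share, red = _PACKAGED_COMPONENTS[name]
    return FoodCategory(name, share, red)


def _packaged_categories() -> tuple[FoodCategory, ...]:
    return tuple(_cat(n) for n in _PACKAGED_COMPONENTS) + (
        FoodCategory("packaged_other", _OTHER_SHARE, _OTHER_REDUCTION),
    )


def build_default_interventions() -> list[InterventionSpec]:
    """The ten default targets, each in mandatory and voluntary form (20 specs)."""
    full_target = (
        FoodCategory("packaged_foods", _PACKAGED_SHARE, 0.36),
        FoodCategory("fast_food_restaurant", _FAST_FOOD_SHARE, 0.40),
        FoodCategory("discretionary", _DISCRETIONARY_SHARE, 0.40),
    )
    bases = [
        (1, "Full target", full_target),
        (2, "Packaged foods target", _packaged_categories()),
        (3, "Fast food & restaurant target",
         (FoodCategory("fast_food_restaurant", _FAST_FOOD_SHARE, 0.40),)),
        (4, "Bread target", (_cat("bread"),)),
        (5, "Processed meats target", (_cat("processed_meats"),)),
        (6, "Sauces target", (_cat("sauces"),)),
        (7, "Package of interventions 4 to 6",
         (_cat("bread"), _cat("processed_meats"), _cat("sauces"))),
        (8, "Snack food target", (_cat("snack_foods"),)),
        (9, "All bread and bakery target", (_cat("bread"), _cat("bakery_other"))),
        (10, "Cheese target", (_cat("cheese"),)),
    ]
    specs = []
    for mode in (MANDATORY, VOLUNTARY):
        for iid, name, cats in bases:
            specs.append(InterventionSpec(id=iid, name=name, mode=mode,
                                          categories=cats))
    return specs


def half_effect(spec: InterventionSpec) -> InterventionSpec:
    """Scenario variant with half the achieved reduction (non-compliance)."""
    if spec.categories is not None:
        cats = tuple(replace(c, reduction=c.reduction / 2) for c in spec.categories)
        return replace(spec, categories=cats)
    return replace(spec, overall=spec.overall / 2)


# ---------------------------------------------------------------------------
# YAML round-trip
# ---------------------------------------------------------------------------

def save_interventions(specs: list[InterventionSpec], path: str | Path) -> None:
    blocks = []
    for s in specs:
        block: dict = {
            "id": s.id, "name": s.name, "mode": s.mode,
            "phase_in_years": s.phase_in_years, "effect_sd": s.effect_sd,
        }
        if s.categories is not None:
            block["categories"] = [
                {"name": c.name, "share": c.intake_share, "reduction": c.reduction}
                for c in s.categories
            ]
        else:
            block["overall_reduction"] = s.overall
        blocks.append(block)
    Path(path).write_text(yaml.safe_dump(blocks, sort_keys=False), encoding="utf-8")


def load_interventions(path: str | Path) -> list[InterventionSpec]:
    blocks = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    specs = []
    for b in blocks:
        cats = None
        if "categories" in b:
            cats = tuple(
                FoodCategory(c["name"], c["share"], c["reduction"])
                for c in b["categories"]
            )
        specs.append(InterventionSpec(
            id=b["id"], name=b["name"], mode=b["mode"],
            phase_in_years=b.get("phase_in_years"),
            categories=cats, overall=b.get("overall_reduction"),
            effect_sd=b.get("effect_sd"),
        ))
    return specs
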