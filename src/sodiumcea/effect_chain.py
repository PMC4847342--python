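"""Sodium -> blood pressure -> cardiovascular risk effect chain.

A daily sodium intake reduction (mmol/day) lowers usual systolic blood
pressure (SBP) through an age-dependent dose-response of the kind estimated
from pooled salt-trial regressions, and a lower usual SBP lowers the risk
of first CHD and stroke events following the log-linear association seen
in large prospective-study meta-analyses: each ``halving_mmHg`` of lower
usual SBP roughly halves event risk, with the association attenuating at
older ages.

The shipped coefficient defaults are documented approximations with the
conventional shapes (salt sensitivity rising with age; risk association
weakening with age); exact values are configuration, not code.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .strata import DISEASES, N_BANDS

#: mass fraction of sodium in NaCl (Na 22.99 / (Na 22.99 + Cl 35.45))
SODIUM_MASS_FRACTION = 0.3934
SODIUM_MOLAR_MASS_G = 22.99  # g/mol


def salt_g_to_sodium_mmol(salt_g: float) -> float:
    """Convert a salt (NaCl) mass in g/day to sodium in mmol/day.

    8.4 g of salt corresponds to ~143.7 mmol of sodium.
    """
    if salt_g < 0:
        raise ValueError("salt mass must be non-negative")
    return salt_g * 1000.0 * SODIUM_MASS_FRACTION / SODIUM_MOLAR_MASS_G


def sodium_mmol_to_salt_g(delta_na: float) -> float:
    if delta_na < 0:
        raise ValueError("sodium amount must be non-negative")
    return delta_na * SODIUM_MOLAR_MASS_G / (1000.0 * SODIUM_MASS_FRACTION)


@dataclass
class DoseResponseParams:
    """SBP fall (mmHg) per 100 mmol/day sodium reduction, by age band."""

    sbp_fall_per_100mmol: np.ndarray = field(
        default_factory=lambda: 3.5 + 0.25 * np.arange(N_BANDS)
    )

    def __post_init__(self) -> None:
        arr = np.asarray(self.sbp_fall_per_100mmol, dtype=float)
        if arr.shape != (N_BANDS,):
            raise ValueError(f"need one coefficient per age band ({N_BANDS})")
        if (arr < 0).any():
            raise ValueError("SBP dose-response coefficients must be non-negative")
        self.sbp_fall_per_100mmol = arr


@dataclass
class RiskTranslation:
    """mmHg of lower usual SBP associated with a halving of event risk.

    Larger values mean a weaker SBP-risk association; defaults increase
    with age and are larger for CHD than for stroke.
    """

    halving_mmHg: dict[str, np.ndarray] = field(
        default_factory=lambda: {
            "chd": 19.0 + 1.0 * np.arange(N_BANDS),
            "stroke": 14.0 + 1.0 * np.arange(N_BANDS),
        }
    )

    def __post_init__(self) -> None:
        for d in DISEASES:
            arr = np.asarray(self.halving_mmHg[d], dtype=float)
            if arr.shape != (N_BANDS,):
                raise ValueError(f"need one halving constant per band for {d}")
            if (arr <= 0).any():
                raise ValueError(f"halving_mmHg for {d} must be positive")
            self.halving_mmHg[d] = arr


@dataclass(frozen=True)
class PhaseIn:
    """Linear ramp of intervention effect from 0 to full over ``duration_years``."""

    duration_years: int
    shape: str = "linear"

    def __post_init__(self) -> None:
        if self.duration_years < 0:
            raise ValueError("phase-in duration must be non-negative")
        if self.shape != "linear":
            raise ValueError(f"unsupported phase-in shape {self.shape!r}")


@dataclass
class EffectChainParams:
    dose_response: DoseResponseParams = field(default_factory=DoseResponseParams)
    risk: RiskTranslation = field(default_factory=RiskTranslation)


def delta_sbp(delta_na: float, age_band: int | np.ndarray,
              params: DoseResponseParams) -> float | np.ndarray:
    """SBP fall (mmHg) for a sodium reduction of ``delta_na`` mmol/day."""
    if delta_na < 0:
        raise ValueError("sodium reduction must be non-negative")
    coeff = params.sbp_fall_per_100mmol[age_band]  # IndexError on unknown band
    return coeff * delta_na / 100.0


def rr_from_delta_sbp(dsbp: float | np.ndarray, age_band: int | np.ndarray,
                      disease: str, rt: RiskTranslation) -> float | np.ndarray:
    """Relative risk of first events after an SBP fall of ``dsbp`` mmHg.

    RR = 0.5 ** (dsbp / halving_mmHg); always in (0, 1] for dsbp >= 0.
    """
    if np.any(np.asarray(dsbp) < 0):
        raise ValueError("SBP fall must be non-negative")
    halving = rt.halving_mmHg[disease][age_band]
    return 0.5 ** (np.asarray(dsbp) / halving)


def phase_in_fraction(t_years: float, p: PhaseIn) -> float:
    """Fraction of the full effect achieved ``t_years`` after launch."""
    if t_years < 0:
        raise ValueError("time since launch must be non-negative")
    if p.duration_years == 0:
        return 1.0
    return min(t_years / p.duration_years, 1.0)


def rr_profile(delta_na_full: float, t_years: float, phase: PhaseIn,
               params: EffectChainParams) -> dict[str, np.ndarray]:
    """Per-band relative risks at time ``t_years`` into the intervention.

    The phase-in scales the *sodium reduction* (the physical exposure), and
    the SBP and risk translations are applied to the ramped exposure.
    """
    frac = phase_in_fraction(t_years, phase)
    delta_na = frac * delta_na_full
    bands = np.arange(N_BANDS)
    dsbp = delta_sbp(delta_na, bands, params.dose_response)
    return {d: np.asarray(rr_from_delta_sbp(dsbp, bands, d, params.risk))
            for d in DISEASES}


# ---------------------------------------------------------------------------
# YAML round-trip
# ---------------------------------------------------------------------------

def save_effect_chain(params: EffectChainParams, path: str | Path) -> None:
    data = {
        "sbp_fall_per_100mmol": params.dose_response.sbp_fall_per_100mmol.tolist(),
        "halving_mmHg": {d: params.risk.halving_mmHg[d].tolist() for d in DISEASES},
    }
    Path(path).write_text(yaml.safe_dump(data), encoding="utf-8")


def load_effect_chain(path: str | Path) -> EffectChainParams:
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return EffectChainParams(
        dose_response=DoseResponseParams(np.asarray(data["sbp_fall_per_100mmol"])),
        risk=RiskTranslation({d: np.asarray(v)
                              for d, v in data["halving_mmHg"].items()}),
    )
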