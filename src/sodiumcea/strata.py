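"""Stratum bookkeeping for the simulated cohort.

Every stratified input and output in the package is indexed by the triple
(sex, five-year age band, ethnicity).  There are 13 age bands covering ages
35-39, 40-44, ..., 95+, two sexes and two ethnic groupings (Maori and
non-Maori), i.e. 52 strata.  Arrays are stored with shape
``(n_sexes, n_bands, n_ethnicities) = (2, 13, 2)``; the flattened stratum
index runs sex-major, then band, then ethnicity.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

SEXES: tuple[str, ...] = ("female", "male")
ETHNICITIES: tuple[str, ...] = ("maori", "non_maori")
DISEASES: tuple[str, ...] = ("chd", "stroke")

N_BANDS = 13
N_SEXES = len(SEXES)
N_ETHNICITIES = len(ETHNICITIES)
N_STRATA = N_SEXES * N_BANDS * N_ETHNICITIES

#: Lower age bound of each five-year band; the last band (95+) is open-ended.
BAND_LOWER: tuple[int, ...] = tuple(35 + 5 * i for i in range(N_BANDS))
BAND_LABELS: tuple[str, ...] = tuple(
    f"{lo}-{lo + 4}" if i < N_BANDS - 1 else "95+" for i, lo in enumerate(BAND_LOWER)
)

#: Simulation stops when a cohort reaches this age.
MAX_AGE = 100

SHAPE = (N_SEXES, N_BANDS, N_ETHNICITIES)


@dataclass(frozen=True)
class StratumKey:
    """One cell of the sex x age-band x ethnicity cross-classification."""

    sex: str
    age_band: int
    ethnicity: str

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if not 0 <= self.age_band < N_BANDS:
            raise ValueError(f"age band index {self.age_band} outside 0..{N_BANDS - 1}")
        if self.ethnicity not in ETHNICITIES:
            raise ValueError(f"unknown ethnicity {self.ethnicity!r}")

    @property
    def band_label(self) -> str:
        return BAND_LABELS[self.age_band]

    @property
    def indices(self) -> tuple[int, int, int]:
        return (SEXES.index(self.sex), self.age_band, ETHNICITIES.index(self.ethnicity))


def band_lower_bound(band: int) -> int:
    if not 0 <= band < N_BANDS:
        raise ValueError(f"age band index {band} outside 0..{N_BANDS - 1}")
    return BAND_LOWER[band]


def band_for_age(age: float) -> int:
    """Five-year band containing ``age``; ages above 95 map to the open band."""
    if age < BAND_LOWER[0]:
        raise ValueError(f"age {age} below the modelled range (35+)")
    return min(int((age - BAND_LOWER[0]) // 5), N_BANDS - 1)


def start_age(band: int) -> int:
    """Representative starting age for a cohort in ``band`` (band midpoint)."""
    return band_lower_bound(band) + 2


def iter_strata() -> Iterator[StratumKey]:
    for sex in SEXES:
        for band in range(N_BANDS):
            for eth in ETHNICITIES:
                yield StratumKey(sex, band, eth)


def stratum_index(key: StratumKey) -> int:
    s, b, e = key.indices
    return (s * N_BANDS + b) * N_ETHNICITIES + e


def flat_indices() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(sex, band, ethnicity) index arrays for the flattened stratum order."""
    s, b, e = np.unravel_index(np.arange(N_STRATA), SHAPE)
    return s, b, e


#: Age-cost multipliers for residential-care spending not captured in the
#: underlying cost data: 1.1 for 65-74, 1.2 for 75-84, 1.3 for 85+.
def age_cost_multiplier(band: int | np.ndarray) -> np.ndarray:
    band = np.asarray(band)
    mult = np.ones(band.shape)
    lower = np.asarray(BAND_LOWER)[band]
    mult[(lower >= 65) & (lower < 75)] = 1.1
    mult[(lower >= 75) & (lower < 85)] = 1.2
    mult[lower >= 85] = 1.3
    return mult
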