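"""Demographic arithmetic shared by every pipeline stage.

Mortality is tracked as monthly probabilities of death in four age bins of a
child's first five years (neonatal = month 0, 1-11 months, 12-35 months,
36-59 months) and four five-year calendar periods labelled by their middle
year (2000 = 1998-2002, 2005 = 2003-07, 2010 = 2008-12, 2015 = 2013-17).
Period rates are synthetic-cohort probabilities: the under-5 mortality rate
is one minus the product of age-bin survival probabilities, each survival
probability raised to the number of months in its bin.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np


class AgeBin(enum.IntEnum):
    """Age bins of the first 60 months of life, by completed months."""

    NEONATAL = 0
    M1_11 = 1
    M12_35 = 2
    M36_59 = 3

    @property
    def n_months(self) -> int:
        return _BIN_MONTHS[self]

    @property
    def start_month(self) -> int:
        return _BIN_START[self]


_BIN_MONTHS = {AgeBin.NEONATAL: 1, AgeBin.M1_11: 11, AgeBin.M12_35: 24, AgeBin.M36_59: 24}
_BIN_START = {AgeBin.NEONATAL: 0, AgeBin.M1_11: 1, AgeBin.M12_35: 12, AgeBin.M36_59: 36}

AGE_BINS: tuple[AgeBin, ...] = tuple(AgeBin)
N_MONTHS = np.array([_BIN_MONTHS[b] for b in AGE_BINS])  # (1, 11, 24, 24)

assert int(N_MONTHS.sum()) == 60


@dataclass(frozen=True)
class Period:
    """Five-year estimation period labelled by its middle calendar year."""

    label: int
    first_year: int
    last_year: int

    def __contains__(self, year: int) -> bool:
        return self.first_year <= year <= self.last_year


PERIODS: tuple[Period, ...] = (
    Period(2000, 1998, 2002),
    Period(2005, 2003, 2007),
    Period(2010, 2008, 2012),
    Period(2015, 2013, 2017),
)
PERIOD_LABELS: tuple[int, ...] = tuple(p.label for p in PERIODS)
N_BINS = len(AGE_BINS) * len(PERIODS)  # 16 age-group x period cells


def period_of_year(year: int) -> Period | None:
    """Return the estimation period containing ``year``, or None if out of scope."""
    for p in PERIODS:
        if year in p:
            return p
    return None


def age_bin_of_month(age_months: int) -> AgeBin | None:
    """Return the age bin of a completed age in months, or None if >= 60."""
    if age_months < 0:
        raise ValueError(f"age_months must be >= 0, got {age_months}")
    if age_months == 0:
        return AgeBin.NEONATAL
    if age_months <= 11:
        return AgeBin.M1_11
    if age_months <= 35:
        return AgeBin.M12_35
    if age_months <= 59:
        return AgeBin.M36_59
    return None


def assign_bin(age_months: int, event_year: int) -> tuple[AgeBin, Period] | None:
    """Map a completed age in months and a calendar year to an (AgeBin, Period) cell.

    Returns None if the age is 60+ months or the year falls outside 1998-2017.
    Negative ages raise ``ValueError``.
    """
    b = age_bin_of_month(age_months)
    p = period_of_year(event_year)
    if b is None or p is None:
        return None
    return b, p


def _validate_q(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if q.shape[-1] != len(AGE_BINS):
        raise ValueError(f"last axis must have {len(AGE_BINS)} age bins, got {q.shape}")
    if not np.all(np.isfinite(q)):
        raise ValueError("monthly probabilities must be finite")
    if np.any(q < 0) or np.any(q > 1):
        raise ValueError("monthly probabilities must lie in [0, 1]")
    return q


def compute_5q0(q) -> np.ndarray | float:
    """Under-5 mortality per 1000 livebirths from monthly death probabilities.

    ``q`` has the four age-bin monthly probabilities on its last axis. The
    synthetic-cohort probability of death before 60 months is
    ``1 - prod_a (1 - q_a) ** n_months(a)``, scaled to per-1000.
    """
    q = _validate_q(q)
    surv = np.prod((1.0 - q) ** N_MONTHS, axis=-1)
    out = 1000.0 * (1.0 - surv)
    return float(out) if out.ndim == 0 else out


def compute_nmr(q) -> np.ndarray | float:
    """Neonatal mortality per 1000 livebirths: 1000 x monthly probability in month 0."""
    q = _validate_q(q)
    out = 1000.0 * q[..., AgeBin.NEONATAL]
    return float(out) if out.ndim == 0 else out
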