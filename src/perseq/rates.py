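"""Closed-form comparison of replication errors and spontaneous deamination.

Two back-of-envelope calculations frame the biology:

* how long double-stranded DNA would have to sit at 37 °C for spontaneous
  5mC deamination to generate as many CpG>TpG events as a *single* round
  of replication by wild-type Pol ε (answer: years); and
* how many CpG>TpG events per day a dividing cell accrues from
  deamination (E1) versus Pol ε misincorporation before (E2) and after
  (E3) proofreading.

All quantities are simple products/ratios of measured constants, kept in
a config block so alternative measured rates flow through.  Internal
values are unrounded; report formatting matches the printed precision
(D to one decimal, E2/E3 to the nearest integer).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

SECONDS_IN_A_YEAR = 365.2425 * 24 * 60 * 60  # Gregorian year
SECONDS_IN_A_DAY = 86400.0


@dataclass(frozen=True)
class RateConstants:
    """Measured inputs to the deamination/replication arithmetic.

    Attributes
    ----------
    E : float
        Wild-type Pol ε C>T errors per replication per 5mCpG.
    deamination_rate : float
        Spontaneous 5mC deamination events per second per 5mCpG in dsDNA
        at 37 °C.
    error_per_repl_exo : float
        Errors per replication per 5mCpG for exonuclease-deficient Pol ε
        (before proofreading).
    error_per_repl_wt : float
        Errors per replication per 5mCpG for wild-type Pol ε (escaping
        proofreading).
    n_cpgs : float
        Number of CpG sites per (human) genome.
    replications_in_a_day : float
        Genome replications per day in a dividing cell.
    """

    E: float = 4.5e-5
    deamination_rate: float = 5.8e-13
    error_per_repl_exo: float = 40.23e-5
    error_per_repl_wt: float = 4.52e-5
    n_cpgs: float = 53.5e6
    replications_in_a_day: float = 0.2
    seconds_in_a_year: float = SECONDS_IN_A_YEAR
    seconds_in_a_day: float = SECONDS_IN_A_DAY

    def __post_init__(self):
        for name in (
            "E", "deamination_rate", "error_per_repl_exo", "error_per_repl_wt",
            "n_cpgs", "replications_in_a_day", "seconds_in_a_year",
            "seconds_in_a_day",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def yearly_deamination_rate(c: RateConstants = RateConstants()) -> float:
    """R: expected deamination events per year per 5mCpG."""
    return c.deamination_rate * c.seconds_in_a_year


def deamination_equivalent_duration(c: RateConstants = RateConstants()) -> float:
    """D = E/R: years of 37 °C incubation generating as many CpG>TpG events
    as one replication by wild-type Pol ε."""
    r = yearly_deamination_rate(c)
    if r == 0:
        raise ZeroDivisionError("yearly deamination rate is zero")
    return c.E / r


def daily_event_estimates(
    c: RateConstants = RateConstants(),
) -> Tuple[float, float, float]:
    """(E1, E2, E3): CpG>TpG events per day per cell from deamination,
    Pol ε before proofreading, and Pol ε escaping proofreading."""
    e1 = c.deamination_rate * c.seconds_in_a_day * c.n_cpgs
    e2 = c.error_per_repl_exo * c.replications_in_a_day * c.n_cpgs
    e3 = c.error_per_repl_wt * c.replications_in_a_day * c.n_cpgs
    return e1, e2, e3


def genome_wide_errors_per_replication(
    rate_per_cpg: float, n_cpgs: float = RateConstants.n_cpgs
) -> float:
    """Genome-wide C:dA errors generated in a single replication."""
    if rate_per_cpg < 0 or n_cpgs <= 0:
        raise ValueError("inputs must be positive")
    return rate_per_cpg * n_cpgs


def report(c: RateConstants = RateConstants()) -> dict:
    """All derived quantities, rounded to reporting precision."""
    e1, e2, e3 = daily_event_estimates(c)
    return {
        "R_per_year_per_5mCpG": float(f"{yearly_deamination_rate(c):.3g}"),
        "D_years": round(deamination_equivalent_duration(c), 1),
        "E1_per_day": round(e1, 2),
        "E2_per_day": round(e2),
        "E3_per_day": round(e3),
        "genome_wide_errors_per_replication": round(
            genome_wide_errors_per_replication(c.error_per_repl_wt, c.n_cpgs), 1
        ),
    }
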