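"""Region- and tract-level rate estimation and descriptive computations.

Region rates come from the model (posterior of expected true counts over
population), not from crude count ratios — correcting the selection-biased
crude ratio is the point of the two-part model.  The two regions are pooled
by intersecting their 95% credibility intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .inference import PosteriorFit
from .model import case_totals

__all__ = [
    "RateEstimate",
    "PooledInterval",
    "region_prevalence",
    "region_incidence",
    "tract_rates",
    "pool_intervals",
    "zero_fraction",
    "category_share",
    "crude_rate",
    "crude_rate_interval",
]

PER = 1e5

#: Tracts with fewer at-risk persons than this are flagged unstable.
DEFAULT_POPULATION_FLOOR = 50.0


@dataclass
class RateEstimate:
    """Point estimate and 95% credibility interval for a rate per 100,000
    (inhabitants for prevalence, person-years for incidence)."""

    scope: str  # region or tract id
    measure: str  # "prevalence" | "incidence"
    category: str  # MND | ALS | PMA | PLS
    point: float
    lower: float
    upper: float
    flagged: bool = False  # unstable (tiny at-risk population)

    def __post_init__(self):
        if not (0.0 <= self.lower <= self.point <= self.upper):
            raise ValueError(
                f"require 0 <= lower <= point <= upper, got "
                f"({self.lower}, {self.point}, {self.upper})"
            )


@dataclass
class PooledInterval:
    measure: str
    category: str
    lower: float
    upper: float

    @property
    def empty(self) -> bool:
        return self.lower > self.upper


def _rate_draw_summary(count_draws: np.ndarray, denominator: float):
    """Population-weighted rate draws per 100,000 from expected-count draws
    summed over all remaining axes."""
    if denominator <= 0:
        raise ValueError("population denominator must be positive")
    totals = count_draws.reshape(count_draws.shape[0], -1).sum(axis=1)
    rates = PER * totals / denominator
    return (
        float(np.quantile(rates, 0.5)),
        float(np.quantile(rates, 0.025)),
        float(np.quantile(rates, 0.975)),
    )


def region_prevalence(
    fit: PosteriorFit, tracts: pd.DataFrame, category: str | None = None
) -> RateEstimate:
    """Period prevalence per 100,000 at-risk inhabitants for the whole
    region: posterior of expected true cases over the study window divided
    by the total at-risk population."""
    if fit.spec.target != "prevalence":
        raise ValueError("fit does not target prevalence")
    category = category or fit.spec.response
    if category != fit.spec.response:
        raise ValueError(
            f"fit is for response {fit.spec.response!r}, not {category!r}"
        )
    denom = float(tracts["pop_over16"].sum())
    lam = fit.expected_true_count_draws()
    point, lo, hi = _rate_draw_summary(lam, denom)
    region = _single_region_label(tracts)
    return RateEstimate(region, "prevalence", category, point, lo, hi)


def region_incidence(
    fit: PosteriorFit,
    tracts: pd.DataFrame,
    category: str | None = None,
    period: list | None = None,
) -> RateEstimate:
    """Incidence per 100,000 person-years: expected new cases per year over
    person-years (at-risk population x number of years)."""
    if fit.spec.target != "incidence":
        raise ValueError("fit does not target incidence")
    category = category or fit.spec.response
    if category != fit.spec.response:
        raise ValueError(
            f"fit is for response {fit.spec.response!r}, not {category!r}"
        )
    years = period if period is not None else fit.data.years
    if len(years) == 0:
        raise ValueError("period must be non-empty")
    n_years = len(years)
    person_years = float(tracts["pop_over16"].sum()) * n_years
    lam = fit.expected_true_count_draws()
    point, lo, hi = _rate_draw_summary(lam, person_years)
    region = _single_region_label(tracts)
    return RateEstimate(region, "incidence", category, point, lo, hi)


def tract_rates(
    fit: PosteriorFit,
    tracts: pd.DataFrame,
    population_floor: float = DEFAULT_POPULATION_FLOOR,
) -> list:
    """Per-tract posterior rate summaries; tracts whose at-risk population is
    below ``population_floor`` are flagged unstable (interpret with
    caution)."""
    lam = fit.expected_true_count_draws()
    measure = fit.spec.target
    pops = tracts["pop_over16"].to_numpy(float)
    n_years = len(fit.data.years) if measure == "incidence" else 1
    out = []
    for i, tid in enumerate(tracts["tract_id"]):
        draws_i = lam[:, i] if lam.ndim == 2 else lam[:, i, :].sum(axis=1)
        point, lo, hi = _rate_draw_summary(draws_i[:, None], pops[i] * n_years)
        out.append(
            RateEstimate(
                str(tid),
                measure,
                fit.spec.response,
                point,
                lo,
                hi,
                flagged=bool(pops[i] < population_floor),
            )
        )
    return out


def pool_intervals(a: RateEstimate, b: RateEstimate) -> PooledInterval:
    """Pool two regions' estimates by intersecting their 95% credibility
    intervals: ``[max(lowers), min(uppers)]``.  An empty intersection is
    returned explicitly (with a warning), never clamped."""
    if a.measure != b.measure:
        raise ValueError(f"measure mismatch: {a.measure!r} vs {b.measure!r}")
    if a.category != b.category:
        raise ValueError(f"category mismatch: {a.category!r} vs {b.category!r}")
    pooled = PooledInterval(
        measure=a.measure,
        category=a.category,
        lower=max(a.lower, b.lower),
        upper=min(a.upper, b.upper),
    )
    if pooled.empty:
        warnings.warn(
            f"credibility intervals for {a.category} {a.measure} do not "
            f"intersect: [{a.lower}, {a.upper}] vs [{b.lower}, {b.upper}]"
        )
    return pooled


def zero_fraction(tracts: pd.DataFrame, category: str = "MND") -> float:
    """Percentage of tracts with zero recorded cases of ``category`` over the
    study window, to one decimal."""
    if len(tracts) == 0:
        raise ValueError("empty tract table")
    totals = case_totals(tracts, category)
    return round(100.0 * float((totals == 0).mean()), 1)


def category_share(counts) -> dict:
    """Percentage share of each diagnostic category among definite
    diagnoses, to one decimal."""
    counts = dict(counts)
    if any(v < 0 for v in counts.values()):
        raise ValueError("counts must be nonnegative")
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("at least one category count must be positive")
    return {k: round(100.0 * v / total, 1) for k, v in counts.items()}


def crude_rate(cases: int, population: float | None = None,
               person_years: float | None = None) -> float:
    """Naive rate per 100,000 — the uncorrected comparator."""
    denom = person_years if person_years is not None else population
    if denom is None or denom <= 0:
        raise ValueError("need a positive population or person-years denominator")
    if cases < 0:
        raise ValueError("cases must be nonnegative")
    return PER * cases / denom


def crude_rate_interval(cases: int, denominator: float):
    """Exact (Garwood) 95% Poisson confidence interval for the crude rate
    per 100,000 — the uncorrected comparator's interval."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    lo = 0.0 if cases == 0 else chi2.ppf(0.025, 2 * cases) / 2.0
    hi = chi2.ppf(0.975, 2 * cases + 2) / 2.0
    return PER * lo / denominator, PER * hi / denominator


def _single_region_label(tracts: pd.DataFrame) -> str:
    regions = tracts["region"].unique() if "region" in tracts.columns else []
    return str(regions[0]) if len(regions) == 1 else "all"
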