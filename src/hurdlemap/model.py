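"""Mathematical core of the two-part spatial hurdle model.

This module holds the covariance/penalty/likelihood primitives shared by the
generator and the fitting engine:

* the Matérn covariance function and its range parameterisation,
* the first-order random-walk (RW1) increment log-density,
* penalised-complexity (PC) prior log-densities for standard deviations and
  for the spatial range,
* the zero-inflated Poisson (ZIP) log-pmf,
* both linear predictors of the two-part model (binomial observation part and
  ZIP count part) plus their joint log-likelihood in reference (row-wise,
  unvectorised) form.

Everything here is deterministic, side-effect free and independently testable
against closed forms; the inference engine re-implements the likelihood in
vectorised form and is cross-checked against this module.
"""

from __future__ import annotations

import json
import math
import numbers
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, kv, gamma as gamma_fn

__all__ = [
    "MaternParams",
    "PCPriorSettings",
    "TwoPartModelSpec",
    "LatentState",
    "matern_covariance",
    "matern_covariance_matrix",
    "range_from_kappa",
    "kappa_from_range",
    "rw1_logdensity",
    "pc_prior_sd_logdensity",
    "pc_prior_range_logdensity",
    "zip_logpmf",
    "part1_linear_predictor",
    "part2_linear_predictor",
    "joint_loglikelihood",
    "build_covariates",
    "case_totals",
    "inverse_logit",
    "DEFAULT_FIXED_EFFECTS",
]

RESPONSE_CATEGORIES = ("MND", "ALS", "PMA", "PLS")

#: Default tract-level fixed effects: sex/age composition of the at-risk
#: population, deprivation quintiles 2-5 (quintile 1 is the reference) and
#: the log population strata.
DEFAULT_FIXED_EFFECTS = (
    "male_frac",
    "share_65plus",
    "dep_q2",
    "dep_q3",
    "dep_q4",
    "dep_q5",
    "log_men_16to64",
    "log_men_65plus",
    "log_women_16to64",
    "log_women_65plus",
)


def inverse_logit(x):
    """Numerically stable logistic function."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Matérn covariance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MaternParams:
    """Parameters of the Matérn covariance family.

    Attributes
    ----------
    sigma2 : float
        Marginal variance, ``sigma2 > 0``.
    kappa : float
        Inverse-scale parameter, ``kappa > 0``.
    nu : float
        Smoothness, ``nu > 0``.  Defaults to 1, the conventional fixed
        smoothness for two-dimensional spatial fields.
    """

    sigma2: float
    kappa: float
    nu: float = 1.0

    def __post_init__(self):
        if not (self.sigma2 > 0):
            raise ValueError(f"sigma2 must be > 0, got {self.sigma2}")
        if not (self.kappa > 0):
            raise ValueError(f"kappa must be > 0, got {self.kappa}")
        if not (self.nu > 0):
            raise ValueError(f"nu must be > 0, got {self.nu}")

    @property
    def range_rho(self) -> float:
        """Spatial range ``rho = sqrt(8 nu) / kappa`` (correlation ~= 0.1)."""
        return math.sqrt(8.0 * self.nu) / self.kappa


def range_from_kappa(p: MaternParams) -> float:
    """Return the range ``rho = sqrt(8 nu) / kappa`` of a Matérn field."""
    return p.range_rho


def kappa_from_range(rho: float, nu: float = 1.0) -> float:
    """Invert the range relation: ``kappa = sqrt(8 nu) / rho``."""
    if not (rho > 0):
        raise ValueError(f"range must be > 0, got {rho}")
    return math.sqrt(8.0 * nu) / rho


def matern_covariance(d, p: MaternParams):
    """Matérn covariance at distance ``d``.

    ``cov(d) = sigma2 / (2^(nu-1) Gamma(nu)) * (kappa d)^nu * K_nu(kappa d)``
    for ``d > 0`` and ``sigma2`` at ``d = 0`` (the limit), where ``K_nu`` is
    the modified Bessel function of the second kind.

    Parameters
    ----------
    d : float or array_like
        Distance(s), must be nonnegative.
    p : MaternParams

    Returns
    -------
    float or ndarray
    """
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr < 0):
        raise ValueError("distances must be nonnegative")
    scaled = p.kappa * d_arr
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = (
            p.sigma2
            / (2.0 ** (p.nu - 1.0) * gamma_fn(p.nu))
            * scaled**p.nu
            * kv(p.nu, scaled)
        )
    cov = np.where(d_arr == 0.0, p.sigma2, cov)
    if np.isscalar(d) or d_arr.ndim == 0:
        return float(cov)
    return cov


def matern_covariance_matrix(coords, p: MaternParams, jitter: float = 0.0) -> np.ndarray:
    """Dense Matérn covariance matrix for a set of planar points.

    Parameters
    ----------
    coords : (n, 2) array_like
    p : MaternParams
    jitter : float
        Added to the diagonal (as a fraction of ``sigma2``) for numerical
        stability when the matrix is factorised.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must have shape (n, 2)")
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    cov = matern_covariance(dist, p)
    if jitter:
        cov = cov + jitter * p.sigma2 * np.eye(len(coords))
    return cov


# ---------------------------------------------------------------------------
# RW1 and PC priors
# ---------------------------------------------------------------------------


def rw1_logdensity(gamma: Sequence[float], precision: float) -> float:
    """Log-density (up to a constant) of a first-order random walk.

    The RW1 prior penalises squared successive differences,

    ``log p(gamma) = ((T-1)/2) log(tau / (2 pi)) - (tau/2) sum (g[t+1]-g[t])^2``

    which is improper of rank ``T-1``; a sum-to-zero constraint on ``gamma``
    makes it identifiable alongside an intercept (callers apply the
    constraint; the density itself is invariant to level shifts).
    """
    g = np.asarray(gamma, dtype=float)
    if g.ndim != 1 or len(g) < 2:
        raise ValueError("gamma must be a vector with at least 2 time points")
    if not (precision > 0):
        raise ValueError(f"precision must be > 0, got {precision}")
    diffs = np.diff(g)
    k = len(g) - 1  # rank of the RW1 structure matrix
    return 0.5 * k * math.log(precision / (2.0 * math.pi)) - 0.5 * precision * float(
        diffs @ diffs
    )


def pc_prior_sd_logdensity(sigma, u: float, alpha: float):
    """PC prior log-density for a standard deviation.

    The penalised-complexity prior for a random-effect standard deviation is
    exponential with rate ``lam = -log(alpha) / u``, calibrated so that
    ``P(sigma > u) = alpha`` exactly.
    """
    if not (u > 0):
        raise ValueError(f"u must be > 0, got {u}")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    lam = -math.log(alpha) / u
    s = np.asarray(sigma, dtype=float)
    if np.any(s < 0):
        raise ValueError("sigma must be nonnegative")
    out = math.log(lam) - lam * s
    if np.isscalar(sigma):
        return float(out)
    return out


def pc_prior_range_logdensity(rho, u: float, alpha: float):
    """PC prior log-density for the Matérn range (2-d field).

    Calibrated by the tail statement ``P(rho < u) = alpha``; the density is
    ``lam * rho^-2 * exp(-lam / rho)`` with ``lam = -log(alpha) * u``.
    """
    if not (u > 0):
        raise ValueError(f"u must be > 0, got {u}")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    lam = -math.log(alpha) * u
    r = np.asarray(rho, dtype=float)
    if np.any(r <= 0):
        raise ValueError("range must be positive")
    out = math.log(lam) - 2.0 * np.log(r) - lam / r
    if np.isscalar(rho):
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Zero-inflated Poisson
# ---------------------------------------------------------------------------


def zip_logpmf(y, theta, pi0):
    """Log-pmf of the zero-inflated Poisson distribution.

    ``P(Y = y) = pi0 * 1{y=0} + (1 - pi0) * Poisson(y; theta)``

    Parameters
    ----------
    y : int or array_like of nonnegative integers
    theta : float or array_like, Poisson mean(s) > 0
    pi0 : float in [0, 1), zero-inflation probability
    """
    y_arr = np.asarray(y)
    if np.any(y_arr < 0) or not np.issubdtype(np.asarray(y_arr).dtype, np.integer):
        y_float = np.asarray(y, dtype=float)
        if np.any(y_float < 0) or np.any(y_float != np.round(y_float)):
            raise ValueError("y must be nonnegative integer(s)")
        y_arr = y_float.astype(np.int64)
    if not (0.0 <= pi0 < 1.0):
        raise ValueError(f"pi0 must be in [0, 1), got {pi0}")
    th = np.asarray(theta, dtype=float)
    if np.any(th <= 0):
        raise ValueError("theta must be > 0")
    y_arr, th = np.broadcast_arrays(y_arr, th)
    pois = y_arr * np.log(th) - th - gammaln(y_arr + 1.0)
    with np.errstate(divide="ignore"):
        log_pi0 = np.log(pi0) if pi0 > 0 else -np.inf
        nonzero = np.log1p(-pi0) + pois
    out = np.where(y_arr == 0, np.logaddexp(log_pi0, nonzero), nonzero)
    if np.isscalar(y) and np.isscalar(theta):
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PCPriorSettings:
    """Calibration of the PC priors.

    ``P(sigma > sd_u) = sd_alpha`` for every random-effect standard
    deviation, and ``P(rho < range_u) = range_alpha`` for the spatial range.
    ``range_u = None`` means "one tenth of the domain diameter", resolved at
    fit time.
    """

    sd_u: float = 1.0
    sd_alpha: float = 0.01
    range_u: float | None = None
    range_alpha: float = 0.05

    def __post_init__(self):
        if not (self.sd_u > 0):
            raise ValueError(f"u must be > 0, got {self.sd_u}")
        if self.range_u is not None and not (self.range_u > 0):
            raise ValueError(f"u must be > 0, got {self.range_u}")
        for a in (self.sd_alpha, self.range_alpha):
            if not (0.0 < a < 1.0):
                raise ValueError(f"alpha must be in (0, 1), got {a}")


@dataclass(frozen=True)
class TwoPartModelSpec:
    """Full specification of the two-part model.

    Part 1 is a binomial GLMM for the probability of an at-risk person being
    an observed case; part 2 a ZIP GLMM for the observed tract counts.  Both
    parts share the Matérn spatial field; each has its own iid heterogeneity.
    The incidence target adds an RW1 yearly effect to part 2.

    ``weighting_rule`` controls how the part-1 probabilities are fed into
    part 2:

    * ``"log_prob_offset"`` (default): the log of the coverage-anchored
      observation probability enters the part-2 linear predictor as an
      offset, so the ZIP mean models observed counts as thinned true counts;
    * ``"likelihood_weight"``: the part-2 log-likelihood terms receive
      inverse-probability weights instead;
    * ``"none"``: the two parts decouple (used for tests and comparators).

    ``coverage_mean`` is the assumed population-mean observation probability
    that anchors the otherwise unidentified level of the selection process
    (the referral-unit coverage fraction); it is a free parameter of the
    procedure, defaulting to 1 (no thinning).
    """

    response: str = "MND"
    target: str = "prevalence"
    fixed_effects: tuple = DEFAULT_FIXED_EFFECTS
    selection_covariates: tuple = ()
    offset_column: str = "pop_over16"
    spatial: bool = True
    heterogeneity: bool = True
    zero_inflation: bool = True
    nu: float = 1.0
    parts: str = "both"  # both | part1 | part2
    weighting_rule: str = "log_prob_offset"
    coverage_mean: float = 1.0
    part1_exposure: bool = False  # optional exposure covariate in part 1
    priors: PCPriorSettings = field(default_factory=PCPriorSettings)

    def __post_init__(self):
        if self.response not in RESPONSE_CATEGORIES:
            raise ValueError(f"unknown response {self.response!r}")
        if self.target not in ("prevalence", "incidence"):
            raise ValueError(f"unknown target {self.target!r}")
        if self.parts not in ("both", "part1", "part2"):
            raise ValueError(f"unknown parts {self.parts!r}")
        if self.weighting_rule not in ("log_prob_offset", "likelihood_weight", "none"):
            raise ValueError(f"unknown weighting_rule {self.weighting_rule!r}")
        if not (0.0 < self.coverage_mean <= 1.0):
            raise ValueError("coverage_mean must be in (0, 1]")
        object.__setattr__(self, "fixed_effects", tuple(self.fixed_effects))
        object.__setattr__(self, "selection_covariates", tuple(self.selection_covariates))

    @property
    def temporal_rw1(self) -> bool:
        """Incidence specifications include the RW1 year effect."""
        return self.target == "incidence"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fixed_effects"] = list(self.fixed_effects)
        d["selection_covariates"] = list(self.selection_covariates)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "TwoPartModelSpec":
        d = dict(d)
        if "priors" in d and isinstance(d["priors"], Mapping):
            d["priors"] = PCPriorSettings(**d["priors"])
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "TwoPartModelSpec":
        return cls.from_dict(json.loads(s))


@dataclass
class LatentState:
    """Latent effects of the two-part model for a fixed tract/year layout."""

    eta1: np.ndarray
    eta2: np.ndarray
    S: np.ndarray
    gamma_t: np.ndarray
    pi0: float = 0.0

    def __post_init__(self):
        self.eta1 = np.asarray(self.eta1, dtype=float)
        self.eta2 = np.asarray(self.eta2, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        self.gamma_t = np.asarray(self.gamma_t, dtype=float)
        n = len(self.S)
        if len(self.eta1) != n or len(self.eta2) != n:
            raise ValueError("eta1, eta2 and S must have matching tract dimension")
        if not (0.0 <= self.pi0 <= 1.0):
            raise ValueError(f"pi0 must be in [0, 1], got {self.pi0}")

    @classmethod
    def zeros(cls, n_tracts: int, n_years: int = 0, pi0: float = 0.0) -> "LatentState":
        return cls(
            eta1=np.zeros(n_tracts),
            eta2=np.zeros(n_tracts),
            S=np.zeros(n_tracts),
            gamma_t=np.zeros(n_years),
            pi0=pi0,
        )


# ---------------------------------------------------------------------------
# Linear predictors and joint likelihood (reference, row-wise form)
# ---------------------------------------------------------------------------


def _covariate_sum(row: Mapping, coefficients: Mapping[str, float]) -> float:
    total = 0.0
    for name, beta in coefficients.items():
        if name == "intercept":
            total += beta
            continue
        if name not in row:
            raise KeyError(f"missing covariate {name!r} in design row")
        total += beta * float(row[name])
    return total


def part1_linear_predictor(
    row: Mapping,
    coefficients: Mapping[str, float],
    latent: LatentState | None = None,
    tract_index: int = 0,
) -> float:
    """Logit-scale linear predictor of the observation (binomial) part.

    ``logit P(x_i) = b0 + eta1_i + S(x_i) + sum_k beta_k * covariate_k``

    The inverse logit is exposed separately via :func:`inverse_logit`.
    """
    lin = _covariate_sum(row, coefficients)
    if latent is not None:
        lin += float(latent.eta1[tract_index]) + float(latent.S[tract_index])
    return lin


def part2_linear_predictor(
    row: Mapping,
    coefficients: Mapping[str, float],
    latent: LatentState | None = None,
    weight_term: float = 0.0,
    tract_index: int = 0,
    year_index: int | None = None,
    offset_column: str = "pop_over16",
) -> float:
    """Log-scale linear predictor of the count (ZIP) part.

    Structurally identical to part 1 on the log scale, plus the
    ``log(pop_over16)`` offset and the part-1 weighting term.
    """
    pop = float(row[offset_column])
    if pop <= 0:
        raise ValueError(f"population offset must be positive, got {pop}")
    lin = _covariate_sum(row, coefficients) + math.log(pop) + weight_term
    if latent is not None:
        lin += float(latent.eta2[tract_index]) + float(latent.S[tract_index])
        if year_index is not None and len(latent.gamma_t):
            lin += float(latent.gamma_t[year_index])
    return lin


def joint_loglikelihood(
    tracts: pd.DataFrame,
    spec: TwoPartModelSpec,
    coefs1: Mapping[str, float],
    coefs2: Mapping[str, float],
    latent: LatentState | None = None,
    weight_terms: Sequence[float] | None = None,
) -> float:
    """Joint log-likelihood of both parts over a tract table (reference form).

    Part 1 contributes a binomial log-likelihood (observed cases out of the
    at-risk population) and part 2 a ZIP log-likelihood of the same counts;
    the parts are coupled through shared latent effects and the weighting
    terms.  Aggregated (prevalence-style) counts are used.  An empty table
    yields 0.
    """
    if len(tracts) == 0:
        return 0.0
    y = case_totals(tracts, spec.response).to_numpy()
    pi0 = latent.pi0 if latent is not None else 0.0
    total = 0.0
    for i, (_, row) in enumerate(tracts.iterrows()):
        n_i = float(row[spec.offset_column])
        if spec.parts in ("both", "part1"):
            lin1 = part1_linear_predictor(row, coefs1, latent, i)
            p = inverse_logit(lin1)
            yi = int(y[i])
            total += (
                gammaln(n_i + 1.0)
                - gammaln(yi + 1.0)
                - gammaln(n_i - yi + 1.0)
                + yi * math.log(p)
                + (n_i - yi) * math.log1p(-p)
            )
        if spec.parts in ("both", "part2"):
            w = float(weight_terms[i]) if weight_terms is not None else 0.0
            lin2 = part2_linear_predictor(
                row, coefs2, latent, w, i, offset_column=spec.offset_column
            )
            total += float(zip_logpmf(int(y[i]), math.exp(lin2), pi0))
    return total


# ---------------------------------------------------------------------------
# Tract-level covariate construction
# ---------------------------------------------------------------------------


def build_covariates(tracts: pd.DataFrame) -> pd.DataFrame:
    """Derive the model covariates from a tract table.

    Individual covariates (sex, age) enter the tract-level equations as
    composition shares of the at-risk population; population strata enter on
    the log scale (log1p to tolerate empty strata).  Deprivation quintiles
    are dummy-coded against quintile 1.
    """
    over16 = tracts["pop_over16"].to_numpy(dtype=float)
    if np.any(over16 <= 0):
        raise ValueError("pop_over16 must be positive for all tracts")
    out = pd.DataFrame(index=tracts.index)
    men_adult = tracts["pop_men_16to64"].to_numpy(float) + tracts[
        "pop_men_65plus"
    ].to_numpy(float)
    old = tracts["pop_men_65plus"].to_numpy(float) + tracts["pop_women_65plus"].to_numpy(
        float
    )
    out["male_frac"] = men_adult / over16
    out["share_65plus"] = old / over16
    dq = tracts["deprivation_q"].to_numpy()
    for q in (2, 3, 4, 5):
        out[f"dep_q{q}"] = (dq == q).astype(float)
    for stratum in ("men_16to64", "men_65plus", "women_16to64", "women_65plus"):
        out[f"log_{stratum}"] = np.log1p(tracts[f"pop_{stratum}"].to_numpy(float))
    if "dist_centre" in tracts.columns:
        out["dist_centre"] = tracts["dist_centre"].to_numpy(float)
    return out


def case_totals(tracts: pd.DataFrame, category: str) -> pd.Series:
    """Total case count per tract for one category, summed over years."""
    cols = [c for c in tracts.columns if c.startswith(f"cases_{category}_")]
    if not cols:
        raise ValueError(f"no case-count columns found for category {category!r}")
    return tracts[cols].sum(axis=1).astype(int)
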