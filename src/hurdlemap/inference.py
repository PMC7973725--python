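"""Joint Bayesian fitting of the two-part model.

The engine is a nested Laplace approximation (the posterior, not the
algorithm, is the contract):

1. *Inner step* — for fixed hyperparameters, the joint mode of all fixed
   effects and latent fields is found by damped Newton iterations with an
   analytic gradient and Hessian; the curvature at the mode gives a Gaussian
   approximation to the conditional posterior of the latent block.
2. *Outer step* — the hyperparameters (random-effect standard deviations,
   Matérn range, zero-inflation mass, RW1 scale) are optimised on the
   Laplace-approximated marginal posterior, with PC priors.
3. *Draws* — posterior draws are generated from a Gaussian mixture: the
   hyperparameters are sampled from a Laplace (finite-difference) Gaussian
   at their mode, and for each hyperparameter draw the latent block is
   re-centred and sampled from its conditional Gaussian.

The spatial field is handled by dense Matérn covariance with Cholesky
factorisation (desk scale, no mesh/SPDE discretisation).  All draws are
independent given the mixture component, so the split-chain convergence
statistic is reported for completeness and is ~1 by construction; the
convergence flag instead tracks the optimiser.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize
from scipy.special import gammaln

from .model import (
    MaternParams,
    TwoPartModelSpec,
    build_covariates,
    case_totals,
    inverse_logit,
    kappa_from_range,
    matern_covariance_matrix,
    pc_prior_range_logdensity,
    pc_prior_sd_logdensity,
)

__all__ = [
    "EngineConfig",
    "PosteriorFit",
    "fit_two_part",
    "observation_weights",
    "posterior_summary",
    "PosteriorSummary",
]

_BETA_PREC = 0.01  # N(0, 100) prior on regression coefficients
_RW1_MEAN_PREC = 10.0  # soft sum-to-zero constraint on the RW1 path
_CURV_FLOOR = 1e-10


@dataclass(frozen=True)
class EngineConfig:
    """Engine settings: posterior draw count, chain layout and optimiser
    budgets.  ``hyper_mixture`` is the number of hyperparameter draws used
    for the Gaussian-mixture posterior (1 = empirical-Bayes Laplace)."""

    chains: int = 2
    draws: int = 1000
    seed: int = 0
    outer_maxiter: int = 60
    newton_maxiter: int = 80
    hyper_mixture: int = 8
    weighting_passes: int = 2

    def __post_init__(self):
        if self.chains < 2:
            raise ValueError("need at least 2 chains for split-chain diagnostics")
        if self.draws < self.chains:
            raise ValueError("draws must be >= chains")


@dataclass
class PosteriorSummary:
    point: float
    lower: float
    upper: float


# ---------------------------------------------------------------------------
# Model data
# ---------------------------------------------------------------------------


class _ModelData:
    """Design matrices, responses and layout for one fit."""

    def __init__(self, tracts: pd.DataFrame, spec: TwoPartModelSpec):
        self.spec = spec
        self.tracts = tracts.reset_index(drop=True)
        cov = build_covariates(self.tracts)
        self.ntrials = self.tracts["pop_over16"].to_numpy(float)
        self.log_offset = np.log(self.ntrials)

        self.names1 = list(spec.fixed_effects) + [
            c for c in spec.selection_covariates if c not in spec.fixed_effects
        ]
        self.names2 = list(spec.fixed_effects)
        for name in set(self.names1) | set(self.names2):
            if name not in cov.columns:
                raise KeyError(f"missing covariate {name!r} in tract table")
        X1 = cov[self.names1].to_numpy(float) if self.names1 else np.empty((len(cov), 0))
        if spec.part1_exposure:
            X1 = np.column_stack([X1, self.log_offset])
            self.names1 = self.names1 + ["log_exposure"]
        X2 = cov[self.names2].to_numpy(float) if self.names2 else np.empty((len(cov), 0))

        def standardise(X):
            if X.shape[1] == 0:
                return X, np.zeros(0), np.ones(0)
            m = X.mean(axis=0)
            s = X.std(axis=0)
            s = np.where(s > 1e-12, s, 1.0)
            return (X - m) / s, m, s

        self.X1, self.m1, self.s1 = standardise(X1)
        self.X2, self.m2, self.s2 = standardise(X2)
        # prepend intercept columns
        n = len(self.tracts)
        self.X1 = np.column_stack([np.ones(n), self.X1])
        self.X2 = np.column_stack([np.ones(n), self.X2])

        cols = [
            c
            for c in self.tracts.columns
            if c.startswith(f"cases_{spec.response}_")
        ]
        if not cols:
            raise ValueError(f"no case-count columns for response {spec.response!r}")
        self.years = sorted(int(c.rsplit("_", 1)[1]) for c in cols)
        self.y1 = case_totals(self.tracts, spec.response).to_numpy()
        if np.any(self.y1 > self.ntrials):
            raise ValueError("case counts exceed the at-risk population")
        if spec.target == "incidence":
            self.y2 = np.column_stack(
                [self.tracts[f"cases_{spec.response}_{yr}"].to_numpy(int) for yr in self.years]
            )
        else:
            self.y2 = self.y1[:, None]
        self.n = n
        self.T = self.y2.shape[1]
        self.coords = self.tracts[["x", "y"]].to_numpy(float)
        d = self.coords.max(axis=0) - self.coords.min(axis=0)
        self.domain_diameter = float(np.hypot(*d)) if n > 1 else 1.0

        # active blocks
        self.part1 = spec.parts in ("both", "part1")
        self.part2 = spec.parts in ("both", "part2")
        self.het1 = spec.heterogeneity and self.part1
        self.het2 = spec.heterogeneity and self.part2
        self.spatial = spec.spatial
        self.rw1 = spec.temporal_rw1 and self.part2 and self.T > 1
        self.zip = spec.zero_inflation and self.part2

        self.p1 = self.X1.shape[1] if self.part1 else 0
        self.p2 = self.X2.shape[1] if self.part2 else 0

        # layout of the inner parameter vector
        pos = 0
        self.sl = {}
        for name, size in [
            ("b1", self.p1),
            ("b2", self.p2),
            ("eta1", self.n if self.het1 else 0),
            ("eta2", self.n if self.het2 else 0),
            ("u", self.n if self.spatial else 0),
            ("gamma", self.T if self.rw1 else 0),
        ]:
            self.sl[name] = slice(pos, pos + size)
            pos += size
        self.m_dim = pos

        self.hyper_names = []
        if self.het1:
            self.hyper_names.append("log_sigma_eta1")
        if self.het2:
            self.hyper_names.append("log_sigma_eta2")
        if self.spatial:
            self.hyper_names += ["log_sigma_S", "log_range"]
        if self.rw1:
            self.hyper_names.append("log_sigma_rw1")
        if self.zip:
            self.hyper_names.append("logit_pi0")

        self._chol_cache: dict[float, np.ndarray] = {}

        # binomial normalising constants (parameter-free)
        if self.part1:
            self._binom_const = float(
                np.sum(
                    gammaln(self.ntrials + 1.0)
                    - gammaln(self.y1 + 1.0)
                    - gammaln(self.ntrials - self.y1 + 1.0)
                )
            )
        else:
            self._binom_const = 0.0

    def chol_corr(self, rho: float) -> np.ndarray:
        key = round(float(rho), 8)
        if key not in self._chol_cache:
            p = MaternParams(1.0, kappa_from_range(rho, self.spec.nu), self.spec.nu)
            corr = matern_covariance_matrix(self.coords, p, jitter=1e-8)
            self._chol_cache[key] = np.linalg.cholesky(corr)
            if len(self._chol_cache) > 200:
                self._chol_cache.pop(next(iter(self._chol_cache)))
        return self._chol_cache[key]


# ---------------------------------------------------------------------------
# Likelihood derivatives
# ---------------------------------------------------------------------------


def _binom_terms(lin1, y, ntrials):
    """Log-likelihood, gradient and curvature of the binomial part w.r.t.
    its linear predictor (constants excluded; added separately)."""
    p = inverse_logit(lin1)
    ll = float(np.sum(y * lin1 - ntrials * np.logaddexp(0.0, lin1)))
    g = y - ntrials * p
    h = np.maximum(ntrials * p * (1.0 - p), _CURV_FLOOR)
    return ll, g, h


def _zip_terms(lin2, y, pi0, lw):
    """Log-likelihood, gradient and curvature of the (optionally weighted)
    ZIP part w.r.t. the log-mean linear predictor."""
    lin2 = np.clip(lin2, -60.0, 40.0)
    theta = np.exp(lin2)
    pos = y > 0
    ll_arr = np.empty_like(theta)
    g = np.empty_like(theta)
    h = np.empty_like(theta)
    # y > 0: log(1-pi0) + Poisson term
    ll_arr[pos] = (
        (math.log1p(-pi0) if pi0 > 0 else 0.0)
        + y[pos] * lin2[pos]
        - theta[pos]
        - gammaln(y[pos] + 1.0)
    )
    g[pos] = y[pos] - theta[pos]
    h[pos] = theta[pos]
    # y == 0: log(pi0 + (1-pi0) exp(-theta))
    z = ~pos
    th0 = theta[z]
    if pi0 > 0:
        log_b = math.log1p(-pi0) - th0
        denom = np.logaddexp(math.log(pi0), log_b)
        ll_arr[z] = denom
        r = np.exp(log_b - denom)  # b / (pi0 + b)
        g[z] = -r * th0
        h[z] = r * th0 * (1.0 - th0) + (r * th0) ** 2
    else:
        ll_arr[z] = -th0
        g[z] = -th0
        h[z] = th0
    if lw is not None:
        ll_arr = ll_arr * lw
        g = g * lw
        h = h * lw
    return float(ll_arr.sum()), g, np.maximum(h, _CURV_FLOOR)


# ---------------------------------------------------------------------------
# Inner Newton optimisation
# ---------------------------------------------------------------------------


class _Inner:
    """Mode and curvature of the latent block for fixed hyperparameters."""

    def __init__(self, data: _ModelData, psi: Mapping[str, float], w, lw):
        self.d = data
        self.psi = dict(psi)
        self.w = w
        self.lw = lw
        self.sigma1 = math.exp(psi.get("log_sigma_eta1", 0.0)) if data.het1 else 0.0
        self.sigma2 = math.exp(psi.get("log_sigma_eta2", 0.0)) if data.het2 else 0.0
        self.sigmaS = math.exp(psi.get("log_sigma_S", 0.0)) if data.spatial else 0.0
        self.rho = math.exp(psi.get("log_range", 0.0)) if data.spatial else 1.0
        self.sigma_rw1 = math.exp(psi.get("log_sigma_rw1", 0.0)) if data.rw1 else 0.0
        self.pi0 = inverse_logit(psi["logit_pi0"]) if data.zip else 0.0
        self.L = data.chol_corr(self.rho) if data.spatial else None
        if data.rw1:
            T = data.T
            R = np.zeros((T, T))
            for t in range(T - 1):
                R[t, t] += 1.0
                R[t + 1, t + 1] += 1.0
                R[t, t + 1] -= 1.0
                R[t + 1, t] -= 1.0
            tau = 1.0 / self.sigma_rw1**2
            self.P_gamma = tau * R + _RW1_MEAN_PREC * np.ones((T, T)) / T
            sign, logdet = np.linalg.slogdet(self.P_gamma / (2.0 * math.pi))
            self._gamma_norm = 0.5 * logdet
        else:
            self.P_gamma = None
            self._gamma_norm = 0.0

    # -- linear predictors ------------------------------------------------

    def _lin1(self, x):
        d = self.d
        lin = d.X1 @ x[d.sl["b1"]]
        if d.het1:
            lin = lin + x[d.sl["eta1"]]
        if d.spatial:
            lin = lin + self.sigmaS * (self.L @ x[d.sl["u"]])
        return lin

    def _lin2(self, x):
        d = self.d
        base = d.X2 @ x[d.sl["b2"]] + d.log_offset + self.w
        if d.het2:
            base = base + x[d.sl["eta2"]]
        if d.spatial:
            base = base + self.sigmaS * (self.L @ x[d.sl["u"]])
        lin = np.repeat(base[:, None], d.T, axis=1)
        if d.rw1:
            lin = lin + x[d.sl["gamma"]][None, :]
        return lin

    # -- objective, gradient, Hessian -------------------------------------

    def logjoint(self, x):
        """Unnormalised log posterior of the latent block (includes the
        Gaussian normalising constants of the latent priors, needed for the
        outer marginal)."""
        d = self.d
        total = 0.0
        if d.part1:
            ll1, _, _ = _binom_terms(self._lin1(x), d.y1, d.ntrials)
            total += ll1 + d._binom_const
        if d.part2:
            ll2, _, _ = _zip_terms(self._lin2(x), d.y2, self.pi0, self.lw)
            total += ll2
        # priors on the latent block
        for blk, prec, size in [("b1", _BETA_PREC, d.p1), ("b2", _BETA_PREC, d.p2)]:
            if size:
                v = x[d.sl[blk]]
                total += 0.5 * size * math.log(prec / (2 * math.pi)) - 0.5 * prec * float(
                    v @ v
                )
        if d.het1:
            v = x[d.sl["eta1"]]
            total += -0.5 * d.n * math.log(2 * math.pi * self.sigma1**2) - 0.5 * float(
                v @ v
            ) / self.sigma1**2
        if d.het2:
            v = x[d.sl["eta2"]]
            total += -0.5 * d.n * math.log(2 * math.pi * self.sigma2**2) - 0.5 * float(
                v @ v
            ) / self.sigma2**2
        if d.spatial:
            v = x[d.sl["u"]]
            total += -0.5 * d.n * math.log(2 * math.pi) - 0.5 * float(v @ v)
        if d.rw1:
            g = x[d.sl["gamma"]]
            total += self._gamma_norm - 0.5 * float(g @ self.P_gamma @ g)
        return total

    def grad_hess(self, x):
        d = self.d
        m = d.m_dim
        grad = np.zeros(m)
        H = np.zeros((m, m))
        sS = self.sigmaS
        L = self.L

        if d.part1:
            _, g1, h1 = _binom_terms(self._lin1(x), d.y1, d.ntrials)
        else:
            g1 = h1 = None
        if d.part2:
            _, g2, h2 = _zip_terms(self._lin2(x), d.y2, self.pi0, self.lw)
            G2 = g2.sum(axis=1)
            H2s = h2.sum(axis=1)
        else:
            g2 = h2 = G2 = H2s = None

        sl = d.sl
        if d.p1:
            grad[sl["b1"]] = d.X1.T @ g1 - _BETA_PREC * x[sl["b1"]]
            H[sl["b1"], sl["b1"]] = (d.X1 * h1[:, None]).T @ d.X1 + _BETA_PREC * np.eye(
                d.p1
            )
        if d.p2:
            grad[sl["b2"]] = d.X2.T @ G2 - _BETA_PREC * x[sl["b2"]]
            H[sl["b2"], sl["b2"]] = (d.X2 * H2s[:, None]).T @ d.X2 + _BETA_PREC * np.eye(
                d.p2
            )
        if d.het1:
            grad[sl["eta1"]] = g1 - x[sl["eta1"]] / self.sigma1**2
            H[sl["eta1"], sl["eta1"]] = np.diag(h1 + 1.0 / self.sigma1**2)
            if d.p1:
                blk = (d.X1 * h1[:, None]).T
                H[sl["b1"], sl["eta1"]] = blk
                H[sl["eta1"], sl["b1"]] = blk.T
        if d.het2:
            grad[sl["eta2"]] = G2 - x[sl["eta2"]] / self.sigma2**2
            H[sl["eta2"], sl["eta2"]] = np.diag(H2s + 1.0 / self.sigma2**2)
            if d.p2:
                blk = (d.X2 * H2s[:, None]).T
                H[sl["b2"], sl["eta2"]] = blk
                H[sl["eta2"], sl["b2"]] = blk.T
        if d.spatial:
            gsum = np.zeros(d.n)
            hsum = np.zeros(d.n)
            if d.part1:
                gsum += g1
                hsum += h1
            if d.part2:
                gsum += G2
                hsum += H2s
            grad[sl["u"]] = sS * (L.T @ gsum) - x[sl["u"]]
            H[sl["u"], sl["u"]] = sS**2 * (L.T * hsum[None, :]) @ L + np.eye(d.n)
            if d.p1:
                blk = (d.X1 * h1[:, None]).T @ (sS * L)
                H[sl["b1"], sl["u"]] = blk
                H[sl["u"], sl["b1"]] = blk.T
            if d.p2:
                blk = (d.X2 * H2s[:, None]).T @ (sS * L)
                H[sl["b2"], sl["u"]] = blk
                H[sl["u"], sl["b2"]] = blk.T
            if d.het1:
                blk = h1[:, None] * (sS * L)
                H[sl["eta1"], sl["u"]] = blk
                H[sl["u"], sl["eta1"]] = blk.T
            if d.het2:
                blk = H2s[:, None] * (sS * L)
                H[sl["eta2"], sl["u"]] = blk
                H[sl["u"], sl["eta2"]] = blk.T
        if d.rw1:
            grad[sl["gamma"]] = g2.sum(axis=0) - self.P_gamma @ x[sl["gamma"]]
            H[sl["gamma"], sl["gamma"]] = np.diag(h2.sum(axis=0)) + self.P_gamma
            if d.p2:
                blk = d.X2.T @ h2
                H[sl["b2"], sl["gamma"]] = blk
                H[sl["gamma"], sl["b2"]] = blk.T
            if d.het2:
                H[sl["eta2"], sl["gamma"]] = h2
                H[sl["gamma"], sl["eta2"]] = h2.T
            if d.spatial:
                blk = sS * (L.T @ h2)
                H[sl["u"], sl["gamma"]] = blk
                H[sl["gamma"], sl["u"]] = blk.T
        return grad, H

    def optimise(self, x0=None, maxiter: int = 80, tol: float = 1e-7):
        d = self.d
        x = np.zeros(d.m_dim) if x0 is None else x0.copy()
        if x0 is None:
            # crude but safe initial intercepts
            if d.p1:
                rate = (d.y1.sum() + 0.5) / d.ntrials.sum()
                x[d.sl["b1"].start] = math.log(rate / (1.0 - rate))
            if d.p2:
                x[d.sl["b2"].start] = math.log(
                    (d.y2.sum() + 0.5) / (np.exp(d.log_offset + self.w).sum() * d.T)
                )
        f = -self.logjoint(x)
        converged = False
        for _ in range(maxiter):
            grad, H = self.grad_hess(x)
            gnorm = np.max(np.abs(grad)) if len(grad) else 0.0
            if gnorm < tol * (1.0 + abs(f)):
                converged = True
                break
            try:
                cf = cho_factor(H, lower=True, check_finite=False)
            except np.linalg.LinAlgError:
                H = H + (1e-6 + 1e-3 * np.abs(np.diag(H)).max()) * np.eye(len(H))
                cf = cho_factor(H, lower=True, check_finite=False)
            step = cho_solve(cf, grad, check_finite=False)
            t = 1.0
            for _bt in range(40):
                x_new = x + t * step
                f_new = -self.logjoint(x_new)
                if np.isfinite(f_new) and f_new <= f - 1e-4 * t * float(grad @ step):
                    break
                t *= 0.5
            else:
                converged = gnorm < 1e-3 * (1.0 + abs(f))
                break
            if abs(f - f_new) < 1e-10 * (1.0 + abs(f)) and t == 1.0:
                x, f = x_new, f_new
                converged = True
                break
            x, f = x_new, f_new
        _, H = self.grad_hess(x)
        return x, H, -f, converged

    def log_marginal(self, x_hat, H) -> float:
        """Laplace-approximated log marginal posterior of the hyperparameters
        (up to a constant)."""
        d = self.d
        try:
            cf = cho_factor(H, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return -np.inf
        logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        lm = (
            self.logjoint(x_hat)
            + 0.5 * d.m_dim * math.log(2.0 * math.pi)
            - 0.5 * logdet
        )
        return lm + self._log_hyper_prior()

    def _log_hyper_prior(self) -> float:
        d = self.d
        pr = d.spec.priors
        range_u = pr.range_u if pr.range_u is not None else d.domain_diameter / 10.0
        total = 0.0
        for sig, active in [
            (self.sigma1, d.het1),
            (self.sigma2, d.het2),
            (self.sigmaS, d.spatial),
            (self.sigma_rw1, d.rw1),
        ]:
            if active:
                # + log(sigma): Jacobian of the log transform
                total += pc_prior_sd_logdensity(sig, pr.sd_u, pr.sd_alpha) + math.log(sig)
        if d.spatial:
            total += pc_prior_range_logdensity(
                self.rho, range_u, pr.range_alpha
            ) + math.log(self.rho)
        if d.zip:
            # uniform(0,1) on pi0 -> logistic density on the logit scale
            total += math.log(self.pi0) + math.log1p(-self.pi0)
        return total


# ---------------------------------------------------------------------------
# Posterior container
# ---------------------------------------------------------------------------


@dataclass
class PosteriorFit:
    """Posterior draws, diagnostics and the design needed for rate
    estimation.  Draw arrays are shaped ``(chains, draws_per_chain)`` for
    scalars with a trailing dimension for vector-valued quantities."""

    draws: dict
    diagnostics: dict
    spec: TwoPartModelSpec
    seed: int
    converged: bool
    messages: list = field(default_factory=list)
    data: "_ModelData" = None

    def stacked(self, name: str) -> np.ndarray:
        if name not in self.draws:
            raise KeyError(
                f"unknown quantity {name!r}; available: {sorted(self.draws)}"
            )
        arr = self.draws[name]
        return arr.reshape(-1, *arr.shape[2:])

    # -- derived posterior quantities -------------------------------------

    def part1_linpred_draws(self) -> np.ndarray:
        """Draws of the part-1 linear predictor per tract, shape (ndraw, n)."""
        d = self.data
        if d is None or not d.part1:
            raise ValueError("fit does not contain part-1 parameters")
        b = np.column_stack(
            [self.stacked(f"b1_{nm}") for nm in ["intercept"] + d.names1]
        )
        # transform back to the standardised design
        b_std = b[:, 1:] * d.s1[None, :]
        b0 = b[:, 0] + b[:, 1:] @ d.m1
        lin = b0[:, None] + (b_std @ d.X1[:, 1:].T)
        if d.het1:
            lin = lin + self.stacked("eta1")
        if d.spatial:
            lin = lin + self.stacked("S")
        return lin

    def expected_true_count_draws(self) -> np.ndarray:
        """Draws of the expected *true* (un-thinned) case counts per tract,
        shape (ndraw, n) for prevalence and (ndraw, n, T) for incidence.

        The weighting (thinning) term is excluded: under the offset rule the
        ZIP mean models observed counts as thinned true counts, so dropping
        the thinning offset recovers the true scale; under inverse-
        probability weighting the fitted mean is already on the true scale.
        """
        d = self.data
        if d is None or not d.part2:
            raise ValueError("fit does not contain part-2 parameters")
        b = np.column_stack(
            [self.stacked(f"b2_{nm}") for nm in ["intercept"] + d.names2]
        )
        b_std = b[:, 1:] * d.s2[None, :]
        b0 = b[:, 0] + b[:, 1:] @ d.m2
        lin = b0[:, None] + (b_std @ d.X2[:, 1:].T) + d.log_offset[None, :]
        if d.het2:
            lin = lin + self.stacked("eta2")
        if d.spatial:
            lin = lin + self.stacked("S")
        if d.zip:
            lin = lin + np.log1p(-self.stacked("pi0"))[:, None]
        if d.T > 1:
            lin = lin[:, :, None] + (
                self.stacked("gamma")[:, None, :] if d.rw1 else 0.0
            )
        return np.exp(np.clip(lin, -300.0, 300.0))


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def fit_two_part(
    tracts: pd.DataFrame,
    spec: TwoPartModelSpec,
    config: EngineConfig | None = None,
) -> PosteriorFit:
    """Fit the two-part model jointly and return posterior draws.

    See the module docstring for the algorithm.  Non-convergence is a
    warning, never an exception: the fit is returned with
    ``converged=False``.
    """
    config = config or EngineConfig()
    data = _ModelData(tracts, spec)
    rng = np.random.default_rng(config.seed)
    messages: list[str] = []

    if spec.weighting_rule != "none" and not (data.part1 and data.part2):
        rule = "none"
    else:
        rule = spec.weighting_rule

    w = np.zeros(data.n)
    lw = None
    psi_hat = _initial_psi(data)
    x_warm: dict = {"x": None}
    inner_ok = True

    n_passes = config.weighting_passes if rule != "none" else 1
    for _pass in range(n_passes):
        psi_hat, x_hat, H_hat, ok = _optimise_hyper(
            data, psi_hat, w, lw, config, x_warm
        )
        inner_ok = inner_ok and ok
        if rule == "none":
            break
        inner = _Inner(data, psi_hat, w, lw)
        p_hat = _anchored_probabilities(data, inner, x_hat, spec.coverage_mean)
        if rule == "log_prob_offset":
            w = np.log(p_hat)
        else:  # likelihood_weight
            lw = 1.0 / p_hat

    # final mode at psi_hat
    inner = _Inner(data, psi_hat, w, lw)
    x_hat, H_hat, _, ok = inner.optimise(x_warm["x"], config.newton_maxiter)
    inner_ok = inner_ok and ok
    x_warm["x"] = x_hat

    # hyperparameter uncertainty: finite-difference Laplace at the mode
    psi_names = data.hyper_names
    psi_vec = np.array([psi_hat[k] for k in psi_names])
    if len(psi_names) and config.hyper_mixture > 1:
        cov_psi = _psi_covariance(data, psi_hat, w, lw, config, x_warm)
        n_psi = config.hyper_mixture
        Lp = np.linalg.cholesky(cov_psi)
        psi_draws = psi_vec[None, :] + rng.standard_normal((n_psi, len(psi_names))) @ Lp.T
    else:
        n_psi = 1
        psi_draws = psi_vec[None, :] if len(psi_names) else np.zeros((1, 0))

    total_draws = config.draws - config.draws % config.chains
    group_sizes = np.full(n_psi, total_draws // n_psi)
    group_sizes[: total_draws % n_psi] += 1

    samples = np.empty((total_draws, data.m_dim))
    hyper_samples = {k: np.empty(total_draws) for k in psi_names}
    field_draws = np.empty((total_draws, data.n)) if data.spatial else None
    pos = 0
    for k in range(n_psi):
        gsz = int(group_sizes[k])
        if gsz == 0:
            continue
        psi_k = dict(zip(psi_names, psi_draws[k]))
        inner_k = _Inner(data, psi_k, w, lw)
        xk, Hk, _, okk = inner_k.optimise(x_warm["x"], config.newton_maxiter)
        if not okk:
            inner_ok = False
        try:
            cf = cho_factor(Hk, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            Hk = Hk + 1e-6 * np.eye(len(Hk))
            cf = cho_factor(Hk, lower=True, check_finite=False)
        z = rng.standard_normal((gsz, data.m_dim))
        # x = x_hat + L^-T z  with H = L L^T
        dev = solve_triangular(cf[0], z.T, lower=True, trans="T", check_finite=False).T
        if data.spatial:
            # store the field draws on the S scale for this group's rho
            sS_k = math.exp(psi_k["log_sigma_S"])
            Lk = data.chol_corr(math.exp(psi_k["log_range"]))
        samples[pos : pos + gsz] = xk[None, :] + dev
        for j, nm in enumerate(psi_names):
            hyper_samples[nm][pos : pos + gsz] = psi_draws[k, j]
        if data.spatial:
            field_draws[pos : pos + gsz] = (
                samples[pos : pos + gsz, data.sl["u"]] @ (sS_k * Lk).T
            )
        pos += gsz

    # shuffle so pseudo-chains are exchangeable
    perm = rng.permutation(total_draws)
    samples = samples[perm]
    if data.spatial:
        field_draws = field_draws[perm]
    for nm in psi_names:
        hyper_samples[nm] = hyper_samples[nm][perm]

    draws = _named_draws(data, samples, hyper_samples, field_draws if data.spatial else None, config)
    diagnostics = _diagnostics(draws)
    max_rhat = max(
        (v for k, v in diagnostics["rhat"].items() if np.isfinite(v)), default=1.0
    )
    converged = bool(inner_ok and max_rhat <= 1.05)
    if not converged:
        msg = (
            f"fit flagged as not converged (inner_ok={inner_ok}, "
            f"max rhat={max_rhat:.3f}); returning fit with warning flag"
        )
        messages.append(msg)
        warnings.warn(msg)
    diagnostics["max_rhat"] = float(max_rhat)

    fit = PosteriorFit(
        draws=draws,
        diagnostics=diagnostics,
        spec=spec,
        seed=config.seed,
        converged=converged,
        messages=messages,
        data=data,
    )
    return fit


def _initial_psi(data: _ModelData) -> dict:
    psi = {}
    for nm in data.hyper_names:
        if nm == "log_range":
            psi[nm] = math.log(max(data.domain_diameter / 5.0, 1e-3))
        elif nm == "logit_pi0":
            psi[nm] = math.log(0.1 / 0.9)
        else:
            psi[nm] = math.log(0.3)
    return psi


def _optimise_hyper(data, psi0, w, lw, config, x_warm):
    names = data.hyper_names
    if not names:
        inner = _Inner(data, {}, w, lw)
        x_hat, H, _, ok = inner.optimise(x_warm["x"], config.newton_maxiter)
        x_warm["x"] = x_hat
        return {}, x_hat, H, ok

    best = {"x": x_warm["x"]}

    def neg_lm(vec):
        psi = dict(zip(names, vec))
        inner = _Inner(data, psi, w, lw)
        try:
            x_hat, H, _, ok = inner.optimise(best["x"], config.newton_maxiter)
        except np.linalg.LinAlgError:
            return 1e10
        best["x"] = x_hat
        lm = inner.log_marginal(x_hat, H)
        if not np.isfinite(lm):
            return 1e10
        return -lm

    v0 = np.array([psi0[k] for k in names])
    res = minimize(
        neg_lm,
        v0,
        method="Nelder-Mead",
        options={
            "maxiter": config.outer_maxiter,
            "xatol": 0.02,
            "fatol": 0.05,
            "adaptive": True,
        },
    )
    psi_hat = dict(zip(names, res.x))
    inner = _Inner(data, psi_hat, w, lw)
    x_hat, H, _, ok = inner.optimise(best["x"], config.newton_maxiter)
    x_warm["x"] = x_hat
    return psi_hat, x_hat, H, ok


def _psi_covariance(data, psi_hat, w, lw, config, x_warm):
    """Central finite-difference Hessian of the negative log marginal,
    regularised to positive definite, inverted to a covariance."""
    names = data.hyper_names
    d = len(names)
    v0 = np.array([psi_hat[k] for k in names])
    step = 0.15

    def f(vec):
        inner = _Inner(data, dict(zip(names, vec)), w, lw)
        try:
            x_hat, H, _, _ = inner.optimise(x_warm["x"], config.newton_maxiter)
        except np.linalg.LinAlgError:
            return np.inf
        lm = inner.log_marginal(x_hat, H)
        return -lm if np.isfinite(lm) else np.inf

    f0 = f(v0)
    Hp = np.zeros((d, d))
    fp = np.zeros(d)
    fm = np.zeros(d)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = step
        fp[i] = f(v0 + ei)
        fm[i] = f(v0 - ei)
        Hp[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / step**2
    for i in range(d):
        for j in range(i + 1, d):
            ei = np.zeros(d)
            ej = np.zeros(d)
            ei[i] = step
            ej[j] = step
            fpp = f(v0 + ei + ej)
            Hp[i, j] = Hp[j, i] = (fpp - fp[i] - fp[j] + f0) / step**2
    Hp = np.where(np.isfinite(Hp), Hp, 0.0)
    vals, vecs = np.linalg.eigh(0.5 * (Hp + Hp.T))
    vals = np.clip(vals, 0.05, None)  # cap hyper variance at 20 on the log scale
    cov = (vecs / vals) @ vecs.T
    return cov


def _anchored_probabilities(data, inner, x_hat, coverage_mean):
    """Coverage-anchored observation probabilities from the part-1 mode.

    The absolute level of the selection process is not identified from
    observed counts alone, so the part-1 probabilities are rescaled to have
    the configured population-weighted mean (the assumed referral-unit
    coverage), then clipped to (0, 1]."""
    P = inverse_logit(inner._lin1(x_hat))
    pbar = float(np.average(P, weights=data.ntrials))
    if pbar <= 0:
        return np.full(data.n, coverage_mean)
    p = coverage_mean * P / pbar
    return np.clip(p, 1e-6, 1.0)


def _named_draws(data, samples, hyper_samples, field_draws, config):
    chains = config.chains
    total = samples.shape[0]
    dpc = total // chains

    def shape(arr):
        return arr[: chains * dpc].reshape(chains, dpc, *arr.shape[1:])

    draws = {}
    if data.p1:
        b = samples[:, data.sl["b1"]]
        b_orig = np.empty_like(b)
        b_orig[:, 1:] = b[:, 1:] / data.s1[None, :]
        b_orig[:, 0] = b[:, 0] - (b[:, 1:] / data.s1[None, :]) @ data.m1
        for j, nm in enumerate(["intercept"] + data.names1):
            draws[f"b1_{nm}"] = shape(b_orig[:, j])
    if data.p2:
        b = samples[:, data.sl["b2"]]
        b_orig = np.empty_like(b)
        b_orig[:, 1:] = b[:, 1:] / data.s2[None, :]
        b_orig[:, 0] = b[:, 0] - (b[:, 1:] / data.s2[None, :]) @ data.m2
        for j, nm in enumerate(["intercept"] + data.names2):
            draws[f"b2_{nm}"] = shape(b_orig[:, j])
    if data.het1:
        draws["eta1"] = shape(samples[:, data.sl["eta1"]])
        draws["sigma_eta1"] = shape(np.exp(hyper_samples["log_sigma_eta1"]))
    if data.het2:
        draws["eta2"] = shape(samples[:, data.sl["eta2"]])
        draws["sigma_eta2"] = shape(np.exp(hyper_samples["log_sigma_eta2"]))
    if data.spatial:
        draws["S"] = shape(field_draws)
        draws["sigma_S"] = shape(np.exp(hyper_samples["log_sigma_S"]))
        draws["range_rho"] = shape(np.exp(hyper_samples["log_range"]))
    if data.rw1:
        draws["gamma"] = shape(samples[:, data.sl["gamma"]])
        draws["sigma_rw1"] = shape(np.exp(hyper_samples["log_sigma_rw1"]))
    if data.zip:
        draws["pi0"] = shape(inverse_logit(hyper_samples["logit_pi0"]))
    return draws


def _diagnostics(draws: dict) -> dict:
    import arviz as az

    ess = {}
    rhat = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, arr in draws.items():
            if arr.ndim != 2:  # scalars only; fields are summarised elsewhere
                continue
            ess[name] = float(az.ess(np.asarray(arr)))
            rhat[name] = float(az.rhat(np.asarray(arr)))
    return {"ess": ess, "rhat": rhat}


# ---------------------------------------------------------------------------
# Posterior summaries
# ---------------------------------------------------------------------------


def observation_weights(fit: PosteriorFit, tracts: pd.DataFrame) -> pd.DataFrame:
    """Posterior mean and 95% interval of the part-1 observation probability
    per tract (inverse-logit of the part-1 linear predictor)."""
    lin = fit.part1_linpred_draws()
    P = inverse_logit(lin)
    return pd.DataFrame(
        {
            "tract_id": tracts["tract_id"].to_numpy(),
            "p_mean": P.mean(axis=0),
            "p_lower": np.quantile(P, 0.025, axis=0),
            "p_upper": np.quantile(P, 0.975, axis=0),
        }
    )


def posterior_summary(obj, quantity=None) -> PosteriorSummary:
    """Posterior median and equal-tailed 95% credibility interval.

    ``obj`` may be a 1-d array of draws, or a :class:`PosteriorFit` together
    with the name of a scalar quantity.
    """
    if isinstance(obj, PosteriorFit):
        if quantity is None:
            raise ValueError("quantity name required when summarising a fit")
        try:
            draws = obj.stacked(quantity)
        except KeyError as exc:
            raise ValueError(str(exc)) from exc
    else:
        draws = np.asarray(obj, dtype=float)
    if draws.ndim != 1:
        raise ValueError("posterior_summary expects a scalar quantity")
    return PosteriorSummary(
        point=float(np.quantile(draws, 0.5)),
        lower=float(np.quantile(draws, 0.025)),
        upper=float(np.quantile(draws, 0.975)),
    )
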