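"""Seeded synthetic census-tract landscapes, disease processes and
selection-biased observed cohorts.

The generator inverts the inference model: tract-level true case counts are
Poisson with a log-rate made of covariate effects, a Matérn-correlated
spatial field, an RW1 yearly effect and the log population-at-risk offset;
patients are then observed with a probability driven by distance to the
region's referral centre and, in the endogenous regime, by the tract's
latent spatial frailty.

Every operation takes an integer seed and is bit-reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .deprivation import quintile_categorise
from .model import MaternParams, build_covariates, inverse_logit

__all__ = [
    "SelectionParams",
    "TruthParams",
    "IndicatorSet",
    "SimulationResult",
    "generate_landscape",
    "sample_matern_field",
    "generate_indicators",
    "simulate_disease",
    "apply_selection",
    "tracts_with_observed_counts",
    "default_truth",
    "validate_tracts",
    "write_tracts_csv",
    "read_tracts_csv",
    "write_patients_csv",
    "read_patients_csv",
    "export_geojson",
]

REGIONS = ("A", "B")
CATEGORIES = ("ALS", "PMA", "PLS")

# Category mix among definite diagnoses and patient marginals (ALS-dominant
# mix, slight male excess, diagnosis age centred in the 60s).
CATEGORY_PROBS = {"ALS": 0.90, "PMA": 0.07, "PLS": 0.03}
MALE_FRACTION = 0.55
AGE_MEAN, AGE_SD = 63.0, 12.0
AGE_MIN, AGE_MAX = 21.0, 95.0

# Sex-by-age population strata proportions (Spanish-census-like structure:
# ~16% under 16, ~17% aged 65+, near-even sex split).
STRATA_PROPS = {
    "men_under16": 0.0835,
    "men_16to64": 0.3390,
    "men_65plus": 0.0740,
    "women_under16": 0.0785,
    "women_16to64": 0.3300,
    "women_65plus": 0.0950,
}

#: Log-normal tract population: median 1,400 (Spanish census-tract norm).
POP_MEDIAN = 1400.0
POP_LOG_SD = 0.45

REGION_SIDE_KM = 40.0  # side of each region's square patch
REGION_OFFSET_KM = 200.0  # x-offset keeping the two patches disjoint


@dataclass(frozen=True)
class SelectionParams:
    """Observation (selection) process on the logit scale.

    ``frailty_coeff = 0`` is the exogenous regime (selection independent of
    the unobserved tract frailty); any nonzero value makes the selection
    endogenous.
    """

    intercept: float = 20.0
    dist_coeff: float = 0.0
    frailty_coeff: float = 0.0

    @property
    def exogenous(self) -> bool:
        return self.frailty_coeff == 0.0


@dataclass(frozen=True)
class TruthParams:
    """Ground-truth parameters of the synthetic disease process.

    ``matern = None`` disables the spatial field (no latent spatial noise).
    """

    base_rate: float = 2.0  # cases per 100,000 person-years at risk
    beta: dict = field(default_factory=dict)  # named covariate effects
    matern: MaternParams | None = field(
        default_factory=lambda: MaternParams(0.25, 0.354, 1.0)
    )
    rw1_sd: float = 0.0
    selection: SelectionParams = field(default_factory=SelectionParams)

    def __post_init__(self):
        if not (self.base_rate > 0):
            raise ValueError(f"base_rate must be > 0, got {self.base_rate}")
        if self.rw1_sd < 0:
            raise ValueError("rw1_sd must be >= 0")


def default_truth() -> TruthParams:
    """Default truth calibrated so the observed landscape shows ~90% zero-case
    tracts at rare-disease rates, with endogenous ~60% observation."""
    return TruthParams(
        base_rate=2.2,
        beta={"dep_q4": 0.10, "dep_q5": 0.20},
        matern=MaternParams(sigma2=0.25, kappa=math.sqrt(8.0) / 10.0, nu=1.0),
        rw1_sd=0.05,
        selection=SelectionParams(intercept=1.1, dist_coeff=-0.045, frailty_coeff=0.6),
    )


# ---------------------------------------------------------------------------
# Landscape
# ---------------------------------------------------------------------------


def generate_landscape(n_tracts_per_region: int, seed: int) -> pd.DataFrame:
    """Generate a two-region synthetic census-tract table.

    Each region occupies its own disjoint planar patch (coordinates in km);
    tract populations are log-normal (median ~1,400) and split into six
    sex-by-age strata; a deprivation score with a mild east-west gradient is
    quintile-coded within each region; ``dist_centre`` is the distance to the
    region's population-weighted centroid (its referral centre).
    """
    if not isinstance(n_tracts_per_region, (int, np.integer)) or n_tracts_per_region < 4:
        raise ValueError(
            f"n_tracts_per_region must be an integer >= 4, got {n_tracts_per_region}"
        )
    rng = np.random.default_rng(seed)
    frames = []
    for r_idx, region in enumerate(REGIONS):
        n = int(n_tracts_per_region)
        x = rng.uniform(0.0, REGION_SIDE_KM, size=n) + r_idx * REGION_OFFSET_KM
        y = rng.uniform(0.0, REGION_SIDE_KM, size=n)
        pop_total = np.maximum(
            np.round(np.exp(rng.normal(math.log(POP_MEDIAN), POP_LOG_SD, size=n))), 60
        ).astype(int)
        strata_names = list(STRATA_PROPS)
        props = np.array([STRATA_PROPS[s] for s in strata_names])
        strata = np.vstack(
            [rng.multinomial(pop_total[i], props) for i in range(n)]
        )
        df = pd.DataFrame(
            {
                "tract_id": [f"{region}-{i:05d}" for i in range(n)],
                "region": region,
                "x": x,
                "y": y,
                "pop_total": pop_total,
            }
        )
        for j, s in enumerate(strata_names):
            df[f"pop_{s}"] = strata[:, j]
        df["pop_over16"] = (
            df["pop_men_16to64"]
            + df["pop_men_65plus"]
            + df["pop_women_16to64"]
            + df["pop_women_65plus"]
        )
        # guard: the offset must be positive
        zero = df["pop_over16"] == 0
        if zero.any():
            df.loc[zero, "pop_men_16to64"] += 1
            df.loc[zero, "pop_total"] += 1
            df.loc[zero, "pop_over16"] += 1
        # deprivation: mild spatial gradient plus tract noise
        grad = (x - x.min()) / REGION_SIDE_KM - 0.5
        df["deprivation"] = 0.8 * grad + rng.normal(0.0, 0.8, size=n)
        df["deprivation_q"] = quintile_categorise(df["deprivation"].to_numpy())
        # referral centre at the population-weighted centroid
        cx = float(np.average(x, weights=pop_total))
        cy = float(np.average(y, weights=pop_total))
        df["dist_centre"] = np.hypot(x - cx, y - cy)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    validate_tracts(out, require_cases=False)
    return out


def validate_tracts(tracts: pd.DataFrame, require_cases: bool = True) -> None:
    """Check tract-table invariants; raise ``ValueError`` on violation."""
    strata_cols = [f"pop_{s}" for s in STRATA_PROPS]
    for col in ["tract_id", "region", "x", "y", "pop_total", "pop_over16"] + strata_cols:
        if col not in tracts.columns:
            raise ValueError(f"tract table missing column {col!r}")
    if not np.all(np.isfinite(tracts[["x", "y"]].to_numpy(float))):
        raise ValueError("tract coordinates must be finite")
    strata_sum = tracts[strata_cols].sum(axis=1)
    if not (strata_sum == tracts["pop_total"]).all():
        raise ValueError("population strata do not sum to pop_total")
    adult = (
        tracts["pop_men_16to64"]
        + tracts["pop_men_65plus"]
        + tracts["pop_women_16to64"]
        + tracts["pop_women_65plus"]
    )
    if not (adult == tracts["pop_over16"]).all():
        raise ValueError("pop_over16 must equal the sum of the adult strata")
    if (tracts[strata_cols].to_numpy() < 0).any():
        raise ValueError("population counts must be nonnegative")
    if require_cases:
        mnd_cols = sorted(c for c in tracts.columns if c.startswith("cases_MND_"))
        if not mnd_cols:
            raise ValueError("tract table has no case-count columns")
        years = [c.rsplit("_", 1)[1] for c in mnd_cols]
        for yr in years:
            parts = sum(tracts[f"cases_{c}_{yr}"] for c in CATEGORIES)
            if not (parts == tracts[f"cases_MND_{yr}"]).all():
                raise ValueError(
                    f"cases_MND_{yr} must equal the sum of ALS/PMA/PLS counts"
                )


# ---------------------------------------------------------------------------
# Matérn field sampling
# ---------------------------------------------------------------------------


def sample_matern_field(
    coords,
    params: MaternParams,
    seed: int,
    n_draws: int = 1,
    jitter: float = 1e-10,
) -> np.ndarray:
    """Draw from a zero-mean Gaussian field with Matérn covariance.

    Uses exact (dense) Cholesky factorisation of the covariance matrix,
    appropriate at desk scale (n <= a few thousand points).  Returns a
    vector of length ``n`` when ``n_draws == 1`` and an ``(n_draws, n)``
    array otherwise.

    Raises
    ------
    np.linalg.LinAlgError
        If the covariance matrix cannot be factorised; the message advises
        increasing ``jitter``.
    """
    from .model import matern_covariance_matrix

    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.shape[0] < 1:
        raise ValueError("need at least one point")
    cov = matern_covariance_matrix(coords, params, jitter=jitter)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "Matérn covariance matrix is not numerically positive definite; "
            "increase the `jitter` argument (e.g. 1e-8) or drop coincident points"
        ) from exc
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_draws, len(coords)))
    draws = z @ chol.T
    return draws[0] if n_draws == 1 else draws


# ---------------------------------------------------------------------------
# Socioeconomic indicators
# ---------------------------------------------------------------------------


@dataclass
class IndicatorSet:
    values: pd.DataFrame  # tracts x 10 indicator matrix
    latent: np.ndarray  # latent deprivation factor, for recovery tests
    loading_names: list
    noise_names: list


def generate_indicators(
    tracts: pd.DataFrame, n_loading: int, n_noise: int, seed: int
) -> IndicatorSet:
    """Generate a tracts x 10 indicator matrix.

    ``n_loading`` indicators share one latent deprivation factor with
    loadings in [0.7, 0.9]; ``n_noise`` indicators are independent noise.
    The latent factor is returned for recovery testing.  The first loading
    indicator is named ``pct_unemployed`` so the index orientation rule has
    an anchor.
    """
    if n_loading + n_noise != 10:
        raise ValueError(
            f"n_loading + n_noise must equal 10, got {n_loading} + {n_noise}"
        )
    if n_loading < 0 or n_noise < 0:
        raise ValueError("indicator counts must be nonnegative")
    rng = np.random.default_rng(seed)
    n = len(tracts)
    latent = rng.standard_normal(n)
    cols = {}
    loading_names, noise_names = [], []
    for j in range(n_loading):
        name = "pct_unemployed" if j == 0 else f"indicator_load_{j:02d}"
        lam = rng.uniform(0.7, 0.9)
        cols[name] = lam * latent + math.sqrt(1.0 - lam**2) * rng.standard_normal(n)
        loading_names.append(name)
    for j in range(n_noise):
        name = f"indicator_noise_{j:02d}"
        cols[name] = rng.standard_normal(n)
        noise_names.append(name)
    values = pd.DataFrame(cols, index=tracts.index)
    return IndicatorSet(
        values=values, latent=latent, loading_names=loading_names, noise_names=noise_names
    )


# ---------------------------------------------------------------------------
# Disease simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulationResult:
    tracts: pd.DataFrame  # copy of the input with true per-year case counts
    patients: pd.DataFrame  # one row per true case
    spatial_field: np.ndarray  # S_i, the latent frailty per tract
    year_effects: np.ndarray  # gamma_t (sum-to-zero RW1 path)
    expected_counts: np.ndarray  # (n_tracts, n_years) Poisson means


def simulate_disease(
    tracts: pd.DataFrame,
    truth: TruthParams,
    years: Sequence[int],
    seed: int,
) -> SimulationResult:
    """Simulate true case counts and patient records per tract-year.

    Per tract-year the true new-case count is Poisson with

    ``log mu_it = log(base_rate / 1e5) + x_i' beta + S_i + gamma_t
                  + log(pop_over16_i)``

    MND counts are split into ALS/PMA/PLS with the fixed category mix;
    patients carry sex and age drawn from the stated marginals, with the age
    quintile computed from region-specific empirical cut points.
    """
    years = list(years)
    if len(years) == 0:
        raise ValueError("year range must be non-empty")
    rng = np.random.default_rng(seed)
    n = len(tracts)

    if truth.matern is not None and truth.matern.sigma2 > 0 and n > 0:
        sub = int(rng.integers(0, 2**31 - 1))
        S = sample_matern_field(
            tracts[["x", "y"]].to_numpy(float), truth.matern, seed=sub, jitter=1e-8
        )
    else:
        S = np.zeros(n)

    n_years = len(years)
    if truth.rw1_sd > 0 and n_years > 1:
        steps = rng.normal(0.0, truth.rw1_sd, size=n_years - 1)
        gamma = np.concatenate([[0.0], np.cumsum(steps)])
        gamma = gamma - gamma.mean()  # sum-to-zero for identifiability
    else:
        gamma = np.zeros(n_years)

    cov = build_covariates(tracts)
    xb = np.zeros(n)
    for name, b in truth.beta.items():
        if name not in cov.columns:
            raise KeyError(f"truth.beta refers to unknown covariate {name!r}")
        xb += b * cov[name].to_numpy(float)

    log_rate = (
        math.log(truth.base_rate / 1e5)
        + xb
        + S
        + np.log(tracts["pop_over16"].to_numpy(float))
    )
    mu = np.exp(log_rate[:, None] + gamma[None, :])  # (n, n_years)
    counts_mnd = rng.poisson(mu)

    out = tracts.copy()
    cat_names = list(CATEGORY_PROBS)
    cat_probs = np.array([CATEGORY_PROBS[c] for c in cat_names])
    counts_cat = np.zeros((n, n_years, len(cat_names)), dtype=int)
    for i in range(n):
        for t in range(n_years):
            if counts_mnd[i, t] > 0:
                counts_cat[i, t] = rng.multinomial(counts_mnd[i, t], cat_probs)
    for t, yr in enumerate(years):
        out[f"cases_MND_{yr}"] = counts_mnd[:, t]
        for c_idx, c in enumerate(cat_names):
            out[f"cases_{c}_{yr}"] = counts_cat[:, t, c_idx]

    records = []
    pid = 0
    tract_ids = tracts["tract_id"].to_numpy()
    regions = tracts["region"].to_numpy()
    for i in range(n):
        for t, yr in enumerate(years):
            for c_idx, c in enumerate(cat_names):
                for _ in range(counts_cat[i, t, c_idx]):
                    sex = "male" if rng.random() < MALE_FRACTION else "female"
                    age = float(
                        np.clip(rng.normal(AGE_MEAN, AGE_SD), AGE_MIN, AGE_MAX)
                    )
                    records.append(
                        (
                            f"P{pid:06d}",
                            tract_ids[i],
                            regions[i],
                            sex,
                            age,
                            yr,
                            c,
                            True,
                        )
                    )
                    pid += 1
    patients = pd.DataFrame(
        records,
        columns=[
            "patient_id",
            "tract_id",
            "region",
            "sex",
            "age_at_diagnosis",
            "year",
            "category",
            "observed",
        ],
    )
    patients["age_q"] = _age_quintiles(patients)
    validate_tracts(out)
    return SimulationResult(
        tracts=out,
        patients=patients,
        spatial_field=S,
        year_effects=gamma,
        expected_counts=mu,
    )


def _age_quintiles(patients: pd.DataFrame) -> np.ndarray:
    """Region-specific empirical age quintiles (fixed cut points when a
    region has too few patients to form them)."""
    q = np.ones(len(patients), dtype=int)
    fallback_cuts = [53.0, 59.0, 66.0, 71.0]
    for region, idx in patients.groupby("region").groups.items():
        ages = patients.loc[idx, "age_at_diagnosis"].to_numpy(float)
        if len(ages) >= 5:
            q[patients.index.get_indexer(idx)] = quintile_categorise(ages)
        else:
            q[patients.index.get_indexer(idx)] = (
                np.searchsorted(fallback_cuts, ages, side="left") + 1
            )
    return q


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------


def apply_selection(
    patients: pd.DataFrame,
    tracts: pd.DataFrame,
    sel: SelectionParams,
    latent_frailty,
    seed: int,
) -> pd.DataFrame:
    """Flag each patient as observed or not.

    Observation probability per patient is
    ``inverse_logit(intercept + dist_coeff * dist_centre + frailty_coeff *
    frailty)`` of the patient's tract.  A nonzero ``frailty_coeff`` creates
    the endogenous (selection-on-unobservables) regime.
    """
    frailty = np.asarray(latent_frailty, dtype=float)
    if len(frailty) != len(tracts):
        raise ValueError(
            f"latent frailty length {len(frailty)} does not match "
            f"{len(tracts)} tracts"
        )
    rng = np.random.default_rng(seed)
    lookup = pd.DataFrame(
        {
            "dist_centre": tracts["dist_centre"].to_numpy(float),
            "frailty": frailty,
        },
        index=tracts["tract_id"].to_numpy(),
    )
    missing = set(patients["tract_id"]) - set(lookup.index)
    if missing:
        raise ValueError(f"patients reference unknown tracts: {sorted(missing)[:5]}")
    d = lookup.loc[patients["tract_id"], "dist_centre"].to_numpy()
    f = lookup.loc[patients["tract_id"], "frailty"].to_numpy()
    p_obs = inverse_logit(sel.intercept + sel.dist_coeff * d + sel.frailty_coeff * f)
    out = patients.copy()
    out["observed"] = rng.random(len(out)) < p_obs
    out["p_observed"] = p_obs
    return out


def tracts_with_observed_counts(
    tracts: pd.DataFrame, patients: pd.DataFrame
) -> pd.DataFrame:
    """Rebuild the per-tract-year case-count columns from observed patients.

    Returns a copy of ``tracts`` whose ``cases_*`` columns count only
    patients with ``observed == True`` — the selection-biased table the
    two-part model is fitted to.
    """
    out = tracts.copy()
    years = sorted(
        {int(c.rsplit("_", 1)[1]) for c in tracts.columns if c.startswith("cases_MND_")}
    )
    if not years:
        years = sorted(patients["year"].unique())
    for yr in years:
        for cat in list(CATEGORIES) + ["MND"]:
            out[f"cases_{cat}_{yr}"] = 0
    obs = patients[patients["observed"]]
    pos = {tid: i for i, tid in enumerate(out["tract_id"])}
    grouped = obs.groupby(["tract_id", "year", "category"]).size()
    for (tid, yr, cat), cnt in grouped.items():
        i = pos[tid]
        out.iloc[i, out.columns.get_loc(f"cases_{cat}_{yr}")] += cnt
        out.iloc[i, out.columns.get_loc(f"cases_MND_{yr}")] += cnt
    validate_tracts(out)
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_tracts_csv(tracts: pd.DataFrame, path) -> None:
    tracts.to_csv(path, index=False)


def read_tracts_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_tracts(df, require_cases=False)
    return df


def write_patients_csv(patients: pd.DataFrame, path) -> None:
    patients.to_csv(path, index=False)


def read_patients_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def export_geojson(tracts: pd.DataFrame, path, half_side_km: float = 0.4,
                   properties: Iterable[str] = ("tract_id", "region")) -> None:
    """Write square tract tiles (centred on centroids) as GeoJSON."""
    feats = []
    for _, row in tracts.iterrows():
        x, y, h = float(row["x"]), float(row["y"]), half_side_km
        ring = [
            [x - h, y - h],
            [x + h, y - h],
            [x + h, y + h],
            [x - h, y + h],
            [x - h, y - h],
        ]
        props = {}
        for p in properties:
            if p in row:
                v = row[p]
                props[p] = v.item() if hasattr(v, "item") else v
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": props,
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
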