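"""Sequential-PCA deprivation index and quintile coding.

The index is the first principal component of a two-stage ("sequential")
PCA over tract-level socioeconomic indicators: a first PCA over all
indicators, a Spearman screen of each indicator against the first component
scores, and a second PCA restricted to the survivors.  PCA is run on the
correlation matrix (indicators are percentages on different scales), the
screen uses ``|rho| >= threshold`` (the sign of a component is arbitrary),
and the final scores are oriented so that higher values mean more deprived.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = ["DeprivationResult", "sequential_pca_index", "quintile_categorise"]


@dataclass
class DeprivationResult:
    index: pd.Series  # deprivation score per tract, mean zero
    retained: list  # indicator names surviving the screen
    correlations: dict  # Spearman rho of each indicator vs first-stage PC1


def _first_component_scores(values: np.ndarray) -> np.ndarray:
    """First-principal-component scores of column-standardised data."""
    sd = values.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    z = (values - values.mean(axis=0)) / sd
    # SVD of the centred matrix == PCA on the correlation matrix
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    return u[:, 0] * s[0]


def sequential_pca_index(
    indicators: pd.DataFrame,
    threshold: float = 0.5,
    orient_column: str | None = "pct_unemployed",
) -> DeprivationResult:
    """Compute the sequential-PCA deprivation index.

    Parameters
    ----------
    indicators : DataFrame
        One row per tract, one numeric column per indicator (no missing
        values).
    threshold : float
        Indicators with ``|Spearman rho| < threshold`` against the
        first-stage first component are dropped before the second PCA.
    orient_column : str or None
        Indicator used to orient the sign of the index (positive Spearman
        correlation with it); falls back to the first retained indicator if
        absent.

    Returns
    -------
    DeprivationResult
        ``index`` has mean zero over tracts; ``retained`` lists the
        surviving indicators; ``correlations`` the screening correlations.

    Raises
    ------
    ValueError
        If fewer than 3 tracts or 2 indicators are supplied, the data
        contain missing values, or fewer than 2 indicators survive the
        screen (the error names the survivors).
    """
    if len(indicators) < 3:
        raise ValueError("need at least 3 tracts")
    if indicators.shape[1] < 2:
        raise ValueError("need at least 2 indicators")
    values = indicators.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("indicator matrix contains missing/non-finite values")

    scores1 = _first_component_scores(values)
    correlations: dict[str, float] = {}
    for j, name in enumerate(indicators.columns):
        col = values[:, j]
        if np.ptp(col) == 0:
            rho = 0.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rho = float(spearmanr(col, scores1).statistic)
            if not np.isfinite(rho):
                rho = 0.0
        correlations[name] = rho

    retained = [n for n in indicators.columns if abs(correlations[n]) >= threshold]
    if len(retained) < 2:
        raise ValueError(
            f"fewer than 2 indicators survive the |rho| >= {threshold} screen; "
            f"survivors: {retained}"
        )

    scores2 = _first_component_scores(indicators[retained].to_numpy(dtype=float))

    ref = orient_column if orient_column in retained else retained[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        orient_rho = spearmanr(indicators[ref].to_numpy(float), scores2).statistic
    if np.isfinite(orient_rho) and orient_rho < 0:
        scores2 = -scores2

    index = pd.Series(scores2 - scores2.mean(), index=indicators.index, name="deprivation")
    return DeprivationResult(index=index, retained=retained, correlations=correlations)


def quintile_categorise(values) -> np.ndarray:
    """Assign empirical quintile labels 1..5 (1 = least deprived, reference).

    Labels follow the empirical quintile cut points of the supplied values;
    ties are broken by assigning the lower quintile (tied values share the
    quintile of their first sorted occurrence).  If all values are identical
    every tract gets label 1 and a warning is issued.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if len(v) < 5:
        raise ValueError("need at least 5 values to form quintiles")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    if np.ptp(v) == 0:
        warnings.warn("all values identical; assigning quintile 1 to every tract")
        return np.ones(len(v), dtype=int)
    n = len(v)
    order = np.argsort(v, kind="stable")
    sorted_vals = v[order]
    # rank of the first occurrence of each value (1-based) -> ties take the
    # lower quintile
    first_rank = np.searchsorted(sorted_vals, v, side="left") + 1
    labels = np.ceil(5.0 * first_rank / n).astype(int)
    return np.clip(labels, 1, 5)
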