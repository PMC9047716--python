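"""Two-sigma area selection and randomization-test significance.

Two thresholds are applied, both reported:

* *relevant* — an area's median MAE lies more than two sample standard
  deviations below the mean of all areas' MAEs (the across-area
  two-sigma rule; lower-tail probability ~0.022 under normality);
* *significant* — the MAE lies more than two standard deviations below
  the mean of a noise distribution obtained by re-running the identical
  regression protocol on i.i.d. standard-normal features of matched
  dimensionality (the randomization test).

p-values come from a normal fit to the noise replicates: the z-scores
of strongly predictive areas sit far beyond any empirical-rank
resolution, so a parametric tail is the only consistent reading; an
empirical rank p-value is available as an option.  No multiple-testing
correction is applied — the hypotheses are per-area by design.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .rank import AreaRankingResult, RankingConfig, rank_area


def two_sigma_tail_probability(decimals: int | None = 3) -> float:
    """Lower-tail normal probability at z = -2, optionally truncated.

    Truncated to three decimals this is the 0.022 quoted alongside the
    two-sigma rule.
    """
    p = float(norm.cdf(-2.0))
    if decimals is None:
        return p
    factor = 10.0**decimals
    return math.floor(p * factor) / factor


@dataclass
class NoiseDistribution:
    """Normal summary of the randomization-test null MAEs."""

    mu: float
    sigma: float
    replicate_maes: np.ndarray

    @property
    def n_replicates(self) -> int:
        return int(self.replicate_maes.size)


@dataclass
class AreaSignificance:
    roi_label: int
    median_mae: float
    z: float
    p_value: float
    relevant: bool
    significant: bool


def two_sigma_select(values) -> np.ndarray:
    """Boolean flags: value < mean - 2 * sample SD (ddof = 1)."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 3:
        raise ValueError("two-sigma selection needs at least 3 values")
    sd = values.std(ddof=1)
    if sd == 0:
        warnings.warn("zero spread among MAEs: no area can be selected")
        return np.zeros(values.size, dtype=bool)
    return values < values.mean() - 2.0 * sd


def build_noise_distribution(
    cohort: pd.DataFrame,
    y: np.ndarray,
    config: RankingConfig,
    n_features: int,
    n_replicates: int = 100,
    seed: int | None = None,
) -> NoiseDistribution:
    """Null MAE distribution from random features through the full protocol.

    Each replicate draws an (n_subjects x n_features) i.i.d. N(0, 1)
    feature matrix — the dimensionality should match a typical
    post-selection area — appends age, and runs the *identical*
    rank_area protocol: same partition splits and same per-model seeds
    as the real areas, so replicate MAEs differ from area MAEs only
    through the features.  Conditioning the null on the shared
    partitions this way removes split-to-split variance that the areas,
    which all use the same splits, never see.  At least 30 replicates
    are required for a usable mean/SD estimate.
    """
    if n_replicates < 30:
        raise ValueError("need at least 30 noise replicates")
    y = np.asarray(y, dtype=float).ravel()
    if np.ptp(y) == 0:
        raise ValueError("degenerate cohort: constant target scores")
    age = cohort["age"].to_numpy(dtype=float)
    if seed is None:
        seed = config.seed
    maes = np.empty(n_replicates)
    for r in range(n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence((seed, 7001, r)))
        X = rng.standard_normal((len(age), n_features))
        table = pd.DataFrame(X, columns=[f"noise_{i}" for i in range(n_features)])
        table["age"] = age
        maes[r] = rank_area(table, y, config).median_mae
    sigma = float(maes.std(ddof=1))
    if sigma == 0:
        raise ValueError("noise distribution has zero spread")
    return NoiseDistribution(mu=float(maes.mean()), sigma=sigma, replicate_maes=maes)


def area_p_value(
    median_mae: float,
    noise: NoiseDistribution,
    empirical: bool = False,
) -> tuple[float, float, bool]:
    """z-score, lower-tail p, and two-sigma significance flag vs noise.

    Smaller MAE than the noise mean gives negative z; ``p = Phi(z)``.
    With ``empirical=True`` the p-value is the rank of the observed MAE
    among the replicates, ``(1 + #{null <= obs}) / (n + 1)``.
    """
    if noise.sigma <= 0:
        raise ValueError("noise distribution has non-positive sigma")
    z = (median_mae - noise.mu) / noise.sigma
    if empirical:
        p = (1.0 + np.sum(noise.replicate_maes <= median_mae)) / (
            noise.n_replicates + 1.0
        )
    else:
        p = float(norm.cdf(z))
    return float(z), float(p), bool(z < -2.0)


def significance_table(
    results: list[AreaRankingResult],
    noise: NoiseDistribution,
    empirical: bool = False,
) -> pd.DataFrame:
    """Per-area significance summary (layout mirrors the headline table)."""
    maes = np.array([r.median_mae for r in results])
    relevant = two_sigma_select(maes)
    rows = []
    for r, rel in zip(results, relevant):
        z, p, sig = area_p_value(r.median_mae, noise, empirical=empirical)
        rows.append(
            AreaSignificance(
                roi_label=r.roi_label,
                median_mae=r.median_mae,
                z=z,
                p_value=p,
                relevant=bool(rel),
                significant=sig,
            )
        )
    return pd.DataFrame(
        {
            "roi_label": [r.roi_label for r in rows],
            "median_mae": [r.median_mae for r in rows],
            "z": [r.z for r in rows],
            "p_value": [r.p_value for r in rows],
            "relevant": [r.relevant for r in rows],
            "significant": [r.significant for r in rows],
        }
    )
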