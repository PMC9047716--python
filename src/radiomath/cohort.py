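"""Synthetic cohort generation calibrated to the study's cohort statistics.

The generator draws, per grade, ages uniform within a band matching the
grade's age mean/SD, and raw scores ``mean + SD * z`` where ``z`` is
multivariate normal.  Scores are rounded to integers (the tests are item
counts) and clipped to each test's maximum.

The user-facing correlation target of a :class:`CohortSpec` is the
*age-partialled* inter-test correlation matrix.  Pooling grades with
different score means induces extra positive correlation that a linear
age regression removes only partly, so the latent ``z`` correlation is
calibrated analytically (see :func:`calibrated_latent_correlation`) so
that the age-partialled correlations of large generated cohorts converge
to the requested targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import SCORE_COLUMNS, TEST_KEYS, TESTS

#: Per-grade cohort descriptors: group size, age mean (SD), and per-test
#: raw-score mean (SD) for Math fluency / Calculation / Applied problems /
#: Quantitative concepts, grades 3-6.
GRADE_TABLE = {
    3: {"n": 24, "age": (8.5, 0.33), "mf": (37.6, 6.9), "calc": (13.0, 2.4), "ap": (29.7, 3.0), "qc": (16.9, 2.1)},
    4: {"n": 24, "age": (9.4, 0.39), "mf": (46.5, 11.3), "calc": (16.8, 2.1), "ap": (33.8, 4.4), "qc": (19.4, 2.8)},
    5: {"n": 17, "age": (10.6, 0.37), "mf": (62.4, 18.6), "calc": (18.4, 1.8), "ap": (35.8, 3.5), "qc": (20.6, 1.6)},
    6: {"n": 12, "age": (11.6, 0.27), "mf": (63.3, 19.6), "calc": (19.3, 2.1), "ap": (39.3, 5.2), "qc": (22.8, 2.1)},
}

#: Target age-partialled correlations between the four tests
#: (order mf, calc, ap, qc).
PARTIAL_CORRELATION_TARGET = np.array(
    [
        [1.000, 0.386, 0.344, 0.360],
        [0.386, 1.000, 0.503, 0.498],
        [0.344, 0.503, 1.000, 0.686],
        [0.360, 0.498, 0.686, 1.000],
    ]
)


@dataclass
class CohortSpec:
    """Statistical description of the cohort to simulate."""

    group_sizes: dict[int, int] = field(
        default_factory=lambda: {g: GRADE_TABLE[g]["n"] for g in GRADE_TABLE}
    )
    score_means: dict[int, dict[str, float]] = field(
        default_factory=lambda: {
            g: {t: GRADE_TABLE[g][t][0] for t in TEST_KEYS} for g in GRADE_TABLE
        }
    )
    score_sds: dict[int, dict[str, float]] = field(
        default_factory=lambda: {
            g: {t: GRADE_TABLE[g][t][1] for t in TEST_KEYS} for g in GRADE_TABLE
        }
    )
    age_means: dict[int, float] = field(
        default_factory=lambda: {g: GRADE_TABLE[g]["age"][0] for g in GRADE_TABLE}
    )
    age_sds: dict[int, float] = field(
        default_factory=lambda: {g: GRADE_TABLE[g]["age"][1] for g in GRADE_TABLE}
    )
    partial_correlation: np.ndarray = field(
        default_factory=lambda: PARTIAL_CORRELATION_TARGET.copy()
    )
    seed: int = 0

    @property
    def n_subjects(self) -> int:
        return sum(self.group_sizes.values())

    def validate(self) -> None:
        R = np.asarray(self.partial_correlation, dtype=float)
        if R.shape != (4, 4):
            raise ValueError("partial correlation matrix must be 4x4")
        if not np.allclose(R, R.T):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(R), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        eig = np.linalg.eigvalsh(R)
        if eig.min() < -1e-10:
            raise ValueError(
                f"correlation matrix not positive semidefinite (min eigenvalue {eig.min():.3g})"
            )


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """CohortSpec calibrated to the published per-grade descriptors."""
    return CohortSpec(seed=seed)


def _mixture_moments(spec: CohortSpec):
    """Analytic moments of the grade mixture needed for calibration."""
    grades = sorted(spec.group_sizes)
    w = np.array([spec.group_sizes[g] for g in grades], dtype=float)
    w /= w.sum()
    age_mu = np.array([spec.age_means[g] for g in grades])
    age_within_var = np.array([spec.age_sds[g] ** 2 for g in grades])
    mu = np.array([[spec.score_means[g][t] for t in TEST_KEYS] for g in grades])
    sd = np.array([[spec.score_sds[g][t] for t in TEST_KEYS] for g in grades])

    abar = float(w @ age_mu)
    age_var = float(w @ (age_mu - abar) ** 2 + w @ age_within_var)
    return grades, w, age_mu, age_within_var, mu, sd, abar, age_var


def calibrated_latent_correlation(spec: CohortSpec) -> np.ndarray:
    """Latent z-correlation matrix whose age-partialled output hits the target.

    A linear regression of score on age leaves residuals composed of the
    within-grade latent part ``SD_t z_t``, the grade-mean residual
    ``r_t(g)`` (grade means are not exactly linear in age), the
    within-grade age jitter times the slope, and integer-rounding noise
    (variance 1/12).  Writing the target partial correlation in those
    moments and solving for the latent correlation is a linear map per
    matrix entry.  The result is projected to the nearest positive
    semidefinite correlation matrix if the moment solution leaves the
    cone (it does not for the default calibration).
    """
    _, w, age_mu, age_within_var, mu, sd, abar, age_var = _mixture_moments(spec)
    ew_age = float(w @ age_within_var)

    slopes = (w @ ((age_mu - abar)[:, None] * (mu - w @ mu))) / age_var  # per test
    resid = mu - w @ mu - np.outer(age_mu - abar, slopes)  # r_t(g)

    esd2 = w @ sd**2  # pooled within-grade latent variance per test
    var_resid = esd2 + w @ resid**2 + slopes**2 * ew_age + 1.0 / 12.0
    cov_struct = (resid * w[:, None]).T @ resid + np.outer(slopes, slopes) * ew_age
    esd_cross = (sd * w[:, None]).T @ sd  # E[SD_t SD_s] over grades

    target = np.asarray(spec.partial_correlation, dtype=float)
    denom = np.sqrt(np.outer(var_resid, var_resid))
    latent = (target * denom - cov_struct) / esd_cross
    np.fill_diagonal(latent, 1.0)
    latent = np.clip((latent + latent.T) / 2.0, -1.0, 1.0)

    eigval, eigvec = np.linalg.eigh(latent)
    if eigval.min() < -1e-10:
        eigval = np.clip(eigval, 0.0, None)
        latent = eigvec @ np.diag(eigval) @ eigvec.T
        d = np.sqrt(np.diag(latent))
        latent = latent / np.outer(d, d)
    return latent


def generate_cohort(spec: CohortSpec, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate one cohort; returns the standard cohort table.

    Columns: subject_id, grade, age, sex, mf_raw, calc_raw, ap_raw,
    qc_raw.  Deterministic under a fixed ``spec.seed`` (or an explicitly
    passed generator).
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    latent = calibrated_latent_correlation(spec)
    chol = np.linalg.cholesky(latent + 1e-12 * np.eye(4))
    max_scores = np.array([TESTS[t][1] for t in TEST_KEYS], dtype=float)

    frames = []
    offset = 0
    for grade in sorted(spec.group_sizes):
        n = spec.group_sizes[grade]
        half_width = spec.age_sds[grade] * np.sqrt(3.0)
        age = rng.uniform(
            spec.age_means[grade] - half_width, spec.age_means[grade] + half_width, n
        )
        z = rng.standard_normal((n, 4)) @ chol.T
        means = np.array([spec.score_means[grade][t] for t in TEST_KEYS])
        sds = np.array([spec.score_sds[grade][t] for t in TEST_KEYS])
        scores = np.clip(np.rint(means + sds * z), 0.0, max_scores).astype(int)
        sex = rng.choice(["M", "F"], size=n)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": [f"sub-{offset + i + 1:04d}" for i in range(n)],
                    "grade": grade,
                    "age": age,
                    "sex": sex,
                    **{SCORE_COLUMNS[t]: scores[:, k] for k, t in enumerate(TEST_KEYS)},
                }
            )
        )
        offset += n
    return pd.concat(frames, ignore_index=True)


def normalize_scores(cohort: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Min-max normalize each test's raw scores to [0, 1] over the cohort.

    Returns the table with added ``<test>_norm`` columns and the
    per-test (min, max) constants used, for the run manifest.
    """
    out = cohort.copy()
    constants: dict[str, tuple[float, float]] = {}
    for t in TEST_KEYS:
        raw = out[SCORE_COLUMNS[t]].to_numpy(dtype=float)
        lo, hi = float(raw.min()), float(raw.max())
        if hi == lo:
            raise ValueError(f"degenerate cohort: test {t} has constant scores")
        out[f"{t}_norm"] = (raw - lo) / (hi - lo)
        constants[t] = (lo, hi)
    return out, constants


def partial_correlation(
    scores: pd.DataFrame | np.ndarray,
    control: np.ndarray,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Pairwise Pearson correlations of control-residualized columns.

    ``control`` (typically age) is regressed out of every column with an
    intercept; the returned matrix is the correlation of the residuals.
    Requires at least 4 rows.  Zero-variance residuals yield NaN in the
    affected entries.
    """
    Y = np.asarray(scores, dtype=float)
    if Y.ndim != 2:
        raise ValueError("scores must be 2-D")
    n = Y.shape[0]
    if n < 4:
        raise ValueError("partial correlation needs at least 4 subjects")
    control = np.asarray(control, dtype=float).reshape(n, -1)
    X = np.column_stack([np.ones(n), control])
    if weights is None:
        weights = np.ones(n)
    Xw = X * weights[:, None]
    beta = np.linalg.solve(X.T @ Xw, X.T @ (Y * weights[:, None]))
    resid = Y - X @ beta
    C = (resid * weights[:, None]).T @ resid
    d = np.sqrt(np.diag(C))
    with np.errstate(divide="ignore", invalid="ignore"):
        P = C / np.outer(d, d)
    return P
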