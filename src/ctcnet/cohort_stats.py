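"""Cohort statistics: impairment classification, proportion CIs, reference
comparisons, sex-stratified GLMs, correlations, and FDR control.

Impairment follows the operational rule: an age-adjusted z strictly below
-1.3 (10th percentile) on any executive-function measure.  Proportion
intervals are Wald by default (this is the interval family that reproduces
the published table arithmetic), with Wilson available behind a flag.
Multiplicity is controlled by the Benjamini-Yekutieli step-up (valid under
arbitrary dependence; Benjamini-Hochberg available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, DataError
from .synthetic import EXECUTIVE_MEASURES, IMPAIRMENT_THRESHOLD

__all__ = [
    "ImpairmentTable",
    "ProportionCI",
    "GLMFit",
    "classify_impairment",
    "impairment_proportion_ci",
    "one_sample_vs_reference",
    "glm_brain_exposure",
    "correlate",
    "fdr_correct",
]


# ---------------------------------------------------------------------------
# impairment classification
# ---------------------------------------------------------------------------


@dataclass
class ImpairmentTable:
    """Per-subject, per-measure impairment flags plus the any-executive flag."""

    flags: pd.DataFrame  # subjects x measures, boolean
    any_executive_impaired: pd.Series  # subject -> bool
    threshold: float
    executive_measures: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        out = self.flags.copy()
        out["any_executive_impaired"] = self.any_executive_impaired
        return out.reset_index()


def classify_impairment(
    scores: pd.DataFrame,
    threshold: float = IMPAIRMENT_THRESHOLD,
    executive_measures: tuple[str, ...] | list[str] = EXECUTIVE_MEASURES,
) -> ImpairmentTable:
    """Flag impairment per measure (z strictly below the threshold) and
    derive the any-executive-impaired flag.

    ``scores`` is long format with columns subject_id, measure, z.
    """
    wide = scores.pivot_table(index="subject_id", columns="measure", values="z")
    unknown = [m for m in executive_measures if m not in wide.columns]
    if unknown:
        raise DataError(f"unknown executive measure(s): {', '.join(unknown)}")
    flags = wide < threshold  # strict inequality: z == threshold is unimpaired
    any_exec = flags[list(executive_measures)].any(axis=1)
    return ImpairmentTable(
        flags=flags,
        any_executive_impaired=any_exec,
        threshold=threshold,
        executive_measures=tuple(executive_measures),
    )


# ---------------------------------------------------------------------------
# proportion confidence intervals
# ---------------------------------------------------------------------------


@dataclass
class ProportionCI:
    k: int
    n: int
    proportion: float  # percent
    ci_low: float  # percent
    ci_high: float  # percent
    level: float
    method: str

    def rounded(self, decimals: int = 2) -> tuple[float, float, float]:
        return (
            round(self.proportion, decimals),
            round(self.ci_low, decimals),
            round(self.ci_high, decimals),
        )

    def __str__(self) -> str:
        p, lo, hi = self.rounded()
        return f"{p:.2f} ({lo:.2f}-{hi:.2f})"


def impairment_proportion_ci(
    k: int, n: int, level: float = 0.95, method: str = "wald"
) -> ProportionCI:
    """Binomial proportion with a confidence interval, reported in percent.

    Wald: p_hat +/- z_{alpha/2} * sqrt(p_hat (1 - p_hat) / n), clipped to
    [0, 100].  Degenerate at k in {0, n} (zero-width interval; a warning is
    issued).  ``method="wilson"`` gives the Wilson score interval instead.
    """
    if n < 1:
        raise DataError("n must be >= 1")
    if not 0 <= k <= n:
        raise DataError("need 0 <= k <= n")
    p = k / n
    z = stats.norm.ppf(1 - (1 - level) / 2)
    if method == "wald":
        half = z * np.sqrt(p * (1 - p) / n)
        lo, hi = p - half, p + half
        if k in (0, n):
            warnings.warn("Wald interval collapses at k=0 or k=n")
    elif method == "wilson":
        denom = 1 + z**2 / n
        center = (p + z**2 / (2 * n)) / denom
        half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
        lo, hi = center - half, center + half
    else:
        raise ConfigurationError(f"unknown interval method {method!r}")
    return ProportionCI(
        k=int(k),
        n=int(n),
        proportion=100.0 * p,
        ci_low=float(np.clip(100.0 * lo, 0.0, 100.0)),
        ci_high=float(np.clip(100.0 * hi, 0.0, 100.0)),
        level=level,
        method=method,
    )


# ---------------------------------------------------------------------------
# reference-population comparison
# ---------------------------------------------------------------------------


def one_sample_vs_reference(
    scores: np.ndarray | pd.Series, mu: float = 0.0
) -> tuple[float, int, float]:
    """Classical one-sample t-test of a measure against the reference
    population mean (mu = 0, sigma = 1 for age-adjusted z-scores).

    Returns (t, df, two-sided p).
    """
    x = np.asarray(scores, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 2:
        raise DataError("need at least 2 observations")
    if np.ptp(x) == 0.0:
        raise DataError("zero variance sample")
    res = stats.ttest_1samp(x, popmean=mu)
    return float(res.statistic), int(len(x) - 1), float(res.pvalue)


# ---------------------------------------------------------------------------
# sex-stratified multivariable GLM
# ---------------------------------------------------------------------------


@dataclass
class GLMFit:
    outcome: str
    stratum: str
    response: str
    coefficients: pd.DataFrame  # index: term; columns: beta, se, p
    covariates: tuple[str, ...]
    n: int

    def beta(self, term: str) -> float:
        return float(self.coefficients.loc[term, "beta"])

    def se(self, term: str) -> float:
        return float(self.coefficients.loc[term, "se"])

    def p(self, term: str) -> float:
        return float(self.coefficients.loc[term, "p"])


def _check_full_rank(design: pd.DataFrame) -> None:
    x = design.to_numpy(float)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify columns involved in the collinearity via QR pivoting
        _, r = np.linalg.qr(x)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(x.shape) * np.finfo(float).eps
        bad = [c for c, d in zip(design.columns, diag) if d < tol]
        raise DataError(
            f"design is rank deficient (rank {rank} < {x.shape[1]}); "
            f"collinear column(s): {', '.join(bad) or 'unidentified'}"
        )


def glm_brain_exposure(
    subjects: pd.DataFrame,
    scores: pd.DataFrame,
    outcome_measure: str,
    region: str,
    stratum: str,
    exposures: tuple[str, ...] = ("dex_auc", "mtx_auc", "it_count"),
    covariates: tuple[str, ...] = ("age_dx", "age_eval", "icv"),
    response: str = "volume",
    one_sided: bool = False,
) -> GLMFit:
    """Sex-stratified multivariable linear model linking regional
    morphometry, chemotherapy exposure and a neurocognitive outcome,
    adjusting for age at diagnosis, age at assessment and intracranial
    volume.

    ``response="volume"`` (default) regresses the regional measurement on
    the neurocognitive z plus exposures, so coefficients carry the
    conventional units (mm^3 per 1-SD z; mm^3 per g x hr/L; mm^3 per
    intrathecal count).  ``response="score"`` regresses the z-score on the
    regional measurement plus exposures instead, matching the generative
    direction of the synthetic cohort.  ``one_sided=True`` halves p-values
    in the direction of the fitted sign.
    """
    import statsmodels.api as sm

    if response not in ("volume", "score"):
        raise ConfigurationError("response must be 'volume' or 'score'")
    sub = subjects[subjects["sex"] == stratum]
    if sub.empty:
        raise DataError(f"no subjects in stratum {stratum!r}")
    z = (
        scores[scores["measure"] == outcome_measure]
        .set_index("subject_id")["z"]
        .rename("z_score")
    )
    if z.empty:
        raise DataError(f"no scores for measure {outcome_measure!r}")
    if region not in sub.columns:
        raise DataError(f"region column {region!r} missing from subject table")
    for col in exposures + covariates:
        if col not in sub.columns:
            raise DataError(f"missing covariate {col!r}")

    merged = sub.set_index("subject_id").join(z, how="inner")
    if response == "volume":
        y = merged[region].astype(float)
        predictors = ["z_score", *exposures]
    else:
        y = merged["z_score"].astype(float)
        predictors = [region, *exposures]
    design = merged[[*predictors, *covariates]].astype(float)
    _check_full_rank(sm.add_constant(design))
    fit = sm.OLS(y, sm.add_constant(design)).fit()

    pvals = fit.pvalues / 2 if one_sided else fit.pvalues
    coef = pd.DataFrame(
        {"beta": fit.params, "se": fit.bse, "p": pvals}
    ).drop(index="const")
    return GLMFit(
        outcome=outcome_measure,
        stratum=stratum,
        response=response,
        coefficients=coef,
        covariates=tuple(covariates),
        n=int(fit.nobs),
    )


# ---------------------------------------------------------------------------
# correlation and FDR
# ---------------------------------------------------------------------------


def correlate(
    metric: np.ndarray | pd.Series, outcome: np.ndarray | pd.Series
) -> tuple[float, float]:
    """Pearson correlation with a two-sided t-based p-value."""
    x = np.asarray(metric, dtype=float)
    y = np.asarray(outcome, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(x) < 3:
        raise DataError("need at least 3 paired observations")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise DataError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def fdr_correct(
    p_values: np.ndarray | list[float], method: str = "by", alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """False-discovery-rate step-up correction.

    ``method="by"`` (default): Benjamini-Yekutieli, with the harmonic-sum
    factor c(m) = sum_{i<=m} 1/i, valid under arbitrary dependence;
    ``"bh"``: Benjamini-Hochberg.  Returns (adjusted p-values, reject
    flags at ``alpha``); adjusted values are monotone and clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise DataError("p-values must lie in [0, 1]")
    sm_method = {"by": "fdr_by", "bh": "fdr_bh"}.get(method)
    if sm_method is None:
        raise ConfigurationError(f"unknown FDR method {method!r}")
    reject, adjusted, _, _ = multipletests(p, alpha=alpha, method=sm_method)
    return adjusted, reject
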