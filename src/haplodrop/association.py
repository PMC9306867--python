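"""Fitness-association post-processing: design matrices, Wald tests, contrasts.

The fitness models themselves (zero-inflated Poisson lifetime breeding,
probit survival, Poisson lifespan, ordinal probit female annual breeding)
are typically fitted externally as Bayesian animal models with a pedigree
relatedness covariance; this module consumes either their posterior draws
or a (mean, covariance) summary and performs the downstream inference:

* a **Wald test** ``W = b' V^{-1} b`` over the haplotype-dosage
  coefficients (7 degrees of freedom for 8 haplotypes with one reference),
  asking whether haplotype identity explains variation in a fitness
  measure at all;
* per-haplotype **contrasts against the mean of the others**,
  ``c_i = b_i - mean_{j != i}(b_j)`` with the reference haplotype's effect
  fixed at 0 and included in the means, flagged when the equal-tailed 95%
  credible interval excludes zero.  The sequential convention is that
  contrasts are only interpreted after a significant Wald test; the caller
  enforces that.

A maximum-likelihood fixed-effects fitter (:func:`fit_glm`) covering the
same error families is provided for synthetic-data validation; it is not a
mixed model and carries no relatedness structure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .haplotypes import Diplotype, HaplotypeSet, diplotype_divergence, dosage_matrix, heterozygosity

logger = logging.getLogger(__name__)

__all__ = [
    "CoefficientSummary",
    "PosteriorDraws",
    "build_design",
    "wald_test",
    "haplotype_vs_rest_contrasts",
    "fit_glm",
    "GLM_FAMILIES",
    "ConvergenceError",
]

GLM_FAMILIES = ("binomial_probit", "poisson_log", "zero_inflated_poisson", "ordinal_probit")


class ConvergenceError(RuntimeError):
    """Raised when a maximum-likelihood fit fails to converge."""


@dataclass
class CoefficientSummary:
    """Point estimates with covariance, as produced by any model fit."""

    mean: np.ndarray
    cov: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        if self.mean.shape[0] != self.cov.shape[0] or self.cov.shape[0] != self.cov.shape[1]:
            raise ValueError("mean / covariance dimensions disagree")
        if len(self.labels) != self.mean.shape[0]:
            raise ValueError("labels do not match coefficient count")
        if not np.allclose(self.cov, self.cov.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")

    def subset(self, labels: Sequence[str]) -> "CoefficientSummary":
        pos = [self.labels.index(l) for l in labels]
        return CoefficientSummary(
            mean=self.mean[pos],
            cov=self.cov[np.ix_(pos, pos)],
            labels=tuple(labels),
        )


@dataclass
class PosteriorDraws:
    """Matrix of posterior samples (rows) over labelled coefficients (columns)."""

    draws: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.draws = np.atleast_2d(np.asarray(self.draws, dtype=float))
        if self.draws.shape[0] < 2:
            raise ValueError("need at least two posterior draws")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("coefficient labels must be unique")
        if self.draws.shape[1] != len(self.labels):
            raise ValueError("draw matrix width does not match labels")

    @classmethod
    def from_file(cls, path: str | Path) -> "PosteriorDraws":
        sep = "," if str(path).endswith(".csv") else "\t"
        df = pd.read_csv(path, sep=sep)
        return cls(draws=df.to_numpy(dtype=float), labels=tuple(df.columns))

    def summary(self) -> CoefficientSummary:
        return CoefficientSummary(
            mean=self.draws.mean(axis=0),
            cov=np.cov(self.draws, rowvar=False),
            labels=self.labels,
        )


def build_design(
    diplotypes: Mapping[str, tuple[str, str]],
    hs: HaplotypeSet,
    reference: str = "H",
    covariates: pd.DataFrame | None = None,
    include_heterozygosity: bool = False,
    include_divergence: bool = False,
    intercept: bool = True,
) -> pd.DataFrame:
    """Design matrix with per-haplotype dosage columns (reference omitted).

    With K haplotypes this yields K-1 dosage columns named ``hap_<label>``,
    so individual-haplotype effects are expressed relative to the
    reference.  Optional heterozygosity / divergence columns and arbitrary
    covariates are appended; column order is intercept, dosages, MHC
    summaries, covariates.
    """
    if reference not in hs.names:
        raise ValueError(f"reference haplotype {reference!r} not in haplotype set")
    dos = dosage_matrix(diplotypes, hs)
    parts = []
    if intercept:
        parts.append(pd.DataFrame({"const": np.ones(len(dos))}, index=dos.index))
    dosage_cols = dos[[h for h in hs.names if h != reference]]
    dosage_cols = dosage_cols.rename(columns=lambda h: f"hap_{h}")
    parts.append(dosage_cols)
    if include_heterozygosity or include_divergence:
        extra = {}
        dips = {i: Diplotype(i, h1, h2) for i, (h1, h2) in diplotypes.items()}
        if include_heterozygosity:
            extra["mhc_het"] = [heterozygosity(dips[i]) for i in dos.index]
        if include_divergence:
            extra["mhc_div"] = [diplotype_divergence(dips[i], hs) for i in dos.index]
        parts.append(pd.DataFrame(extra, index=dos.index))
    if covariates is not None:
        parts.append(covariates.loc[dos.index])
    return pd.concat(parts, axis=1)


def wald_test(
    summary: CoefficientSummary,
    subset: Sequence[str],
    allow_pinv: bool = True,
) -> tuple[float, int, float]:
    """Wald test of H0: all ``subset`` coefficients are zero.

    Returns (statistic, df, p) with ``W = b' V^{-1} b`` and p from the
    upper tail of chi-square with df = len(subset).  A singular
    sub-covariance falls back to the Moore-Penrose pseudo-inverse (logged)
    unless ``allow_pinv`` is False.
    """
    sub = summary.subset(subset)
    b, v = sub.mean, sub.cov
    try:
        w = float(b @ np.linalg.solve(v, b))
    except np.linalg.LinAlgError:
        if not allow_pinv:
            raise
        logger.warning("singular covariance in Wald test; using pseudo-inverse")
        w = float(b @ np.linalg.pinv(v) @ b)
    df = len(subset)
    return w, df, float(stats.chi2.sf(w, df))


def haplotype_vs_rest_contrasts(
    draws: PosteriorDraws,
    haplotype_labels: Sequence[str],
    reference: str | None = None,
    interval: float = 0.95,
) -> pd.DataFrame:
    """Per-haplotype contrast against the mean of all other haplotypes.

    ``haplotype_labels`` names the columns of ``draws`` holding haplotype
    coefficients; if ``reference`` is given it is treated as an additional
    haplotype whose effect is identically 0 in every draw (the usual
    reference-coding convention) and is included both as a contrast row
    and in the "rest" means.  ``flagged`` marks contrasts whose
    equal-tailed credible interval excludes zero.
    """
    cols = {l: i for i, l in enumerate(draws.labels)}
    missing = [l for l in haplotype_labels if l not in cols]
    if missing:
        raise ValueError(f"labels not present in draws: {missing}")
    mat = draws.draws[:, [cols[l] for l in haplotype_labels]]
    names = list(haplotype_labels)
    if reference is not None:
        if reference in names:
            raise ValueError(f"reference {reference!r} duplicated in haplotype labels")
        mat = np.hstack([mat, np.zeros((mat.shape[0], 1))])
        names.append(reference)
    k = mat.shape[1]
    if k < 2:
        raise ValueError("need at least two haplotypes for contrasts")
    total = mat.sum(axis=1, keepdims=True)
    # b_i - mean of the others, in the numerically symmetric form
    contrasts = (k * mat - total) / (k - 1)
    lo_q, hi_q = (1 - interval) / 2, 1 - (1 - interval) / 2
    lo = np.quantile(contrasts, lo_q, axis=0)
    hi = np.quantile(contrasts, hi_q, axis=0)
    est = contrasts.mean(axis=0)
    # interval exclusion of zero, with an absolute guard against float
    # residue from the contrast arithmetic (degenerate draws give +/-1e-16)
    tol = 1e-12
    return pd.DataFrame(
        {
            "haplotype": names,
            "estimate": est,
            "lower": lo,
            "upper": hi,
            "flagged": (lo > tol) | (hi < -tol),
        }
    )


def _check_converged(result, family: str) -> None:
    retvals = getattr(result, "mle_retvals", None)
    if retvals is not None and not retvals.get("converged", True):
        raise ConvergenceError(f"{family} fit did not converge: {retvals}")


def fit_glm(
    response: Sequence[float] | np.ndarray,
    design: pd.DataFrame,
    family: str,
    zero_inflation_fixed: float | None = None,
    maxiter: int = 500,
) -> CoefficientSummary:
    """Maximum-likelihood fixed-effects fit for the supported error families.

    Families: ``binomial_probit`` (0/1 response), ``poisson_log`` (counts),
    ``zero_inflated_poisson`` (counts, logit-scale inflation intercept
    shared across individuals), ``ordinal_probit`` (ordered categories; the
    design must not contain an intercept column, which is absorbed into
    the thresholds).  The covariance is the inverse observed information.

    ``zero_inflation_fixed=0`` collapses the zero-inflated model to its
    nested plain Poisson, which is then fitted directly.

    Perfect separation in the probit family triggers a warned, lightly
    ridge-regularised refit rather than an error.
    """
    import statsmodels.api as sm
    from statsmodels.discrete.count_model import ZeroInflatedPoisson
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    y = np.asarray(response, dtype=float)
    x = np.asarray(design, dtype=float)
    labels = tuple(design.columns)

    if family == "binomial_probit":
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError("binomial_probit requires a 0/1 response")
        model = sm.Probit(y, x)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", category=RuntimeWarning)
                res = model.fit(disp=0, maxiter=maxiter)
            _check_converged(res, family)
        except Exception:
            logger.warning("probit fit unstable (possible separation); ridge fallback")
            res = model.fit_regularized(alpha=1e-4, L1_wt=0.0, disp=0, maxiter=maxiter)
            hess = model.hessian(res.params)
            cov = np.linalg.inv(-hess + 1e-8 * np.eye(len(res.params)))
            return CoefficientSummary(np.asarray(res.params), cov, labels)
        return CoefficientSummary(np.asarray(res.params), np.asarray(res.cov_params()), labels)

    if family == "poisson_log" or (
        family == "zero_inflated_poisson" and zero_inflation_fixed == 0
    ):
        res = sm.Poisson(y, x).fit(disp=0, maxiter=maxiter)
        _check_converged(res, family)
        return CoefficientSummary(np.asarray(res.params), np.asarray(res.cov_params()), labels)

    if family == "zero_inflated_poisson":
        if zero_inflation_fixed is not None:
            raise ValueError("only zero_inflation_fixed=0 (nested Poisson) is supported")
        model = ZeroInflatedPoisson(y, x, exog_infl=np.ones((len(y), 1)), inflation="logit")
        res = model.fit(disp=0, maxiter=maxiter, method="bfgs")
        _check_converged(res, family)
        zip_labels = ("inflate_const",) + labels
        return CoefficientSummary(np.asarray(res.params), np.asarray(res.cov_params()), zip_labels)

    if family == "ordinal_probit":
        if "const" in design.columns:
            raise ValueError(
                "ordinal_probit design must not include an intercept column "
                "(thresholds absorb it)"
            )
        model = OrderedModel(y, x, distr="probit")
        res = model.fit(method="bfgs", disp=0, maxiter=maxiter)
        _check_converged(res, family)
        n_thresh = len(res.params) - len(labels)
        all_labels = labels + tuple(f"threshold_{i}" for i in range(n_thresh))
        return CoefficientSummary(np.asarray(res.params), np.asarray(res.cov_params()), all_labels)

    raise ValueError(f"unknown family {family!r}; choose from {GLM_FAMILIES}")
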