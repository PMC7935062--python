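"""Phylogenetic generalized least squares for FLP trait associations.

The binary FLP state (present/absent) is regressed on socioecological
predictors under a Brownian-motion error covariance implied by the
phylogeny — the generalized least squares formulation equivalent to
phylogenetically independent contrasts.  The response is treated as 0/1
Gaussian, matching the standard caper-style comparative analysis; a
phylogenetic logistic model is deliberately out of scope.

Two standard model families are provided: a *social* model (migratory
status, social dominance, body length) and a *climate* model (mean
temperature, mean precipitation, and the predictability of each), each
fittable with or without sexually monochromic species.
"""

from __future__ import annotations

import dataclasses
import logging

import dendropy
import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats

from . import trees
from .errors import InsufficientDataError, InvalidArgumentError

__all__ = ["PGLSFit", "brownian_vcv", "pgls_fit", "run_flp_models",
           "SOCIAL_PREDICTORS", "CLIMATE_PREDICTORS"]

log = logging.getLogger(__name__)

brownian_vcv = trees.brownian_vcv

SOCIAL_PREDICTORS = ("migratory", "dominance", "body_length")
CLIMATE_PREDICTORS = ("mean_temperature", "mean_precipitation",
                      "temperature_predictability",
                      "precipitation_predictability")


@dataclasses.dataclass
class PGLSFit:
    """Coefficient table and metadata from one generalized fit."""

    coefficients: pd.DataFrame  # index: term; estimate, se, t, p
    n_species: int
    df_resid: int
    sigma2: float
    log_likelihood: float
    covariance_model: str = "brownian"
    excluded_monochromic: bool = False
    model: str = ""

    def beta(self, term: str) -> float:
        return float(self.coefficients.loc[term, "estimate"])

    def p(self, term: str) -> float:
        return float(self.coefficients.loc[term, "p"])


def pgls_fit(response, design: pd.DataFrame, covariance: np.ndarray,
             ) -> PGLSFit:
    """Generalized least squares with a fixed error covariance.

    Solves ``b = (X' V^-1 X)^-1 X' V^-1 y`` with ``sigma^2`` from the
    V-weighted residual sum of squares; standard errors from
    ``sigma^2 (X' V^-1 X)^-1`` and two-sided p-values on ``n - p`` degrees
    of freedom.  With ``V = I`` this reduces exactly to OLS.  A ridge of
    1e-10 is added (and logged) if V is not positive definite.
    """
    y = np.asarray(response, dtype=float).ravel()
    X = design.to_numpy(dtype=float)
    V = np.asarray(covariance, dtype=float)
    n, p = X.shape
    if y.size != n or V.shape != (n, n):
        raise InvalidArgumentError("response, design and covariance "
                                   "dimensions do not align")
    if n <= p:
        raise InsufficientDataError(f"n={n} rows for p={p} parameters")
    try:
        Lch = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        log.warning("covariance not positive definite; adding 1e-10 ridge")
        Lch = np.linalg.cholesky(V + 1e-10 * np.eye(n))
    # whiten: solve L z = x  =>  z' z = x' V^-1 x
    Xw = scipy.linalg.solve_triangular(Lch, X, lower=True)
    yw = scipy.linalg.solve_triangular(Lch, y, lower=True)
    rank = np.linalg.matrix_rank(Xw)
    if rank < p:
        # name the offending columns for the caller
        bad = []
        for j in range(p):
            others = np.delete(Xw, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(design.columns[j])
        raise InvalidArgumentError(
            f"rank-deficient design (rank {rank} < {p}); "
            f"collinear columns include {bad}")
    XtX = Xw.T @ Xw
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    resid = yw - Xw @ beta
    df = n - p
    sigma2 = float(resid @ resid) / df
    cov_beta = sigma2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov_beta))
    tvals = beta / se
    pvals = 2.0 * scipy.stats.t.sf(np.abs(tvals), df)
    logdet = 2.0 * float(np.sum(np.log(np.diag(Lch))))
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2 * df / n)
                 + logdet + n)
    coef = pd.DataFrame(
        {"estimate": beta, "se": se, "t": tvals, "p": pvals},
        index=list(design.columns))
    return PGLSFit(coefficients=coef, n_species=n, df_resid=df,
                   sigma2=sigma2, log_likelihood=float(ll))


def run_flp_models(covariates: pd.DataFrame, tree: dendropy.Tree,
                   model: str = "social",
                   exclude_monochromic: bool = False) -> PGLSFit:
    """Fit the social or climate PGLS model of binary FLP.

    Filters species (optionally dropping monochromic ones and any lacking
    complete predictors or a tip in the tree), prunes the tree to match,
    builds the Brownian covariance, and fits FLP ~ predictors with an
    intercept.
    """
    if model == "social":
        predictors = list(SOCIAL_PREDICTORS)
    elif model == "climate":
        predictors = list(CLIMATE_PREDICTORS)
    else:
        raise InvalidArgumentError("model must be 'social' or 'climate'")
    missing = [c for c in predictors + ["species", "flp"]
               if c not in covariates.columns]
    if missing:
        raise InvalidArgumentError(f"covariate table lacks columns {missing}")
    df = covariates.dropna(subset=predictors + ["flp"]).copy()
    if exclude_monochromic and "chromatism" in df.columns:
        df = df[df["chromatism"] != "monochromic"]
    in_tree = set(trees.tip_labels(tree))
    df = df[df["species"].isin(in_tree)]
    if len(df) < 10:
        raise InsufficientDataError(
            f"only {len(df)} species left after filtering")
    sub = (tree if len(df) == len(in_tree)
           else trees.prune_to_data(tree, df["species"].tolist()))
    V, labels = trees.brownian_vcv(sub)
    df = df.set_index("species").loc[labels]
    design = pd.DataFrame({"intercept": np.ones(len(df))}, index=df.index)
    for c in predictors:
        design[c] = df[c].astype(float)
    fit = pgls_fit(df["flp"].to_numpy(dtype=float), design, V)
    fit.excluded_monochromic = exclude_monochromic
    fit.model = model
    return fit
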