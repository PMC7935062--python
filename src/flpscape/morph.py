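"""Discriminant androchromy scoring and morphological regressions.

Within each species a two-group Fisher discriminant is trained on patch
colors of androchrome males versus Class-1 (fully heterochromic) females.
Projecting all specimens onto this axis yields a continuous LD1 score of
androchromy — oriented and standardized so the male training mean sits at
+1 and the Class-1 female training mean at -1.  Relative bill length
(a specimen's bill minus its species mean) is then regressed on LD1 over
females to ask whether male-like plumage comes with male-like bills; a
Bonferroni-corrected per-test alpha controls the family-wise error across
species, and Blomberg's K asks whether the fitted slopes carry
phylogenetic signal.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, NamedTuple, Sequence

import dendropy
import numpy as np
import pandas as pd
import scipy.stats
from sklearn.decomposition import PCA

from . import trees
from .errors import (InsufficientDataError, InvalidArgumentError,
                     MissingDataError)

__all__ = [
    "DiscriminantAxis", "SlopeResult", "BonferroniAlpha",
    "train_discriminant", "project_ld1", "relative_measure",
    "fit_morph_slope", "bonferroni_alpha", "blomberg_k",
    "run_morph_analysis",
]

MEASUREMENTS = ("bill", "wing", "bill_over_wing")


@dataclasses.dataclass
class DiscriminantAxis:
    """Stored per-species discriminant: standardization, reduction, axis.

    ``weights`` is unit-norm in the reduced (principal component) space;
    the affine standardization (``center``, ``scale``) maps the training
    male mean to +1 and the Class-1 female mean to -1.
    """

    species: str
    feature_cols: list[str]
    mu: np.ndarray
    sigma: np.ndarray
    pca: PCA
    weights: np.ndarray
    center: float
    scale: float
    validated: bool
    n_males: int
    n_females: int


class BonferroniAlpha(NamedTuple):
    exact: float
    rounded: float


@dataclasses.dataclass
class SlopeResult:
    species: str
    measurement: str
    slope: float
    se: float
    p_value: float
    n_females: int
    significant: bool


def _color_features(df: pd.DataFrame) -> list[str]:
    cols = [c for c in df.columns if c.startswith("patch")]
    if not cols:
        raise InvalidArgumentError("no patchNN_R/G/B columns found")
    return cols


def _fisher_axis(X: np.ndarray, y: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray, PCA, np.ndarray]:
    """Standardize, reduce, and fit the two-group Fisher direction."""
    n_train = len(X)
    mu = X.mean(axis=0)
    sigma = X.std(axis=0, ddof=0)
    sigma[sigma == 0] = 1.0
    Z = (X - mu) / sigma
    max_comp = min(n_train - 2, Z.shape[1])
    pca = PCA(n_components=max_comp, svd_solver="full")
    R_full = pca.fit_transform(Z)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_comp = max(1, min(int(np.searchsorted(cum, 0.95) + 1), max_comp))
    R = R_full[:, :n_comp]
    m1, m0 = R[y == 1].mean(axis=0), R[y == 0].mean(axis=0)
    d1, d0 = R[y == 1] - m1, R[y == 0] - m0
    Sw = np.atleast_2d(d1.T @ d1 + d0.T @ d0)  # pooled within-class scatter
    try:
        w = np.linalg.solve(Sw, m1 - m0)
    except np.linalg.LinAlgError:
        w = np.linalg.pinv(Sw) @ (m1 - m0)
    norm = np.linalg.norm(w)
    if not np.isfinite(norm) or norm == 0:
        raise InvalidArgumentError(
            f"singular pooled covariance after reduction "
            f"(n_comp={n_comp}, n_train={n_train})")
    w = w / norm
    if (R @ w)[y == 1].mean() < (R @ w)[y == 0].mean():
        w = -w
    pca.components_ = pca.components_[:n_comp]
    pca.explained_variance_ = pca.explained_variance_[:n_comp]
    pca.explained_variance_ratio_ = pca.explained_variance_ratio_[:n_comp]
    pca.n_components_ = n_comp
    return mu, sigma, pca, w


def _loo_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Leave-one-out LD1 score of each training specimen."""
    out = np.empty(len(X))
    for i in range(len(X)):
        keep = np.arange(len(X)) != i
        try:
            mu, sigma, pca, w = _fisher_axis(X[keep], y[keep])
        except InvalidArgumentError:
            return np.zeros(len(X))  # cannot refit: treat as inseparable
        z = (X[i] - mu) / sigma
        out[i] = (z @ pca.components_.T) @ w
    return out


def train_discriminant(color_records: pd.DataFrame, species: str,
                       min_group: int = 3,
                       validation: str = "loo") -> DiscriminantAxis:
    """Fisher discriminant separating androchrome males from Class-1 females.

    Features are standardized, reduced to leading principal components
    (capped at ``n_train - 2``, retaining >= 95% of variance), and a
    two-group Fisher axis is computed on the reduced space.  The axis is
    ``validated`` iff the training groups can be told apart on LD1.  The
    default criterion (``'loo'``) demands non-overlapping *leave-one-out*
    score ranges: with tens of color channels and ~16 training skins the
    in-sample ranges separate even for identical groups, so the resampled
    check is what distinguishes real separation from overfitting.
    ``'no_overlap'`` uses the in-sample ranges; ``'2sd'`` requires the mean
    separation to exceed twice the pooled within-group SD.
    """
    sub = color_records[color_records["species"] == species]
    cols = _color_features(color_records)
    males = sub[(sub["sex"] == "male") & (sub["plumage_class"] >= 3)]
    females = sub[(sub["sex"] == "female") & (sub["plumage_class"] == 1)]
    if len(males) < min_group or len(females) < min_group:
        raise InsufficientDataError(
            f"{species}: need >= {min_group} androchrome males and Class-1 "
            f"females, got {len(males)} / {len(females)}")
    X = pd.concat([males, females])[cols].to_numpy(dtype=float)
    y = np.concatenate([np.ones(len(males)), np.zeros(len(females))])
    if not np.all(np.isfinite(X)):
        raise MissingDataError(f"{species}: non-finite patch values")
    try:
        mu, sigma, pca, w = _fisher_axis(X, y)
    except InvalidArgumentError as exc:
        raise InvalidArgumentError(f"{species}: {exc}") from None
    proj = ((X - mu) / sigma) @ pca.components_.T @ w
    pm, pf = proj[y == 1], proj[y == 0]
    center = 0.5 * (pm.mean() + pf.mean())
    scale = 0.5 * (pm.mean() - pf.mean())
    if validation == "loo":
        loo = _loo_scores(X, y)
        validated = bool(loo[y == 1].min() > loo[y == 0].max())
    elif validation == "no_overlap":
        validated = bool(pm.min() > pf.max())
    elif validation == "2sd":
        pooled = np.sqrt(0.5 * (pm.var(ddof=1) + pf.var(ddof=1)))
        validated = bool(pm.mean() - pf.mean() > 2.0 * pooled)
    else:
        raise InvalidArgumentError(f"unknown validation rule {validation!r}")
    if scale <= 0:
        validated = False
        scale = 1.0
    return DiscriminantAxis(
        species=species, feature_cols=cols, mu=mu, sigma=sigma, pca=pca,
        weights=w, center=center, scale=scale, validated=validated,
        n_males=len(males), n_females=len(females))


def project_ld1(axis: DiscriminantAxis, color_records: pd.DataFrame,
                allow_unvalidated: bool = False) -> pd.Series:
    """LD1 scores for specimens of the axis's species.

    Scores are the stored affine projection: the androchrome-male training
    mean maps to +1, the Class-1 female mean to -1, their midpoint to 0.
    """
    if not axis.validated and not allow_unvalidated:
        raise InvalidArgumentError(
            f"{axis.species}: discriminant axis failed validation")
    sub = color_records[color_records["species"] == axis.species]
    missing = [c for c in axis.feature_cols if c not in sub.columns]
    if missing:
        raise MissingDataError(f"missing patch columns: {missing}")
    X = sub[axis.feature_cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        bad = [axis.feature_cols[j]
               for j in np.unique(np.nonzero(~np.isfinite(X))[1])]
        raise MissingDataError(f"non-finite patch values in: {bad}")
    Z = (X - axis.mu) / axis.sigma
    R = Z @ axis.pca.components_.T
    scores = (R @ axis.weights - axis.center) / axis.scale
    return pd.Series(scores, index=sub["specimen"].to_numpy(), name="ld1")


def relative_measure(morpho_records: pd.DataFrame, species: str,
                     measurement: str = "bill") -> pd.Series:
    """Within-species centered morphometric (both sexes in the mean)."""
    if measurement not in MEASUREMENTS:
        raise InvalidArgumentError(
            f"measurement must be one of {MEASUREMENTS}")
    sub = morpho_records[morpho_records["species"] == species]
    if len(sub) < 2:
        raise InsufficientDataError(
            f"{species}: need >= 2 specimens, got {len(sub)}")
    if measurement == "bill":
        vals = sub["bill_mm"].astype(float)
    elif measurement == "wing":
        vals = sub["wing_mm"].astype(float)
    else:
        wing = sub["wing_mm"].astype(float)
        if (wing == 0).any():
            raise InvalidArgumentError(
                f"{species}: zero wing length in bill/wing ratio")
        vals = sub["bill_mm"].astype(float) / wing
    centered = vals - vals.mean()
    return pd.Series(centered.to_numpy(), index=sub["specimen"].to_numpy(),
                     name=f"relative_{measurement}")


def fit_morph_slope(ld1_scores: pd.Series, relative_values: pd.Series,
                    female_specimens: Sequence[str], alpha: float,
                    species: str = "", measurement: str = "bill",
                    ) -> SlopeResult:
    """OLS of a relative morphometric on LD1 over female specimens.

    Males contribute to axis training and species-mean centering but not
    to the regression.  Two-sided t-test on the slope; significance at
    ``alpha``.
    """
    idx = [s for s in female_specimens
           if s in ld1_scores.index and s in relative_values.index]
    if len(idx) < 3:
        raise InsufficientDataError(
            f"{species}: need >= 3 females with LD1 and morphometrics, "
            f"got {len(idx)}")
    x = ld1_scores.loc[idx].to_numpy(dtype=float)
    y = relative_values.loc[idx].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise InvalidArgumentError(f"{species}: zero LD1 variance")
    res = scipy.stats.linregress(x, y)
    return SlopeResult(
        species=species, measurement=measurement,
        slope=float(res.slope), se=float(res.stderr),
        p_value=float(res.pvalue), n_females=len(idx),
        significant=bool(res.pvalue < alpha))


def bonferroni_alpha(n_tests: int, family_alpha: float = 0.05,
                     ) -> BonferroniAlpha:
    """Per-test alpha = family_alpha / n_tests (exact and 2-significant-figure)."""
    if n_tests < 1:
        raise InvalidArgumentError("n_tests must be >= 1")
    if not 0.0 < family_alpha < 1.0:
        raise InvalidArgumentError("family_alpha must be in (0, 1)")
    exact = family_alpha / n_tests
    digits = -int(np.floor(np.log10(exact))) + 1
    return BonferroniAlpha(exact=exact, rounded=round(exact, digits))


def blomberg_k(tree: dendropy.Tree, species_values: Mapping[str, float],
               n_perm: int = 999, seed: int | None = None,
               ) -> tuple[float, float]:
    """Blomberg's K and a one-tailed permutation p-value.

    K compares the observed ratio of tip variance around the
    phylogenetically corrected mean (MSE0) to the phylogenetically
    standardized error (MSE, the V-inverse quadratic form) against its
    Brownian-motion expectation from trace identities of the tree's
    covariance matrix.  K ~ 1 under Brownian evolution; K < 1 means less
    signal than Brownian expectation.  The p-value is the fraction of
    tip-label permutations with K at least as large as observed.
    """
    shared = [lb for lb in trees.tip_labels(tree) if lb in species_values]
    if len(shared) < 4:
        raise InsufficientDataError(
            f"need >= 4 species shared between tree and values, "
            f"got {len(shared)}")
    sub = (tree if len(shared) == len(trees.tip_labels(tree))
           else trees.prune_to_data(tree, shared))
    V, labels = trees.brownian_vcv(sub)
    x = np.array([float(species_values[lb]) for lb in labels])
    if np.ptp(x) == 0:
        raise InvalidArgumentError("trait is constant; K undefined")
    n = len(x)
    Vinv = np.linalg.inv(V)
    ones = np.ones(n)
    denom_mean = float(ones @ Vinv @ ones)
    expected = (np.trace(V) - n / denom_mean) / (n - 1)

    def k_of(vals: np.ndarray) -> float:
        ahat = float(ones @ Vinv @ vals) / denom_mean
        d = vals - ahat
        mse0 = float(d @ d) / (n - 1)
        mse = float(d @ Vinv @ d) / (n - 1)
        return (mse0 / mse) / expected

    k_obs = k_of(x)
    rng = np.random.default_rng(None if seed is None else [int(seed), 0x_B10])
    perms = np.array([k_of(rng.permutation(x)) for _ in range(n_perm)])
    p = float(np.mean(perms >= k_obs))
    return float(k_obs), p


def run_morph_analysis(color_df: pd.DataFrame, morpho_df: pd.DataFrame,
                       measurement: str = "bill", family_alpha: float = 0.05,
                       min_group: int = 3, validation: str = "loo",
                       ) -> tuple[pd.DataFrame, BonferroniAlpha]:
    """Per-species discriminant + slope pipeline over a color/morpho panel.

    Trains an axis per species, drops species whose axis fails validation
    (or cannot be trained), sets the Bonferroni alpha from the number of
    species actually tested, and fits the female slope of the relative
    morphometric on LD1.  Returns the slope table and the alpha used.
    """
    axes = {}
    for sp in sorted(color_df["species"].unique()):
        try:
            ax = train_discriminant(color_df, sp, min_group=min_group,
                                    validation=validation)
        except (InsufficientDataError, InvalidArgumentError):
            continue
        if ax.validated:
            axes[sp] = ax
    if not axes:
        raise InsufficientDataError("no species with a validated axis")
    alpha = bonferroni_alpha(len(axes), family_alpha)
    rows = []
    for sp, ax in axes.items():
        ld1 = project_ld1(ax, color_df)
        rel = relative_measure(morpho_df, sp, measurement)
        females = morpho_df.loc[
            (morpho_df["species"] == sp) & (morpho_df["sex"] == "female"),
            "specimen"]
        try:
            res = fit_morph_slope(ld1, rel, list(females), alpha.exact,
                                  species=sp, measurement=measurement)
        except (InsufficientDataError, InvalidArgumentError):
            continue
        rows.append(dataclasses.asdict(res))
    return pd.DataFrame(rows), alpha
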