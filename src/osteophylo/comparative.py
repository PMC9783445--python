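"""Phylogenetic generalized least squares with ML/REML-optimized Pagel's
lambda and tip-height variance weights, phylogenetic ANCOVA, Nagelkerke
pseudo-R-squared, body-mass imputation from cross-sectional area, and
size-correction residuals.

The error covariance of the GLS is W(lambda) = lambda-scaled phylogenetic
covariance with the diagonal left at tip heights.  On an ultrametric tree
this is the familiar Pagel-lambda PGLS; on a non-ultrametric tree the
unequal diagonal doubles as the variance-heterogeneity weights (a fossil
tip that ends above the present has accumulated less variance).  The
profile (restricted) log-likelihood is maximized over lambda in [0, 1] by
bounded one-dimensional optimization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .trees import TimeTree, phylo_vcv

__all__ = [
    "PGLSFit",
    "pgls_fit",
    "phylo_ancova",
    "nagelkerke_pseudo_r2",
    "predict_body_mass",
    "size_correct",
    "match_species",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class PGLSFit:
    """Result of a lambda-PGLS fit."""

    beta: np.ndarray
    se: np.ndarray
    tstat: np.ndarray
    pvalue: np.ndarray
    coef_names: list[str]
    lambda_hat: float
    loglik: float  # at lambda_hat, under the fitting criterion
    loglik_ml: float  # ML log-likelihood at lambda_hat (for pseudo-R^2)
    sigma2_hat: float
    residuals: np.ndarray
    n: int
    p: int
    method: str
    tip_names: list[str] = field(default_factory=list)
    pseudo_r2: float | None = None
    group_test: dict | None = None  # {"F":..., "df":(q, n-p), "p":...}

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.beta,
                "se": self.se,
                "t": self.tstat,
                "p": self.pvalue,
            },
            index=self.coef_names,
        )


def _profile_loglik(
    lam: float,
    y: np.ndarray,
    X: np.ndarray,
    V1: np.ndarray,
    reml: bool,
) -> tuple[float, np.ndarray, float, np.ndarray]:
    """Profile log-likelihood at lambda (sigma2 profiled out analytically).

    Returns (loglik, beta, sigma2_hat, residuals).
    """
    n, p = X.shape
    W = lam * V1
    np.fill_diagonal(W, np.diag(V1))
    try:
        cho = cho_factor(W, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate trees
        raise ValueError(f"non-PSD weight matrix at lambda={lam}: {exc}") from exc
    logdet_W = 2.0 * np.sum(np.log(np.diag(cho[0])))
    Wi_X = cho_solve(cho, X)
    Wi_y = cho_solve(cho, y)
    XtWiX = X.T @ Wi_X
    beta = np.linalg.solve(XtWiX, X.T @ Wi_y)
    r = y - X @ beta
    rss = max(float(r @ cho_solve(cho, r)), 1e-30)  # guard exact fits
    if reml:
        df = n - p
        sigma2 = rss / df
        sign, logdet_XtWiX = np.linalg.slogdet(XtWiX)
        ll = -0.5 * (
            df * (_LOG2PI + np.log(sigma2)) + logdet_W + logdet_XtWiX + df
        )
    else:
        sigma2 = rss / n
        ll = -0.5 * (n * (_LOG2PI + np.log(sigma2)) + logdet_W + n)
    return ll, beta, sigma2, r


def pgls_fit(
    y: np.ndarray,
    X: np.ndarray,
    tree: TimeTree,
    tip_names: list[str] | None = None,
    coef_names: list[str] | None = None,
    method: str = "REML",
    lam: float | None = None,
) -> PGLSFit:
    """Fit y = X beta + eps, eps ~ N(0, sigma2 W(lambda)), lambda in [0, 1].

    Rows of ``y``/``X`` follow ``tip_names`` (default: tree tip order;
    a subset of the tree's tips is allowed — the corresponding covariance
    submatrix is used).  ``lam`` fixes lambda instead of optimizing it.
    Coefficient tests are two-sided t-tests on the GLS standard errors with
    n - p degrees of freedom.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        raise ValueError("y and X have incompatible shapes")
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need more observations than parameters plus one")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient design matrix")
    if method not in ("REML", "ML"):
        raise ValueError("method must be 'REML' or 'ML'")
    names = tip_names if tip_names is not None else tree.tip_names()
    _, V1 = phylo_vcv(tree, 1.0, tip_order=list(names))
    reml = method == "REML"

    if lam is None:
        res = optimize.minimize_scalar(
            lambda l: -_profile_loglik(l, y, X, V1, reml)[0],
            bounds=(0.0, 1.0),
            method="bounded",
            options={"xatol": 1e-6},
        )
        candidates = [float(res.x), 0.0, 1.0]
        lam_hat = max(
            candidates, key=lambda l: _profile_loglik(l, y, X, V1, reml)[0]
        )
    else:
        if not 0.0 <= lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        lam_hat = float(lam)

    ll, beta, sigma2, r = _profile_loglik(lam_hat, y, X, V1, reml)
    ll_ml = ll if not reml else _profile_loglik(lam_hat, y, X, V1, False)[0]

    # standard errors at lambda-hat
    W = lam_hat * V1
    np.fill_diagonal(W, np.diag(V1))
    cho = cho_factor(W, lower=True)
    XtWiX = X.T @ cho_solve(cho, X)
    s2_unbiased = float(r @ cho_solve(cho, r)) / (n - p)
    cov_beta = s2_unbiased * np.linalg.inv(XtWiX)
    se = np.sqrt(np.diag(cov_beta))
    tstat = beta / se
    pvalue = 2.0 * stats.t.sf(np.abs(tstat), df=n - p)

    return PGLSFit(
        beta=beta,
        se=se,
        tstat=tstat,
        pvalue=pvalue,
        coef_names=coef_names or [f"x{j}" for j in range(p)],
        lambda_hat=lam_hat,
        loglik=ll,
        loglik_ml=ll_ml,
        sigma2_hat=sigma2,
        residuals=r,
        n=n,
        p=p,
        method=method,
        tip_names=list(names),
    )


def phylo_ancova(
    trait: pd.Series,
    group: pd.Series,
    tree: TimeTree,
    covariate: pd.Series | None = None,
    method: str = "REML",
) -> PGLSFit:
    """Phylogenetic ANCOVA: trait ~ group (+ covariate) by lambda-PGLS.

    ``group`` is a categorical factor (e.g. lifestyle); the group effect is
    reported as a Wald F-test on the group dummy block in
    ``fit.group_test``.  Requires at least two groups with at least three
    members each.
    """
    species = trait.index.intersection(group.index)
    if covariate is not None:
        species = species.intersection(covariate.index)
    species = [s for s in tree.tip_names() if s in set(species)]
    if not species:
        raise ValueError("no species shared between trait table and tree")
    yv = trait.loc[species].astype(float)
    gv = group.loc[species]
    counts = gv.value_counts()
    if len(counts) < 2:
        raise ValueError("need at least two groups")
    small = counts[counts < 3]
    if len(small):
        raise ValueError(
            f"group(s) with fewer than 3 members: {dict(small)}"
        )
    levels = sorted(counts.index)
    cols = [np.ones(len(species))]
    names = ["intercept"]
    for lev in levels[1:]:
        cols.append((gv == lev).to_numpy(dtype=float))
        names.append(f"group[{lev}]")
    q = len(levels) - 1
    if covariate is not None:
        cols.append(covariate.loc[species].to_numpy(dtype=float))
        names.append("covariate")
    X = np.column_stack(cols)

    fit = pgls_fit(
        yv.to_numpy(), X, tree, tip_names=species, coef_names=names, method=method
    )

    # Wald F-test on the group block
    sel = slice(1, 1 + q)
    _, V1 = phylo_vcv(tree, 1.0, tip_order=species)
    W = fit.lambda_hat * V1
    np.fill_diagonal(W, np.diag(V1))
    cho = cho_factor(W, lower=True)
    XtWiX = X.T @ cho_solve(cho, X)
    s2 = float(fit.residuals @ cho_solve(cho, fit.residuals)) / (fit.n - fit.p)
    cov_beta = s2 * np.linalg.inv(XtWiX)
    b = fit.beta[sel]
    Fstat = float(b @ np.linalg.solve(cov_beta[sel, sel], b)) / q
    pF = float(stats.f.sf(Fstat, q, fit.n - fit.p))
    fit.group_test = {"F": Fstat, "df": (q, fit.n - fit.p), "p": pF}
    return fit


def nagelkerke_pseudo_r2(
    fit: PGLSFit, null_fit: PGLSFit, ceiling: bool = False
) -> float:
    """Likelihood-ratio pseudo-R-squared of a fit against its nested null.

    R2 = 1 - exp(-(2/n)(logL_full - logL_null)) on the ML log-likelihoods.
    For a continuous response the Nagelkerke ceiling term is not needed and
    is off by default; ``ceiling=True`` divides by
    1 - exp((2/n) logL_null), the maximum attainable value.
    """
    if fit.n != null_fit.n:
        raise ValueError("full and null fits use different data")
    n = fit.n
    d = fit.loglik_ml - null_fit.loglik_ml
    if d < -1e-8:
        warnings.warn(
            "full-model log-likelihood below the null's (lambda optimizer "
            "artifact); pseudo-R^2 clipped at 0",
            stacklevel=2,
        )
    r2 = 1.0 - np.exp(-2.0 * max(d, 0.0) / n)
    if ceiling:
        denom = 1.0 - np.exp(2.0 * null_fit.loglik_ml / n)
        if denom > 0:
            r2 /= denom
    return float(min(max(r2, 0.0), 1.0))


def _intercept_null(fit_y, species, tree, method):
    X0 = np.ones((len(species), 1))
    return pgls_fit(
        fit_y, X0, tree, tip_names=species, coef_names=["intercept"], method=method
    )


def predict_body_mass(
    table: pd.DataFrame,
    tree: TimeTree,
    mass_col: str = "body_mass_g",
    csa_col: str = "csa_mm2",
    method: str = "REML",
) -> tuple[pd.DataFrame, PGLSFit]:
    """Impute body mass from humeral cross-sectional area by PGLS allometry.

    log10(mass) is regressed on log10(CSA) over species with both known
    (extant database masses); predictions fill ``body_mass_pred_g`` for
    every species with a CSA (fossils included, flagged in
    ``body_mass_imputed``).  Species lacking a CSA keep their database
    mass.  The fit's ``pseudo_r2`` is against an intercept-only null.
    """
    table = table.copy()
    tips = set(tree.tip_names())
    known = table.index[
        table[mass_col].notna() & table[csa_col].notna() & table.index.isin(tips)
    ]
    if len(known) < 10:
        raise ValueError(
            f"need >= 10 species with both mass and CSA, found {len(known)}"
        )
    species = [s for s in tree.tip_names() if s in set(known)]
    y = np.log10(table.loc[species, mass_col].to_numpy(dtype=float))
    x = np.log10(table.loc[species, csa_col].to_numpy(dtype=float))
    X = np.column_stack([np.ones_like(x), x])
    fit = pgls_fit(
        y, X, tree, tip_names=species,
        coef_names=["intercept", "log10_csa"], method=method,
    )
    null = _intercept_null(y, species, tree, method)
    fit.pseudo_r2 = nagelkerke_pseudo_r2(fit, null)

    has_csa = table[csa_col].notna()
    pred = fit.beta[0] + fit.beta[1] * np.log10(
        table.loc[has_csa, csa_col].astype(float)
    )
    table["body_mass_pred_g"] = np.nan
    table.loc[has_csa, "body_mass_pred_g"] = 10.0**pred
    table.loc[~has_csa, "body_mass_pred_g"] = table.loc[~has_csa, mass_col]
    table["body_mass_imputed"] = has_csa & table[mass_col].isna()
    return table, fit


def size_correct(
    trait: pd.Series,
    body_mass: pd.Series,
    tree: TimeTree,
    method: str = "REML",
) -> tuple[pd.Series, PGLSFit]:
    """Residuals of PGLS(trait ~ log10 body mass): the size-corrected trait.

    These residuals feed the convergence test, the group summaries, and the
    phenograms.  With an intercept in the design they are invariant to a
    rescaling of mass units.
    """
    species = [
        s
        for s in tree.tip_names()
        if s in trait.index and s in body_mass.index
        and pd.notna(trait[s]) and pd.notna(body_mass[s])
    ]
    y = trait.loc[species].to_numpy(dtype=float)
    x = np.log10(body_mass.loc[species].to_numpy(dtype=float))
    X = np.column_stack([np.ones_like(x), x])
    fit = pgls_fit(
        y, X, tree, tip_names=species,
        coef_names=["intercept", "log10_mass"], method=method,
    )
    null = _intercept_null(y, species, tree, method)
    fit.pseudo_r2 = nagelkerke_pseudo_r2(fit, null)
    return pd.Series(fit.residuals, index=species, name=trait.name), fit


def match_species(
    tree: TimeTree, table_index: pd.Index
) -> dict[str, list[str]]:
    """Pre-flight exact, case-sensitive name matching report."""
    tips = set(tree.tip_names())
    tab = set(table_index)
    return {
        "matched": sorted(tips & tab),
        "tree_only": sorted(tips - tab),
        "table_only": sorted(tab - tips),
    }
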