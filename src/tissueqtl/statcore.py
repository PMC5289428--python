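"""Shared numerical core: OLS over many genes, empirical-Bayes variance
shrinkage, moderated t/F statistics, Benjamini-Hochberg adjustment and
Spearman rank correlation.

The moderated statistics follow the classical empirical-Bayes treatment of
gene-wise linear models: each gene g has residual variance s_g^2 on d_g
degrees of freedom, the variances are assumed exchangeable with a scaled
inverse-chi-square prior (d0, s0^2), and the posterior variance

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

replaces s_g^2 in t and F statistics, which then gain d0 extra degrees of
freedom.  Hyperparameters are estimated by moment-matching the log sample
variances against the scaled-F marginal (digamma/trigamma equations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "GeneFit",
    "GeneFitSet",
    "VariancePrior",
    "aliased_columns",
    "drop_aliased",
    "ols_fit",
    "estimate_variance_prior",
    "moderated_t",
    "moderated_f",
    "bh_adjust",
    "spearman_corr",
]

#: Sentinel prior df meaning "variances are effectively constant":
#: the posterior variance is s0^2 exactly and t statistics use normal tails.
INF_DF = np.inf


class AliasedDesignError(ValueError):
    """Design matrix is rank deficient after column screening."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; aliased columns: "
            + ", ".join(map(str, self.columns))
        )


def aliased_columns(design: pd.DataFrame, tol: float = 1e-9) -> list[str]:
    """Names of columns linearly dependent on the columns to their left.

    Scans left to right, so earlier columns win: with an intercept first,
    a redundant dummy later in the frame is the one reported.
    """
    X = np.asarray(design, dtype=float)
    aliased: list[str] = []
    kept: list[int] = []
    for j in range(X.shape[1]):
        cols = kept + [j]
        if np.linalg.matrix_rank(X[:, cols], tol=tol * max(1.0, np.abs(X).max())) == len(cols):
            kept.append(j)
        else:
            aliased.append(design.columns[j])
    return aliased


def drop_aliased(design: pd.DataFrame, keep: tuple[str, ...] = ()) -> tuple[pd.DataFrame, list[str]]:
    """Return (reduced design, dropped column names).

    Columns named in ``keep`` are moved to the front of the scan so that they
    survive aliasing whenever a full-rank design containing them exists.
    """
    order = [c for c in design.columns if c in keep] + [c for c in design.columns if c not in keep]
    dropped = aliased_columns(design[order])
    reduced = design[[c for c in design.columns if c not in dropped]]
    return reduced, dropped


@dataclass
class VariancePrior:
    """Scaled inverse-chi-square prior on gene-wise residual variances."""

    d0: float  # prior degrees of freedom; np.inf when variances are constant
    s02: float  # prior variance (squared log-expression units)

    def __post_init__(self):
        # d0 = 0 is the no-shrinkage limit (classical t/F); estimation always
        # returns d0 > 0 but the limit is accepted for classical statistics.
        if not (self.d0 >= 0):
            raise ValueError("prior df d0 must be nonnegative")
        if not (self.s02 > 0):
            raise ValueError("prior variance s0^2 must be positive")

    def posterior_variance(self, s2, d):
        """Shrunken variance s~^2 = (d0 s0^2 + d s^2)/(d0 + d)."""
        s2 = np.asarray(s2, dtype=float)
        d = np.asarray(d, dtype=float)
        if np.isinf(self.d0):
            return np.full(np.broadcast(s2, d).shape, self.s02)
        return (self.d0 * self.s02 + d * s2) / (self.d0 + d)


@dataclass
class GeneFit:
    """OLS result for a single response (one gene, or one stacked gene set)."""

    coef: pd.Series  # beta-hat per design column
    stdev_unscaled: pd.Series  # u_j: SE(beta_j) = u_j * s
    sigma2: float  # residual variance s^2 = RSS / d
    df_resid: float  # d = n - rank(design)
    n_used: int
    xtx_inv: np.ndarray | None = None  # unscaled coefficient covariance

    @property
    def ok(self) -> bool:
        """False when d = 0 (saturated fit, s^2 undefined)."""
        return self.df_resid > 0


@dataclass
class GeneFitSet:
    """OLS fits of many genes against one shared design.

    When every gene uses the same rows (no missing values), ``xtx_inv`` is
    the single shared unscaled covariance matrix of the coefficients.
    """

    coef: pd.DataFrame  # genes x p
    stdev_unscaled: pd.DataFrame  # genes x p
    sigma2: pd.Series  # per-gene residual variance
    df_resid: pd.Series  # per-gene residual df
    n_used: pd.Series
    design_columns: list[str] = field(default_factory=list)
    xtx_inv: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.coef)

    @property
    def genes(self) -> pd.Index:
        return self.coef.index

    def __getitem__(self, gene) -> GeneFit:
        return GeneFit(
            coef=self.coef.loc[gene],
            stdev_unscaled=self.stdev_unscaled.loc[gene],
            sigma2=float(self.sigma2.loc[gene]),
            df_resid=float(self.df_resid.loc[gene]),
            n_used=int(self.n_used.loc[gene]),
            xtx_inv=self.xtx_inv,
        )


def _fit_block(Y: np.ndarray, X: np.ndarray):
    """Vectorized OLS of row-responses Y (g x n) on design X (n x p)."""
    n, p = X.shape
    xtx = X.T @ X
    xtx_inv = np.linalg.inv(xtx)
    coef = Y @ X @ xtx_inv.T  # g x p
    resid = Y - coef @ X.T
    rss = np.einsum("ij,ij->i", resid, resid)
    d = n - p
    sigma2 = rss / d if d > 0 else np.full(len(Y), np.nan)
    u = np.sqrt(np.diag(xtx_inv))
    return coef, u, np.maximum(sigma2, 0.0), d, xtx_inv


def ols_fit(responses: pd.DataFrame, design: pd.DataFrame) -> GeneFitSet:
    """Fit per-gene OLS of every row of ``responses`` on ``design``.

    Parameters
    ----------
    responses
        Genes x samples matrix (log-scale expression).  NaN entries trigger a
        per-gene complete-case fit.
    design
        Samples x covariates frame; must be full column rank and NaN-free.

    Raises
    ------
    AliasedDesignError
        If the design is rank deficient (the aliased columns are named).
    """
    if not responses.columns.equals(design.index):
        if set(responses.columns) != set(design.index):
            raise ValueError("responses columns and design rows name different samples")
        design = design.loc[responses.columns]
    if design.isna().any().any():
        raise ValueError("design matrix contains missing values")
    dup = design.columns[design.columns.duplicated()]
    if len(dup):
        raise AliasedDesignError(dup.unique())
    bad = aliased_columns(design)
    if bad:
        raise AliasedDesignError(bad)

    X = np.asarray(design, dtype=float)
    Y = np.asarray(responses, dtype=float)
    genes = responses.index
    cols = list(design.columns)
    n, p = X.shape

    if not np.isnan(Y).any():
        coef, u, sigma2, d, xtx_inv = _fit_block(Y, X)
        if d == 0:
            warnings.warn("saturated fit: residual df is 0, s^2 undefined")
        return GeneFitSet(
            coef=pd.DataFrame(coef, index=genes, columns=cols),
            stdev_unscaled=pd.DataFrame(np.tile(u, (len(genes), 1)), index=genes, columns=cols),
            sigma2=pd.Series(sigma2, index=genes),
            df_resid=pd.Series(float(d), index=genes),
            n_used=pd.Series(n, index=genes),
            design_columns=cols,
            xtx_inv=xtx_inv,
        )

    # complete-case per gene; shared xtx_inv no longer applies
    coef = np.full((len(genes), p), np.nan)
    uu = np.full((len(genes), p), np.nan)
    s2 = np.full(len(genes), np.nan)
    dd = np.zeros(len(genes))
    nn = np.zeros(len(genes), dtype=int)
    for i in range(len(genes)):
        mask = ~np.isnan(Y[i])
        Xi = X[mask]
        nn[i] = mask.sum()
        if nn[i] < p or np.linalg.matrix_rank(Xi) < p:
            continue
        ci, ui, s2i, di, _ = _fit_block(Y[i : i + 1, mask], Xi)
        coef[i], uu[i], s2[i], dd[i] = ci[0], ui, s2i[0], di
    return GeneFitSet(
        coef=pd.DataFrame(coef, index=genes, columns=cols),
        stdev_unscaled=pd.DataFrame(uu, index=genes, columns=cols),
        sigma2=pd.Series(s2, index=genes),
        df_resid=pd.Series(dd, index=genes),
        n_used=pd.Series(nn, index=genes),
        design_columns=cols,
        xtx_inv=None,
    )


def _trigamma_inverse(x: float, n_iter: int = 50) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration on 1/y scale."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(n_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_variance_prior(s2, d) -> VariancePrior:
    """Estimate (d0, s0^2) by moment-matching log sample variances.

    With s_g^2 ~ s0^2 * F(d, d0), the statistic
    e_g = log s_g^2 - digamma(d/2) + log(d/2) has mean
    log s0^2 + digamma(d0/2) - log(d0/2) and variance
    trigamma(d/2) + trigamma(d0/2); inverting the trigamma equation gives d0
    and then s0^2.  When the observed spread of e_g does not exceed the
    trigamma(d/2) floor, the variances are treated as constant (d0 = inf).
    """
    s2 = np.asarray(s2, dtype=float)
    d = np.broadcast_to(np.asarray(d, dtype=float), s2.shape)
    ok = np.isfinite(s2) & (d >= 1)
    s2, d = s2[ok], d[ok]
    if s2.size and np.all(s2 == 0):
        raise ValueError("degenerate variances: all residual variances are zero")
    pos = s2 > 0
    s2, d = s2[pos], d[pos]
    if s2.size < 2:
        raise ValueError("need at least 2 positive residual variances")
    if s2.size < 10:
        warnings.warn(
            f"only {s2.size} usable variances; prior hyperparameters are a wide-tolerance estimate"
        )
    e = np.log(s2) - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - np.mean(special.polygamma(1, d / 2.0))
    if evar <= 0:
        # spread of log s^2 no larger than its sampling floor: constant prior
        return VariancePrior(d0=INF_DF, s02=float(np.mean(s2)))
    d0 = 2.0 * _trigamma_inverse(evar)
    if np.isinf(d0):
        return VariancePrior(d0=INF_DF, s02=float(np.mean(s2)))
    s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return VariancePrior(d0=float(d0), s02=s02)


def _as_arrays(fit, coef_name):
    """Extract (beta, u, s2, d) for one coefficient from a GeneFit or GeneFitSet."""
    if isinstance(fit, GeneFit):
        if coef_name not in fit.coef.index:
            raise KeyError(f"coefficient {coef_name!r} not in fit")
        beta = np.asarray([fit.coef[coef_name]])
        u = np.asarray([fit.stdev_unscaled[coef_name]])
        s2 = np.asarray([fit.sigma2])
        d = np.asarray([fit.df_resid])
        index = None
    else:
        if coef_name not in fit.coef.columns:
            raise KeyError(f"coefficient {coef_name!r} not in fit")
        beta = fit.coef[coef_name].to_numpy()
        u = fit.stdev_unscaled[coef_name].to_numpy()
        s2 = fit.sigma2.to_numpy()
        d = fit.df_resid.to_numpy(dtype=float)
        index = fit.genes
    if np.any(u == 0):
        raise ValueError(f"coefficient {coef_name!r} not estimable (zero unscaled SE)")
    return beta, u, s2, d, index


def moderated_t(fit, prior: VariancePrior, coef: str):
    """Moderated t statistic for one named coefficient.

    Returns a DataFrame (t, p, df_total) indexed by gene for a GeneFitSet, or
    a scalar tuple (t, p, df_total) for a single GeneFit.  With d0 = 0 this is
    the ordinary OLS t; with d0 = inf the denominator is s0 exactly and tail
    probabilities are normal.
    """
    beta, u, s2, d, index = _as_arrays(fit, coef)
    s2_post = prior.posterior_variance(s2, d)
    t = beta / (u * np.sqrt(s2_post))
    if np.isinf(prior.d0):
        df_total = np.full_like(t, np.inf)
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        df_total = prior.d0 + d
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    if index is None:
        return float(t[0]), float(p[0]), float(df_total[0])
    return pd.DataFrame({"t": t, "p": p, "df_total": df_total}, index=index)


def moderated_f(fit, prior: VariancePrior, coefs: list[str]):
    """Moderated F test that the named coefficients are jointly zero.

    F~ = beta_J' V_J^{-1} beta_J / (k * s~^2) with V_J the unscaled
    covariance submatrix; numerator df k = len(coefs), denominator df d0 + d.
    Requires a shared design (no per-gene missingness).  For a single
    coefficient F~ = t~^2 exactly.
    """
    single = isinstance(fit, GeneFit)
    if fit.xtx_inv is None:
        raise ValueError("joint F test needs the shared unscaled covariance (complete-case design)")
    cols = list(fit.coef.index) if single else list(fit.coef.columns)
    missing = [c for c in coefs if c not in cols]
    if missing:
        raise KeyError(f"coefficients not in fit: {missing}")
    idx = [cols.index(c) for c in coefs]
    V = fit.xtx_inv[np.ix_(idx, idx)]
    Vinv = np.linalg.inv(V)
    k = len(coefs)

    if single:
        B = fit.coef[coefs].to_numpy()[None, :]
        s2 = np.asarray([fit.sigma2])
        d = np.asarray([fit.df_resid], dtype=float)
        index = None
    else:
        B = fit.coef[coefs].to_numpy()
        s2 = fit.sigma2.to_numpy()
        d = fit.df_resid.to_numpy(dtype=float)
        index = fit.genes
    s2_post = prior.posterior_variance(s2, d)
    quad = np.einsum("ij,jk,ik->i", B, Vinv, B)
    F = quad / (k * s2_post)
    if np.isinf(prior.d0):
        df_den = np.full_like(F, np.inf)
        p = stats.chi2.sf(k * F, k)
    else:
        df_den = prior.d0 + d
        p = stats.f.sf(F, k, df_den)
    if index is None:
        return float(F[0]), float(p[0]), k, float(df_den[0])
    return pd.DataFrame({"F": F, "p": p, "df_num": k, "df_den": df_den}, index=index)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending order, capped at 1;
    ties share the adjusted value of their largest rank.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-d vector")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1] with no missing entries")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def spearman_corr(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of average ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("undefined correlation: constant input vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])
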