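"""Per-gene time-course testing with an empirical-Bayes moderated F.

Model
-----
Each gene g is fit by ordinary least squares on a cell-means design (one
indicator column per time level), so the coefficients are the per-time
means and the residual variance is s2_g on d_g degrees of freedom. The
residual variances are shrunk toward a prior by assuming
``1/sigma2_g ~ chi2(d0) / (d0 * s0^2)``, whose hyperparameters (d0, s0^2)
are estimated by moment-matching the log sample variances against the
scaled-F distribution they follow under the model. The posterior variance

    s2_tilde_g = (d0 * s0^2 + d_g * s2_g) / (d0 + d_g)

replaces s2_g in the F statistic for the set of neighboring-timepoint
contrasts (1-0, 2-1, 3-2, 6-3, 24-6). Because those r = 5 contrasts span
the full between-time space, the numerator equals the classical one-way
between-group sum of squares; the moderated F is referred to an
F(r, d0 + d_g) distribution. d0 = 0 recovers the classical ANOVA F;
d0 = +inf pools every gene's variance to s0^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

from .errors import UserInputError

DEFAULT_ALPHA = 5e-7


# ---------------------------------------------------------------------------
# design and contrasts


def build_design(sample_sheet: pd.DataFrame, levels: Sequence[float] | None = None) -> pd.DataFrame:
    """Cell-means (one indicator column per time level) design matrix.

    Rows follow the sample sheet's order; columns are the ordered time
    levels. When ``levels`` is given, any sample time outside it is an
    error; levels without samples are allowed but flagged via a zero
    column sum.
    """
    times = sample_sheet["time_h"].astype(float).to_numpy()
    if levels is None:
        levels = sorted(set(times))
    levels = [float(t) for t in levels]
    unknown = sorted(set(times) - set(levels))
    if unknown:
        raise UserInputError(f"sample times {unknown} not in design levels {levels}")
    data = {t: (times == t).astype(float) for t in levels}
    design = pd.DataFrame(data, index=sample_sheet["sample_id"].tolist())
    design.columns = [f"t{t:g}" for t in levels]
    design.attrs["levels"] = levels
    return design


def neighboring_contrasts(levels: Sequence[float]) -> pd.DataFrame:
    """Successive-difference contrast matrix (one row per neighboring pair)."""
    levels = [float(t) for t in levels]
    if len(levels) < 2:
        raise UserInputError("need at least 2 time levels for contrasts")
    if sorted(levels) != levels:
        raise UserInputError("levels must be sorted ascending")
    rows = []
    names = []
    for lo, hi in zip(levels, levels[1:]):
        row = np.zeros(len(levels))
        row[levels.index(hi)] = 1.0
        row[levels.index(lo)] = -1.0
        rows.append(row)
        names.append(f"t{hi:g}-t{lo:g}")
    return pd.DataFrame(rows, index=names, columns=[f"t{t:g}" for t in levels])


# ---------------------------------------------------------------------------
# per-gene OLS fits


@dataclass
class GeneFits:
    """Per-gene OLS summaries under the cell-means design.

    coef: levels x genes per-time means; s2/df: residual variance and df;
    n_per_level: per-gene sample counts at each level (varies only when a
    gene has missing cells).
    """

    coef: pd.DataFrame
    s2: pd.Series
    df: pd.Series
    n_per_level: pd.DataFrame
    levels: list[float]


def fit_gene_models(matrix: pd.DataFrame, design: pd.DataFrame) -> GeneFits:
    """Per-gene OLS on the cell-means design (group means + residual var).

    ``matrix`` is genes x samples; ``design`` rows must match its columns.
    NaN cells are dropped per gene; a gene with no observed value at all
    is an error, and genes with zero residual df are flagged (df = 0).
    """
    if list(matrix.columns) != list(design.index):
        raise UserInputError("design rows do not match matrix columns")
    levels = design.attrs.get("levels")
    if levels is None:
        raise UserInputError("design must come from build_design()")
    X = design.to_numpy()                       # n_samples x n_levels
    Y = matrix.to_numpy(dtype=float)            # n_genes x n_samples
    genes = matrix.index

    all_missing = np.all(np.isnan(Y), axis=1)
    if np.any(all_missing):
        bad = genes[all_missing][0]
        raise UserInputError(f"gene {bad!r} has no observed values")

    if not np.any(np.isnan(Y)):
        n_t = X.sum(axis=0)                     # samples per level
        n_per = np.tile(n_t, (len(genes), 1))
        sums = Y @ X
        with np.errstate(invalid="ignore", divide="ignore"):
            means = sums / n_t
        fitted = np.where(n_t > 0, means, 0.0) @ X.T
        rss = ((Y - fitted) ** 2).sum(axis=1)
        df = np.full(len(genes), Y.shape[1] - int((n_t > 0).sum()))
    else:
        means = np.empty((len(genes), X.shape[1]))
        n_per = np.empty_like(means)
        rss = np.empty(len(genes))
        df = np.empty(len(genes), dtype=int)
        for i in range(len(genes)):
            obs = ~np.isnan(Y[i])
            n_t = X[obs].sum(axis=0)
            n_per[i] = n_t
            with np.errstate(invalid="ignore", divide="ignore"):
                means[i] = (Y[i, obs] @ X[obs]) / n_t
            fitted = np.where(n_t > 0, means[i], 0.0) @ X[obs].T
            rss[i] = ((Y[i, obs] - fitted) ** 2).sum()
            df[i] = int(obs.sum()) - int((n_t > 0).sum())

    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = np.where(df > 0, rss / np.maximum(df, 1), 0.0)
    coef = pd.DataFrame(means.T, index=design.columns, columns=genes)
    return GeneFits(
        coef=coef,
        s2=pd.Series(s2, index=genes, name="s2"),
        df=pd.Series(df, index=genes, name="df"),
        n_per_level=pd.DataFrame(n_per, index=genes, columns=design.columns),
        levels=list(levels),
    )


# ---------------------------------------------------------------------------
# empirical-Bayes variance prior


@dataclass(frozen=True)
class EBayesParams:
    """Hyperparameters of the inverse-chi-square variance prior."""

    prior_df: float      # d0; may be math.inf
    prior_var: float     # s0^2

    def __post_init__(self):
        if not (self.prior_df > 0):
            raise UserInputError("prior_df must be > 0")
        if not (self.prior_var > 0):
            raise UserInputError("prior_var must be > 0")


def trigamma_inverse(y: float, tol: float = 1e-10, max_x: float = 1e6) -> float:
    """Solve trigamma(x) = y for x > 0 by monotone bisection.

    trigamma is strictly decreasing on (0, inf). Values of y at or below
    trigamma(max_x) return +inf (the flat-prior limit).
    """
    if y <= float(special.polygamma(1, max_x)):
        return math.inf
    lo = 1e-8
    while special.polygamma(1, lo) < y:  # pragma: no cover - lo is tiny
        lo /= 10.0
    hi = max_x
    for _ in range(200):
        mid = math.sqrt(lo * hi)  # geometric bisection: x spans 14 decades
        if special.polygamma(1, mid) > y:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * lo:
            break
    return math.sqrt(lo * hi)


def estimate_variance_prior(fits: GeneFits) -> EBayesParams:
    """Moment-match (d0, s0^2) from the spread of log residual variances.

    Under the model, e_g = log s2_g - digamma(d_g/2) + log(d_g/2) has mean
    log s0^2 + digamma(d0/2) - log(d0/2) and excess variance
    trigamma(d0/2) beyond the sampling term trigamma(d_g/2). When the
    empirical spread does not exceed the sampling term the prior df is
    +inf and s0^2 is the pooled (df-weighted) variance.
    """
    s2 = fits.s2.to_numpy(dtype=float)
    df = fits.df.to_numpy(dtype=float)
    usable = (df > 0) & (s2 > 0)
    if not np.any(fits.df.to_numpy() > 0):
        raise UserInputError("no gene has positive residual df")
    s2u, dfu = s2[usable], df[usable]
    pooled = float(np.sum(df[df > 0] * s2[df > 0]) / np.sum(df[df > 0]))
    if s2u.size < 2:
        return EBayesParams(math.inf, pooled if pooled > 0 else 1.0)

    e = np.log(s2u) - special.digamma(dfu / 2.0) + np.log(dfu / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(np.mean(special.polygamma(1, dfu / 2.0)))
    if evar <= 0:
        return EBayesParams(math.inf, pooled)
    d0 = 2.0 * trigamma_inverse(evar)
    if math.isinf(d0):
        return EBayesParams(math.inf, pooled)
    s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return EBayesParams(d0, s02)


# ---------------------------------------------------------------------------
# moderated F test and ranking


def moderated_f_test(
    fits: GeneFits,
    contrasts: pd.DataFrame,
    prior: EBayesParams | None,
) -> pd.DataFrame:
    """Moderated F over the contrast set, per gene.

    ``prior=None`` or prior_df = 0-like behaviour is obtained with
    ``EBayesParams`` being optional: pass None for the classical
    (unmoderated) ANOVA F. Genes with d_g = 0 and no prior receive p = 1
    and a ``flagged`` mark.

    Returns a DataFrame indexed by gene with columns F, p, s2_post,
    df_num, df_den, flagged.
    """
    C = contrasts.to_numpy(dtype=float)
    if list(contrasts.columns) != list(fits.coef.index):
        raise UserInputError("contrast columns do not match design levels")
    r = C.shape[0]
    genes = fits.coef.columns
    B = fits.coef.to_numpy()                    # levels x genes
    s2 = fits.s2.to_numpy(dtype=float)
    df = fits.df.to_numpy(dtype=float)

    if prior is None:
        d0, s02 = 0.0, 0.0
    else:
        d0, s02 = prior.prior_df, prior.prior_var

    if math.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_den = np.full_like(s2, math.inf)
    else:
        s2_post = (d0 * s02 + df * s2) / np.where(d0 + df > 0, d0 + df, 1.0)
        df_den = d0 + df

    n_per = fits.n_per_level.to_numpy(dtype=float)
    uniform = np.all(n_per == n_per[0]) if len(genes) else True
    D = C @ B                                   # r x genes contrast estimates

    def _quadform(n_t: np.ndarray, d: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore"):
            V = C @ np.diag(np.where(n_t > 0, 1.0 / n_t, np.inf)) @ C.T
        if not np.all(np.isfinite(V)):
            raise UserInputError("contrasts not estimable: empty time level")
        try:
            sol = np.linalg.solve(V, d)
        except np.linalg.LinAlgError:
            raise UserInputError("singular contrast covariance") from None
        return np.einsum("ij,ij->j", d, sol) if d.ndim == 2 else float(d @ sol)

    if uniform:
        Q = _quadform(n_per[0], D)
    else:
        Q = np.array([_quadform(n_per[i], D[:, i]) for i in range(len(genes))])

    # zero-residual-df genes are excluded from inference: p = 1, flagged
    flagged = df <= 0
    denom = r * np.where(s2_post > 0, s2_post, np.inf)
    F = np.where(flagged, 0.0, Q / denom)
    # zero posterior variance with positive numerator -> infinite evidence
    F = np.where((s2_post <= 0) & (Q > 0) & ~flagged, math.inf, F)

    p = np.ones_like(F)
    if math.isinf(d0):
        p[~flagged] = stats.chi2.sf(r * F[~flagged], r)
    else:
        ok = ~flagged
        p[ok] = stats.f.sf(F[ok], r, df_den[ok])
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    p[np.isinf(F)] = np.nextafter(0, 1)

    return pd.DataFrame(
        {
            "F": F,
            "p": p,
            "s2_post": s2_post,
            "df_num": float(r),
            "df_den": df_den,
            "flagged": flagged,
        },
        index=genes,
    )


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (step-up)."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def rank_and_threshold(result: pd.DataFrame, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Sort by ascending p (ties by gene id), rank 1..G, flag p < alpha.

    Adds a BH-adjusted column (``p_bh``) for reference; the significance
    flag uses the fixed alpha cutoff only.
    """
    if not (0 < alpha < 1):
        raise UserInputError("alpha must be in (0, 1)")
    out = result.copy()
    out["p_bh"] = benjamini_hochberg(out["p"].to_numpy())
    order = np.lexsort((out.index.astype(str), out["p"].to_numpy()))
    out = out.iloc[order]
    out["rank"] = np.arange(1, len(out) + 1)
    out["significant"] = out["p"] < alpha
    return out


# ---------------------------------------------------------------------------
# sklearn-style estimator


class ModeratedFTest(SelectorMixin, BaseEstimator):
    """Empirical-Bayes moderated F test over neighboring-time contrasts.

    A feature-selection style estimator: ``fit(X, y)`` takes X of shape
    (n_samples, n_genes) and y the per-sample time in hours; ``transform``
    keeps the genes passing the significance cutoff.

    Parameters
    ----------
    alpha : float
        Significance cutoff on the moderated-F p-value.
    moderation : {"ebayes", "none", "pool"}
        "ebayes" estimates (d0, s0^2) from the data; "none" gives the
        classical ANOVA F; "pool" forces d0 = +inf (complete pooling).

    Attributes
    ----------
    levels_ : list of time levels; coef_ : per-time means (levels x genes);
    s2_, df_residual_ : residual variances and df; prior_df_, prior_var_ :
    estimated hyperparameters; fstat_, pvalue_, rank_, significant_ :
    per-gene results; results_ : the ranked DataFrame.
    """

    def __init__(self, alpha: float = DEFAULT_ALPHA, moderation: str = "ebayes"):
        self.alpha = alpha
        self.moderation = moderation

    def fit(self, X, y):
        if self.moderation not in ("ebayes", "none", "pool"):
            raise UserInputError(f"unknown moderation {self.moderation!r}")
        if isinstance(X, pd.DataFrame):
            genes = list(X.columns)
            sample_ids = [str(s) for s in X.index]
            values = X.to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
            if values.ndim != 2:
                raise UserInputError("X must be 2-dimensional (samples x genes)")
            genes = [f"g{i}" for i in range(values.shape[1])]
            sample_ids = [f"s{i}" for i in range(values.shape[0])]
        y = np.asarray(y, dtype=float)
        if y.shape[0] != values.shape[0]:
            raise UserInputError("y length must equal the number of samples")

        sheet = pd.DataFrame({"sample_id": sample_ids, "time_h": y})
        design = build_design(sheet)
        matrix = pd.DataFrame(values.T, index=pd.Index(genes, name="gene_id"),
                              columns=sample_ids)
        fits = fit_gene_models(matrix, design)
        contrasts = neighboring_contrasts(design.attrs["levels"])
        if self.moderation == "none":
            prior = None
        else:
            prior = estimate_variance_prior(fits)
            if self.moderation == "pool":
                prior = EBayesParams(math.inf, prior.prior_var)
        res = moderated_f_test(fits, contrasts, prior)
        ranked = rank_and_threshold(res, alpha=self.alpha)

        self.n_features_in_ = values.shape[1]
        self.feature_names_in_ = np.asarray(genes, dtype=object)
        self.levels_ = fits.levels
        self.coef_ = fits.coef
        self.s2_ = fits.s2
        self.df_residual_ = fits.df
        self.prior_df_ = prior.prior_df if prior is not None else 0.0
        self.prior_var_ = prior.prior_var if prior is not None else float("nan")
        self.fstat_ = res["F"].to_numpy()
        self.pvalue_ = res["p"].to_numpy()
        self.results_ = ranked
        self.rank_ = ranked["rank"].reindex(genes).to_numpy()
        self.significant_ = res["p"].to_numpy() < self.alpha
        return self

    def _get_support_mask(self):
        if not hasattr(self, "significant_"):
            raise UserInputError("ModeratedFTest is not fitted")
        return self.significant_

    def __sklearn_is_fitted__(self):
        return hasattr(self, "significant_")


def rank_genes(
    matrix: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    moderation: str = "ebayes",
) -> pd.DataFrame:
    """One-call pipeline on a genes x samples matrix + sample sheet.

    Thin wrapper over :class:`ModeratedFTest`; returns the ranked table.
    """
    cols = list(matrix.columns)
    sheet = sample_sheet.set_index("sample_id").loc[cols].reset_index()
    est = ModeratedFTest(alpha=alpha, moderation=moderation)
    est.fit(matrix.T, sheet["time_h"].to_numpy())
    out = est.results_.copy()
    out.index.name = "gene_id"
    out.attrs["prior_df"] = est.prior_df_
    out.attrs["prior_var"] = est.prior_var_
    return out
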