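"""Weighted per-gene linear models with empirical-Bayes moderated t-statistics.

Each gene's log2-CPM profile is fit by weighted least squares on a
cell-means design (one coefficient per time point), using the
observation-level precision weights from the mean-variance trend. The
gene-wise residual variances are then shrunk toward a common prior: the
marginal distribution of the log residual variances is matched to a
scaled F by method of moments (digamma/trigamma inversion), yielding a
prior degree of freedom d0 and prior variance s0^2, and the posterior
variance ``(d0*s0^2 + d*s^2)/(d0 + d)`` replaces s^2 in the t-statistic,
which gains d0 extra degrees of freedom.

The two contrasts of the treatment time course are the sequential
differences 30 min - 0 and 3 h - 30 min, oriented so a positive log2
fold change means upregulation at the later time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from tcresponse.containers import TIME_POINTS

#: The two sequential contrasts, later time minus earlier time.
DEFAULT_CONTRASTS: dict[str, np.ndarray] = {
    "30min-0": np.array([-1.0, 1.0, 0.0]),
    "3h-30min": np.array([0.0, -1.0, 1.0]),
}


def design_matrix(design: pd.DataFrame, time_points=TIME_POINTS) -> pd.DataFrame:
    """Cell-means design: one indicator column per time point."""
    cols = {tp: (design["time"] == tp).astype(float) for tp in time_points}
    X = pd.DataFrame(cols, index=design.index)
    empty = [tp for tp in time_points if X[tp].sum() == 0]
    if empty:
        raise ValueError(f"no samples for time point(s) {empty}")
    return X


@dataclass
class LinearFits:
    """Per-gene weighted least-squares fits on a shared design."""

    coef: pd.DataFrame            # genes x p, log2 units
    cov_unscaled: np.ndarray      # genes x p x p, (X'WX)^-1
    sigma2: pd.Series             # residual variance per gene
    df_resid: int
    design_cols: list[str]


@dataclass
class ModeratedFit:
    """Linear fits plus the empirical-Bayes variance moderation."""

    fits: LinearFits
    d0: float                     # prior df (may be inf)
    s0_sq: float                  # prior variance
    sigma2_post: pd.Series        # posterior (moderated) variances

    @property
    def df_total(self) -> float:
        return self.d0 + self.fits.df_resid


def fit_models(
    log_cpm_mat: pd.DataFrame,
    weights: pd.DataFrame,
    design_mat: pd.DataFrame,
) -> LinearFits:
    """Weighted least squares per gene.

    ``weights`` must be positive, genes x samples. Raises on a
    rank-deficient design, naming the collinear columns.
    """
    X = design_mat.to_numpy(dtype=float)
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # columns whose removal restores full column rank are the culprits
        bad = [
            c for i, c in enumerate(design_mat.columns)
            if np.linalg.matrix_rank(np.delete(X, i, axis=1)) == rank
        ]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")

    W = weights.reindex(index=log_cpm_mat.index, columns=log_cpm_mat.columns)
    Wv = W.to_numpy(dtype=float)
    if (Wv <= 0).any():
        raise ValueError("weights must be positive")
    Y = log_cpm_mat.to_numpy(dtype=float)

    xtwx = np.einsum("sp,gs,sq->gpq", X, Wv, X)          # genes x p x p
    xtwy = np.einsum("sp,gs->gp", X, Wv * Y)             # genes x p
    cov_unscaled = np.linalg.inv(xtwx)
    coef = np.einsum("gpq,gq->gp", cov_unscaled, xtwy)
    resid = Y - coef @ X.T
    df_resid = n - p
    sigma2 = (Wv * resid**2).sum(axis=1) / df_resid
    return LinearFits(
        coef=pd.DataFrame(coef, index=log_cpm_mat.index, columns=design_mat.columns),
        cov_unscaled=cov_unscaled,
        sigma2=pd.Series(sigma2, index=log_cpm_mat.index, name="sigma2"),
        df_resid=df_resid,
        design_cols=list(design_mat.columns),
    )


# ---------------------------------------------------------------------------
# empirical-Bayes variance moderation
# ---------------------------------------------------------------------------

def trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve ``trigamma(x) = y`` for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma is positive; no solution for y <= 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        step = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += step
        if -step / x < tol:
            break
    return float(x)


def estimate_prior(sigma2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) from gene-wise variances.

    Matches mean and variance of ``log(s^2)`` to the scaled-F model: if
    the moment equation leaves no excess spread beyond the chi-square
    sampling noise, d0 is infinite (no variance heterogeneity) and s0^2
    is the common value.
    """
    s2 = np.asarray(sigma2, dtype=float)
    s2 = s2[s2 > 0]
    if s2.size < 2:
        raise ValueError("need >= 2 genes with positive residual variance")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var > 0:
        d0 = 2.0 * trigamma_inverse(e_var)
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # no spread beyond chi-square noise: variances share one value, best
        # estimated by their mean (exact when they are literally identical)
        d0 = np.inf
        s0_sq = float(np.mean(s2))
    return d0, s0_sq


def moderate(fits: LinearFits, d0_override: float | None = None) -> ModeratedFit:
    """Shrink gene-wise variances toward the fitted prior.

    ``d0_override=0`` bypasses shrinkage entirely (ordinary t);
    ``d0_override=np.inf`` forces full shrinkage to the prior.
    """
    s2 = fits.sigma2.to_numpy(dtype=float)
    d = fits.df_resid
    if d0_override is not None and d0_override == 0:
        return ModeratedFit(fits, 0.0, float("nan"), fits.sigma2.copy())
    d0, s0_sq = estimate_prior(s2, d)
    if d0_override is not None:
        d0 = float(d0_override)
    if np.isinf(d0):
        post = np.full_like(s2, s0_sq)
    else:
        post = (d0 * s0_sq + d * s2) / (d0 + d)
    return ModeratedFit(fits, d0, s0_sq, pd.Series(post, index=fits.sigma2.index))


# ---------------------------------------------------------------------------
# contrasts
# ---------------------------------------------------------------------------

def test_contrasts(
    mfit: ModeratedFit,
    contrasts: dict[str, np.ndarray] | None = None,
    add_bh: bool = True,
) -> dict[str, pd.DataFrame]:
    """Moderated t-test for each contrast.

    Returns one table per contrast: ``gene_id`` index with columns
    ``log2fc``, ``t``, ``p`` (two-sided, t distribution on d0 + d df)
    and, for reporting only, a Benjamini-Hochberg ``bh_fdr`` column.
    """
    if contrasts is None:
        contrasts = DEFAULT_CONTRASTS
    fits = mfit.fits
    p_dim = len(fits.design_cols)
    results: dict[str, pd.DataFrame] = {}
    df_total = mfit.df_total
    s_post = np.sqrt(mfit.sigma2_post.to_numpy(dtype=float))
    for name, c in contrasts.items():
        c = np.asarray(c, dtype=float)
        if c.shape != (p_dim,):
            raise ValueError(
                f"contrast {name!r} has length {c.size}, design has {p_dim} coefficients"
            )
        lfc = fits.coef.to_numpy() @ c
        u = np.sqrt(np.einsum("p,gpq,q->g", c, fits.cov_unscaled, c))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = lfc / (u * s_post)
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
        p = np.clip(p, np.nextafter(0, 1), 1.0)
        tab = pd.DataFrame({"log2fc": lfc, "t": t, "p": p}, index=fits.coef.index)
        if add_bh:
            tab["bh_fdr"] = multipletests(tab["p"].to_numpy(), method="fdr_bh")[1]
        tab.index.name = "gene_id"
        results[name] = tab
    return results


def run_differential_expression(
    log_cpm_mat: pd.DataFrame,
    weights: pd.DataFrame,
    design: pd.DataFrame,
    contrasts: dict[str, np.ndarray] | None = None,
) -> dict[str, pd.DataFrame]:
    """Fit, moderate and test in one call (design is the sample table)."""
    X = design_matrix(design)
    fits = fit_models(log_cpm_mat, weights, X)
    mfit = moderate(fits)
    return test_contrasts(mfit, contrasts)
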