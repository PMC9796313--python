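"""Between-sample normalization and mean-variance precision weights.

Implements the normalization layer the study's statistics rest on:

* **TMM** scaling factors — the trimmed mean of M-values between each
  sample and a reference, robust to composition bias. The factor for a
  sample is ``2**f`` where ``f`` is the precision-weighted mean of
  gene-wise log2 expression ratios after double trimming (30% from each
  M tail, 5% from each A tail); factors are rescaled to geometric mean 1.
* **log2-CPM** and **log2-RPKM** transforms with a prior count.
* **voom-style precision weights** — per-gene least-squares residual
  standard deviations define a mean-variance trend (lowess of sqrt-sd
  on average log2 count); each observation's predicted sd at its fitted
  abundance gives an inverse-variance weight ``sd**-4`` for the
  downstream weighted linear models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess

from tcresponse.containers import CountExperiment

logger = logging.getLogger(__name__)


@dataclass
class NormalizationResult:
    """Library sizes, TMM factors and the derived expression matrices."""

    lib_sizes: pd.Series          # reads per sample
    tmm: pd.Series                # dimensionless, geometric mean 1
    log_cpm: pd.DataFrame         # log2 counts per million (effective sizes)
    rpkm: pd.DataFrame | None = None  # log2 reads/kb exon/million

    @property
    def effective_lib_sizes(self) -> pd.Series:
        return self.lib_sizes * self.tmm


@dataclass
class PrecisionWeights:
    """Observation-level inverse-variance weights and the fitted trend."""

    weights: pd.DataFrame               # genes x samples, > 0
    trend: np.ndarray                   # (k, 2) knots: mean log2 count, sqrt-sd

    def predict_sqrt_sd(self, log_count: np.ndarray) -> np.ndarray:
        """Trend value by linear interpolation, constant beyond the range."""
        return np.interp(log_count, self.trend[:, 0], self.trend[:, 1])


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_low_counts(
    exp: CountExperiment, min_cpm: float = 1.0, min_samples: int = 2
) -> CountExperiment:
    """Keep genes with CPM >= ``min_cpm`` in at least ``min_samples`` samples.

    The study does not state a filter; these defaults are the package's
    own and the decision is logged with before/after gene counts.
    """
    if min_cpm < 0 or min_samples < 0:
        raise ValueError("filter thresholds must be >= 0")
    lib = exp.library_sizes().to_numpy()
    cpm = exp.counts.to_numpy() / lib * 1e6
    keep = (cpm >= min_cpm).sum(axis=1) >= min_samples
    kept = exp.gene_ids[keep]
    logger.info(
        "low-count filter (min_cpm=%g in >=%d samples): kept %d of %d genes",
        min_cpm, min_samples, keep.sum(), exp.n_genes,
    )
    return exp.subset_genes(kept)


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------

def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float,
    abs_trim: float,
) -> float:
    """TMM factor of one sample against the reference (unscaled)."""
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        logger.warning("sample shares no positive gene with reference; factor set to 1")
        return 1.0
    o, r = obs[pos], ref[pos]
    po, pr = o / lib_obs, r / lib_ref
    M = np.log2(po / pr)
    A = 0.5 * np.log2(po * pr)
    # inverse of the delta-method binomial variance of M
    v = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)

    n = len(M)
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abs_trim) + 1
    hi_a = n + 1 - lo_a
    rm, ra = rankdata(M), rankdata(A)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(M[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(
    counts: pd.DataFrame,
    logratio_trim: float = 0.30,
    abs_trim: float = 0.05,
    ref_sample: str | None = None,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factor per sample.

    The reference sample is the one whose upper quartile of CPM is
    closest to the mean upper quartile (unless ``ref_sample`` names
    one). Factors are rescaled to geometric mean 1.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValueError("every sample must have positive library size")
    mat = counts.to_numpy(dtype=float)
    if ref_sample is None:
        uq = np.quantile(mat / lib.to_numpy(), 0.75, axis=0)
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_idx = counts.columns.get_loc(ref_sample)
    ref = mat[:, ref_idx]
    lib_ref = lib.iloc[ref_idx]
    factors = np.array([
        1.0 if s == ref_idx
        else _tmm_pair(mat[:, s], ref, lib.iloc[s], lib_ref, logratio_trim, abs_trim)
        for s in range(mat.shape[1])
    ])
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm")


# ---------------------------------------------------------------------------
# expression transforms
# ---------------------------------------------------------------------------

def log_cpm(
    counts: pd.DataFrame,
    effective_lib_sizes: pd.Series | None = None,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """log2 counts per million: ``log2((count + prior) / (lib + 1) * 1e6)``."""
    if effective_lib_sizes is None:
        effective_lib_sizes = counts.sum(axis=0).astype(float)
    lib = effective_lib_sizes.reindex(counts.columns).to_numpy(dtype=float)
    if (lib <= 0).any():
        raise ValueError("effective library sizes must be > 0")
    out = np.log2((counts.to_numpy(dtype=float) + prior_count) / (lib + 1.0) * 1e6)
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def rpkm(
    counts: pd.DataFrame,
    lib_sizes: pd.Series,
    gene_lengths: pd.Series,
    prior_count: float = 0.5,
    log: bool = True,
) -> pd.DataFrame:
    """Reads per kilobase of exon per million library reads.

    ``(count + prior) / (length_kb) / (lib_size_millions)``, on the log2
    scale by default. Genes without a length get missing values rather
    than zeros.
    """
    lib = lib_sizes.reindex(counts.columns).to_numpy(dtype=float)
    lengths = gene_lengths.reindex(counts.index).to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        lin = (
            (counts.to_numpy(dtype=float) + prior_count)
            / (lengths[:, None] / 1e3)
            / (lib[None, :] / 1e6)
        )
        out = np.log2(lin) if log else lin
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


# ---------------------------------------------------------------------------
# voom precision weights
# ---------------------------------------------------------------------------

_SQRT_SD_FLOOR = 1e-2  # keeps weights finite on a flat/zero-variance trend


def voom_weights(
    log_cpm_mat: pd.DataFrame,
    design_matrix: pd.DataFrame,
    lib_sizes: pd.Series | None = None,
    span: float = 0.5,
) -> PrecisionWeights:
    """Mean-variance precision weights for weighted linear modelling.

    Per gene, an ordinary least-squares fit of log2-CPM on the design
    yields a residual standard deviation; lowess of sqrt(sd) on average
    log2 count (log2-CPM shifted by the mean log library size when
    ``lib_sizes`` is given) defines the trend. Each observation's
    predicted sqrt-sd is read off at its fitted log2 count and the
    weight is ``predicted_sd**-4``, clipped away from zero.
    """
    X = design_matrix.to_numpy(dtype=float)
    Y = log_cpm_mat.to_numpy(dtype=float)
    n, p = X.shape
    if n - np.linalg.matrix_rank(X) < 2:
        raise ValueError("need at least 2 residual degrees of freedom")

    pinv = np.linalg.pinv(X)
    coef = Y @ pinv.T                      # genes x p
    fitted = coef @ X.T                    # genes x n
    resid = Y - fitted
    df_resid = n - np.linalg.matrix_rank(X)
    sigma = np.sqrt((resid**2).sum(axis=1) / df_resid)
    use = sigma > 1e-10
    if not use.any():
        raise ValueError("all genes have zero residual variance; degenerate input")

    if lib_sizes is not None:
        shift = float(np.mean(np.log2(lib_sizes.to_numpy(dtype=float) + 1.0))) - np.log2(1e6)
        obs_shift = np.log2(lib_sizes.reindex(log_cpm_mat.columns).to_numpy(dtype=float) + 1.0) - np.log2(1e6)
    else:
        shift = 0.0
        obs_shift = np.zeros(n)

    mean_log_count = Y.mean(axis=1) + shift
    sqrt_sd = np.sqrt(sigma)
    # non-robust lowess: the fit at any abundance depends only on genes
    # within the local window
    trend = lowess(sqrt_sd[use], mean_log_count[use], frac=span, it=0,
                   return_sorted=True)
    # collapse duplicate x for interpolation
    xs, idx = np.unique(trend[:, 0], return_index=True)
    knots = np.column_stack([xs, trend[idx, 1]])

    fitted_log_count = fitted + obs_shift[None, :]
    pred = np.interp(fitted_log_count, knots[:, 0], knots[:, 1])
    pred = np.clip(pred, _SQRT_SD_FLOOR, None)
    w = pred**-4.0
    weights = pd.DataFrame(w, index=log_cpm_mat.index, columns=log_cpm_mat.columns)
    return PrecisionWeights(weights=weights, trend=knots)


def normalize_experiment(
    exp: CountExperiment,
    prior_count: float = 0.5,
    use_effective_for_rpkm: bool = False,
) -> NormalizationResult:
    """TMM factors + log2-CPM (+ log2-RPKM when lengths are present).

    RPKM uses raw library sizes by default; ``use_effective_for_rpkm``
    switches to TMM-effective sizes.
    """
    lib = exp.library_sizes()
    tmm = tmm_factors(exp.counts)
    eff = lib * tmm
    lcpm = log_cpm(exp.counts, eff, prior_count=prior_count)
    rpkm_mat = None
    if exp.gene_lengths is not None:
        rpkm_lib = eff if use_effective_for_rpkm else lib
        rpkm_mat = rpkm(exp.counts, rpkm_lib, exp.gene_lengths, prior_count=prior_count)
    return NormalizationResult(lib_sizes=lib, tmm=tmm, log_cpm=lcpm, rpkm=rpkm_mat)
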