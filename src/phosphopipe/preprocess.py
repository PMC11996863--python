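"""Raw site table to analysis-ready matrix.

The stage order mirrors the analysis the pipeline reproduces: log2
transform, class-I localization filter (probability >= 0.75), truncated
normal KNN imputation of the missing-not-at-random low-intensity dropouts,
per-sample median normalization, and surrogate-variable estimation for
unmodeled systematic variation.  Tests downstream include the surrogate
variable as a model covariate; the SV-subtracted matrix is only for
visualization, clustering and PCA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import PhosphoSiteTable

logger = logging.getLogger(__name__)

#: lower bound on fitted sigma (log2 units) to avoid division blow-ups
SIGMA_FLOOR = 0.05


def log2_transform(table: PhosphoSiteTable) -> PhosphoSiteTable:
    """Replace every intensity by its log2; missing values stay missing.

    Raises
    ------
    ValueError
        On any zero or negative intensity, naming the offending cell.
    """
    vals = table.intensities.to_numpy(float)
    bad = (vals <= 0) & ~np.isnan(vals)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-positive intensity {vals[i, j]!r} at site "
            f"{table.site_ids[i]!r}, sample {table.sample_ids[j]!r}"
        )
    out = table.intensities.copy()
    out[:] = np.log2(vals)
    return table.with_intensities(out)


def filter_class1(table: PhosphoSiteTable, min_prob: float = 0.75) -> PhosphoSiteTable:
    """Keep class-I sites: localization probability >= ``min_prob`` (inclusive)."""
    if not 0 <= min_prob <= 1:
        raise ValueError("min_prob must be in [0, 1]")
    keep = table.meta.index[table.meta["localization_probability"] >= min_prob]
    return table.subset_sites(keep)


# ---------------------------------------------------------------------------
# truncated-normal fitting (the TN of KNN-TN)
# ---------------------------------------------------------------------------


@dataclass
class TruncatedNormalFit:
    """Left-truncated Gaussian MLE of one site's observed intensities."""

    mu: float
    sigma: float
    truncation_point: float
    n_observed: int

    def standardize(self, x):
        return (np.asarray(x, float) - self.mu) / self.sigma

    def destandardize(self, z):
        return self.mu + self.sigma * np.asarray(z, float)


def fit_truncated_normal(values, truncation_point) -> TruncatedNormalFit:
    """MLE of (mu, sigma) for observations left-truncated at known points.

    ``truncation_point`` may be a scalar or one limit per observation (the
    per-sample limits of detection).  When every observation sits more than
    4 sample-sd above its truncation point the truncation is negligible and
    the sample moments are returned directly.  Fitted sigma is floored at
    ``SIGMA_FLOOR``.
    """
    x = np.asarray(values, float)
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 3:
        raise ValueError("need >= 3 observed values to fit")
    trunc = np.broadcast_to(np.asarray(truncation_point, float), x.shape)
    m, sd = float(np.mean(x)), float(np.std(x, ddof=1))
    sd = max(sd, SIGMA_FLOOR)
    if np.all(x > trunc + 4 * sd):
        return TruncatedNormalFit(m, sd, float(np.max(trunc)), n)

    def nll(theta):
        mu, log_sigma = theta
        sigma = np.exp(log_sigma)
        # log f(x) - log P(X > L) per observation
        ll = stats.norm.logpdf(x, mu, sigma) - stats.norm.logsf(trunc, mu, sigma)
        return -np.sum(ll)

    # with few observations piled on the truncation point the likelihood is
    # unbounded (mu -> -inf, sigma -> inf); bound the search around the
    # sample moments to keep the fit proper
    bounds = [(m - 4 * sd, m + 2 * sd), (np.log(SIGMA_FLOOR), np.log(4 * sd))]
    res = optimize.minimize(
        nll, x0=[m, np.log(sd)], method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500},
    )
    mu, sigma = float(res.x[0]), float(np.exp(res.x[1]))
    return TruncatedNormalFit(mu, max(sigma, SIGMA_FLOOR), float(np.max(trunc)), n)


def impute_knn_tn(
    matrix: pd.DataFrame,
    k: int = 10,
    min_shared: int = 4,
) -> pd.DataFrame:
    """Truncated-normal KNN imputation of a log2 intensity matrix.

    Each site is standardized by its left-truncated-normal fit (truncation
    at the per-sample minimum observed log2 intensity, the proxy for each
    sample's detection limit).  Neighbors are the ``k`` sites closest in
    root-mean-square distance over jointly observed standardized entries
    (at least ``min_shared`` shared entries); a missing entry is the mean of
    the neighbors' standardized values at that sample, mapped back through
    the target site's (mu, sigma).  Observed entries are never altered.

    Sites with fewer than 3 observations, or without any usable neighbor at
    a sample, fall back to the site's fitted (or global) mean, with a log
    record.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = matrix.to_numpy(float)
    n_sites, n_samples = X.shape
    observed = ~np.isnan(X)
    if observed.all():
        return matrix.copy()
    sample_min = np.nanmin(np.where(observed, X, np.inf), axis=0)

    mus = np.empty(n_sites)
    sigmas = np.empty(n_sites)
    global_mean = float(np.nanmean(X))
    n_sparse = 0
    for i in range(n_sites):
        obs = observed[i]
        if obs.sum() < 3:
            n_sparse += 1
            mus[i] = np.nanmean(X[i]) if obs.any() else global_mean
            sigmas[i] = SIGMA_FLOOR
            continue
        fit = fit_truncated_normal(X[i, obs], sample_min[obs])
        mus[i], sigmas[i] = fit.mu, fit.sigma
    if n_sparse:
        logger.info("%d site(s) with <3 observations imputed from their mean", n_sparse)

    Z = (X - mus[:, None]) / sigmas[:, None]
    Zf = np.where(observed, Z, 0.0)
    M = observed.astype(float)
    shared = M @ M.T
    sq = Zf**2
    d2_sum = (sq @ M.T) + (M @ sq.T) - 2 * (Zf @ Zf.T)
    with np.errstate(invalid="ignore", divide="ignore"):
        d2_mean = np.where(shared > 0, d2_sum / np.maximum(shared, 1), np.inf)
    d2_mean[shared < min_shared] = np.inf
    np.fill_diagonal(d2_mean, np.inf)

    out = X.copy()
    need = np.flatnonzero(~observed.all(axis=1))
    # stable neighbor order: distance, then site order
    order_key = np.arange(n_sites) * 1e-12
    n_fallback = 0
    for i in need:
        d = d2_mean[i] + order_key
        finite = np.isfinite(d)
        if not finite.any():
            out[i, ~observed[i]] = mus[i]
            n_fallback += 1
            continue
        cand = np.flatnonzero(finite)
        neighbors = cand[np.argsort(d[cand], kind="stable")][:k]
        for j in np.flatnonzero(~observed[i]):
            donors = neighbors[observed[neighbors, j]]
            if len(donors) == 0:
                out[i, j] = mus[i]
                n_fallback += 1
            else:
                out[i, j] = mus[i] + sigmas[i] * float(np.mean(Z[donors, j]))
    if n_fallback:
        logger.info("%d missing cell(s) fell back to the site mean", n_fallback)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def impute_sample_minimum(matrix: pd.DataFrame) -> pd.DataFrame:
    """Baseline imputation: replace missing with the sample's minimum observed
    value (the naive limit-of-detection substitution KNN-TN is compared to)."""
    X = matrix.to_numpy(float).copy()
    col_min = np.nanmin(X, axis=0)
    idx = np.where(np.isnan(X))
    X[idx] = col_min[idx[1]]
    return pd.DataFrame(X, index=matrix.index, columns=matrix.columns)


def median_normalize(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Shift each sample so all sample medians equal the median of medians.

    Returns the normalized matrix and the applied per-sample shifts.
    """
    if matrix.isna().any().any():
        raise ValueError("median normalization expects a complete matrix")
    medians = matrix.median(axis=0)
    target = float(np.median(medians.to_numpy()))
    shifts = target - medians
    logger.info("median normalization shifts: %s", shifts.round(4).to_dict())
    return matrix + shifts, shifts


# ---------------------------------------------------------------------------
# surrogate variable
# ---------------------------------------------------------------------------


@dataclass
class SurrogateVariable:
    """One latent batch direction estimated from the residual matrix.

    ``scores`` is the first right singular vector of the design-projected
    residuals: unit norm and orthogonal to every design column by
    construction.  ``covariate`` is the factor-score refinement used for
    model adjustment: each sample's raw column regressed on the residual
    loadings, centered and unit-normalized.  Unlike ``scores`` it retains
    the batch component that happens to align with the design in a finite
    sample, so including it as a covariate removes batch-design
    confounding instead of silently leaving it in the contrasts.
    """

    scores: pd.Series
    variance_explained: float
    covariate: pd.Series | None = None

    @property
    def model_scores(self) -> pd.Series:
        """Scores to use as the adjustment covariate in linear models."""
        return self.covariate if self.covariate is not None else self.scores


def estimate_surrogate_variable(
    matrix: pd.DataFrame, design_matrix: pd.DataFrame, n_sv: int = 1
) -> SurrogateVariable:
    """Surrogate variable of a sites x samples matrix given a design.

    The matrix is residualized on the design across samples; the leading
    right singular vector of the residuals is the surrogate variable
    (orthogonal to the design), and ``variance_explained`` is its squared
    singular value as a fraction of total residual variance.  The factor
    loadings (first left singular vector) are then used to score every raw
    sample column, giving the ``covariate`` series for model adjustment.
    """
    if n_sv != 1:
        raise ValueError("only a single surrogate variable is supported")
    X = design_matrix.to_numpy(float)
    Y = matrix.to_numpy(float)
    if list(design_matrix.index) != list(matrix.columns):
        raise ValueError("design rows must match matrix sample columns")
    H = X @ np.linalg.pinv(X)
    R = Y - Y @ H.T
    total = float(np.sum(R**2))
    if total <= 1e-12 * Y.size:
        raise ValueError("residual matrix is (numerically) zero; no SV to estimate")
    u, s, vt = np.linalg.svd(R, full_matrices=False)
    v = vt[0]
    # deterministic sign: largest-|loading| element positive
    v = v * np.sign(v[np.argmax(np.abs(v))])
    g = u[:, 0]
    cov = Y.T @ g
    cov = cov - cov.mean()
    nrm = np.linalg.norm(cov)
    if nrm > 0:
        cov = cov / nrm
        cov = cov * np.sign(cov[np.argmax(np.abs(cov))])
    return SurrogateVariable(
        scores=pd.Series(v, index=matrix.columns, name="SV"),
        variance_explained=float(s[0] ** 2 / total),
        covariate=pd.Series(cov, index=matrix.columns, name="SV"),
    )


def adjust_matrix_for_sv(
    matrix: pd.DataFrame,
    design_matrix: pd.DataFrame,
    sv: SurrogateVariable,
) -> pd.DataFrame:
    """Remove the fitted SV component from every site.

    The SV coefficient is estimated per site jointly with the design and
    only the SV term is subtracted, so design-attributable signal is
    untouched.  Intended for visualization/clustering/PCA; statistical
    tests include the SV as a covariate instead.
    """
    v = sv.model_scores.reindex(matrix.columns).to_numpy()
    X = np.column_stack([design_matrix.to_numpy(float), v])
    beta = matrix.to_numpy() @ np.linalg.pinv(X).T
    sv_coef = beta[:, -1]
    out = matrix.to_numpy() - np.outer(sv_coef, v)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def pca_qc(matrix: pd.DataFrame, n_components: int = 2) -> pd.DataFrame:
    """Sample scores on the first principal components of the row-centered
    matrix, with a deterministic sign convention (largest-|loading| sample
    score positive per component)."""
    Y = matrix.to_numpy(float)
    Y = Y - Y.mean(axis=1, keepdims=True)
    _, s, vt = np.linalg.svd(Y, full_matrices=False)
    comps = []
    for i in range(min(n_components, vt.shape[0])):
        v = vt[i] * s[i]
        v = v * np.sign(v[np.argmax(np.abs(v))]) if np.any(v) else v
        comps.append(v)
    return pd.DataFrame(
        np.column_stack(comps),
        index=matrix.columns,
        columns=[f"PC{i + 1}" for i in range(len(comps))],
    )
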