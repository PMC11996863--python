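"""Empirical-Bayes moderated linear-model statistics.

Per site, an ordinary least-squares fit of a shared design matrix yields a
coefficient vector, unscaled standard errors and a residual variance
``s2_g`` on ``d_g`` degrees of freedom.  The residual variances are shrunk
toward a common prior by modeling ``s2_g ~ s0^2 * chi^2_{d0}/d0`` scaled
inverse-chi-square mixing, estimated by matching the moments of
``log s2_g`` to a log-F distribution.  The moderated t statistic replaces
``s_g`` with the posterior standard deviation

    s2_post = (d0 * s0^2 + d_g * s2_g) / (d0 + d_g)

and gains ``d0`` extra degrees of freedom; the moderated F statistic is the
mean of squared moderated t values over an orthogonalized contrast set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: canonical contrast names produced by the pipeline
CONTRASTS = (
    "ctl_ins_vs_bas",
    "t2d_ins_vs_bas",
    "t2d_vs_ctl_basal",
    "t2d_vs_ctl_ins",
    "stim_ratio_diff",
    "sex_F",
)


@dataclass
class LinearFit:
    """Per-site OLS results for a shared design matrix.

    Attributes
    ----------
    coefficients
        Sites x coefficients estimates.
    xtx_inv
        ``(X'X)^{-1}`` of the shared design (coefficients x coefficients).
    s2
        Per-site residual variance (0 when ``df == 0``).
    df
        Residual degrees of freedom (scalar; the matrix is complete).
    columns
        Design-matrix column names.
    """

    coefficients: pd.DataFrame
    xtx_inv: np.ndarray
    s2: pd.Series
    df: int
    columns: list[str]

    def contrast_estimates(self, contrast: np.ndarray) -> tuple[pd.Series, float]:
        """Return per-site contrast estimate and its unscaled standard error."""
        c = np.asarray(contrast, float)
        beta_c = self.coefficients.to_numpy() @ c
        u = float(np.sqrt(c @ self.xtx_inv @ c))
        return pd.Series(beta_c, index=self.coefficients.index), u


@dataclass
class ModerationParams:
    """Empirical-Bayes prior: ``d0`` may be ``inf`` (complete shrinkage)."""

    d0: float
    s0_2: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ValueError("d0 must be >= 0")
        if self.d0 > 0 and not self.s0_2 > 0:
            raise ValueError("s0_2 must be > 0")

    def posterior_s2(self, s2: np.ndarray, df: float) -> np.ndarray:
        if self.d0 == 0:
            return np.asarray(s2, float)
        if np.isinf(self.d0):
            return np.full(np.shape(s2), self.s0_2)
        return (self.d0 * self.s0_2 + df * np.asarray(s2, float)) / (self.d0 + df)


def fit_linear_model(matrix: pd.DataFrame, design_matrix: pd.DataFrame) -> LinearFit:
    """OLS of every site (row of ``matrix``) on a shared design.

    Parameters
    ----------
    matrix
        Complete sites x samples frame.
    design_matrix
        Samples x coefficients frame; rows must align with the matrix columns.

    Raises
    ------
    ValueError
        If the design is rank deficient (the error names collinear columns)
        or has no residual degrees of freedom.
    """
    X = design_matrix.to_numpy(float)
    n, p = X.shape
    if list(design_matrix.index) != list(matrix.columns):
        raise ValueError("design rows must match matrix sample columns")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name a minimal set of columns that do not extend the rank
        bad = []
        acc = np.empty((n, 0))
        for j, name in enumerate(design_matrix.columns):
            cand = np.column_stack([acc, X[:, j]])
            if np.linalg.matrix_rank(cand) == acc.shape[1]:
                bad.append(name)
            else:
                acc = cand
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    if n <= p:
        raise ValueError(f"need more samples ({n}) than coefficients ({p})")
    Y = matrix.to_numpy(float)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = Y @ X @ xtx_inv.T
    resid = Y - beta @ X.T
    df = n - p
    s2 = (resid**2).sum(axis=1) / df
    return LinearFit(
        coefficients=pd.DataFrame(beta, index=matrix.index, columns=design_matrix.columns),
        xtx_inv=xtx_inv,
        s2=pd.Series(s2, index=matrix.index),
        df=df,
        columns=list(design_matrix.columns),
    )


def fit_moderation(s2: np.ndarray, df: float) -> ModerationParams:
    """Estimate the variance prior ``(d0, s0^2)`` by moment matching.

    With ``e_g = log s2_g - digamma(df/2) + log(df/2)``, the model implies
    ``var(e) = trigamma(df/2) + trigamma(d0/2)``; ``d0`` is found by monotone
    inversion of the trigamma function and ``s0^2`` from the mean equation.
    A non-positive variance deficit gives ``d0 = inf``.
    """
    s2 = np.asarray(s2, float)
    s2 = s2[np.isfinite(s2)]
    if len(s2) < 10:
        raise ValueError("need >= 10 residual variances to fit moderation")
    if np.all(s2 == 0):
        raise ValueError("all residual variances are zero")
    # guard against exact zeros (perfectly fit sites)
    floor = np.min(s2[s2 > 0]) * 1e-12
    log_s2 = np.log(np.maximum(s2, floor))
    e = log_s2 - special.digamma(df / 2) + np.log(df / 2)
    target = np.var(e, ddof=1) - special.polygamma(1, df / 2)
    if target <= 0:
        return ModerationParams(d0=np.inf, s0_2=float(np.exp(np.mean(e))))
    d0 = 2 * _trigamma_inverse(target)
    s0_2 = np.exp(np.mean(e) + special.digamma(d0 / 2) - np.log(d0 / 2))
    return ModerationParams(d0=float(d0), s0_2=float(s0_2))


def _trigamma_inverse(y: float) -> float:
    """Solve ``trigamma(x) = y`` for x > 0 (trigamma is strictly decreasing)."""
    if y <= 0:
        return np.inf
    # bracket: trigamma(x) ~ 1/x + 1/(2x^2) for large x, ~ 1/x^2 for small x
    lo, hi = 1e-8, 1e8
    while special.polygamma(1, hi) > y:  # pragma: no cover - y tiny
        hi *= 10
    while special.polygamma(1, lo) < y:  # pragma: no cover - y huge
        lo /= 10
    return float(optimize.brentq(lambda x: special.polygamma(1, x) - y, lo, hi, xtol=1e-12))


def moderated_t(
    fit: LinearFit,
    params: ModerationParams,
    contrast: np.ndarray | str,
) -> pd.DataFrame:
    """Two-sided moderated t-test of one contrast.

    Returns a frame with ``log2fc, t, df_total, p, fdr`` per site.  With
    ``d0 = 0`` this is the ordinary t-test; with ``d0 = inf`` the statistic
    is Gaussian with the prior standard deviation.
    """
    if isinstance(contrast, str):
        c = np.zeros(len(fit.columns))
        c[fit.columns.index(contrast)] = 1.0
    else:
        c = np.asarray(contrast, float)
    beta_c, u = fit.contrast_estimates(c)
    if u == 0:
        raise ValueError("contrast has zero unscaled standard error")
    s2_post = params.posterior_s2(fit.s2.to_numpy(), fit.df)
    t = beta_c.to_numpy() / (u * np.sqrt(s2_post))
    df_total = params.d0 + fit.df
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df_total)
    return pd.DataFrame(
        {
            "log2fc": beta_c,
            "t": t,
            "df_total": df_total,
            "p": p,
            "fdr": bh_fdr(p),
        },
        index=fit.coefficients.index,
    )


def moderated_f(
    fit: LinearFit,
    params: ModerationParams,
    contrasts: np.ndarray,
) -> pd.DataFrame:
    """Moderated F-test of a set of contrasts (rows of ``contrasts``).

    The contrast estimates are whitened by the Cholesky factor of their
    unscaled covariance, so the statistic equals the mean of squared
    moderated t values over an orthogonalized contrast set.  A single
    contrast reduces to the square of :func:`moderated_t`.
    """
    C = np.atleast_2d(np.asarray(contrasts, float))
    k = C.shape[0]
    if k < 1:
        raise ValueError("need at least one contrast")
    V = C @ fit.xtx_inv @ C.T  # unscaled covariance of C beta
    L = np.linalg.cholesky(V)
    B = fit.coefficients.to_numpy() @ C.T  # sites x k
    Z = np.linalg.solve(L, B.T).T  # whitened
    s2_post = params.posterior_s2(fit.s2.to_numpy(), fit.df)
    F = (Z**2).sum(axis=1) / (k * s2_post)
    df_total = params.d0 + fit.df
    if np.isinf(df_total):
        p = stats.chi2.sf(k * F, k)
    else:
        p = stats.f.sf(F, k, df_total)
    return pd.DataFrame(
        {"F": F, "df1": k, "df_total": df_total, "p": p, "fdr": bh_fdr(p)},
        index=fit.coefficients.index,
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def paired_stimulation_ratios(
    matrix: pd.DataFrame, design: pd.DataFrame
) -> pd.DataFrame:
    """Per-cell-line log2(insulin/basal) stimulation ratios.

    ``matrix`` is log2 scale (sites x samples); the returned frame has one
    column per cell line with both treatments present.  Unpaired cell lines
    are dropped with a warning.
    """
    ratios = {}
    for cell_line, grp in design.groupby("cell_line", sort=True):
        by_tr = grp.set_index("treatment")["sample_id"]
        if "basal" not in by_tr.index or "insulin" not in by_tr.index:
            logger.warning("cell line %s lacks a basal/insulin pair; skipped", cell_line)
            continue
        ratios[cell_line] = matrix[by_tr["insulin"]] - matrix[by_tr["basal"]]
    if not ratios:
        raise ValueError("no cell line has both treatments")
    return pd.DataFrame(ratios, index=matrix.index)


# ---------------------------------------------------------------------------
# pipeline-level contrast runner
# ---------------------------------------------------------------------------


def build_design_matrix(
    design: pd.DataFrame,
    terms: list[str],
    sv: pd.Series | None = None,
) -> pd.DataFrame:
    """Treatment-coded design matrix for a sample subset.

    ``terms`` may contain ``treatment`` (insulin vs basal), ``phenotype``
    (T2D vs CTL), ``sex`` (F vs M) and ``cell_line`` (fixed effects for
    pairing, first line as reference).  An intercept is always included;
    the surrogate variable, when given, enters as a numeric covariate.
    """
    idx = design["sample_id"]
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(design))}
    for term in terms:
        if term == "treatment":
            cols["treatment"] = (design["treatment"] == "insulin").to_numpy(float)
        elif term == "phenotype":
            cols["phenotype"] = (design["phenotype"] == "T2D").to_numpy(float)
        elif term == "sex":
            cols["sex"] = (design["sex"] == "F").to_numpy(float)
        elif term == "cell_line":
            lines = sorted(design["cell_line"].unique())
            for line in lines[1:]:
                cols[f"cell_line[{line}]"] = (design["cell_line"] == line).to_numpy(float)
        else:
            raise ValueError(f"unknown design term {term!r}")
    X = pd.DataFrame(cols, index=idx)
    if sv is not None:
        X["SV"] = sv.reindex(idx).to_numpy()
    return X


def run_contrasts(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    sv: pd.Series | None = None,
) -> pd.DataFrame:
    """All canonical contrasts on a complete, normalized log2 matrix.

    * ``ctl_ins_vs_bas`` / ``t2d_ins_vs_bas`` — paired moderated t of
      insulin vs basal within each phenotype (cell-line fixed effects + SV).
    * ``t2d_vs_ctl_basal`` / ``t2d_vs_ctl_ins`` — unpaired moderated t of
      phenotype within one treatment state (+ SV).
    * ``stim_ratio_diff`` — unpaired moderated t comparing per-cell-line
      stimulation ratios between phenotypes (the impaired/emergent
      interaction test).
    * ``sex_F`` — moderated t of sex (F - M) on basal samples (+ phenotype
      and SV covariates); the squared statistic is the single-contrast
      moderated F screen for dimorphism.

    Returns a long frame with ``site_id, contrast, log2fc, t, df_total, p,
    fdr`` rows; FDR is computed within each contrast family.
    """
    pieces = []

    def _run(sub: pd.DataFrame, terms: list[str], coef: str, name: str) -> None:
        data = matrix[sub["sample_id"]]
        X = build_design_matrix(sub, terms, sv)
        fit = fit_linear_model(data, X)
        params = fit_moderation(fit.s2.to_numpy(), fit.df)
        res = moderated_t(fit, params, coef)
        res.insert(0, "contrast", name)
        pieces.append(res.rename_axis("site_id").reset_index())

    for pheno, name in (("CTL", "ctl_ins_vs_bas"), ("T2D", "t2d_ins_vs_bas")):
        sub = design[design["phenotype"] == pheno]
        _run(sub, ["treatment", "cell_line"], "treatment", name)
    for treatment, name in (("basal", "t2d_vs_ctl_basal"), ("insulin", "t2d_vs_ctl_ins")):
        sub = design[design["treatment"] == treatment]
        _run(sub, ["phenotype"], "phenotype", name)

    # interaction: unpaired t on per-cell-line stimulation ratios; the SV
    # enters as the per-line insulin-minus-basal score difference so batch
    # drift does not leak into the ratios
    ratios = paired_stimulation_ratios(matrix, design)
    line_info = (
        design.drop_duplicates("cell_line")
        .set_index("cell_line")
        .loc[ratios.columns]
        .rename_axis("cell_line")
        .reset_index()
    )
    line_design = pd.DataFrame(
        {
            "sample_id": line_info["cell_line"],
            "cell_line": line_info["cell_line"],
            "phenotype": line_info["phenotype"].to_numpy(),
            "sex": line_info["sex"].to_numpy(),
            "treatment": "basal",
        }
    )
    delta_sv = None
    if sv is not None:
        by_line = design.pivot(index="cell_line", columns="treatment", values="sample_id")
        by_line = by_line.loc[ratios.columns]
        delta_sv = pd.Series(
            sv.reindex(by_line["insulin"]).to_numpy()
            - sv.reindex(by_line["basal"]).to_numpy(),
            index=pd.Index(ratios.columns, name="sample_id"),
        )
    X_ratio = build_design_matrix(line_design, ["phenotype"], delta_sv)
    fit = fit_linear_model(ratios, X_ratio)
    params = fit_moderation(fit.s2.to_numpy(), fit.df)
    res = moderated_t(fit, params, "phenotype")
    res.insert(0, "contrast", "stim_ratio_diff")
    pieces.append(res.rename_axis("site_id").reset_index())

    sub = design[design["treatment"] == "basal"]
    _run(sub, ["sex", "phenotype"], "sex", "sex_F")

    out = pd.concat(pieces, ignore_index=True)
    return out[["site_id", "contrast", "log2fc", "t", "df_total", "p", "fdr"]]


def contrast_frame(results: pd.DataFrame, contrast: str) -> pd.DataFrame:
    """Extract one contrast from the long results frame, indexed by site."""
    sub = results[results["contrast"] == contrast]
    if sub.empty:
        raise ValueError(f"contrast {contrast!r} absent from results")
    return sub.set_index("site_id").drop(columns="contrast")
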