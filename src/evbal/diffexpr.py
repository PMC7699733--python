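"""Covariate-corrected moderated differential expression of log-iBAQ values.

Per protein, an ordinary least-squares fit of log2(x+1) intensity on an
intercept + cancer-status + covariate (gender, smoking) design, followed by
empirical-Bayes variance moderation: residual variances s_g^2 are assumed
scaled inverse-chi-square with prior (d0, s0^2) estimated by the method of
moments on log residual variances, shrunk to

    s_post^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

and the moderated t statistic beta_g / (u_g * s_post) referred to a t
distribution with d_g + d0 degrees of freedom.  With d0 = 0 the moderated t
reduces exactly to the ordinary OLS t.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .containers import QuantMatrix, SampleMetadata

logger = logging.getLogger("evbal")


class DesignError(ValueError):
    """The design matrix is rank-deficient or misaligned."""


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------


def build_design(
    meta: SampleMetadata,
    covariates: Sequence[str] = ("gender", "smoking"),
    contrast_column: str = "cancer_status",
    contrast_level: str = "YES",
) -> pd.DataFrame:
    """Intercept + contrast indicator + treatment-coded covariate dummies.

    Unused covariate levels are dropped automatically; a rank-deficient
    design raises :class:`DesignError` naming the collinear columns.
    """
    t = meta.table
    cols = {"intercept": np.ones(len(t))}
    cols[contrast_column] = (t[contrast_column] == contrast_level).astype(float).values
    for cov in covariates:
        if cov not in t.columns:
            raise DesignError(f"covariate {cov!r} absent from metadata")
        levels = sorted(t[cov].astype(str).unique())
        for level in levels[1:]:  # first observed level is the reference
            cols[f"{cov}[{level}]"] = (t[cov].astype(str) == level).astype(float).values
    X = pd.DataFrame(cols, index=t.index)
    rank = np.linalg.matrix_rank(X.values)
    if rank < X.shape[1]:
        collinear = _find_collinear(X)
        raise DesignError(f"design matrix is rank deficient; collinear columns: {collinear}")
    return X


def _find_collinear(X: pd.DataFrame) -> list[str]:
    kept: list[str] = []
    bad: list[str] = []
    for col in X.columns:
        trial = X[kept + [col]].values
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            kept.append(col)
        else:
            bad.append(col)
    return bad


# ---------------------------------------------------------------------------
# Empirical-Bayes variance moderation
# ---------------------------------------------------------------------------


def _trigamma(x):
    return polygamma(1, x)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(75):
        tri = float(_trigamma(y))
        dif = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y = y + dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi-square prior.

    Matches residual variances to a scaled F distribution via the moments
    of log(s^2): returns (prior df d0, prior variance s0^2), with d0 = inf
    when the observed spread of log variances is no larger than expected
    from chi-square sampling alone.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        return np.inf, float(np.median(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(_trigamma(df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_2 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # no excess spread beyond chi-square sampling: infinite prior df,
        # scale estimated by the arithmetic mean of the variances
        d0 = np.inf
        s0_2 = float(s2[ok].mean())
    return d0, s0_2


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------


@dataclass
class DEResult:
    """Per-protein differential-expression statistics.

    ``table`` columns: log2fc (cancer − control coefficient), s2
    (residual variance), t (moderated), p_value, adj_p_value,
    n_detected_control, n_detected_cancer, low_detection (excluded from the
    prior fit).  ``df_prior``/``s2_prior`` record the fitted empirical-Bayes
    prior; ``df_residual`` the per-fit residual degrees of freedom.
    """

    table: pd.DataFrame
    df_prior: float
    s2_prior: float
    df_residual: float
    design: pd.DataFrame

    def significant(self, alpha: float = 0.05, adjusted: bool = True) -> pd.Index:
        col = "adj_p_value" if adjusted else "p_value"
        return self.table.index[self.table[col] < alpha]


def adjust_bh(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fit_moderated_model(
    m: QuantMatrix,
    meta: SampleMetadata,
    covariates: Sequence[str] = ("gender", "smoking"),
    min_detections: int = 3,
    prior_df: float | None = None,
) -> DEResult:
    """Fit the moderated two-group model to a log-scale matrix.

    ``m`` must already be on the log2(x+1) scale; zeros are data (not
    missing).  Proteins with fewer than ``min_detections`` total detections
    are flagged and excluded from the empirical-Bayes prior fit but still
    reported.  ``prior_df`` overrides the estimated prior df (0 disables
    moderation entirely).
    """
    meta = meta.aligned_to(m)
    status = meta.table["cancer_status"]
    for level in ("NO", "YES"):
        if (status == level).sum() < 2:
            raise DesignError(f"need >=2 samples with cancer_status={level}")
    X = build_design(meta, covariates)
    Xv = X.values
    n, k = Xv.shape
    df_resid = float(n - k)
    if df_resid <= 0:
        raise DesignError("no residual degrees of freedom")

    Y = m.data.T.values  # samples × proteins
    pinv = np.linalg.pinv(Xv)
    beta = pinv @ Y  # k × proteins
    resid = Y - Xv @ beta
    s2 = (resid**2).sum(axis=0) / df_resid
    # unscaled standard error of the contrast coefficient
    XtX_inv = np.linalg.inv(Xv.T @ Xv)
    contrast_idx = list(X.columns).index("cancer_status")
    u = float(np.sqrt(XtX_inv[contrast_idx, contrast_idx]))
    log2fc = beta[contrast_idx]

    detected = m.detected()
    cancer_mask = (status == "YES").values
    n_det_cancer = detected.loc[:, cancer_mask].sum(axis=1).values
    n_det_control = detected.loc[:, ~cancer_mask].sum(axis=1).values
    low = (n_det_cancer + n_det_control) < min_detections
    if low.any():
        logger.info(
            "fit_moderated_model: %d proteins below %d detections excluded "
            "from the prior fit",
            int(low.sum()),
            min_detections,
        )

    if prior_df is not None:
        d0 = float(prior_df)
        if d0 > 0:
            _, s0_2 = fit_variance_prior(s2[~low], df_resid)
        else:
            s0_2 = float(np.median(s2[s2 > 0])) if (s2 > 0).any() else 1.0
    else:
        d0, s0_2 = fit_variance_prior(s2[~low], df_resid)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + df_resid * s2) / (d0 + df_resid)
        df_total = df_resid + d0
    if d0 == 0:
        s2_post = s2.copy()
        df_total = df_resid

    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = log2fc / (u * np.sqrt(s2_post))
    tstat = np.where(np.isfinite(tstat), tstat, 0.0)
    if np.isinf(df_total):
        pvals = 2.0 * stats.norm.sf(np.abs(tstat))
    else:
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df_total)
    adj = adjust_bh(pvals)

    table = pd.DataFrame(
        {
            "gene_symbol": m.gene_symbols.values,
            "log2fc": log2fc,
            "s2": s2,
            "s2_post": s2_post,
            "t": tstat,
            "p_value": pvals,
            "adj_p_value": adj,
            "n_detected_control": n_det_control,
            "n_detected_cancer": n_det_cancer,
            "low_detection": low,
        },
        index=m.data.index,
    )
    return DEResult(table, float(d0), float(s0_2), df_resid, X)


def volcano_table(de: DEResult, alpha: float = 0.05) -> pd.DataFrame:
    """Plotting-ready volcano table: log2FC, −log10 p, significance flags."""
    t = de.table
    if t.empty:
        return pd.DataFrame(
            columns=["gene_symbol", "log2fc", "neg_log10_p", "sig_raw", "sig_adjusted"]
        )
    with np.errstate(divide="ignore"):
        neg_log10 = -np.log10(t["p_value"].values)
    return pd.DataFrame(
        {
            "gene_symbol": t["gene_symbol"].values,
            "log2fc": t["log2fc"].values,
            "neg_log10_p": neg_log10,
            "sig_raw": t["p_value"].values < alpha,
            "sig_adjusted": t["adj_p_value"].values < alpha,
        },
        index=t.index,
    )
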