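import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import digamma, polygamma

from evbal import (
    QuantMatrix,
    SimulationConfig,
    adjust_bh,
    build_design,
    fit_moderated_model,
    generate_cohort,
    log_transform,
    quantile_normalize,
    volcano_table,
)
from evbal.diffexpr import DesignError, fit_variance_prior

from conftest import make_metadata, make_quant


def _ebayes_oracle(Y, groups, d0=None, s0_2=None):
    """Independent re-derivation of the moderated t from the published
    empirical-Bayes formulas, for a two-group design without covariates."""
    Y = np.asarray(Y, dtype=float)
    g = np.asarray(groups, dtype=bool)
    n1, n2 = (~g).sum(), g.sum()
    n = n1 + n2
    df = n - 2
    mean1 = Y[:, ~g].mean(axis=1)
    mean2 = Y[:, g].mean(axis=1)
    beta = mean2 - mean1
    rss = ((Y[:, ~g] - mean1[:, None]) ** 2).sum(axis=1) + (
        (Y[:, g] - mean2[:, None]) ** 2
    ).sum(axis=1)
    s2 = rss / df
    u = np.sqrt(1.0 / n1 + 1.0 / n2)
    if d0 is None:
        # method of moments on log s2
        z = np.log(s2)
        e = z - digamma(df / 2) + np.log(df / 2)
        evar = e.var(ddof=1) - polygamma(1, df / 2)
        assert evar > 0
        # invert trigamma by bisection
        lo, hi = 1e-6, 1e8
        for _ in range(200):
            mid = np.sqrt(lo * hi)
            if polygamma(1, mid) > evar:
                lo = mid
            else:
                hi = mid
        d0 = 2 * lo
        s0_2 = np.exp(e.mean() + digamma(d0 / 2) - np.log(d0 / 2))
    s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
    t = beta / (u * np.sqrt(s2_post))
    p = 2 * stats.t.sf(np.abs(t), df + d0)
    return beta, t, p, d0, s0_2


class TestModeratedModel:
    def test_prior_df_zero_reduces_to_ordinary_t(self):
        rng = np.random.default_rng(0)
        Y = rng.normal(20, 2, size=(200, 10))
        m = make_quant(Y)
        meta = make_metadata(5, 5)
        de = fit_moderated_model(m, meta, covariates=(), prior_df=0.0, min_detections=0)
        # ordinary two-sample equal-variance t via the regression identity
        g = np.array([False] * 5 + [True] * 5)
        _, t_ref, _, _, _ = _ebayes_oracle(Y, g, d0=0.0, s0_2=1.0)
        assert np.abs(de.table["t"].values - t_ref).max() < 1e-8

    def test_matches_independent_ebayes_oracle(self):
        rng = np.random.default_rng(1)
        scale = 0.5 + rng.gamma(2.0, 1.0, size=300)
        Y = 20 + rng.normal(0, 1, size=(300, 6)) * np.sqrt(scale)[:, None]
        m = make_quant(Y)
        meta = make_metadata(3, 3)
        de = fit_moderated_model(m, meta, covariates=(), min_detections=0)
        g = np.array([False] * 3 + [True] * 3)
        beta, t_ref, p_ref, d0, s0_2 = _ebayes_oracle(Y, g)
        assert abs(de.df_prior - d0) < 1e-4 * max(d0, 1.0)
        assert np.abs(de.table["log2fc"].values - beta).max() < 1e-10
        assert np.abs(de.table["t"].values - t_ref).max() < 1e-6
        assert np.abs(de.table["p_value"].values - p_ref).max() < 1e-6

    def test_matches_limma_reference(self, tmp_path):
        """Cross-check against the Bioconductor reference implementation."""
        rng = np.random.default_rng(7)
        scale = 0.3 + rng.gamma(2.0, 1.0, size=80)
        Y = 20 + rng.normal(0, 1, size=(80, 6)) * np.sqrt(scale)[:, None]
        pd.DataFrame(Y).to_csv(tmp_path / "y.csv", index=False)
        r_code = (
            "suppressMessages(library(limma));"
            f'y <- as.matrix(read.csv("{tmp_path}/y.csv"));'
            "design <- cbind(Intercept=1, cancer=c(0,0,0,1,1,1));"
            "fit <- eBayes(lmFit(y, design));"
            'write.csv(data.frame(t=fit$t[,"cancer"], p=fit$p.value[,"cancer"]),'
            f'"{tmp_path}/limma.csv", row.names=FALSE)'
        )
        proc = subprocess.run(
            ["Rscript", "-e", r_code], capture_output=True, text=True, timeout=300
        )
        assert proc.returncode == 0, proc.stderr
        lim = pd.read_csv(tmp_path / "limma.csv")
        de = fit_moderated_model(
            make_quant(Y), make_metadata(3, 3), covariates=(), min_detections=0
        )
        assert np.abs(lim["t"].values - de.table["t"].values).max() < 1e-8
        assert np.abs(lim["p"].values - de.table["p_value"].values).max() < 1e-8

    def test_null_p_values_approximately_uniform(self):
        rng = np.random.default_rng(42)
        Y = rng.normal(20, 1.0, size=(1000, 24))
        de = fit_moderated_model(
            make_quant(Y), make_metadata(12, 12), covariates=(), min_detections=0
        )
        ks = stats.kstest(de.table["p_value"].values, "uniform").statistic
        assert ks < 0.05

    def test_orthogonal_covariate_leaves_log2fc_unchanged(self):
        rng = np.random.default_rng(5)
        Y = rng.normal(20, 2, size=(100, 8))
        # gender perfectly balanced within each cancer group -> orthogonal
        meta_plain = make_metadata(4, 4)
        meta_cov = make_metadata(
            4, 4, gender=["F", "F", "M", "M", "F", "F", "M", "M"]
        )
        de1 = fit_moderated_model(
            make_quant(Y), meta_plain, covariates=(), min_detections=0
        )
        de2 = fit_moderated_model(
            make_quant(Y), meta_cov, covariates=("gender",), min_detections=0
        )
        assert np.abs(
            de1.table["log2fc"].values - de2.table["log2fc"].values
        ).max() < 1e-10

    def test_rank_deficient_design_names_collinear_column(self):
        # gender coincides with cancer status -> collinear
        meta = make_metadata(3, 3, gender=["F", "F", "F", "M", "M", "M"])
        with pytest.raises(DesignError, match="gender"):
            build_design(meta, ("gender",))

    def test_too_few_samples_per_group_rejected(self):
        m = make_quant(np.ones((5, 3)))
        meta = make_metadata(1, 2)
        with pytest.raises(DesignError):
            fit_moderated_model(m, meta, covariates=())

    def test_low_detection_proteins_flagged_but_reported(self):
        vals = np.ones((3, 6)) * 100.0
        vals[0, :] = 0.0
        vals[0, 0] = 50.0  # single detection
        de = fit_moderated_model(
            make_quant(vals), make_metadata(3, 3), covariates=(), min_detections=3
        )
        assert de.table["low_detection"].tolist() == [True, False, False]
        assert len(de.table) == 3


class TestBH:
    def test_hand_computed_example(self):
        assert np.allclose(adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_degenerate(self):
        assert adjust_bh([0.2]).tolist() == [0.2]
        assert adjust_bh([1.0, 1.0]).tolist() == [1.0, 1.0]

    def test_monotone_step_up_and_bounds(self):
        rng = np.random.default_rng(0)
        p = rng.random(100)
        adj = adjust_bh(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.5])


class TestVolcano:
    def test_neg_log10_and_flags(self):
        rng = np.random.default_rng(2)
        Y = rng.normal(20, 1, size=(50, 6))
        de = fit_moderated_model(
            make_quant(Y), make_metadata(3, 3), covariates=(), min_detections=0
        )
        v = volcano_table(de)
        i = de.table["p_value"].values.argmin()
        assert np.isclose(
            v["neg_log10_p"].iloc[i], -np.log10(de.table["p_value"].iloc[i])
        )
        assert round(-np.log10(0.05), 3) == 1.301
        assert (v["sig_adjusted"] == (de.table["adj_p_value"] < 0.05)).all()


class TestPriorFit:
    def test_infinite_prior_for_homogeneous_variances(self):
        s2 = np.full(200, 2.5)
        d0, s0 = fit_variance_prior(s2, 10)
        assert np.isinf(d0)
        assert s0 == pytest.approx(2.5)

    def test_finite_prior_recovered_from_inverse_chisq_draws(self):
        rng = np.random.default_rng(10)
        d0_true, s0_true, df = 6.0, 2.0, 8
        prior_var = d0_true * s0_true / stats.chi2.rvs(d0_true, size=20000, random_state=rng)
        s2 = prior_var * stats.chi2.rvs(df, size=20000, random_state=rng) / df
        d0, s0 = fit_variance_prior(s2, df)
        assert abs(d0 - d0_true) / d0_true < 0.15
        assert abs(s0 - s0_true) / s0_true < 0.1
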