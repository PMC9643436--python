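"""Unit tests for the empirical-Bayes ComBat core."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

import opncombat as oc
from opncombat.combat import build_design, eb_shrink, standardize
from opncombat.data import ValidationError

from conftest import planted_dataset


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def test_build_design_shapes(toy_dataset):
    _, meta = toy_dataset
    d = build_design(meta, "batch", ["sex"])
    assert d.batch_onehot.shape == (6, 2)
    assert d.covariate_matrix.shape == (6, 1)
    assert d.covariate_columns == ["sex[m]"]
    d0 = build_design(meta, "batch", [])
    assert d0.covariate_matrix.shape == (6, 0)


def test_build_design_rejects_collinear_and_constant_covariates(toy_dataset):
    feat, meta = toy_dataset
    tab = meta.table.copy()
    tab["copy_of_batch"] = tab["batch"]
    tab["const"] = "x"
    meta2 = oc.SampleMetadata(
        tab, batch_vars=["batch"],
        categorical_covariates=["sex", "copy_of_batch", "const"],
    )
    with pytest.raises(ValidationError, match="collinear"):
        build_design(meta2, "batch", ["copy_of_batch"])
    with pytest.raises(ValidationError, match="constant"):
        build_design(meta2, "batch", ["const"])


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def test_standardize_matches_group_mean_oracle():
    """gamma_hat for the shifted batch equals the difference of standardized
    batch means computed independently from raw group summaries."""
    feat, meta = planted_dataset(n=200, p=20, shift=1.0, seed=3)
    design = build_design(meta, "batch", [])
    Z, alpha, beta, sigma2, const = standardize(feat, design)
    assert not const.any()
    # independent oracle: per-batch means/variances straight from the data
    Y = feat.values.to_numpy()
    lab = meta.batch_labels("batch").to_numpy()
    na, nb = (lab == "a").sum(), (lab == "b").sum()
    grand = (na * Y[lab == "a"].mean(0) + nb * Y[lab == "b"].mean(0)) / (na + nb)
    resid = Y.copy()
    resid[lab == "a"] -= Y[lab == "a"].mean(0)
    resid[lab == "b"] -= Y[lab == "b"].mean(0)
    pooled = (resid**2).sum(0) / (na + nb)
    z_oracle = (Y - grand) / np.sqrt(pooled)
    np.testing.assert_allclose(Z, z_oracle, atol=1e-10)
    np.testing.assert_allclose(alpha, grand, atol=1e-10)
    # weighted batch means of Z cancel (standardization identity)
    wmean = (na * Z[lab == "a"].mean(0) + nb * Z[lab == "b"].mean(0)) / (na + nb)
    np.testing.assert_allclose(wmean, 0.0, atol=1e-10)


def test_standardize_flags_constant_feature(toy_dataset):
    feat, meta = toy_dataset
    vals = feat.values.copy()
    vals["fc"] = 7.0
    feat_const = oc.FeatureMatrix(vals)
    h, est = oc.harmonize_single(feat_const, meta, "batch", eb=False)
    assert est.constant_features == ["fc"]
    np.testing.assert_array_equal(h.values["fc"], vals["fc"])


def test_standardized_scores_centered_and_unit_scale():
    rng = np.random.default_rng(0)
    ids = [f"s{i}" for i in range(30)]
    feat = oc.FeatureMatrix(
        pd.DataFrame(rng.normal(2, 3, size=(30, 4)), index=ids)
    )
    meta = oc.SampleMetadata(
        pd.DataFrame({"b": ["x"] * 15 + ["y"] * 15}, index=ids), batch_vars=["b"]
    )
    design = build_design(meta, "b", [])
    Z, alpha, *_ = standardize(feat, design)
    np.testing.assert_allclose(Z.mean(0), 0.0, atol=1e-12)
    # pooled within-batch variance of Z is exactly 1 by construction
    lab = meta.batch_labels("b").to_numpy()
    resid = Z.copy()
    for lv in ("x", "y"):
        resid[lab == lv] -= Z[lab == lv].mean(0)
    np.testing.assert_allclose((resid**2).sum(0) / 30, 1.0, atol=1e-12)


# ---------------------------------------------------------------------------
# empirical Bayes
# ---------------------------------------------------------------------------

def _naive_eb_oracle(Z, labels, levels, tol=1e-4, max_iter=1000):
    """Straight-line scalar reimplementation of the EB fixed point."""
    gamma_star = []
    delta2_star = []
    for lv in levels:
        sel = labels == lv
        n = sel.sum()
        Zi = Z[sel]
        g_hat = Zi.mean(axis=0)
        d_hat = Zi.var(axis=0, ddof=1)
        g_bar = g_hat.mean()
        t2 = g_hat.var(ddof=1)
        m = d_hat.mean()
        s2 = d_hat.var(ddof=1)
        lam = (2 * s2 + m**2) / s2
        th = (m * s2 + m**3) / s2
        gs = np.empty_like(g_hat)
        ds = np.empty_like(d_hat)
        for j in range(Z.shape[1]):
            g_old, d_old = g_hat[j], d_hat[j]
            for _ in range(max_iter):
                g_new = (t2 * n * g_hat[j] + d_old * g_bar) / (t2 * n + d_old)
                s = 0.0
                for v in Zi[:, j]:
                    s += (v - g_new) ** 2
                d_new = (0.5 * s + th) / (n / 2.0 + lam - 1.0)
                change = max(abs(g_new - g_old), abs(d_new - d_old))
                g_old, d_old = g_new, d_new
                if change < tol:
                    break
            gs[j], ds[j] = g_old, d_old
        gamma_star.append(gs)
        delta2_star.append(ds)
    return np.array(gamma_star), np.array(delta2_star)


def test_eb_matches_naive_fixed_point_oracle():
    """Both routes iterate to the unique fixed point of the two update
    equations; run both to a tight tolerance and compare."""
    feat, meta = planted_dataset(n=120, p=50, shift=0.6, scale=1.3, seed=9)
    design = build_design(meta, "batch", [])
    Z, *_ = standardize(feat, design)
    _, _, gamma_star, delta2_star, _ = eb_shrink(
        Z, design, tol=1e-10, max_iter=10000
    )
    lab = meta.batch_labels("batch").to_numpy()
    g_o, d_o = _naive_eb_oracle(Z, lab, design.levels, tol=1e-10, max_iter=10000)
    np.testing.assert_allclose(gamma_star, g_o, atol=1e-8)
    np.testing.assert_allclose(delta2_star, d_o, atol=1e-8)


def test_eb_shrinks_toward_prior_mean():
    feat, meta = planted_dataset(n=150, p=40, shift=0.8, scale=1.4, seed=5)
    design = build_design(meta, "batch", [])
    Z, *_ = standardize(feat, design)
    gamma_hat, _, gamma_star, _, priors = eb_shrink(Z, design)
    for i, pp in enumerate(priors):
        assert np.all(
            np.abs(gamma_star[i] - pp["gamma_bar"])
            <= np.abs(gamma_hat[i] - pp["gamma_bar"]) + 1e-12
        )


def test_eb_no_shrinkage_limit_with_huge_gamma_spread():
    """When gamma_hat varies enormously across features (tau2 -> inf),
    the posterior mean collapses onto gamma_hat."""
    rng = np.random.default_rng(1)
    n, p = 60, 30
    labels = np.array(["a"] * 30 + ["b"] * 30)
    # plant per-feature batch shifts with a huge spread
    shifts = rng.normal(0, 1000, size=p)
    Y = rng.normal(size=(n, p))
    Y[labels == "b"] += shifts
    feat = oc.FeatureMatrix(
        pd.DataFrame(Y, index=[f"s{i}" for i in range(n)])
    )
    meta = oc.SampleMetadata(
        pd.DataFrame({"batch": labels}, index=feat.sample_ids), batch_vars=["batch"]
    )
    design = build_design(meta, "batch", [])
    Z, *_ = standardize(feat, design)
    gamma_hat, _, gamma_star, _, _ = eb_shrink(Z, design)
    np.testing.assert_allclose(gamma_star, gamma_hat, rtol=0.02, atol=1e-3)


# ---------------------------------------------------------------------------
# adjustment
# ---------------------------------------------------------------------------

def test_two_batches_eb_off_equalizes_moments():
    feat, meta = planted_dataset(n=200, p=30, shift=1.0, scale=1.5, seed=2)
    h, _ = oc.harmonize_single(feat, meta, "batch", eb=False)
    Y = h.values.to_numpy()
    lab = meta.batch_labels("batch").to_numpy()
    ga, gb = Y[lab == "a"], Y[lab == "b"]
    np.testing.assert_allclose(ga.mean(0), gb.mean(0), atol=1e-8)
    np.testing.assert_allclose(ga.var(0, ddof=1), gb.var(0, ddof=1), atol=1e-8)


def test_second_pass_is_pure_residual_rescale():
    """A second EB-off pass cannot find any batch effect left to remove:
    it only contracts residuals by the deterministic factor sqrt((n-k)/n)
    coming from the 1/n pooled-variance convention, leaving per-batch
    moments equalized."""
    n, k = 150, 2
    feat, meta = planted_dataset(n=n, p=25, shift=0.7, scale=1.2, seed=8)
    h1, est1 = oc.harmonize_single(feat, meta, "batch", eb=False)
    h2, est2 = oc.harmonize_single(h1, meta, "batch", eb=False)
    # no location effect remains for the second pass to estimate
    np.testing.assert_allclose(est2.gamma_hat, 0.0, atol=1e-10)
    c = np.sqrt((n - k) / n)
    expected = est1.alpha[None, :] + (
        h1.values.to_numpy() - est1.alpha[None, :]
    ) * c
    np.testing.assert_allclose(h2.values.to_numpy(), expected, atol=1e-8)
    # and per-batch moments stay equalized
    Y = h2.values.to_numpy()
    lab = meta.batch_labels("batch").to_numpy()
    np.testing.assert_allclose(
        Y[lab == "a"].mean(0), Y[lab == "b"].mean(0), atol=1e-8
    )


def test_covariate_contrast_preserved():
    """Planted binary covariate effect 1.0: the batch-adjusted contrast
    attributable to the covariate survives harmonization within 5%."""
    feat, meta = planted_dataset(
        n=200, p=40, shift=0.8, scale=1.3, seed=6, covariate_effect=1.0
    )
    Y = feat.values.to_numpy()
    lab = meta.batch_labels("batch").to_numpy()
    cov = (meta.covariate("cov") == "1").to_numpy().astype(float)
    X = np.column_stack([np.ones(len(cov)), (lab == "b").astype(float), cov])

    def contrast(M):
        return np.linalg.lstsq(X, M, rcond=None)[0][2].mean()

    h, _ = oc.harmonize_single(feat, meta, "batch", ["cov"], eb=True)
    pre, post = contrast(Y), contrast(h.values.to_numpy())
    assert abs(post - pre) / abs(pre) < 0.05


def test_sample_permutation_commutes_with_harmonization():
    feat, meta = planted_dataset(n=80, p=10, shift=0.5, seed=4)
    h, _ = oc.harmonize_single(feat, meta, "batch", ["cov"], eb=True)
    rng = np.random.default_rng(0)
    perm = rng.permutation(list(feat.sample_ids))
    h_perm, _ = oc.harmonize_single(
        feat.reorder(perm), meta.reorder(perm), "batch", ["cov"], eb=True
    )
    np.testing.assert_allclose(
        h_perm.values.to_numpy(), h.values.loc[perm].to_numpy(), atol=1e-10
    )


def test_matches_bioconductor_sva_reference(tmp_path):
    """Independent oracle: sva::ComBat (parametric EB, with a protected
    covariate) agrees with harmonize_single on a small fixture."""
    if shutil.which("Rscript") is None:
        pytest.fail("Rscript not available for the reference cross-check")
    feat, meta = planted_dataset(
        n=40, p=12, shift=0.7, scale=1.3, seed=7, covariate_effect=0.5
    )
    h, _ = oc.harmonize_single(feat, meta, "batch", ["cov"], eb=True)
    feat.values.to_csv(tmp_path / "Y.csv", header=False, index=False)
    meta.table.to_csv(tmp_path / "meta.csv", index=False)
    script = f"""
    suppressMessages(library(sva))
    Y <- as.matrix(read.csv("{tmp_path}/Y.csv", header=FALSE))
    meta <- read.csv("{tmp_path}/meta.csv")
    mod <- model.matrix(~factor(cov), data=meta)
    out <- ComBat(dat=t(Y), batch=meta$batch, mod=mod, par.prior=TRUE)
    write.table(t(out), "{tmp_path}/sva.csv", sep=",",
                row.names=FALSE, col.names=FALSE)
    """
    subprocess.run(
        ["Rscript", "-e", script], check=True, capture_output=True, text=True
    )
    ref = np.loadtxt(tmp_path / "sva.csv", delimiter=",")
    np.testing.assert_allclose(h.values.to_numpy(), ref, atol=1e-3)


def test_apply_combat_feature_mismatch_raises(toy_dataset):
    feat, meta = toy_dataset
    _, est = oc.harmonize_single(feat, meta, "batch", eb=False)
    renamed = oc.FeatureMatrix(
        feat.values.rename(columns={"fa": "other"})
    )
    from opncombat.combat import apply_combat, build_design as bd

    with pytest.raises(ValidationError, match="different features"):
        apply_combat(renamed, bd(meta, "batch", []), est)
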