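"""Design construction and Gibbs-sampler correctness checks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dermabs import (
    DermalAbsorptionLMM,
    ModelParams,
    PriorSpec,
    SyntheticTruth,
    build_design,
    generate_logit_dataset,
)
from dermabs.model import PARAM_NAMES

from conftest import TRUE_PARAMS


def _tiny_table():
    rows = []
    cells = [
        ("dilution", "organic_solvent", [1, 0, 0, 0, 0]),
        ("concentrate", "solid", [1, 1, 0, 1, 0]),
        ("concentrate", "water_based", [1, 1, 0, 0, 1]),
        ("dilution", "other", [1, 0, 1, 0, 0]),
    ]
    for i, (status, cat, _) in enumerate(cells):
        rows.append(
            {
                "substance": f"s{i % 2}",
                "study_id": f"st{i}",
                "formulation_category": cat,
                "status": status,
                "group_id": f"g{i}",
                "target_concentration": 1.0,
                "fraction_absorbed": 0.1,
                "y": -2.2,
            }
        )
    return pd.DataFrame(rows), [c[2] for c in cells]


def test_fixed_effect_coding_uses_dilution_and_organic_solvent_reference():
    table, expected_rows = _tiny_table()
    design = build_design(table)
    np.testing.assert_array_equal(design.X, np.array(expected_rows, dtype=float))


def test_substance_columns_are_status_specific():
    table, _ = _tiny_table()
    design = build_design(table)
    # row 0: substance s0 dilution -> even column; row 2: s0 concentrate -> odd
    assert design.b_col[0] % 2 == 0
    assert design.b_col[2] == design.b_col[0] + 1


def test_unseen_category_label_rejected():
    table, _ = _tiny_table()
    table.loc[0, "formulation_category"] = "aqueous"
    with pytest.raises(ValueError, match="aqueous"):
        build_design(table)


def test_empty_table_rejected():
    table, _ = _tiny_table()
    with pytest.raises(ValueError):
        DermalAbsorptionLMM(table.iloc[0:0])


def test_identical_seeds_give_bit_identical_draws(balanced_cell_weights):
    truth = SyntheticTruth.reduced(
        n_substances=10, seed=5, cell_weights=balanced_cell_weights
    )
    prepared, _ = generate_logit_dataset(truth)
    a = DermalAbsorptionLMM(prepared).fit(draws=50, burnin=20, seed=11)
    b = DermalAbsorptionLMM(prepared).fit(draws=50, burnin=20, seed=11)
    pd.testing.assert_frame_equal(a.posterior, b.posterior)
    c = DermalAbsorptionLMM(prepared).fit(draws=50, burnin=20, seed=12)
    assert not a.posterior.equals(c.posterior)


def test_collapsed_sampler_matches_conjugate_regression_posterior(
    balanced_cell_weights,
):
    """With random effects omitted, Gibbs draws of the fixed effects and the
    residual variance must match the closed-form normal-inverse-chi-squared
    posterior of Bayesian linear regression (KS distance < 0.05)."""
    zero = ModelParams(
        **{**TRUE_PARAMS, "var_substance_dilution": 0.0,
           "var_substance_concentrate": 0.0, "rho_substance": 0.0,
           "var_study": 0.0, "var_within": 0.0},
        var_resid=0.8,
    )
    truth = SyntheticTruth.reduced(
        n_substances=12, seed=21, params=zero, cell_weights=balanced_cell_weights
    )
    prepared, _ = generate_logit_dataset(truth)
    model = DermalAbsorptionLMM(prepared, include_random_effects=False)
    res = model.fit(draws=2000, burnin=300, seed=9)

    design = build_design(prepared)
    X, y = design.X, design.y
    n, p = X.shape
    XtX = X.T @ X
    beta_hat = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta_hat
    s2 = float(resid @ resid) / (n - p)
    cov_unscaled = np.linalg.inv(XtX)
    rng = np.random.default_rng(123)
    sigma2 = (n - p) * s2 / rng.chisquare(n - p, size=2000)
    L = np.linalg.cholesky(cov_unscaled)
    betas = beta_hat + (
        np.sqrt(sigma2)[:, None] * (rng.standard_normal((2000, p)) @ L.T)
    )
    for j, name in enumerate(PARAM_NAMES[:5]):
        ks = stats.ks_2samp(res.posterior[name], betas[:, j]).statistic
        assert ks < 0.05, f"{name}: KS={ks:.3f}"
    ks_var = stats.ks_2samp(res.posterior["var_resid"], sigma2).statistic
    assert ks_var < 0.05


def test_degenerate_simulation_recovers_fixed_effects(balanced_cell_weights):
    """All random-effect variances zero and a tiny residual: posterior means
    of the fixed effects sit on the generating values."""
    degen = ModelParams(
        **{**TRUE_PARAMS, "var_substance_dilution": 0.0,
           "var_substance_concentrate": 0.0, "rho_substance": 0.0,
           "var_study": 0.0, "var_within": 0.0},
        var_resid=0.01,
    )
    truth = SyntheticTruth.reduced(
        n_substances=16, seed=2, params=degen, cell_weights=balanced_cell_weights
    )
    prepared, _ = generate_logit_dataset(truth)
    res = DermalAbsorptionLMM(prepared).fit(draws=400, burnin=200, seed=3)
    means = res.posterior[list(PARAM_NAMES[:5])].mean()
    for name in PARAM_NAMES[:5]:
        assert means[name] == pytest.approx(TRUE_PARAMS[name], abs=0.1)


def test_substance_label_invariance(balanced_cell_weights):
    """Renaming substances permutes design columns but leaves posterior
    summaries unchanged within Monte-Carlo error."""
    truth = SyntheticTruth.reduced(
        n_substances=15, seed=13, cell_weights=balanced_cell_weights
    )
    prepared, _ = generate_logit_dataset(truth)
    res_a = DermalAbsorptionLMM(prepared).fit(draws=600, burnin=250, seed=4)

    renamed = prepared.table.copy()
    subs = sorted(renamed["substance"].unique())
    mapping = {s: f"zz{len(subs) - i:03d}" for i, s in enumerate(subs)}
    renamed["substance"] = renamed["substance"].map(mapping)
    res_b = DermalAbsorptionLMM(renamed).fit(draws=600, burnin=250, seed=4)

    for name in PARAM_NAMES[:5]:
        assert res_a.posterior[name].mean() == pytest.approx(
            res_b.posterior[name].mean(), abs=0.2
        )
    for name in ("var_substance_dilution", "var_substance_concentrate", "var_study"):
        assert res_a.posterior[name].mean() == pytest.approx(
            res_b.posterior[name].mean(), rel=0.4
        )


def test_summary_reports_ten_parameters_with_intervals(small_fit):
    _, _, _, results = small_fit
    s = results.summary()
    assert list(s.index) == list(PARAM_NAMES[:10])
    assert (s["hpdi_2.5"] <= s["mean"]).all()
    assert (s["mean"] <= s["hpdi_97.5"]).all()
    assert (s["ess"] > 10).all()
    for name in ("var_substance_dilution", "var_substance_concentrate",
                 "var_study", "var_within", "var_resid"):
        assert (results.posterior[name] > 0).all()


def test_prior_spec_rejects_improper_settings():
    with pytest.raises(ValueError):
        PriorSpec(fixed_effect_variance=0.0)
    with pytest.raises(ValueError):
        PriorSpec(G_df=1.0)
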