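"""Fixed-effects DiD estimator and multiway clustered variance, checked
against closed forms, an explicit-dummy statsmodels oracle, and a
brute-force inclusion-exclusion oracle."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from snfdid.estimation import (ModelSpec, fe_ols_core, fit_fe_ols,
                               fit_stratified, multiway_cluster_vcov,
                               relative_change, within_transform)
from snfdid.exceptions import (DomainError, SingularityError,
                               SpecificationError)


def _toy_panel(rng, n_episodes=200, n_fac_per_setting=4, n_months=6,
               effect=0.0, with_fp=True):
    """Random small panel with the episode-pair structure."""
    rows = []
    ann = n_months // 2
    for e in range(n_episodes):
        m = rng.integers(0, n_months)
        post = int(m >= ann)
        hosp = f"H{rng.integers(n_fac_per_setting)}"
        snf = f"S{rng.integers(n_fac_per_setting)}"
        fp = int(rng.random() < 0.7) if with_fp else 0
        latent = rng.normal(10, 3)
        for treat, facility in ((0, hosp), (1, snf)):
            y = latent + 0.3 * m + treat * post * effect + rng.normal(0, 1)
            rows.append({"episode_id": f"E{e}", "beneficiary_id": f"B{e}",
                         "treat": treat, "post": post,
                         "treat_post": treat * post, "fp": fp,
                         "fp_post": fp * post,
                         "treat_post_fp": treat * post * fp,
                         "period": "pre" if post == 0 else "post",
                         "facility_id": facility, "ym": f"m{m:02d}",
                         "n_dx": y, "x1": rng.normal()})
    return pd.DataFrame(rows)


def test_2x2_closed_form_did_identity():
    """With one facility per setting and two time cells, the interaction
    coefficient is the textbook double difference of cell means."""
    rng = np.random.default_rng(0)
    panel = _toy_panel(rng, n_episodes=400, n_fac_per_setting=1, n_months=2,
                       effect=1.5)
    spec = ModelSpec(outcome="n_dx", covariates=(),
                     clusters=("beneficiary",))
    res = fit_fe_ols(panel, spec)
    cell = panel.groupby(["treat", "post"])["n_dx"].mean()
    dd = (cell[1, 1] - cell[1, 0]) - (cell[0, 1] - cell[0, 0])
    assert res.beta["treat_post"] == pytest.approx(dd, abs=1e-8)


@pytest.mark.parametrize("interaction", ["two_way", "three_way"])
def test_demeaned_ols_matches_explicit_dummy_oracle(interaction):
    """Coefficients from FE absorption equal explicit-dummy OLS to 1e-6."""
    rng = np.random.default_rng(1)
    panel = _toy_panel(rng, n_episodes=240, n_fac_per_setting=3, n_months=5,
                       effect=0.8)
    spec = ModelSpec(outcome="n_dx", interaction=interaction,
                     covariates=("x1",), clusters=("beneficiary",))
    res = fit_fe_ols(panel, spec)

    x = pd.concat([panel[spec.interaction_terms() + ["x1"]].astype(float),
                   pd.get_dummies(panel["facility_id"], drop_first=True,
                                  dtype=float),
                   pd.get_dummies(panel["ym"], drop_first=True, dtype=float)],
                  axis=1)
    x = sm.add_constant(x)
    oracle = sm.OLS(panel["n_dx"], x).fit()
    for term in res.beta:
        assert res.beta[term] == pytest.approx(oracle.params[term], abs=1e-6)


def test_singleton_clusters_reduce_to_hc1():
    """Each observation its own cluster -> HC1 sandwich of the explicit-dummy
    regression (same N-K scaling, fixed effects counted)."""
    rng = np.random.default_rng(2)
    df = _toy_panel(rng, n_episodes=150, n_fac_per_setting=2, n_months=4)
    fac_codes = pd.factorize(df["facility_id"])[0]
    ym_codes = pd.factorize(df["ym"])[0]
    z = within_transform(df[["n_dx", "treat_post", "x1"]].to_numpy(float),
                         [fac_codes, ym_codes])
    yd, xd = z[:, 0], z[:, 1:]
    beta = np.linalg.lstsq(xd, yd, rcond=None)[0]
    resid = yd - xd @ beta
    k_model = 2 + (fac_codes.max() + 1 - 1) + (ym_codes.max() + 1 - 1) + 1
    vcov, _, _ = multiway_cluster_vcov(
        xd, resid, {"obs": np.arange(len(df))}, k_model)

    x = pd.concat([df[["treat_post", "x1"]].astype(float),
                   pd.get_dummies(df["facility_id"], drop_first=True, dtype=float),
                   pd.get_dummies(df["ym"], drop_first=True, dtype=float)], axis=1)
    x = sm.add_constant(x)
    oracle = sm.OLS(df["n_dx"], x).fit(cov_type="HC1")
    block = oracle.cov_params().loc[["treat_post", "x1"], ["treat_post", "x1"]]
    assert np.allclose(vcov, block.to_numpy(), rtol=1e-6)


def test_two_way_cgm_equals_bruteforce_inclusion_exclusion():
    """V(A,B) == V_A + V_B - V_{A∩B}, each term built by explicit loops."""
    rng = np.random.default_rng(3)
    n, k = 120, 2
    x = rng.normal(size=(n, k))
    u = rng.normal(size=n)
    a = rng.integers(0, 8, n)
    b = rng.integers(0, 5, n)
    k_model = k
    vcov, counts, _ = multiway_cluster_vcov(
        x, u, {"a": a, "b": b}, k_model)

    def brute(labels):
        bread = np.linalg.inv(x.T @ x)
        groups = {}
        for i, lab in enumerate(labels):
            groups.setdefault(lab, []).append(i)
        meat = np.zeros((k, k))
        for idx in groups.values():
            s = sum(x[i] * u[i] for i in idx)
            meat += np.outer(s, s)
        g = len(groups)
        c = (g / (g - 1)) * ((n - 1) / (n - k_model))
        return c * bread @ meat @ bread

    expected = (brute([f"a{v}" for v in a]) + brute([f"b{v}" for v in b])
                - brute([f"{i}-{j}" for i, j in zip(a, b)]))
    assert np.allclose(vcov, expected, rtol=1e-10)
    assert counts["a"] == 8 and counts["b"] == 5


def test_vcov_permutation_invariance():
    rng = np.random.default_rng(4)
    n = 90
    x = rng.normal(size=(n, 2))
    u = rng.normal(size=n)
    cl = {"a": rng.integers(0, 6, n), "b": rng.integers(0, 4, n)}
    v1, _, _ = multiway_cluster_vcov(x, u, cl, 2)
    perm = rng.permutation(n)
    v2, _, _ = multiway_cluster_vcov(x[perm], u[perm],
                                     {m: c[perm] for m, c in cl.items()}, 2)
    assert np.allclose(v1, v2, rtol=1e-10)


def test_single_cluster_dimension_errors():
    rng = np.random.default_rng(5)
    x = rng.normal(size=(30, 1))
    with pytest.raises(SpecificationError, match="single cluster"):
        multiway_cluster_vcov(x, rng.normal(size=30),
                              {"t": np.zeros(30, dtype=int)}, 1)


def test_outcome_shift_leaves_interaction_unchanged():
    """Adding a constant to all outcomes is absorbed by the fixed effects."""
    rng = np.random.default_rng(6)
    panel = _toy_panel(rng, n_episodes=200, effect=0.5)
    spec = ModelSpec(outcome="n_dx", covariates=(), clusters=("beneficiary",))
    r1 = fit_fe_ols(panel, spec)
    shifted = panel.assign(n_dx=panel["n_dx"] + 100.0)
    r2 = fit_fe_ols(shifted, spec)
    assert r1.beta["treat_post"] == pytest.approx(r2.beta["treat_post"], abs=1e-8)


def test_collinear_column_raises_listing_it():
    rng = np.random.default_rng(7)
    panel = _toy_panel(rng, n_episodes=100)
    panel["dup"] = panel["treat_post"]
    spec = ModelSpec(outcome="n_dx", covariates=("dup",),
                     clusters=("beneficiary",), on_collinear="error")
    with pytest.raises(SingularityError) as err:
        fit_fe_ols(panel, spec)
    assert err.value.columns  # names the dependent column(s)


def test_facility_constant_covariates_reported_absorbed(small_sim):
    res = fit_fe_ols(small_sim["panel"], ModelSpec(outcome="n_dx"))
    # static facility attributes are absorbed by the facility effects
    assert "s_chain" in res.dropped and "h_vbp" in res.dropped
    assert "covid_rate" not in res.dropped  # time-varying survives
    assert res.absorbed["post"] == "time fixed effects"
    assert res.n_obs == 2 * res.n_episodes


def test_relative_change_examples_and_rounding():
    assert relative_change(0.83, 11.7) == 7.1
    assert relative_change(0.88, 6.49) == 13.6
    assert relative_change(0.0, 5.0) == 0.0
    assert relative_change(0.098, 0.038) == 258  # integer above 100
    with pytest.raises(DomainError):
        relative_change(1.0, 0.0)


def test_stratified_degenerate_equals_pooled():
    rng = np.random.default_rng(8)
    panel = _toy_panel(rng, n_episodes=150, effect=0.7)
    panel["fp"] = 1
    panel["fp_post"] = panel["post"]
    panel["treat_post_fp"] = panel["treat_post"]
    spec = ModelSpec(outcome="n_dx", covariates=(), clusters=("beneficiary",))
    pooled = fit_fe_ols(panel, spec)
    strat = fit_stratified(panel, spec, "for_profit")
    assert strat.beta["treat_post"] == pytest.approx(
        pooled.beta["treat_post"], abs=1e-10)
    with pytest.raises(SpecificationError, match="empty"):
        fit_stratified(panel, spec, "nfp")


def test_stratified_estimates_bracket_pooled_on_balanced_design():
    """On a balanced design the pooled DiD is a convex mix of the stratum
    DiDs, so it must lie between them."""
    rng = np.random.default_rng(9)
    frames = []
    for fp, effect, tag in ((1, 1.2, "f"), (0, 0.4, "n")):
        part = _toy_panel(rng, n_episodes=300, n_fac_per_setting=1,
                          n_months=2, effect=effect, with_fp=False)
        part["fp"] = fp
        part["fp_post"] = fp * part["post"]
        part["treat_post_fp"] = fp * part["treat_post"]
        part["episode_id"] = tag + part["episode_id"]
        part["beneficiary_id"] = tag + part["beneficiary_id"]
        part["facility_id"] = tag + part["facility_id"]
        frames.append(part)
    panel = pd.concat(frames, ignore_index=True)
    spec = ModelSpec(outcome="n_dx", covariates=(), clusters=("beneficiary",))
    pooled = fit_fe_ols(panel, spec).beta["treat_post"]
    b_fp = fit_stratified(panel, spec, "fp").beta["treat_post"]
    b_nfp = fit_stratified(panel, spec, "nfp").beta["treat_post"]
    assert min(b_fp, b_nfp) - 1e-9 <= pooled <= max(b_fp, b_nfp) + 1e-9
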