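"""REML core: oracles, frozen cross-checks, Satterthwaite, EMMs."""

import numpy as np
import pandas as pd
import pytest

import repeatkit as rk
from repeatkit.errors import DegenerateDataError, DesignError
from repeatkit.lmm import (ModelSpec, RandomStructure, categorical,
                           continuous, emmeans, fit_reml,
                           fixed_effects_table, pairwise_contrasts,
                           satterthwaite)
from repeatkit.pipeline import rank_cortisol_spec, repeatability_spec

from _oracles import balanced_anova_components, grid_search_reml
from conftest import make_grouped_data

SPEC_Y = ModelSpec(response="y")


# ----------------------------------------------------------------------
# basic behaviour and error handling

def test_perfect_within_group_agreement_gives_R_one():
    """Individuals {1,1} and {3,3}: no within variance, v_between = 2 by the
    balanced one-way identity (MSB - MSW)/m = (4 - 0)/2."""
    df = pd.DataFrame({"individual_id": ["A", "A", "B", "B"],
                       "y": [1.0, 1.0, 3.0, 3.0]})
    fit = fit_reml(df, SPEC_Y)
    assert fit.v_within == pytest.approx(0.0, abs=1e-10)
    assert fit.v_between == pytest.approx(2.0, rel=1e-8)
    R = fit.v_between / (fit.v_between + fit.v_within)
    assert R == pytest.approx(1.0)


def test_constant_response_is_degenerate():
    df = pd.DataFrame({"individual_id": list("AABBCC"), "y": [5.0] * 6})
    with pytest.raises(DegenerateDataError):
        fit_reml(df, SPEC_Y)


def test_rank_deficient_design_names_aliased_column():
    df = make_grouped_data(6, 3, 1.0, 1.0, seed=0)
    df["x1"] = np.arange(len(df), dtype=float)
    df["x2"] = 2.0 * df["x1"]
    spec = ModelSpec(response="y", fixed=(continuous("x1"), continuous("x2")))
    with pytest.raises(DesignError, match="x2|x1"):
        fit_reml(df, spec)


def test_missing_values_are_rejected_not_dropped():
    df = make_grouped_data(6, 3, 1.0, 1.0, seed=0)
    df.loc[3, "y"] = np.nan
    with pytest.raises(ValueError, match="missing"):
        fit_reml(df, SPEC_Y)
    df2 = make_grouped_data(6, 3, 1.0, 1.0, seed=0)
    df2["x"] = 1.0 * np.arange(len(df2))
    df2.loc[5, "x"] = np.nan
    spec = ModelSpec(response="y", fixed=(continuous("x"),))
    with pytest.raises(ValueError, match="missing"):
        fit_reml(df2, spec)


def test_log_transform_requires_positive_response():
    df = make_grouped_data(4, 3, 1.0, 1.0, seed=0)
    spec = ModelSpec(response="y", transform="log")
    with pytest.raises(ValueError, match="non-positive"):
        fit_reml(df, spec)


# ----------------------------------------------------------------------
# oracle equivalences

@pytest.mark.parametrize("seed", range(6))
def test_balanced_reml_equals_anova_estimators(seed):
    """On balanced one-way data REML equals the method-of-moments ANOVA
    estimators whenever MSB >= MSW, and R equals the classical ICC."""
    rng = np.random.default_rng(seed)
    G = int(rng.integers(5, 15))
    m = int(rng.integers(2, 6))
    df = make_grouped_data(G, m, v_between=1.5, v_within=1.0,
                           seed=1000 + seed)
    fit = fit_reml(df, SPEC_Y)
    g = df["individual_id"].to_numpy()
    vb, vw, icc = balanced_anova_components(df["y"].to_numpy(), g)
    if vb > 0:
        assert fit.v_between == pytest.approx(vb, abs=1e-6)
        assert fit.v_within == pytest.approx(vw, abs=1e-6)
        R = fit.v_between / (fit.v_between + fit.v_within)
        assert R == pytest.approx(icc, abs=1e-6)


def test_reml_matches_dense_grid_search_with_covariates():
    rng = np.random.default_rng(5)
    df = make_grouped_data(30, 4, v_between=1.0, v_within=1.0, seed=5)
    df["x"] = rng.normal(size=len(df))
    df["y"] = df["y"] + 0.5 * df["x"]
    spec = ModelSpec(response="y", fixed=(continuous("x"),))
    fit = fit_reml(df, spec)
    design = fit._X
    vb, vw = grid_search_reml(fit._y, fit._X, fit._groups)
    assert fit.v_between == pytest.approx(vb, abs=1e-3)
    assert fit.v_within == pytest.approx(vw, abs=1e-3)


def test_reml_loglik_is_a_local_maximum():
    df = make_grouped_data(20, 4, 0.8, 1.2, seed=9)
    fit = fit_reml(df, SPEC_Y)
    base = fit.neg2_reml(fit.theta)
    for f_b in (0.8, 0.95, 1.05, 1.25):
        for f_w in (0.8, 0.95, 1.05, 1.25):
            theta = fit.theta * np.array([f_b, f_w])
            assert fit.neg2_reml(theta) >= base - 1e-8


def test_matches_statsmodels_mixedlm():
    import statsmodels.formula.api as smf

    df = make_grouped_data(25, 4, 0.7, 1.3, seed=21)
    df["x"] = np.random.default_rng(2).normal(size=len(df))
    df["y"] = df["y"] + 0.3 * df["x"]
    spec = ModelSpec(response="y", fixed=(continuous("x", center=False),))
    fit = fit_reml(df, spec)
    m = smf.mixedlm("y ~ x", df, groups=df["individual_id"]).fit(reml=True)
    assert fit.v_between == pytest.approx(m.cov_re.iloc[0, 0], rel=1e-4)
    assert fit.v_within == pytest.approx(m.scale, rel=1e-4)
    assert fit.beta["(Intercept)"] == pytest.approx(m.params["Intercept"],
                                                    rel=1e-4)
    assert fit.beta["x"] == pytest.approx(m.params["x"], rel=1e-4)


def test_affine_recoding_of_covariate_rescales_slope_only():
    df = make_grouped_data(15, 3, 1.0, 1.0, seed=31)
    df["x"] = np.random.default_rng(3).normal(size=len(df))
    df["y"] = df["y"] + 0.4 * df["x"]
    spec = ModelSpec(response="y", fixed=(continuous("x"),))
    fit1 = fit_reml(df, spec)
    df2 = df.assign(x=3.0 * df["x"] + 10.0)
    fit2 = fit_reml(df2, spec)
    assert fit2.beta["x"] == pytest.approx(fit1.beta["x"] / 3.0, rel=1e-7)
    # the restricted likelihood shifts by exactly -log|a| for a column
    # scaled by a (the log|X'V^-1X| term); everything else is invariant
    assert fit2.loglik_reml == pytest.approx(fit1.loglik_reml - np.log(3.0),
                                             abs=1e-7)
    assert fit2.v_between == pytest.approx(fit1.v_between, rel=1e-7)
    assert fit2.v_within == pytest.approx(fit1.v_within, rel=1e-7)


# ----------------------------------------------------------------------
# frozen cross-check: random-intercept model on the committed fixture
# (reference values computed once with lme4/lmerTest, REML, Satterthwaite)

FROZEN_A = {
    "v_between": 0.3225482405,
    "v_within": 0.0294134800,
    "loglik": -15.9372902998,
    # term: (estimate, se, df, t, p)
    "coefs": {
        "(Intercept)": (7.420653483096, 0.265732929428, 8.514068950,
                        27.9252311675, 1.133156292e-09),
        "rank_index": (0.370737674177, 0.468119575690, 14.068780938,
                       0.7919721657, 0.441526610400587),
        "weight_start": (0.001691102941, 0.002028272416, 12.966451905,
                         0.8337651922, 0.419508150327288),
        "measurement[1]": (0.153306226939, 0.097345528178, 18.273598888,
                           1.5748666611, 0.132441370470293),
        "group_id[group2]": (0.378042793095, 0.372451161958, 8.202622153,
                             1.0150130586, 0.339100760382601),
    },
}


def test_random_intercept_fit_matches_frozen_reference(fixture_frames):
    per_test, _ = fixture_frames
    fit = fit_reml(per_test, repeatability_spec("cortisol_resp_2h", "log"))
    assert fit.converged and not fit.boundary
    assert fit.v_between == pytest.approx(FROZEN_A["v_between"], rel=1e-5)
    assert fit.v_within == pytest.approx(FROZEN_A["v_within"], rel=1e-5)
    assert fit.loglik_reml == pytest.approx(FROZEN_A["loglik"], abs=1e-6)
    table = fixed_effects_table(fit).set_index("term")
    for term, (est, se, df, t, p) in FROZEN_A["coefs"].items():
        row = table.loc[term]
        assert row["estimate"] == pytest.approx(est, rel=1e-5, abs=1e-9)
        assert row["se"] == pytest.approx(se, rel=1e-5)
        assert row["df"] == pytest.approx(df, rel=2e-3)
        assert row["t_value"] == pytest.approx(t, rel=1e-4)
        assert row["p_value"] == pytest.approx(p, rel=5e-3)


# frozen cross-check: random-slope model (intercept + sampling-time slopes,
# unstructured covariance); the fixture fit is singular (rank-deficient G),
# which the machinery must handle the same way the reference stack does.

FROZEN_B = {
    "v_within": 468148.73123389,
    "loglik": -526.82588265,
    "coefs": {
        "(Intercept)": (842.084140946, 220.929593699, 60.806144870),
        "sampling_time[resp_1h]": (1097.456435300, 359.811546524,
                                   10.650729597),
        "sampling_time[resp_2h]": (1474.249355205, 428.560536912,
                                   10.439176236),
        "rank_index": (-264.491669398, 484.268264368, 29.310394377),
        "weight_start": (1.048590404, 1.545253641, 27.292388737),
        "measurement[1]": (58.565513989, 169.365576597, 53.497857423),
        "group_id[group2]": (277.981907117, 255.880576374, 26.665569760),
        "sampling_time[resp_1h]:rank_index": (150.174290827,
                                              1117.925249907, 13.797591243),
        "sampling_time[resp_2h]:rank_index": (157.230509128,
                                              1321.390427463, 13.869972507),
    },
    "emmeans": {
        "baseline": (1010.35785150, 148.67223646),
        "resp_1h": (2107.81428680, 286.18325037),
        "resp_2h": (2484.60720670, 357.75616899),
    },
    # later level minus earlier level
    "contrasts": {
        "resp_1h - baseline": (1097.45643530, 359.81154652, 10.650729597,
                               3.05008676, 0.011434872),
        "resp_2h - baseline": (1474.24935520, 428.56053691, 10.439176236,
                               3.44000259, 0.005951270),
        "resp_2h - resp_1h": (376.79291990, 212.94406796, 24.313747730,
                              1.76944549, 0.089362554),
    },
}


@pytest.fixture(scope="module")
def slope_fit(fixture_frames):
    _, long = fixture_frames
    return fit_reml(long, rank_cortisol_spec())


def test_random_slope_fit_matches_frozen_reference(slope_fit):
    fit = slope_fit
    assert fit.converged
    assert fit.q_random == 3 and fit.G.shape == (3, 3)
    assert fit.v_within == pytest.approx(FROZEN_B["v_within"], rel=1e-5)
    assert fit.loglik_reml == pytest.approx(FROZEN_B["loglik"], abs=1e-5)
    # G is positive semi-definite (boundary rank-deficiency allowed)
    eig = np.linalg.eigvalsh(fit.G)
    assert eig.min() >= -1e-6 * max(eig.max(), 1.0)
    table = fixed_effects_table(fit).set_index("term")
    for term, (est, se, df) in FROZEN_B["coefs"].items():
        row = table.loc[term]
        assert row["estimate"] == pytest.approx(est, rel=1e-4)
        assert row["se"] == pytest.approx(se, rel=1e-4)
        assert row["df"] == pytest.approx(df, rel=1e-2)


def test_emmeans_and_contrasts_match_frozen_reference(slope_fit):
    emms = emmeans(slope_fit, "sampling_time")
    frame = emms.to_frame().set_index("level")
    for level, (mean, se) in FROZEN_B["emmeans"].items():
        assert frame.loc[level, "emmean"] == pytest.approx(mean, rel=1e-5)
        assert frame.loc[level, "se"] == pytest.approx(se, rel=1e-4)
    contrasts = {c.name: c for c in pairwise_contrasts(emms)}
    assert len(contrasts) == 3
    for name, (est, se, df, t, p) in FROZEN_B["contrasts"].items():
        c = contrasts[name]
        assert c.estimate == pytest.approx(est, rel=1e-5)
        assert c.se == pytest.approx(se, rel=1e-4)
        assert c.df == pytest.approx(df, rel=1e-2)
        assert c.t_value == pytest.approx(t, rel=1e-3)
        assert c.p_value == pytest.approx(p, rel=2e-2)


# ----------------------------------------------------------------------
# Satterthwaite degrees of freedom

def test_balanced_one_way_intercept_df_is_groups_minus_one():
    """In a balanced one-way random-effects model the intercept's variance
    is MSB/(G m), carrying the classical G - 1 degrees of freedom."""
    df = make_grouped_data(6, 4, v_between=2.0, v_within=1.0, seed=13)
    fit = fit_reml(df, SPEC_Y)
    assert not fit.boundary
    res = satterthwaite(fit, np.array([1.0]))
    assert res.df == pytest.approx(5.0, rel=0.02)


def test_boundary_fit_falls_back_to_residual_df():
    """With v_between estimated at 0 the model collapses to ordinary
    regression: df = n_obs - rank(X)."""
    df = make_grouped_data(12, 3, v_between=0.0, v_within=1.0, seed=44)
    # ensure the boundary is hit for this seed
    fit = fit_reml(df, SPEC_Y)
    assert fit.boundary and fit.v_between == 0.0
    with pytest.warns(UserWarning, match="residual df"):
        res = satterthwaite(fit, np.array([1.0]))
    assert res.df == pytest.approx(fit.n_obs - 1)


# ----------------------------------------------------------------------
# estimated marginal means

def _factor_data(seed=0, beta=(0.0, 1.0, 2.5)):
    rng = np.random.default_rng(seed)
    G, levels = 10, ["a", "b", "c"]
    rows = []
    for i in range(G):
        u = rng.normal(0, 1)
        w = rng.normal(0, 1)
        for rep in range(2):
            for k, lev in enumerate(levels):
                rows.append((f"id{i}", lev, w,
                             beta[k] + u + rng.normal(0, 0.5)))
    return pd.DataFrame(rows, columns=["individual_id", "time", "w", "y"])


def test_balanced_emms_equal_raw_level_means():
    df = _factor_data(seed=1)
    spec = ModelSpec(response="y", fixed=(categorical("time"),))
    fit = fit_reml(df, spec)
    emms = emmeans(fit, "time")
    raw = df.groupby("time")["y"].mean()
    for lev, mean in zip(emms.levels, emms.emmean):
        assert mean == pytest.approx(raw[lev], abs=1e-8)


def test_centered_covariate_leaves_balanced_emms_unchanged():
    df = _factor_data(seed=2)
    spec0 = ModelSpec(response="y", fixed=(categorical("time"),))
    spec1 = ModelSpec(response="y",
                      fixed=(categorical("time"), continuous("w")))
    e0 = emmeans(fit_reml(df, spec0), "time")
    e1 = emmeans(fit_reml(df, spec1), "time")
    np.testing.assert_allclose(e0.emmean, e1.emmean, atol=1e-8)


def test_equal_level_means_give_zero_contrasts():
    """A factor whose level means coincide exactly yields t = 0, p = 1."""
    rows = []
    for i, base in enumerate([0.0, 4.0, -2.0, 1.0]):
        for k, lev in enumerate(["a", "b", "c"]):
            rows.append((f"id{i}", lev, base + [-1.0, 0.0, 1.0][k]))
            rows.append((f"id{i}", lev, base + [1.0, 0.0, -1.0][k]))
    df = pd.DataFrame(rows, columns=["individual_id", "time", "y"])
    spec = ModelSpec(response="y", fixed=(categorical("time"),))
    fit = fit_reml(df, spec)
    emms = emmeans(fit, "time")
    for c in pairwise_contrasts(emms):
        assert c.estimate == pytest.approx(0.0, abs=1e-10)
        assert c.t_value == pytest.approx(0.0, abs=1e-8)
        assert c.p_value == pytest.approx(1.0, abs=1e-6)


def test_model_spec_round_trips_through_yaml_blocks(fixture_frames):
    """A model declared as YAML-style blocks fits identically to the same
    model built programmatically."""
    import yaml

    from repeatkit.lmm import model_spec_from_dict

    text = """
    response: cortisol_resp_2h
    transform: log
    group: individual_id
    fixed:
      - {name: rank_index, kind: continuous}
      - {name: weight_start, kind: continuous}
      - {name: measurement, kind: categorical, reference: "2"}
      - {name: group_id, kind: categorical}
    random: intercept
    """
    spec = model_spec_from_dict(yaml.safe_load(text))
    per_test, _ = fixture_frames
    fit_yaml = fit_reml(per_test, spec)
    fit_code = fit_reml(per_test,
                        repeatability_spec("cortisol_resp_2h", "log"))
    assert fit_yaml.v_between == pytest.approx(fit_code.v_between, rel=1e-9)
    assert fit_yaml.loglik_reml == pytest.approx(fit_code.loglik_reml,
                                                 abs=1e-9)
    pd.testing.assert_series_equal(fit_yaml.beta, fit_code.beta)


def test_emmeans_requires_a_categorical_factor():
    df = make_grouped_data(5, 3, 1.0, 1.0, seed=3)
    fit = fit_reml(df, SPEC_Y)
    with pytest.raises(DesignError):
        emmeans(fit, "nonexistent")
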