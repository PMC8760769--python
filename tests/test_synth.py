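"""Synthetic-study generator: determinism, structure, moments, limits."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import repeatkit as rk
from repeatkit.errors import ConfigurationError
from repeatkit.pipeline import PipelineConfig, _analysis_frames, \
    repeatability_spec


def test_identical_seeds_give_byte_identical_studies():
    a, _ = rk.generate_study(rk.SyntheticParams(seed=123))
    b, _ = rk.generate_study(rk.SyntheticParams(seed=123))
    for name in ("individuals", "tests", "samples", "rank_indices",
                 "retreats"):
        pd.testing.assert_frame_equal(getattr(a, name), getattr(b, name))
        assert getattr(a, name).to_csv() == getattr(b, name).to_csv()


def test_different_seeds_differ():
    a, _ = rk.generate_study(rk.SyntheticParams(seed=1))
    b, _ = rk.generate_study(rk.SyntheticParams(seed=2))
    assert not a.samples["concentration"].equals(b.samples["concentration"])


def test_default_design_counts():
    params = rk.SyntheticParams()
    tests, samples, _ = rk.generate_cortisol(params)
    assert len(samples) == 2 * 6 * 2 * 3 == 72
    assert len(tests) == 24
    retreats, _ = rk.generate_retreats(params)
    per = retreats.groupby(["focal_id", "phase"]).size()
    assert (per == 30).all()
    per_day = retreats.groupby(["focal_id", "phase", "day_index"]).size()
    assert (per_day == 10).all()


def test_generate_study_composes_the_standalone_fragments():
    params = rk.SyntheticParams(seed=99)
    ds, truth = rk.generate_study(params)
    tests, samples, _ = rk.generate_cortisol(params)
    retreats, dominance = rk.generate_retreats(params)
    pd.testing.assert_frame_equal(ds.tests, tests)
    pd.testing.assert_frame_equal(ds.samples, samples)
    pd.testing.assert_frame_equal(ds.retreats, retreats)
    np.testing.assert_array_equal(truth.dominance, dominance)


def test_generated_study_passes_validation():
    ds, _ = rk.generate_study(rk.SyntheticParams(seed=3))
    ds.validate()  # raises on any invariant violation


def test_vanishing_within_variance_gives_repeatability_one():
    """v_within -> 0 with v_between > 0: repeated log-measures of each
    individual coincide and the fitted R is 1."""
    params = rk.SyntheticParams(seed=5, v_between=0.3, v_within=1e-12,
                                beta={})
    ds, _ = rk.generate_study(params)
    per_test, _ = _analysis_frames(ds, PipelineConfig())
    logc = np.log(per_test["cortisol_resp_2h"].to_numpy())
    # identical on the log scale per individual (up to fp noise from exp/log)
    spread = per_test.assign(logc=logc).groupby("individual_id")["logc"].std()
    assert spread.max() < 1e-4
    spec = rk.ModelSpec(response="cortisol_resp_2h", transform="log")
    R, vc, fit = rk.adjusted_repeatability(per_test, spec)
    assert R == pytest.approx(1.0, abs=1e-6)


@pytest.mark.parametrize("kwargs", [
    {"v_between": -0.1},
    {"v_within": 0.0},
    {"steepness": -1.0},
    {"group_size": 0},
    {"v_between": (0.1, 0.2)},          # wrong triple length
])
def test_invalid_params_rejected(kwargs):
    with pytest.raises(ConfigurationError):
        rk.SyntheticParams(**kwargs)


def test_single_female_group_cannot_have_retreats():
    with pytest.raises(ConfigurationError, match="group_size"):
        rk.generate_retreats(rk.SyntheticParams(group_size=1))


def test_moments_converge_to_specified_components():
    """Empirical between/within variance of simulated log values approaches
    (v_between, v_within) as the design grows."""
    vb, vw = 0.5, 0.25
    params = rk.SyntheticParams(
        n_groups=2, group_size=150, n_phases=6,
        v_between=vb, v_within=vw, seed=17,
        beta={},  # no covariate effects: moments are clean
    )
    tests, samples, _ = rk.generate_cortisol(params)
    sub = samples[samples["sampling_time"] == "resp_2h"]
    logc = np.log(sub["concentration"].to_numpy())
    g = sub["individual_id"].to_numpy()
    from _oracles import balanced_anova_components
    vb_hat, vw_hat, _ = balanced_anova_components(logc, g)
    n = len(sub)
    assert vb_hat == pytest.approx(vb, abs=6 * vb / np.sqrt(300))
    assert vw_hat == pytest.approx(vw, abs=6 * vw / np.sqrt(n))


def test_per_time_variances_allow_distinct_true_repeatabilities():
    params = rk.SyntheticParams(v_between=(0.0, 0.3, 0.3),
                                v_within=(0.3, 0.3, 0.1))
    np.testing.assert_allclose(params.true_repeatability, [0.0, 0.5, 0.75])


def test_zero_between_variance_truncation_bias_matches_closed_form():
    """With no true individual differences the boundary-truncated REML
    estimate has mean E[max(F-1,0)/(F+1)] = 0.1135 at 12 individuals x 2
    phases (F ~ F(11, 12); balanced one-way identity), a small positive
    truncation bias."""
    spec = rk.ModelSpec(response="cortisol_resp_2h", transform="log")
    rs = []
    for seed in range(200):
        params = rk.SyntheticParams(seed=seed, v_between=0.0, v_within=0.2,
                                    beta={})
        tests, samples, _ = rk.generate_cortisol(params)
        sub = samples[samples["sampling_time"] == "resp_2h"]
        sub = sub.rename(columns={"concentration": "cortisol_resp_2h"})
        R, _, _ = rk.adjusted_repeatability(sub, spec)
        rs.append(R)
    assert np.mean(rs) == pytest.approx(0.1135, abs=0.035)


def test_strong_hierarchy_ranks_match_latent_dominance():
    """At steepness 50 retreat outcomes are essentially deterministic;
    observed indices order groupmates almost exactly as the latent
    dominance does (binomial opponent sampling leaves a small residual)."""
    rhos = []
    for seed in range(100):
        params = rk.SyntheticParams(seed=seed, steepness=50.0)
        retreats, dom = rk.generate_retreats(params)
        ids = params.individual_ids()
        for g in range(params.n_groups):
            members = ids[g * 6:(g + 1) * 6]
            dmem = dom[g * 6:(g + 1) * 6]
            for phase in (1, 2):
                out = rk.rank_indices_for_group(retreats, members, phase)
                r = out.set_index("individual_id")["index"]
                rhos.append(spearmanr(r.loc[members], dmem).statistic)
    rhos = np.asarray(rhos)
    assert rhos.mean() >= 0.97
    assert rhos.min() >= 0.9
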