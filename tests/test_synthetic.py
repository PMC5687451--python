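"""Generator checks: determinism, degenerate configs, statistical structure."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from childmbg.demography import PERIODS
from childmbg.gp import chol_psd, matern_cov_xy
from childmbg.grids import GridSpec
from childmbg.synthetic import (
    SurveyDesign,
    TruthConfig,
    make_reference_nationals,
    simulate_cbh,
    simulate_sbh,
    simulate_world,
)


def test_same_seed_gives_identical_world():
    cfg = TruthConfig(nrows=20, ncols=20, seed=7)
    w1, w2 = simulate_world(cfg), simulate_world(cfg)
    np.testing.assert_array_equal(w1.truth_q, w2.truth_q)
    np.testing.assert_array_equal(w1.population, w2.population)
    np.testing.assert_array_equal(w1.admin2, w2.admin2)


def test_zero_heterogeneity_reduces_to_baseline():
    cfg = TruthConfig(
        nrows=10, ncols=10, gp_sd=0.0, covariate_effects=(0.0, 0.0, 0.0),
        period_trend=0.0, seed=1,
    )
    w = simulate_world(cfg)
    for b, q in enumerate(cfg.baseline_q):
        np.testing.assert_allclose(w.truth_q[b], q, rtol=1e-12)


def test_degenerate_config_rejected():
    with pytest.raises(ValueError):
        TruthConfig(gp_rho=1.5)
    with pytest.raises(ValueError):
        TruthConfig(gp_sd=-0.1)
    with pytest.raises(ValueError):
        TruthConfig(nrows=0)


def test_admin_hierarchy_nests(small_world):
    w = small_world
    # every admin2 label encodes its admin1, every admin1 its country
    assert np.array_equal(w.admin2 // 100, w.admin1)
    assert np.array_equal(w.admin1 // 100, w.country)


def test_variogram_recovers_configured_range():
    """Empirical-variogram range estimate over replicates lands within 25%."""
    grid = GridSpec(nrows=50, ncols=50, pixel_km=5.0)
    coords = grid.flat_centers()
    true_range, sd = 80.0, 1.0
    chol = chol_psd(matern_cov_xy(coords, coords, true_range, sd))
    rng = np.random.default_rng(42)
    sub = rng.choice(len(coords), 400, replace=False)
    d = np.linalg.norm(coords[sub][:, None] - coords[sub][None, :], axis=-1)
    iu = np.triu_indices(len(sub), k=1)
    dists = d[iu]
    # fit only up to ~half the domain span; beyond that the finite-domain
    # empirical variogram is dominated by the replicate-level mean
    bins = np.linspace(5, 125, 13)
    which = np.digitize(dists, bins)
    cand = np.linspace(20, 200, 91)
    est = []
    for _ in range(100):
        z = chol @ rng.standard_normal(len(coords))
        sq = 0.5 * (z[sub][:, None] - z[sub][None, :]) ** 2
        emp = np.array([sq[iu][which == k].mean() for k in range(1, len(bins))])
        mid = 0.5 * (bins[:-1] + bins[1:])
        best, best_sse = None, np.inf
        for r in cand:
            model = sd**2 - matern_cov_xy(np.zeros((1, 2)), np.column_stack([mid, np.zeros_like(mid)]), r, sd)[0]
            sse = np.sum((emp - model) ** 2)
            if sse < best_sse:
                best, best_sse = r, sse
        est.append(best)
    mean_est = float(np.mean(est))
    assert abs(mean_est - true_range) / true_range < 0.25


def test_cbh_no_mortality_means_no_deaths(small_world):
    w = dataclasses.replace(small_world)
    w.truth_q = np.zeros_like(small_world.truth_q)
    cbh = simulate_cbh(w, SurveyDesign(n_clusters=20), seed=0)
    assert cbh["death_cmc"].isna().all()


def test_cbh_certain_neonatal_death_kills_every_child(small_world):
    w = dataclasses.replace(small_world)
    w.truth_q = np.zeros_like(small_world.truth_q)
    w.truth_q[0] = 1.0  # neonatal certain death
    cbh = simulate_cbh(w, SurveyDesign(n_clusters=20), seed=0)
    assert (cbh["death_cmc"] == cbh["birth_cmc"]).all()


def test_cbh_deterministic_given_seed(small_world):
    d = SurveyDesign(n_clusters=30)
    a = simulate_cbh(small_world, d, seed=9)
    b = simulate_cbh(small_world, d, seed=9)
    pd.testing.assert_frame_equal(a, b)


def test_tabulated_rates_converge_to_flat_truth():
    """Pooled empirical monthly probability per bin matches a spatially flat
    truth within 3 binomial standard errors at large child-month counts."""
    from childmbg.birth_histories import tabulate_cbh

    cfg = TruthConfig(
        nrows=10, ncols=10, gp_sd=0.0, covariate_effects=(0.0, 0.0, 0.0),
        period_trend=0.0, seed=2,
    )
    w = simulate_world(cfg)
    cbh = simulate_cbh(w, SurveyDesign(n_clusters=150, mothers_per_cluster=25), seed=3)
    bt = tabulate_cbh(cbh)
    g = bt.groupby("age_bin")[["deaths", "exposure"]].sum()
    assert g["exposure"].sum() > 50_000
    for b, q in enumerate(cfg.baseline_q):
        e, d = g.loc[b, "exposure"], g.loc[b, "deaths"]
        se = np.sqrt(q * (1 - q) / e)
        assert abs(d / e - q) < 3 * se


def test_sbh_collapse_identities(small_world):
    sbh, latent = simulate_sbh(
        small_world, SurveyDesign(instrument="SBH", n_clusters=50), seed=4
    )
    assert (sbh["cd"] <= sbh["ceb"]).all()
    assert sbh["ceb"].sum() == len(latent)
    assert sbh["cd"].sum() == latent["death_cmc"].notna().sum()
    # per-mother reconstruction agrees exactly; childless mothers report zero
    per_mother = latent.groupby("mother_id")["death_cmc"].agg(lambda s: s.notna().sum())
    merged = sbh.set_index("mother_id")["cd"]
    pd.testing.assert_series_equal(
        per_mother.sort_index(), merged.loc[per_mother.index].sort_index(),
        check_names=False, check_dtype=False,
    )
    childless = merged.index.difference(per_mother.index)
    assert (sbh.set_index("mother_id").loc[childless, "ceb"] == 0).all()


def test_reference_nationals_perturbation(small_world):
    truth = small_world.true_nationals()
    ref0 = make_reference_nationals(small_world)
    pd.testing.assert_frame_equal(ref0, truth)
    ref = make_reference_nationals(small_world, multiplier=1.05)
    np.testing.assert_allclose(ref["q5"], 1.05 * truth["q5"], rtol=1e-12)
    np.testing.assert_allclose(ref["nmr"], 1.05 * truth["nmr"], rtol=1e-12)


def test_true_nationals_are_population_weighted(small_world):
    w = small_world
    q5, _ = w.true_rate_surfaces()
    nat = w.true_nationals()
    c0 = nat[(nat["country"] == 0) & (nat["period"] == PERIODS[0].label)]["q5"].iloc[0]
    m = w.country == 0
    expected = np.average(q5[0][m], weights=w.population[m])
    assert c0 == pytest.approx(expected, rel=1e-12)


def test_survey_design_validation():
    with pytest.raises(ValueError):
        SurveyDesign(recall_years=18)
    with pytest.raises(ValueError):
        SurveyDesign(bias_ratio=0.0)
    with pytest.raises(ValueError):
        SurveyDesign(instrument="FBH")
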