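"""Space-time binomial model: recovery, draw coherence, and guards."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from childmbg.demography import PERIODS
from childmbg.geostat import (
    CandidateMaps,
    GeostatSpec,
    draw_candidate_fields,
    fit_geostat,
)
from childmbg.gp import sample_matern_ar1
from childmbg.grids import GridSpec

PERIOD_LABELS = [p.label for p in PERIODS]


def make_bt(grid, q_true, n_clusters, exposure, rng):
    rows = rng.integers(0, grid.nrows, n_clusters)
    cols = rng.integers(0, grid.ncols, n_clusters)
    parts = []
    for t, plabel in enumerate(PERIOD_LABELS):
        q = q_true[t, rows, cols]
        parts.append(
            pd.DataFrame(
                {
                    "source_id": "s", "loc_type": "point", "loc_id": np.arange(n_clusters),
                    "row": rows, "col": cols, "age_bin": 0, "period": plabel,
                    "exposure": float(exposure),
                    "deaths": rng.binomial(exposure, q).astype(float),
                    "weight": 1.0,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


@pytest.fixture(scope="module")
def fitted_small():
    """A small fitted model with a genuine spatial field, shared by draw tests."""
    grid = GridSpec(20, 20, pixel_km=5.0)
    rng = np.random.default_rng(0)
    z = sample_matern_ar1(grid.flat_centers(), 4, 60.0, 0.5, 0.8, rng)
    q = expit(logit(0.03) + z).reshape(4, 20, 20)
    bt = make_bt(grid, q, 250, 800, rng)
    spec = GeostatSpec(
        n_draws=200, seed=0, polish=False, knot_rows=6, knot_cols=6,
        sd_grid=(0.2, 0.5), rho_grid=(0.8,), range_grid=(30.0, 60.0, 120.0),
    )
    post = fit_geostat(bt, np.empty((len(bt), 0)), grid, spec)
    return grid, q, bt, post


def test_doubling_counts_leaves_rates_unchanged(fitted_small):
    grid, q, bt, post = fitted_small
    doubled = bt.copy()
    doubled["exposure"] *= 2
    doubled["deaths"] *= 2
    spec = post.spec
    post2 = fit_geostat(doubled, np.empty((len(bt), 0)), grid, spec)
    pix = {p: np.empty((grid.n_pixels, 0)) for p in PERIOD_LABELS}
    f1 = draw_candidate_fields(post, pix, n_draws=400, seed=1).mean(axis=0)
    f2 = draw_candidate_fields(post2, pix, n_draws=400, seed=2).mean(axis=0)
    assert np.max(np.abs(f1 - f2)) < 0.01


def test_single_draw_is_coherent_map(fitted_small):
    grid, _, _, post = fitted_small
    pix = {p: np.empty((grid.n_pixels, 0)) for p in PERIOD_LABELS}
    f = draw_candidate_fields(post, pix, n_draws=1, seed=3)
    assert f.shape == (1, 4, 20, 20)
    assert ((f > 0) & (f < 1)).all()


def test_draws_deterministic_given_seed(fitted_small):
    grid, _, _, post = fitted_small
    pix = {p: np.empty((grid.n_pixels, 0)) for p in PERIOD_LABELS}
    a = draw_candidate_fields(post, pix, n_draws=20, seed=5)
    b = draw_candidate_fields(post, pix, n_draws=20, seed=5)
    np.testing.assert_array_equal(a, b)


def test_monte_carlo_means_converge(fitted_small):
    grid, _, _, post = fitted_small
    pix = {p: np.empty((grid.n_pixels, 0)) for p in PERIOD_LABELS}
    small = draw_candidate_fields(post, pix, n_draws=100, seed=7)
    big = draw_candidate_fields(post, pix, n_draws=2000, seed=8)
    se = big.std(axis=0) / np.sqrt(100)
    within = np.abs(small.mean(axis=0) - big.mean(axis=0)) <= 2 * se
    assert within.mean() > 0.93  # ~95% expected under Gaussian MC error


def test_adjacent_pixels_more_correlated_than_distant(fitted_small):
    grid, _, _, post = fitted_small
    pix = {p: np.empty((grid.n_pixels, 0)) for p in PERIOD_LABELS}
    f = draw_candidate_fields(post, pix, n_draws=500, seed=9)[:, 0]  # first period
    a = f[:, 10, 10]
    near = f[:, 10, 11]
    far = f[:, 0, 19]
    c_near = np.corrcoef(a, near)[0, 1]
    c_far = np.corrcoef(a, far)[0, 1]
    assert c_near > c_far


def test_memory_guard_refuses_oversized_draws(fitted_small):
    grid, _, _, post = fitted_small
    from dataclasses import replace

    tiny = replace(post.spec, draw_budget_bytes=1000)
    post_small = replace_spec(post, tiny)
    pix = {p: np.empty((grid.n_pixels, 0)) for p in PERIOD_LABELS}
    with pytest.raises(MemoryError):
        draw_candidate_fields(post_small, pix, n_draws=100, seed=0)


def replace_spec(post, spec):
    from dataclasses import replace

    return replace(post, spec=spec)


def test_candidate_maps_persist_round_trip(tmp_path):
    rng = np.random.default_rng(6)
    cm = CandidateMaps(
        draws=rng.uniform(0.001, 0.1, (3, 4, 4, 2, 2)), grid=GridSpec(2, 2), seed=9
    )
    cm.save(tmp_path / "maps")
    back = CandidateMaps.load(tmp_path / "maps")
    np.testing.assert_array_equal(back.draws, cm.draws)
    assert back.grid == cm.grid and back.seed == 9


def test_candidate_maps_validate_probability_range():
    grid = GridSpec(2, 2)
    with pytest.raises(ValueError):
        CandidateMaps(draws=np.zeros((1, 4, 4, 2, 2)), grid=grid)


def test_zero_exposure_rows_dropped():
    grid = GridSpec(10, 10, pixel_km=5.0)
    rng = np.random.default_rng(4)
    q = np.full((4, 10, 10), 0.02)
    bt = make_bt(grid, q, 100, 500, rng)
    bt.loc[bt.index[:5], "exposure"] = 0.0
    bt.loc[bt.index[:5], "deaths"] = 0.0
    spec = GeostatSpec(
        n_draws=10, seed=0, polish=False, knot_rows=4, knot_cols=4,
        sd_grid=(0.1,), rho_grid=(0.8,), range_grid=(50.0,),
    )
    post = fit_geostat(bt, np.empty((len(bt), 0)), grid, spec)
    assert post.diagnostics["n_rows"] == len(bt) - 5


def test_mixed_age_bins_rejected(small_survey_bt, small_world):
    spec = GeostatSpec(n_draws=10)
    with pytest.raises(ValueError):
        fit_geostat(
            small_survey_bt, np.full((len(small_survey_bt), 1), 0.02),
            small_world.grid, spec,
        )
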