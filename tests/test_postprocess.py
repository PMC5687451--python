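"""Surfaces, aggregation, raking and masking against loop oracles."""

import numpy as np
import pandas as pd
import pytest

from childmbg.demography import compute_5q0, compute_nmr
from childmbg.geostat import CandidateMaps
from childmbg.grids import GridSpec
from childmbg.postprocess import (
    aggregate,
    apply_mask,
    apply_raking,
    compute_raking_factors,
    summarize_surface,
    surfaces_from_draws,
)

GRID = GridSpec(4, 4, pixel_km=5.0)


@pytest.fixture(scope="module")
def cm():
    rng = np.random.default_rng(0)
    draws = rng.uniform(0.001, 0.05, size=(30, 4, 4, 4, 4))
    return CandidateMaps(draws=draws, grid=GRID)


def test_surfaces_match_per_draw_loop_oracle(cm):
    q5, nmr = surfaces_from_draws(cm)
    n, t = cm.draws.shape[0], cm.draws.shape[2]
    for d in range(0, n, 7):
        for tt in range(t):
            for r in range(4):
                for c in range(4):
                    q = cm.draws[d, :, tt, r, c]
                    assert q5[d, tt, r, c] == pytest.approx(compute_5q0(q), abs=1e-12)
                    assert nmr[d, tt, r, c] == pytest.approx(compute_nmr(q), abs=1e-12)


def test_nmr_never_exceeds_q5(cm):
    q5, nmr = surfaces_from_draws(cm)
    assert (nmr <= q5 + 1e-12).all()


def test_zero_draws_give_zero_surfaces():
    draws = np.full((3, 4, 4, 2, 2), 1e-12)
    cm0 = CandidateMaps(draws=draws, grid=GridSpec(2, 2))
    q5, nmr = surfaces_from_draws(cm0)
    assert q5 == pytest.approx(0.0, abs=1e-6)


def test_uniform_field_aggregates_to_itself():
    draws = np.full((5, 4, 2, 2), 123.0)
    pop = np.ones((2, 2))
    labels = np.zeros((2, 2), dtype=int)
    agg = aggregate(draws, pop, labels, 0)
    np.testing.assert_allclose(agg.draws, 123.0)


def test_weighted_mean_example():
    draws = np.zeros((1, 4, 1, 2))
    draws[0, :, 0, 0] = 100.0
    draws[0, :, 0, 1] = 200.0
    pop = np.array([[1.0, 3.0]])
    labels = np.zeros((1, 2), dtype=int)
    agg = aggregate(draws, pop, labels, 0)
    np.testing.assert_allclose(agg.draws[0], 175.0)


def test_aggregation_matches_loop_oracle():
    rng = np.random.default_rng(1)
    draws = rng.uniform(10, 300, (8, 4, 5, 5))
    pop = rng.uniform(0.1, 10, (5, 5))
    labels = rng.integers(0, 3, (5, 5))
    agg = aggregate(draws, pop, labels, 2)
    for i, u in enumerate(agg.units):
        m = labels == u
        for d in range(8):
            for t in range(4):
                expected = np.average(draws[d, t][m], weights=pop[m])
                assert agg.draws[i, d, t] == pytest.approx(expected, abs=1e-9)


def test_aggregation_coherent_across_levels():
    """National aggregate equals the population-weighted mean of admin-1
    aggregates computed from the same draws and weights."""
    rng = np.random.default_rng(2)
    draws = rng.uniform(10, 300, (6, 4, 6, 6))
    pop = rng.uniform(0.1, 10, (6, 6))
    admin1 = rng.integers(0, 4, (6, 6))
    country = np.zeros((6, 6), dtype=int)
    nat = aggregate(draws, pop, country, 0)
    a1 = aggregate(draws, pop, admin1, 1)
    recombined = np.einsum("udt,u->dt", a1.draws, a1.weights) / a1.weights.sum()
    np.testing.assert_allclose(nat.draws[0], recombined, atol=1e-9)


def ref_table(values):
    rows = []
    for (c, p), v in values.items():
        rows.append({"country": c, "period": p, "q5": v})
    return pd.DataFrame(rows)


def make_national(mean_value):
    draws = np.full((1, 50, 4), float(mean_value))
    from childmbg.postprocess import AdminAggregate

    return AdminAggregate(level=0, units=np.array([0]), draws=draws,
                          weights=np.array([1.0]), indicator="q5")


def test_raking_factor_trivial_cases():
    nat = make_national(100.0)
    ref = ref_table({(0, p): 100.0 for p in (2000, 2005, 2010, 2015)})
    f = compute_raking_factors(nat, ref)
    np.testing.assert_allclose(f["factor"], 1.0)
    ref2 = ref_table({(0, p): 50.0 for p in (2000, 2005, 2010, 2015)})
    f2 = compute_raking_factors(nat, ref2)
    np.testing.assert_allclose(f2["factor"], 0.5)


def test_missing_reference_cell_raises():
    nat = make_national(100.0)
    ref = ref_table({(0, 2000): 100.0})
    with pytest.raises(KeyError):
        compute_raking_factors(nat, ref)


def test_raking_identity_and_ratio_preservation():
    rng = np.random.default_rng(3)
    draws = rng.uniform(10, 300, (5, 4, 3, 3))
    country = np.zeros((3, 3), dtype=int)
    ones = pd.DataFrame(
        [{"country": 0, "period": p, "indicator": "q5", "factor": 1.0}
         for p in (2000, 2005, 2010, 2015)]
    )
    np.testing.assert_array_equal(apply_raking(draws, country, ones), draws)
    half = ones.assign(factor=0.5)
    raked = apply_raking(draws, country, half)
    np.testing.assert_allclose(raked, 0.5 * draws)
    # scalar multiplication preserves within-country pixel ratios
    np.testing.assert_allclose(
        raked[0, 0] / raked[0, 0].max(), draws[0, 0] / draws[0, 0].max()
    )


def test_raking_closure_end_to_end():
    rng = np.random.default_rng(4)
    draws = rng.uniform(50, 200, (40, 4, 4, 4))
    pop = rng.uniform(1, 5, (4, 4))
    country = (np.arange(16).reshape(4, 4) // 8).astype(int)
    nat = aggregate(draws, pop, country, 0)
    ref = nat.summary().groupby(["unit", "period"])["mean"].first().reset_index()
    ref = ref.rename(columns={"unit": "country", "mean": "q5"})
    ref["q5"] *= 1.07
    factors = compute_raking_factors(nat, ref)
    raked = apply_raking(draws, country, factors)
    nat2 = aggregate(raked, pop, country, 0)
    post = nat2.posterior_mean()
    ref_idx = ref.set_index(["country", "period"])["q5"]
    for i, u in enumerate(nat2.units):
        for t, p in enumerate((2000, 2005, 2010, 2015)):
            assert post[i, t] == pytest.approx(ref_idx.loc[(u, p)], rel=1e-9)


def test_nonpositive_factor_rejected():
    draws = np.full((1, 4, 1, 1), 10.0)
    bad = pd.DataFrame(
        [{"country": 0, "period": p, "indicator": "q5", "factor": -1.0}
         for p in (2000, 2005, 2010, 2015)]
    )
    with pytest.raises(ValueError):
        apply_raking(draws, np.zeros((1, 1), dtype=int), bad)


def test_mask_threshold_and_idempotence():
    rng = np.random.default_rng(5)
    draws = rng.uniform(10, 100, (10, 4, 2, 2))
    surf = summarize_surface(draws, GridSpec(2, 2, pixel_km=1.0), "q5")
    landcover = np.zeros((2, 2), dtype=int)
    pop = np.array([[10.0, 9.0], [100.0, 100.0]])  # density per km2 at 1 km pixels
    masked = apply_mask(surf, landcover, pop)
    assert not masked.mask[0, 0]  # exactly at threshold: not masked
    assert masked.mask[0, 1]  # below ten per km2: masked
    assert np.isnan(masked.mean[:, 0, 1]).all()
    again = apply_mask(masked, landcover, pop)
    np.testing.assert_array_equal(again.mask, masked.mask)
    np.testing.assert_array_equal(np.isnan(again.mean), np.isnan(masked.mean))


def test_barren_landcover_masked_even_if_populated():
    draws = np.full((4, 4, 1, 2), 50.0)
    surf = summarize_surface(draws, GridSpec(1, 2, pixel_km=1.0), "q5")
    landcover = np.array([[1, 0]])
    pop = np.full((1, 2), 1000.0)
    masked = apply_mask(surf, landcover, pop)
    assert masked.mask[0, 0] and not masked.mask[0, 1]


def test_grid_mismatch_raises():
    draws = np.full((2, 4, 2, 2), 50.0)
    surf = summarize_surface(draws, GridSpec(2, 2), "q5")
    with pytest.raises(ValueError, match="do not match"):
        apply_mask(surf, np.zeros((3, 3)), np.ones((2, 2)))


def test_interval_bounds_bracket_mean(cm):
    q5, _ = surfaces_from_draws(cm)
    surf = summarize_surface(q5, GRID, "q5")
    assert (surf.lower <= surf.mean + 1e-9).all()
    assert (surf.mean <= surf.upper + 1e-9).all()
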