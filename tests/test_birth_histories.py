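"""CBH tabulation against an independent per-child month-walk oracle."""

import numpy as np
import pandas as pd
import pytest

from childmbg.birth_histories import apply_bias_ratios, tabulate_cbh, validate_bintable
from childmbg.demography import assign_bin
from childmbg.synthetic import cmc


def child(birth_cmc, death_cmc=np.nan, survey_cmc=cmc(2016, 7), cluster=0, mother=0):
    return {
        "source_id": "s0",
        "cluster_id": cluster,
        "row": 3,
        "col": 4,
        "polygon_id": -1,
        "mother_id": mother,
        "mother_age": 30,
        "birth_cmc": birth_cmc,
        "death_cmc": death_cmc,
        "survey_cmc": survey_cmc,
    }


def oracle_tabulate(children):
    """Pure-python month walk, independent of the vectorized implementation."""
    cells = {}
    for rec in children:
        birth = rec["birth_cmc"]
        death = rec["death_cmc"]
        for m in range(60):
            mc = birth + m
            if mc >= rec["survey_cmc"]:
                break
            if not np.isnan(death) and death < mc:
                break
            year = (mc - 1) // 12 + 1900
            got = assign_bin(m, year)
            if got is None:
                continue
            key = (int(got[0]), got[1].label)
            e, d = cells.get(key, (0.0, 0.0))
            died = (not np.isnan(death)) and death == mc
            cells[key] = (e + 1.0, d + (1.0 if died else 0.0))
    return cells


def test_hand_walked_example():
    # born Jan 2003, alive at a June 2003 interview: months 0..4 observed,
    # 1 neonatal exposure + 4 months in the 1-11mo bin, all period 2005
    df = pd.DataFrame([child(cmc(2003, 1), survey_cmc=cmc(2003, 6))])
    bt = tabulate_cbh(df)
    assert bt["deaths"].sum() == 0
    assert set(bt["period"]) == {2005}
    by_bin = bt.set_index("age_bin")["exposure"]
    assert by_bin[0] == 1.0
    assert by_bin[1] == 4.0
    assert bt["exposure"].sum() == 5.0


def test_death_in_first_month():
    df = pd.DataFrame([child(cmc(2010, 3), death_cmc=cmc(2010, 3))])
    bt = tabulate_cbh(df)
    assert len(bt) == 1
    assert bt.iloc[0]["age_bin"] == 0
    assert bt.iloc[0]["exposure"] == 1.0
    assert bt.iloc[0]["deaths"] == 1.0


def test_matches_month_walk_oracle_on_random_children():
    rng = np.random.default_rng(8)
    children = []
    for i in range(1000):
        birth = int(rng.integers(cmc(1995, 1), cmc(2016, 6)))
        if rng.random() < 0.25:
            death = birth + int(rng.integers(0, 80))
        else:
            death = np.nan
        children.append(child(birth, death, cluster=int(rng.integers(0, 5)), mother=i))
    df = pd.DataFrame(children)
    # drop children whose death falls after the interview (not observable)
    df.loc[df["death_cmc"] >= df["survey_cmc"], "death_cmc"] = np.nan
    bt = tabulate_cbh(df)
    got = {
        (int(r["age_bin"]), int(r["period"])): 0 for _, r in bt.iterrows()
    }
    agg = bt.groupby(["age_bin", "period"])[["exposure", "deaths"]].sum()
    expected = oracle_tabulate(df.to_dict("records"))
    assert set(agg.index) == set(expected)
    for key, (e, d) in expected.items():
        assert agg.loc[key, "exposure"] == pytest.approx(e, abs=1e-9)
        assert agg.loc[key, "deaths"] == pytest.approx(d, abs=1e-9)


def test_permutation_invariance(small_world):
    from childmbg.synthetic import SurveyDesign, simulate_cbh

    cbh = simulate_cbh(small_world, SurveyDesign(n_clusters=40), seed=2)
    bt1 = tabulate_cbh(cbh)
    shuffled = cbh.sample(frac=1.0, random_state=0).reset_index(drop=True)
    bt2 = tabulate_cbh(shuffled)
    key = ["source_id", "loc_type", "loc_id", "age_bin", "period"]
    pd.testing.assert_frame_equal(
        bt1.sort_values(key).reset_index(drop=True),
        bt2.sort_values(key).reset_index(drop=True),
    )


def test_exposure_conserved_under_source_partition(small_world):
    from childmbg.synthetic import SurveyDesign, simulate_cbh

    cbh = simulate_cbh(small_world, SurveyDesign(n_clusters=40), seed=3)
    whole = tabulate_cbh(cbh)
    half1 = tabulate_cbh(cbh.iloc[: len(cbh) // 2])
    half2 = tabulate_cbh(cbh.iloc[len(cbh) // 2 :])
    assert whole["exposure"].sum() == half1["exposure"].sum() + half2["exposure"].sum()
    assert whole["deaths"].sum() == half1["deaths"].sum() + half2["deaths"].sum()


def test_only_sixteen_cells_ever_appear(small_survey_bt):
    cells = set(zip(small_survey_bt["age_bin"], small_survey_bt["period"]))
    assert cells <= {(b, p) for b in range(4) for p in (2000, 2005, 2010, 2015)}


def test_bad_records_rejected():
    df = pd.DataFrame(
        [
            child(cmc(2010, 5), death_cmc=cmc(2010, 2)),  # death before birth
            child(np.nan),  # missing birth date
            child(cmc(2010, 5)),
        ]
    )
    bt = tabulate_cbh(df)
    # only the valid child tabulated
    assert bt["exposure"].sum() == 60.0 or bt["exposure"].sum() > 0


def test_bias_ratio_identity_and_scaling(small_survey_bt):
    bt = small_survey_bt
    same = apply_bias_ratios(bt, pd.DataFrame({"source_id": ["survey0"], "ratio": [1.0]}))
    pd.testing.assert_frame_equal(same, bt)
    up = apply_bias_ratios(bt, pd.DataFrame({"source_id": ["survey0"], "ratio": [1.1]}))
    capped = bt["deaths"] * 1.1 > bt["exposure"]
    np.testing.assert_allclose(
        up.loc[~capped, "deaths"], 1.1 * bt.loc[~capped, "deaths"], rtol=1e-12
    )


def test_bias_ratio_caps_deaths_at_exposure():
    bt = pd.DataFrame(
        {
            "source_id": ["a"], "loc_type": ["point"], "loc_id": [0], "row": [0],
            "col": [0], "age_bin": [0], "period": [2000], "exposure": [4.0],
            "deaths": [3.0], "weight": [1.0],
        }
    )
    out = apply_bias_ratios(bt, pd.DataFrame({"source_id": ["a"], "ratio": [2.0]}))
    assert out["deaths"].iloc[0] == 4.0


def test_negative_ratio_rejected(small_survey_bt):
    with pytest.raises(ValueError):
        apply_bias_ratios(small_survey_bt, pd.DataFrame({"source_id": ["s"], "ratio": [-1.0]}))


def test_bintable_validator_catches_violations(small_survey_bt):
    bad = small_survey_bt.copy()
    bad.loc[bad.index[0], "deaths"] = bad.loc[bad.index[0], "exposure"] + 5
    with pytest.raises(ValueError):
        validate_bintable(bad)
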