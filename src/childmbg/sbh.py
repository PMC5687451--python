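"""Partitioning summary birth histories into age- and period-specific bins.

Summary birth histories (SBH) report only children ever born (CEB) and
children died (CD) per mother. To enter the binomial space-time model these
must be spread over the 16 age-bin x period cells. The partition model is
trained on data where complete birth histories (CBH) are available: for each
mother age group (5-year bands 15-19 ... 45-49) it learns

- the multinomial distribution of *deaths* over the 16 cells,
- the multinomial distribution of *exposure months* over the 16 cells,
- the mean exposure months contributed per child ever born,

each via a multinomial-logit regression on mother-age-group indicators and a
(centred) survey-year covariate. Older mothers' children were born earlier,
so their deaths and exposures concentrate in earlier periods — the structure
the model exploits.

Allocation is deterministic (expected counts): a mother's CD is split across
cells by the predicted death shares and her CEB converted to exposure months
by the per-child exposure factor times the predicted exposure shares.
Uncertainty is propagated later by the geostatistical model, not here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from childmbg.demography import AGE_BINS, N_BINS, PERIODS
from childmbg.birth_histories import BINTABLE_COLUMNS, validate_bintable
from childmbg.synthetic import MOTHER_AGE_GROUPS, cmc_year, mother_age_group

logger = logging.getLogger(__name__)

N_GROUPS = len(MOTHER_AGE_GROUPS)
PERIOD_INDEX = {p.label: i for i, p in enumerate(PERIODS)}


def _cell_index(age_bin: np.ndarray, period_label: np.ndarray) -> np.ndarray:
    t = np.array([PERIOD_INDEX[p] for p in np.atleast_1d(period_label)])
    return np.asarray(age_bin) * len(PERIODS) + t


def cell_to_bin_period(cell: int) -> tuple[int, int]:
    """Inverse of the 16-cell flattening: returns (age_bin, period_label)."""
    return cell // len(PERIODS), PERIODS[cell % len(PERIODS)].label


def _period_index_of_years(years: np.ndarray) -> np.ndarray:
    conds = [(years >= p.first_year) & (years <= p.last_year) for p in PERIODS]
    return np.select(conds, np.arange(len(PERIODS)), default=-1)


def _mother_cells(latent_cbh: pd.DataFrame) -> pd.DataFrame:
    """Death and exposure-month counts per (mother age group, survey year,
    16-cell) from one or more concatenated latent CBH tables."""
    parts = []
    years = cmc_year(latent_cbh["survey_cmc"].to_numpy())
    for y in np.unique(years):
        parts.append(_mother_cells_one(latent_cbh[years == y], int(y)))
    return pd.concat(parts, ignore_index=True)


def _mother_cells_one(df: pd.DataFrame, year: int) -> pd.DataFrame:
    group = mother_age_group(df["mother_age"].to_numpy())
    deaths_acc = np.zeros((N_GROUPS, N_BINS))
    exp_acc = np.zeros((N_GROUPS, N_BINS))
    bin_edges = np.array([1, 12, 36])  # completed months -> age-bin index

    has_death = df["death_cmc"].notna().to_numpy()
    if has_death.any():
        bcmc = df["birth_cmc"].to_numpy()[has_death]
        dcmc = df["death_cmc"].to_numpy()[has_death].astype(int)
        age_m = dcmc - bcmc
        t = _period_index_of_years(cmc_year(dcmc))
        ok = (age_m < 60) & (t >= 0)
        cell = np.digitize(age_m[ok], bin_edges) * len(PERIODS) + t[ok]
        np.add.at(deaths_acc, (group[has_death][ok], cell), 1.0)

    birth = df["birth_cmc"].to_numpy(dtype=int)
    death = df["death_cmc"].to_numpy(dtype=float)
    survey = df["survey_cmc"].to_numpy(dtype=int)
    for m in range(60):
        abin = int(np.digitize(m, bin_edges))
        month_cmc = birth + m
        ok = (np.isnan(death) | (death >= month_cmc)) & (month_cmc < survey)
        t = _period_index_of_years(cmc_year(month_cmc))
        ok &= t >= 0
        if not ok.any():
            continue
        np.add.at(exp_acc, (group[ok], abin * len(PERIODS) + t[ok]), 1.0)

    g_idx, c_idx = np.nonzero(deaths_acc + exp_acc)
    return pd.DataFrame(
        {
            "group": g_idx,
            "year": year,
            "cell": c_idx,
            "deaths": deaths_acc[g_idx, c_idx],
            "exposure": exp_acc[g_idx, c_idx],
        }
    )


def _fit_multinomial(cells: pd.DataFrame, value: str, year_center: float):
    """Fit share model P(cell | group, year) on aggregated counts."""
    sub = cells[cells[value] > 0]
    x = np.column_stack(
        [
            np.eye(N_GROUPS)[sub["group"].to_numpy()],
            (sub["year"].to_numpy() - year_center) / 5.0,
        ]
    )
    y = sub["cell"].to_numpy()
    if len(np.unique(y)) < 2:
        # degenerate training set: all mass in one cell
        only = int(y[0]) if len(y) else 0
        return {"classes": [only], "coef": None, "intercept": None}
    clf = LogisticRegression(C=10.0, max_iter=5000, fit_intercept=True)
    clf.fit(x, y, sample_weight=sub[value].to_numpy())
    return {
        "classes": clf.classes_.astype(int).tolist(),
        "coef": clf.coef_.tolist(),
        "intercept": clf.intercept_.tolist(),
    }


def _predict_shares(model: dict, group: int, year: float, year_center: float) -> np.ndarray:
    shares = np.zeros(N_BINS)
    classes = model["classes"]
    if model["coef"] is None:
        shares[classes[0]] = 1.0
        return shares
    x = np.concatenate([np.eye(N_GROUPS)[group], [(year - year_center) / 5.0]])
    coef = np.asarray(model["coef"])
    intercept = np.asarray(model["intercept"])
    if coef.shape[0] == 1:  # binary case: sklearn stores one row
        eta = np.array([-(coef[0] @ x + intercept[0]), coef[0] @ x + intercept[0]])
    else:
        eta = coef @ x + intercept
    eta -= eta.max()
    p = np.exp(eta)
    p /= p.sum()
    shares[np.asarray(classes)] = p
    return shares


@dataclass
class SBHPartitionModel:
    """Fitted mapping from (mother age group, survey year) to bin shares."""

    death_model: dict
    exposure_model: dict
    exposure_per_child: dict[int, float]  # mother age group -> mean exposure months/child
    year_center: float
    groups_fitted: list[int]
    diagnostics: dict = field(default_factory=dict)

    def death_shares(self, group: int, year: float) -> np.ndarray:
        return _predict_shares(self.death_model, group, year, self.year_center)

    def exposure_shares(self, group: int, year: float) -> np.ndarray:
        return _predict_shares(self.exposure_model, group, year, self.year_center)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "format": "childmbg-sbh-partition-v1",
            "death_model": self.death_model,
            "exposure_model": self.exposure_model,
            "exposure_per_child": {str(k): v for k, v in self.exposure_per_child.items()},
            "year_center": self.year_center,
            "groups_fitted": self.groups_fitted,
            "diagnostics": self.diagnostics,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SBHPartitionModel":
        d = json.loads(Path(path).read_text())
        return cls(
            death_model=d["death_model"],
            exposure_model=d["exposure_model"],
            exposure_per_child={int(k): v for k, v in d["exposure_per_child"].items()},
            year_center=d["year_center"],
            groups_fitted=d["groups_fitted"],
            diagnostics=d.get("diagnostics", {}),
        )


def fit_sbh_partition(latent_cbh: pd.DataFrame) -> SBHPartitionModel:
    """Fit the partition model on data where complete histories are available.

    ``latent_cbh`` is one or more concatenated CBH child tables (the paired
    training data). Groups with no observed children are flagged in the
    diagnostics and fall back to the pooled year effect at prediction time.
    """
    if latent_cbh.empty:
        raise ValueError("cannot fit SBH partition model on empty training data")
    cells = _mother_cells(latent_cbh)
    year_center = float(cells["year"].mean())
    death_model = _fit_multinomial(cells, "deaths", year_center)
    exposure_model = _fit_multinomial(cells, "exposure", year_center)

    group = mother_age_group(latent_cbh["mother_age"].to_numpy())
    exposure_per_child: dict[int, float] = {}
    total_exp = cells.groupby("group")["exposure"].sum()
    n_children = pd.Series(group).value_counts()
    overall = float(cells["exposure"].sum() / max(len(latent_cbh), 1))
    missing = []
    for g in range(N_GROUPS):
        if g in n_children.index and n_children[g] > 0 and g in total_exp.index:
            exposure_per_child[g] = float(total_exp[g] / n_children[g])
        else:
            exposure_per_child[g] = overall
            missing.append(g)
    if missing:
        logger.warning("no training children for mother age groups %s; using pooled exposure factor", missing)

    # in-sample reproduction of aggregate death shares
    obs = np.zeros(N_BINS)
    for _, r in cells.iterrows():
        obs[int(r["cell"])] += r["deaths"]
    obs_share = obs / obs.sum() if obs.sum() > 0 else obs
    pred = np.zeros(N_BINS)
    wsum = 0.0
    for g, n in n_children.items():
        pred += n * _predict_shares(death_model, int(g), year_center, year_center)
        wsum += n
    pred /= max(wsum, 1.0)
    pred = pred / pred.sum() if pred.sum() > 0 else pred
    diagnostics = {
        "max_abs_death_share_error": float(np.max(np.abs(pred - obs_share))),
        "groups_without_training_children": missing,
    }
    return SBHPartitionModel(
        death_model=death_model,
        exposure_model=exposure_model,
        exposure_per_child=exposure_per_child,
        year_center=year_center,
        groups_fitted=sorted(set(range(N_GROUPS)) - set(missing)),
        diagnostics=diagnostics,
    )


def partition_sbh(model: SBHPartitionModel, sbh: pd.DataFrame) -> pd.DataFrame:
    """Allocate SBH records into a bin table using the fitted partition model.

    Mothers with CD > CEB are rejected (counted in the log); mothers with
    CEB = 0 contribute nothing. Total allocated deaths equal total accepted
    CD exactly. Cell exposures are floored at the allocated deaths so the
    bin-table invariant (deaths <= exposure) holds by construction.
    """
    bad = sbh["cd"] > sbh["ceb"]
    if bad.any():
        logger.warning("rejected %d SBH records with CD > CEB", int(bad.sum()))
    ok = sbh[~bad & (sbh["ceb"] > 0)]
    if ok.empty:
        return pd.DataFrame(columns=BINTABLE_COLUMNS)

    # precompute shares per (group, year) combination present
    combos = ok[["mother_age_group", "survey_year"]].drop_duplicates()
    share_cache = {
        (int(g), int(y)): (model.death_shares(int(g), y), model.exposure_shares(int(g), y))
        for g, y in combos.itertuples(index=False)
    }

    recs = []
    is_poly = ok["polygon_id"].to_numpy() >= 0
    loc_type = np.where(is_poly, "polygon", "point")
    loc_id = np.where(is_poly, ok["polygon_id"].to_numpy(), ok["cluster_id"].to_numpy())
    for i, (_, r) in enumerate(ok.iterrows()):
        g = int(r["mother_age_group"])
        dsh, esh = share_cache[(g, int(r["survey_year"]))]
        deaths = r["cd"] * dsh
        exposure = r["ceb"] * model.exposure_per_child[g] * esh
        exposure = np.maximum(exposure, deaths)
        nz = (exposure > 0) | (deaths > 0)
        for cell in np.where(nz)[0]:
            b, p = cell_to_bin_period(cell)
            recs.append(
                (r["source_id"], loc_type[i], loc_id[i], r["row"], r["col"], b, p,
                 exposure[cell], deaths[cell])
            )
    long = pd.DataFrame(
        recs,
        columns=["source_id", "loc_type", "loc_id", "row", "col", "age_bin", "period",
                 "exposure", "deaths"],
    )
    bt = long.groupby(
        ["source_id", "loc_type", "loc_id", "row", "col", "age_bin", "period"],
        as_index=False,
    ).sum()
    bt["weight"] = 1.0
    return validate_bintable(bt[BINTABLE_COLUMNS])


def pooled_q5(bt: pd.DataFrame) -> float:
    """Pooled synthetic-cohort 5q0 (per 1000) from a bin table, pooling
    locations and periods within each age bin."""
    from childmbg.demography import compute_5q0

    g = bt.groupby("age_bin")[["deaths", "exposure"]].sum()
    q = np.zeros(len(AGE_BINS))
    for b in AGE_BINS:
        if int(b) in g.index and g.loc[int(b), "exposure"] > 0:
            q[int(b)] = g.loc[int(b), "deaths"] / g.loc[int(b), "exposure"]
    return float(compute_5q0(q))
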