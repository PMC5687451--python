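"""Tabulation of complete birth histories into the 16-cell bin table.

A bin table (``BinTable``) is the pipeline's likelihood currency: one row per
(source, location, age bin, period) holding total exposure months and death
events. The month-exposure rule: a month counts as an exposure if the child
was alive at the beginning of it; the death event falls in the bin of the
child's completed age in months and the period of the death's calendar year.
Dates are resolved to the calendar month (century-month code); day-of-month
is ignored. A child alive at the interview contributes exposure only through
the month before the interview month.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from childmbg.demography import AGE_BINS, PERIODS, age_bin_of_month, period_of_year
from childmbg.synthetic import cmc_year

logger = logging.getLogger(__name__)


def _period_labels_of_years(years: np.ndarray) -> np.ndarray:
    """Vectorized year -> period label; -1 outside the study span."""
    conds = [(years >= p.first_year) & (years <= p.last_year) for p in PERIODS]
    return np.select(conds, [p.label for p in PERIODS], default=-1)

BINTABLE_COLUMNS = [
    "source_id",
    "loc_type",
    "loc_id",
    "row",
    "col",
    "age_bin",
    "period",
    "exposure",
    "deaths",
    "weight",
]


def validate_bintable(bt: pd.DataFrame) -> pd.DataFrame:
    """Check bin-table invariants; returns the table unchanged."""
    missing = set(BINTABLE_COLUMNS) - set(bt.columns)
    if missing:
        raise ValueError(f"bin table missing columns: {sorted(missing)}")
    if len(bt):
        if not np.isfinite(bt[["exposure", "deaths"]].to_numpy()).all():
            raise ValueError("exposure/deaths must be finite")
        if (bt["exposure"] < 0).any() or (bt["deaths"] < 0).any():
            raise ValueError("exposure/deaths must be >= 0")
        if (bt["deaths"] > bt["exposure"] + 1e-9).any():
            raise ValueError("deaths cannot exceed exposure months")
        if (bt["weight"] <= 0).any():
            raise ValueError("weights must be positive")
        if not bt["age_bin"].isin([int(b) for b in AGE_BINS]).all():
            raise ValueError("unknown age bin codes")
        if not bt["period"].isin([p.label for p in PERIODS]).all():
            raise ValueError("unknown period labels")
    return bt


def tabulate_cbh(children: pd.DataFrame) -> pd.DataFrame:
    """Tabulate child records into a bin table.

    Walks each child's lived months (at most 60): month ``m`` after birth
    contributes one exposure month to the bin of completed age ``m`` and the
    period of its calendar year, provided the child was alive at the start of
    the month and the month precedes the interview month; the death month
    additionally contributes one death event. Months in calendar years
    outside 1998-2017 are dropped. Records with a missing birth date or a
    death date before the birth date are rejected (counted in the log).
    """
    children = children.copy()
    n0 = len(children)
    bad_birth = children["birth_cmc"].isna()
    bad_order = (~bad_birth) & children["death_cmc"].notna() & (
        children["death_cmc"] < children["birth_cmc"]
    )
    rejected = bad_birth | bad_order
    if rejected.any():
        logger.warning(
            "rejected %d/%d child records (%d missing birth date, %d death before birth)",
            int(rejected.sum()), n0, int(bad_birth.sum()), int(bad_order.sum()),
        )
    children = children[~rejected]
    if children.empty:
        return pd.DataFrame(columns=BINTABLE_COLUMNS)

    birth = children["birth_cmc"].to_numpy(dtype=int)
    death = children["death_cmc"].to_numpy(dtype=float)
    survey = children["survey_cmc"].to_numpy(dtype=int)
    polygon = children["polygon_id"].to_numpy() if "polygon_id" in children else np.full(len(children), -1)
    is_poly = polygon >= 0

    key_cols = {
        "source_id": children["source_id"].to_numpy(),
        "loc_type": np.where(is_poly, "polygon", "point"),
        "loc_id": np.where(is_poly, polygon, children["cluster_id"].to_numpy()),
        "row": children["row"].to_numpy(),
        "col": children["col"].to_numpy(),
    }

    parts = []
    for m in range(60):
        abin = age_bin_of_month(m)
        month_cmc = birth + m
        alive_at_start = np.isnan(death) | (death >= month_cmc)
        observed = month_cmc < survey
        ok = alive_at_start & observed
        if not ok.any():
            continue
        periods = _period_labels_of_years(cmc_year(month_cmc[ok]))
        in_scope = periods != -1
        if not in_scope.any():
            continue
        idx = np.where(ok)[0][in_scope]
        died_here = np.nan_to_num(death[idx], nan=-1) == month_cmc[idx]
        parts.append(
            pd.DataFrame(
                {
                    **{k: v[idx] for k, v in key_cols.items()},
                    "age_bin": int(abin),
                    "period": periods[in_scope],
                    "exposure": 1.0,
                    "deaths": died_here.astype(float),
                }
            )
        )
    if not parts:
        return pd.DataFrame(columns=BINTABLE_COLUMNS)
    long = pd.concat(parts, ignore_index=True)
    bt = (
        long.groupby(
            ["source_id", "loc_type", "loc_id", "row", "col", "age_bin", "period"],
            as_index=False,
        )
        .agg(exposure=("exposure", "sum"), deaths=("deaths", "sum"))
    )
    bt["weight"] = 1.0
    return validate_bintable(bt[BINTABLE_COLUMNS])


def apply_bias_ratios(bt: pd.DataFrame, ratios: pd.DataFrame | None) -> pd.DataFrame:
    """Apply source-specific bias ratios to a bin table.

    Ratios are positive multipliers, specific to data source (matched on
    ``source_id``), acting on death counts — an empirical-probability-scale
    adjustment that leaves exposure (the sample-size proxy) unchanged.
    Sources without a ratio default to 1. Adjusted deaths are capped at the
    row's exposure with a logged warning.
    """
    validate_bintable(bt)
    out = bt.copy()
    if ratios is None or len(ratios) == 0:
        return out
    if (ratios["ratio"] <= 0).any():
        raise ValueError("bias ratios must be positive")
    lookup = ratios.set_index("source_id")["ratio"]
    r = out["source_id"].map(lookup).fillna(1.0).to_numpy()
    out["deaths"] = out["deaths"].to_numpy() * r
    over = out["deaths"] > out["exposure"]
    if over.any():
        logger.warning("capped deaths at exposure on %d rows after bias adjustment", int(over.sum()))
        out.loc[over, "deaths"] = out.loc[over, "exposure"]
    return validate_bintable(out)
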