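"""From candidate maps to reported surfaces: rates, aggregation, raking, masking.

Candidate maps (joint posterior draws of monthly death probability per age
bin) are converted draw-wise into under-5 (5q0) and neonatal (NMR) mortality
rates per 1000 livebirths, aggregated with population weights to admin-2,
admin-1 and national levels, calibrated ("raked") so that national
population-weighted posterior means match a reference national table, and
finally masked for reporting where land cover is barren/sparsely vegetated
or population density falls below ten persons per square kilometre.

Raking is multiplicative on the rate scale applied to every draw, so the
calibration propagates coherently into all uncertainty summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from childmbg.demography import AgeBin, N_MONTHS, PERIODS
from childmbg.geostat import CandidateMaps
from childmbg.grids import GridSpec

logger = logging.getLogger(__name__)

DENSITY_THRESHOLD_PER_KM2 = 10.0
PERIOD_LABELS = tuple(p.label for p in PERIODS)


def surfaces_from_draws(cm: CandidateMaps) -> tuple[np.ndarray, np.ndarray]:
    """Per-draw 5q0 and NMR pixel arrays, each (n_draws, n_periods, nrows, ncols).

    Applies the synthetic-cohort identity draw-wise: under-5 mortality is
    1000 x (1 - prod over age bins of (1 - q_bin)^months), neonatal
    mortality 1000 x q_neonatal.
    """
    q = cm.draws  # (N, 4, T, r, c)
    if q.shape[1] != len(N_MONTHS):
        raise ValueError(f"expected {len(N_MONTHS)} age bins, got {q.shape[1]}")
    surv = np.prod((1.0 - q) ** N_MONTHS[None, :, None, None, None], axis=1)
    q5 = 1000.0 * (1.0 - surv)
    nmr = 1000.0 * q[:, int(AgeBin.NEONATAL)]
    return q5, nmr


@dataclass
class MortalitySurface:
    """Pixel summaries (mean and equal-tailed 95% interval) per period."""

    mean: np.ndarray  # (T, r, c)
    lower: np.ndarray
    upper: np.ndarray
    grid: GridSpec
    indicator: str
    mask: np.ndarray | None = None  # True where masked (no-data)


def summarize_surface(
    rate_draws: np.ndarray, grid: GridSpec, indicator: str
) -> MortalitySurface:
    """Mean and 2.5/97.5% quantiles over draws."""
    lo, hi = np.quantile(rate_draws, [0.025, 0.975], axis=0)
    return MortalitySurface(
        mean=rate_draws.mean(axis=0), lower=lo, upper=hi, grid=grid, indicator=indicator
    )


@dataclass
class AdminAggregate:
    """Population-weighted draws of a rate at one admin level."""

    level: int
    units: np.ndarray  # unit ids
    draws: np.ndarray  # (n_units, n_draws, n_periods)
    weights: np.ndarray  # total population per unit
    indicator: str

    def posterior_mean(self) -> np.ndarray:
        return self.draws.mean(axis=1)  # (n_units, T)

    def summary(self) -> pd.DataFrame:
        lo, hi = np.quantile(self.draws, [0.025, 0.975], axis=1)
        rows = []
        for i, u in enumerate(self.units):
            for t, plabel in enumerate(PERIOD_LABELS):
                rows.append(
                    {
                        "unit": int(u),
                        "level": self.level,
                        "period": plabel,
                        "indicator": self.indicator,
                        "mean": self.draws[i, :, t].mean(),
                        "lower": lo[i, t],
                        "upper": hi[i, t],
                        "population": self.weights[i],
                    }
                )
        return pd.DataFrame(rows)


def aggregate(
    rate_draws: np.ndarray,
    population: np.ndarray,
    labels: np.ndarray,
    level: int,
    indicator: str = "q5",
) -> AdminAggregate:
    """Population-weighted aggregation of per-draw pixel rates to admin units.

    The unit rate in each draw is the population-weighted mean of its pixel
    rates, so summaries at every level derive from the same candidate maps.
    Units with zero total population yield no-data (NaN) with a warning.
    """
    n, t = rate_draws.shape[:2]
    flat = rate_draws.reshape(n, t, -1)
    pop = population.ravel()
    lab = labels.ravel()
    units = np.unique(lab)
    out = np.full((len(units), n, t), np.nan)
    wsum = np.empty(len(units))
    for i, u in enumerate(units):
        m = lab == u
        w = pop[m]
        wsum[i] = w.sum()
        if wsum[i] <= 0:
            logger.warning("admin unit %s has zero population; aggregate is no-data", u)
            continue
        out[i] = flat[:, :, m] @ (w / wsum[i])
    return AdminAggregate(level=level, units=units, draws=out, weights=wsum, indicator=indicator)


def compute_raking_factors(national: AdminAggregate, reference: pd.DataFrame) -> pd.DataFrame:
    """Raking factors: reference national rate / model posterior mean.

    ``reference`` must have columns (country, period, <indicator>) covering
    every country x period cell. Multiplying the model by the returned
    factor reproduces the reference.
    """
    col = national.indicator
    post = national.posterior_mean()
    rows = []
    ref_idx = reference.set_index(["country", "period"])
    for i, u in enumerate(national.units):
        for t, plabel in enumerate(PERIOD_LABELS):
            key = (int(u), plabel)
            if key not in ref_idx.index:
                raise KeyError(f"reference table missing country={u}, period={plabel}")
            ref = float(ref_idx.loc[key, col])
            model = post[i, t]
            if not np.isfinite(model) or model <= 0:
                raise ValueError(f"invalid model mean for country={u}, period={plabel}")
            rows.append({"country": int(u), "period": plabel, "indicator": col, "factor": ref / model})
    factors = pd.DataFrame(rows)
    logger.info(
        "raking factors (%s): median %.3f, IQR %.3f-%.3f",
        col,
        factors["factor"].median(),
        factors["factor"].quantile(0.25),
        factors["factor"].quantile(0.75),
    )
    return factors


def apply_raking(
    rate_draws: np.ndarray, country_labels: np.ndarray, factors: pd.DataFrame
) -> np.ndarray:
    """Multiply every draw's pixel rates by its country x period raking factor.

    Rates are clipped to [0, 1000] afterwards with a warning if any clipping
    occurs (an unbounded ratio can push a pathological draw past certainty).
    """
    if (factors["factor"] <= 0).any():
        raise ValueError("raking factors must be positive")
    out = rate_draws.copy()
    lab = country_labels
    fidx = factors.set_index(["country", "period"])["factor"]
    for t, plabel in enumerate(PERIOD_LABELS):
        fmap = np.ones(lab.max() + 1)
        for c in np.unique(lab):
            key = (int(c), plabel)
            if key not in fidx.index:
                raise KeyError(f"no raking factor for country={c}, period={plabel}")
            fmap[c] = fidx.loc[key]
        out[:, t] *= fmap[lab][None, :, :]
    n_clip = int((out > 1000.0).sum() + (out < 0.0).sum())
    if n_clip:
        logger.warning("raking clipped %d draw-pixels to [0, 1000]", n_clip)
        out = np.clip(out, 0.0, 1000.0)
    return out


def apply_mask(
    surface: MortalitySurface,
    landcover: np.ndarray,
    population: np.ndarray,
    barren_code: int = 1,
) -> MortalitySurface:
    """Apply the reporting mask: barren land cover or density < 10 per km^2.

    Masked pixels become NaN in all summaries; the mask raster is stored on
    the returned surface. Idempotent.
    """
    g = surface.grid
    if landcover.shape != g.shape or population.shape != g.shape:
        raise ValueError(
            f"raster grids do not match: surface {g.shape}, landcover {landcover.shape}, "
            f"population {population.shape}"
        )
    density = population / g.pixel_area_km2
    mask = (landcover == barren_code) | (density < DENSITY_THRESHOLD_PER_KM2)
    def _apply(a):
        out = a.copy()
        out[:, mask] = np.nan
        return out

    return MortalitySurface(
        mean=_apply(surface.mean),
        lower=_apply(surface.lower),
        upper=_apply(surface.upper),
        grid=g,
        indicator=surface.indicator,
        mask=mask,
    )
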