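"""Trend arithmetic: annualized decline, 2030 projection, required pace.

Annualization is continuous (log-scale): the annualized rate of change
between rates r0 and r1 over t years is ln(r0/r1)/t, positive when
mortality declines. Under this convention the pace equivalent to a
two-thirds reduction over 25 years — the MDG 4 benchmark — is ln(3)/25,
which prints as 4.4% per year; doubling it gives 8.8%. The SDG 3.2 targets
are 25 under-5 deaths and 12 neonatal deaths per 1000 livebirths by 2030.

All statistics are computed per posterior draw and summarized afterwards,
never on posterior summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SDG_U5_TARGET = 25.0  # deaths per 1000 livebirths
SDG_NEONATAL_TARGET = 12.0
MDG4_AROC = np.log(3.0) / 25.0  # two-thirds reduction over 1990-2015
PROJECTION_YEARS = 15  # 2015 -> 2030


def aroc(r_start, r_end, years: float):
    """Annualized rate of decline between two rates (fraction/year, log scale)."""
    r_start = np.asarray(r_start, dtype=float)
    r_end = np.asarray(r_end, dtype=float)
    if years <= 0:
        raise ValueError("years must be > 0")
    if np.any(r_start <= 0) or np.any(r_end <= 0):
        raise ValueError("rates must be positive")
    out = np.log(r_start / r_end) / years
    return float(out) if out.ndim == 0 else out


def project(r_now, rate: "np.ndarray | float", years: float = PROJECTION_YEARS):
    """Project a rate forward assuming a sustained annualized decline."""
    r_now = np.asarray(r_now, dtype=float)
    if np.any(r_now <= 0):
        raise ValueError("rates must be positive")
    out = r_now * np.exp(-np.asarray(rate) * years)
    return float(out) if out.ndim == 0 else out


def required_aroc(r_now, target: float, years: float = PROJECTION_YEARS):
    """Annualized decline needed to reach ``target`` in ``years`` (<= 0 if already met)."""
    r_now = np.asarray(r_now, dtype=float)
    if np.any(r_now <= 0) or target <= 0:
        raise ValueError("rates must be positive")
    if years <= 0:
        raise ValueError("years must be > 0")
    out = np.log(r_now / target) / years
    return float(out) if out.ndim == 0 else out


@dataclass
class TrendSurface:
    """Per-pixel trend summaries (means over draws) with draw arrays retained."""

    aroc_draws: np.ndarray  # (N, r, c) 2000-2015 annualized decline
    projected_2030_draws: np.ndarray  # (N, r, c) per 1000
    required_draws: np.ndarray  # (N, r, c) pace needed to hit the target
    target: float

    @property
    def aroc_mean(self):
        return self.aroc_draws.mean(axis=0)

    @property
    def projected_2030_mean(self):
        return self.projected_2030_draws.mean(axis=0)

    @property
    def required_mean(self):
        return self.required_draws.mean(axis=0)

    def on_track_share(self) -> np.ndarray:
        """Per-draw fraction of pixels projected at or below the target."""
        n = self.projected_2030_draws.shape[0]
        return (self.projected_2030_draws.reshape(n, -1) <= self.target).mean(axis=1)


def trend_surface(
    rate_draws: np.ndarray,
    target: float = SDG_U5_TARGET,
    start_period: int = 0,
    end_period: int = -1,
    span_years: float = 15.0,
) -> TrendSurface:
    """Draw-wise trend surfaces from per-period rate draws (N, T, r, c)."""
    r0 = np.clip(rate_draws[:, start_period], 1e-6, None)
    r1 = np.clip(rate_draws[:, end_period], 1e-6, None)
    a = aroc(r0, r1, span_years)
    return TrendSurface(
        aroc_draws=a,
        projected_2030_draws=project(r1, a),
        required_draws=required_aroc(r1, target),
        target=target,
    )


def classify_sdg(
    ts: TrendSurface,
    population: np.ndarray,
    mdg_pace: float = MDG4_AROC,
) -> pd.DataFrame:
    """Population-weighted attainment shares (%) with draw-based intervals.

    Categories: already at/below the target in 2015; on track (projected
    2030 rate at or below the target); achieved a decline faster than the
    MDG 4 pace; requiring more than the MDG 4 pace; requiring more than
    double the MDG 4 pace.
    """
    if population.shape != ts.aroc_draws.shape[1:]:
        raise ValueError("population raster does not match trend surface")
    n = ts.aroc_draws.shape[0]
    w = population.ravel()
    if w.sum() <= 0:
        raise ValueError("population raster has no mass")
    w = w / w.sum()

    r2015 = ts.projected_2030_draws.reshape(n, -1) * np.exp(
        ts.aroc_draws.reshape(n, -1) * PROJECTION_YEARS
    )  # invert the projection to recover the 2015 draws
    req = ts.required_draws.reshape(n, -1)
    achieved = ts.aroc_draws.reshape(n, -1)

    shares = {
        "met_target_2015": (r2015 <= ts.target) @ w,
        "on_track_2030": (ts.projected_2030_draws.reshape(n, -1) <= ts.target) @ w,
        "aroc_faster_than_mdg4": (achieved > mdg_pace) @ w,
        "requires_above_mdg4": (req > mdg_pace) @ w,
        "requires_above_double_mdg4": (req > 2 * mdg_pace) @ w,
    }
    rows = []
    for name, s in shares.items():
        s = 100.0 * s
        rows.append(
            {
                "category": name,
                "share_mean": float(s.mean()),
                "share_lower": float(np.quantile(s, 0.025)),
                "share_upper": float(np.quantile(s, 0.975)),
            }
        )
    return pd.DataFrame(rows)
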