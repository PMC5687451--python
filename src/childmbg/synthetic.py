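"""Synthetic study generator: truth surfaces, populations, admin units, surveys.

Generates a complete self-contained study region with the statistical
structure the downstream analysis assumes:

- a latent logit-scale monthly death probability per pixel, age bin and
  period, composed of an age-bin baseline, a declining period trend, linear
  covariate effects and a separable Matern x AR1 Gaussian-process residual;
- smooth covariate rasters and a log-normal population raster;
- a nested country / admin-1 / admin-2 hierarchy built by hierarchical
  nearest-centroid (Voronoi) partition of the pixel grid;
- cluster surveys with complete birth histories (per-child birth and death
  months simulated month by month from the pixel truth) and summary birth
  histories (children ever born / died per mother, collapsed from a latent
  complete history that is retained for training the partition model);
- polygon-referenced surveys where only the admin-2 unit of each cluster is
  recorded;
- reference national mortality tables for calibration, optionally perturbed.

Default sizes are desk scale: a 50 x 50 grid of 5 km pixels in 3 countries.
Baseline monthly probabilities correspond to an under-5 mortality rate of
roughly 125 per 1000 livebirths with a neonatal rate near 35 per 1000,
declining over the four periods — levels typical of high-burden settings in
the early 2000s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit, logit

from childmbg.demography import AGE_BINS, PERIODS, AgeBin, period_of_year
from childmbg.gp import chol_psd, matern_cov_xy, sample_matern_ar1
from childmbg.grids import GridSpec, write_ascii_grid

LANDCOVER_NORMAL = 0
LANDCOVER_BARREN = 1

#: months are counted in DHS-style century-month code: (year-1900)*12 + month
def cmc(year: int, month: int = 1) -> int:
    return (year - 1900) * 12 + month


def cmc_year(c) -> np.ndarray:
    return (np.asarray(c) - 1) // 12 + 1900


@dataclass(frozen=True)
class TruthConfig:
    """Configuration of the synthetic truth."""

    nrows: int = 50
    ncols: int = 50
    pixel_km: float = 5.0
    n_countries: int = 3
    n_admin1_per_country: int = 2
    n_admin2_per_admin1: int = 3
    n_covariates: int = 3
    covariate_effects: tuple[float, ...] = (-0.3, 0.2, 0.1)
    gp_range_km: float = 100.0
    gp_sd: float = 0.3
    gp_rho: float = 0.8
    matern_nu: float = 1.5
    baseline_q: tuple[float, float, float, float] = (0.035, 0.004, 0.0015, 0.0008)
    period_trend: float = -0.18  # logit decline per 5-year period
    mean_density: float = 40.0  # persons per km^2
    barren_frac: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.nrows <= 0 or self.ncols <= 0:
            raise ValueError("grid must be non-empty")
        if not -1.0 < self.gp_rho < 1.0:
            raise ValueError("gp_rho must be in (-1, 1)")
        if self.gp_sd < 0:
            raise ValueError("gp_sd must be >= 0")
        if len(self.covariate_effects) != self.n_covariates:
            raise ValueError("covariate_effects length must equal n_covariates")
        if any(not 0.0 < q < 1.0 for q in self.baseline_q):
            raise ValueError("baseline_q must lie in (0, 1)")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.nrows, self.ncols, self.pixel_km)


@dataclass
class SyntheticWorld:
    """A fully realized synthetic study region."""

    config: TruthConfig
    grid: GridSpec
    covariates: np.ndarray  # (n_cov, n_periods, nrows, ncols)
    population: np.ndarray  # (nrows, ncols)
    landcover: np.ndarray  # (nrows, ncols) int codes
    country: np.ndarray  # (nrows, ncols) int labels
    admin1: np.ndarray  # country*100 + k
    admin2: np.ndarray  # admin1*100 + m
    truth_q: np.ndarray  # (4 bins, 4 periods, nrows, ncols) monthly probabilities

    def admin_labels(self, level: int) -> np.ndarray:
        return {0: self.country, 1: self.admin1, 2: self.admin2}[level]

    def true_rate_surfaces(self) -> tuple[np.ndarray, np.ndarray]:
        """True (q5, nmr) per-1000 surfaces, each (n_periods, nrows, ncols)."""
        from childmbg.demography import N_MONTHS

        q = self.truth_q  # (4, T, r, c)
        surv = np.prod((1.0 - q) ** N_MONTHS[:, None, None, None], axis=0)
        q5 = 1000.0 * (1.0 - surv)
        nmr = 1000.0 * q[AgeBin.NEONATAL]
        return q5, nmr

    def true_nationals(self) -> pd.DataFrame:
        """Population-weighted true national 5q0 and NMR per country and period."""
        q5, nmr = self.true_rate_surfaces()
        rows = []
        for cid in np.unique(self.country):
            m = self.country == cid
            w = self.population[m]
            w = w / w.sum()
            for t, p in enumerate(PERIODS):
                rows.append(
                    {
                        "country": int(cid),
                        "period": p.label,
                        "q5": float(q5[t][m] @ w),
                        "nmr": float(nmr[t][m] @ w),
                    }
                )
        return pd.DataFrame(rows)


def _smooth_field(rng: np.random.Generator, shape, sigma_px: float) -> np.ndarray:
    f = gaussian_filter(rng.standard_normal(shape), sigma_px, mode="reflect")
    return (f - f.mean()) / (f.std() + 1e-12)


def _hierarchical_partition(cfg: TruthConfig, rng: np.random.Generator):
    """Nested nearest-centroid partition into country / admin1 / admin2 labels."""
    grid = cfg.grid
    xy = grid.flat_centers()

    def nearest(points, seeds):
        d = ((points[:, None, :] - seeds[None, :, :]) ** 2).sum(-1)
        return d.argmin(1)

    def pick_seeds(points, k):
        idx = rng.choice(len(points), size=min(k, len(points)), replace=False)
        return points[idx]

    country = nearest(xy, pick_seeds(xy, cfg.n_countries))
    admin1 = np.empty_like(country)
    admin2 = np.empty_like(country)
    for c in range(cfg.n_countries):
        mc = country == c
        a1 = nearest(xy[mc], pick_seeds(xy[mc], cfg.n_admin1_per_country))
        admin1[mc] = c * 100 + a1
        for a in np.unique(a1):
            ma = np.where(mc)[0][a1 == a]
            a2 = nearest(xy[ma], pick_seeds(xy[ma], cfg.n_admin2_per_admin1))
            admin2[ma] = (c * 100 + a) * 100 + a2
    shape = grid.shape
    return country.reshape(shape), admin1.reshape(shape), admin2.reshape(shape)


def simulate_world(cfg: TruthConfig) -> SyntheticWorld:
    """Draw a synthetic world from the configured generative model.

    Reproducible: the same config (including seed) yields an identical world.
    """
    rng = np.random.default_rng(cfg.seed)
    grid = cfg.grid
    n_t = len(PERIODS)
    shape = grid.shape
    sigma_px = max(2.0, 0.06 * max(shape))

    country, admin1, admin2 = _hierarchical_partition(cfg, rng)

    # covariates: persistent smooth fields with small per-period innovations
    covs = np.empty((cfg.n_covariates, n_t, *shape))
    for c in range(cfg.n_covariates):
        base = _smooth_field(rng, shape, sigma_px)
        for t in range(n_t):
            f = base + 0.3 * _smooth_field(rng, shape, sigma_px)
            covs[c, t] = (f - f.mean()) / (f.std() + 1e-12)

    pop_field = _smooth_field(rng, shape, sigma_px)
    population = np.exp(0.9 * pop_field)
    population *= cfg.mean_density * grid.pixel_area_km2 / population.mean()

    barren_field = _smooth_field(rng, shape, sigma_px)
    thresh = np.quantile(barren_field, 1.0 - cfg.barren_frac) if cfg.barren_frac > 0 else np.inf
    landcover = np.where(barren_field > thresh, LANDCOVER_BARREN, LANDCOVER_NORMAL)

    # latent logit-scale residual field, independent across age bins
    coords = grid.flat_centers()
    if cfg.gp_sd > 0:
        chol = chol_psd(matern_cov_xy(coords, coords, cfg.gp_range_km, cfg.gp_sd, cfg.matern_nu))
    else:
        chol = None
    truth_q = np.empty((len(AGE_BINS), n_t, *shape))
    betas = np.asarray(cfg.covariate_effects)
    for b, _bin in enumerate(AGE_BINS):
        z = sample_matern_ar1(
            coords, n_t, cfg.gp_range_km, cfg.gp_sd, cfg.gp_rho, rng, cfg.matern_nu, chol=chol
        ).reshape(n_t, *shape)
        for t in range(n_t):
            lin = logit(cfg.baseline_q[b]) + cfg.period_trend * t
            lin = lin + np.tensordot(betas, covs[:, t], axes=1) + z[t]
            truth_q[b, t] = expit(np.clip(lin, -12.0, 12.0))

    return SyntheticWorld(
        config=cfg,
        grid=grid,
        covariates=covs,
        population=population,
        landcover=landcover,
        country=country,
        admin1=admin1,
        admin2=admin2,
        truth_q=truth_q,
    )


@dataclass(frozen=True)
class SurveyDesign:
    """Design of one synthetic survey."""

    source_id: str = "survey0"
    instrument: str = "CBH"  # or "SBH"
    n_clusters: int = 200
    mothers_per_cluster: int = 15
    survey_year: int = 2016
    recall_years: int = 17
    bias_ratio: float = 1.0
    polygon: bool = False  # if True, only the admin-2 unit of each cluster is recorded
    births_per_mother_year: float = 0.22

    def __post_init__(self):
        if self.instrument not in ("CBH", "SBH"):
            raise ValueError("instrument must be CBH or SBH")
        if not 1 <= self.recall_years <= 17:
            raise ValueError("recall_years must be in 1..17")
        if self.bias_ratio <= 0:
            raise ValueError("bias_ratio must be positive")


def _sample_clusters(world: SyntheticWorld, n: int, rng: np.random.Generator):
    pop = world.population.ravel()
    ok = pop > 0
    p = np.where(ok, pop, 0.0)
    p = p / p.sum()
    flat = rng.choice(pop.size, size=n, replace=True, p=p)
    rows, cols = np.unravel_index(flat, world.grid.shape)
    return rows, cols


def _truth_lookup(world: SyntheticWorld):
    """Return q(bin_idx, year, rows, cols) with years clamped to the study span."""
    year0 = {p.label: i for i, p in enumerate(PERIODS)}

    def q(bin_idx, years, rows, cols):
        t = np.empty(len(years), dtype=int)
        for i, y in enumerate(np.atleast_1d(years)):
            p = period_of_year(int(min(max(y, PERIODS[0].first_year), PERIODS[-1].last_year)))
            t[i] = year0[p.label]
        return world.truth_q[bin_idx, t, rows, cols]

    return q


def simulate_cbh(
    world: SyntheticWorld, design: SurveyDesign, seed: int = 0, return_mothers: bool = False
):
    """Simulate a complete-birth-history survey.

    Each child's survival is simulated month by month from the true monthly
    probability of its pixel, age bin and calendar period. Births are spread
    over the recall window, constrained to months after the mother's 15th
    birthday so that older mothers report older children. One row per child:
    birth and death century-month codes (death NaN if alive at interview).
    """
    rng = np.random.default_rng(seed)
    rows, cols = _sample_clusters(world, design.n_clusters, rng)
    survey_cmc = cmc(design.survey_year, 7)
    window_lo = survey_cmc - design.recall_years * 12

    recs = []
    n_mothers = design.n_clusters * design.mothers_per_cluster
    m_cluster = np.repeat(np.arange(design.n_clusters), design.mothers_per_cluster)
    m_age = rng.integers(15, 50, size=n_mothers)
    m15_cmc = survey_cmc - (m_age - 15) * 12
    lo = np.maximum(window_lo, m15_cmc)
    hi = survey_cmc - 1
    span_years = np.maximum(hi - lo, 0) / 12.0
    n_children = rng.poisson(design.births_per_mother_year * span_years)

    child_mother = np.repeat(np.arange(n_mothers), n_children)
    n_total = child_mother.size
    birth_cmc = lo[child_mother] + (
        rng.random(n_total) * (hi - lo[child_mother] + 1)
    ).astype(int)

    c_rows = rows[m_cluster[child_mother]]
    c_cols = cols[m_cluster[child_mother]]
    qfun = _truth_lookup(world)

    death_cmc = np.full(n_total, np.nan)
    alive = np.ones(n_total, dtype=bool)
    from childmbg.demography import age_bin_of_month

    for m in range(60):
        month_cmc = birth_cmc + m
        at_risk = alive & (month_cmc < survey_cmc)
        if not at_risk.any():
            break
        idx = np.where(at_risk)[0]
        years = cmc_year(month_cmc[idx])
        q = qfun(int(age_bin_of_month(m)), years, c_rows[idx], c_cols[idx])
        died = rng.random(idx.size) < q
        death_cmc[idx[died]] = month_cmc[idx[died]]
        alive[idx[died]] = False

    df = pd.DataFrame(
        {
            "source_id": design.source_id,
            "cluster_id": m_cluster[child_mother],
            "row": c_rows,
            "col": c_cols,
            "polygon_id": world.admin2[c_rows, c_cols] if design.polygon else -1,
            "mother_id": child_mother,
            "mother_age": m_age[child_mother],
            "birth_cmc": birth_cmc,
            "death_cmc": death_cmc,
            "survey_cmc": survey_cmc,
        }
    )
    if design.polygon:
        # public view of a polygon survey: exact pixel unknown
        df["row"] = -1
        df["col"] = -1
    if not return_mothers:
        return df
    mothers = pd.DataFrame(
        {
            "mother_id": np.arange(n_mothers),
            "cluster_id": m_cluster,
            "row": -1 if design.polygon else rows[m_cluster],
            "col": -1 if design.polygon else cols[m_cluster],
            "polygon_id": world.admin2[rows[m_cluster], cols[m_cluster]] if design.polygon else -1,
            "mother_age": m_age,
            "survey_cmc": survey_cmc,
        }
    )
    return df, mothers


MOTHER_AGE_GROUPS = ("15-19", "20-24", "25-29", "30-34", "35-39", "40-44", "45-49")


def mother_age_group(age_years) -> np.ndarray:
    """5-year mother age band index (0 = 15-19 ... 6 = 45-49)."""
    return np.clip((np.asarray(age_years) - 15) // 5, 0, 6).astype(int)


def simulate_sbh(
    world: SyntheticWorld, design: SurveyDesign, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a summary-birth-history survey.

    Simulates a full complete birth history first, then collapses it to one
    row per mother (children ever born, children died, mother age group),
    discarding dates; mothers without children appear with CEB = CD = 0.
    Returns ``(sbh, latent_cbh)``; the latent complete history is retained
    for training and validating the partition model.
    """
    latent, mothers = simulate_cbh(
        world, replace(design, instrument="CBH"), seed=seed, return_mothers=True
    )
    per_mother = latent.groupby("mother_id").agg(
        ceb=("birth_cmc", "size"),
        cd=("death_cmc", lambda s: int(s.notna().sum())),
    )
    sbh = mothers.merge(per_mother, on="mother_id", how="left")
    sbh[["ceb", "cd"]] = sbh[["ceb", "cd"]].fillna(0).astype(int)
    sbh["source_id"] = design.source_id
    sbh["mother_age_group"] = mother_age_group(sbh["mother_age"])
    sbh["survey_year"] = design.survey_year
    return sbh, latent


def make_reference_nationals(
    world: SyntheticWorld,
    multiplier: float = 1.0,
    jitter_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Reference national 5q0/NMR table standing in for external estimates.

    Starts from the population-weighted truth and applies a fixed
    ``multiplier`` and, optionally, independent log-normal jitter of scale
    ``jitter_sd`` per country x period x indicator, emulating disagreement
    between the mapped estimates and the national reference series.
    """
    ref = world.true_nationals().copy()
    rng = np.random.default_rng(seed)
    for col in ("q5", "nmr"):
        f = multiplier * np.exp(jitter_sd * rng.standard_normal(len(ref))) if jitter_sd > 0 else multiplier
        ref[col] = ref[col] * f
    return ref


# ---------------------------------------------------------------------------
# on-disk interchange


def admin_geojson(world: SyntheticWorld, level: int) -> dict:
    """Admin polygons at a level as a GeoJSON FeatureCollection (pixel unions)."""
    from shapely.geometry import box, mapping
    from shapely.ops import unary_union

    labels = world.admin_labels(level)
    g = world.grid
    feats = []
    for uid in np.unique(labels):
        rr, cc = np.where(labels == uid)
        boxes = [
            box(
                g.x0 + c * g.pixel_km,
                g.y0 + (g.nrows - r - 1) * g.pixel_km,
                g.x0 + (c + 1) * g.pixel_km,
                g.y0 + (g.nrows - r) * g.pixel_km,
            )
            for r, c in zip(rr, cc)
        ]
        feats.append(
            {
                "type": "Feature",
                "properties": {"id": int(uid), "level": level},
                "geometry": mapping(unary_union(boxes)),
            }
        )
    return {"type": "FeatureCollection", "features": feats}


def write_world(world: SyntheticWorld, outdir: str | Path) -> None:
    """Write rasters (ASCII grid), admin GeoJSON, truth and nationals CSV."""
    import json

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    g = world.grid
    write_ascii_grid(out / "population.asc", g, world.population)
    write_ascii_grid(out / "landcover.asc", g, world.landcover.astype(float))
    for c in range(world.covariates.shape[0]):
        for t, p in enumerate(PERIODS):
            write_ascii_grid(out / f"cov{c}_{p.label}.asc", g, world.covariates[c, t])
    for level in (0, 1, 2):
        (out / f"admin{level}.geojson").write_text(json.dumps(admin_geojson(world, level)))
    recs = []
    for b, abin in enumerate(AGE_BINS):
        for t, p in enumerate(PERIODS):
            flat = world.truth_q[b, t].ravel()
            recs.append(
                pd.DataFrame(
                    {
                        "age_bin": abin.name,
                        "period": p.label,
                        "pixel": np.arange(flat.size),
                        "q_month": flat,
                    }
                )
            )
    pd.concat(recs).to_csv(out / "truth_q.csv", index=False)
    world.true_nationals().to_csv(out / "true_nationals.csv", index=False)
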