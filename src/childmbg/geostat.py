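"""Bayesian space-time binomial model with a Matern x AR1 residual process.

One model per age bin. Death counts at point locations follow a binomial
likelihood whose logit-probability combines an intercept, coefficients on
the logit-scale stacker predictions, and a spatiotemporal Gaussian-process
residual with separable covariance: Matern (smoothness 3/2 by default) in
space times a stationary first-order autoregression across the four
estimation periods.

Inference is a desk-scale Gaussian (Laplace) approximation on a reduced-rank
representation of the residual field: the process is projected onto a coarse
grid of knots (a predictive-process basis), the joint posterior mode of the
fixed effects and knot weights is found by penalized iteratively reweighted
least squares, and hyperparameters (spatial range, marginal SD, temporal
correlation) are chosen by maximizing the Laplace-approximate marginal
likelihood over a coarse grid followed by a simplex polish (empirical
Bayes). Posterior candidate maps are joint draws of the latent field at all
pixels from the Gaussian approximation at the selected hyperparameters —
spatially coherent draws, not independent per-pixel marginals. Fractional
exposures and deaths (from polygon resampling and SBH partitioning) are
handled by the weighted binomial log-likelihood, with each row's
contribution scaled by its weight.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize
from scipy.special import expit, logit

from childmbg.demography import AGE_BINS, PERIODS
from childmbg.gp import ar1_precision, matern_cov_xy
from childmbg.grids import GridSpec

logger = logging.getLogger(__name__)

PERIOD_INDEX = {p.label: i for i, p in enumerate(PERIODS)}
N_T = len(PERIODS)


@dataclass(frozen=True)
class GeostatSpec:
    """Inference settings for one age-bin model."""

    n_draws: int = 1000
    seed: int = 0
    knot_rows: int = 8
    knot_cols: int = 8
    matern_nu: float = 1.5
    tau_beta: float = 10.0  # SD of the weak Gaussian prior on fixed effects
    range_grid: tuple[float, ...] | None = None  # km; default scaled to the domain
    sd_grid: tuple[float, ...] = (0.05, 0.1, 0.2, 0.4, 0.8)
    rho_grid: tuple[float, ...] = (0.3, 0.6, 0.9)
    polish: bool = True
    polish_maxfev: int = 40
    max_newton: int = 60
    draw_budget_bytes: int = 2_000_000_000

    def __post_init__(self):
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")


def _knot_coords(grid: GridSpec, spec: GeostatSpec) -> np.ndarray:
    xs = grid.x0 + (np.arange(spec.knot_cols) + 0.5) / spec.knot_cols * grid.ncols * grid.pixel_km
    ys = grid.y0 + (np.arange(spec.knot_rows) + 0.5) / spec.knot_rows * grid.nrows * grid.pixel_km
    xx, yy = np.meshgrid(xs, ys)
    return np.column_stack([xx.ravel(), yy.ravel()])


def _projector(coords: np.ndarray, knots: np.ndarray, range_km: float, nu: float):
    """Predictive-process projector C_su C_uu^{-1} and knot-precision pieces."""
    c_uu = matern_cov_xy(knots, knots, range_km, 1.0, nu)
    c_uu[np.diag_indices_from(c_uu)] += 1e-8
    cf = cho_factor(c_uu, lower=True)
    proj = cho_solve(cf, matern_cov_xy(knots, coords, range_km, 1.0, nu)).T
    cu_inv = cho_solve(cf, np.eye(len(knots)))
    logdet_cu = 2.0 * np.log(np.diag(cf[0])).sum()
    return proj, cu_inv, logdet_cu


class _LaplaceFit:
    """Penalized IRLS for the joint mode and the Laplace marginal likelihood."""

    def __init__(self, x, proj, t_idx, deaths, exposure, spec: GeostatSpec):
        n, self.p = x.shape
        self.m = proj.shape[1]
        self.k = self.m * N_T
        design = np.zeros((n, self.p + self.k))
        design[:, : self.p] = x
        for t in range(N_T):
            rows = t_idx == t
            design[np.ix_(rows, self.p + t * self.m + np.arange(self.m))] = proj[rows]
        self.design = design
        self.d = deaths
        self.e = exposure
        self.spec = spec

    def q_full(self, cu_inv, logdet_cu, sd, rho):
        a_inv = ar1_precision(N_T, rho)
        q = np.kron(a_inv, cu_inv) / sd**2
        sign, logdet_a_inv = np.linalg.slogdet(a_inv)
        logdet_q = self.m * logdet_a_inv - N_T * logdet_cu - 2 * self.k * np.log(sd)
        qf = np.zeros((self.p + self.k, self.p + self.k))
        qf[: self.p, : self.p] = np.eye(self.p) / self.spec.tau_beta**2
        qf[self.p :, self.p :] = q
        logdet_qf = logdet_q - 2 * self.p * np.log(self.spec.tau_beta)
        return qf, logdet_qf

    def _objective(self, z, qf):
        eta = self.design @ z
        ll = self.d @ eta - self.e @ np.logaddexp(0.0, eta)
        return -ll + 0.5 * z @ qf @ z

    def mode(self, qf, z0=None):
        z = np.zeros(self.p + self.k) if z0 is None else z0.copy()
        f = self._objective(z, qf)
        cf = None
        for _ in range(self.spec.max_newton):
            eta = self.design @ z
            prob = expit(eta)
            g = self.design.T @ (self.d - self.e * prob) - qf @ z
            w = self.e * prob * (1.0 - prob) + 1e-12
            h = (self.design.T * w) @ self.design + qf
            cf = cho_factor(h, lower=True)
            step = cho_solve(cf, g)
            # backtracking line search
            alpha = 1.0
            for _ in range(30):
                z_new = z + alpha * step
                f_new = self._objective(z_new, qf)
                if f_new <= f + 1e-12:
                    break
                alpha *= 0.5
            moved = np.max(np.abs(alpha * step))
            z, f = z_new, f_new
            if moved < 1e-7:
                break
        logdet_h = 2.0 * np.log(np.diag(cf[0])).sum()
        return z, f, cf, logdet_h

    def marginal_ll(self, cu_inv, logdet_cu, sd, rho, z0=None):
        qf, logdet_qf = self.q_full(cu_inv, logdet_cu, sd, rho)
        z, f, cf, logdet_h = self.mode(qf, z0)
        return -f + 0.5 * logdet_qf - 0.5 * logdet_h, z, cf


@dataclass
class GeostatPosterior:
    """Laplace posterior for one age-bin model at selected hyperparameters."""

    age_bin: int
    beta_names: list[str]
    mode: np.ndarray  # (p + m*T,) joint mode of fixed effects and knot weights
    chol_hessian: tuple  # cho_factor of the Hessian at the mode
    range_km: float
    sd: float
    rho: float
    knots: np.ndarray
    grid: GridSpec
    spec: GeostatSpec
    marginal_ll: float
    converged: bool
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_beta(self) -> int:
        return len(self.beta_names)

    def beta_mean(self) -> np.ndarray:
        return self.mode[: self.n_beta]

    def beta_cov(self) -> np.ndarray:
        k = len(self.mode)
        eye = np.eye(k)
        cov = cho_solve(self.chol_hessian, eye)
        return cov[: self.n_beta, : self.n_beta]

    def beta_ci(self, level: float = 0.95) -> np.ndarray:
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2.0)
        mu = self.beta_mean()
        sd = np.sqrt(np.diag(self.beta_cov()))
        return np.column_stack([mu - z * sd, mu + z * sd])

    def sample_params(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Joint Gaussian draws of (beta, knot weights), shape (n, p + m*T)."""
        low = self.chol_hessian[0]
        eps = rng.standard_normal((len(self.mode), n))
        return (self.mode[:, None] + solve_triangular(low.T, eps, lower=False)).T


def stacker_design(stacker_probs: np.ndarray) -> np.ndarray:
    """[1, logit(stacker_1), ..., logit(stacker_S)] design matrix."""
    probs = np.clip(np.asarray(stacker_probs, dtype=float), 1e-6, 1 - 1e-6)
    return np.column_stack([np.ones(len(probs)), logit(probs)])


def fit_geostat(
    bt,
    stacker_probs: np.ndarray,
    grid: GridSpec,
    spec: GeostatSpec,
    age_bin: int | None = None,
) -> GeostatPosterior:
    """Fit the space-time binomial model for one age bin.

    ``bt`` holds point-located rows of a single age bin; ``stacker_probs``
    is the aligned (n, S) matrix of out-of-fold sub-model predictions on the
    probability scale. Rows with zero exposure are dropped.
    """
    bins = bt["age_bin"].unique()
    if age_bin is None:
        if len(bins) != 1:
            raise ValueError("bt must contain a single age bin (or pass age_bin)")
        age_bin = int(bins[0])
    else:
        keep = bt["age_bin"] == age_bin
        stacker_probs = np.asarray(stacker_probs)[keep.to_numpy()]
        bt = bt[keep]
    pos = bt["exposure"].to_numpy() > 0
    bt = bt[pos]
    stacker_probs = np.asarray(stacker_probs)[pos]

    wt = bt["weight"].to_numpy(dtype=float)
    d = bt["deaths"].to_numpy(dtype=float) * wt
    e = bt["exposure"].to_numpy(dtype=float) * wt
    t_idx = bt["period"].map(PERIOD_INDEX).to_numpy()
    xy = np.column_stack(grid.center_xy(bt["row"].to_numpy(), bt["col"].to_numpy()))
    x = stacker_design(stacker_probs)
    beta_names = ["intercept"] + [f"stacker{j}" for j in range(x.shape[1] - 1)]

    knots = _knot_coords(grid, spec)
    domain = float(np.hypot(grid.ncols * grid.pixel_km, grid.nrows * grid.pixel_km))
    range_grid = spec.range_grid or tuple(domain * f for f in (0.08, 0.15, 0.3, 0.5, 0.9))

    best = {"ll": -np.inf}
    z_warm = None
    proj_cache: dict[float, tuple] = {}
    for rng_km in range_grid:
        proj, cu_inv, logdet_cu = _projector(xy, knots, rng_km, spec.matern_nu)
        proj_cache[rng_km] = (proj, cu_inv, logdet_cu)
        lap = _LaplaceFit(x, proj, t_idx, d, e, spec)
        for sd, rho in itertools.product(spec.sd_grid, spec.rho_grid):
            ll, z, cf = lap.marginal_ll(cu_inv, logdet_cu, sd, rho, z0=z_warm)
            z_warm = z
            if ll > best["ll"]:
                best = {"ll": ll, "range": rng_km, "sd": sd, "rho": rho, "z": z, "cf": cf}

    if spec.polish:
        def neg_ll(theta):
            r, s = np.exp(theta[0]), np.exp(theta[1])
            rho = np.tanh(theta[2])
            r = float(np.clip(r, 1e-3 * domain, 10 * domain))
            s = float(np.clip(s, 1e-4, 10.0))
            proj, cu_inv, logdet_cu = _projector(xy, knots, r, spec.matern_nu)
            lap = _LaplaceFit(x, proj, t_idx, d, e, spec)
            ll, z, cf = lap.marginal_ll(cu_inv, logdet_cu, s, rho, z0=best["z"])
            neg_ll.state = (r, s, rho, z, cf, ll)
            return -ll

        theta0 = np.array(
            [np.log(best["range"]), np.log(best["sd"]), np.arctanh(np.clip(best["rho"], -0.99, 0.99))]
        )
        res = minimize(
            neg_ll, theta0, method="Nelder-Mead",
            options={"maxfev": spec.polish_maxfev, "xatol": 1e-3, "fatol": 1e-4},
        )
        if -res.fun > best["ll"]:
            neg_ll(res.x)  # refresh state at optimum
            r, s, rho, z, cf, ll = neg_ll.state
            best = {"ll": ll, "range": r, "sd": s, "rho": rho, "z": z, "cf": cf}

    # convergence diagnostic: gradient norm at the mode
    proj, cu_inv, logdet_cu = _projector(xy, knots, best["range"], spec.matern_nu)
    lap = _LaplaceFit(x, proj, t_idx, d, e, spec)
    qf, _ = lap.q_full(cu_inv, logdet_cu, best["sd"], best["rho"])
    eta = lap.design @ best["z"]
    g = lap.design.T @ (d - e * expit(eta)) - qf @ best["z"]
    grad_norm = float(np.max(np.abs(g)))
    converged = grad_norm < 1e-3 * max(1.0, float(e.sum()) / len(e))
    if not converged:
        logger.warning("geostat fit for bin %d flagged: gradient norm %.3g", age_bin, grad_norm)

    return GeostatPosterior(
        age_bin=age_bin,
        beta_names=beta_names,
        mode=best["z"],
        chol_hessian=best["cf"],
        range_km=best["range"],
        sd=best["sd"],
        rho=best["rho"],
        knots=knots,
        grid=grid,
        spec=spec,
        marginal_ll=best["ll"],
        converged=converged,
        diagnostics={"grad_norm": grad_norm, "n_rows": len(e)},
    )


@dataclass
class CandidateMaps:
    """Joint posterior draws of monthly death probability per pixel.

    ``draws`` has shape (n_draws, n_age_bins, n_periods, nrows, ncols).
    """

    draws: np.ndarray
    grid: GridSpec
    period_labels: tuple[int, ...] = tuple(p.label for p in PERIODS)
    seed: int | None = None

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def __post_init__(self):
        if np.any(self.draws <= 0) or np.any(self.draws >= 1):
            raise ValueError("candidate-map probabilities must lie in (0, 1)")

    def save(self, path) -> None:
        """Persist draws as a compressed array with a JSON sidecar manifest."""
        import json
        from pathlib import Path

        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"), draws=self.draws)
        manifest = {
            "format": "childmbg-candidate-maps-v1",
            "shape": list(self.draws.shape),
            "dims": ["draw", "age_bin", "period", "row", "col"],
            "period_labels": list(self.period_labels),
            "seed": self.seed,
            "grid": {
                "nrows": self.grid.nrows, "ncols": self.grid.ncols,
                "pixel_km": self.grid.pixel_km, "x0": self.grid.x0, "y0": self.grid.y0,
            },
        }
        path.with_suffix(".json").write_text(json.dumps(manifest))

    @classmethod
    def load(cls, path) -> "CandidateMaps":
        import json
        from pathlib import Path

        path = Path(path)
        manifest = json.loads(path.with_suffix(".json").read_text())
        draws = np.load(path.with_suffix(".npz"))["draws"]
        return cls(
            draws=draws,
            grid=GridSpec(**manifest["grid"]),
            period_labels=tuple(manifest["period_labels"]),
            seed=manifest["seed"],
        )


def draw_candidate_fields(
    post: GeostatPosterior,
    pixel_stacker_probs: dict[int, np.ndarray],
    n_draws: int | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Draw joint posterior fields for one age bin.

    ``pixel_stacker_probs`` maps period label -> (n_pixels, S) stacker
    probabilities at every pixel (row-major). Returns an array
    (n_draws, n_periods, nrows, ncols) of monthly death probabilities.
    """
    n = n_draws if n_draws is not None else post.spec.n_draws
    grid = post.grid
    need = n * N_T * grid.n_pixels * 8
    if need > post.spec.draw_budget_bytes:
        raise MemoryError(
            f"draw array would need {need} bytes (> budget {post.spec.draw_budget_bytes}); "
            "reduce n_draws or tile the grid"
        )
    rng = np.random.default_rng(post.spec.seed if seed is None else seed)
    params = post.sample_params(n, rng)  # (n, p + m*T)
    p0 = post.n_beta
    m = len(post.knots)
    proj_pix = _projector(grid.flat_centers(), post.knots, post.range_km, post.spec.matern_nu)[0]
    out = np.empty((n, N_T, grid.nrows, grid.ncols))
    for t, plabel in enumerate(p.label for p in PERIODS):
        x_pix = stacker_design(pixel_stacker_probs[plabel])  # (npix, p)
        eta = x_pix @ params[:, :p0].T + proj_pix @ params[:, p0 + t * m : p0 + (t + 1) * m].T
        out[:, t] = expit(eta).T.reshape(n, grid.nrows, grid.ncols)
    return np.clip(out, 1e-12, 1 - 1e-12)


def fit_all_bins(
    bt,
    stackers,
    grid: GridSpec,
    spec: GeostatSpec,
) -> dict[int, GeostatPosterior]:
    """Fit the four age-bin models from a bin table and a fitted StackerSet."""
    posteriors = {}
    oos = stackers.oos_matrix()
    for b in AGE_BINS:
        mask = (bt["age_bin"] == int(b)).to_numpy()
        posteriors[int(b)] = fit_geostat(bt[mask], oos[mask], grid, spec)
    return posteriors


def draw_candidate_maps(
    posteriors: dict[int, "GeostatPosterior"],
    stackers,
    n_draws: int | None = None,
    seed: int = 0,
) -> CandidateMaps:
    """Candidate maps across all four age bins (deterministic given seed)."""
    bins = sorted(posteriors)
    grid = posteriors[bins[0]].grid
    arrays = []
    for i, b in enumerate(bins):
        pix = {
            p.label: stackers.raster_matrix(b, p.label) for p in PERIODS
        }
        arrays.append(draw_candidate_fields(posteriors[b], pix, n_draws=n_draws, seed=seed + i))
    draws = np.stack(arrays, axis=1)
    return CandidateMaps(draws=draws, grid=grid, seed=seed)
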