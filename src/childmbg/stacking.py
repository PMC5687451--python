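"""Stacked generalization: sub-model ensembles feeding the geostatistical model.

For every age bin and period, four sub-models — a generalised additive model
(GAM), boosted regression trees (BRT), lasso and ridge regression — are fit
to the empirical monthly death probability (deaths / exposure months) of the
point-located data, with exposure as the observation weight. Each sub-model
predicts every observation out of sample under five-fold cross-validation
(folds spatially blocked by admin-1 unit when block labels are supplied);
full-data refits produce per-pixel prediction rasters. The out-of-fold
predictions become covariates for the space-time model, which learns how to
weight the sub-models without overfitting — the stacking step removes
unpredictive covariates and captures non-linear covariate effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.linear_model import Lasso, Ridge

from childmbg.demography import PERIODS

logger = logging.getLogger(__name__)

SUBMODELS = ("GAM", "BRT", "LASSO", "RIDGE")
CLAMP = (1e-6, 1.0 - 1e-6)
PERIOD_INDEX = {p.label: i for i, p in enumerate(PERIODS)}


def assign_folds(n_or_index, n_folds: int = 5, seed: int = 0, blocks=None) -> np.ndarray:
    """Assign rows to cross-validation folds.

    Without ``blocks``: a seeded random partition balanced within one row.
    With ``blocks`` (one label per row, e.g. the admin-1 unit of the point):
    whole blocks are assigned to folds by a greedy longest-processing-time
    heuristic balancing block sizes, so no block spans two folds.
    """
    n = len(n_or_index) if hasattr(n_or_index, "__len__") else int(n_or_index)
    if n < n_folds:
        raise ValueError(f"need at least {n_folds} rows, got {n}")
    rng = np.random.default_rng(seed)
    if blocks is None:
        order = rng.permutation(n)
        folds = np.empty(n, dtype=int)
        folds[order] = np.arange(n) % n_folds
        return folds
    blocks = np.asarray(blocks)
    uniq, inv = np.unique(blocks, return_inverse=True)
    sizes = np.bincount(inv)
    # shuffle before sorting so ties break randomly but reproducibly
    perm = rng.permutation(len(uniq))
    order = perm[np.argsort(sizes[perm], kind="stable")[::-1]]
    load = np.zeros(n_folds)
    block_fold = np.empty(len(uniq), dtype=int)
    for b in order:
        f = int(np.argmin(load))
        block_fold[b] = f
        load[f] += sizes[b]
    return block_fold[inv]


def _empirical_logit(deaths, exposure):
    p = (np.asarray(deaths) + 0.5) / (np.asarray(exposure) + 1.0)
    return logit(np.clip(p, *CLAMP))


class _SubModel:
    """One sub-model: fits on (X, deaths, exposure), predicts probabilities."""

    def __init__(self, kind: str, seed: int = 0):
        self.kind = kind
        self.seed = seed
        self._lo = None
        self._hi = None

    def fit(self, x, deaths, exposure):
        x = np.asarray(x, dtype=float)
        self._lo, self._hi = x.min(0), x.max(0)
        w = np.asarray(exposure, dtype=float)
        if self.kind == "GAM":
            import statsmodels.api as sm
            from statsmodels.gam.api import BSplines, GLMGam

            ncov = x.shape[1]
            self._bs = BSplines(x, df=[5] * ncov, degree=[3] * ncov)
            # half-event smoothing keeps the binomial fit away from perfect separation
            prob = np.clip((np.asarray(deaths) + 0.5) / (w + 1.0), *CLAMP)
            model = GLMGam(
                prob, exog=np.ones((len(prob), 1)), smoother=self._bs,
                family=sm.families.Binomial(), var_weights=w,
            )
            self._fit = model.fit()
        else:
            y = _empirical_logit(deaths, exposure)
            if self.kind == "BRT":
                est = GradientBoostingRegressor(
                    max_depth=3, n_estimators=200, learning_rate=0.05,
                    subsample=0.8, random_state=self.seed,
                )
            elif self.kind == "LASSO":
                est = Lasso(alpha=0.005, max_iter=20000)
            elif self.kind == "RIDGE":
                est = Ridge(alpha=1.0)
            else:
                raise ValueError(f"unknown sub-model {self.kind}")
            self._mu, self._sd = x.mean(0), x.std(0) + 1e-12
            est.fit((x - self._mu) / self._sd, y, sample_weight=w)
            self._fit = est
        return self

    def predict(self, x) -> np.ndarray:
        x = np.clip(np.asarray(x, dtype=float), self._lo, self._hi)
        if self.kind == "GAM":
            p = self._fit.predict(np.ones((len(x), 1)), exog_smooth=x)
        else:
            p = expit(self._fit.predict((x - self._mu) / self._sd))
        return np.clip(p, *CLAMP)

    @property
    def coef_(self):
        return getattr(self._fit, "coef_", None)


@dataclass
class StackerSet:
    """Fitted stacking ensemble for all (age bin, period) strata."""

    submodels: tuple[str, ...]
    folds: np.ndarray  # fold label per bin-table row
    oos: pd.DataFrame  # out-of-sample probability per row x sub-model
    rasters: dict  # (age_bin, period_label, submodel) -> (nrows, ncols) array
    models: dict = field(default_factory=dict)  # (age_bin, period_label, submodel) -> _SubModel
    manifest: dict = field(default_factory=dict)

    def oos_matrix(self, rows_idx=None) -> np.ndarray:
        m = self.oos[list(self.submodels)].to_numpy()
        return m if rows_idx is None else m[rows_idx]

    def raster_matrix(self, age_bin: int, period_label: int) -> np.ndarray:
        """(n_pixels, n_submodels) probability predictions, row-major pixels."""
        cols = [self.rasters[(age_bin, period_label, s)].ravel() for s in self.submodels]
        return np.column_stack(cols)


def covariate_rows(covariates: np.ndarray, bt: pd.DataFrame) -> np.ndarray:
    """Extract covariate values at each bin-table row's pixel and period."""
    t = bt["period"].map(PERIOD_INDEX).to_numpy()
    r = bt["row"].to_numpy(dtype=int)
    c = bt["col"].to_numpy(dtype=int)
    return np.stack([covariates[k, t, r, c] for k in range(covariates.shape[0])], axis=1)


def fit_stackers(
    bt: pd.DataFrame,
    covariates: np.ndarray,
    n_folds: int = 5,
    seed: int = 0,
    blocks=None,
    submodels: tuple[str, ...] = SUBMODELS,
) -> StackerSet:
    """Fit the stacking ensemble per (age bin, period) stratum.

    ``bt`` must be point-located (rows/cols are pixel indices). Returns
    out-of-fold predictions for every row, full-data-refit rasters per
    stratum and sub-model, and a provenance manifest recording which model
    produced each prediction. A sub-model whose fit raises is dropped for
    that stratum with a warning; at least one must survive.
    """
    if (bt["loc_type"] != "point").any():
        raise ValueError("fit_stackers requires point-located rows; resample polygons first")
    bt = bt.reset_index(drop=True)
    folds = assign_folds(len(bt), n_folds=n_folds, seed=seed, blocks=blocks)
    x_all = covariate_rows(covariates, bt)
    oos = pd.DataFrame(np.nan, index=bt.index, columns=list(submodels))
    rasters: dict = {}
    models: dict = {}
    manifest: dict = {"n_folds": n_folds, "seed": seed, "strata": []}

    for (abin, plabel), grp in bt.groupby(["age_bin", "period"]):
        idx = grp.index.to_numpy()
        x = x_all[idx]
        d = grp["deaths"].to_numpy()
        e = grp["exposure"].to_numpy()
        t = PERIOD_INDEX[plabel]
        x_pix = np.stack([covariates[k, t].ravel() for k in range(covariates.shape[0])], axis=1)
        survived = []
        for kind in submodels:
            try:
                for f in range(n_folds):
                    tr = folds[idx] != f
                    te = ~tr
                    if te.sum() == 0:
                        continue
                    if tr.sum() < 10:
                        raise RuntimeError("too few training rows in fold complement")
                    m = _SubModel(kind, seed=seed + f).fit(x[tr], d[tr], e[tr])
                    oos.iloc[idx[te], oos.columns.get_loc(kind)] = m.predict(x[te])
                full = _SubModel(kind, seed=seed).fit(x, d, e)
                shape = covariates.shape[2:]
                rasters[(int(abin), int(plabel), kind)] = full.predict(x_pix).reshape(shape)
                models[(int(abin), int(plabel), kind)] = full
                survived.append(kind)
            except Exception as err:  # noqa: BLE001 - sub-model failure is recoverable
                logger.warning("sub-model %s failed for bin %s period %s: %s", kind, abin, plabel, err)
                oos[kind] = oos[kind].where(~oos.index.isin(idx), np.nan)
        if not survived:
            raise RuntimeError(f"all sub-models failed for bin {abin}, period {plabel}")
        manifest["strata"].append(
            {"age_bin": int(abin), "period": int(plabel), "submodels": survived, "n_rows": len(idx)}
        )

    kept = [s for s in submodels if oos[s].notna().all()]
    if not kept:
        raise RuntimeError("no sub-model produced predictions for every stratum")
    dropped = [s for s in submodels if s not in kept]
    if dropped:
        logger.warning("dropping sub-models without full coverage: %s", dropped)
    return StackerSet(
        submodels=tuple(kept),
        folds=folds,
        oos=oos[kept],
        rasters={k: v for k, v in rasters.items() if k[2] in kept},
        models={k: v for k, v in models.items() if k[2] in kept},
        manifest=manifest,
    )
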