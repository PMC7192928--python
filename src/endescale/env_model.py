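"""Environmental heterogeneity, the spatial autocovariate, and the
endemism-heterogeneity linear mixed model.

Heterogeneity is the sample standard deviation (ddof=1) of fine subcell
values within each grid cell; aggregating grain pools the subcells of
the merged block before taking the SD.  The model regresses an endemism
surface on the four standardized variation terms plus an autoregressive
spatial covariate, with a random intercept per continent, fit by maximum
likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .endemism import EndemismSurface
from .grid_comm import Grid

__all__ = [
    "LAYER_NAMES",
    "EnvLayerSet",
    "env_heterogeneity",
    "aggregate_env",
    "spatial_autocovariate",
    "ModelSpec",
    "ModelFit",
    "build_model_spec",
    "fit_endemism_model",
    "likelihood_ratio_test",
]

LAYER_NAMES = ("temperature", "precipitation", "productivity", "elevation")


@dataclass
class EnvLayerSet:
    """Fine-resolution environmental values: per cell, a block of subcells.

    ``layers[name]`` has shape (n_cells, n_subcells); ``k`` is the side
    of the square subcell block within each cell (n_subcells = k*k for
    native layers; pooled blocks after aggregation keep the flat count).
    """

    grid: Grid
    k: int
    layers: dict[str, np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        for name, arr in self.layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[0] != self.grid.n_cells:
                raise ValueError(f"layer {name!r} must be (n_cells, n_subcells)")
            if arr.shape[1] < 2:
                raise ValueError(f"layer {name!r} has < 2 subcells per cell")
            self.layers[name] = arr

    @property
    def n_subcells(self) -> int:
        return next(iter(self.layers.values())).shape[1]


def env_heterogeneity(env: EnvLayerSet, grid: Optional[Grid] = None) -> pd.DataFrame:
    """Per-cell, per-layer sample SD of subcell values (ddof=1).

    Returns a DataFrame indexed by cell id with one column per layer.
    """
    if grid is not None and grid != env.grid:
        raise ValueError("grid does not match the environment layer set")
    if env.n_subcells < 2:
        raise ValueError("need at least 2 subcells per cell for a standard deviation")
    out = {
        name: np.std(arr, axis=1, ddof=1) for name, arr in env.layers.items()
    }
    return pd.DataFrame(out, index=env.grid.cell_ids)


def aggregate_env(env: EnvLayerSet, factor: int) -> EnvLayerSet:
    """Pool subcells over factor x factor cell blocks onto the coarse grid."""
    coarse, mapping = env.grid.coarsen(factor)
    n_sub = env.n_subcells
    pooled_n = n_sub * factor * factor
    layers: dict[str, np.ndarray] = {}
    order = np.argsort(mapping, kind="stable")
    kept = order[mapping[order] >= 0]
    for name, arr in env.layers.items():
        pooled = arr[kept].reshape(coarse.n_cells, pooled_n)
        layers[name] = pooled
    return EnvLayerSet(grid=coarse, k=env.k * factor, layers=layers)


def spatial_autocovariate(
    surface: EndemismSurface | np.ndarray,
    grid: Optional[Grid] = None,
    max_neighbor_order: int = 1,
    weighting: str = "inverse-distance",
) -> np.ndarray:
    """Weighted mean of the response over rook neighbours of each cell.

    Order 1 uses the 4 rook neighbours; order 2 adds the next ring (cells
    at rook-graph distance 2).  Weights are inverse centroid distance or
    equal.  Edge cells average over their existing neighbours; a cell
    with no neighbours gets 0 with a warning.
    """
    if isinstance(surface, EndemismSurface):
        values = surface.values
        grid = surface.grid if grid is None else grid
        if grid != surface.grid:
            raise ValueError("surface and grid do not match")
    else:
        values = np.asarray(surface, dtype=float)
        if grid is None:
            raise ValueError("grid required when passing a bare value array")
    if values.shape != (grid.n_cells,):
        raise ValueError("values must hold one entry per grid cell")
    if weighting not in ("inverse-distance", "equal"):
        raise ValueError(f"unknown weighting {weighting!r}")
    v = values.reshape(grid.n_rows, grid.n_cols)
    num = np.zeros_like(v)
    den = np.zeros_like(v)
    for dr, dc in grid.neighbor_offsets(max_neighbor_order):
        dist = np.hypot(dr, dc) * grid.grain
        w = 1.0 / dist if weighting == "inverse-distance" else 1.0
        src_r = slice(max(dr, 0), grid.n_rows + min(dr, 0))
        dst_r = slice(max(-dr, 0), grid.n_rows + min(-dr, 0))
        src_c = slice(max(dc, 0), grid.n_cols + min(dc, 0))
        dst_c = slice(max(-dc, 0), grid.n_cols + min(-dc, 0))
        num[dst_r, dst_c] += w * v[src_r, src_c]
        den[dst_r, dst_c] += w
    if (den == 0).any():
        warnings.warn("cells without neighbours assigned autocovariate 0", stacklevel=2)
    out = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    return out.reshape(grid.n_cells)


@dataclass
class ModelSpec:
    """Inputs to the mixed model: response, raw predictors, grouping."""

    response: np.ndarray
    predictors: pd.DataFrame
    groups: np.ndarray
    standardize: bool = True

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=float)
        self.groups = np.asarray(self.groups)
        n = len(self.response)
        if len(self.predictors) != n or len(self.groups) != n:
            raise ValueError("response, predictors and groups must align")
        if self.predictors.isna().any().any():
            raise ValueError("missing predictor values")


@dataclass
class ModelFit:
    """Fixed-effect estimates, 95% CIs, random variance, residuals."""

    params: pd.Series
    conf_int: pd.DataFrame
    random_effect_var: float
    residuals: np.ndarray = field(repr=False)
    loglik: float = np.nan
    method: str = "mixed-ml"


def standardize_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Center to mean 0 and scale to SD 1 (population SD, ddof=0)."""
    mu = df.mean()
    sd = df.std(ddof=0)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValueError(f"constant predictor columns cannot be standardized: {bad}")
    return (df - mu) / sd


def build_model_spec(
    surface: EndemismSurface,
    heterogeneity: pd.DataFrame,
    regions: "RegionLabels",
    max_neighbor_order: int = 1,
    weighting: str = "inverse-distance",
) -> ModelSpec:
    """Assemble the standard model: 4 variation terms + autocovariate,
    continent grouping, restricted to occupied cells."""
    autocov = spatial_autocovariate(
        surface, max_neighbor_order=max_neighbor_order, weighting=weighting
    )
    occ = surface.occupied
    predictors = heterogeneity.loc[np.flatnonzero(occ)].copy()
    predictors.columns = [f"{c}_variation" for c in predictors.columns]
    predictors["autocov"] = autocov[occ]
    return ModelSpec(
        response=surface.values[occ],
        predictors=predictors.reset_index(drop=True),
        groups=np.asarray(regions.continent)[occ],
    )


def fit_endemism_model(spec: ModelSpec) -> ModelFit:
    """Random-intercept-per-continent linear mixed model, ML fit.

    Predictors are standardized first when ``spec.standardize`` is set.
    With a single group the model degrades to an ordinary least-squares
    fit with a warning.
    """
    import statsmodels.api as sm

    X = spec.predictors
    if spec.standardize:
        X = standardize_columns(X)
    exog = sm.add_constant(X, has_constant="add")
    n_groups = len(np.unique(spec.groups))
    if n_groups < 2:
        warnings.warn(
            "single grouping level: falling back to fixed-effects-only OLS",
            stacklevel=2,
        )
        res = sm.OLS(spec.response, exog).fit()
        ci = res.conf_int(alpha=0.05)
        ci.columns = ["lower", "upper"]
        return ModelFit(
            params=res.params,
            conf_int=ci,
            random_effect_var=0.0,
            residuals=np.asarray(res.resid),
            loglik=float(res.llf),
            method="ols",
        )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(spec.response, exog, groups=spec.groups)
            res = model.fit(reml=False)
            if float(np.asarray(res.cov_re).ravel()[0]) <= 0:
                raise np.linalg.LinAlgError("random-effect variance at boundary")
            if not np.all(np.isfinite(np.asarray(res.bse_fe, dtype=float))):
                raise np.linalg.LinAlgError("non-finite fixed-effect standard errors")
    except (np.linalg.LinAlgError, ValueError):
        # random-effect variance at the boundary: the mixed fit is singular,
        # so refit with group fixed effects instead (equivalent at var -> 0)
        warnings.warn(
            "singular mixed fit; refitting with continent fixed-effect dummies",
            stacklevel=2,
        )
        dummies = pd.get_dummies(
            pd.Series(spec.groups, name="grp"), drop_first=True, dtype=float
        ).reset_index(drop=True)
        exog2 = pd.concat([exog.reset_index(drop=True), dummies], axis=1)
        res = sm.OLS(spec.response, exog2).fit()
        keep = list(exog.columns)
        ci = res.conf_int(alpha=0.05).loc[keep]
        ci.columns = ["lower", "upper"]
        return ModelFit(
            params=res.params[keep],
            conf_int=ci,
            random_effect_var=0.0,
            residuals=np.asarray(res.resid),
            loglik=float(res.llf),
            method="ols-group-dummies",
        )
    fe = res.fe_params
    se = res.bse_fe
    try:
        resid = np.asarray(res.resid)
    except (ValueError, np.linalg.LinAlgError):
        resid = spec.response - np.asarray(exog) @ np.asarray(fe)  # marginal residuals
    from scipy.stats import norm

    z = norm.ppf(0.975)
    ci = pd.DataFrame(
        {"lower": fe - z * se, "upper": fe + z * se}, index=fe.index
    )
    return ModelFit(
        params=fe,
        conf_int=ci,
        random_effect_var=float(np.asarray(res.cov_re).ravel()[0]),
        residuals=resid,
        loglik=float(res.llf),
        method="mixed-ml",
    )


def likelihood_ratio_test(full: ModelFit, reduced: ModelFit, df: int) -> tuple[float, float]:
    """LR statistic and p-value comparing nested ML fits."""
    from scipy.stats import chi2

    stat = 2.0 * (full.loglik - reduced.loglik)
    return stat, float(chi2.sf(max(stat, 0.0), df))
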