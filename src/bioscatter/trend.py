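"""Hierarchical spatio-temporal trend modelling of aerial arthropod abundance.

The workflow mirrors the abundance analysis: a modelling table joins the
band-500 m abundance estimates with footprint-mean covariates; a ladder of
candidate additive models (year smooth, 2-D spatial smooth, random
intercepts for radar / month / grid cell, climate and land-cover smooths,
and a year-by-radar interaction) is fitted with double-penalty shrinkage
and AR(1) pre-whitened errors; candidates are ranked by AIC; residual
spatial structure is diagnosed with Moran's I correlograms; and the
selected fit produces per-year abundance predictions with delta-method
standard errors, plus first-to-last-year change maps.

Abundance densities are log10(x + 1)-transformed before the Gaussian fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gam import Linear, PenalizedGAM, RandomIntercept, Smooth, Smooth2D
from .geometry import CvpLattice
from .raster import Raster

__all__ = [
    "ModelSpec",
    "MoranResult",
    "assemble_model_table",
    "estimate_rho",
    "fit_trend_gam",
    "morans_i_correlogram",
    "select_best_model",
    "default_candidate_ladder",
    "predict_map",
    "annual_trend",
]

CLIMATE_COVARIATES = ("tmax", "rain", "wind")
LANDCOVER_COVARIATES = ("arable", "urban", "woodland", "grassland")
OTHER_COVARIATES = ("alan", "elevation")


@dataclass
class ModelSpec:
    """A named candidate model: a list of gam terms plus fit options."""

    name: str
    terms: list = field(default_factory=list)
    select: bool = True
    ar_rho: float = 0.0
    series: str | None = "cell"
    log_response: bool = True

    def estimator(self) -> PenalizedGAM:
        return PenalizedGAM(
            terms=list(self.terms), select=self.select, ar_rho=self.ar_rho, series=self.series
        )


def assemble_model_table(
    estimates: pd.DataFrame,
    covariates: dict[str, Raster],
    lattice: CvpLattice,
    window: int | None = None,
    log_response: bool = True,
    footprint_radius_km: float = 2.5,
) -> pd.DataFrame:
    """Join abundance estimates with footprint-mean covariates per column.

    One row per (cell, date, window) estimate; covariates are disc means
    over the 2.5 km column footprint; rows with a missing covariate are
    dropped.  Diurnal and nocturnal tables should be assembled separately
    by passing ``window``.
    """
    est = estimates.copy()
    if window is not None:
        est = est[est["window"] == window]
    cells = {(c.grid_row, c.grid_col): c for c in lattice.cells}
    foot: dict[tuple[int, int], dict[str, float]] = {}
    for key, cell in cells.items():
        foot[key] = {
            name: r.disc_mean(cell.easting, cell.northing, footprint_radius_km)
            for name, r in covariates.items()
        }
    rows = []
    for _, rec in est.iterrows():
        key = (int(rec["grid_row"]), int(rec["grid_col"]))
        cov = foot.get(key)
        if cov is None or any(not np.isfinite(v) for v in cov.values()):
            continue
        cell = cells[key]
        date = pd.Timestamp(rec["date"])
        resp = float(rec["density_per_km3"])
        rows.append(
            {
                "cell": f"{rec['site_id']}_{key[0]:02d}_{key[1]:02d}",
                "radar": rec["site_id"],
                "x": cell.easting,
                "y": cell.northing,
                "year": float(date.year),
                "month": int(date.month),
                "date": date,
                "window": rec.get("window", 0),
                **cov,
                "density_per_km3": resp,
                "response": np.log10(resp + 1.0) if log_response else resp,
            }
        )
    return pd.DataFrame(rows)


def estimate_rho(residuals, series=None) -> float:
    """Pooled lag-1 autocorrelation of residuals within ordered series.

    Scale-invariant; raises on zero-variance residuals.
    """
    r = np.asarray(residuals, dtype=float)
    if r.std() == 0:
        raise ValueError("zero-variance residuals: rho is undefined")
    if series is None:
        groups = [np.arange(r.size)]
    else:
        s = pd.Series(np.asarray(series))
        groups = [np.asarray(ix) for ix in s.groupby(s, sort=False).groups.values()]
    num = 0.0
    den = 0.0
    for idx in groups:
        if idx.size < 2:
            continue
        g = r[idx]
        g = g - g.mean()
        num += float(np.sum(g[1:] * g[:-1]))
        den += float(np.sum(g**2))
    if den == 0:
        raise ValueError("no series with >= 2 observations")
    return num / den


def estimate_rho_refined(
    spec: ModelSpec, table: pd.DataFrame, response: str = "response", n_iter: int = 2
) -> float:
    """Feasible-GLS estimate of the AR(1) parameter for a candidate model.

    A pilot fit at rho = 0 gives residuals whose pooled lag-1
    autocorrelation underestimates rho (series are short and the fit
    absorbs part of the autocorrelated noise); the estimate is first
    corrected for the within-series fitted-mean bias, (1 + rho)/T, and
    then refined by measuring the residual autocorrelation left in the
    pre-whitened innovations and folding it back in.
    """
    pilot = fit_trend_gam(replace_rho(spec, 0.0), table, response)
    cells = table[spec.series] if spec.series else pd.Series(np.zeros(len(table)))
    rho = estimate_rho(pilot.residuals_, cells)
    t_bar = float(cells.groupby(cells, sort=False).size().mean())
    rho = rho + (1.0 + rho) / t_bar
    for _ in range(n_iter):
        rho = float(np.clip(rho, 0.0, 0.95))
        fit = fit_trend_gam(replace_rho(spec, rho), table, response)
        u = _innovations(fit.residuals_, cells, rho)
        delta = float(np.corrcoef(u[1:], u[:-1])[0, 1]) if u.size > 2 else 0.0
        rho = rho + delta
    return float(np.clip(rho, 0.0, 0.95))


def replace_rho(spec: ModelSpec, rho: float) -> ModelSpec:
    return ModelSpec(spec.name, list(spec.terms), spec.select, rho, spec.series,
                     spec.log_response)


def _innovations(residuals: np.ndarray, series: pd.Series, rho: float) -> np.ndarray:
    out = []
    s = pd.Series(np.asarray(series))
    for _, idx in s.groupby(s, sort=False).groups.items():
        g = residuals[np.asarray(idx)]
        if g.size > 1:
            out.append(g[1:] - rho * g[:-1])
    return np.concatenate(out) if out else np.zeros(0)


def fit_trend_gam(spec: ModelSpec, table: pd.DataFrame, response: str = "response") -> PenalizedGAM:
    """Fit one candidate additive model to a modelling table."""
    terms = []
    for t in spec.terms:
        if isinstance(t, RandomIntercept) and table[t.var].nunique() < 2:
            continue  # degenerate factor: drop with a population-level fallback
        terms.append(t)
    est = PenalizedGAM(terms=terms, select=spec.select, ar_rho=spec.ar_rho, series=spec.series)
    est.fit(table, table[response].to_numpy(dtype=float))
    return est


@dataclass
class MoranResult:
    bin_edges_km: np.ndarray
    observed_i: np.ndarray
    expected_i: float
    p_values: np.ndarray
    n_pairs: np.ndarray
    n_perm: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo_km": self.bin_edges_km[:-1],
                "bin_hi_km": self.bin_edges_km[1:],
                "moran_i": self.observed_i,
                "expected_i": self.expected_i,
                "p_value": self.p_values,
                "n_pairs": self.n_pairs,
            }
        )


def morans_i_correlogram(residuals, coords, bin_edges_km, n_perm: int = 199, seed: int = 0) -> MoranResult:
    """Moran's I per distance band with permutation p-values.

    Binary distance-band weights; expectation under independence is
    -1/(n-1).  Bins with no pairs are flagged with NaN.  P-values are
    one-sided (large I) and reported unadjusted across bins.
    """
    z = np.asarray(residuals, dtype=float)
    xy = np.asarray(coords, dtype=float)
    n = z.size
    if n < 10:
        raise ValueError("need at least 10 points for a correlogram")
    edges = np.asarray(bin_edges_km, dtype=float)
    z = z - z.mean()
    denom = float(np.sum(z**2))
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    iu = ~np.eye(n, dtype=bool)
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(z) for _ in range(n_perm)])
    obs = np.full(edges.size - 1, np.nan)
    pvals = np.full(edges.size - 1, np.nan)
    npairs = np.zeros(edges.size - 1, dtype=int)
    for b in range(edges.size - 1):
        w = iu & (d >= edges[b]) & (d < edges[b + 1])
        s0 = float(w.sum())
        npairs[b] = int(s0)
        if s0 == 0:
            continue
        obs[b] = n / s0 * float(z @ w @ z) / denom
        perm_i = n / s0 * np.einsum("pi,ij,pj->p", perms, w, perms) / denom
        pvals[b] = (1.0 + np.sum(perm_i >= obs[b])) / (n_perm + 1.0)
    return MoranResult(edges, obs, -1.0 / (n - 1), pvals, npairs, n_perm, seed)


def default_candidate_ladder(
    table: pd.DataFrame,
    ar_rho: float = 0.0,
    with_year_by_radar: bool = True,
    k_year: int = 6,
    k_cov: int = 8,
    k_xy: int = 30,
) -> list[ModelSpec]:
    """The seven-candidate hierarchical ladder, nesting the full model.

    (1) intercept + f(year); (2) + f(x, y); (3) + random intercepts
    (radar, month, grid cell); (4) + climate smooths; (5) + land-cover
    smooths; (6) full (+ ALAN, elevation); (7) full + year-by-radar
    smooths.  Terms whose covariates are absent from the table are skipped.
    """

    def s(var, **kw):
        return Smooth(var, **kw) if var in table.columns else None

    def present(terms):
        return [t for t in terms if t is not None]

    year = s("year", k=min(k_year, max(4, table["year"].nunique())))
    xy = Smooth2D("x", "y", k=k_xy)
    res = [RandomIntercept(v) for v in ("radar", "month", "cell") if v in table.columns]
    climate = present([s(v, k=k_cov) for v in CLIMATE_COVARIATES])
    land = present([s(v, k=k_cov) for v in LANDCOVER_COVARIATES])
    other = present([s(v, k=k_cov) for v in OTHER_COVARIATES])
    ladder = [
        ModelSpec("m1_year", [year], ar_rho=ar_rho),
        ModelSpec("m2_space", [year, xy], ar_rho=ar_rho),
        ModelSpec("m3_random", [year, xy, *res], ar_rho=ar_rho),
        ModelSpec("m4_climate", [year, xy, *res, *climate], ar_rho=ar_rho),
        ModelSpec("m5_landcover", [year, xy, *res, *climate, *land], ar_rho=ar_rho),
        ModelSpec("m6_full", [year, xy, *res, *climate, *land, *other], ar_rho=ar_rho),
    ]
    if with_year_by_radar and "radar" in table.columns and table["radar"].nunique() > 1:
        ybr = Smooth("year", k=min(k_year, max(4, table["year"].nunique())), by="radar")
        ladder.append(
            ModelSpec("m7_year_by_radar", [year, ybr, xy, *res, *climate, *land, *other],
                      ar_rho=ar_rho)
        )
    return ladder


def select_best_model(
    candidates: list[ModelSpec], table: pd.DataFrame, response: str = "response"
) -> pd.DataFrame:
    """Fit every candidate and rank by AIC; failures are recorded, not fatal.

    Returns a frame sorted by AIC carrying delta-AIC, adjusted R^2,
    deviance explained and the fitted estimator per candidate.
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate models")
    rows = []
    for i, spec in enumerate(candidates):
        try:
            fit = fit_trend_gam(spec, table, response)
            rows.append(
                {
                    "name": spec.name,
                    "index": i,
                    "aic": fit.aic_,
                    "adj_r2": fit.adj_r2_,
                    "deviance_explained": fit.deviance_explained_,
                    "edf": fit.edf_,
                    "fit": fit,
                    "error": None,
                }
            )
        except Exception as exc:  # noqa: BLE001 - candidate failure is data
            rows.append(
                {"name": spec.name, "index": i, "aic": np.inf, "adj_r2": np.nan,
                 "deviance_explained": np.nan, "edf": np.nan, "fit": None, "error": str(exc)}
            )
    out = pd.DataFrame(rows)
    ok = out["error"].isna()
    out = pd.concat(
        [out[ok].sort_values(["aic", "index"], kind="stable"), out[~ok]], ignore_index=True
    )
    best = out.loc[out["error"].isna(), "aic"].min()
    out["delta_aic"] = out["aic"] - best
    return out


def predict_map(
    fit: PenalizedGAM,
    covariates: dict[str, Raster],
    years,
    template: Raster | None = None,
) -> dict[float, dict[str, Raster]]:
    """Per-year rasters of predicted (log) density, SE and extrapolation flag.

    Random-intercept terms are evaluated at the population level (the
    prediction frame carries none of their factor levels).
    """
    template = template or next(iter(covariates.values()))
    x, y = template.pixel_centres()
    xx, yy = np.meshgrid(x, y)
    base = pd.DataFrame({"x": xx.ravel(), "y": yy.ravel()})
    for name, r in covariates.items():
        base[name] = r.sample(xx.ravel(), yy.ravel())
    needed = _fit_columns(fit)
    out: dict[float, dict[str, Raster]] = {}
    for yr in years:
        frame = base.copy()
        frame["year"] = float(yr)
        for col in needed:
            if col not in frame.columns:
                frame[col] = "__population__"
        mu, se, extrap = fit.predict(frame, return_se=True, return_extrapolation=True)
        shape = xx.shape
        out[float(yr)] = {
            "prediction": Raster(mu.reshape(shape), template.x_min, template.y_min, template.cell_size),
            "se": Raster(se.reshape(shape), template.x_min, template.y_min, template.cell_size),
            "extrapolation": Raster(
                extrap.reshape(shape).astype(float), template.x_min, template.y_min, template.cell_size
            ),
        }
    return out


def _fit_columns(fit: PenalizedGAM) -> set[str]:
    cols: set[str] = set()
    for b in fit.built_:
        t = b.term
        for attr in ("var", "xvar", "yvar", "by"):
            v = getattr(t, attr, None)
            if isinstance(v, str):
                cols.add(v)
    return cols


def annual_trend(fit: PenalizedGAM, table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean prediction (+/- SE) per year, and a first-vs-last change map.

    The per-year mean is the model prediction averaged over every cell in
    the table; the change map is the per-cell difference between the last
    and first year (on the model's response scale, log if logged).
    """
    years = np.sort(table["year"].unique())
    if years.size < 2:
        raise ValueError("need at least 2 years for a trend")
    cells = table.drop_duplicates("cell")
    annual = []
    per_year_cell = {}
    for yr in years:
        frame = cells.copy()
        frame["year"] = float(yr)
        mu, se = fit.predict(frame, return_se=True)
        annual.append({"year": float(yr), "mean_prediction": float(mu.mean()),
                       "se": float(np.sqrt(np.mean(se**2)))})
        per_year_cell[yr] = mu
    change = pd.DataFrame(
        {
            "cell": cells["cell"].to_numpy(),
            "x": cells["x"].to_numpy(dtype=float),
            "y": cells["y"].to_numpy(dtype=float),
            "change": per_year_cell[years[-1]] - per_year_cell[years[0]],
        }
    )
    return pd.DataFrame(annual), change
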