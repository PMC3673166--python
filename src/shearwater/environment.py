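"""Behaviour vs environment: multinomial regression and use-vs-availability.

Daily dominant behaviours at migration locations are related to single
environmental covariates (net primary productivity, chlorophyll-a, sea
surface temperature) with a 3-category multinomial logit (reference
category: rest), fitted per migratory direction.  A two-sample
Kolmogorov-Smirnov test compares the covariate distribution at used
locations against locations sampled uniformly at random from the
behaviour's 95% occupancy contour (use vs availability).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
import shapely.geometry as sgeom
import statsmodels.api as sm
from scipy.interpolate import RegularGridInterpolator
from scipy.stats import ks_2samp

from shearwater.labelling import LABELS
from shearwater.migration import OccupancyContour
from shearwater.synthetic import EnvRaster


# ---------------------------------------------------------------------------
# raster sampling


def sample_raster(raster: EnvRaster, lats, lons) -> np.ndarray:
    """Bilinear interpolation of a raster at lat/lon points.

    Out-of-extent points yield NaN with a warning; NaN cells propagate.
    """
    lats = np.atleast_1d(np.asarray(lats, float))
    lons = np.atleast_1d(np.asarray(lons, float))
    interp = RegularGridInterpolator(
        (raster.lats, raster.lons),
        raster.values,
        method="linear",
        bounds_error=False,
        fill_value=np.nan,
    )
    vals = interp(np.column_stack([lats, lons]))
    if np.isnan(vals).any() and not np.isnan(raster.values).all():
        oob = (
            (lats < raster.lats.min())
            | (lats > raster.lats.max())
            | (lons < raster.lons.min())
            | (lons > raster.lons.max())
        )
        if oob.any():
            warnings.warn(f"{int(oob.sum())} locations outside raster extent -> NaN")
    return vals


# ---------------------------------------------------------------------------
# multinomial behaviour ~ covariate model


@dataclass
class MultinomFit:
    """3-category multinomial logit of behaviour on one covariate.

    Coefficients are for the non-reference categories (flight, forage)
    relative to rest; each has an intercept and a slope.
    """

    variable: str
    coef: pd.DataFrame  # index (category, term), columns coef/se/ci_low/ci_high
    curves: pd.DataFrame  # x plus p_<label> and CI bounds per label
    converged: bool
    penalized: bool
    loglike: float
    n: int

    def predict_proba(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, float))
        eta = np.zeros((len(x), 3))
        for j, lab in enumerate(LABELS[1:], start=1):
            b = self.coef.loc[(lab, "intercept"), "coef"]
            m = self.coef.loc[(lab, "slope"), "coef"]
            eta[:, j] = b + m * x
        ex = np.exp(eta - eta.max(axis=1, keepdims=True))
        return ex / ex.sum(axis=1, keepdims=True)


def fit_behaviour_env_model(
    samples: pd.DataFrame,
    variable: str,
    n_curve: int = 100,
    min_per_class: int = 30,
) -> MultinomFit:
    """Fit behaviour ~ covariate by maximum-likelihood multinomial logit.

    ``samples`` needs columns ``behaviour`` (rest/flight/forage) and
    ``variable``.  Requires at least ``min_per_class`` samples of every
    behaviour.  On non-convergence (e.g. complete separation) the fit is
    flagged and refitted with a ridge penalty.
    """
    df = samples.dropna(subset=[variable]).copy()
    counts = df["behaviour"].value_counts()
    missing = [lab for lab in LABELS if counts.get(lab, 0) < min_per_class]
    if missing:
        raise ValueError(
            f"behaviours {missing} have fewer than {min_per_class} samples"
        )
    # centre/scale the covariate for numerical stability; report on raw scale
    x = df[variable].to_numpy(float)
    mu, sd = x.mean(), x.std()
    sd = sd if sd > 0 else 1.0
    z = (x - mu) / sd
    y = pd.Categorical(df["behaviour"], categories=LABELS).codes
    X = sm.add_constant(z)

    penalized = False
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MNLogit(y, X).fit(disp=False, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", True))
        params = np.asarray(res.params)  # (2 terms, 2 non-ref categories)
        bse = np.asarray(res.bse)
        llf = float(res.llf)
    except Exception:
        converged = False
        params = bse = None
        llf = float("nan")
    if not converged or params is None or not np.all(np.isfinite(params)):
        penalized = True
        params, bse, llf = _ridge_mnlogit(z, y)

    rows = []
    for j, lab in enumerate(LABELS[1:]):
        # un-standardise: slope_raw = slope_z / sd; intercept_raw shifts by mu
        b0z, b1z = params[0, j], params[1, j]
        s0z, s1z = bse[0, j], bse[1, j]
        b1 = b1z / sd
        b0 = b0z - b1z * mu / sd
        s1 = s1z / sd
        # intercept SE on the raw scale via linear combination variance
        s0 = float(np.sqrt(s0z**2 + (mu / sd) ** 2 * s1z**2))
        for term, c, s in (("intercept", b0, s0), ("slope", b1, s1)):
            rows.append(
                {
                    "category": lab,
                    "term": term,
                    "coef": float(c),
                    "se": float(s),
                    "ci_low": float(c - 1.96 * s),
                    "ci_high": float(c + 1.96 * s),
                }
            )
    coef = pd.DataFrame(rows).set_index(["category", "term"])

    fit = MultinomFit(
        variable=variable,
        coef=coef,
        curves=pd.DataFrame(),
        converged=converged,
        penalized=penalized,
        loglike=llf,
        n=len(df),
    )
    fit.curves = _probability_curves(fit, params, bse, mu, sd, x, n_curve)
    return fit


def _ridge_mnlogit(z: np.ndarray, y: np.ndarray, alpha: float = 1.0):
    """Ridge-penalized fallback fit (used when the MLE does not converge)."""
    from sklearn.linear_model import LogisticRegression

    lr = LogisticRegression(C=1.0 / alpha, max_iter=1000)
    lr.fit(z[:, None], y)
    # express as contrasts vs the rest (reference) category
    inter = lr.intercept_ - lr.intercept_[0]
    slope = lr.coef_[:, 0] - lr.coef_[0, 0]
    params = np.array([[inter[1], inter[2]], [slope[1], slope[2]]])
    bse = np.full_like(params, np.nan)
    return params, bse, float("nan")


def _probability_curves(fit, params, bse, mu, sd, x_raw, n_curve):
    """P(behaviour | x) over the observed range with delta-method 95% bands."""
    xs = np.linspace(x_raw.min(), x_raw.max(), n_curve)
    proba = fit.predict_proba(xs)
    out = {"x": xs}
    # simulation-based bands from the asymptotic normal of the coefficients
    rng = np.random.default_rng(0)
    if np.all(np.isfinite(bse)):
        draws = 300
        etas = np.zeros((draws, n_curve, 3))
        zs = (xs - mu) / sd
        for j in range(2):
            b = rng.normal(params[0, j], bse[0, j], draws)
            m = rng.normal(params[1, j], bse[1, j], draws)
            etas[:, :, j + 1] = b[:, None] + m[:, None] * zs[None, :]
        ex = np.exp(etas - etas.max(axis=2, keepdims=True))
        ps = ex / ex.sum(axis=2, keepdims=True)
        lo = np.percentile(ps, 2.5, axis=0)
        hi = np.percentile(ps, 97.5, axis=0)
    else:
        lo = hi = np.full((n_curve, 3), np.nan)
    for i, lab in enumerate(LABELS):
        out[f"p_{lab}"] = proba[:, i]
        out[f"p_{lab}_lo"] = lo[:, i]
        out[f"p_{lab}_hi"] = hi[:, i]
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# use vs availability


def sample_points_in_contour(
    contour: OccupancyContour, n: int, seed: int
) -> pd.DataFrame:
    """Uniform points inside the contour polygons by rejection sampling."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not contour.polygons:
        raise ValueError("contour has no polygons")
    rng = np.random.default_rng(seed)
    minx = min(p.bounds[0] for p in contour.polygons)
    miny = min(p.bounds[1] for p in contour.polygons)
    maxx = max(p.bounds[2] for p in contour.polygons)
    maxy = max(p.bounds[3] for p in contour.polygons)
    union = shapely.unary_union(contour.polygons)
    out_lon, out_lat = [], []
    guard = 0
    while len(out_lon) < n:
        m = max(4 * (n - len(out_lon)), 64)
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        inside = shapely.contains_xy(union, xs, ys)
        out_lon.extend(xs[inside])
        out_lat.extend(ys[inside])
        guard += 1
        if guard > 1000:
            raise RuntimeError("rejection sampling failed to fill the contour")
    return pd.DataFrame({"lon": out_lon[:n], "lat": out_lat[:n]})


def use_vs_availability_ks(
    used: pd.DataFrame,
    contour: OccupancyContour,
    raster: EnvRaster,
    n_random: int = 200,
    seed: int = 0,
) -> dict:
    """Two-sample KS test: covariate at used locations vs random availability.

    ``used`` needs ``lat``/``lon`` columns.  Random locations are drawn
    uniformly from the contour; both sets are sampled from the raster and
    compared.  Returns the KS statistic, the p-value and the two value
    arrays.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    rand = sample_points_in_contour(contour, n_random, seed)
    used_vals = sample_raster(raster, used["lat"], used["lon"])
    rand_vals = sample_raster(raster, rand["lat"], rand["lon"])
    used_vals = used_vals[~np.isnan(used_vals)]
    rand_vals = rand_vals[~np.isnan(rand_vals)]
    if len(rand_vals) == 0:
        raise ValueError("raster is fully missing inside the contour")
    if np.array_equal(np.sort(used_vals), np.sort(rand_vals)):
        return {"statistic": 0.0, "p_value": 1.0, "used": used_vals, "random": rand_vals}
    res = ks_2samp(used_vals, rand_vals)
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "used": used_vals,
        "random": rand_vals,
    }
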