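"""Covariate-engineering formulas used upstream of the distribution models.

Covers: Rao's quadratic-entropy heterogeneity index for canopy-height
histograms, the isometric log-ratio transform for compositional canopy
strata, Pearson/GVIF collinearity screening, z-score standardization,
short-series climate extrapolation, Euclidean distance surfaces (rivers,
roads), and the opportunistic-record quality filters.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.ops import unary_union


# --- Rao's Q ----------------------------------------------------------------

def rao_q(values, frequencies) -> float:
    """Rao's quadratic entropy Q = sum_ij d_ij p_i p_j.

    ``values`` are the class values (e.g. integer canopy heights in meters),
    ``frequencies`` their relative frequencies; d_ij is the Euclidean
    (absolute) distance between values.  Q is the expected height difference
    between two pixels drawn with replacement; it is zero iff all values with
    positive frequency coincide.
    """
    v = np.asarray(values, dtype=float)
    p = np.asarray(frequencies, dtype=float)
    if v.shape != p.shape or v.ndim != 1:
        raise ValueError("values and frequencies must be 1-D of equal length")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("frequencies must be non-negative and sum to 1")
    d = np.abs(v[:, None] - v[None, :])
    return float(p @ d @ p)


def rao_q_horizontal(grid_values: np.ndarray, window: int = 3) -> np.ndarray:
    """Moving-window Rao's Q over a 2-D grid of cell values.

    Each output cell is Rao's Q of the ``window``-by-``window`` neighborhood
    (edge-truncated), quantifying local horizontal heterogeneity of, e.g.,
    canopy cover.  The window size is configurable; 3 cells of the 100 m grid
    is the default neighborhood.
    """
    g = np.asarray(grid_values, dtype=float)
    if g.ndim != 2:
        raise ValueError("grid_values must be 2-D")
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    r = window // 2
    out = np.empty_like(g)
    ny, nx = g.shape
    for i in range(ny):
        for j in range(nx):
            patch = g[max(0, i - r):i + r + 1, max(0, j - r):j + r + 1].ravel()
            vals, counts = np.unique(patch, return_counts=True)
            out[i, j] = rao_q(vals, counts / counts.sum())
    return out


# --- isometric log-ratio ----------------------------------------------------

def _helmert_basis(d: int) -> np.ndarray:
    """Orthonormal Helmert-style contrast basis, rows spanning the simplex."""
    V = np.zeros((d - 1, d))
    for i in range(1, d):
        V[i - 1, :i] = 1.0 / i
        V[i - 1, i] = -1.0
        V[i - 1] *= np.sqrt(i / (i + 1.0))
    return V


def ilr_transform(proportions) -> np.ndarray:
    """Isometric log-ratio coordinates (length D-1) of a composition.

    Accepts a 1-D composition or an (n, D) array of compositions; inputs are
    closed (rescaled to sum 1) first, so the transform is invariant to
    rescaling.  Zero or negative parts are rejected — apply a zero-replacement
    (e.g. multiplicative replacement with half the detection limit) upstream.
    """
    x = np.asarray(proportions, dtype=float)
    one = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] < 2:
        raise ValueError("compositions need at least two parts")
    if np.any(x <= 0):
        raise ValueError("compositional parts must be strictly positive; "
                         "apply the configured zero-replacement before "
                         "transforming")
    x = x / x.sum(axis=1, keepdims=True)
    V = _helmert_basis(x.shape[1])
    z = np.log(x) @ V.T
    return z[0] if one else z


def ilr_inverse(coords) -> np.ndarray:
    """Inverse ILR: coordinates back to a closed composition."""
    z = np.asarray(coords, dtype=float)
    one = z.ndim == 1
    z = np.atleast_2d(z)
    V = _helmert_basis(z.shape[1] + 1)
    logx = z @ V
    x = np.exp(logx - logx.max(axis=1, keepdims=True))
    x = x / x.sum(axis=1, keepdims=True)
    return x[0] if one else x


# --- collinearity screening -------------------------------------------------

def gvif(table: pd.DataFrame) -> pd.Series:
    """Generalized variance-inflation factor of each column against the rest.

    Computed from correlation-matrix determinants,
    GVIF_i = det(R_i) det(R_-i) / det(R); for one-degree-of-freedom columns
    this equals the ordinary VIF.
    """
    R = np.corrcoef(table.to_numpy(dtype=float), rowvar=False)
    detR = np.linalg.det(R)
    out = {}
    for k, name in enumerate(table.columns):
        idx = [i for i in range(R.shape[0]) if i != k]
        out[name] = float(np.linalg.det(R[np.ix_(idx, idx)]) / detR)
    return pd.Series(out)


def select_covariates(table: pd.DataFrame, abundance=None, r_max: float = 0.7,
                      gvif_max: float = 5.0):
    """Screen covariates for collinearity.

    Highly correlated pairs (|Pearson r| > ``r_max``) are processed in
    descending |r|; within a pair the covariate with the higher |correlation
    with abundance| is kept when an abundance vector is supplied, else the
    lexicographically first name (deterministic builds).  Covariates are then
    dropped greedily, worst first, until every GVIF <= ``gvif_max``.

    Returns ``(retained_names, diagnostics)``; diagnostics reports dropped
    names with reasons, and the maxima of |r| and GVIF among the retained set.
    """
    if table.shape[1] < 2:
        raise ValueError("need at least two covariates")
    diagnostics = {"dropped": [], "constant": []}
    work = table.copy()
    const = [c for c in work.columns if work[c].std(ddof=0) == 0]
    for c in const:
        diagnostics["constant"].append(c)
        work = work.drop(columns=c)

    def keep_of(a, b):
        if abundance is not None:
            ra = abs(np.corrcoef(work[a], abundance)[0, 1])
            rb = abs(np.corrcoef(work[b], abundance)[0, 1])
            if not np.isclose(ra, rb):
                return (a, b) if ra >= rb else (b, a)
        return (a, b) if a <= b else (b, a)

    while work.shape[1] >= 2:
        R = work.corr().abs()
        np.fill_diagonal(R.values, 0.0)
        r_peak = R.values.max()
        if r_peak <= r_max:
            break
        i, j = np.unravel_index(np.argmax(R.values), R.shape)
        keep, drop = keep_of(R.index[i], R.columns[j])
        diagnostics["dropped"].append(
            {"name": drop, "reason": "pearson", "r": float(r_peak),
             "partner": keep})
        work = work.drop(columns=drop)

    while work.shape[1] >= 2:
        g = gvif(work)
        if g.max() <= gvif_max:
            break
        worst = g.sort_values(ascending=False)
        top = worst.index[0]
        diagnostics["dropped"].append(
            {"name": top, "reason": "gvif", "gvif": float(worst.iloc[0])})
        work = work.drop(columns=top)

    retained = list(work.columns)
    if len(retained) >= 2:
        R = work.corr().abs()
        np.fill_diagonal(R.values, 0.0)
        diagnostics["max_abs_r"] = float(R.values.max())
        diagnostics["max_gvif"] = float(gvif(work).max())
    else:
        diagnostics["max_abs_r"] = 0.0
        diagnostics["max_gvif"] = 1.0
    return retained, diagnostics


# --- standardization --------------------------------------------------------

class CovariateStandardizer:
    """z-score standardization with exact inverse, sklearn-transformer style.

    Fitted attributes ``mean_`` and ``scale_`` (population sd) allow the
    original scale to be recovered; constant columns are rejected.
    """

    def get_params(self, deep=True):
        return {}

    def set_params(self, **params):
        return self

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        sd = X.std(ddof=0)
        bad = sd[sd == 0].index.tolist()
        if bad:
            raise ValueError(f"constant covariate(s) cannot be standardized: "
                             f"{bad}")
        self.mean_ = X.mean()
        self.scale_ = sd
        self.columns_ = list(X.columns)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X)
        return (X[self.columns_] - self.mean_) / self.scale_

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)

    def inverse_transform(self, Z: pd.DataFrame) -> pd.DataFrame:
        Z = pd.DataFrame(Z)
        return Z[self.columns_] * self.scale_ + self.mean_


def standardize(table: pd.DataFrame):
    """Functional wrapper: returns (standardized table, fitted standardizer)."""
    st = CovariateStandardizer().fit(table)
    return st.transform(table), st


# --- climate extrapolation --------------------------------------------------

def extrapolate_climate(annual_series: pd.Series, target_years,
                        method: str = "linear") -> pd.Series:
    """Extend an annual climate series to later years.

    ``linear`` fits an ordinary least-squares line through the observed years
    (the primary approach); ``last_year`` repeats the final observed value and
    ``mean`` the observed-period average (the sensitivity alternatives).
    """
    s = pd.Series(annual_series).astype(float).sort_index()
    years = np.asarray(s.index, dtype=float)
    target_years = np.asarray(list(target_years), dtype=int)
    if method == "linear":
        if len(s) < 2:
            raise ValueError("linear extrapolation needs at least two "
                             "observed years")
        slope, intercept = np.polyfit(years, s.to_numpy(), 1)
        vals = slope * target_years + intercept
    elif method == "last_year":
        vals = np.full(len(target_years), s.iloc[-1])
    elif method == "mean":
        vals = np.full(len(target_years), s.mean())
    else:
        raise ValueError(f"unknown method {method!r}")
    return pd.Series(vals, index=target_years)


# --- distance surfaces ------------------------------------------------------

def distance_surface(features, domain, log: bool = False,
                     log_floor: float | None = None) -> np.ndarray:
    """Per-cell Euclidean distance from cell centroids to the nearest feature.

    ``features`` is an iterable of shapely geometries (watercourses, access
    roads, settlements) in the same projected meters as the domain.  With
    ``log=True`` the distance is floored at ``log_floor`` (default: half the
    cell size, so that on-feature cells do not produce log 0) before taking
    the logarithm.
    """
    feats = list(features) if not hasattr(features, "geom_type") else [features]
    if not feats:
        raise ValueError("at least one feature is required")
    merged = unary_union(feats)
    d = np.array([merged.distance(Point(xy)) for xy in domain.centroids])
    if log:
        eps = domain.cell_size / 2.0 if log_floor is None else log_floor
        d = np.log(np.maximum(d, eps))
    return d


# --- occurrence quality filters ---------------------------------------------

PLACEHOLDER_UNCERTAINTIES = (301.0, 999.0, 3036.0, 9999.0)

_RULES = ("invalid_coordinates", "basis_of_record", "placeholder_uncertainty",
          "coarse_resolution", "uncertainty_above_max")


def filter_occurrences(records: pd.DataFrame, max_uncertainty_m: float = 1000.0,
                       min_resolution_deg: float = 0.01,
                       placeholders=PLACEHOLDER_UNCERTAINTIES):
    """Quality filters for opportunistic occurrence records.

    Rules applied in order; a record rejected by an earlier rule is not
    re-counted by later ones:

    1. valid, finite coordinates present;
    2. fossil or living (cultivated) specimens excluded via basis-of-record;
    3. default/placeholder coordinate uncertainties (301, 999, 3036, 9999 m)
       excluded;
    4. coordinate resolution of 0.01 degrees or coarser excluded;
    5. coordinate uncertainty above 1000 m excluded — records with absent
       uncertainty metadata are retained.

    Returns ``(retained, rejection_counts)``; counts sum to the number of
    rows removed.
    """
    df = records.copy()
    counts = dict.fromkeys(_RULES, 0)
    mask = pd.Series(True, index=df.index)

    lon = pd.to_numeric(df.get("longitude"), errors="coerce")
    lat = pd.to_numeric(df.get("latitude"), errors="coerce")
    ok = lon.notna() & lat.notna()
    counts["invalid_coordinates"] = int((mask & ~ok).sum())
    mask &= ok

    if "basis_of_record" in df:
        basis = df["basis_of_record"].astype(str).str.upper()
        ok = ~basis.isin(["FOSSIL_SPECIMEN", "LIVING_SPECIMEN"])
        counts["basis_of_record"] = int((mask & ~ok).sum())
        mask &= ok

    unc = pd.to_numeric(df.get("coordinate_uncertainty_m"), errors="coerce")
    ok = ~unc.isin(list(placeholders))
    counts["placeholder_uncertainty"] = int((mask & ~ok).sum())
    mask &= ok

    if "coordinate_resolution_deg" in df:
        res = pd.to_numeric(df["coordinate_resolution_deg"], errors="coerce")
        ok = res.isna() | (res < min_resolution_deg)
        counts["coarse_resolution"] = int((mask & ~ok).sum())
        mask &= ok

    ok = unc.isna() | (unc <= max_uncertainty_m)
    counts["uncertainty_above_max"] = int((mask & ~ok).sum())
    mask &= ok

    return df[mask], counts
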