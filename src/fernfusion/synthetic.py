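"""Synthetic study systems with the statistical structure the models assume.

The real monitoring data (annual censuses of three relict fern species in
fixed population polygons, plus a handful of opportunistic presence records)
are restricted-access, so every downstream stage is exercised on synthetic
data generated here: a projected grid domain, smooth spatially correlated
covariates (climate, topography, canopy strata, road/river distances),
latent Gaussian fields drawn from the same SPDE x AR(1) machinery the models
fit, population polygons with missing survey years, overdispersed counts,
and road-biased presence records replicated across years.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString, box

from .covariates import distance_surface
from .domain import GridDomain, generate_domain
from .gmrf import ar1_precision, kronecker_st_precision, sample_gmrf, \
    spde_precision
from .mesh import Mesh, build_mesh, projector
from .observations import COUNT_COLUMNS, ObservationSet, PRESENCE_COLUMNS


# --- covariates -------------------------------------------------------------

@dataclass
class CovariateStack:
    """Per cell-year covariates plus ancillary surfaces."""

    names: list
    X: np.ndarray                  # (n_cells, T, P)
    strata: np.ndarray             # (n_cells, K) canopy-height proportions
    roads: list                    # shapely line features
    log_road_dist: np.ndarray      # (n_cells,)
    domain: GridDomain = None

    def table(self) -> pd.DataFrame:
        """Long-format (cell_id, year, name, value) table."""
        n, T, P = self.X.shape
        recs = []
        for p, name in enumerate(self.names):
            for t, year in enumerate(self.domain.years):
                recs.append(pd.DataFrame({
                    "cell_id": self.domain.cell_ids, "year": year,
                    "name": name, "value": self.X[:, t, p]}))
        return pd.concat(recs, ignore_index=True)


def _grf_on_cells(domain, mesh, A, range_m, sd, rng):
    if sd == 0:
        return np.zeros(domain.n_cells)
    Q = spde_precision(mesh, range_m, sd)
    x = sample_gmrf(Q, 1, rng)[0]
    return np.asarray(A @ x)


def generate_covariates(domain: GridDomain, seed: int, field_params: dict,
                        n_roads: int = 3, mesh: Mesh | None = None
                        ) -> CovariateStack:
    """Simulate a covariate stack over the domain.

    ``field_params`` maps covariate names to dicts with keys ``range`` (m),
    ``sd``, and optional ``trend`` (additive change per year, giving the
    smooth interannual variation of climate series) and ``noise_sd``
    (per-year independent wiggle).  Canopy strata (4 height classes closed to
    sum 1) and a log road-distance surface are always produced.
    """
    for name, fp in field_params.items():
        if fp.get("sd", 1.0) < 0:
            raise ValueError(f"negative variance for covariate {name!r}")
    rng = np.random.default_rng(seed)
    if mesh is None:
        edge = max(min(fp.get("range", 1e9)
                       for fp in field_params.values()) / 3.0,
                   domain.cell_size)
        mesh = build_mesh(domain.boundary, max_edge_inner=edge,
                          max_edge_outer=2 * edge,
                          extension=2 * edge, cutoff=edge / 5.0)
    A = projector(mesh, domain.centroids)
    T = domain.n_years
    names = list(field_params)
    X = np.zeros((domain.n_cells, T, len(names)))
    for p, name in enumerate(names):
        fp = field_params[name]
        base = _grf_on_cells(domain, mesh, A, fp.get("range", 2000.0),
                             fp.get("sd", 1.0), rng)
        trend = fp.get("trend", 0.0)
        noise_sd = fp.get("noise_sd", 0.0)
        for t in range(T):
            wiggle = noise_sd * rng.standard_normal() if noise_sd else 0.0
            X[:, t, p] = base + trend * t + wiggle

    # canopy strata: softmax of three fields -> 4 closed proportions
    logits = np.column_stack([
        _grf_on_cells(domain, mesh, A, 1500.0, 0.8, rng) for _ in range(3)])
    logits = np.column_stack([logits, np.zeros(domain.n_cells)])
    strata = np.exp(logits - logits.max(axis=1, keepdims=True))
    strata = strata / strata.sum(axis=1, keepdims=True)

    # roads: random cross-domain line segments
    xmin, ymin, xmax, ymax = domain.boundary.bounds
    roads = []
    for _ in range(n_roads):
        xs = rng.uniform(xmin, xmax, 2)
        ys = rng.uniform(ymin, ymax, 2)
        roads.append(LineString([(xs[0], ys[0]), (xs[1], ys[1])]))
    log_rd = distance_surface(roads, domain, log=True)
    return CovariateStack(names=names, X=X, strata=strata, roads=roads,
                          log_road_dist=log_rd, domain=domain)


# --- latent truth -----------------------------------------------------------

@dataclass
class SyntheticTruth:
    """Generative parameters and realized fields/intensities."""

    hypers: dict                   # ranges, sds, rhos, psi, svc scales
    beta: np.ndarray
    intercepts: np.ndarray
    u: np.ndarray                  # (T*n,) or zeros
    delta: np.ndarray              # (S, T*n)
    omega: np.ndarray              # (n,)
    svc_scales: np.ndarray
    eta: np.ndarray                # (S, n_cells, T)
    lam: np.ndarray
    domain: GridDomain = None
    mesh: Mesh = None
    covariates: CovariateStack = None
    families: tuple = ("poisson", "negbin", "poisson")
    seed: int | None = None

    def __post_init__(self):
        for key in ("rho_u", "rho_d"):
            if key in self.hypers and not abs(self.hypers[key]) < 1:
                raise ValueError(f"|{key}| must be < 1")
        if self.hypers.get("psi", 1.0) <= 0:
            raise ValueError("psi must be positive")


def simulate_latent_fields(domain: GridDomain, mesh: Mesh, truth_hypers: dict,
                           seed: int, covariates: CovariateStack | None = None,
                           beta=None, intercepts=None,
                           families=("poisson", "negbin", "poisson"),
                           n_species: int = 3) -> SyntheticTruth:
    """Draw the latent fields and intensities of the generative model.

    ``truth_hypers`` may contain: range_u, sd_u, rho_u (shared field);
    range_d, sd_d, rho_d (species fields, one shared triple); range_w, sd_w
    and svc_scales (SVC field; species 2, 3 are exact linear scalings of the
    reference-species field); psi.  A component with sd = 0 is identically
    zero.  Fields with singular precision are rejected.
    """
    rng = np.random.default_rng(seed)
    n, T = mesh.n_nodes, domain.n_years
    A = projector(mesh, domain.centroids)
    S = n_species
    h = truth_hypers

    def st_field(range_m, sd, rho):
        if sd == 0:
            return np.zeros(n * T)
        Qs = spde_precision(mesh, range_m, sd)
        Qt = ar1_precision(T, rho)
        return sample_gmrf(kronecker_st_precision(Qs, Qt), 1, rng)[0]

    u = st_field(h.get("range_u", 5000.0), h.get("sd_u", 0.0),
                 h.get("rho_u", 0.7))
    delta = np.stack([
        st_field(h.get("range_d", 3000.0), h.get("sd_d", 0.0),
                 h.get("rho_d", 0.7)) for _ in range(S)])
    if h.get("sd_w", 0.0) > 0:
        Qw = spde_precision(mesh, h.get("range_w", 3000.0), h["sd_w"])
        omega = sample_gmrf(Qw, 1, rng)[0]
    else:
        omega = np.zeros(n)
    svc_scales = np.asarray(h.get("svc_scales", np.ones(S)), dtype=float)

    P = covariates.X.shape[2] if covariates is not None else 0
    beta = np.zeros(P) if beta is None else np.asarray(beta, float)
    intercepts = (np.zeros(S) if intercepts is None
                  else np.asarray(intercepts, float))

    tcode = domain.years - domain.years.mean()
    eta = np.zeros((S, domain.n_cells, T))
    for j in range(S):
        for t in range(T):
            e = np.full(domain.n_cells, intercepts[j])
            if P:
                e = e + covariates.X[:, t, :] @ beta
            e = e + A @ u[t * n:(t + 1) * n]
            e = e + A @ delta[j, t * n:(t + 1) * n]
            e = e + svc_scales[j] * (A @ omega) * tcode[t]
            eta[j, :, t] = e
    lam = np.exp(eta)
    return SyntheticTruth(hypers=dict(h), beta=beta, intercepts=intercepts,
                          u=u, delta=delta, omega=omega,
                          svc_scales=svc_scales, eta=eta, lam=lam,
                          domain=domain, mesh=mesh, covariates=covariates,
                          families=tuple(families), seed=seed)


# --- observations -----------------------------------------------------------

def _intersect_cells(geom, domain: GridDomain):
    """(cell ids, intersection areas) of a polygon with the grid."""
    xmin, ymin, xmax, ymax = geom.bounds
    cs, (ox, oy) = domain.cell_size, domain.origin
    i0 = max(int((xmin - ox) // cs), 0)
    i1 = min(int((xmax - ox) // cs), domain.nx - 1)
    j0 = max(int((ymin - oy) // cs), 0)
    j1 = min(int((ymax - oy) // cs), domain.ny - 1)
    cells, areas = [], []
    for jj in range(j0, j1 + 1):
        for ii in range(i0, i1 + 1):
            cid = jj * domain.nx + ii
            a = geom.intersection(domain.cell_polygons[cid]).area
            if a > 1e-9:
                cells.append(cid)
                areas.append(a)
    return np.array(cells, dtype=int), np.array(areas)


DEFAULT_POPULATIONS = {
    "counts": (22, 17, 11),                      # populations per species
    "area_ranges_ha": ((0.24, 1.15), (0.34, 1.26), (0.65, 2.6)),
}
DEFAULT_MISSING = {"beta_a": 1.3, "beta_b": 3.3, "min": 0.07, "max": 0.82}
DEFAULT_BIAS = {"n_locations": (24, 13, 10), "b0": 2.0, "b1": 1.0}


def simulate_observations(truth: SyntheticTruth, populations_spec=None,
                          missing_spec=None, bias_spec=None,
                          seed: int = 0, populations=None) -> ObservationSet:
    """Draw the observation layer conditional on the latent truth.

    Counts: for each population polygon, per intersected cell and year, a
    Poisson (or negative binomial for the overdispersed species) draw with
    mean (intersection area) x lambda; survey years are masked per population
    with a missing probability drawn once from a Beta calibrated to the
    observed missing-rate distribution (7-82%, median ~27%).

    Presences: per species, a fixed number of locations sampled
    proportionally to intensity times a logistic accessibility weight
    decreasing in log road distance, then replicated across all years as
    independent records (timeless replication).
    """
    pspec = {**DEFAULT_POPULATIONS, **(populations_spec or {})}
    mspec = {**DEFAULT_MISSING, **(missing_spec or {})}
    bspec = {**DEFAULT_BIAS, **(bias_spec or {})}
    rng = np.random.default_rng(seed)
    domain = truth.domain
    S = truth.lam.shape[0]
    T = domain.n_years

    # population polygons: squares fully inside the domain (or supplied)
    xmin, ymin, xmax, ymax = domain.boundary.bounds
    pop_rows, count_rows = [], []
    if populations is not None:
        pop_list = [(r["population"], int(r["species"]), r["geometry"])
                    for _, r in populations.iterrows()]
    else:
        pop_list = []
        pop_id = 0
        for j in range(S):
            lo, hi = np.asarray(pspec["area_ranges_ha"][j]) * 1e4
            for _ in range(pspec["counts"][j]):
                area = np.exp(rng.uniform(np.log(lo), np.log(hi)))
                side = np.sqrt(area)
                cx = rng.uniform(xmin + side / 2, xmax - side / 2)
                cy = rng.uniform(ymin + side / 2, ymax - side / 2)
                geom = box(cx - side / 2, cy - side / 2,
                           cx + side / 2, cy + side / 2)
                pop_list.append((f"pop_{j}_{pop_id}", j, geom))
                pop_id += 1
    for name, j, geom in pop_list:
        if not domain.boundary.covers(geom):
            raise ValueError("population polygon falls outside the domain")
        pop_rows.append({"population": name, "species": j,
                         "geometry": geom, "area": geom.area})
        cells, areas = _intersect_cells(geom, domain)
        p_miss = np.clip(rng.beta(mspec["beta_a"], mspec["beta_b"]),
                         mspec["min"], mspec["max"])
        miss = rng.random(T) < p_miss
        if miss.all():
            miss[rng.integers(T)] = False  # every population has a census
        for t, year in enumerate(domain.years):
            for cid, a in zip(cells, areas):
                if miss[t]:
                    y = np.nan
                else:
                    mu = a * truth.lam[j, cid, t]
                    if truth.families[j] == "negbin":
                        psi = truth.hypers.get("psi", 1.0)
                        y = (0.0 if mu == 0 else float(
                            rng.negative_binomial(psi, psi / (psi + mu))))
                    else:
                        y = float(rng.poisson(mu))
                count_rows.append({
                    "species": j, "population": name, "cell": int(cid),
                    "year": int(year), "count": y, "area": float(a),
                    "missing": bool(miss[t])})

    counts = pd.DataFrame(count_rows, columns=COUNT_COLUMNS)
    populations = pd.DataFrame(pop_rows)

    # presences: intensity-weighted, road-biased, replicated over years
    cov = truth.covariates
    log_rd = (cov.log_road_dist if cov is not None
              else np.zeros(domain.n_cells))
    pres_rows = []
    t_mid = T // 2
    for j in range(S):
        lam_mid = truth.lam[j, :, t_mid]
        access = 1.0 / (1.0 + np.exp(-(bspec["b0"] - bspec["b1"]
                                       * (log_rd - log_rd.mean()))))
        w = lam_mid * domain.areas * access
        n_loc = bspec["n_locations"][j]
        if w.sum() <= 0 or n_loc == 0:
            continue
        chosen = rng.choice(domain.n_cells, size=min(n_loc, domain.n_cells),
                            replace=False, p=w / w.sum())
        for cid in chosen:
            x, y = domain.centroids[cid]
            for year in domain.years:
                pres_rows.append({"species": j, "cell": int(cid),
                                  "year": int(year), "presence": 1,
                                  "log_road_dist": float(log_rd[cid]),
                                  "x": float(x), "y": float(y)})
    presences = pd.DataFrame(pres_rows, columns=PRESENCE_COLUMNS)
    return ObservationSet(counts=counts, presences=presences,
                          populations=populations,
                          meta={"seed": seed, "families": truth.families})


DEFAULT_TRUTH_HYPERS = {
    "range_u": 5000.0, "sd_u": 0.6, "rho_u": 0.7,
    "range_d": 3000.0, "sd_d": 0.8, "rho_d": 0.7,
    "range_w": 3000.0, "sd_w": 0.0,
    "psi": 0.05,
    "svc_scales": (1.0, 1.0, 1.0),
}
DEFAULT_BETA = (0.4, -0.3, 0.25, -0.2)
DEFAULT_INTERCEPTS = (-6.0, -6.3, -5.7)
DEFAULT_FIELD_PARAMS = {
    "bio01": {"range": 4000.0, "sd": 1.0, "trend": 0.02},
    "bio07": {"range": 4000.0, "sd": 1.0, "trend": 0.01},
    "tpi": {"range": 1500.0, "sd": 1.0},
    "rao_q_vertical": {"range": 1500.0, "sd": 1.0},
}


def make_fixture(seed: int = 0, extent_m: float = 10_000.0,
                 cell_size_m: float = 100.0, n_years: int = 10,
                 truth_hypers: dict | None = None, beta=None,
                 intercepts=None, populations_spec=None, missing_spec=None,
                 bias_spec=None, field_params: dict | None = None,
                 mesh_params: dict | None = None):
    """End-to-end synthetic study system.

    Defaults mirror the study's shape: a 100 m prediction grid, 10 annual
    surveys, 3 species with 22/17/11 population polygons (areas drawn in the
    observed per-species ranges), missing-year rates centered near 27%, and
    47 presence locations (24/13/10) replicated over the years.

    Returns (domain, mesh, covariates, truth, observations).
    """
    rng = np.random.SeedSequence(seed)
    s_dom, s_cov, s_lat, s_obs = [int(s.generate_state(1)[0] % (2 ** 31))
                                  for s in rng.spawn(4)]
    domain = generate_domain(s_dom, extent_m, cell_size_m, n_years)
    mp = {"max_edge_inner": extent_m / 8, "max_edge_outer": extent_m / 4,
          "extension": extent_m / 5, "cutoff": extent_m / 40}
    mp.update(mesh_params or {})
    mesh = build_mesh(domain.boundary, **mp)
    fp = dict(DEFAULT_FIELD_PARAMS if field_params is None else field_params)
    covariates = generate_covariates(domain, s_cov, fp, mesh=mesh)
    hypers = {**DEFAULT_TRUTH_HYPERS, **(truth_hypers or {})}
    beta = np.asarray(DEFAULT_BETA[:len(fp)] if beta is None else beta, float)
    intercepts = np.asarray(DEFAULT_INTERCEPTS if intercepts is None
                            else intercepts, float)
    truth = simulate_latent_fields(domain, mesh, hypers, s_lat,
                                   covariates=covariates, beta=beta,
                                   intercepts=intercepts)
    obs = simulate_observations(truth, populations_spec=populations_spec,
                                missing_spec=missing_spec,
                                bias_spec=bias_spec, seed=s_obs)
    return domain, mesh, covariates, truth, obs
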