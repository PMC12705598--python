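"""Laplace-approximation machinery for the latent Gaussian model.

Fitting alternates two loops.  The inner loop maximizes the latent-field
posterior for fixed hyperparameters with Newton iterations on the sparse
penalized likelihood (the Gaussian approximation at the mode is the latent
posterior surrogate).  The outer loop optimizes the Laplace-approximate log
marginal posterior of the hyperparameters with Nelder-Mead on transformed
(log / arctanh) coordinates.  Hyperparameter uncertainty is summarized by a
Gaussian at the outer mode with finite-difference Hessian; posterior sampling
re-solves the inner problem at each sampled hyperparameter so that both
levels of uncertainty propagate into predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize
from scipy.sparse.linalg import splu

from .configs import ModelConfig
from .gmrf import ar1_precision, kronecker_st_precision, spde_precision
from .likelihood import (DEFAULT_FAMILIES, cloglog_derivs,
                         count_family_derivs, year_codes)
from .mesh import Mesh, projector
from . import priors as pr

_DENSE_LIMIT = 600  # latent dimension below which dense Cholesky is used


@dataclass
class FitOptions:
    max_outer: int = 250
    outer_ftol: float = 1e-3
    inner_tol: float = 1e-6
    inner_max: int = 50
    hess_step: float = 0.05
    n_theta_draws: int = 15
    optimize_hypers: bool = True


# --- hyperparameter bookkeeping --------------------------------------------

@dataclass
class HyperLayout:
    """Names and transforms of the outer-loop parameter vector."""

    names: list = field(default_factory=list)      # natural-scale names
    transforms: list = field(default_factory=list)  # 'log' | 'atanh' | 'id'

    def add(self, name, transform):
        self.names.append(name)
        self.transforms.append(transform)

    def to_natural(self, z):
        out = {}
        for name, tr, v in zip(self.names, self.transforms, z):
            out[name] = float(np.exp(v) if tr == "log"
                              else np.tanh(v) if tr == "atanh" else v)
        return out

    def to_transformed(self, natural: dict):
        z = []
        for name, tr in zip(self.names, self.transforms):
            v = natural[name]
            z.append(np.log(v) if tr == "log"
                     else np.arctanh(v) if tr == "atanh" else v)
        return np.array(z)

    def log_jacobian(self, z):
        """log |d natural / d z| summed over coordinates."""
        out = 0.0
        for tr, v in zip(self.transforms, z):
            if tr == "log":
                out += v
            elif tr == "atanh":
                out += np.log1p(-np.tanh(v) ** 2)
        return out


def build_hyper_layout(config: ModelConfig, n_species: int,
                       tie_species_hypers: bool,
                       families) -> HyperLayout:
    lay = HyperLayout()
    if config.spatial_only_effect:
        lay.add("range_u", "log")
        lay.add("sd_u", "log")
    if config.shared_st_effect:
        lay.add("range_u", "log")
        lay.add("sd_u", "log")
        lay.add("rho_u", "atanh")
    if config.species_st_effects:
        if tie_species_hypers:
            lay.add("range_d", "log")
            lay.add("sd_d", "log")
            lay.add("rho_d", "atanh")
        else:
            for j in range(n_species):
                lay.add(f"range_d{j}", "log")
                lay.add(f"sd_d{j}", "log")
                lay.add(f"rho_d{j}", "atanh")
    if config.svc_effect:
        lay.add("range_w", "log")
        lay.add("sd_w", "log")
        for j in range(1, n_species):
            lay.add(f"alpha_{j}", "id")
    if any(f == "negbin" for f in families[:n_species]):
        lay.add("psi", "log")
    return lay


def default_priors() -> dict:
    """Study-calibrated prior specifications, keyed by component."""
    return {
        "field": pr.matern_field_prior(),
        "svc_field": pr.svc_field_prior(),
        "ar1": pr.ar1_prior(),
        "psi": pr.overdispersion_prior(),
        "fixed": pr.gaussian_fixed_prior(),
        "svc_scale": pr.gaussian_fixed_prior(sd=10.0),
    }


def _prior_median(spec: pr.PCPriorSpec, which: str) -> float:
    c = spec.calibration
    if which == "range":
        lam = -np.log(c["alpha_range"]) * c["range0"]
        return lam / np.log(2.0)
    if which == "sd":
        lam = -np.log(c["alpha_sd"]) / c["sd0"]
        return np.log(2.0) / lam
    raise ValueError(which)


def hyper_prior_logpdf(natural: dict, priors: dict) -> float:
    lp = 0.0
    if "range_u" in natural:
        lp += pr.pc_prior_logdensity(priors["field"],
                                     (natural["range_u"], natural["sd_u"]))
    if "rho_u" in natural:
        lp += pr.pc_prior_logdensity(priors["ar1"], natural["rho_u"])
    for name in natural:
        if name.startswith("range_d"):
            sd_name = "sd_d" + name[len("range_d"):]
            lp += pr.pc_prior_logdensity(priors["field"],
                                         (natural[name], natural[sd_name]))
        elif name.startswith("rho_d"):
            lp += pr.pc_prior_logdensity(priors["ar1"], natural[name])
        elif name.startswith("alpha_"):
            lp += pr.pc_prior_logdensity(priors["svc_scale"], natural[name])
    if "range_w" in natural:
        lp += pr.pc_prior_logdensity(priors["svc_field"],
                                     (natural["range_w"], natural["sd_w"]))
    if "psi" in natural:
        lp += pr.pc_prior_logdensity(priors["psi"], natural["psi"])
    return float(lp)


def initial_hypers(layout: HyperLayout, priors: dict) -> dict:
    """Prior medians (numerical where no closed form is convenient)."""
    out = {}
    for name in layout.names:
        if name.startswith("range_w"):
            out[name] = _prior_median(priors["svc_field"], "range")
        elif name.startswith("sd_w"):
            out[name] = _prior_median(priors["svc_field"], "sd")
        elif name.startswith("range"):
            out[name] = _prior_median(priors["field"], "range")
        elif name.startswith("sd"):
            out[name] = _prior_median(priors["field"], "sd")
        elif name.startswith("rho"):
            out[name] = 0.5  # near the PC-prior median for P(rho>0)=0.9
        elif name.startswith("alpha"):
            out[name] = 0.0
        elif name == "psi":
            out[name] = priors["psi"].calibration.get("psi0", 1.0)
    return out


# --- latent layout and design ----------------------------------------------

@dataclass
class LatentLayout:
    """Block offsets of the latent state vector."""

    blocks: dict            # name -> (offset, size)
    dim: int
    n_nodes: int
    n_years: int
    n_species: int
    n_covariates: int

    def slice(self, name):
        off, size = self.blocks[name]
        return slice(off, off + size)


def build_latent_layout(config: ModelConfig, n_nodes, n_years, n_species,
                        n_covariates) -> LatentLayout:
    blocks, off = {}, 0

    def add(name, size):
        nonlocal off
        blocks[name] = (off, size)
        off += size

    if config.independent_fixed_effects:
        add("beta", n_species * n_covariates)
    else:
        add("beta", n_covariates)
    add("icpt", n_species)
    if config.data_fusion:
        add("theta", n_species)
        add("gamma", 1)
    if config.spatial_only_effect:
        add("u", n_nodes)
    if config.shared_st_effect:
        add("u", n_nodes * n_years)
    if config.species_st_effects:
        for j in range(n_species):
            add(f"delta_{j}", n_nodes * n_years)
    if config.svc_effect:
        add("omega", n_nodes)
    return LatentLayout(blocks=blocks, dim=off, n_nodes=n_nodes,
                        n_years=n_years, n_species=n_species,
                        n_covariates=n_covariates)


class ModelData:
    """Design matrices and response vectors for one dataset + configuration.

    Rows are the fitted observations: non-missing count records first, then
    presence records when the configuration fuses data.  The design is split
    into a hyperparameter-free part and the SVC part (whose species scaling
    coefficients are hyperparameters), recombined per outer evaluation.
    """

    def __init__(self, config: ModelConfig, obs, domain, X, mesh: Mesh,
                 families=DEFAULT_FAMILIES, n_species=None):
        self.config = config
        self.domain = domain
        self.mesh = mesh
        self.families = tuple(families)
        counts = obs.counts
        self.n_species = int(n_species if n_species is not None
                             else counts["species"].max() + 1)
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, None, :].repeat(domain.n_years, axis=1)
        self.X = X  # (n_cells, T, P)
        self.layout = build_latent_layout(
            config, mesh.n_nodes, domain.n_years, self.n_species, X.shape[2])
        self.A_cells = projector(mesh, domain.centroids)
        self.tcode = year_codes(domain.years)

        fit_counts = counts[~counts["missing"]].reset_index(drop=True)
        self.counts = fit_counts
        self.y_count = fit_counts["count"].to_numpy(float)
        self.logarea = np.log(fit_counts["area"].to_numpy(float))
        self.sp_count = fit_counts["species"].to_numpy(int)
        if config.data_fusion:
            if obs.presences is None or not len(obs.presences):
                raise ValueError("configuration fuses data but no presence "
                                 "records were supplied")
            self.presences = obs.presences.reset_index(drop=True)
        else:
            self.presences = None
        self._build_design()

    # -- design assembly --
    def _rows_for(self, species, cells, years_idx, road=None):
        """Triplet lists for a batch of observation rows."""
        lay = self.layout
        cfg = self.config
        n, T = lay.n_nodes, lay.n_years
        A = self.A_cells[cells]  # (m, n) csr
        m = len(species)
        rows_base, cols_base, vals_base = [], [], []
        r_idx = np.arange(m)

        # fixed effects
        P = lay.n_covariates
        Xrows = self.X[cells, years_idx, :]  # (m, P)
        boff = lay.blocks["beta"][0]
        for p in range(P):
            rows_base.append(r_idx)
            if cfg.independent_fixed_effects:
                cols_base.append(boff + species * P + p)
            else:
                cols_base.append(np.full(m, boff + p))
            vals_base.append(Xrows[:, p])
        ioff = lay.blocks["icpt"][0]
        rows_base.append(r_idx)
        cols_base.append(ioff + species)
        vals_base.append(np.ones(m))
        if road is not None:
            toff = lay.blocks["theta"][0]
            rows_base.append(r_idx)
            cols_base.append(toff + species)
            vals_base.append(np.ones(m))
            goff = lay.blocks["gamma"][0]
            rows_base.append(r_idx)
            cols_base.append(np.full(m, goff))
            vals_base.append(np.asarray(road, float))

        Acoo = A.tocoo()
        if "u" in lay.blocks:
            uoff = lay.blocks["u"][0]
            if cfg.spatial_only_effect:
                rows_base.append(Acoo.row)
                cols_base.append(uoff + Acoo.col)
                vals_base.append(Acoo.data)
            else:
                rows_base.append(Acoo.row)
                cols_base.append(uoff + years_idx[Acoo.row] * n + Acoo.col)
                vals_base.append(Acoo.data)
        if cfg.species_st_effects:
            for j in range(self.n_species):
                doff = lay.blocks[f"delta_{j}"][0]
                sel = species[Acoo.row] == j
                rows_base.append(Acoo.row[sel])
                cols_base.append(doff + years_idx[Acoo.row[sel]] * n
                                 + Acoo.col[sel])
                vals_base.append(Acoo.data[sel])

        base = sparse.coo_matrix(
            (np.concatenate(vals_base),
             (np.concatenate(rows_base), np.concatenate(cols_base))),
            shape=(m, lay.dim)).tocsr()

        om = None
        if cfg.svc_effect:
            woff = lay.blocks["omega"][0]
            vals = Acoo.data * self.tcode[years_idx[Acoo.row]]
            om = sparse.coo_matrix((vals, (Acoo.row, woff + Acoo.col)),
                                   shape=(m, lay.dim)).tocsr()
        return base, om

    def _build_design(self):
        c = self.counts
        cells = c["cell"].to_numpy(int)
        yidx = self.domain.year_index(c["year"].to_numpy(int))
        sp = self.sp_count
        base_c, om_c = self._rows_for(sp, cells, yidx)
        parts_base, parts_om = [base_c], [om_c]
        sp_all = [sp]
        if self.presences is not None:
            p = self.presences
            pc = p["cell"].to_numpy(int)
            py = self.domain.year_index(p["year"].to_numpy(int))
            psp = p["species"].to_numpy(int)
            base_p, om_p = self._rows_for(psp, pc, py,
                                          road=p["log_road_dist"].to_numpy())
            parts_base.append(base_p)
            parts_om.append(om_p)
            sp_all.append(psp)
        self.n_count_rows = base_c.shape[0]
        self.A_base = sparse.vstack([b for b in parts_base]).tocsr()
        oms = [o for o in parts_om if o is not None]
        self.A_omega = sparse.vstack(oms).tocsr() if oms else None
        self.row_species = np.concatenate(sp_all)
        self.n_rows = self.A_base.shape[0]

    def design(self, natural: dict):
        """Row design matrix for given hyperparameters (SVC scaling folded in)."""
        if self.A_omega is None:
            return self.A_base
        scales = np.ones(self.n_species)
        for j in range(1, self.n_species):
            scales[j] = natural.get(f"alpha_{j}", 0.0)
        D = sparse.diags(scales[self.row_species])
        return (self.A_base + D @ self.A_omega).tocsr()

    # -- likelihood over rows --
    def row_loglik(self, eta, natural, pointwise=False):
        ll = np.empty(self.n_rows)
        g = np.empty(self.n_rows)
        w = np.empty(self.n_rows)
        nc = self.n_count_rows
        psi = natural.get("psi")
        for j in range(self.n_species):
            m = np.nonzero(self.sp_count == j)[0]
            if len(m) == 0:
                continue
            fam = self.families[j]
            ll[m], g[m], w[m] = count_family_derivs(
                self.y_count[m], eta[m], self.logarea[m], fam, psi)
        if self.presences is not None:
            yb = self.presences["presence"].to_numpy(float)
            ll[nc:], g[nc:], w[nc:] = cloglog_derivs(yb, eta[nc:])
        if pointwise:
            return ll, g, w
        return float(ll.sum()), g, w

    # -- prior precision --
    def prior_precision(self, natural: dict, priors: dict):
        """(Q_prior block-diagonal sparse, analytic log-determinant)."""
        lay = self.layout
        cfg = self.config
        n, T = lay.n_nodes, lay.n_years
        diag_blocks = []
        logdet = 0.0
        sd_fix = priors["fixed"].calibration["sd"]

        def fixed_block(size):
            nonlocal logdet
            q = np.full(size, 1.0 / sd_fix ** 2)
            logdet += size * np.log(1.0 / sd_fix ** 2)
            return sparse.diags(q)

        for name, (off, size) in lay.blocks.items():
            if name in ("beta", "icpt", "theta", "gamma"):
                diag_blocks.append(fixed_block(size))
            elif name == "u":
                Qs = spde_precision(self.mesh, natural["range_u"],
                                    natural["sd_u"])
                lds = _logdet_sparse(Qs)
                if cfg.spatial_only_effect:
                    diag_blocks.append(Qs)
                    logdet += lds
                else:
                    rho = natural["rho_u"]
                    Qt = ar1_precision(T, rho)
                    diag_blocks.append(kronecker_st_precision(Qs, Qt))
                    logdet += T * lds - n * (T - 1) * np.log1p(-rho ** 2)
            elif name.startswith("delta_"):
                j = int(name.split("_")[1])
                rng_ = natural.get("range_d", natural.get(f"range_d{j}"))
                sd_ = natural.get("sd_d", natural.get(f"sd_d{j}"))
                rho = natural.get("rho_d", natural.get(f"rho_d{j}"))
                Qs = spde_precision(self.mesh, rng_, sd_)
                Qt = ar1_precision(T, rho)
                diag_blocks.append(kronecker_st_precision(Qs, Qt))
                logdet += (T * _logdet_sparse(Qs)
                           - n * (T - 1) * np.log1p(-rho ** 2))
            elif name == "omega":
                Qs = spde_precision(self.mesh, natural["range_w"],
                                    natural["sd_w"])
                diag_blocks.append(Qs)
                logdet += _logdet_sparse(Qs)
        Q = sparse.block_diag(diag_blocks, format="csc")
        return Q, float(logdet)


def _logdet_sparse(Q) -> float:
    """Log-determinant of a sparse SPD matrix (dense Cholesky at desk scale)."""
    L = np.linalg.cholesky(Q.toarray())
    return float(2.0 * np.sum(np.log(np.diag(L))))


class _Solver:
    """Factorize Q_post, exposing solve and logdet; dense or sparse LU."""

    def __init__(self, Q):
        self.dim = Q.shape[0]
        if self.dim <= _DENSE_LIMIT:
            self._cf = cho_factor(Q.toarray())
            self._lu = None
            self.logdet = float(2.0 * np.sum(np.log(np.diag(self._cf[0]))))
        else:
            self._lu = splu(Q.tocsc())
            self._cf = None
            self.logdet = float(np.sum(np.log(np.abs(self._lu.U.diagonal()))))

    def solve(self, b):
        if self._cf is not None:
            return cho_solve(self._cf, b)
        return self._lu.solve(b)


def newton_latent(md: ModelData, natural: dict, Q_prior, x0=None,
                  tol=1e-6, max_iter=50):
    """Inner Newton optimization of the latent field given hyperparameters.

    Returns (x_mode, Q_post, solver, loglik_at_mode, n_iter, converged).
    """
    A = md.design(natural)
    x = np.zeros(md.layout.dim) if x0 is None else x0.copy()
    ll, g, w = md.row_loglik(A @ x, natural)
    obj = ll - 0.5 * x @ (Q_prior @ x)
    solver = None
    Q_post = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        grad = A.T @ g - Q_prior @ x
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        W = sparse.diags(np.maximum(w, 1e-12))
        Q_post = (Q_prior + (A.T @ W @ A)).tocsc()
        solver = _Solver(Q_post)
        step = solver.solve(grad)
        # backtracking line search on the penalized likelihood
        t = 1.0
        for _ in range(30):
            x_new = x + t * step
            ll_new, g_new, w_new = md.row_loglik(A @ x_new, natural)
            obj_new = ll_new - 0.5 * x_new @ (Q_prior @ x_new)
            if np.isfinite(obj_new) and obj_new >= obj - 1e-12:
                break
            t *= 0.5
        if abs(obj_new - obj) < 1e-10 * (1 + abs(obj)) and t == 1.0:
            x, ll, g, w, obj = x_new, ll_new, g_new, w_new, obj_new
            converged = True
            break
        x, ll, g, w, obj = x_new, ll_new, g_new, w_new, obj_new
    if solver is None or not converged:
        W = sparse.diags(np.maximum(w, 1e-12))
        Q_post = (Q_prior + (A.T @ W @ A)).tocsc()
        solver = _Solver(Q_post)
        if not converged and it >= max_iter:
            # accept a near-stationary point at a loose gradient tolerance
            converged = np.max(np.abs(A.T @ g - Q_prior @ x)) < 100 * tol
    return x, Q_post, solver, ll, it, converged


def laplace_objective(md: ModelData, z: np.ndarray, hyper_layout: HyperLayout,
                      priors: dict, warm: dict, options: FitOptions):
    """Negative Laplace-approximate log marginal posterior at transformed z."""
    natural = hyper_layout.to_natural(z)
    try:
        Q_prior, logdet_prior = md.prior_precision(natural, priors)
    except (ValueError, OverflowError, np.linalg.LinAlgError):
        return 1e10
    x0 = warm.get("x")
    try:
        x, Q_post, solver, ll, _, conv = newton_latent(
            md, natural, Q_prior, x0=x0, tol=options.inner_tol,
            max_iter=options.inner_max)
    except (ValueError, RuntimeError, np.linalg.LinAlgError):
        return 1e10
    warm["x"] = x
    lp_theta = hyper_prior_logpdf(natural, priors) + hyper_layout.log_jacobian(z)
    log_marg = (lp_theta + 0.5 * logdet_prior - 0.5 * x @ (Q_prior @ x)
                + ll - 0.5 * solver.logdet)
    if not np.isfinite(log_marg):
        return 1e10
    return -float(log_marg)


def fd_hessian(fun, z0, step=0.05):
    """Central finite-difference Hessian."""
    q = len(z0)
    H = np.zeros((q, q))
    f0 = fun(z0)
    for i in range(q):
        ei = np.zeros(q); ei[i] = step
        fpp = fun(z0 + ei); fmm = fun(z0 - ei)
        H[i, i] = (fpp - 2 * f0 + fmm) / step ** 2
        for j in range(i + 1, q):
            ej = np.zeros(q); ej[j] = step
            fpq = fun(z0 + ei + ej)
            fmq = fun(z0 - ei + ej)
            fqm = fun(z0 + ei - ej)
            fmn = fun(z0 - ei - ej)
            H[i, j] = H[j, i] = (fpq - fmq - fqm + fmn) / (4 * step ** 2)
    return H


def make_pd(H, floor=1e-6):
    """Symmetrize and clip eigenvalues so the matrix is positive definite."""
    Hs = 0.5 * (H + H.T)
    vals, vecs = np.linalg.eigh(Hs)
    vals = np.maximum(vals, floor)
    return vecs @ np.diag(vals) @ vecs.T
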