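"""The integrated species distribution model estimator.

``IntegratedSDM`` is a scikit-learn-style estimator: construct with the model
configuration and options, call :meth:`fit` with an observation set, then
draw posterior samples, predict intensity surfaces, and map net change.
Module-level functions (:func:`fit`, :func:`sample_posterior`,
:func:`predict_intensity`, :func:`change_map`) are thin wrappers.
"""

from __future__ import annotations

import inspect
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.linalg import cholesky, solve_triangular
from scipy.optimize import minimize

from .configs import ModelConfig, get_config
from .inference import (FitOptions, HyperLayout, ModelData, _Solver,
                        build_hyper_layout, default_priors, fd_hessian,
                        hyper_prior_logpdf, initial_hypers, laplace_objective,
                        make_pd, newton_latent)
from .likelihood import DEFAULT_FAMILIES
from .mesh import Mesh, build_mesh, projector


@dataclass
class PosteriorResult:
    """Laplace fit: latent mode, Gaussian approximation, hyper summary."""

    config: ModelConfig
    model_data: ModelData
    hyper_layout: HyperLayout
    priors: dict
    theta_z: np.ndarray            # transformed hyperparameter mode
    theta: dict                    # natural-scale hyperparameter mode
    theta_cov_z: np.ndarray        # Gaussian covariance on transformed scale
    latent_mode: np.ndarray
    Q_post: sparse.spmatrix
    loglik_mode: float
    log_marginal: float
    converged: bool
    trace: dict = field(default_factory=dict)
    options: FitOptions = field(default_factory=FitOptions)
    seed: int | None = None


@dataclass
class PredictionSurface:
    """Per species-cell-year posterior summaries of eta and lambda."""

    species: np.ndarray
    cell: np.ndarray
    year: np.ndarray
    summaries: pd.DataFrame   # columns eta_mean, eta_sd, eta_q..., lambda_...


@dataclass
class ChangeMap:
    """Posterior of the per-cell log-intensity difference between two years."""

    species: int
    year_a: int
    year_b: int
    cell: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    significant: np.ndarray
    level: float = 0.95


class IntegratedSDM:
    """Joint count + presence species distribution model with GMRF fields.

    Parameters
    ----------
    model : str | ModelConfig
        One of the 22 catalogued structures ("M1".."M22") or an explicit
        configuration.
    families : tuple of str
        Count observation family per species ("poisson" / "negbin").
    priors : dict | None
        Prior specifications (see ``inference.default_priors``).
    tie_species_hypers : bool
        Share one (range, sd, rho) triple across the species-specific
        spatio-temporal fields (desk-scale default) instead of estimating
        one triple per species.
    mesh_params : dict | None
        Arguments to ``build_mesh`` when no mesh is supplied to ``fit``.
    max_outer, outer_ftol, inner_tol, inner_max, hess_step, n_theta_draws,
    optimize_hypers : see ``inference.FitOptions``.
    """

    def __init__(self, model="M21", families=DEFAULT_FAMILIES, priors=None,
                 tie_species_hypers=True, mesh_params=None, max_outer=250,
                 outer_ftol=1e-3, inner_tol=1e-6, inner_max=50,
                 hess_step=0.05, n_theta_draws=15, optimize_hypers=True,
                 seed=0):
        self.model = model
        self.families = families
        self.priors = priors
        self.tie_species_hypers = tie_species_hypers
        self.mesh_params = mesh_params
        self.max_outer = max_outer
        self.outer_ftol = outer_ftol
        self.inner_tol = inner_tol
        self.inner_max = inner_max
        self.hess_step = hess_step
        self.n_theta_draws = n_theta_draws
        self.optimize_hypers = optimize_hypers
        self.seed = seed

    # -- sklearn plumbing --
    @classmethod
    def _param_names(cls):
        sig = inspect.signature(cls.__init__)
        return [p for p in sig.parameters if p != "self"]

    def get_params(self, deep=True):
        return {name: getattr(self, name) for name in self._param_names()}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self._param_names():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def _options(self) -> FitOptions:
        return FitOptions(max_outer=self.max_outer, outer_ftol=self.outer_ftol,
                          inner_tol=self.inner_tol, inner_max=self.inner_max,
                          hess_step=self.hess_step,
                          n_theta_draws=self.n_theta_draws,
                          optimize_hypers=self.optimize_hypers)

    # -- fitting --
    def fit(self, obs, domain, X, mesh: Mesh | None = None,
            theta_init: dict | None = None, fixed_hypers: dict | None = None):
        """Fit the configured model to an observation set.

        Parameters
        ----------
        obs : ObservationSet
        domain : GridDomain
        X : array (n_cells, P) or (n_cells, T, P) of standardized covariates.
        mesh : optional prebuilt mesh; otherwise built from the domain
            boundary with ``mesh_params``.
        theta_init : optional natural-scale starting hyperparameters.
        fixed_hypers : natural-scale hyperparameters to hold fixed (skips the
            outer optimization entirely when it covers all of them).
        """
        config = (self.model if isinstance(self.model, ModelConfig)
                  else get_config(self.model))
        priors = self.priors if self.priors is not None else default_priors()
        options = self._options()
        if mesh is None:
            mp = dict(self.mesh_params or {})
            mesh = build_mesh(domain.boundary, **mp)
        md = ModelData(config, obs, domain, X, mesh, families=self.families)
        hyper_layout = build_hyper_layout(config, md.n_species,
                                          self.tie_species_hypers,
                                          self.families)

        natural0 = initial_hypers(hyper_layout, priors)
        if theta_init:
            natural0.update(theta_init)
        if fixed_hypers:
            natural0.update(fixed_hypers)
        z0 = (hyper_layout.to_transformed(natural0)
              if hyper_layout.names else np.zeros(0))
        warm: dict = {}
        trace: dict = {"objective": []}

        def objective(z):
            val = laplace_objective(md, z, hyper_layout, priors, warm, options)
            trace["objective"].append(float(val))
            return val

        skip_outer = (not hyper_layout.names or not options.optimize_hypers
                      or (fixed_hypers is not None
                          and set(fixed_hypers) >= set(hyper_layout.names)))
        if skip_outer:
            z_hat = z0
            f_hat = objective(z0)
            outer_converged = True
        else:
            # explicit initial simplex: Nelder-Mead's default barely perturbs
            # zero coordinates, stalling e.g. log-psi started at 0
            simplex = np.vstack([z0] + [z0 + 0.5 * np.eye(len(z0))[i]
                                        for i in range(len(z0))])
            res = minimize(objective, z0, method="Nelder-Mead",
                           options={"maxiter": options.max_outer,
                                    "fatol": options.outer_ftol,
                                    "xatol": 1e-3,
                                    "initial_simplex": simplex})
            z_hat, f_hat = res.x, res.fun
            outer_converged = bool(res.success or res.status == 2)

        natural = hyper_layout.to_natural(z_hat)
        if fixed_hypers:
            natural.update(fixed_hypers)
        Q_prior, logdet_prior = md.prior_precision(natural, priors)
        x_mode, Q_post, solver, ll_mode, n_it, inner_conv = newton_latent(
            md, natural, Q_prior, x0=warm.get("x"), tol=options.inner_tol,
            max_iter=options.inner_max)

        q = len(hyper_layout.names)
        if q and not skip_outer:
            H = fd_hessian(objective, z_hat, step=options.hess_step)
            cov_z = np.linalg.inv(make_pd(H))
        else:
            cov_z = np.zeros((q, q))

        self.result_ = PosteriorResult(
            config=config, model_data=md, hyper_layout=hyper_layout,
            priors=priors, theta_z=np.asarray(z_hat), theta=natural,
            theta_cov_z=cov_z, latent_mode=x_mode, Q_post=Q_post,
            loglik_mode=float(ll_mode), log_marginal=-float(f_hat),
            converged=bool(outer_converged and inner_conv),
            trace=trace, options=options, seed=self.seed)
        self.theta_ = natural
        self.latent_mode_ = x_mode
        self.converged_ = self.result_.converged
        self.mesh_ = mesh
        self.domain_ = domain
        return self

    def sample(self, n_samples: int, seed: int | None = None):
        return sample_posterior(self.result_, n_samples,
                                seed if seed is not None else self.seed)

    def predict_intensity(self, years=None, n_samples=200, seed=None,
                          samples=None):
        return predict_intensity(self.result_, self.domain_, years,
                                 n_samples=n_samples,
                                 seed=seed if seed is not None else self.seed,
                                 samples=samples)


# --- posterior sampling -----------------------------------------------------

def sample_posterior(result: PosteriorResult, n_samples: int,
                     seed: int | None = 0):
    """Joint samples of hyperparameters and the latent field.

    Hyperparameters are drawn from the Gaussian approximation at the outer
    mode (on the transformed scale); for each distinct hyperparameter draw
    the latent Gaussian approximation is re-solved and latent draws are taken
    from it, so hyperparameter uncertainty propagates into the field.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    rng = np.random.default_rng(seed)
    md = result.model_data
    q = len(result.hyper_layout.names)
    opts = result.options
    has_hyper_var = q and np.any(np.diag(result.theta_cov_z) > 0)
    n_theta = max(1, min(opts.n_theta_draws, n_samples)) if has_hyper_var else 1
    if has_hyper_var:
        Lz = np.linalg.cholesky(make_pd(result.theta_cov_z, floor=1e-12))
        zs = result.theta_z[None, :] + rng.standard_normal((n_theta, q)) @ Lz.T
        # weakly identified directions can produce absurd draws; keep the
        # transformed coordinates within a wide but finite box
        zs = np.clip(zs, result.theta_z - 12.0, result.theta_z + 12.0)
    else:
        zs = np.tile(result.theta_z, (n_theta, 1)) if q else np.zeros((n_theta, 0))
    counts = np.full(n_theta, n_samples // n_theta)
    counts[: n_samples % n_theta] += 1

    latent = np.empty((n_samples, md.layout.dim))
    thetas = []
    pos = 0
    for k in range(n_theta):
        natural = result.hyper_layout.to_natural(zs[k])
        try:
            Q_prior, _ = md.prior_precision(natural, result.priors)
            x_k, Q_k, _, _, _, _ = newton_latent(
                md, natural, Q_prior, x0=result.latent_mode,
                tol=result.options.inner_tol, max_iter=20)
            U = cholesky(Q_k.toarray(), lower=False)
        except (ValueError, OverflowError, RuntimeError,
                np.linalg.LinAlgError):
            # numerically extreme hyperparameter draw: fall back to the mode
            natural = dict(result.theta)
            x_k, Q_k = result.latent_mode, result.Q_post
            U = cholesky(Q_k.toarray(), lower=False)
        z = rng.standard_normal((md.layout.dim, counts[k]))
        draws = solve_triangular(U, z, lower=False).T + x_k
        latent[pos:pos + counts[k]] = draws
        thetas.extend([natural] * counts[k])
        pos += counts[k]
    theta_df = pd.DataFrame(thetas) if thetas and thetas[0] else pd.DataFrame(
        index=range(n_samples))
    return {"latent": latent, "theta": theta_df, "layout": md.layout,
            "result": result}


# --- prediction -------------------------------------------------------------

def _eta_samples_at(result, samples, species, cells, years_idx, road=None):
    """Latent-predictor samples at arbitrary (species, cell, year) rows."""
    md = result.model_data
    base, om = md._rows_for(np.asarray(species, int), np.asarray(cells, int),
                            np.asarray(years_idx, int), road=road)
    latent = samples["latent"]
    eta = np.asarray((base @ latent.T))
    if om is not None:
        theta = samples["theta"]
        scales = np.ones((md.n_species, latent.shape[0]))
        for j in range(1, md.n_species):
            col = f"alpha_{j}"
            if col in theta:
                scales[j] = theta[col].to_numpy()
        sp = np.asarray(species, int)
        eta = eta + np.asarray(om @ latent.T) * scales[sp]
    return eta  # (n_rows, n_samples)


_QUANTS = (0.025, 0.25, 0.75, 0.975)


def predict_intensity(result: PosteriorResult, domain, years=None,
                      n_samples: int = 200, seed: int | None = 0,
                      samples=None, allow_extrapolation=False) -> PredictionSurface:
    """Posterior summaries of log-intensity and intensity per cell-year."""
    if years is None:
        years = domain.years
    years = np.atleast_1d(np.asarray(years, int))
    out_of_range = (years < domain.years[0]) | (years > domain.years[-1])
    if np.any(out_of_range) and not allow_extrapolation:
        raise ValueError(f"years {years[out_of_range]} outside the fitted "
                         "range; extrapolation must be enabled explicitly "
                         "and supplied with extrapolated covariates")
    if samples is None:
        samples = sample_posterior(result, n_samples, seed)
    md = result.model_data
    rows = []
    for j in range(md.n_species):
        for y in years:
            t = int(domain.year_index(y))
            cells = domain.cell_ids
            eta = _eta_samples_at(result, samples,
                                  np.full(len(cells), j), cells,
                                  np.full(len(cells), t))
            qs = np.quantile(eta, _QUANTS, axis=1)
            lam = np.exp(eta)
            lam_qs = np.quantile(lam, _QUANTS, axis=1)
            df = pd.DataFrame({
                "species": j, "cell": cells, "year": y,
                "eta_mean": eta.mean(axis=1), "eta_sd": eta.std(axis=1),
                "lambda_mean": lam.mean(axis=1), "lambda_sd": lam.std(axis=1)})
            for q, row, lrow in zip(_QUANTS, qs, lam_qs):
                df[f"eta_q{q}"] = row
                df[f"lambda_q{q}"] = lrow
            rows.append(df)
    summ = pd.concat(rows, ignore_index=True)
    return PredictionSurface(species=summ["species"].to_numpy(),
                             cell=summ["cell"].to_numpy(),
                             year=summ["year"].to_numpy(), summaries=summ)


def change_map(result: PosteriorResult, domain, species: int, year_a: int,
               year_b: int, n_samples: int = 200, seed: int | None = 0,
               level: float = 0.95, samples=None) -> ChangeMap:
    """Posterior of eta(., year_b) - eta(., year_a) with significance mask.

    A cell is flagged significant when the central credible interval at
    ``level`` excludes zero.
    """
    if samples is None:
        samples = sample_posterior(result, n_samples, seed)
    ta = int(domain.year_index(year_a))
    tb = int(domain.year_index(year_b))
    cells = domain.cell_ids
    sp = np.full(len(cells), species)
    eta_a = _eta_samples_at(result, samples, sp, cells,
                            np.full(len(cells), ta))
    eta_b = _eta_samples_at(result, samples, sp, cells,
                            np.full(len(cells), tb))
    diff = eta_b - eta_a
    alpha = (1.0 - level) / 2.0
    lower = np.quantile(diff, alpha, axis=1)
    upper = np.quantile(diff, 1.0 - alpha, axis=1)
    mean = diff.mean(axis=1)
    sig = (lower > 0) | (upper < 0)
    return ChangeMap(species=species, year_a=year_a, year_b=year_b,
                     cell=cells, mean=mean, lower=lower, upper=upper,
                     significant=sig, level=level)


def fit(config, obs, domain, X, mesh=None, **estimator_kwargs) -> PosteriorResult:
    """Functional wrapper over :class:`IntegratedSDM`."""
    est = IntegratedSDM(model=config, **estimator_kwargs)
    est.fit(obs, domain, X, mesh=mesh)
    return est.result_
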