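"""Observation likelihoods and the latent predictor of the joint model.

The latent log-intensity for species j at cell s and year t is

    eta_j(s,t) = sum_i beta_i X_i(s,t) + u(s,t) + delta_j(s,t)
                 + omega_j(s) * T(s,t)

with u a shared separable spatio-temporal field, delta_j species-specific
fields, and omega_j = alpha_j * omega a spatially varying year-trend
coefficient shared across species up to linear scaling (alpha fixed to 1 for
the reference species).  T(s,t) is the integer year centered at the series
midpoint.

Counts are Poisson (negative binomial for the overdispersed species) with
mean |a_s| * exp(eta); presences are Bernoulli with the complementary
log-log link, p = 1 - exp(-exp(eta_total)), where eta_total adds a
species-specific intercept and the road-distance observational covariate.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import sparse
from scipy.special import expit, gammaln

from .configs import ModelConfig

_CLOGLOG_A_MAX = 50.0
_CLOGLOG_A_MIN = 1e-12


# --- pointwise log-likelihoods and their eta-derivatives --------------------

def poisson_logpmf(y, log_mu):
    y = np.asarray(y, dtype=float)
    log_mu = np.asarray(log_mu, dtype=float)
    ylogmu = np.where(y > 0, y * log_mu, 0.0)
    with np.errstate(over="ignore"):
        return ylogmu - np.exp(log_mu) - gammaln(y + 1.0)


def negbin_logpmf(y, log_mu, psi):
    """Negative binomial with mean mu and variance mu + mu^2/psi."""
    y = np.asarray(y, dtype=float)
    log_mu = np.asarray(log_mu, dtype=float)
    log_psi_mu = np.logaddexp(np.log(psi), log_mu)
    ylog = np.where(y > 0, y * (log_mu - log_psi_mu), 0.0)
    return (gammaln(y + psi) - gammaln(psi) - gammaln(y + 1.0)
            + psi * (np.log(psi) - log_psi_mu) + ylog)


def cloglog_logpmf(y, eta_total):
    """Bernoulli log-pmf under p = 1 - exp(-exp(eta_total)).

    The implied intensity a = exp(eta_total) is clamped to keep p strictly
    inside (0, 1); clamping at the documented bounds logs a warning.
    """
    y = np.asarray(y, dtype=float)
    a = np.exp(np.asarray(eta_total, dtype=float))
    if np.any(a > _CLOGLOG_A_MAX) or np.any((a < _CLOGLOG_A_MIN) & (y > 0)):
        warnings.warn("cloglog probabilities clamped away from {0,1}",
                      RuntimeWarning, stacklevel=2)
    a = np.clip(a, _CLOGLOG_A_MIN, _CLOGLOG_A_MAX)
    log_p = np.log(-np.expm1(-a))
    return np.where(y > 0, log_p, -a)


def count_family_derivs(y, eta, log_area, family, psi=None):
    """(loglik, gradient, curvature) of a count observation w.r.t. eta.

    ``curvature`` is the negated second derivative (the IRLS weight, >= 0).
    """
    log_mu = log_area + eta
    if family == "poisson":
        mu = np.exp(np.minimum(log_mu, 700.0))
        return poisson_logpmf(y, log_mu), y - mu, mu
    if family == "negbin":
        ll = negbin_logpmf(y, log_mu, psi)
        r = expit(log_mu - np.log(psi))  # mu / (psi + mu), overflow-safe
        g = y - (y + psi) * r
        w = (y + psi) * r * (1.0 - r)
        return ll, g, w
    raise ValueError(f"unknown count family {family!r}")


def cloglog_derivs(y, eta_total):
    """(loglik, gradient, curvature) of a cloglog Bernoulli w.r.t. eta."""
    y = np.asarray(y, dtype=float)
    a = np.clip(np.exp(np.asarray(eta_total, dtype=float)),
                _CLOGLOG_A_MIN, _CLOGLOG_A_MAX)
    s = np.exp(-a)
    p = -np.expm1(-a)
    ll = np.where(y > 0, np.log(p), -a)
    g1 = a * s / p
    g = np.where(y > 0, g1, -a)
    w = np.where(y > 0, g1 * (a / p - 1.0), a)
    return ll, g, np.maximum(w, 0.0)


# --- predictor assembly (reference implementation) --------------------------

def year_codes(years) -> np.ndarray:
    """Integer years centered at the series midpoint (the SVC trend code)."""
    years = np.asarray(years, dtype=float)
    return years - years.mean()


def assemble_predictor(config: ModelConfig, state: dict, X: np.ndarray,
                       A: sparse.spmatrix, years) -> np.ndarray:
    """Dense reference evaluation of eta for every (species, cell, year).

    Parameters
    ----------
    state : dict
        ``beta`` — (P,) shared or (S, P) independent coefficients;
        ``intercepts`` — (S,) species count intercepts;
        ``u`` — shared field on mesh nodes, (n,) spatial-only or (T*n,)
        spatio-temporal (time-major); ``delta`` — (S, T*n); ``omega`` — (n,);
        ``svc_scales`` — (S,) with the reference species fixed at 1.
        Missing/inactive entries may be omitted.
    X : (n_cells, P) covariate matrix (time-constant here; time-varying
        covariates enter through the fitting design directly).
    A : (n_cells, n_nodes) projector from mesh nodes to cell centroids.

    Returns eta with shape (S, n_cells, T); inactive components contribute 0.
    """
    n_cells = A.shape[0]
    T = len(years)
    S = len(state.get("intercepts", np.zeros(1)))
    tcode = year_codes(years)
    n_nodes = A.shape[1]
    eta = np.zeros((S, n_cells, T))

    beta = np.asarray(state.get("beta", np.zeros(X.shape[1])))
    for j in range(S):
        b = beta[j] if (config.independent_fixed_effects and beta.ndim == 2) \
            else beta
        fixed = X @ np.asarray(b)
        eta[j] += fixed[:, None]
        icpt = np.asarray(state.get("intercepts", np.zeros(S)))[j]
        eta[j] += icpt

    if config.spatial_only_effect and "u" in state:
        eta += (A @ np.asarray(state["u"]))[None, :, None]
    if config.shared_st_effect and "u" in state:
        u = np.asarray(state["u"]).reshape(T, n_nodes)
        eta += (A @ u.T)[None, :, :]
    if config.species_st_effects and "delta" in state:
        delta = np.asarray(state["delta"])
        for j in range(S):
            dj = delta[j].reshape(T, n_nodes)
            eta[j] += A @ dj.T
    if config.svc_effect and "omega" in state:
        w = A @ np.asarray(state["omega"])
        scales = np.asarray(state.get("svc_scales", np.ones(S)))
        for j in range(S):
            eta[j] += scales[j] * np.outer(w, tcode)
    return eta


# --- likelihood terms -------------------------------------------------------

DEFAULT_FAMILIES = ("poisson", "negbin", "poisson")


def loglik_counts(counts, eta_obs, psi, families=DEFAULT_FAMILIES,
                  pointwise=False):
    """Count-data log-likelihood.

    ``counts`` is the observation table (missing rows contribute zero and may
    be included); ``eta_obs`` the latent log-intensity aligned row-wise.
    """
    y = counts["count"].to_numpy(dtype=float)
    keep = ~counts["missing"].to_numpy(dtype=bool)
    if np.any(y[keep] < 0):
        raise ValueError("counts must be non-negative")
    sp = counts["species"].to_numpy(dtype=int)
    log_area = np.log(counts["area"].to_numpy(dtype=float))
    eta_obs = np.asarray(eta_obs, dtype=float)
    ll = np.zeros(len(y))
    for j in np.unique(sp):
        m = keep & (sp == j)
        if not m.any():
            continue
        fam = families[j]
        if fam == "poisson":
            ll[m] = poisson_logpmf(y[m], log_area[m] + eta_obs[m])
        else:
            ll[m] = negbin_logpmf(y[m], log_area[m] + eta_obs[m], psi)
    return ll if pointwise else float(ll.sum())


def loglik_presence(presences, eta_total, pointwise=False):
    """Bernoulli-cloglog log-likelihood of the presence records.

    ``eta_total`` must already include the species presence intercept and the
    road-distance observational term.
    """
    y = presences["presence"].to_numpy(dtype=float)
    ll = cloglog_logpmf(y, eta_total)
    return ll if pointwise else float(ll.sum())


def gmrf_logpdf(x, Q) -> float:
    """Log density of x ~ N(0, Q^{-1}) for sparse positive-definite Q."""
    x = np.asarray(x, dtype=float)
    Qd = Q.toarray() if sparse.issparse(Q) else np.asarray(Q)
    L = np.linalg.cholesky(Qd)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return float(0.5 * logdet - 0.5 * x @ (Qd @ x)
                 - 0.5 * len(x) * np.log(2.0 * np.pi))


def joint_loglik(config: ModelConfig, components: dict) -> dict:
    """Additive assembly of the joint model log-density.

    ``components`` maps term names ("counts", "presence", latent GMRF terms,
    prior terms) to scalars; the presence term is included only under data
    fusion — supplying one without fusion triggers a warning and is ignored.
    Returns the components actually used plus their "total".
    """
    used = dict(components)
    if not config.data_fusion and "presence" in used:
        warnings.warn("presence likelihood supplied but the configuration "
                      "does not fuse data; ignoring it", RuntimeWarning,
                      stacklevel=2)
        used.pop("presence")
    used["total"] = float(sum(used.values()))
    return used
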