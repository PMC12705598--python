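"""Model comparison and predictive diagnostics.

* Leave-population-out cross-validation (LPOCV): each fold removes every
  count observation of one population (their cells share redistributed
  individuals, so leaving out single observations would leak information),
  refits, and scores the held-out observations by their posterior predictive
  density; the log-score is the mean log density over observations.
* WAIC from pointwise posterior log-likelihood samples.
* Coverage/amplitude/MAE report: percentage of observations inside central
  posterior intervals of the intensity (pPCPI-I at 75/95%) and of the
  posterior predictive counts (pPCPI-PPD at 95%), interval amplitudes
  (overall and for missing survey years), and the mean absolute error of the
  posterior-mean intensity.
* A buffer-radius spatial-redundancy diagnostic between two point sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import logsumexp

from .likelihood import negbin_logpmf, poisson_logpmf, cloglog_logpmf
from .model import IntegratedSDM, PosteriorResult, sample_posterior, \
    _eta_samples_at
from .observations import ObservationSet


@dataclass
class EvaluationReport:
    model_id: str
    log_score: float | None = None
    waic: float | None = None
    p_waic: float | None = None
    per_species: pd.DataFrame = None
    extras: dict = field(default_factory=dict)


# --- pointwise likelihood over fitted rows ----------------------------------

def _pointwise_loglik(result: PosteriorResult, samples) -> np.ndarray:
    """(n_samples, n_rows) log-likelihood of every fitted observation row."""
    md = result.model_data
    latent = samples["latent"]
    theta = samples["theta"]
    eta = np.asarray(md.A_base @ latent.T)
    if md.A_omega is not None:
        scales = np.ones((md.n_species, latent.shape[0]))
        for j in range(1, md.n_species):
            col = f"alpha_{j}"
            if col in theta:
                scales[j] = theta[col].to_numpy()
        eta = eta + np.asarray(md.A_omega @ latent.T) * scales[md.row_species]
    n_s = latent.shape[0]
    ll = np.empty((n_s, md.n_rows))
    psi = (theta["psi"].to_numpy() if "psi" in theta
           else np.full(n_s, np.nan))
    nc = md.n_count_rows
    for j in range(md.n_species):
        m = np.nonzero(md.sp_count == j)[0]
        if len(m) == 0:
            continue
        log_mu = md.logarea[m][None, :] + eta[m].T
        if md.families[j] == "poisson":
            ll[:, m] = poisson_logpmf(md.y_count[m][None, :], log_mu)
        else:
            ll[:, m] = negbin_logpmf(md.y_count[m][None, :], log_mu,
                                     psi[:, None])
    if md.presences is not None:
        yb = md.presences["presence"].to_numpy(float)
        ll[:, nc:] = cloglog_logpmf(yb[None, :], eta[nc:].T)
    return ll


def waic(result: PosteriorResult, n_samples: int = 400, seed: int = 0,
         samples=None):
    """Watanabe-Akaike information criterion.

    WAIC = -2 (lppd - p_waic); lppd sums the log posterior-mean pointwise
    likelihoods, p_waic the pointwise posterior variances of the
    log-likelihood.  Returns (waic, p_waic, lppd).
    """
    if samples is None:
        if n_samples < 2:
            raise ValueError("WAIC needs at least two posterior samples")
        samples = sample_posterior(result, n_samples, seed)
    ll = _pointwise_loglik(result, samples)
    if ll.shape[0] < 2:
        raise ValueError("WAIC needs at least two posterior samples")
    lppd = float(np.sum(logsumexp(ll, axis=0) - np.log(ll.shape[0])))
    p_w = float(np.sum(ll.var(axis=0, ddof=1)))
    return -2.0 * (lppd - p_w), p_w, lppd


# --- LPOCV ------------------------------------------------------------------

def _count_ppd_logdens(result, samples, rows: pd.DataFrame) -> np.ndarray:
    """Rao-Blackwellized log PPD density of count rows (one per row)."""
    md = result.model_data
    yidx = md.domain.year_index(rows["year"].to_numpy(int))
    eta = _eta_samples_at(result, samples, rows["species"].to_numpy(int),
                          rows["cell"].to_numpy(int), yidx)
    log_mu = np.log(rows["area"].to_numpy(float))[:, None] + eta
    y = rows["count"].to_numpy(float)
    theta = samples["theta"]
    n_s = eta.shape[1]
    psi = theta["psi"].to_numpy() if "psi" in theta else np.full(n_s, np.nan)
    out = np.empty(len(rows))
    sp = rows["species"].to_numpy(int)
    for i in range(len(rows)):
        if md.families[sp[i]] == "poisson":
            lp = poisson_logpmf(y[i], log_mu[i])
        else:
            lp = negbin_logpmf(y[i], log_mu[i], psi)
        out[i] = logsumexp(lp) - np.log(n_s)
    return out


def _fold_seed(root: int, population) -> int:
    import hashlib
    h = hashlib.sha256(f"{root}:{population}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def lpocv_logscore(estimator: IntegratedSDM, obs: ObservationSet, domain, X,
                   mesh=None, n_samples: int = 200, seed: int = 0,
                   freeze_hyperparameters: bool = False,
                   holdout_populations=None):
    """Leave-population-out cross-validated log-score.

    For each population, all its count observations are removed, the model
    is refit on the remainder (presence records are never held out), and the
    held-out observations are scored under their posterior predictive
    distribution.  Returns (log_score, per_observation DataFrame).

    ``freeze_hyperparameters`` fixes fold hyperparameters at the full-data
    mode (refitting only the latent field), a documented speed option; the
    default re-optimizes per fold.
    """
    pops = obs.counts["population"].unique()
    if len(pops) < 2:
        raise ValueError("LPOCV needs at least two populations")
    if holdout_populations is not None:
        pops = [g for g in pops if g in set(holdout_populations)]
    fixed = None
    if freeze_hyperparameters:
        full = IntegratedSDM(**estimator.get_params())
        full.fit(obs, domain, X, mesh=mesh)
        fixed = full.result_.theta
    records = []
    # per-population fold seeds: independent of observation/population order
    fold_seeds = [_fold_seed(seed, g) for g in pops]
    for g, fs in zip(pops, fold_seeds):
        held = obs.counts[(obs.counts["population"] == g)
                          & (~obs.counts["missing"])]
        if held.empty:
            continue
        train_counts = obs.counts[obs.counts["population"] != g]
        train = ObservationSet(counts=train_counts.reset_index(drop=True),
                               presences=obs.presences,
                               populations=obs.populations)
        est = IntegratedSDM(**estimator.get_params())
        est.fit(train, domain, X, mesh=mesh, fixed_hypers=fixed)
        samples = sample_posterior(est.result_, n_samples, fs)
        logdens = _count_ppd_logdens(est.result_, samples, held)
        for (_, r), ld in zip(held.iterrows(), logdens):
            records.append({"population": g, "species": int(r["species"]),
                            "cell": int(r["cell"]), "year": int(r["year"]),
                            "count": float(r["count"]),
                            "log_density": float(ld)})
    per_obs = pd.DataFrame(records)
    return float(per_obs["log_density"].mean()), per_obs


# --- coverage / amplitude / MAE ---------------------------------------------

def coverage_report(result: PosteriorResult, obs: ObservationSet,
                    levels=(0.75, 0.95), n_samples: int = 300,
                    seed: int = 0, samples=None) -> EvaluationReport:
    """Temporal-interpolation diagnostics per species.

    Intervals are central posterior intervals of the expected count
    mu = area * lambda (pPCPI-I) and of simulated predictive counts
    (pPCPI-PPD, 95%).  Coverage and MAE use observed records only;
    NA-amplitude statistics summarize interval widths at missing records.
    """
    if samples is None:
        samples = sample_posterior(result, n_samples, seed)
    rng = np.random.default_rng(seed)
    md = result.model_data
    c = obs.counts.reset_index(drop=True)
    yidx = md.domain.year_index(c["year"].to_numpy(int))
    eta = _eta_samples_at(result, samples, c["species"].to_numpy(int),
                          c["cell"].to_numpy(int), yidx)
    mu = c["area"].to_numpy(float)[:, None] * np.exp(eta)
    theta = samples["theta"]
    n_s = mu.shape[1]
    psi = theta["psi"].to_numpy() if "psi" in theta else np.full(n_s, 1.0)
    # simulated predictive counts per posterior sample
    ypred = np.empty_like(mu)
    sp = c["species"].to_numpy(int)
    for j in range(md.n_species):
        m = sp == j
        if not m.any():
            continue
        if md.families[j] == "poisson":
            ypred[m] = rng.poisson(mu[m])
        else:
            p = psi[None, :] / (psi[None, :] + mu[m])
            ypred[m] = rng.negative_binomial(psi[None, :], p)
    missing = c["missing"].to_numpy(bool)
    y = c["count"].to_numpy(float)
    mu_mean = mu.mean(axis=1)

    rows = []
    for j in range(md.n_species):
        m = sp == j
        mo = m & ~missing
        mm = m & missing
        row = {"species": j}
        for lev in levels:
            a = (1 - lev) / 2
            lo = np.quantile(mu[m], a, axis=1)
            hi = np.quantile(mu[m], 1 - a, axis=1)
            amp = hi - lo
            obs_mask = ~missing[m]
            if obs_mask.any():
                yj = y[m][obs_mask]
                row[f"ppcpi_i_{int(lev*100)}"] = 100.0 * np.mean(
                    (yj >= lo[obs_mask]) & (yj <= hi[obs_mask]))
                row[f"amp_i_{int(lev*100)}_mean"] = float(amp[obs_mask].mean())
                row[f"amp_i_{int(lev*100)}_sd"] = float(amp[obs_mask].std())
            if missing[m].any():
                row[f"amp_i_{int(lev*100)}_na_mean"] = float(
                    amp[~obs_mask].mean())
                row[f"amp_i_{int(lev*100)}_na_sd"] = float(amp[~obs_mask].std())
        # PPD at 95%
        lo = np.quantile(ypred[m], 0.025, axis=1)
        hi = np.quantile(ypred[m], 0.975, axis=1)
        amp = hi - lo
        obs_mask = ~missing[m]
        if obs_mask.any():
            yj = y[m][obs_mask]
            row["ppcpi_ppd_95"] = 100.0 * np.mean(
                (yj >= lo[obs_mask]) & (yj <= hi[obs_mask]))
            row["amp_ppd_95_mean"] = float(amp[obs_mask].mean())
            row["amp_ppd_95_sd"] = float(amp[obs_mask].std())
            row["mae"] = float(np.mean(np.abs(yj - mu_mean[m][obs_mask])))
        if missing[m].any():
            row["amp_ppd_95_na_mean"] = float(amp[~obs_mask].mean())
            row["amp_ppd_95_na_sd"] = float(amp[~obs_mask].std())
        rows.append(row)
    per_species = pd.DataFrame(rows).set_index("species")
    return EvaluationReport(model_id=result.config.model_id,
                            per_species=per_species)


# --- spatial redundancy -----------------------------------------------------

def spatial_redundancy(points_a, points_b, radius_m: float,
                       symmetric: bool = False) -> float:
    """Percentage of ``points_b`` lying within ``radius_m`` of any point in
    ``points_a`` (buffer-overlap diagnostic between monitoring polygons'
    centroids and opportunistic records).

    With ``symmetric=True`` the two directed percentages are averaged.
    """
    a = np.atleast_2d(np.asarray(points_a, float))
    b = np.atleast_2d(np.asarray(points_b, float))
    if len(a) == 0 or len(b) == 0:
        raise ValueError("point sets must be non-empty")
    if radius_m <= 0:
        raise ValueError("radius must be positive")
    d, _ = cKDTree(a).query(b)
    pct = 100.0 * float(np.mean(d <= radius_m))
    if symmetric:
        d2, _ = cKDTree(b).query(a)
        pct = 0.5 * (pct + 100.0 * float(np.mean(d2 <= radius_m)))
    return pct
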