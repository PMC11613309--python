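"""Stand-alone process-model calibration.

Two routes are provided, matching the two process models:

* :func:`mcmc_calibrate` -- adaptive random-walk Metropolis within prior
  bounds, with a Gaussian likelihood whose mean is the model prediction and
  whose standard deviation defaults to one.  Used for the flux mini-model
  (and anything else exposing a vectorised log-likelihood).
* :func:`gradient_calibrate_lv` -- gradient descent (Adam) on the mean
  squared error between predicted and observed prey densities, with
  gradients from analytic forward sensitivities integrated alongside the
  state; parameters are clipped to their bounds after every step.  Used for
  the predator-prey model, where the observation budget is tiny and the
  training schedule is measured in tens of thousands of epochs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels, flux, lv
from .nn import adam_update_array, fresh_adam_state

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def gaussian_log_likelihood(y_obs: np.ndarray, y_pred: np.ndarray, sd: float = 1.0):
    """Sum over observations of Normal(y | prediction, sd) log-density.

    ``y_pred`` may carry leading batch axes; the sum runs over the last axis.
    """
    y_obs = np.asarray(y_obs, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    n = y_obs.shape[-1]
    resid = y_obs - y_pred
    return -n * (_LOG_SQRT_2PI + np.log(sd)) - np.sum(resid * resid, axis=-1) / (2.0 * sd * sd)


# ----------------------------------------------------------------- posteriors
@dataclass
class Posterior:
    """MCMC output: per-chain draws, log-posterior traces, acceptance rates
    and the MAP over all post-burn-in draws (first half discarded)."""

    chains: np.ndarray  # (n_chains, n_iter, d)
    logpost: np.ndarray  # (n_chains, n_iter)
    acceptance: np.ndarray  # (n_chains,)
    param_names: tuple | None = None
    burn_fraction: float = 0.5

    @property
    def n_burn(self) -> int:
        return int(self.chains.shape[1] * self.burn_fraction)

    def draws(self) -> np.ndarray:
        """Post-burn-in draws pooled over chains, (n, d)."""
        return self.chains[:, self.n_burn :, :].reshape(-1, self.chains.shape[2])

    def map_estimate(self) -> np.ndarray:
        lp = self.logpost[:, self.n_burn :]
        c, i = np.unravel_index(np.argmax(lp), lp.shape)
        return self.chains[c, i + self.n_burn, :]

    def to_csv(self, path) -> None:
        names = self.param_names or tuple(f"p{i}" for i in range(self.chains.shape[2]))
        rows = []
        for c in range(self.chains.shape[0]):
            frame = pd.DataFrame(self.chains[c], columns=list(names))
            frame.insert(0, "iteration", np.arange(self.chains.shape[1]))
            frame.insert(0, "chain", c)
            frame["logpost"] = self.logpost[c]
            rows.append(frame)
        pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def mcmc_calibrate(
    loglik_fn,
    lo: np.ndarray,
    hi: np.ndarray,
    n_iter: int = 5000,
    n_chains: int = 3,
    seed: int = 0,
    init: np.ndarray | None = None,
    target_accept: float = 0.234,
    param_names: tuple | None = None,
) -> Posterior:
    """Adaptive random-walk Metropolis within uniform prior bounds.

    ``loglik_fn(theta)`` takes a (n_chains, d) array and returns (n_chains,)
    log-likelihoods.  Proposals are Gaussian with per-parameter scale
    ``c * (2.4 / sqrt(d)) * width_j``; the global factor ``c`` adapts during
    burn-in towards ``target_accept``.  Proposals outside the bounds are
    rejected (uniform prior support).  Reproducible per seed.
    """
    lo = np.asarray(lo, dtype=np.float64)
    hi = np.asarray(hi, dtype=np.float64)
    d = len(lo)
    width = hi - lo
    rng = np.random.default_rng(seed)
    if init is None:
        theta = lo + width * (0.5 + 0.1 * rng.standard_normal((n_chains, d)))
        theta = np.clip(theta, lo + 1e-9 * width, hi - 1e-9 * width)
    else:
        theta = np.broadcast_to(np.asarray(init, dtype=np.float64), (n_chains, d)).copy()
    lp = np.asarray(loglik_fn(theta), dtype=np.float64)

    base = (2.4 / np.sqrt(d)) * width
    scale = np.full(n_chains, 0.05)  # adapted towards target_accept during burn-in
    n_burn = n_iter // 2
    chains = np.empty((n_chains, n_iter, d))
    logpost = np.empty((n_chains, n_iter))
    accepted = np.zeros(n_chains)
    window_accepts = np.zeros(n_chains)
    window = 50

    for it in range(n_iter):
        prop = theta + rng.standard_normal((n_chains, d)) * (scale[:, None] * base)
        inside = np.all((prop >= lo) & (prop <= hi), axis=1)
        lp_prop = np.full(n_chains, -np.inf)
        if inside.any():
            lp_eval = np.asarray(loglik_fn(prop[inside]), dtype=np.float64)
            lp_prop[inside] = lp_eval
        accept = np.log(rng.random(n_chains)) < (lp_prop - lp)
        theta[accept] = prop[accept]
        lp[accept] = lp_prop[accept]
        accepted += accept
        window_accepts += accept
        chains[:, it, :] = theta
        logpost[:, it] = lp
        if (it + 1) % window == 0 and it < n_burn:
            rate = window_accepts / window
            if np.all(rate == 0.0):
                warnings.warn(
                    f"zero acceptance over the last {window} iterations; "
                    "proposal step may be too large",
                    RuntimeWarning,
                )
            scale *= np.exp(1.5 * (rate - target_accept))
            scale = np.clip(scale, 1e-4, 10.0)
            window_accepts[:] = 0.0
    return Posterior(
        chains=chains,
        logpost=logpost,
        acceptance=accepted / n_iter,
        param_names=param_names,
    )


# ------------------------------------------------------------ model-specific
def make_lv_loglik(
    obs: lv.ObservationSet,
    response: str,
    init_state: lv.LVState,
    horizon: float,
    step: float,
    internal_step: float = 0.5,
    sd: float = 1.0,
):
    """Vectorised log-likelihood of LV parameters given prey observations.

    Accepts theta arrays of shape (B, 3) for type I (r, b, m) or (B, 4) for
    type III (r, b, m, s).
    """
    type3 = response == lv.TYPE_III
    n_out = int(round(horizon / step)) + 1
    substeps = max(1, int(round(step / internal_step)))
    idx = np.asarray(obs.indices)
    y_obs = np.asarray(obs.x_obs, dtype=np.float64)

    def loglik(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(np.asarray(theta, dtype=np.float64))
        B = theta.shape[0]
        params = np.zeros((B, 4))
        params[:, : theta.shape[1]] = theta
        traj = _kernels.lv_rk4(
            params,
            np.full(B, float(init_state.x)),
            np.full(B, float(init_state.y)),
            np.full(B, type3),
            n_out,
            float(step),
            substeps,
        )
        pred = traj[:, idx, 0]
        out = gaussian_log_likelihood(y_obs, pred, sd=sd)
        out[~np.isfinite(pred).all(axis=1)] = -np.inf
        return out

    return loglik


def make_flux_loglik(daily_df: pd.DataFrame, obs_rows: np.ndarray, sd: float = 1.0, target_col: str = "P_obs"):
    """Vectorised log-likelihood of flux-model parameters.

    The model runs over each site's full contiguous daily series (the water
    balance is a recursion) and the likelihood is evaluated only at
    ``obs_rows`` (positions into ``daily_df``), so sparse observation
    schedules are supported.
    """
    obs_rows = np.asarray(obs_rows)
    y_obs = daily_df[target_col].to_numpy(dtype=np.float64)[obs_rows]
    site_col = daily_df["site_id"].to_numpy()
    sites = list(dict.fromkeys(site_col))
    site_data = []
    for s in sites:
        pos = np.flatnonzero(site_col == s)
        covs = np.column_stack(
            [daily_df[c].to_numpy(dtype=np.float64)[pos] for c in flux.COVARIATE_COLUMNS]
        )
        site_data.append((pos, covs))

    def loglik(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(np.asarray(theta, dtype=np.float64))
        B = theta.shape[0]
        pred_all = np.empty((B, len(daily_df)))
        for pos, covs in site_data:
            n = covs.shape[0]
            cap = theta[:, list(flux.PARAM_NAMES).index("capacity")]
            P, *_ = _kernels.flux_forward(
                np.ascontiguousarray(theta),
                np.ascontiguousarray(np.broadcast_to(covs[None], (B, n, 6))),
                0.7 * cap,
                np.zeros(B),
            )
            pred_all[:, pos] = P
        return gaussian_log_likelihood(y_obs, pred_all[:, obs_rows], sd=sd)

    return loglik


def calibrate_flux_pm(
    daily_df: pd.DataFrame,
    obs_rows: np.ndarray,
    n_iter: int = 3000,
    n_chains: int = 2,
    seed: int = 0,
    sd: float = 1.0,
) -> tuple[flux.PMParams, Posterior]:
    """MCMC-calibrate the flux mini-model and return (MAP parameters, posterior)."""
    lo, hi = flux.prior_bounds()
    post = mcmc_calibrate(
        make_flux_loglik(daily_df, obs_rows, sd=sd),
        lo,
        hi,
        n_iter=n_iter,
        n_chains=n_chains,
        seed=seed,
        param_names=flux.PARAM_NAMES,
    )
    return flux.PMParams.from_array(post.map_estimate()), post


# ------------------------------------------------------- gradient calibration
def _clip_to_bounds(params: np.ndarray, bounds: dict, type3: np.ndarray) -> np.ndarray:
    names = ("r", "b", "m", "s")
    for j, name in enumerate(names):
        lo, hi = bounds[name]
        params[:, j] = np.clip(params[:, j], lo, hi)
    params[~type3, 3] = 0.0
    return params


def gradient_calibrate_lv_batch(
    obs_idx: np.ndarray,
    obs_x: np.ndarray,
    init_params: np.ndarray,
    type3: np.ndarray,
    x0: np.ndarray,
    y0: np.ndarray,
    n_out: int,
    step: float,
    epochs: int,
    lr: float,
    substeps: int = 1,
    bounds: dict = lv.LV_BOUNDS,
) -> tuple[np.ndarray, np.ndarray]:
    """Batched gradient calibration of LV parameters.

    Each batch member has its own observation schedule ``obs_idx[i]`` (grid
    positions), observations ``obs_x[i]``, initial parameter vector and
    fixed initial state.  The MSE between predicted and observed prey is
    minimised with Adam; gradients come from forward sensitivities
    integrated with the same RK4 scheme.  For type I members the searching
    time is inert (zero sensitivity).  Returns (params (B, 4),
    loss curves (B, epochs)).
    """
    B = obs_idx.shape[0]
    params = np.array(init_params, dtype=np.float64, copy=True)
    type3 = np.asarray(type3, dtype=bool)
    state = fresh_adam_state(params.shape)
    curves = np.empty((B, epochs))
    K = obs_idx.shape[1]
    obs_idx = np.ascontiguousarray(obs_idx, dtype=np.int64)
    x0 = np.asarray(x0, dtype=np.float64)
    y0 = np.asarray(y0, dtype=np.float64)
    for ep in range(epochs):
        pred, sens = _kernels.lv_rk4_sens_obs(
            params, x0, y0, type3, n_out, step, substeps, obs_idx
        )
        resid = pred - obs_x
        curves[:, ep] = np.mean(resid * resid, axis=1)
        if not np.all(np.isfinite(curves[:, ep])):
            raise FloatingPointError(f"non-finite calibration loss at epoch {ep}")
        grad = 2.0 * np.einsum("bk,bkp->bp", resid, sens) / K
        params = adam_update_array(params, grad, state, lr)
        params = _clip_to_bounds(params, bounds, type3)
    return params, curves


def gradient_calibrate(
    pm_config: lv.LVConfig,
    obs: lv.ObservationSet,
    epochs: int,
    lr: float,
    bounds: dict = lv.LV_BOUNDS,
    internal_step: float = 0.5,
) -> tuple[lv.LVParams, np.ndarray]:
    """Calibrate one LV process model to prey observations by gradient
    descent from its configured initial parameter values.  Returns the
    fitted parameters and the per-epoch loss curve."""
    type3 = pm_config.response == lv.TYPE_III
    n_out = int(round(pm_config.horizon / pm_config.step)) + 1
    substeps = max(1, int(round(pm_config.step / internal_step)))
    params, curves = gradient_calibrate_lv_batch(
        obs_idx=np.asarray(obs.indices)[None, :],
        obs_x=np.asarray(obs.x_obs, dtype=np.float64)[None, :],
        init_params=pm_config.params.as_array()[None, :],
        type3=np.array([type3]),
        x0=np.array([float(pm_config.init.x)]),
        y0=np.array([float(pm_config.init.y)]),
        n_out=n_out,
        step=pm_config.step,
        epochs=epochs,
        lr=lr,
        substeps=substeps,
        bounds=bounds,
    )
    p = params[0]
    fitted = lv.LVParams(r=p[0], b=p[1], m=p[2], s=p[3] if type3 else None)
    return fitted, curves[0]
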