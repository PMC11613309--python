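"""A miniature light-use-efficiency ecosystem model.

Daily gross primary productivity (GPP, ``P``) follows the classical
light-use-efficiency form

    P_k = beta * phi_k * faPPFD_k * f_T,k * f_D,k * f_W,P,k

where ``beta`` is the potential light-use efficiency, ``phi`` the
photosynthetically active radiation, ``faPPFD`` the absorbed fraction and
the ``f`` terms are unitless environmental modifiers in [0, 1]:

* ``f_T``: logistic in a seasonally acclimated temperature state (an
  exponential moving average of air temperature with window ``tau_temp``),
  midpoint ``t_opt`` and steepness ``k_temp``;
* ``f_D = exp(-kappa_vpd * D)``: exponential decline in vapour pressure
  deficit;
* ``f_W,P``: piecewise-linear ramp in relative soil water
  (theta_soil / capacity) between fractions ``wp_lo`` and ``wp_hi``.

Evapotranspiration is tied to productivity, ``E = alpha_et * P * D^0.6 *
f_W,E``, with ``f_W,E`` a ramp from 0 to ``we_hi``.  The water balance keeps
three pools: soil, surface and snow.  Precipitation falls as snow at or
below 0 C and as rain otherwise; snow melts at a degree-day rate
``melt_rate``; rain and melt pass through the surface pool and infiltrate
the soil the same day; soil above ``capacity`` runs off the same day; E is
extracted from soil and capped by availability.  All pools stay >= 0 and the
daily balance theta_k - theta_{k-1} = R_k - E_k - runoff_k closes exactly.

This is a deliberately small, fully documented stand-in for production
light-use-efficiency models: it preserves their structure (LUE core, soil
water feeding back on P through f_W,P, E coupled to P and soil through
f_W,E, three water pools) with eleven named parameters.  It is not a port of
any published parameterisation and is also used, structurally perturbed, as
the data-generating "truth" of the synthetic case study.

Every operation dispatches between a numba fast path (plain numbers,
batched over parameter vectors) and a tape path (autodiff Tensors), so the
model can sit inside a neural network's forward pass with gradients flowing
through it.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from . import autodiff as ad
from .autodiff import Tensor

#: covariate columns expected by the model, in kernel order
COVARIATE_COLUMNS = ("T", "D", "phi", "R", "fappfd", "co2")

#: calibratable parameters: name -> (default/truth value, lower, upper)
PARAM_TABLE = {
    "beta": (0.7, 0.1, 2.0),  # potential light-use efficiency (g C per mol PAR)
    "t_opt": (1.0, -5.0, 10.0),  # temperature modifier midpoint (deg C)
    "k_temp": (0.3, 0.05, 1.5),  # temperature modifier steepness (1/deg C)
    "tau_temp": (7.0, 1.0, 30.0),  # temperature acclimation window (days)
    "kappa_vpd": (0.35, 0.0, 1.5),  # VPD sensitivity (1/kPa)
    "wp_lo": (0.05, 0.0, 0.4),  # f_W,P ramp start (fraction of capacity)
    "wp_hi": (0.55, 0.3, 1.0),  # f_W,P ramp end (fraction of capacity)
    "we_hi": (0.5, 0.2, 1.0),  # f_W,E ramp end (fraction of capacity)
    "capacity": (200.0, 50.0, 500.0),  # soil bucket capacity (mm)
    "melt_rate": (3.0, 0.5, 10.0),  # degree-day snow melt (mm / deg C / day)
    "alpha_et": (0.25, 0.05, 1.0),  # transpiration coefficient (mm per g C)
}

PARAM_NAMES = tuple(PARAM_TABLE)
NU_E = _kernels.NU_E


def prior_bounds() -> tuple[np.ndarray, np.ndarray]:
    lo = np.array([PARAM_TABLE[n][1] for n in PARAM_NAMES])
    hi = np.array([PARAM_TABLE[n][2] for n in PARAM_NAMES])
    return lo, hi


@dataclass
class PMParams:
    """Named parameter vector with prior bounds (see :data:`PARAM_TABLE`)."""

    values: dict

    def __post_init__(self):
        unknown = set(self.values) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameters: {sorted(unknown)}")
        for name in PARAM_NAMES:
            self.values.setdefault(name, PARAM_TABLE[name][0])
        self.validate()

    def validate(self) -> None:
        for name, v in self.values.items():
            if isinstance(v, Tensor):
                continue
            lo, hi = PARAM_TABLE[name][1], PARAM_TABLE[name][2]
            if np.any(np.asarray(v) < lo) or np.any(np.asarray(v) > hi):
                raise ValueError(f"{name}={v} outside prior bounds [{lo}, {hi}]")

    @classmethod
    def defaults(cls, **overrides) -> "PMParams":
        return cls({n: overrides.get(n, PARAM_TABLE[n][0]) for n in PARAM_NAMES})

    @classmethod
    def from_array(cls, arr) -> "PMParams":
        if isinstance(arr, Tensor):
            return cls({n: arr[i] for i, n in enumerate(PARAM_NAMES)})
        arr = np.asarray(arr, dtype=np.float64)
        return cls({n: arr[..., i] for i, n in enumerate(PARAM_NAMES)})

    def as_array(self) -> np.ndarray:
        """Stack values into (..., n_params); plain values only."""
        vals = [np.asarray(self.values[n], dtype=np.float64) for n in PARAM_NAMES]
        return np.stack(np.broadcast_arrays(*vals), axis=-1)

    def __getitem__(self, name):
        return self.values[name]

    # ------------------------------------------------------------- config IO
    def to_config(self, path) -> None:
        """(name, value, lower, upper) rows, one parameter per line."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["name", "value", "lower", "upper"])
            for n in PARAM_NAMES:
                w.writerow([n, float(np.asarray(self.values[n])), PARAM_TABLE[n][1], PARAM_TABLE[n][2]])

    @classmethod
    def from_config(cls, path) -> "PMParams":
        values = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                values[row["name"]] = float(row["value"])
        return cls(values)


@dataclass
class FluxState:
    """Daily state: productivity, transpiration and the three water pools."""

    P: float = 0.0
    E: float = 0.0
    theta_soil: float = 0.0
    theta_surface: float = 0.0
    theta_snow: float = 0.0

    @property
    def theta(self):
        return self.theta_soil + self.theta_surface + self.theta_snow


@dataclass
class ModifierSet:
    """Unitless multipliers of the light-use-efficiency core, each in [0, 1]."""

    f_temp: float
    f_vpd: float
    f_wp: float
    f_we: float


@dataclass
class FluxSeries:
    """Daily model outputs; arrays (or Tensors on the tape path) of length n."""

    P: object
    E: object
    theta_soil: object
    theta_snow: object
    runoff: object

    @property
    def theta(self):
        return self.theta_soil + self.theta_snow

    def __len__(self):
        return len(ad.value_of(self.P))


def default_init_pools(params: PMParams):
    """(soil, snow) starting pools: soil at 0.7 capacity, no snow.

    The soil pool is a function of the capacity parameter, so on the tape
    path gradients flow through the initial condition too."""
    return 0.7 * params["capacity"], 0.0


# --------------------------------------------------------------- single steps
def compute_modifiers(cov: dict, t_smooth, soil_prev, params: PMParams) -> ModifierSet:
    """Modifiers for one day given the acclimated temperature state and the
    previous day's soil pool."""
    p = params.values
    f_temp = ad.sigmoid(p["k_temp"] * (t_smooth - p["t_opt"]))
    f_vpd = ad.exp(-p["kappa_vpd"] * cov["D"])
    w = soil_prev / p["capacity"]
    f_wp = ad.clip((w - p["wp_lo"]) / (p["wp_hi"] - p["wp_lo"]), 0.0, 1.0)
    f_we = ad.clip(w / p["we_hi"], 0.0, 1.0)
    return ModifierSet(f_temp=f_temp, f_vpd=f_vpd, f_wp=f_wp, f_we=f_we)


def gpp_step(cov: dict, mods: ModifierSet, params: PMParams):
    """P = beta * phi * faPPFD * f_temp * f_vpd * f_W,P (light-use-efficiency core)."""
    return params["beta"] * cov["phi"] * cov["fappfd"] * mods.f_temp * mods.f_vpd * mods.f_wp


def water_balance_step(state: FluxState, cov: dict, params: PMParams, gpp, f_we):
    """Advance the water pools by one day.

    ``state`` carries the previous day's pools; ``gpp`` and ``f_we`` are the
    current day's productivity and soil-water E-modifier.  Returns the new
    :class:`FluxState` (with this day's P and E) and the day's runoff.
    """
    for name in ("T", "D", "R"):
        v = ad.value_of(cov[name])
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite covariate {name}")
    T, D, R = cov["T"], cov["D"], cov["R"]
    snow_prev, soil_prev = state.theta_snow, state.theta_soil
    cold = np.asarray(ad.value_of(T)) <= 0.0
    snow_in = ad.where(cold, R, 0.0)
    rain = ad.where(cold, 0.0, R)
    melt = ad.minimum(snow_prev, params["melt_rate"] * ad.maximum(T, 0.0))
    snow = snow_prev + snow_in - melt
    inflow = rain + melt
    e_demand = params["alpha_et"] * gpp * np.power(np.maximum(ad.value_of(D), 0.0), NU_E) * f_we
    et = ad.minimum(e_demand, soil_prev + inflow)
    soil_t = soil_prev + inflow - et
    runoff = ad.maximum(soil_t - params["capacity"], 0.0)
    soil = soil_t - runoff
    new = FluxState(P=gpp, E=et, theta_soil=soil, theta_surface=0.0, theta_snow=snow)
    return new, runoff


# ----------------------------------------------------------------- full runs
def _covariate_arrays(covariates) -> dict:
    if isinstance(covariates, pd.DataFrame):
        missing = [c for c in COVARIATE_COLUMNS if c not in covariates.columns]
        if missing:
            raise ValueError(f"missing covariate columns: {missing}")
        if "date" in covariates.columns:
            dates = pd.to_datetime(covariates["date"])
            gaps = dates.diff().dt.days.iloc[1:]
            if len(gaps) and not np.all(gaps == 1):
                raise ValueError("covariate series has gaps; a contiguous daily series is required")
        return {c: covariates[c].to_numpy(dtype=np.float64) for c in COVARIATE_COLUMNS}
    return {c: np.asarray(covariates[c], dtype=np.float64) for c in COVARIATE_COLUMNS}


def run_pm(
    covariates,
    params: PMParams,
    init: FluxState | None = None,
    gpp_perturbation=None,
    backend: str = "auto",
) -> FluxSeries:
    """Run the mini-model over a contiguous daily covariate series.

    ``covariates``: DataFrame (or mapping of arrays) with columns
    T, D, phi, R, fappfd, co2.  ``params`` values may be scalars, batched
    arrays of shape (B,), or Tensors (tape path; used by the physics
    embedding).  ``gpp_perturbation(cov_day, P) -> P`` optionally distorts
    productivity before it enters the transpiration/water subsystems (used
    by the synthetic-data generator to plant structural mismatch).

    Returns a :class:`FluxSeries`; with batched parameters each field has
    shape (B, n).
    """
    cov = _covariate_arrays(covariates)
    n = len(cov["T"])
    if init is None:
        soil0, snow0 = default_init_pools(params)
    else:
        soil0, snow0 = init.theta_soil, init.theta_snow

    plain = gpp_perturbation is None and not any(
        isinstance(v, Tensor) for v in params.values.values()
    ) and not isinstance(soil0, Tensor)
    if backend == "fast" or (backend == "auto" and plain):
        arr = params.as_array()
        batched = arr.ndim == 2
        if not batched:
            arr = arr[None, :]
        B = arr.shape[0]
        covs = np.ascontiguousarray(
            np.broadcast_to(
                np.column_stack([cov[c] for c in COVARIATE_COLUMNS])[None, :, :], (B, n, 6)
            )
        )
        P, E, soil, snow, runoff = _kernels.flux_forward(
            np.ascontiguousarray(arr),
            covs,
            np.broadcast_to(np.asarray(ad.value_of(soil0), dtype=np.float64), (B,)).copy(),
            np.broadcast_to(np.asarray(ad.value_of(snow0), dtype=np.float64), (B,)).copy(),
        )
        if not batched:
            P, E, soil, snow, runoff = P[0], E[0], soil[0], snow[0], runoff[0]
        return FluxSeries(P=P, E=E, theta_soil=soil, theta_snow=snow, runoff=runoff)

    # generic (tape-compatible) path: same recursion, one day at a time
    state = FluxState(theta_soil=soil0, theta_snow=snow0)
    t_smooth = cov["T"][0]
    P_days, E_days, soil_days, snow_days, runoff_days = [], [], [], [], []
    for k in range(n):
        day = {c: cov[c][k] for c in COVARIATE_COLUMNS}
        if k > 0:
            t_smooth = t_smooth + (day["T"] - t_smooth) / params["tau_temp"]
        mods = compute_modifiers(day, t_smooth, state.theta_soil, params)
        gpp = gpp_step(day, mods, params)
        if gpp_perturbation is not None:
            gpp = gpp_perturbation(day, gpp)
        state, runoff = water_balance_step(state, day, params, gpp, mods.f_we)
        P_days.append(state.P)
        E_days.append(state.E)
        soil_days.append(state.theta_soil)
        snow_days.append(state.theta_snow)
        runoff_days.append(runoff)

    if any(isinstance(v, Tensor) for v in P_days + soil_days):
        pack = ad.stack
    else:
        pack = np.array
    return FluxSeries(
        P=pack(P_days),
        E=pack(E_days),
        theta_soil=pack(soil_days),
        theta_snow=pack(snow_days),
        runoff=pack(runoff_days),
    )


def run_pm_sites(df: pd.DataFrame, params: PMParams, backend: str = "auto") -> pd.DataFrame:
    """Run the model separately per site of a multi-site daily table.

    Returns a copy of ``df`` with columns P_pm, E_pm, theta_pm appended,
    aligned row-by-row.
    """
    out = df.copy()
    for col in ("P_pm", "E_pm", "theta_pm"):
        out[col] = np.nan
    for _, idx in df.groupby("site_id", sort=False).groups.items():
        sub = df.loc[idx]
        series = run_pm(sub, params, backend=backend)
        out.loc[idx, "P_pm"] = ad.value_of(series.P)
        out.loc[idx, "E_pm"] = ad.value_of(series.E)
        out.loc[idx, "theta_pm"] = ad.value_of(series.theta)
    return out
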