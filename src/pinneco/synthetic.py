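"""Synthetic study systems.

Two fixture families, both fully generated in code:

* the predator-prey scenario suite (data sparsity; + structural error in the
  process model; + observation noise), with all printed constants of the
  study design;
* multi-site daily forest carbon-flux datasets: five sites spanning boreal to
  mediterranean climates and evergreen/deciduous canopies, observed over
  four to seven years.  The "truth" is the flux mini-model run with
  site-specific parameter offsets plus *planted structural mismatch* --
  distortions the process model cannot represent (a radiation-saturation
  term and a site-varying precipitation sensitivity) -- plus heteroscedastic
  observation noise.  The noise-free truth is kept alongside for oracle
  tests, and the planted mismatch gives the variable-importance analysis a
  known signal to recover.

All climate functional forms and default tables here are generator
inventions (real eddy-covariance data is not shipped); they aim for
realistic magnitudes, not for any particular site.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import autodiff as ad
from . import flux, lv

# ----------------------------------------------------------------- LV suite
#: printed constants of the predator-prey design
BOX1_TRUE_PARAMS = lv.LVParams(r=0.1, b=0.02, m=0.04, s=0.025)
BOX1_INIT = lv.LVState(x=10.0, y=10.0)
BOX1_PM_INIT_MISSPEC = lv.LVState(x=12.0, y=10.0)
BOX1_HORIZON = 130.0
BOX1_STEP = 0.5
BOX1_N_OBS = 9
BOX1_NOISE_SD = 0.5


@dataclass
class Box1Scenario:
    """The three printed conditions: (i) data sparsity, (ii) + structural
    error in the process model (type I instead of type III response, with
    mis-specified initial prey density), (iii) + observation noise."""

    id: str

    def __post_init__(self):
        if self.id not in ("i", "ii", "iii"):
            raise ValueError(f"scenario must be 'i', 'ii' or 'iii', got {self.id!r}")

    @property
    def generator_response(self) -> str:
        return lv.TYPE_III

    @property
    def pm_response(self) -> str:
        return lv.TYPE_III if self.id == "i" else lv.TYPE_I

    @property
    def pm_init(self) -> lv.LVState:
        return BOX1_INIT if self.id == "i" else BOX1_PM_INIT_MISSPEC

    @property
    def noise_sd(self) -> float:
        return BOX1_NOISE_SD if self.id == "iii" else 0.0

    @property
    def n_obs(self) -> int:
        return BOX1_N_OBS


def gen_box1(scenario: Box1Scenario, seed: int, internal_step: float = 0.05):
    """Generate one predator-prey scenario realisation.

    Returns (full type III trajectory, prey observation set, process-model
    config).  The process-model config carries the structure and (fixed,
    not estimated) initial conditions of the scenario, with parameters at
    the generator's printed values as the calibration starting point.
    """
    traj = lv.integrate(
        BOX1_TRUE_PARAMS, BOX1_INIT, BOX1_HORIZON, BOX1_STEP, lv.TYPE_III, internal_step
    )
    obs = lv.observe(traj, scenario.n_obs, scenario.noise_sd, seed)
    if scenario.pm_response == lv.TYPE_III:
        pm_params = lv.LVParams(
            r=BOX1_TRUE_PARAMS.r, b=BOX1_TRUE_PARAMS.b, m=BOX1_TRUE_PARAMS.m, s=BOX1_TRUE_PARAMS.s
        )
    else:
        pm_params = lv.LVParams(r=BOX1_TRUE_PARAMS.r, b=BOX1_TRUE_PARAMS.b, m=BOX1_TRUE_PARAMS.m)
    pm_config = lv.LVConfig(
        params=pm_params,
        init=scenario.pm_init,
        horizon=BOX1_HORIZON,
        step=BOX1_STEP,
        response=scenario.pm_response,
        seed=seed,
    )
    return traj, obs, pm_config


# ------------------------------------------------------------------ flux sites
@dataclass
class SiteSpec:
    """Climate, phenology and truth-model configuration of one site."""

    site_id: str
    t_mean: float  # mean annual air temperature (deg C)
    t_amp: float  # seasonal temperature amplitude (deg C)
    phi_max: float  # midsummer clear-sky PAR (mol m-2 day-1 scale)
    precip_regime: str  # temperate | boreal | mediterranean
    phenology: str  # evergreen | deciduous
    years: tuple = (2006, 2007, 2008)
    co2: float = 390.0
    beta_offset: float = 1.0  # site multiplier on potential light-use efficiency
    precip_sens: float = 0.0  # site-varying precipitation sensitivity (1/mm)
    mismatch: dict = field(default_factory=lambda: {"radiation_saturation": True, "precip_sensitivity": True})
    phi_sat: float = 35.0  # radiation half-saturation of the planted mismatch

    def __post_init__(self):
        if len(self.years) < 1:
            raise ValueError("a site needs at least one year")
        if self.phenology not in ("evergreen", "deciduous"):
            raise ValueError(f"unknown phenology {self.phenology!r}")
        if self.precip_regime not in ("temperate", "boreal", "mediterranean"):
            raise ValueError(f"unknown precipitation regime {self.precip_regime!r}")


def default_sites(years: tuple = (2006, 2007, 2008)) -> list[SiteSpec]:
    """Five sites spanning boreal to mediterranean climate and evergreen to
    deciduous canopies, with site-varying truth parameters and planted
    structural mismatch.  The first site is the canonical transfer target
    (its precipitation sensitivity is zero so the radiation saturation is
    the dominant planted signal there)."""
    return [
        SiteSpec("site1_boreal", 4.0, 13.0, 38.0, "boreal", "evergreen", years, 392.0, 1.0, 0.0),
        SiteSpec("site2_montane", 7.0, 10.0, 42.0, "temperate", "evergreen", years, 390.0, 0.9, 0.006),
        SiteSpec("site3_lowland", 10.0, 9.0, 44.0, "temperate", "deciduous", years, 391.0, 1.1, 0.010),
        SiteSpec("site4_oceanic", 12.0, 7.0, 45.0, "temperate", "deciduous", years, 389.0, 1.0, 0.014),
        SiteSpec("site5_mediterranean", 15.0, 8.0, 50.0, "mediterranean", "evergreen", years, 393.0, 0.85, 0.004),
    ]


def study_sites() -> list[SiteSpec]:
    """The full-size layout: five sites observed over four to seven years."""
    sites = default_sites()
    spans = [(2002, 2008), (2004, 2008), (2003, 2008), (2005, 2008), (2004, 2008)]
    for site, (y0, y1) in zip(sites, spans):
        site.years = tuple(range(y0, y1 + 1))
    return sites


def _phenology_curve(doy: np.ndarray, phenology: str) -> np.ndarray:
    if phenology == "evergreen":
        return 0.78 + 0.04 * np.sin(2.0 * np.pi * (doy - 110.0) / 365.0)
    up = 1.0 / (1.0 + np.exp(-(doy - 120.0) / 7.0))
    down = 1.0 / (1.0 + np.exp((doy - 285.0) / 10.0))
    return 0.10 + 0.72 * up * down


def _wet_probability(doy: np.ndarray, regime: str) -> np.ndarray:
    if regime == "temperate":
        return np.full_like(doy, 0.35, dtype=np.float64)
    if regime == "boreal":
        return np.full_like(doy, 0.30, dtype=np.float64)
    # mediterranean: wet winters, dry summers
    return 0.28 + 0.22 * np.cos(2.0 * np.pi * (doy - 15.0) / 365.0)


def _rain_scale(doy: np.ndarray, regime: str) -> np.ndarray:
    if regime == "mediterranean":
        return 3.0 + 5.0 * np.cos(2.0 * np.pi * (doy - 15.0) / 365.0) ** 2
    base = 6.0 if regime == "temperate" else 4.0
    return np.full_like(doy, base, dtype=np.float64)


def gen_climate(site: SiteSpec, seed: int) -> pd.DataFrame:
    """Generate a daily covariate series for one site.

    Temperature is a seasonal sinusoid plus AR(1) noise; radiation a
    clear-sky sinusoid damped by cloudiness (coupled to rain occurrence);
    vapour pressure deficit grows exponentially with temperature and drops
    on wet days; precipitation is a seasonal occurrence/intensity process;
    faPPFD follows the phenology curve, held constant within 8-day blocks
    (the resolution of the satellite product it emulates); CO2 is constant
    per site.
    """
    rng = np.random.default_rng([seed, zlib.crc32(site.site_id.encode()) % (2**31)])
    dates = pd.date_range(f"{site.years[0]}-01-01", f"{site.years[-1]}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy().astype(np.float64)
    n = len(dates)

    season = np.sin(2.0 * np.pi * (doy - 110.0) / 365.0)
    ar = np.empty(n)
    eps = rng.normal(0.0, 2.0, size=n)
    ar[0] = eps[0]
    for k in range(1, n):
        ar[k] = 0.7 * ar[k - 1] + eps[k]
    T = site.t_mean + site.t_amp * season + ar

    wet = rng.random(n) < _wet_probability(doy, site.precip_regime)
    R = np.where(wet, rng.exponential(_rain_scale(doy, site.precip_regime)), 0.0)

    cloud = np.clip(1.0 - 0.45 * wet - 0.15 * rng.random(n), 0.25, 1.0)
    phi = site.phi_max * np.clip(0.5 + 0.5 * season, 0.05, None) * cloud

    D = 0.6 * np.exp(0.055 * (T - 10.0)) * (1.0 - 0.5 * wet) * np.exp(rng.normal(0.0, 0.25, n))
    D = np.clip(D, 0.01, None)

    block_start_doy = doy[(np.arange(n) // 8) * 8]  # 8-day step-constant
    fappfd = np.clip(_phenology_curve(block_start_doy, site.phenology), 0.0, 1.0)

    return pd.DataFrame(
        {
            "site_id": site.site_id,
            "date": dates.strftime("%Y-%m-%d"),
            "year": dates.year,
            "doy": doy.astype(int),
            "T": T,
            "D": D,
            "phi": phi,
            "R": R,
            "fappfd": fappfd,
            "co2": site.co2,
        }
    )


def true_params(site: SiteSpec) -> flux.PMParams:
    """The truth-model parameters of a site: defaults with the site's
    light-use-efficiency offset."""
    lo, hi = flux.PARAM_TABLE["beta"][1], flux.PARAM_TABLE["beta"][2]
    beta = float(np.clip(flux.PARAM_TABLE["beta"][0] * site.beta_offset, lo, hi))
    return flux.PMParams.defaults(beta=beta)


def mismatch_perturbation(site: SiteSpec):
    """The planted structural distortions of a site's truth model, applied
    to productivity inside the recursion (so the water cycle feels them)."""
    saturate = site.mismatch.get("radiation_saturation", False)
    psens = site.mismatch.get("precip_sensitivity", False) and site.precip_sens > 0

    if not saturate and not psens:
        return None

    def perturb(day, gpp):
        if saturate:
            gpp = gpp / (1.0 + day["phi"] / site.phi_sat)
        if psens:
            gpp = gpp * np.exp(-site.precip_sens * day["R"])
        return gpp

    return perturb


def gen_flux_truth(
    covariates: pd.DataFrame, site: SiteSpec, seed: int, noise: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate (observed P, noise-free true P) for one site's covariates.

    The truth is the mini-model with site parameters plus the site's planted
    mismatch; observation noise is Gaussian with a floor plus a sqrt(P)
    component (heteroscedastic, near-Gaussian)."""
    rng = np.random.default_rng([seed + 1, zlib.crc32(site.site_id.encode()) % (2**31)])
    series = flux.run_pm(covariates, true_params(site), gpp_perturbation=mismatch_perturbation(site))
    p_true = np.asarray(ad.value_of(series.P), dtype=np.float64)
    if noise:
        sd = 0.05 + 0.08 * np.sqrt(np.maximum(p_true, 0.0))
        p_obs = p_true + rng.normal(0.0, 1.0, size=len(p_true)) * sd
    else:
        p_obs = p_true.copy()
    return p_obs, p_true


def make_dataset(sites: list[SiteSpec] | None = None, seed: int = 0, noise: bool = True):
    """Assemble the multi-site daily table (schema: site_id, date, year, doy,
    T, D, phi, R, fappfd, co2, P_obs, P_true) plus a manifest describing
    sites, seed and flags.  Deterministic per seed."""
    from .training import FluxDataset  # local import to avoid a cycle

    sites = sites if sites is not None else default_sites()
    frames = []
    for site in sites:
        cov = gen_climate(site, seed)
        p_obs, p_true = gen_flux_truth(cov, site, seed, noise=noise)
        cov["P_obs"] = p_obs
        cov["P_true"] = p_true
        frames.append(cov)
    df = pd.concat(frames, ignore_index=True)
    manifest = {
        "seed": seed,
        "noise": noise,
        "sites": [
            {
                "site_id": s.site_id,
                "years": list(s.years),
                "phenology": s.phenology,
                "precip_regime": s.precip_regime,
                "beta_offset": s.beta_offset,
                "precip_sens": s.precip_sens,
                "mismatch": s.mismatch,
            }
            for s in sites
        ],
    }
    return FluxDataset(df, has_observed_targets=True), manifest
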