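"""Predator-prey process models: differentiable Lotka-Volterra simulators.

Two variants of the classical predator-prey system are provided: a model
with a sigmoidal (type III) functional response, used as the data-generating
"truth", and a structurally simplified model with a linear (type I) feeding
rate, used as a deliberately mis-specified process model:

    type III:  dx/dt = r x - b x^2 y / (1 + s x^2)
               dy/dt = b x^2 y / (1 + s x^2) - m y

    type I:    dx/dt = r x - b x y
               dy/dt = b x y - m y

with prey density x, predator density y, prey growth rate r, feeding rate b,
predator mortality m and prey searching time s (type III only).

Integration is classical fixed-step RK4.  Numerics run through a numba fast
path when all inputs are plain numbers; when parameters or initial densities
are autodiff :class:`~pinneco.autodiff.Tensor` objects, the same scheme runs
on the tape so that gradients of any trajectory summary with respect to
parameters and initial conditions are available.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import _kernels
from . import autodiff as ad
from .autodiff import Tensor

TYPE_I = "typeI"
TYPE_III = "typeIII"

#: prior bounds used when calibrating LV parameters (rates are positive)
LV_BOUNDS = {
    "r": (0.01, 0.5),
    "b": (0.001, 0.2),
    "m": (0.005, 0.3),
    "s": (0.001, 0.2),
}


@dataclass
class LVParams:
    """Rates of the predator-prey system. ``s`` only for type III."""

    r: float
    b: float
    m: float
    s: float | None = None

    def __post_init__(self):
        for name in ("r", "b", "m"):
            v = getattr(self, name)
            if not isinstance(v, Tensor) and v < 0:
                raise ValueError(f"rate {name} must be >= 0, got {v}")
        if self.s is not None and not isinstance(self.s, Tensor) and self.s < 0:
            raise ValueError(f"searching time s must be >= 0, got {self.s}")

    def response(self) -> str:
        return TYPE_III if self.s is not None else TYPE_I

    def as_array(self) -> np.ndarray:
        return np.array([self.r, self.b, self.m, 0.0 if self.s is None else self.s])


@dataclass
class LVState:
    """Densities at a time point."""

    x: float
    y: float
    t: float = 0.0


@dataclass
class LVTrajectory:
    """Densities on a uniform time grid."""

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __len__(self):
        return len(self.times)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["t", "x", "y"])
            for t, x, y in zip(self.times, ad.value_of(self.x), ad.value_of(self.y)):
                w.writerow([t, x, y])

    @classmethod
    def from_csv(cls, path) -> "LVTrajectory":
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(times=arr[:, 0], x=arr[:, 1], y=arr[:, 2])


@dataclass
class ObservationSet:
    """Noisy prey readings at a subset of grid times."""

    times: np.ndarray
    x_obs: np.ndarray
    indices: np.ndarray  # positions on the trajectory grid

    def __len__(self):
        return len(self.times)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["t", "x_obs"])
            for t, x in zip(self.times, self.x_obs):
                w.writerow([t, x])


def _check_response(response: str) -> bool:
    if response not in (TYPE_I, TYPE_III):
        raise ValueError(f"response must be {TYPE_I!r} or {TYPE_III!r}, got {response!r}")
    return response == TYPE_III


def lv_rhs(x, y, r, b, m, s, type3: bool):
    """Right-hand side of the system; works on floats, arrays and Tensors."""
    if type3:
        u = x * x
        g = b * u * y / (1.0 + s * u)
    else:
        g = b * x * y
    return r * x - g, g - m * y


def lv_derivatives(state: LVState, params: LVParams, response: str):
    """(dx/dt, dy/dt) at ``state`` under the given functional response."""
    type3 = _check_response(response)
    for name, v in (("prey density x", state.x), ("predator density y", state.y)):
        if not isinstance(v, Tensor) and np.any(np.asarray(v) < 0):
            raise ValueError(f"negative {name}: {v}")
    if type3 and params.s is None:
        raise ValueError("type III response requires a searching time s")
    s = params.s if params.s is not None else 0.0
    return lv_rhs(state.x, state.y, params.r, params.b, params.m, s, type3)


def _is_plain(*values) -> bool:
    return not any(isinstance(v, Tensor) for v in values)


def integrate(
    params: LVParams,
    init: LVState,
    horizon: float,
    step: float,
    response: str,
    internal_step: float = 0.05,
) -> LVTrajectory:
    """Integrate the system over ``horizon`` and report on a grid of ``step``.

    RK4 runs internally at ``internal_step`` (sub-multiples of ``step``), and
    the solution is reported at the requested output spacing.  Raises if the
    state becomes non-finite, identifying the time of failure.
    """
    type3 = _check_response(response)
    if step <= 0:
        raise ValueError("step must be > 0")
    n_steps = horizon / step
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError(f"horizon {horizon} is not a multiple of step {step}")
    n_out = int(round(n_steps)) + 1
    substeps = max(1, int(round(step / internal_step)))
    times = np.arange(n_out) * step

    s = params.s if params.s is not None else 0.0
    if _is_plain(params.r, params.b, params.m, s, init.x, init.y):
        traj = _kernels.lv_rk4(
            np.array([[params.r, params.b, params.m, s]], dtype=np.float64),
            np.array([float(init.x)]),
            np.array([float(init.y)]),
            np.array([type3]),
            n_out,
            float(step),
            substeps,
        )[0]
        if not np.all(np.isfinite(traj)):
            bad = np.argmax(~np.isfinite(traj).all(axis=1))
            raise FloatingPointError(f"non-finite state at t={times[bad]:g}")
        return LVTrajectory(times=times, x=traj[:, 0], y=traj[:, 1])

    # autodiff path: same scheme on the tape
    h = step / substeps
    x, y = ad.as_tensor(init.x), ad.as_tensor(init.y)
    r, b, m = ad.as_tensor(params.r), ad.as_tensor(params.b), ad.as_tensor(params.m)
    s = ad.as_tensor(s)
    xs, ys = [x], [y]
    for k in range(1, n_out):
        for _ in range(substeps):
            k1x, k1y = lv_rhs(x, y, r, b, m, s, type3)
            k2x, k2y = lv_rhs(x + 0.5 * h * k1x, y + 0.5 * h * k1y, r, b, m, s, type3)
            k3x, k3y = lv_rhs(x + 0.5 * h * k2x, y + 0.5 * h * k2y, r, b, m, s, type3)
            k4x, k4y = lv_rhs(x + h * k3x, y + h * k3y, r, b, m, s, type3)
            x = x + (h / 6.0) * (k1x + 2.0 * k2x + 2.0 * k3x + k4x)
            y = y + (h / 6.0) * (k1y + 2.0 * k2y + 2.0 * k3y + k4y)
        if not (np.all(np.isfinite(ad.value_of(x))) and np.all(np.isfinite(ad.value_of(y)))):
            raise FloatingPointError(f"non-finite state at t={times[k]:g}")
        xs.append(x)
        ys.append(y)
    return LVTrajectory(times=times, x=ad.stack(xs), y=ad.stack(ys))


def observe(
    traj: LVTrajectory, n_obs: int, noise_sd: float, seed: int | np.random.Generator
) -> ObservationSet:
    """Draw prey readings at ``n_obs`` distinct grid times (uniform, without
    replacement), perturbed by centred Gaussian noise of sd ``noise_sd``.

    Negative readings produced by noise are kept as-is.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_obs > len(traj):
        raise ValueError(f"n_obs={n_obs} exceeds the {len(traj)} grid points")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(traj), size=n_obs, replace=False))
    x = ad.value_of(traj.x)[idx]
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, size=n_obs)
    return ObservationSet(times=traj.times[idx], x_obs=x, indices=idx)


def hamiltonian(x, y, params: LVParams):
    """Conserved quantity of the type I system along exact interior orbits:
    H(x, y) = b x + b y - m ln x - r ln y."""
    return params.b * x + params.b * y - params.m * np.log(x) - params.r * np.log(y)


# ----------------------------------------------------------------- config IO
@dataclass
class LVConfig:
    """A complete simulator configuration, serialisable to YAML."""

    params: LVParams
    init: LVState
    horizon: float
    step: float
    response: str
    seed: int | None = None

    def to_yaml(self, path) -> None:
        doc = {
            "params": {k: v for k, v in vars(self.params).items() if v is not None},
            "init": {"x": self.init.x, "y": self.init.y},
            "horizon": self.horizon,
            "step": self.step,
            "response": self.response,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(doc))

    @classmethod
    def from_yaml(cls, path) -> "LVConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(
            params=LVParams(**doc["params"]),
            init=LVState(x=doc["init"]["x"], y=doc["init"]["y"]),
            horizon=doc["horizon"],
            step=doc["step"],
            response=doc["response"],
            seed=doc.get("seed"),
        )

    def simulate(self, internal_step: float = 0.05) -> LVTrajectory:
        return integrate(self.params, self.init, self.horizon, self.step, self.response, internal_step)
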