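"""Hybrid model variants: how a neural network and a process model combine.

Six ways of using (or not using) process knowledge are implemented, each a
:class:`ModelVariant` bundling networks, an optional process-model handle and
a loss:

* ``pm`` - the calibrated process model alone;
* ``naive`` - a plain MLP from covariates to the target;
* ``bias_correction`` - an MLP from process-model outputs (P, E, theta) to
  the target;
* ``parallel_physics`` - an MLP trained on the residual; the prediction is
  network + process model;
* ``regularisation`` - an MLP whose loss adds a penalty
  ``lambda * MSE(y_phy, y_nn)`` tying predictions to the process model
  (the process model is *not* added at prediction time);
* ``domain_adaptation`` - a naive MLP pre-trained on simulator output and
  fine-tuned on observations (the protocol lives in
  :mod:`pinneco.training`);
* ``embedding`` - a parameter network feeds a differentiable process model
  whose outputs feed a bias-correction network; trained end-to-end with
  gradients flowing through the process model.

The losses are mean-squared errors (a linear last layer plus MSE is
regression under a normality assumption):

    parallel:     MSE(y, y_nn + y_phy)
    regularised:  MSE(y, y_nn) + lambda * MSE(y_phy, y_nn)
    embedding:    MSE(y, y_nn) + lambda * MSE(y, y_phy)

with lambda in [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from . import flux
from .autodiff import Tensor
from .nn import MLP, MLPSpec

VARIANT_KINDS = (
    "pm",
    "naive",
    "bias_correction",
    "parallel_physics",
    "regularisation",
    "domain_adaptation",
    "embedding",
)

#: variants whose network consumes environmental covariates X
_X_INPUT = {"naive", "parallel_physics", "regularisation", "domain_adaptation"}


@dataclass
class LossSpec:
    """Loss kind plus regularisation weight lambda (in [0, 1])."""

    kind: str = "mse"
    lam: float = 0.0

    def __post_init__(self):
        if self.kind not in ("mse", "parallel", "regularised", "embedding"):
            raise ValueError(f"unknown loss kind {self.kind!r}")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lambda must be in [0, 1], got {self.lam}")


def _coerce(x):
    return x if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)


def _mse(a, b):
    d = _coerce(a) - _coerce(b)
    if isinstance(d, Tensor):
        return (d * d).mean()
    return float(np.mean(d * d))


def loss_mse(y, y_nn):
    """Plain mean squared error."""
    _check_lengths(y, y_nn)
    return _mse(y, y_nn)


def loss_parallel(y, y_nn, y_phy):
    """Residual-learning loss: MSE(y, y_nn + y_phy)."""
    _check_lengths(y, y_nn, y_phy)
    return _mse(y, _coerce(y_nn) + _coerce(y_phy))


def loss_regularised(y, y_nn, y_phy, lam):
    """Data term plus lambda-weighted network/process consistency term."""
    _check_lengths(y, y_nn, y_phy)
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    return loss_mse(y, y_nn) + lam * _mse(y_phy, y_nn)


def loss_embedding(y, y_nn, y_phy, lam):
    """Joint loss of the embedding: both the bias-corrected output and the
    process-model output are pulled towards the observations."""
    _check_lengths(y, y_nn, y_phy)
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    return loss_mse(y, y_nn) + lam * _mse(y, y_phy)


def _check_lengths(*series):
    lengths = {len(ad.value_of(s)) for s in series}
    if len(lengths) > 1:
        raise ValueError(f"series length mismatch: {sorted(lengths)}")


# -------------------------------------------------------------------- scaler
@dataclass
class Standardizer:
    """Feature z-scoring with training-set statistics."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, x: np.ndarray) -> "Standardizer":
        x = np.asarray(x, dtype=np.float64)
        sd = x.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        return cls(mean=x.mean(axis=0), sd=sd)

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=np.float64) - self.mean) / self.sd


def covariate_features(df, cyclic_doy: bool = True) -> np.ndarray:
    """Design matrix from a daily table: T, D, phi, R, faPPFD, CO2 and the
    day of year, the latter as a (sin, cos) pair by default to remove the
    artificial discontinuity at year boundaries (set ``cyclic_doy=False`` to
    feed the integer day directly)."""
    base = np.column_stack([np.asarray(df[c], dtype=np.float64) for c in flux.COVARIATE_COLUMNS])
    doy = np.asarray(df["doy"], dtype=np.float64)
    if cyclic_doy:
        ang = 2.0 * np.pi * doy / 365.25
        return np.column_stack([base, np.sin(ang), np.cos(ang)])
    return np.column_stack([base, doy])


def n_features(cyclic_doy: bool = True) -> int:
    return len(flux.COVARIATE_COLUMNS) + (2 if cyclic_doy else 1)


# ------------------------------------------------------------------- variant
@dataclass
class ModelVariant:
    """A trained (or trainable) hybrid model."""

    kind: str
    networks: list = field(default_factory=list)
    pm_params: flux.PMParams | None = None
    loss: LossSpec = field(default_factory=LossSpec)
    scaler: Standardizer | None = None
    target_scaler: Standardizer | None = None
    cyclic_doy: bool = True

    def __post_init__(self):
        if self.kind not in VARIANT_KINDS:
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.kind == "embedding" and self.networks and len(self.networks) != 2:
            raise ValueError("embedding needs exactly two networks (parameter net, bias net)")

    # --------------------------------------------------------------- persist
    def save(self, path) -> None:
        doc = {
            "kind": self.kind,
            "loss": {"kind": self.loss.kind, "lam": self.loss.lam},
            "cyclic_doy": self.cyclic_doy,
            "networks": [n.state_dict() for n in self.networks],
            "scaler": None
            if self.scaler is None
            else {"mean": self.scaler.mean.tolist(), "sd": self.scaler.sd.tolist()},
            "target_scaler": None
            if self.target_scaler is None
            else {"mean": self.target_scaler.mean.tolist(), "sd": self.target_scaler.sd.tolist()},
            "pm_params": None
            if self.pm_params is None
            else {k: float(np.asarray(v)) for k, v in self.pm_params.values.items()},
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def load(cls, path) -> "ModelVariant":
        doc = json.loads(Path(path).read_text())
        return cls(
            kind=doc["kind"],
            networks=[MLP.from_state_dict(s) for s in doc["networks"]],
            pm_params=None if doc["pm_params"] is None else flux.PMParams(doc["pm_params"]),
            loss=LossSpec(**doc["loss"]),
            scaler=None
            if doc["scaler"] is None
            else Standardizer(np.asarray(doc["scaler"]["mean"]), np.asarray(doc["scaler"]["sd"])),
            target_scaler=None
            if doc["target_scaler"] is None
            else Standardizer(
                np.asarray(doc["target_scaler"]["mean"]), np.asarray(doc["target_scaler"]["sd"])
            ),
            cyclic_doy=doc["cyclic_doy"],
        )


def build_variant(
    kind: str,
    hidden=(32, 32),
    activation: str = "relu",
    lam: float = 0.0,
    pm_params: flux.PMParams | None = None,
    cyclic_doy: bool = True,
    rng: np.random.Generator | None = None,
) -> ModelVariant:
    """Construct an untrained variant with the appropriate network shapes."""
    rng = rng if rng is not None else np.random.default_rng(0)
    loss = {
        "parallel_physics": LossSpec("parallel", 0.0),
        "regularisation": LossSpec("regularised", lam),
        "embedding": LossSpec("embedding", lam),
    }.get(kind, LossSpec("mse", 0.0))
    nets: list[MLP] = []
    if kind in _X_INPUT:
        nets = [MLP(MLPSpec(n_features(cyclic_doy), tuple(hidden), 1, activation), rng=rng)]
    elif kind == "bias_correction":
        nets = [MLP(MLPSpec(3, tuple(hidden), 1, activation), rng=rng)]
    elif kind == "embedding":
        n_par = len(flux.PARAM_NAMES)
        nets = [
            MLP(MLPSpec(n_features(cyclic_doy), (32, 32), n_par, "relu"), rng=rng),
            MLP(MLPSpec(3, (32, 32), 1, "relu"), rng=rng),
        ]
    return ModelVariant(kind=kind, networks=nets, pm_params=pm_params, loss=loss, cyclic_doy=cyclic_doy)


# ---------------------------------------------------------------- embedding
def squash_to_bounds(raw, lo: np.ndarray, hi: np.ndarray):
    """Map unconstrained values into prior bounds via a scaled sigmoid."""
    return lo + (hi - lo) * ad.sigmoid(raw)


def embedding_forward(param_net: MLP, bias_net: MLP, df, pm_input_scaler: Standardizer | None = None,
                      cyclic_doy: bool = True, init: flux.FluxState | None = None):
    """Full forward pass of the physics embedding on one contiguous series.

    The parameter network maps (standardized) covariates to per-day raw
    parameter outputs; these are averaged over data points (evaluation batch
    = the full series) and squashed into the prior bounds, so the process
    model receives a single parameter vector tau-hat.  The model runs on the
    tape, its (P, E, theta) outputs feed the bias-correction network, and
    gradients reach the parameter network through the process model.

    Returns (y_nn, y_phy, tau_hat) as Tensors; y_phy is the P component.
    """
    x = covariate_features(df, cyclic_doy)
    scaler = pm_input_scaler if pm_input_scaler is not None else Standardizer.fit(x)
    raw = param_net(scaler.transform(x))  # (n, n_params)
    avg = raw.mean(axis=0)  # average over data points
    lo, hi = flux.prior_bounds()
    tau = squash_to_bounds(avg, lo, hi)
    params = flux.PMParams.from_array(tau)
    series = flux.run_pm(df, params, init=init)
    y_phy = series.P
    feats = ad.stack([series.P, series.E, series.theta], axis=1)  # (n, 3)
    # standardize on the tape so gradients see the normalisation too
    mu = feats.mean(axis=0, keepdims=True)
    centred = feats - mu
    sd = ad.sqrt((centred * centred).mean(axis=0, keepdims=True) + 1e-8)
    y_nn = bias_net(centred / sd)
    return y_nn.reshape(-1), y_phy, tau


# ------------------------------------------------------------------ predict
def predict(variant: ModelVariant, df, pm_outputs: np.ndarray | None = None) -> np.ndarray:
    """Predict the target for a daily table.

    ``pm_outputs``: (n, 3) array of process-model outputs (P, E, theta),
    required by bias_correction and parallel_physics (its P column is added
    to the network output).  Kinds naive / regularisation / domain_adaptation
    predict from covariates alone; ``pm`` returns the process-model P;
    ``embedding`` returns the bias-correction network output.
    """
    needs_pm = variant.kind in ("pm", "bias_correction", "parallel_physics")
    if needs_pm and pm_outputs is None:
        if variant.pm_params is None:
            raise ValueError(f"variant {variant.kind!r} needs pm_outputs or pm_params")
        out = flux.run_pm_sites(df, variant.pm_params)
        pm_outputs = out[["P_pm", "E_pm", "theta_pm"]].to_numpy()
    if variant.kind == "pm":
        return pm_outputs[:, 0]
    if variant.kind == "embedding":
        y_nn, _, _ = embedding_forward(
            variant.networks[0], variant.networks[1], df, variant.scaler, variant.cyclic_doy
        )
        return ad.value_of(y_nn)
    if variant.kind == "bias_correction":
        x = np.asarray(pm_outputs, dtype=np.float64)
    else:
        x = covariate_features(df, variant.cyclic_doy)
    if variant.scaler is not None:
        x = variant.scaler.transform(x)
    y = ad.value_of(variant.networks[0](x)).reshape(-1)
    if variant.target_scaler is not None:
        y = y * variant.target_scaler.sd[0] + variant.target_scaler.mean[0]
    if variant.kind == "parallel_physics":
        y = y + pm_outputs[:, 0]
    return y
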