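"""Training protocols: blocked cross-validation, sparse subsetting, random
hyper-parameter search, variant training and the two-phase domain-adaptation
protocol (simulator pre-training followed by fine-tuning on observations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc

from . import autodiff as ad
from . import flux, variants
from .nn import Adam
from .variants import ModelVariant, Standardizer, build_variant, covariate_features


@dataclass
class FluxDataset:
    """A daily table plus a taint flag marking whether its targets are real
    observations.  Simulator-generated pre-training data carries
    ``has_observed_targets=False``; the domain-adaptation phase-1 trainer
    refuses anything else."""

    df: pd.DataFrame
    has_observed_targets: bool = True

    def __len__(self):
        return len(self.df)


# ------------------------------------------------------------------ subsetting
def sparsify_weekly(df: pd.DataFrame, group: str | None = "site_id") -> pd.DataFrame:
    """Keep every 7th row starting at the first (one data point per week,
    systematically selected).  Applied per site when ``group`` is present."""
    if len(df) == 0:
        raise ValueError("empty input series")
    if group is not None and group in df.columns:
        parts = [sub.iloc[::7] for _, sub in df.groupby(group, sort=False)]
        return pd.concat(parts)
    return df.iloc[::7]


# ------------------------------------------------------------ cross-validation
BLOCKINGS = ("temporal_year", "spatial_site", "spatiotemporal")


@dataclass
class CVPlan:
    """Blocked cross-validation: one fold per held-out contiguous block
    (a full year, a whole site, or a site-year), test block excluded from
    every fold."""

    blocking: str
    folds: list  # list of (train_index, val_index) pandas indices
    test_index: object
    block_labels: list = field(default_factory=list)


def _blocks(df: pd.DataFrame, blocking: str) -> pd.Series:
    if blocking == "temporal_year":
        return df["year"].astype(str)
    if blocking == "spatial_site":
        return df["site_id"].astype(str)
    if blocking == "spatiotemporal":
        return df["site_id"].astype(str) + "/" + df["year"].astype(str)
    raise ValueError(f"unknown blocking {blocking!r}; choose from {BLOCKINGS}")


def make_cv_plan(df: pd.DataFrame, blocking: str, test_spec: dict) -> CVPlan:
    """Build a blocked CV plan.

    ``test_spec`` marks the held-out test block, e.g. ``{"year": 2008}`` or
    ``{"site_id": "site1"}`` (or both); matching rows never appear in any
    fold.
    """
    test_mask = np.ones(len(df), dtype=bool)
    for key, val in test_spec.items():
        test_mask &= (df[key] == val).to_numpy()
    work = df.loc[~test_mask]
    labels = _blocks(work, blocking)
    unique = list(dict.fromkeys(labels))
    if len(unique) < 2:
        raise ValueError(f"need at least 2 blocks for cross-validation, got {len(unique)}")
    folds = []
    for held in unique:
        val_idx = work.index[labels == held]
        train_idx = work.index[labels != held]
        folds.append((train_idx, val_idx))
    return CVPlan(blocking=blocking, folds=folds, test_index=df.index[test_mask], block_labels=unique)


def check_cv_plan(plan: CVPlan) -> None:
    """Invariants: folds partition the training blocks; the test block is
    absent from every fold; no row is in both train and validation."""
    test = set(plan.test_index)
    for train_idx, val_idx in plan.folds:
        if test & set(train_idx) or test & set(val_idx):
            raise ValueError("test block appears inside a cross-validation fold")
        if set(train_idx) & set(val_idx):
            raise ValueError("row appears in both train and validation of one fold")


# ------------------------------------------------------------- latin hypercube
def latin_hypercube(lo: np.ndarray, hi: np.ndarray, n: int, seed: int) -> np.ndarray:
    """n stratified draws per parameter over [lo, hi]: one draw per
    equal-probability stratum in every dimension."""
    lo, hi = np.asarray(lo, dtype=np.float64), np.asarray(hi, dtype=np.float64)
    sampler = qmc.LatinHypercube(d=len(lo), seed=seed)
    u = sampler.random(n)
    return lo + u * (hi - lo)


# ------------------------------------------------------------ variant training
@dataclass
class TrainResult:
    variant: ModelVariant
    loss_curve: np.ndarray
    val_curve: np.ndarray | None = None


_PM_COLS = ("P_pm", "E_pm", "theta_pm")


def _needs_pm_columns(kind: str) -> bool:
    return kind in ("bias_correction", "parallel_physics", "regularisation")


def train_variant(
    variant: ModelVariant,
    df_train: pd.DataFrame,
    epochs: int,
    lr: float,
    seed: int = 0,
    df_val: pd.DataFrame | None = None,
    daily_df: pd.DataFrame | None = None,
    train_mask: np.ndarray | None = None,
    target_col: str = "P_obs",
) -> TrainResult:
    """Train a variant full-batch with Adam for a fixed number of epochs.

    Process-model-consuming variants expect the calibrated model's outputs
    (columns P_pm, E_pm, theta_pm) to be present in ``df_train`` -- they are
    computed once on the full contiguous daily table (see
    :func:`pinneco.flux.run_pm_sites`) so sparse subsetting cannot break the
    water-balance recursion.  The embedding variant instead needs the full
    ``daily_df`` plus a ``train_mask`` selecting the rows that carry
    training targets, because its process model runs inside the forward
    pass.  No early stopping: the epoch budget is fixed and the loss curve
    is returned for inspection.

    ``seed`` is reserved for stochastic training modes (mini-batching); the
    default full-batch training is deterministic given the variant's
    initialisation, so identical inputs give bit-identical results.
    """
    if not np.all(np.isfinite(df_train[target_col].to_numpy())):
        raise ValueError("non-finite training targets")
    if variant.kind == "embedding":
        return _train_embedding(variant, daily_df, train_mask, epochs, lr, target_col)
    if _needs_pm_columns(variant.kind):
        missing = [c for c in _PM_COLS if c not in df_train.columns]
        if missing:
            raise ValueError(f"{variant.kind} training needs process-model columns {missing}")

    y = df_train[target_col].to_numpy(dtype=np.float64)
    if variant.kind == "bias_correction":
        x = df_train[list(_PM_COLS)].to_numpy(dtype=np.float64)
    else:
        x = covariate_features(df_train, variant.cyclic_doy)
    variant.scaler = Standardizer.fit(x)
    xs = variant.scaler.transform(x)

    if variant.kind == "parallel_physics":
        target = y - df_train["P_pm"].to_numpy(dtype=np.float64)
    else:
        target = y
    variant.target_scaler = Standardizer.fit(target.reshape(-1, 1))
    t_std = variant.target_scaler.transform(target.reshape(-1, 1)).reshape(-1)

    y_phy_std = None
    if variant.kind == "regularisation":
        y_phy_std = variant.target_scaler.transform(
            df_train["P_pm"].to_numpy(dtype=np.float64).reshape(-1, 1)
        ).reshape(-1)

    net = variant.networks[0]
    opt = Adam(net.parameters, lr=lr)
    curve = np.empty(epochs)
    val_curve = None
    lam = variant.loss.lam
    for ep in range(epochs):
        opt.zero_grad()
        pred = net(xs).reshape(-1)
        if variant.kind == "regularisation":
            loss = variants.loss_regularised(t_std, pred, y_phy_std, lam)
        else:
            loss = variants.loss_mse(t_std, pred)
        loss.backward()
        opt.step()
        curve[ep] = loss.item()
        if not np.isfinite(curve[ep]):
            raise FloatingPointError(f"non-finite training loss at epoch {ep}")
    if df_val is not None:
        pm_val = df_val[list(_PM_COLS)].to_numpy() if _needs_pm_columns(variant.kind) or variant.kind == "pm" else None
        pred = variants.predict(variant, df_val, pm_outputs=pm_val)
        val_curve = np.array([float(np.mean((df_val[target_col].to_numpy() - pred) ** 2))])
    return TrainResult(variant=variant, loss_curve=curve, val_curve=val_curve)


def _train_embedding(variant, daily_df, train_mask, epochs, lr, target_col):
    if daily_df is None:
        raise ValueError("embedding training needs the full daily table (daily_df)")
    mask = np.ones(len(daily_df), dtype=bool) if train_mask is None else np.asarray(train_mask, dtype=bool)
    x_all = covariate_features(daily_df, variant.cyclic_doy)
    variant.scaler = Standardizer.fit(x_all[mask])
    # positions of each site's rows in the original frame, for mask alignment
    site_rows = [np.flatnonzero((daily_df["site_id"] == s).to_numpy()) for s in daily_df["site_id"].unique()]
    subs = [daily_df.iloc[rows] for rows in site_rows]
    masks = [mask[rows] for rows in site_rows]
    param_net, bias_net = variant.networks
    opt = Adam([*param_net.parameters, *bias_net.parameters], lr=lr)
    lam = variant.loss.lam
    curve = np.empty(epochs)
    for ep in range(epochs):
        opt.zero_grad()
        total = None
        for sub, msk in zip(subs, masks):
            if not msk.any():
                continue
            y = sub.loc[msk, target_col].to_numpy(dtype=np.float64)
            y_nn, y_phy, _ = variants.embedding_forward(
                param_net, bias_net, sub, variant.scaler, variant.cyclic_doy
            )
            idx = np.flatnonzero(msk)
            loss = variants.loss_embedding(y, y_nn[idx], y_phy[idx], lam)
            total = loss if total is None else total + loss
        total.backward()
        opt.step()
        curve[ep] = total.item()
        if not np.isfinite(curve[ep]):
            raise FloatingPointError(f"non-finite training loss at epoch {ep}")
    return TrainResult(variant=variant, loss_curve=curve)


# ------------------------------------------------------------- random search
@dataclass
class SearchSpace:
    """Ranges of the combined random grid search: architectures and
    optimisation parameters are drawn jointly and each combination is scored
    by mean validation MSE across folds."""

    n_layers: tuple = (1, 2)
    width: tuple = (16, 64)
    log10_lr: tuple = (-3.5, -2.0)
    batch_sizes: tuple = ("full",)
    lam: tuple | None = None  # sampled only for the regularisation variant
    n_draws: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")

    def sample(self, rng: np.random.Generator) -> dict:
        n_layers = int(rng.integers(self.n_layers[0], self.n_layers[1] + 1))
        width = int(rng.integers(self.width[0], self.width[1] + 1))
        cand = {
            "hidden": tuple([width] * n_layers),
            "lr": float(10.0 ** rng.uniform(*self.log10_lr)),
            "batch_size": self.batch_sizes[int(rng.integers(len(self.batch_sizes)))],
        }
        if self.lam is not None:
            cand["lam"] = float(rng.uniform(*self.lam))
        return cand


def random_search(
    space: SearchSpace,
    kind: str,
    df: pd.DataFrame,
    plan: CVPlan,
    epochs: int = 500,
    evaluator=None,
    pm_params: flux.PMParams | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Draw ``space.n_draws`` candidates, score each by mean validation MSE
    over the folds of ``plan``, and return (best candidate, full log).

    ``evaluator(candidate, train_df, val_df) -> float`` may replace the
    default train-and-score routine (e.g. for testing the selection logic).
    """
    rng = np.random.default_rng(space.seed)
    candidates = [space.sample(rng) for _ in range(space.n_draws)]

    def default_eval(cand, train_df, val_df):
        variant = build_variant(
            kind,
            hidden=cand["hidden"],
            lam=cand.get("lam", 0.0),
            pm_params=pm_params,
            rng=np.random.default_rng(space.seed),
        )
        train_variant(variant, train_df, epochs=epochs, lr=cand["lr"], df_val=val_df)
        pm_val = val_df[list(_PM_COLS)].to_numpy() if _needs_pm_columns(kind) else None
        pred = variants.predict(variant, val_df, pm_outputs=pm_val)
        return float(np.mean((val_df["P_obs"].to_numpy() - pred) ** 2))

    evaluator = evaluator if evaluator is not None else default_eval
    rows = []
    for i, cand in enumerate(candidates):
        scores = []
        for train_idx, val_idx in plan.folds:
            scores.append(evaluator(cand, df.loc[train_idx], df.loc[val_idx]))
        rows.append({"candidate": i, **{k: str(v) for k, v in cand.items()}, "val_mse": float(np.mean(scores))})
    log = pd.DataFrame(rows)
    if not np.isfinite(log["val_mse"]).any():
        raise FloatingPointError("all random-search candidates diverged (non-finite loss)")
    best = candidates[int(log["val_mse"].idxmin())]
    return best, log


# --------------------------------------------------------- domain adaptation
@dataclass
class AdaptationPlan:
    """Two-phase protocol: Latin-hypercube draws of process-model parameters
    drive simulations on surrogate covariates (phase 1, pre-training an
    emulator), then the network is re-trained on the observations (phase 2).
    The network input layout is identical in both phases; parameter draws are
    not inputs."""

    n_prior_samples: int = 40
    surrogate_harmonics: int = 3
    pretrain_epochs: int = 400
    pretrain_lr: float = 3e-3
    finetune_epochs: int = 400
    finetune_lr: float = 1e-3
    seed: int = 0
    #: keep every k-th simulated day in the pooled pre-training set (the
    #: simulation itself always runs daily); use 7 to mirror a weekly
    #: observation schedule and bound the pre-training cost
    pretrain_stride: int = 1


def _harmonic_design(doy: np.ndarray, n_harmonics: int) -> np.ndarray:
    ang = 2.0 * np.pi * doy / 365.25
    return np.column_stack(
        [np.ones_like(ang)]
        + [f(k * ang) for k in range(1, n_harmonics + 1) for f in (np.sin, np.cos)]
    )


def harmonic_surrogate(
    df: pd.DataFrame,
    n_harmonics: int = 3,
    rng: np.random.Generator | None = None,
    template: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Smooth-seasonal covariate surrogate: per covariate, harmonic (Fourier)
    regression on the day of year with ``n_harmonics`` annual harmonics,
    plus residual bootstrap noise.  Physical ranges are re-imposed
    (faPPFD in [0,1]; phi, R, D >= 0).

    The regression is fitted on ``df`` (which may be sparse) and evaluated on
    ``template`` (default: ``df`` itself), so simulations can cover a full
    daily grid even when observations are weekly."""
    rng = rng if rng is not None else np.random.default_rng(0)
    template = df if template is None else template
    design_fit = _harmonic_design(df["doy"].to_numpy(dtype=np.float64), n_harmonics)
    design_out = _harmonic_design(template["doy"].to_numpy(dtype=np.float64), n_harmonics)
    out = template.copy()
    for col in ("T", "D", "phi", "R", "fappfd"):
        y = df[col].to_numpy(dtype=np.float64)
        coef, *_ = np.linalg.lstsq(design_fit, y, rcond=None)
        resid = y - design_fit @ coef
        sim = design_out @ coef + rng.choice(resid, size=len(template), replace=True)
        if col == "fappfd":
            sim = np.clip(sim, 0.0, 1.0)
        elif col in ("phi", "R", "D"):
            sim = np.clip(sim, 0.0, None)
        out[col] = sim
    return out


def iter_contiguous(df: pd.DataFrame):
    """Yield sub-frames that are contiguous daily runs (split per site and at
    date gaps), so the water-balance recursion never straddles a hole."""
    for _, sub in df.groupby("site_id", sort=False) if "site_id" in df.columns else [(None, df)]:
        dates = pd.to_datetime(sub["date"])
        breaks = np.flatnonzero(dates.diff().dt.days.to_numpy()[1:] != 1) + 1
        start = 0
        for stop in [*breaks, len(sub)]:
            yield sub.iloc[start:stop]
            start = stop


def domain_adapt(
    plan: AdaptationPlan,
    observations: FluxDataset,
    daily_template: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ModelVariant, dict]:
    """Run the two-phase domain-adaptation protocol and return the trained
    variant plus a log with both loss curves.

    Phase 1 simulates (X_SIM, y_SIM): for each Latin-hypercube draw of the
    process-model parameters, the surrogate generates one covariate series
    (per site) and the process model simulates the target; the pooled
    simulations pre-train a naive-architecture network.  Phase 1 never reads
    observed targets (asserted through the dataset taint flag).  Phase 2
    fine-tunes on the observations with the phase-1 feature scaling.

    ``daily_template`` (optional) is a contiguous daily covariate table the
    surrogate is evaluated on, so simulations run on a full daily grid even
    when the observations are sparse.
    """
    rng = rng if rng is not None else np.random.default_rng(plan.seed)
    obs_df = observations.df
    lo, hi = flux.prior_bounds()
    taus = latin_hypercube(lo, hi, plan.n_prior_samples, seed=int(rng.integers(2**31 - 1)))

    template = daily_template if daily_template is not None else obs_df
    site_pairs = []
    for site, sub in obs_df.groupby("site_id", sort=False):
        tmpl_site = template[template["site_id"] == site]
        for chunk in iter_contiguous(tmpl_site):
            site_pairs.append((sub, chunk))

    sims = []
    for i in range(plan.n_prior_samples):
        params = flux.PMParams.from_array(taus[i])
        for sub, chunk in site_pairs:
            xsim = harmonic_surrogate(sub, plan.surrogate_harmonics, rng, template=chunk)
            series = flux.run_pm(xsim, params)
            frame = xsim.copy()
            frame["P_obs"] = ad.value_of(series.P)
            if plan.pretrain_stride > 1:
                frame = frame.iloc[:: plan.pretrain_stride]
            sims.append(frame)
    pretrain = FluxDataset(pd.concat(sims, ignore_index=True), has_observed_targets=False)
    assert not pretrain.has_observed_targets, "phase 1 must train on simulated targets only"

    variant = build_variant("domain_adaptation", rng=rng)
    if plan.pretrain_epochs > 0:
        res1 = train_variant(variant, pretrain.df, epochs=plan.pretrain_epochs, lr=plan.pretrain_lr)
        curve1 = res1.loss_curve
    else:  # pragma: no cover - degenerate budget
        curve1 = np.array([])

    # phase 2: keep phase-1 scalers, continue on real observations
    curve2 = np.array([])
    if plan.finetune_epochs > 0:
        if not observations.has_observed_targets:
            raise ValueError("phase 2 expects a dataset with observed targets")
        x = covariate_features(obs_df, variant.cyclic_doy)
        xs = variant.scaler.transform(x)
        t_std = variant.target_scaler.transform(
            obs_df["P_obs"].to_numpy(dtype=np.float64).reshape(-1, 1)
        ).reshape(-1)
        net = variant.networks[0]
        opt = Adam(net.parameters, lr=plan.finetune_lr)
        curve2 = np.empty(plan.finetune_epochs)
        for ep in range(plan.finetune_epochs):
            opt.zero_grad()
            loss = variants.loss_mse(t_std, net(xs).reshape(-1))
            loss.backward()
            opt.step()
            curve2[ep] = loss.item()
    return variant, {"pretrain_curve": curve1, "finetune_curve": curve2, "n_sim_rows": len(pretrain.df)}
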