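"""Training protocols: weekly sparsification, blocked CV mechanics, Latin
hypercube stratification, the random search, variant training and the
two-phase domain-adaptation protocol."""

import numpy as np
import pandas as pd
import pytest

from pinneco import flux, variants
from pinneco.training import (
    AdaptationPlan,
    FluxDataset,
    SearchSpace,
    check_cv_plan,
    domain_adapt,
    harmonic_surrogate,
    latin_hypercube,
    make_cv_plan,
    random_search,
    sparsify_weekly,
    train_variant,
)


def _series(n, site="s1", start="2006-01-01"):
    dates = pd.date_range(start, periods=n, freq="D")
    return pd.DataFrame(
        {
            "site_id": site,
            "date": dates.strftime("%Y-%m-%d"),
            "year": dates.year,
            "doy": dates.dayofyear,
        }
    )


class TestSparsify:
    @pytest.mark.parametrize("n,expected", [(28, 4), (365, 53), (6, 1)])
    def test_weekly_row_counts(self, n, expected):
        out = sparsify_weekly(_series(n))
        assert len(out) == expected

    def test_selected_days_are_1_8_15(self):
        out = sparsify_weekly(_series(365))
        assert list(out["doy"].iloc[:4]) == [1, 8, 15, 22]
        assert out["doy"].iloc[-1] == 365

    def test_applied_per_site(self):
        df = pd.concat([_series(28, "a"), _series(21, "b")], ignore_index=True)
        out = sparsify_weekly(df)
        assert (out["site_id"] == "a").sum() == 4
        assert (out["site_id"] == "b").sum() == 3

    def test_double_stride_composes_to_49(self):
        df = _series(365)
        twice = sparsify_weekly(sparsify_weekly(df), group=None)
        stride49 = df.iloc[::49]
        assert list(twice["doy"]) == list(stride49["doy"])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sparsify_weekly(_series(365).iloc[:0])


@pytest.fixture(scope="module")
def df():
    frames = []
    for site in ("s1", "s2", "s3", "s4"):
        for year in (2005, 2006, 2007, 2008, 2009):
            frames.append(_series(10, site, f"{year}-03-01"))
    return pd.concat(frames, ignore_index=True)


class TestCVPlans:
    def test_temporal_blocking_one_fold_per_year(self, df):
        plan = make_cv_plan(df, "temporal_year", {"year": 2008})
        assert len(plan.folds) == 4  # 2005, 2006, 2007, 2009
        check_cv_plan(plan)
        for train_idx, val_idx in plan.folds:
            assert df.loc[val_idx, "year"].nunique() == 1

    def test_spatial_blocking_one_fold_per_site(self, df):
        plan = make_cv_plan(df, "spatial_site", {"site_id": "s1"})
        assert len(plan.folds) == 3
        check_cv_plan(plan)

    def test_test_year_absent_from_every_fold(self, df):
        plan = make_cv_plan(df, "temporal_year", {"year": 2008})
        for train_idx, val_idx in plan.folds:
            assert not (df.loc[train_idx, "year"] == 2008).any()
            assert not (df.loc[val_idx, "year"] == 2008).any()

    def test_folds_partition_training_blocks(self, df):
        plan = make_cv_plan(df, "spatiotemporal", {"year": 2008})
        val_union = set()
        for _, val_idx in plan.folds:
            assert not val_union & set(val_idx)
            val_union |= set(val_idx)
        assert val_union == set(df.index[df["year"] != 2008])

    def test_too_few_blocks_raise(self, df):
        one_year = df[df["year"] == 2005]
        with pytest.raises(ValueError, match="at least 2"):
            make_cv_plan(one_year, "temporal_year", {"year": 2008})

    def test_corrupted_plan_detected(self, df):
        plan = make_cv_plan(df, "temporal_year", {"year": 2008})
        plan.folds[0] = (plan.folds[0][0].append(plan.test_index[:1]), plan.folds[0][1])
        with pytest.raises(ValueError, match="test block"):
            check_cv_plan(plan)


class TestLatinHypercube:
    def test_one_draw_per_stratum_in_every_dimension(self):
        lo, hi = flux.prior_bounds()
        n = 16
        draws = latin_hypercube(lo, hi, n, seed=5)
        assert draws.shape == (n, len(lo))
        unit = (draws - lo) / (hi - lo)
        for j in range(unit.shape[1]):
            strata = np.floor(unit[:, j] * n).astype(int)
            assert sorted(strata) == list(range(n))

    def test_draws_respect_bounds(self):
        lo, hi = np.array([0.0, -5.0]), np.array([1.0, 5.0])
        draws = latin_hypercube(lo, hi, 50, seed=1)
        assert np.all(draws >= lo) and np.all(draws <= hi)


class TestTrainVariant:
    def test_zero_learning_rate_changes_nothing(self, single_site_dataset, rng):
        df = flux.run_pm_sites(single_site_dataset.df.iloc[:120], flux.PMParams.defaults())
        variant = variants.build_variant("naive", rng=rng)
        before = [w.value.copy() for w in variant.networks[0].weights]
        result = train_variant(variant, df, epochs=20, lr=0.0)
        for b, w in zip(before, variant.networks[0].weights):
            np.testing.assert_array_equal(b, w.value)
        assert np.ptp(result.loss_curve) == 0.0

    def test_linear_target_is_learned_to_near_zero_loss(self, single_site_dataset, rng):
        df = single_site_dataset.df.iloc[:200].copy()
        x = variants.covariate_features(df)
        df["P_obs"] = x @ np.linspace(0.1, 0.4, x.shape[1])  # linear in features
        variant = variants.build_variant("naive", hidden=(16,), rng=rng)
        result = train_variant(variant, df, epochs=1200, lr=5e-3)
        assert result.loss_curve[-1] < 1e-3
        assert result.loss_curve[-1] < result.loss_curve[0] / 100

    def test_same_seed_reproduces_final_loss_bitwise(self, single_site_dataset):
        df = flux.run_pm_sites(single_site_dataset.df.iloc[:120], flux.PMParams.defaults())
        losses = []
        for _ in range(2):
            variant = variants.build_variant("parallel_physics", rng=np.random.default_rng(9))
            res = train_variant(variant, df, epochs=50, lr=1e-3)
            losses.append(res.loss_curve[-1])
        assert losses[0] == losses[1]

    def test_pm_columns_required_for_hybrids(self, single_site_dataset, rng):
        df = single_site_dataset.df.iloc[:60]
        variant = variants.build_variant("parallel_physics", rng=rng)
        with pytest.raises(ValueError, match="P_pm"):
            train_variant(variant, df, epochs=5, lr=1e-3)

    def test_nonfinite_targets_rejected(self, single_site_dataset, rng):
        df = single_site_dataset.df.iloc[:60].copy()
        df.loc[df.index[3], "P_obs"] = np.nan
        variant = variants.build_variant("naive", rng=rng)
        with pytest.raises(ValueError, match="non-finite"):
            train_variant(variant, df, epochs=5, lr=1e-3)


class TestRandomSearch:
    def _plan(self, df):
        return make_cv_plan(df, "temporal_year", {"year": 2008})

    def test_single_draw_is_returned(self, single_site_dataset):
        df = single_site_dataset.df
        space = SearchSpace(n_draws=1, seed=0)
        best, log = random_search(
            space, "naive", df, self._plan(df), evaluator=lambda c, tr, va: 1.0
        )
        assert len(log) == 1
        assert best["hidden"]

    def test_identical_candidates_score_identically(self, single_site_dataset):
        df = single_site_dataset.df
        space = SearchSpace(n_draws=3, seed=4)
        calls = []

        def stub(cand, tr, va):
            calls.append(cand)
            return float(len(str(cand)))  # deterministic function of candidate

        _, log = random_search(space, "naive", df, self._plan(df), evaluator=stub)
        # same candidate dict -> same recorded score
        scores = dict(zip(log["hidden"].astype(str) + log["lr"].astype(str), log["val_mse"]))
        for _, row in log.iterrows():
            assert scores[str(row["hidden"]) + str(row["lr"])] == row["val_mse"]

    def test_planted_optimum_is_selected(self, single_site_dataset):
        df = single_site_dataset.df
        space = SearchSpace(n_draws=5, seed=2)
        rng = np.random.default_rng(3)
        winner = {}

        def stub(cand, tr, va):
            if not winner:
                winner["pick"] = cand["lr"]  # first candidate evaluated wins
            return 0.0 if cand["lr"] == winner["pick"] else float(rng.uniform(1, 2))

        best, log = random_search(space, "naive", df, self._plan(df), evaluator=stub)
        assert best["lr"] == winner["pick"]
        assert log["val_mse"].min() == 0.0

    def test_lambda_sampled_only_when_requested(self):
        space = SearchSpace(n_draws=1, seed=0, lam=(0.0, 1.0))
        cand = space.sample(np.random.default_rng(0))
        assert 0.0 <= cand["lam"] <= 1.0
        cand2 = SearchSpace(n_draws=1, seed=0).sample(np.random.default_rng(0))
        assert "lam" not in cand2


class TestDomainAdaptation:
    def test_phase1_never_touches_observed_targets(self, single_site_dataset, rng):
        """The pre-training dataset is simulator output by construction; the
        protocol rejects fine-tuning data that claims to be simulated."""
        obs = FluxDataset(single_site_dataset.df.iloc[:150].copy(), has_observed_targets=False)
        plan = AdaptationPlan(n_prior_samples=3, pretrain_epochs=5, finetune_epochs=5, seed=0)
        with pytest.raises(ValueError, match="observed targets"):
            domain_adapt(plan, obs, rng=rng)

    def test_zero_finetune_epochs_returns_pure_emulator(self, single_site_dataset, rng):
        obs = FluxDataset(single_site_dataset.df.iloc[:150].copy())
        plan = AdaptationPlan(n_prior_samples=3, pretrain_epochs=10, finetune_epochs=0, seed=0)
        variant, log = domain_adapt(plan, obs, rng=rng)
        assert len(log["finetune_curve"]) == 0
        assert len(log["pretrain_curve"]) == 10
        assert log["n_sim_rows"] == 3 * 150

    def test_emulator_improves_with_more_prior_samples(self, single_site_dataset):
        """Median over seeds: an emulator pre-trained on 40 hypercube draws
        predicts fresh simulator output better than one trained on 4."""
        obs_df = single_site_dataset.df.iloc[:365].copy()
        lo, hi = flux.prior_bounds()
        errs = {4: [], 40: []}
        for seed in range(3):
            fresh_tau = latin_hypercube(lo, hi, 5, seed=100 + seed)
            fresh_frames = []
            for tau in fresh_tau:
                params = flux.PMParams.from_array(tau)
                frame = obs_df.copy()
                frame["P_obs"] = np.asarray(flux.run_pm(frame, params).P)
                fresh_frames.append(frame)
            fresh = pd.concat(fresh_frames, ignore_index=True)
            for n in errs:
                plan = AdaptationPlan(
                    n_prior_samples=n, pretrain_epochs=300, finetune_epochs=0, seed=seed
                )
                variant, _ = domain_adapt(
                    plan, FluxDataset(obs_df), rng=np.random.default_rng(seed)
                )
                pred = variants.predict(variant, fresh)
                errs[n].append(float(np.mean((fresh["P_obs"].to_numpy() - pred) ** 2)))
        assert np.median(errs[40]) < np.median(errs[4])

    def test_finetuning_fits_observations_better_than_emulator(self, single_site_dataset):
        obs_df = single_site_dataset.df.iloc[:365].copy()
        gains = []
        for seed in range(3):
            plan0 = AdaptationPlan(n_prior_samples=8, pretrain_epochs=200, finetune_epochs=0, seed=seed)
            plan1 = AdaptationPlan(
                n_prior_samples=8, pretrain_epochs=200, finetune_epochs=200, seed=seed
            )
            y = obs_df["P_obs"].to_numpy()
            em, _ = domain_adapt(plan0, FluxDataset(obs_df), rng=np.random.default_rng(seed))
            ft, _ = domain_adapt(plan1, FluxDataset(obs_df), rng=np.random.default_rng(seed))
            mse_em = float(np.mean((y - variants.predict(em, obs_df)) ** 2))
            mse_ft = float(np.mean((y - variants.predict(ft, obs_df)) ** 2))
            gains.append(mse_em - mse_ft)
        assert np.median(gains) > 0

    def test_surrogate_respects_physical_ranges(self, single_site_dataset, rng):
        sim = harmonic_surrogate(single_site_dataset.df, rng=rng)
        assert sim["fappfd"].between(0, 1).all()
        assert (sim["phi"] >= 0).all()
        assert (sim["R"] >= 0).all()
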