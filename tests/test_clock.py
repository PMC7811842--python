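import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import rnaclock as rc
from rnaclock.clock import CVResult, ClockModel
from rnaclock.errors import (
    GeneMismatchError,
    PreconditionError,
    ValidationError,
)
from rnaclock.normalize import NormalizedMatrix

from ._oracles import one_se_oracle


class TestMtryGrid:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (1000, [2, 9, 44, 211, 1000]),
            (100, [2, 26, 51, 75, 100]),
            (2, [2]),
            (3, [2, 3]),
        ],
    )
    def test_printed_grids_and_degenerate_cases(self, p, expected):
        assert rc.mtry_grid(p, 5) == expected

    def test_too_few_features_rejected(self):
        with pytest.raises(PreconditionError):
            rc.mtry_grid(1)

    @given(st.integers(min_value=2, max_value=5000), st.integers(min_value=1, max_value=8))
    def test_grid_is_ascending_within_bounds(self, p, length):
        grid = rc.mtry_grid(p, length)
        assert grid == sorted(set(grid))
        assert grid[0] >= 1 and grid[-1] <= p


def _cv_table(mtrys, rmses, ses):
    return pd.DataFrame(
        {
            "mean_rmse": rmses,
            "se_rmse": ses,
            "mean_r2": 0.5,
            "mean_mae": rmses,
        },
        index=pd.Index(mtrys, name="mtry"),
    )


class TestOneSeRule:
    def test_single_candidate(self):
        assert rc.select_one_se(_cv_table([44], [5.0], [0.3])) == 44

    def test_simplest_within_one_se_chosen(self):
        # best RMSE 5.0 at mtry 44 with SE 0.1; mtry 2 at 5.05 is within 5.1
        table = _cv_table([2, 44, 211], [5.05, 5.0, 6.0], [0.2, 0.1, 0.1])
        assert rc.select_one_se(table) == 2

    def test_all_within_one_se_gives_smallest(self):
        table = _cv_table([2, 9, 44], [5.01, 5.0, 5.02], [0.5, 0.5, 0.5])
        assert rc.select_one_se(table) == 2

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=1, max_value=30),
                st.floats(min_value=0, max_value=3),
            ),
            min_size=1,
            max_size=8,
        )
    )
    def test_matches_bruteforce_and_never_exceeds_threshold(self, rows):
        mtrys = list(range(2, 2 + len(rows)))
        rmses = [r for r, _ in rows]
        ses = [s for _, s in rows]
        table = _cv_table(mtrys, rmses, ses)
        chosen = rc.select_one_se(table)
        assert chosen == one_se_oracle(mtrys, rmses, ses)
        best = int(np.argmin(rmses))
        assert table.loc[chosen, "mean_rmse"] <= rmses[best] + ses[best]


@pytest.fixture(scope="module")
def trained(small_cohort_module):
    corrected, meta = small_cohort_module
    genes = rc.top_variable_genes(corrected, 40)
    model = rc.train_clock(
        corrected, meta["age"], gene_set=genes, folds=5, repeats=2, trees=60, seed=11
    )
    return model, corrected, meta


@pytest.fixture(scope="module")
def small_cohort_module():
    cfg = rc.SimulationConfig(
        n_batches=4,
        samples_per_batch=25,
        n_genes=150,
        n_age_genes=60,
        age_slope_sd=0.025,
        batch_shift_sd=0.5,
        seed=13,
    )
    counts, meta, _ = rc.simulate_cohort(cfg)
    f = rc.tmm_factors(counts)
    corrected, _ = rc.fit_combat(rc.normalize_log2(counts, f), meta)
    return corrected, meta


class TestTrainClock:
    def test_deterministic_under_fixed_seed(self, small_cohort_module):
        corrected, meta = small_cohort_module
        genes = rc.top_variable_genes(corrected, 20)
        kw = dict(gene_set=genes, folds=5, repeats=1, trees=40, seed=3)
        m1 = rc.train_clock(corrected, meta["age"], **kw)
        m2 = rc.train_clock(corrected, meta["age"], **kw)
        pd.testing.assert_frame_equal(m1.cv.table, m2.cv.table)
        p1 = rc.predict_age(m1, corrected)
        p2 = rc.predict_age(m2, corrected)
        np.testing.assert_array_equal(p1.to_numpy(), p2.to_numpy())

    def test_fewer_samples_than_folds_rejected(self, small_cohort_module):
        corrected, meta = small_cohort_module
        few = corrected.values.iloc[:, :5]
        with pytest.raises(PreconditionError, match="folds"):
            rc.train_clock(few, meta["age"].iloc[:5], folds=10)

    def test_constant_ages_rejected(self, small_cohort_module):
        corrected, meta = small_cohort_module
        ages = pd.Series(50.0, index=meta.index)
        with pytest.raises(PreconditionError, match="constant"):
            rc.train_clock(corrected, ages, folds=5)

    def test_ages_out_of_range_rejected(self, small_cohort_module):
        corrected, meta = small_cohort_module
        ages = meta["age"].copy()
        ages.iloc[0] = 150.0
        with pytest.raises(ValidationError):
            rc.train_clock(corrected, ages, folds=5)

    def test_constant_gene_dropped_with_warning(self, small_cohort_module):
        corrected, meta = small_cohort_module
        vals = corrected.values.copy()
        vals.iloc[0, :] = 5.0
        flat = NormalizedMatrix(values=vals, provenance="batch_corrected")
        with pytest.warns(UserWarning, match="constant gene"):
            model = rc.train_clock(
                flat, meta["age"], folds=5, repeats=1, trees=20, seed=1,
                grid=[2],
            )
        assert vals.index[0] not in model.genes

    def test_in_sample_error_below_cv_error(self, trained):
        model, corrected, meta = trained
        preds = rc.predict_age(model, corrected)
        in_sample = rc.compute_metrics(preds, meta["age"])
        assert in_sample.rmse < model.cv.chosen_row["mean_rmse"]


class _StubForest:
    """Regressor stub emitting fixed raw outputs."""

    def __init__(self, raw):
        self.raw = np.asarray(raw, dtype=float)

    def predict(self, X):
        return self.raw[: len(X)]


def _stub_model(raw):
    genes = ["g1", "g2"]
    return ClockModel(
        genes=genes,
        center=pd.Series(0.0, index=genes),
        scale=pd.Series(1.0, index=genes),
        forest=_StubForest(raw),
        cv=None,
    )


class TestPredictAge:
    def test_raw_outputs_clamped_to_bounds(self):
        model = _stub_model([150.0, -3.0, 55.0])
        mat = pd.DataFrame(
            np.zeros((2, 3)), index=["g1", "g2"], columns=["a", "b", "c"]
        )
        preds = rc.predict_age(model, mat)
        assert preds.tolist() == [110.0, 0.0, 55.0]

    def test_missing_model_genes_listed(self, trained):
        model, corrected, _ = trained
        pruned = corrected.values.drop(index=model.genes[:3])
        with pytest.raises(GeneMismatchError, match=model.genes[0]):
            rc.predict_age(model, pruned)

    def test_non_finite_input_rejected(self):
        model = _stub_model([50.0])
        mat = pd.DataFrame(
            [[np.nan], [1.0]], index=["g1", "g2"], columns=["a"]
        )
        with pytest.raises(ValidationError):
            rc.predict_age(model, mat)

    def test_predictions_always_within_bounds(self, trained):
        model, corrected, _ = trained
        preds = rc.predict_age(model, corrected)
        assert (preds >= 0).all() and (preds <= 110).all()


def _signal_frame(rng, n=120):
    """Three informative features and one pure-noise feature."""
    age = rng.uniform(0, 100, n)
    X = pd.DataFrame(
        {
            "sig1": age * 0.05 + rng.normal(0, 0.5, n),
            "sig2": -age * 0.03 + rng.normal(0, 0.5, n),
            "sig3": age * 0.04 + rng.normal(0, 0.5, n),
            "noise": rng.normal(0, 1, n),
        }
    ).T
    X.columns = [f"s{i}" for i in range(n)]
    ages = pd.Series(age, index=X.columns)
    return X, ages


class TestImportance:
    def test_noise_feature_scores_below_signal_across_seeds(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X, ages = _signal_frame(rng)
            model = rc.train_clock(
                X, ages, folds=5, repeats=1, trees=60, seed=seed, grid=[2]
            )
            table = rc.importance(model).table
            if table.loc["noise", "score"] < table.loc[
                ["sig1", "sig2", "sig3"], "score"
            ].min():
                wins += 1
        assert wins >= 9

    def test_constant_feature_scores_zero_when_forced_in(self):
        rng = np.random.default_rng(5)
        X, ages = _signal_frame(rng)
        Xc = pd.concat(
            [X, pd.DataFrame([np.ones(X.shape[1])], index=["flat"], columns=X.columns)]
        )
        from sklearn.ensemble import RandomForestRegressor

        Z = Xc.T.to_numpy()
        forest = RandomForestRegressor(n_estimators=40, random_state=0).fit(
            Z, ages.to_numpy()
        )
        model = ClockModel(
            genes=Xc.index.tolist(),
            center=pd.Series(0.0, index=Xc.index),
            scale=pd.Series(1.0, index=Xc.index),
            forest=forest,
            cv=None,
            train_X=Z,
            train_y=ages.to_numpy(),
        )
        table = rc.importance(model).table
        assert table.loc["flat", "score"] == 0.0
        assert not table.loc["flat", "important"]

    def test_label_shuffle_kills_importance_flags(self, small_cohort_module):
        corrected, meta = small_cohort_module
        genes = rc.top_variable_genes(corrected, 30)
        real = rc.train_clock(
            corrected, meta["age"], gene_set=genes, folds=5, repeats=1,
            trees=60, seed=2, grid=[10],
        )
        rng = np.random.default_rng(2)
        shuffled = pd.Series(
            rng.permutation(meta["age"].to_numpy()), index=meta.index
        )
        null = rc.train_clock(
            corrected, shuffled, gene_set=genes, folds=5, repeats=1,
            trees=60, seed=2, grid=[10],
        )
        real_table = rc.importance(real).table
        null_table = rc.importance(null).table
        # the statistic has a small positive bias even under the null, so
        # the null flag rate is not zero; the contrast is what matters
        assert real_table["important"].mean() > 0.5
        assert (
            null_table["important"].mean()
            < real_table["important"].mean() - 0.25
        )
        assert null_table["score"].mean() < 1.0 < real_table["score"].mean()


class TestSerialization:
    def test_roundtrip_preserves_predictions_and_cv(self, tmp_path, trained):
        model, corrected, _ = trained
        rc.save_clock(model, tmp_path / "clock")
        loaded = rc.load_clock(tmp_path / "clock")
        assert loaded.genes == model.genes
        assert loaded.cv.chosen_mtry == model.cv.chosen_mtry
        pd.testing.assert_frame_equal(loaded.cv.table, model.cv.table)
        p1 = rc.predict_age(model, corrected)
        p2 = rc.predict_age(loaded, corrected)
        np.testing.assert_allclose(p1, p2)
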