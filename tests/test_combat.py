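import numpy as np
import pandas as pd
import pytest

import rnaclock as rc
from rnaclock.errors import (
    GeneMismatchError,
    PreconditionError,
    SingletonBatchError,
)
from rnaclock.normalize import NormalizedMatrix


def _meta_for(columns, batches):
    return pd.DataFrame(
        {
            "age": 50.0,
            "sex": "female",
            "health": "healthy",
            "tissue": "blood",
            "batch": batches,
        },
        index=pd.Index(columns, name="sample_id"),
    )


def _norm(values, columns=None):
    df = pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(values.shape[0])],
        columns=columns or [f"s{j}" for j in range(values.shape[1])],
    )
    return NormalizedMatrix(values=df, provenance="uncorrected")


class TestFitCombat:
    def test_single_batch_rejected(self):
        norm = _norm(np.random.default_rng(0).normal(5, 1, (10, 6)))
        meta = _meta_for(norm.samples, ["b1"] * 6)
        with pytest.raises(PreconditionError, match="2 batches"):
            rc.fit_combat(norm, meta)

    def test_singleton_batch_error_names_batch(self):
        norm = _norm(np.random.default_rng(0).normal(5, 1, (10, 5)))
        meta = _meta_for(norm.samples, ["b1", "b1", "b1", "b1", "lonely"])
        with pytest.raises(SingletonBatchError, match="lonely"):
            rc.fit_combat(norm, meta)

    def test_constant_shift_between_two_batches_removed(self):
        """Two batches differing by a constant shift per gene: corrected
        batch means equalize and the estimated locations track the truth."""
        rng = np.random.default_rng(1)
        n_genes, n_per = 200, 60
        base = rng.normal(6, 1, (n_genes, 1))
        d = 1.5
        y1 = base + rng.normal(0, 0.4, (n_genes, n_per))
        y2 = base + d + rng.normal(0, 0.4, (n_genes, n_per))
        norm = _norm(np.hstack([y1, y2]))
        meta = _meta_for(norm.samples, ["b1"] * n_per + ["b2"] * n_per)
        corrected, model = rc.fit_combat(norm, meta)

        m1 = corrected.values.iloc[:, :n_per].mean(axis=1)
        m2 = corrected.values.iloc[:, n_per:].mean(axis=1)
        # residual batch-mean differences are at the sampling-noise scale
        assert np.quantile((m1 - m2).abs(), 0.95) < 0.15

        # location effects on the log2 scale: +-d/2 after centering
        gamma_log2 = model.gamma_star.mul(np.sqrt(model.pooled_var), axis=1)
        est = gamma_log2.loc["b2"] - gamma_log2.loc["b1"]
        assert est.mean() == pytest.approx(d, abs=0.1)
        centered = gamma_log2 - gamma_log2.mean(axis=0)
        truth = np.vstack([np.full(n_genes, -d / 2), np.full(n_genes, d / 2)])
        r = np.corrcoef(centered.to_numpy().ravel(), truth.ravel())[0, 1]
        assert r > 0.99

    def test_dimensions_and_gene_order_preserved(self, small_corrected):
        norm, corrected, _ = small_corrected
        assert corrected.values.shape == norm.values.shape
        assert list(corrected.genes) == list(norm.genes)
        assert list(corrected.samples) == list(norm.samples)
        assert corrected.provenance == "batch_corrected"

    def test_mean_only_reduces_to_batch_centering(self):
        """With scale effects fixed and no shrinkage, correction equals
        per-batch mean-centering plus the (weighted) grand mean."""
        rng = np.random.default_rng(2)
        norm = _norm(rng.normal(5, 1, (50, 30)))
        batches = ["b1"] * 10 + ["b2"] * 12 + ["b3"] * 8
        meta = _meta_for(norm.samples, batches)
        corrected, _ = rc.fit_combat(norm, meta, mean_only=True)

        y = norm.values
        direct = y.copy()
        grand = pd.Series(0.0, index=y.index)
        for b in ("b1", "b2", "b3"):
            cols = [s for s, lab in zip(y.columns, batches) if lab == b]
            grand += y[cols].mean(axis=1) * (len(cols) / len(batches))
        for b in ("b1", "b2", "b3"):
            cols = [s for s, lab in zip(y.columns, batches) if lab == b]
            direct[cols] = y[cols].sub(y[cols].mean(axis=1), axis=0).add(grand, axis=0)
        np.testing.assert_allclose(corrected.values, direct, atol=1e-10)

    def test_age_slopes_survive_correction(self):
        """With age-balanced batches, true per-gene age slopes are preserved
        through correction."""
        cfg = rc.SimulationConfig(
            n_batches=5,
            samples_per_batch=40,
            n_genes=300,
            n_age_genes=120,
            age_slope_sd=0.02,
            batch_shift_sd=1.0,
            seed=23,
        )
        counts, meta, truth = rc.simulate_cohort(cfg)
        f = rc.tmm_factors(counts)
        corrected, _ = rc.fit_combat(rc.normalize_log2(counts, f), meta)
        age = meta["age"].to_numpy()
        age_c = age - age.mean()
        post = (
            corrected.values.loc[truth.age_slopes.index].to_numpy() @ age_c
        ) / (age_c @ age_c)
        r = np.corrcoef(post, truth.age_slopes.to_numpy())[0, 1]
        assert r > 0.9

    def test_zero_variance_gene_flagged_and_untouched(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(5, 1, (20, 12))
        vals[4, :] = 7.0  # constant gene
        norm = _norm(vals)
        meta = _meta_for(norm.samples, ["b1"] * 6 + ["b2"] * 6)
        corrected, model = rc.fit_combat(norm, meta)
        assert model.zero_variance_genes == ["g4"]
        np.testing.assert_allclose(corrected.values.loc["g4"], 7.0)

    def test_model_serializes_to_json(self, tmp_path, small_corrected):
        _, _, model = small_corrected
        model.to_json(tmp_path / "model.json")
        import json

        obj = json.loads((tmp_path / "model.json").read_text())
        assert set(obj["batches"]) == set(model.batch_sizes.index)


@pytest.fixture(scope="module")
def reference():
    cfg = rc.SimulationConfig(
        n_batches=3,
        samples_per_batch=25,
        n_genes=150,
        n_age_genes=40,
        batch_shift_sd=0.6,
        seed=31,
    )
    return rc.simulate_cohort(cfg)


class TestProjectNewBatch:

    @staticmethod
    def _joint_corrected(counts, meta, new):
        """Corrected values of the union cohort (originals + new batch)."""
        combined = pd.concat([counts, new], axis=1)
        meta2 = pd.concat(
            [
                meta[["batch"]].astype(str),
                pd.DataFrame({"batch": "__new_batch__"}, index=new.columns),
            ]
        )
        f = rc.tmm_factors(combined)
        corrected, _ = rc.fit_combat(rc.normalize_log2(combined, f), meta2)
        return corrected

    def test_duplicated_batch_matches_original_corrected_values(self, reference):
        counts, meta, _ = reference
        dup_cols = meta.index[meta["batch"] == "B01"]
        new = counts[dup_cols].copy()
        new.columns = [f"copy_{c}" for c in dup_cols]
        projected = rc.project_new_batch(counts, meta, new)
        joint = self._joint_corrected(counts, meta, new)
        diff = np.abs(
            projected.values.to_numpy() - joint.values[dup_cols].to_numpy()
        )
        assert (diff < 0.1).mean() >= 0.95

    def test_global_shift_in_new_batch_removed(self, reference):
        """A +1 log2 global shift (counts doubled) injected into an uploaded
        copy of a batch is corrected away: the new samples land on the
        originals' corrected values."""
        counts, meta, _ = reference
        dup_cols = meta.index[meta["batch"] == "B02"]
        new = (counts[dup_cols] * 2).copy()
        new.columns = [f"shifted_{c}" for c in dup_cols]
        projected = rc.project_new_batch(counts, meta, new)
        joint = self._joint_corrected(counts, meta, new)
        diff = np.abs(
            projected.values.to_numpy() - joint.values[dup_cols].to_numpy()
        )
        assert (diff < 0.1).mean() >= 0.95

    def test_low_gene_overlap_rejected(self, reference):
        counts, meta, _ = reference
        new = counts.iloc[:60, :5].copy()  # 40% of reference genes
        new.columns = [f"n{i}" for i in range(5)]
        with pytest.raises(GeneMismatchError, match="50%"):
            rc.project_new_batch(counts, meta, new)

    def test_partial_overlap_imputes_with_warning(self, reference):
        counts, meta, _ = reference
        new = counts.iloc[:120, :4].copy()  # 80% overlap
        new.columns = [f"n{i}" for i in range(4)]
        with pytest.warns(UserWarning, match="imputed as zero"):
            projected = rc.project_new_batch(counts, meta, new)
        assert list(projected.genes) == list(counts.index)

    def test_single_sample_warns_but_runs(self, reference):
        counts, meta, _ = reference
        new = counts.iloc[:, [0]].copy()
        new.columns = ["solo"]
        with pytest.warns(UserWarning, match="single new sample"):
            projected = rc.project_new_batch(counts, meta, new)
        assert projected.values.shape == (counts.shape[0], 1)
        assert np.isfinite(projected.values.to_numpy()).all()

    def test_empty_input_rejected(self, reference):
        counts, meta, _ = reference
        with pytest.raises(PreconditionError, match="no new samples"):
            rc.project_new_batch(counts, meta, counts.iloc[:, :0])
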