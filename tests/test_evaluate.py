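"""Cross-validation mechanics, predictability scoring, evaluation settings,
selection ability and reporting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import phenogp as pg
from phenogp import evaluate as E
from phenogp import preprocess as pp


FAST_OPTS = {"chain_length": 300, "burn_in": 80,
             "grid_sizes": {"n_lam": 6, "n_mix": 2, "l21_n": 2},
             "tol": 1e-4, "l21_max_iter": 60}


class TestKfoldPartition:
    @pytest.mark.parametrize("n,expected", [(74, [24, 25, 25]),
                                            (119, [39, 40, 40])])
    def test_fold_sizes(self, n, expected):
        ids = [f"s{i}" for i in range(n)]
        folds = E.kfold_partition(ids, E.CVScheme(K=3, repetitions=1, seed=0), 0)
        assert sorted(len(f) for f in folds) == expected

    def test_disjoint_union(self):
        ids = [f"s{i}" for i in range(50)]
        folds = E.kfold_partition(ids, E.CVScheme(seed=3), 4)
        flat = [s for f in folds for s in f]
        assert sorted(flat) == sorted(ids)
        assert len(set(flat)) == len(flat)

    def test_deterministic_given_seed_and_repetition(self):
        ids = [f"s{i}" for i in range(30)]
        scheme = E.CVScheme(seed=9)
        a = E.kfold_partition(ids, scheme, 2)
        b = E.kfold_partition(ids, scheme, 2)
        c = E.kfold_partition(ids, scheme, 3)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))
        assert any(not np.array_equal(x, y) for x, y in zip(a, c))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="cannot split"):
            E.kfold_partition(["a", "b"], E.CVScheme(K=3), 0)


class TestPredictability:
    def test_perfect_and_antiperfect(self):
        y = np.array([1.0, 2, 3, 5])
        assert E.predictability(y, y) == 1.0
        assert E.predictability(y, -y) == -1.0

    def test_constant_prediction_is_na(self):
        assert np.isnan(E.predictability([1.0, 2, 3], [4.0, 4, 4]))
        assert np.isnan(E.predictability([4.0, 4, 4], [1.0, 2, 3]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            E.predictability([1, 2, 3], [1, 2])


def _cv_block(n, p, noise, seed, t=2):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, p)),
                     index=[f"s{i}" for i in range(n)],
                     columns=[f"x{j}" for j in range(p)])
    B = rng.normal(size=(p, t))
    Y = pd.DataFrame(X.to_numpy() @ B + noise * rng.normal(size=(n, t)),
                     index=X.index, columns=[f"y{k}" for k in range(t)])
    return pp.SettingBlock("S1", "chlf", "F", X, Y)


class TestNestedCV:
    def test_noise_free_linear_signal_ridge(self):
        block = _cv_block(80, 5, noise=0.0, seed=1)
        rec = E.nested_cv_evaluate(block, "RR",
                                   E.CVScheme(repetitions=2, seed=0), FAST_OPTS)
        assert rec.mean >= 0.99

    def test_pure_noise_near_zero(self):
        rng = np.random.default_rng(2)
        block = _cv_block(119, 10, noise=1.0, seed=2)
        block.Y_train.iloc[:, :] = rng.normal(size=block.Y_train.shape)
        rec = E.nested_cv_evaluate(block, "RR",
                                   E.CVScheme(repetitions=3, seed=1), FAST_OPTS)
        assert abs(rec.mean) < 0.2

    def test_bit_reproducible_under_seed(self):
        block = _cv_block(40, 6, noise=0.5, seed=3)
        scheme = E.CVScheme(repetitions=2, seed=5)
        r1 = E.nested_cv_evaluate(block, "EN", scheme, FAST_OPTS)
        r2 = E.nested_cv_evaluate(block, "EN", scheme, FAST_OPTS)
        pd.testing.assert_frame_equal(r1.detail, r2.detail)

    def test_mean_recomputable_from_repetition_values(self):
        block = _cv_block(45, 6, noise=0.8, seed=4)
        rec = E.nested_cv_evaluate(block, "RR",
                                   E.CVScheme(repetitions=4, seed=2), FAST_OPTS)
        vals = rec.per_repetition.dropna()
        assert rec.mean == pytest.approx(float(vals.mean()), abs=1e-12)

    def test_gblup_rejected_for_chlf(self):
        block = _cv_block(30, 5, noise=0.5, seed=5)
        with pytest.raises(ValueError, match="not applicable"):
            E.nested_cv_evaluate(block, "GBLUP", E.CVScheme(repetitions=1))


class TestConditionAhead:
    @pytest.fixture(scope="class")
    def persistent_family(self):
        # high heritability, no GxE: the genetic signal persists across
        # conditions, so condition-ahead prediction stays strong
        cfg = pg.SimConfig(n_individuals=119, n_markers=100, n_qtl=10,
                           var_G=1.0, var_E=0.3, var_GxE=0.0, var_eps=0.05,
                           seed=31)
        g, phen, tr, _ = pg.simulate_family(cfg)
        return {"F1": pp.FamilyData(g, phen, tr)}

    def test_gp_predictability_persists(self, persistent_family):
        blocks = pp.assemble_setting("S3", persistent_family, "snp")
        recs = E.condition_ahead_evaluate(blocks, ["RR"],
                                          E.CVScheme(seed=0), FAST_OPTS)
        means = [r.detail["r"].mean() for r in recs]
        assert np.median(means) >= 0.8

    def test_holdout_never_in_training(self, persistent_family):
        blocks = pp.assemble_setting("S3", persistent_family, "chlf")
        for b in blocks:
            assert not set(b.X_train.index) & set(b.X_test.index)
            assert len(b.X_test) == 20

    def test_record_carries_condition_pair(self, persistent_family):
        blocks = pp.assemble_setting("S3", persistent_family, "chlf")
        recs = E.condition_ahead_evaluate(blocks[:1], ["RR"],
                                          E.CVScheme(seed=0), FAST_OPTS)
        assert (recs[0].train_condition, recs[0].test_condition) == (2, 3)


class TestCrossFamily:
    def test_transfer_positive_and_shuffle_null(self, two_families):
        fams, _ = two_families
        blocks = pp.assemble_setting("S4", fams, "snp")
        recs = E.cross_family_evaluate(blocks, ["RR"], E.CVScheme(seed=0),
                                       FAST_OPTS)
        transfer = np.concatenate([r.detail["r"].to_numpy() for r in recs])
        assert np.nanmedian(transfer) > 0

        rng = np.random.default_rng(0)
        shuffled = []
        for b in blocks:
            Y_shuf = b.Y_test.copy()
            Y_shuf.iloc[:, :] = rng.permutation(Y_shuf.to_numpy())
            shuffled.append(pp.SettingBlock(
                "S4", b.predictor_source, b.family, b.X_train, b.Y_train,
                b.X_test, Y_shuf, test_family=b.test_family))
        null_recs = E.cross_family_evaluate(shuffled, ["RR"],
                                            E.CVScheme(seed=0), FAST_OPTS)
        null = np.concatenate([r.detail["r"].to_numpy() for r in null_recs])
        assert abs(np.nanmedian(null)) < 0.25


class TestSelectionAbility:
    def test_perfect_prediction(self):
        obs = np.arange(100.0)
        sa = E.selection_ability(obs, obs, 20, "best")
        assert sa.proportion == 100.0

    def test_reversed_ranking_disjoint(self):
        obs = np.arange(40.0)
        sa = E.selection_ability(obs, -obs, 20, "best")
        assert sa.proportion == 0.0

    def test_worst_direction(self):
        obs = np.arange(50.0)
        sa = E.selection_ability(obs, obs, 10, "worst")
        assert sa.proportion == 100.0

    def test_proportion_is_multiple_of_unit(self, rng):
        obs = rng.normal(size=60)
        pred = rng.normal(size=60)
        sa = E.selection_ability(obs, pred, 20)
        assert sa.proportion % (100 / 20) == 0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            obs = rng.normal(size=50)
            pred = rng.normal(size=50)
            sa = E.selection_ability(obs, pred, 15, "best")
            top_obs = set(sorted(range(50), key=lambda i: (-obs[i], i))[:15])
            top_pred = set(sorted(range(50), key=lambda i: (-pred[i], i))[:15])
            assert sa.proportion == pytest.approx(
                100 * len(top_obs & top_pred) / 15)

    def test_random_predictions_match_hypergeometric_mean(self, rng):
        props = []
        obs = np.arange(100.0)
        for _ in range(1000):
            props.append(E.selection_ability(obs, rng.normal(size=100),
                                             20).proportion)
        assert abs(np.mean(props) - 20.0) < 5.0

    def test_oversized_selection_rejected(self):
        with pytest.raises(ValueError):
            E.selection_ability(np.arange(10.0), np.arange(10.0), 20)


@settings(max_examples=20, deadline=None)
@given(st.integers(0, 10 ** 6), st.integers(5, 40), st.integers(2, 5))
def test_kfold_properties(seed, n, k):
    ids = [f"s{i}" for i in range(n)]
    if n < k:
        return
    folds = E.kfold_partition(ids, E.CVScheme(K=k, seed=seed % 100), seed % 7)
    sizes = [len(f) for f in folds]
    assert max(sizes) - min(sizes) <= 1
    assert sorted(s for f in folds for s in f) == sorted(ids)


class TestMakeReport:
    def test_report_files(self, tmp_path):
        block = _cv_block(36, 5, noise=0.5, seed=6)
        recs = [E.nested_cv_evaluate(block, m, E.CVScheme(repetitions=2, seed=0),
                                     FAST_OPTS) for m in ("RR", "mLASSO")]
        sel = [E.selection_ability(np.arange(30.0), np.arange(30.0), 10,
                                   method="RR", trait="LC")]
        written = E.make_report(recs, tmp_path, selection=sel,
                                metadata={"seed": 0})
        assert (tmp_path / "summary.csv").exists()
        assert (tmp_path / "S1_chlf_by_trait.csv").exists()
        assert (tmp_path / "selection_ability.csv").exists()
        summary = pd.read_csv(tmp_path / "summary.csv")
        assert set(summary["method"]) == {"RR", "mLASSO"}

    def test_empty_records_metadata_only(self, tmp_path):
        written = E.make_report([], tmp_path, metadata={"seed": 1})
        assert list(written) == ["metadata"]
        assert (tmp_path / "metadata.json").exists()


def test_performance_matrix_shape(two_families):
    fams, _ = two_families
    blocks = pp.assemble_setting("S1", {"A": fams["A"]}, "chlf")
    recs = [E.nested_cv_evaluate(blocks[0], m, E.CVScheme(repetitions=1, seed=0),
                                 FAST_OPTS) for m in ("RR", "mLASSO")]
    mat = E.performance_matrix(recs, "A")
    assert mat.shape == (2, 9)
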