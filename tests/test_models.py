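import numpy as np
import pandas as pd
import pytest

from physioload.core import FeatureTable
from physioload.models import (DataLevelFusion, ModelSpec, fuse_feature_level,
                               run_benchmark, split_dataset, train_mlp,
                               tune_classical)

FAST_MLP = dict(lr_grid=[5e-4], batch_grid=[32], epochs=150, hidden=(32, 16, 16))


def _table(n_per_class=116, n_feat=2, sep=1.5, seed=0, labels=(0, 1)):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(sep * k, 1.0, (n_per_class, n_feat))
                   for k in range(len(labels))])
    y = np.repeat(labels, n_per_class)
    cols = [f"f{i}" for i in range(n_feat)]
    return FeatureTable(pd.DataFrame(X, columns=cols), y)


def test_split_ratio_and_stratification():
    table = _table()
    train, test = split_dataset(table, seed=0)
    assert len(train) == 185 and len(test) == 47  # 232 * 0.2 rounded
    c_train, c_test = train.class_counts(), test.class_counts()
    assert abs(c_train[0] - c_train[1]) <= 1
    assert abs(c_test[0] - c_test[1]) <= 1


def test_split_deterministic():
    table = _table()
    a1, b1 = split_dataset(table, seed=5)
    a2, b2 = split_dataset(table, seed=5)
    pd.testing.assert_frame_equal(a1.data, a2.data)
    pd.testing.assert_frame_equal(b1.data, b2.data)


def test_split_single_class_fails():
    table = _table(labels=(0,))
    with pytest.raises(ValueError):
        split_dataset(table, seed=0)


def test_knn_selects_k1_when_1nn_is_perfect():
    # clusters of singletons: every point's nearest neighbour has its label,
    # larger k mixes the interleaved grid and degrades accuracy
    rng = np.random.default_rng(2)
    grid = np.stack(np.meshgrid(np.arange(10.0), np.arange(10.0)), -1).reshape(-1, 2)
    y = ((grid[:, 0] + grid[:, 1]) % 2).astype(int)
    X = np.repeat(grid, 3, axis=0) + rng.normal(0, 0.02, (300, 2))
    y = np.repeat(y, 3)
    table = FeatureTable(pd.DataFrame(X, columns=["a", "b"]), y)
    chosen, _ = tune_classical(ModelSpec("knn", seed=0), table)
    assert dict(chosen)["k"] == 1


def test_grid_of_one_returned_directly():
    table = _table(n_per_class=30)
    chosen, model = tune_classical(ModelSpec("svm", grid={"kernel": ["linear"]}),
                                   table)
    assert dict(chosen)["kernel"] == "linear"
    assert model.score(table.X(), table.labels) > 0.5


def test_cv_tie_breaks_to_simpler_candidate():
    # perfectly separable data: many k values reach 100 % -> smallest k wins
    table = _table(sep=20.0, n_per_class=40)
    chosen, _ = tune_classical(ModelSpec("knn", seed=1), table)
    assert dict(chosen)["k"] == 1


def test_mlp_learns_separable_data():
    table = _table(sep=3.0, seed=4)
    train, test = split_dataset(table, seed=0)
    _, model = train_mlp(train, seed=0, **FAST_MLP)
    assert model.score(test.X(), test.labels) >= 0.95


def test_mlp_chance_on_shuffled_labels():
    rng = np.random.default_rng(5)
    accs = []
    for seed in range(5):
        table = _table(sep=3.0, seed=seed)
        shuffled = FeatureTable(table.data, rng.permutation(table.labels))
        train, test = split_dataset(shuffled, seed=seed)
        _, model = train_mlp(train, seed=seed, **FAST_MLP)
        accs.append(model.score(test.X(), test.labels))
    assert 0.40 <= np.mean(accs) <= 0.60


def test_mlp_deterministic_per_seed():
    table = _table(seed=6)
    train, test = split_dataset(table, seed=0)
    _, m1 = train_mlp(train, seed=3, **FAST_MLP)
    _, m2 = train_mlp(train, seed=3, **FAST_MLP)
    assert m1.score(test.X(), test.labels) == m2.score(test.X(), test.labels)
    np.testing.assert_array_equal(m1.predict(test.X()), m2.predict(test.X()))


def test_feature_level_fusion_dimensions():
    n = 50
    rng = np.random.default_rng(7)
    y = np.repeat([0, 1], n // 2)
    pupil = FeatureTable(pd.DataFrame(rng.normal(size=(n, 2)),
                                      columns=["pcps_mean", "pcps_var"]), y)
    eeg = FeatureTable(pd.DataFrame(rng.normal(size=(n, 32)),
                                    columns=[f"psd_{i}" for i in range(32)]), y)
    fused = fuse_feature_level(pupil, eeg)
    assert len(fused.columns) == 34
    assert len(fused) == n


def test_feature_level_fusion_errors_and_renaming():
    rng = np.random.default_rng(8)
    y = np.repeat([0, 1], 10)
    a = FeatureTable(pd.DataFrame(rng.normal(size=(20, 2)), columns=["x", "y"]), y)
    b = FeatureTable(pd.DataFrame(rng.normal(size=(20, 3)),
                                  columns=["x", "u", "v"]), y)
    fused = fuse_feature_level(a, b)
    assert "pupil_x" in fused.columns and "eeg_x" in fused.columns
    short = FeatureTable(pd.DataFrame(rng.normal(size=(10, 2)),
                                      columns=["x", "y"]), y[:10])
    with pytest.raises(ValueError):
        fuse_feature_level(a, short)


def test_data_fusion_robust_to_noise_modality():
    """Fusing an informative with a pure-noise modality costs little.

    Averaged over independent dataset draws, the fusion network must stay
    within 5 accuracy points of the single informative modality.
    """
    diffs = []
    for seed in range(5):
        rng = np.random.default_rng(40 + seed)
        n = 116
        Xp = np.vstack([rng.normal(0, 1, (n, 2)), rng.normal(3.0, 1, (n, 2))])
        Xe = rng.normal(0, 1, (2 * n, 32))
        y = np.repeat([0, 1], n)
        perm = rng.permutation(2 * n)
        Xp, Xe, y = Xp[perm], Xe[perm], y[perm]
        n_tr = 186
        fusion = DataLevelFusion(pupil_hidden=(64, 32, 16),
                                 eeg_hidden=(64, 32, 16), epochs=150, seed=seed)
        fusion.fit(Xp[:n_tr], Xe[:n_tr], y[:n_tr])
        acc_f = fusion.score(Xp[n_tr:], Xe[n_tr:], y[n_tr:])
        table = FeatureTable(pd.DataFrame(Xp, columns=["a", "b"]), y)
        train = table.select(np.arange(n_tr))
        _, mp = train_mlp(train, seed=seed, lr_grid=[5e-4], batch_grid=[64],
                          epochs=150, hidden=(64, 32, 16))
        acc_p = np.mean(mp.predict(Xp[n_tr:]) == y[n_tr:])
        diffs.append(acc_f - acc_p)
    assert np.mean(diffs) >= -0.05


def test_data_fusion_chance_on_pure_noise():
    rng = np.random.default_rng(10)
    accs = []
    for seed in range(3):
        Xp = rng.normal(0, 1, (200, 2))
        Xe = rng.normal(0, 1, (200, 8))
        y = np.repeat([0, 1], 100)
        perm = rng.permutation(200)
        fusion = DataLevelFusion(pupil_hidden=(16, 8, 8), eeg_hidden=(16, 8, 8),
                                 epochs=100, seed=seed)
        fusion.fit(Xp[perm][:160], Xe[perm][:160], y[perm][:160])
        accs.append(fusion.score(Xp[perm][160:], Xe[perm][160:], y[perm][160:]))
    assert 0.35 <= np.mean(accs) <= 0.65


def test_data_fusion_deterministic():
    rng = np.random.default_rng(11)
    Xp, Xe = rng.normal(size=(100, 2)), rng.normal(size=(100, 4))
    y = np.tile([0, 1], 50)
    preds = []
    for _ in range(2):
        f = DataLevelFusion(pupil_hidden=(8, 8, 4), eeg_hidden=(8, 8, 4),
                            epochs=50, seed=2)
        f.fit(Xp, Xe, y)
        preds.append(f.predict(Xp, Xe))
    np.testing.assert_array_equal(preds[0], preds[1])


def test_benchmark_shape_and_filters():
    table = _table(n_per_class=40, labels=(0, 1, 2), sep=1.0)
    res = run_benchmark({"pcps": table}, tasks=["0-2"], families=["nb"],
                        n_seeds=2, grids={"nb": {"variant": ["gaussian"]}})
    assert len(res) == 1
    assert res.iloc[0]["task"] == "0-2"
    assert res.iloc[0]["modality"] == "pcps"
    assert 0.0 <= res.iloc[0]["mean_acc_pct"] <= 100.0


def test_benchmark_single_seed_has_zero_sd():
    table = _table(n_per_class=40)
    res = run_benchmark({"m": table}, tasks=["0-1"], families=["nb"], n_seeds=1,
                        grids={"nb": {"variant": ["gaussian"]}})
    assert res.iloc[0]["sd_acc_pct"] == 0.0


def test_no_leakage_canary_stays_at_chance():
    """A feature equal to the label on test rows only must not help.

    The training rows carry pure noise in every column, so any accuracy
    above chance could only come from test-set information reaching the
    model — standardization or tuning on test rows.
    """
    accs = []
    for seed in range(5):
        rng = np.random.default_rng(100 + seed)
        n = 200
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, 3))
        table = FeatureTable(pd.DataFrame(X, columns=["a", "b", "canary"]), y)
        train, test = split_dataset(table, seed=seed)
        # plant the canary: on test rows the third column equals the label
        test.data.loc[:, "canary"] = test.labels.astype(float)
        _, model = tune_classical(ModelSpec("svm", seed=seed,
                                            grid={"kernel": ["linear", "rbf"]}),
                                  train)
        accs.append(model.score(test.X(), test.labels))
    assert 0.35 <= np.mean(accs) <= 0.65


def test_benchmark_monotone_in_effect_size():
    meds = []
    for sep in (0.0, 1.0, 3.0):
        accs = []
        for seed in range(3):
            table = _table(n_per_class=60, sep=sep, seed=seed)
            train, test = split_dataset(table, seed=seed)
            _, model = tune_classical(
                ModelSpec("nb", grid={"variant": ["gaussian"]}, seed=seed), train)
            accs.append(model.score(test.X(), test.labels))
        meds.append(np.median(accs))
    assert meds[0] <= meds[1] + 0.05 <= meds[2] + 0.10
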