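import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from thermoseg import PixelSVMSegmenter, evaluate, make_split, train_model
from thermoseg.classify import confusion_metrics, family_columns


def feature_table(rng, n=400, prevalence=0.25, sep=3.0, n_features=4):
    """Linearly separated two-class table with TD_BL-style column names."""
    labels = (rng.uniform(size=n) < prevalence).astype(int)
    names = ["t_ini", "std_bl", "k_bl", "sk_bl", "p90_bl", "sampen_bl"]
    cols = {"pixel_row": np.zeros(n, int), "pixel_col": np.arange(n),
            "label": labels}
    for name in names[:n_features]:
        cols[name] = rng.standard_normal(n) + sep * labels
    for name in names[n_features:]:
        cols[name] = rng.standard_normal(n)
    return pd.DataFrame(cols)


class TestMakeSplit:
    def test_partition_and_balance(self, rng):
        labels = (rng.uniform(size=1000) < 0.1).astype(int)
        split = make_split(labels, seed=4)
        union = np.concatenate([split.train_idx_all, split.test_idx_all,
                                split.validation_idx])
        assert np.array_equal(np.sort(union), np.arange(1000))
        assert len(split.train_idx_all) == 200
        cls = labels[split.train_idx]
        assert (cls == 0).sum() == (cls == 1).sum()
        n_min = min((labels[split.train_idx_all] == c).sum() for c in (0, 1))
        assert len(split.train_idx) == 2 * n_min

    def test_balanced_input_unchanged(self, rng):
        labels = np.r_[np.zeros(500, int), np.ones(500, int)]
        split = make_split(labels, seed=0)
        # both classes ~100 in train; downsampling removes at most the
        # class-count difference
        rec = split.balance_record["train"]
        assert sum(rec["after"].values()) == 2 * min(rec["before"].values())

    def test_fractions_must_sum_below_one(self, rng):
        labels = (rng.uniform(size=100) < 0.5).astype(int)
        with pytest.raises(ValueError, match="fraction"):
            make_split(labels, train_frac=0.6, test_frac=0.6)

    def test_many_random_configurations_contract(self, rng):
        """Split/balance contract over random label configurations."""
        for _ in range(100):
            n = int(rng.integers(60, 400))
            labels = (rng.uniform(size=n) < rng.uniform(0.15, 0.85)).astype(int)
            if labels.sum() in (0, n):
                continue
            try:
                split = make_split(labels, seed=int(rng.integers(2 ** 31)))
            except ValueError:
                continue  # class absent from a raw split: documented error
            union = np.concatenate([split.train_idx_all, split.test_idx_all,
                                    split.validation_idx])
            assert np.array_equal(np.sort(union), np.arange(n))
            for idx in (split.train_idx, split.test_idx):
                cls = labels[idx]
                assert (cls == 0).sum() == (cls == 1).sum()
                assert np.all(np.isin(idx, union))

    def test_deterministic(self, rng):
        labels = (rng.uniform(size=300) < 0.3).astype(int)
        s1 = make_split(labels, seed=9)
        s2 = make_split(labels, seed=9)
        assert np.array_equal(s1.train_idx, s2.train_idx)
        assert np.array_equal(s1.validation_idx, s2.validation_idx)


class TestModel:
    def test_separable_features_reach_perfect_train_accuracy(self, rng):
        table = feature_table(rng, sep=6.0)
        split = make_split(table["label"].to_numpy(), seed=1)
        model = train_model(table, split, "td_bl")
        X = table[model.feature_columns_].to_numpy()
        y = table["label"].to_numpy()
        assert (model.predict(X[split.train_idx]) == y[split.train_idx]).all()

    def test_shuffled_labels_give_chance_cv(self, rng):
        from sklearn.model_selection import KFold, cross_val_score
        accs = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = r.standard_normal((200, 4))
            y = r.permutation(np.r_[np.zeros(100, int), np.ones(100, int)])
            cv = KFold(10, shuffle=True, random_state=seed)
            accs.append(cross_val_score(PixelSVMSegmenter(), X, y, cv=cv).mean())
        assert abs(np.mean(accs) - 0.5) < 0.05

    def test_constant_column_changes_nothing(self, rng):
        """A zero-variance feature is standardized to zeros, so adding it
        leaves kernel distances (and predictions) unchanged vs dropping it."""
        X = rng.standard_normal((300, 4)) \
            + 2.0 * (rng.uniform(size=300) < 0.4)[:, None].astype(float)
        y = (X[:, 0] > 1.0).astype(int)
        if len(np.unique(y)) < 2:
            y[:5] = 1 - y[:5]
        with_const = np.column_stack([X, np.full(300, 7.0)])
        base = PixelSVMSegmenter().fit(X, y)
        alt = PixelSVMSegmenter().fit(with_const, y)
        assert np.array_equal(base.predict(X), alt.predict(with_const))

    def test_imputation_and_scaling_fit_on_train_only(self, rng):
        table = feature_table(rng)
        split = make_split(table["label"].to_numpy(), seed=3)
        model = train_model(table, split, "td_bl")
        means = model.pipeline_["scale"].mean_
        X = table[model.feature_columns_].to_numpy()
        assert np.allclose(
            means, model.pipeline_["impute"].transform(
                X[split.train_idx]).mean(axis=0))
        assert not np.allclose(means, X.mean(axis=0))

    def test_fold_statistics_differ_across_folds(self, rng):
        """No leakage: each CV fold refits its own scaler."""
        table = feature_table(rng)
        X = table[family_columns("td_bl", table)].to_numpy()
        y = table["label"].to_numpy()
        m1 = clone(PixelSVMSegmenter()).fit(X[:150], y[:150])
        m2 = clone(PixelSVMSegmenter()).fit(X[150:300], y[150:300])
        assert not np.allclose(m1.pipeline_["scale"].mean_,
                               m2.pipeline_["scale"].mean_)

    def test_unknown_family_raises(self, rng):
        table = feature_table(rng)
        with pytest.raises(ValueError, match="family"):
            family_columns("dl_bl", table)


class TestMetrics:
    def test_perfect_predictor(self):
        m = confusion_metrics([0, 0, 1, 1], [0, 0, 1, 1])
        assert m["accuracy"] == m["sensitivity"] == m["specificity"] == 100.0

    def test_all_negative_predictor_at_ten_percent_prevalence(self):
        y = np.r_[np.zeros(90, int), np.ones(10, int)]
        m = confusion_metrics(y, np.zeros(100, int))
        assert m["accuracy"] == pytest.approx(90.0)
        assert m["sensitivity"] == pytest.approx(0.0)
        assert m["specificity"] == pytest.approx(100.0)

    def test_undefined_metric_is_nan(self):
        m = confusion_metrics(np.zeros(10, int), np.zeros(10, int))
        assert np.isnan(m["sensitivity"])

    def test_metrics_recomputable_from_confusion(self, rng):
        table = feature_table(rng, sep=2.0)
        split = make_split(table["label"].to_numpy(), seed=5)
        model = train_model(table, split, "td_bl")
        res = evaluate(model, table, split)
        c = res.confusion
        total = sum(c.values())
        assert res.accuracy == pytest.approx(100 * (c["tp"] + c["tn"]) / total)
        assert res.sensitivity == pytest.approx(
            100 * c["tp"] / (c["tp"] + c["fn"]))
        assert res.specificity == pytest.approx(
            100 * c["tn"] / (c["tn"] + c["fp"]))
        assert len(res.cv_scores) == 10


def test_pipeline_determinism_small_patient(noiseless_cfg):
    """simulate -> features -> split -> train -> evaluate is reproducible."""
    from thermoseg import generate_video, run_patient
    cfg = noiseless_cfg
    cfg.noise_sd = 0.1
    cfg.slow_amp = 0.2
    cfg.class_params["healthy"].cardiac_amp = 0.08
    cfg.class_params["tumor"].cardiac_amp = 0.08
    video, mask = generate_video(cfg)
    r1 = run_patient(video, mask, seed=2, families=("td_bl",))
    r2 = run_patient(video, mask, seed=2, families=("td_bl",))
    a, b = r1.results["td_bl"], r2.results["td_bl"]
    assert (a.accuracy, a.sensitivity, a.specificity) == \
        (b.accuracy, b.sensitivity, b.specificity)
    assert np.array_equal(a.cv_scores, b.cv_scores)
    assert np.array_equal(a.prediction_map, b.prediction_map)
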