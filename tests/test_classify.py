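"""Random-forest training, OOB bookkeeping and the extension loop."""

import warnings

import numpy as np
import pandas as pd
import pytest

import lcbucket as lb
from lcbucket.classify import RFParams, case_weights
from lcbucket.errors import SchemaMismatchError, UserInputError
from lcbucket.features import stack


def _table(n_per_class=(6, 6, 6), n_feat=20, seed=0, schema="s", separable=True):
    rng = np.random.default_rng(seed)
    rows = []
    for ci, n in enumerate(n_per_class):
        for j in range(n):
            x = rng.normal(size=n_feat)
            if separable:
                x[ci] += 4.0  # class ci loads on feature ci
            rows.append((f"c{ci}s{j}", f"class{ci}", pd.Series(
                x, index=[f"f{i}" for i in range(n_feat)])))
    return stack(rows, schema)


def test_case_weights_inverse_frequency_rule():
    labels = pd.Series(["A"] * 2 + ["B"] * 8)
    w = case_weights(labels)
    np.testing.assert_allclose(w[:2], 0.25)
    np.testing.assert_allclose(w[2:], 0.0625)
    # per-class totals equal to machine precision
    assert w[:2].sum() == pytest.approx(w[2:].sum(), abs=1e-15)


def test_default_mtry_is_floor_sqrt_p():
    assert RFParams().resolve_mtry(700) == 26
    assert RFParams(mtry=5).resolve_mtry(700) == 5
    assert RFParams().resolve_mtry(2) == 1


def test_training_deterministic_under_fixed_seed():
    t = _table()
    b1 = lb.train(t, RFParams(n_trees=100, seed=7))
    b2 = lb.train(t, RFParams(n_trees=100, seed=7))
    assert b1.oob_error == b2.oob_error
    pd.testing.assert_frame_equal(b1.oob_confusion, b2.oob_confusion)


def test_oob_confusion_rows_sum_to_class_counts():
    t = _table(n_per_class=(4, 8, 6))
    b = lb.train(t, RFParams(n_trees=200, seed=0))
    counts = t.y.value_counts()
    for c in b.classes:
        assert b.oob_confusion.loc[c].sum() == counts[c]
    total = b.oob_confusion.to_numpy().sum()
    assert b.oob_error == pytest.approx(
        1.0 - np.trace(b.oob_confusion.to_numpy()) / total)


def test_predict_votes_sum_to_one_and_favor_own_class():
    t = _table()
    b = lb.train(t, RFParams(n_trees=100, seed=0))
    label, votes = lb.predict(b, t.X.iloc[0], t.schema_id)
    assert votes.sum() == pytest.approx(1.0)
    assert label == t.y.iloc[0]
    assert votes[t.y.iloc[0]] == votes.max()


def test_predict_all_zero_vector_warns_but_returns():
    t = _table()
    b = lb.train(t, RFParams(n_trees=50, seed=0))
    zero = pd.Series(0.0, index=t.X.columns)
    with pytest.warns(UserWarning, match="no signal"):
        label, votes = lb.predict(b, zero, t.schema_id)
    assert label in b.classes


def test_predict_refuses_schema_mismatch():
    t = _table()
    b = lb.train(t, RFParams(n_trees=20, seed=0))
    with pytest.raises(SchemaMismatchError):
        lb.predict(b, t.X.iloc[0], "other-schema")


def test_evaluate_perfect_and_unseen_class():
    t = _table()
    b = lb.train(t, RFParams(n_trees=200, seed=0))
    conf, acc = lb.evaluate(b, t)
    assert acc == 1.0
    assert np.trace(conf.to_numpy()) == len(t)
    # held-out sample of a class the model never saw -> extra row
    extra = _table(n_per_class=(2,), seed=5)
    extra.y[:] = "classZ"
    extra = lb.FeatureTable(X=extra.X, y=extra.y, schema_id=t.schema_id)
    conf2, acc2 = lb.evaluate(b, extra)
    assert "classZ" in conf2.index and "classZ" not in conf2.columns
    assert acc2 == 0.0


def test_confusion_orientation_true_rows_predicted_columns():
    t = _table()
    b = lb.train(t, RFParams(n_trees=50, seed=0))
    conf, _ = lb.evaluate(b, t)
    assert conf.index.name == "true"
    assert conf.columns.name == "predicted"


def test_singleton_class_errors_unless_allowed():
    t = _table(n_per_class=(1, 6))
    with pytest.raises(UserInputError, match="singleton"):
        lb.train(t, RFParams(n_trees=20, seed=0))
    with pytest.warns(UserWarning, match="singleton"):
        b = lb.train(t, RFParams(n_trees=20, seed=0), allow_singleton=True)
    # the singleton class is excluded from OOB stats
    assert b.oob_confusion.loc["class0"].sum() == 0


def test_extension_with_nothing_new_reproduces_parent():
    t = _table()
    b = lb.train(t, RFParams(n_trees=100, seed=3))
    empty = lb.FeatureTable(X=t.X.iloc[0:0], y=t.y.iloc[0:0], schema_id=t.schema_id)
    b2 = lb.extend_training(b, empty)
    assert b2.oob_error == b.oob_error
    assert b2.manifest["parent_hash"] == b.bundle_hash


def test_extension_manifest_union_and_refusals():
    t1 = _table(n_per_class=(4, 4))
    t2 = _table(n_per_class=(3, 3), seed=1)
    t2 = lb.FeatureTable(X=t2.X.rename(index=lambda s: "new_" + s),
                         y=t2.y.rename(index=lambda s: "new_" + s),
                         schema_id=t1.schema_id)
    b1 = lb.train(t1, RFParams(n_trees=50, seed=0))
    b2 = lb.extend_training(b1, t2)
    assert sorted(b2.manifest["sample_ids"]) == sorted(
        list(t1.X.index) + list(t2.X.index))
    wrong = lb.FeatureTable(X=t2.X, y=t2.y, schema_id="different")
    with pytest.raises(SchemaMismatchError):
        lb.extend_training(b1, wrong)
    t3 = lb.FeatureTable(X=t2.X, y=t2.y, schema_id=t1.schema_id,
                         provenance={"reference_hash": "other"})
    b1.manifest["reference_hash"] = "original"
    with pytest.raises(SchemaMismatchError, match="reference"):
        lb.extend_training(b1, t3)


def test_label_permutation_gives_chance_level_oob():
    t = _table(n_per_class=(9, 9, 9), seed=2)
    rng = np.random.default_rng(0)
    t_perm = lb.FeatureTable(X=t.X, y=pd.Series(rng.permutation(t.y.to_numpy()),
                                                index=t.y.index, name="class_label"),
                             schema_id=t.schema_id)
    b = lb.train(t_perm, RFParams(n_trees=300, seed=0))
    k, n = 3, len(t_perm)
    se = np.sqrt((1 / k) * (1 - 1 / k) / n)
    assert abs((1.0 - b.oob_error) - 1 / k) <= 3 * se


def test_bundle_save_load_roundtrip(tmp_path):
    t = _table()
    b = lb.train(t, RFParams(n_trees=30, seed=0))
    lb.save_bundle(b, tmp_path / "model")
    back = lb.load_bundle(tmp_path / "model")
    assert back.oob_error == b.oob_error
    assert back.classes == b.classes
    assert back.schema_id == b.schema_id
    label1, _ = lb.predict(b, t.X.iloc[0], t.schema_id)
    label2, _ = lb.predict(back, t.X.iloc[0], t.schema_id)
    assert label1 == label2
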