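"""PUK kernel, training-set preparation, SMO training and evaluation."""

import numpy as np
import pandas as pd
import pytest

from pyrodenoise.classifier import (
    CLASS_ORDER,
    PukSvmModel,
    evaluate,
    prepare_training_sets,
    predict_mask,
    puk_gram,
    puk_kernel,
    train,
)
from pyrodenoise.features import FEATURE_COLUMNS


def _toy_instances(n_per_class=60, sep=10.0, seed=0):
    """Feature tables with classes at controlled distances (schema-shaped).

    ``n_per_class`` may be an int or a per-label dict.
    """
    rng = np.random.default_rng(seed)
    rows = []
    centers = {"clean": 0.0, "insertion": sep, "deletion": 2 * sep, "substitution": 3 * sep}
    idx = 0
    for label, mu in centers.items():
        n = n_per_class if isinstance(n_per_class, int) else n_per_class[label]
        for _ in range(n):
            idx += 1
            rows.append(
                {
                    "read_id": f"t{idx}",
                    "position": idx,
                    "phred": mu + rng.normal(0, 0.3),
                    "homopolymer_code": "N",
                    "carry_forward_sensitive": False,
                    "flow_intensity": mu + rng.normal(0, 0.3),
                    "prev_phred": 30,
                    "next_phred": 30,
                    "prev_homopolymer_code": "N",
                    "next_homopolymer_code": "N",
                    "prev_flow_intensity": 1.0,
                    "next_flow_intensity": 1.0,
                    "prev_max_uncalled": 0.0,
                    "next_max_uncalled": mu + rng.normal(0, 0.3),
                    "label": label,
                }
            )
    return pd.DataFrame(rows)


def test_puk_kernel_closed_forms():
    x = np.array([1.0, 2.0, 3.0])
    assert puk_kernel(x, x) == pytest.approx(1.0)
    # at distance sigma / (2 sqrt(2^(1/omega) - 1)) the kernel halves for omega=1
    omega, sigma = 1.0, 2.5
    d = sigma / (2.0 * np.sqrt(2.0 ** (1.0 / omega) - 1.0))
    y = x + np.array([d, 0.0, 0.0])
    assert puk_kernel(x, y, omega, sigma) == pytest.approx(0.5)
    # symmetric, decreasing in distance, bounded by (0, 1]
    z = x + 1.0
    assert puk_kernel(x, z) == pytest.approx(puk_kernel(z, x))
    assert puk_kernel(x, z) > puk_kernel(x, z + 5.0) > 0.0


def test_puk_kernel_validates_parameters():
    x = np.zeros(3)
    with pytest.raises(ValueError):
        puk_kernel(x, x, omega=-1.0)
    with pytest.raises(ValueError):
        puk_kernel(x, np.zeros(4))


def test_puk_gram_positive_semidefinite(rng):
    X = rng.normal(size=(50, 7))
    K = puk_gram(X, X, omega=1.3, sigma=0.8)
    assert np.allclose(K, K.T)
    eigvals = np.linalg.eigvalsh(K)
    assert eigvals.min() >= -1e-8


def test_prepare_training_sets_counts_and_determinism():
    inst = _toy_instances(
        n_per_class={"clean": 7500, "insertion": 1500, "deletion": 1500, "substitution": 1500},
        seed=3,
    )
    sets = prepare_training_sets(inst, seed=5)
    counts = sets.subset_a["label"].value_counts().to_dict()
    assert counts == {"clean": 700, "insertion": 132, "deletion": 132, "substitution": 132}
    again = prepare_training_sets(inst, seed=5)
    pd.testing.assert_frame_equal(sets.subset_a, again.subset_a)
    pd.testing.assert_frame_equal(sets.subset_b, again.subset_b)


def test_prepare_training_sets_dereplicates_and_separates():
    inst = _toy_instances(n_per_class=300, seed=4)
    dup = pd.concat([inst, inst.iloc[:100]], ignore_index=True)
    sets = prepare_training_sets(dup, seed=1)
    feats = list(FEATURE_COLUMNS)
    a = sets.subset_a[feats]
    b = sets.subset_b[feats]
    merged = a.merge(b, how="inner", on=feats)
    assert len(merged) == 0  # disjoint at feature-vector level
    both = pd.concat([a, b])
    assert not both.duplicated().any()


def test_prepare_training_sets_native_ratio():
    # 4000 clean / 100 error instances with unique vectors -> ratio 40:1
    table = _toy_instances(n_per_class=100, seed=7)
    clean_rows = []
    for i in range(4000):
        row = table[table["label"] == "clean"].iloc[0].copy()
        row["phred"] = float(i)  # unique vectors
        clean_rows.append(row)
    err_rows = []
    labels = ["insertion", "deletion", "substitution"]
    for i in range(100):
        row = table[table["label"] == labels[i % 3]].iloc[0].copy()
        row["phred"] = 10000.0 + i
        row["label"] = labels[i % 3]
        err_rows.append(row)
    table = pd.DataFrame(clean_rows + err_rows)
    with pytest.warns(UserWarning):
        sets = prepare_training_sets(table, seed=2)
    assert sets.native_clean_to_error == pytest.approx(40.0)


def test_prepare_training_sets_missing_class_rejected():
    inst = _toy_instances(n_per_class=50)
    no_del = inst[inst["label"] != "deletion"]
    with pytest.raises(ValueError, match="deletion"):
        prepare_training_sets(no_del)


def test_train_separable_toy_reaches_perfect_accuracy():
    inst = _toy_instances(n_per_class=300, sep=10.0, seed=8)
    sets = prepare_training_sets(inst, balance={c: 20 for c in CLASS_ORDER} | {"clean": 25}, seed=3)
    model = train(sets)
    pred = model.predict_frame(sets.subset_a)
    assert (pred == sets.subset_a["label"].to_numpy()).mean() == 1.0


def test_decision_values_match_sklearn_ovo():
    from sklearn.svm import SVC

    inst = _toy_instances(n_per_class=120, sep=3.0, seed=9)
    sets = prepare_training_sets(inst, balance={"clean": 40, "insertion": 30, "deletion": 30, "substitution": 30}, seed=3)
    model = train(sets, omega=1.2, sigma=0.9, C=2.0)
    from pyrodenoise.features import encode_matrix

    Xb, _ = encode_matrix(sets.subset_b)
    Xn = model.normalize(Xb)
    ours = model.decision_pairs(Xn)
    Xa, _ = encode_matrix(sets.subset_a)
    Xan = model.normalize(Xa)
    y = np.array([CLASS_ORDER.index(l) for l in sets.subset_a["label"]])
    svc = SVC(C=2.0, kernel=lambda A, B: puk_gram(A, B, 1.2, 0.9), decision_function_shape="ovo")
    svc.fit(Xan, y)
    theirs = svc.decision_function(Xn)
    assert np.allclose(ours, theirs, atol=1e-8)


def test_model_serialization_roundtrip(tmp_path):
    inst = _toy_instances(n_per_class=100, sep=2.0, seed=10)
    sets = prepare_training_sets(inst, balance={"clean": 30, "insertion": 20, "deletion": 20, "substitution": 20}, seed=3)
    model = train(sets)
    path = tmp_path / "model.json"
    model.save(path)
    back = PukSvmModel.load(path)
    pred1 = model.predict_frame(sets.subset_b)
    pred2 = back.predict_frame(sets.subset_b)
    assert (pred1 == pred2).all()
    # and a retrain on the same data gives identical predictions
    model2 = train(prepare_training_sets(inst, balance={"clean": 30, "insertion": 20, "deletion": 20, "substitution": 20}, seed=3))
    assert (model2.predict_frame(sets.subset_b) == pred1).all()


def test_corrupt_model_document_rejected(tmp_path):
    path = tmp_path / "bad.json"
    path.write_text('{"format": "something-else"}')
    with pytest.raises(ValueError, match="model document"):
        PukSvmModel.load(path)


class _ConstantModel:
    """Stub predictor for the evaluation arithmetic."""

    def __init__(self, label):
        self.label = label

    def predict_frame(self, frame, chunk=0):
        return np.array([self.label] * len(frame), dtype=object)


def test_evaluate_degenerate_predictors_and_arithmetic():
    inst = _toy_instances(n_per_class=50, seed=11)
    sens, spec, conf = evaluate(_ConstantModel("clean"), inst)
    assert sens == 0.0 and spec == 1.0
    sens, spec, conf = evaluate(_ConstantModel("insertion"), inst)
    assert sens == 1.0 and spec == 0.0
    # hand-check against the emitted confusion matrix
    tp = conf.loc[["insertion", "deletion", "substitution"], ["insertion", "deletion", "substitution"]].to_numpy().sum()
    fn = conf.loc[["insertion", "deletion", "substitution"], "clean"].sum()
    assert sens == pytest.approx(tp / (tp + fn))
    with pytest.raises(ValueError):
        evaluate(_ConstantModel("clean"), inst.iloc[:0])


def test_predict_mask_bounds_and_schema(references, sim_batch):
    refs, _ = references
    reads, _ = sim_batch
    sample = reads[:25]
    inst = _toy_instances(n_per_class=80, sep=2.0, seed=12)
    sets = prepare_training_sets(inst, balance={"clean": 25, "insertion": 15, "deletion": 15, "substitution": 15}, seed=3)
    model = train(sets)
    masks = predict_mask(model, sample)
    assert set(masks) == {r.read_id for r in sample}
    for read in sample:
        assert all(1 <= p <= len(read) for p in masks[read.read_id])
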