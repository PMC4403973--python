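"""Position-level error classifier: SVM with the Pearson VII universal kernel.

Training data preparation mirrors the published protocol: the labeled
instance table is dereplicated on exact feature-vector equality, split 1:9
into subset A (training) and subset B (held-out, native class ratio) in a
stratified way, and subset A is then balanced to 132 instances per error type
plus 700 clean instances by uniform random selection.

The kernel is

    K(x, y) = 1 / [1 + (2 * sqrt(2^(1/omega) - 1) * ||x - y|| / sigma)^2]^omega

a Pearson-VII-shaped radial kernel whose tail weight interpolates between
Gaussian and Lorentzian. Training uses scikit-learn's SVC (libsvm, a
sequential-minimal-optimization solver) with this kernel precomputed; the
default hyperparameters are omega = sigma = C = 1.

Prediction is performed by this module's own code from the serialized support
set — pairwise one-vs-one kernel-sum decisions and majority voting with a
deterministic tie-break (clean < insertion < deletion < substitution) — so a
saved model is a self-contained JSON document and predictions are exactly
reproducible. Features are min-max normalized to [0, 1] with statistics
frozen from subset A.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.svm import SVC

from pyrodenoise.features import FEATURE_COLUMNS, encode_matrix, features_frame
from pyrodenoise.flowgram_io import FlowRead

CLASS_ORDER = ("clean", "insertion", "deletion", "substitution")

DEFAULT_BALANCE = {"insertion": 132, "deletion": 132, "substitution": 132, "clean": 700}


@dataclass
class TrainingSets:
    """Dereplicated, stratified 1:9 split with a balanced training subset."""

    subset_a: pd.DataFrame
    subset_b: pd.DataFrame
    split_seed: int
    native_clean_to_error: float


def prepare_training_sets(
    instances: pd.DataFrame,
    ratio: float = 0.1,
    balance: dict[str, int] | None = None,
    seed: int = 0,
) -> TrainingSets:
    """Dereplicate, stratify-split 1:9, and balance the training subset.

    ``instances`` must carry the 13 feature columns plus ``label``. When a
    class has fewer instances than its balance target, all targets are scaled
    down proportionally (with a warning).
    """
    balance = dict(DEFAULT_BALANCE if balance is None else balance)
    feature_cols = list(FEATURE_COLUMNS)
    for cls in CLASS_ORDER:
        if (instances["label"] == cls).sum() == 0:
            raise ValueError(f"class {cls!r} absent from the instance table")
    derep = instances.drop_duplicates(subset=feature_cols, keep="first").reset_index(drop=True)
    n_clean = int((derep["label"] == "clean").sum())
    n_err = int((derep["label"] != "clean").sum())
    native = n_clean / max(n_err, 1)

    rng = np.random.default_rng(seed)
    a_parts: list[pd.DataFrame] = []
    b_parts: list[pd.DataFrame] = []
    for cls in CLASS_ORDER:
        grp = derep[derep["label"] == cls]
        perm = rng.permutation(len(grp))
        n_a = max(1, int(round(len(grp) * ratio)))
        a_parts.append(grp.iloc[perm[:n_a]])
        b_parts.append(grp.iloc[perm[n_a:]])
    a_raw = pd.concat(a_parts).reset_index(drop=True)
    subset_b = pd.concat(b_parts).reset_index(drop=True)

    avail = a_raw["label"].value_counts().to_dict()
    scale = min(avail.get(cls, 0) / tgt for cls, tgt in balance.items())
    if scale < 1.0:
        warnings.warn(
            f"training subset smaller than the balance targets; scaling targets by {scale:.3f}"
        )
        balance = {cls: max(1, int(tgt * scale)) for cls, tgt in balance.items()}
    picks: list[pd.DataFrame] = []
    for cls in CLASS_ORDER:
        grp = a_raw[a_raw["label"] == cls]
        take = rng.permutation(len(grp))[: balance[cls]]
        picks.append(grp.iloc[np.sort(take)])
    subset_a = pd.concat(picks).reset_index(drop=True)
    return TrainingSets(subset_a, subset_b, seed, native)


def puk_kernel(x, y, omega: float = 1.0, sigma: float = 1.0) -> float:
    """Pearson VII universal kernel value for two vectors."""
    if omega <= 0 or sigma <= 0:
        raise ValueError("omega and sigma must be positive")
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    d = float(np.linalg.norm(x - y))
    c = 2.0 * np.sqrt(2.0 ** (1.0 / omega) - 1.0) / sigma
    return float(1.0 / (1.0 + (c * d) ** 2) ** omega)


def puk_gram(X, Y, omega: float = 1.0, sigma: float = 1.0) -> np.ndarray:
    """PUK Gram matrix between row sets X and Y."""
    if omega <= 0 or sigma <= 0:
        raise ValueError("omega and sigma must be positive")
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    d = cdist(X, Y)
    c = 2.0 * np.sqrt(2.0 ** (1.0 / omega) - 1.0) / sigma
    return 1.0 / (1.0 + (c * d) ** 2) ** omega


@dataclass
class PukSvmModel:
    """Serializable one-vs-one PUK-SVM with frozen normalization statistics."""

    omega: float
    sigma: float
    C: float
    feature_names: list[str]
    norm_min: np.ndarray
    norm_max: np.ndarray
    classes: list[str]
    support_vectors: np.ndarray  # normalized
    dual_coef: np.ndarray  # (n_classes - 1, n_SV), libsvm packed layout
    intercept: np.ndarray  # one per class pair, (i, j) i < j in class order
    n_support: np.ndarray
    version: str = "1"

    # -- normalization ---------------------------------------------------
    def normalize(self, X: np.ndarray) -> np.ndarray:
        span = self.norm_max - self.norm_min
        span = np.where(span == 0.0, 1.0, span)
        return (np.asarray(X, dtype=np.float64) - self.norm_min) / span

    # -- decision machinery ----------------------------------------------
    def _class_slices(self) -> list[slice]:
        ends = np.cumsum(self.n_support)
        starts = np.concatenate([[0], ends[:-1]])
        return [slice(int(s), int(e)) for s, e in zip(starts, ends)]

    def decision_pairs(self, X_norm: np.ndarray) -> np.ndarray:
        """One-vs-one decision values, one column per class pair (i<j).

        Each value is the kernel sum over the two classes' support vectors
        with their dual coefficients plus the pair intercept; positive votes
        for the first class of the pair.
        """
        K = puk_gram(X_norm, self.support_vectors, self.omega, self.sigma)
        slices = self._class_slices()
        n_cls = len(self.classes)
        cols = []
        p = 0
        for i in range(n_cls):
            for j in range(i + 1, n_cls):
                dec = (
                    K[:, slices[i]] @ self.dual_coef[j - 1, slices[i]]
                    + K[:, slices[j]] @ self.dual_coef[i, slices[j]]
                    + self.intercept[p]
                )
                cols.append(dec)
                p += 1
        return np.column_stack(cols)

    def predict_norm(self, X_norm: np.ndarray, chunk: int = 20000) -> np.ndarray:
        """Class labels for pre-normalized rows (chunked for memory)."""
        out = np.empty(len(X_norm), dtype=object)
        n_cls = len(self.classes)
        pairs = [(i, j) for i in range(n_cls) for j in range(i + 1, n_cls)]
        for start in range(0, len(X_norm), chunk):
            block = X_norm[start : start + chunk]
            dec = self.decision_pairs(block)
            votes = np.zeros((len(block), n_cls), dtype=np.int32)
            for p, (i, j) in enumerate(pairs):
                pos = dec[:, p] > 0
                votes[pos, i] += 1
                votes[~pos, j] += 1
            # argmax takes the first maximum: ties break toward the earlier
            # class in CLASS_ORDER (clean < insertion < deletion < substitution)
            winners = np.argmax(votes, axis=1)
            out[start : start + chunk] = np.asarray(self.classes, dtype=object)[winners]
        return out

    def predict_frame(self, frame: pd.DataFrame, chunk: int = 20000) -> np.ndarray:
        """Class labels for a feature table (13 schema columns required)."""
        missing = [c for c in FEATURE_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"feature table is missing schema columns: {missing}")
        X, names = encode_matrix(frame)
        if names != self.feature_names:
            raise ValueError("feature schema mismatch with the trained model")
        return self.predict_norm(self.normalize(X), chunk=chunk)

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "format": "pyrodenoise-puk-svm",
            "version": self.version,
            "omega": self.omega,
            "sigma": self.sigma,
            "C": self.C,
            "feature_names": self.feature_names,
            "norm_min": self.norm_min.tolist(),
            "norm_max": self.norm_max.tolist(),
            "classes": self.classes,
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept.tolist(),
            "n_support": self.n_support.tolist(),
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "PukSvmModel":
        doc = json.loads(text)
        if doc.get("format") != "pyrodenoise-puk-svm":
            raise ValueError("not a pyrodenoise classifier model document")
        return cls(
            omega=doc["omega"],
            sigma=doc["sigma"],
            C=doc["C"],
            feature_names=list(doc["feature_names"]),
            norm_min=np.asarray(doc["norm_min"], dtype=np.float64),
            norm_max=np.asarray(doc["norm_max"], dtype=np.float64),
            classes=list(doc["classes"]),
            support_vectors=np.asarray(doc["support_vectors"], dtype=np.float64),
            dual_coef=np.asarray(doc["dual_coef"], dtype=np.float64),
            intercept=np.asarray(doc["intercept"], dtype=np.float64),
            n_support=np.asarray(doc["n_support"], dtype=np.int64),
            version=str(doc["version"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "PukSvmModel":
        return cls.from_json(Path(path).read_text())


def train(
    sets: TrainingSets,
    omega: float = 1.0,
    sigma: float = 1.0,
    C: float = 1.0,
) -> PukSvmModel:
    """Fit the one-vs-one PUK SVM on subset A (SMO via libsvm)."""
    frame = sets.subset_a
    X, names = encode_matrix(frame)
    norm_min = X.min(axis=0)
    norm_max = X.max(axis=0)
    span = np.where(norm_max - norm_min == 0.0, 1.0, norm_max - norm_min)
    Xn = (X - norm_min) / span
    y = np.array([CLASS_ORDER.index(l) for l in frame["label"]])
    present = sorted(set(y))
    if len(present) < 2:
        raise ValueError("training subset must contain at least two classes")

    svc = SVC(
        C=C,
        kernel=lambda A, B: puk_gram(A, B, omega, sigma),
        decision_function_shape="ovo",
    )
    svc.fit(Xn, y)
    classes = [CLASS_ORDER[int(c)] for c in svc.classes_]
    return PukSvmModel(
        omega=omega,
        sigma=sigma,
        C=C,
        feature_names=names,
        norm_min=norm_min,
        norm_max=norm_max,
        classes=classes,
        support_vectors=Xn[svc.support_],
        dual_coef=svc.dual_coef_.copy(),
        intercept=svc.intercept_.copy(),
        n_support=svc.n_support_.copy(),
    )


def evaluate(
    model: PukSvmModel,
    subset_b: pd.DataFrame,
) -> tuple[float, float, pd.DataFrame]:
    """Sensitivity, specificity and the per-class confusion matrix on subset B.

    Any error class counts as positive: sensitivity = TP / (TP + FN),
    specificity = TN / (TN + FP), both over per-position calls.
    """
    if len(subset_b) == 0:
        raise ValueError("held-out subset is empty")
    pred = model.predict_frame(subset_b)
    true = subset_b["label"].to_numpy()
    t_idx = np.array([CLASS_ORDER.index(t) for t in true])
    p_idx = np.array([CLASS_ORDER.index(p) for p in pred])
    counts = np.bincount(t_idx * len(CLASS_ORDER) + p_idx, minlength=16).reshape(4, 4)
    confusion = pd.DataFrame(counts, index=list(CLASS_ORDER), columns=list(CLASS_ORDER))
    actual_err = true != "clean"
    pred_err = pred != "clean"
    tp = int(np.sum(actual_err & pred_err))
    fn = int(np.sum(actual_err & ~pred_err))
    tn = int(np.sum(~actual_err & ~pred_err))
    fp = int(np.sum(~actual_err & pred_err))
    sensitivity = tp / (tp + fn) if (tp + fn) else 0.0
    specificity = tn / (tn + fp) if (tn + fp) else 0.0
    return sensitivity, specificity, confusion


def predict_mask(
    model: PukSvmModel,
    reads: list[FlowRead],
) -> dict[str, set[int]]:
    """Flag likely-erroneous 1-based positions per read.

    Features are extracted, normalized with the model's frozen statistics and
    classified; every position with a non-clean prediction enters the mask.
    """
    if not reads:
        return {}
    frame = features_frame(reads)
    pred = model.predict_frame(frame)
    masks: dict[str, set[int]] = {r.read_id: set() for r in reads}
    for rid, pos, label in zip(frame["read_id"], frame["position"], pred):
        if label != "clean":
            masks[rid].add(int(pos))
    return masks
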