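"""Random-forest origin classification with OOB evaluation.

The forest configuration follows the conventions of ranger-style RF
fingerprint classifiers: a large number of trees (5000 in production;
tests use fewer),
mtry = floor(sqrt(p)) features tried per split, terminal node size 1,
and inverse-class-frequency case weights w_i = 1/(k * n_class(i)) so
every class contributes equal total weight regardless of its size.
Forests are grown by scikit-learn's RandomForestClassifier; case weights
enter via ``sample_weight`` (weighted bootstrap contributions and
weighted impurity), the closest scikit-learn analogue of ranger's
``case.weights``.

The out-of-bag error — fraction of training samples misclassified by
the majority vote of only those trees whose bootstrap excluded them —
is the routine generalization estimate; it needs no held-out data, which
matters when every labeled sample should end up in the training table.

A trained model travels as an :class:`RFModelBundle`: forest + feature
schema id + class list + OOB confusion + a manifest of exactly which
samples trained it.  Extension ("continuous learning") appends verified
new samples to the table and retrains from scratch; lineage is recorded
via the parent bundle hash.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from ._util import stable_hash
from .errors import SchemaMismatchError, UserInputError
from .features import FeatureTable, concat_tables

__all__ = [
    "RFParams",
    "RFModelBundle",
    "case_weights",
    "train",
    "predict",
    "evaluate",
    "extend_training",
    "save_bundle",
    "load_bundle",
]


@dataclass(frozen=True)
class RFParams:
    """Forest hyperparameters (production default n_trees=5000)."""

    n_trees: int = 500
    mtry: Optional[int] = None  # None -> floor(sqrt(p))
    min_node_size: int = 1
    seed: int = 0
    weight_mode: str = "inverse"  # or "proportional"

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.weight_mode not in ("inverse", "proportional"):
            raise ValueError(f"unknown weight_mode {self.weight_mode!r}")

    def resolve_mtry(self, p: int) -> int:
        m = self.mtry if self.mtry is not None else int(math.floor(math.sqrt(p)))
        return max(1, min(m, p))


def case_weights(labels: pd.Series, mode: str = "inverse") -> np.ndarray:
    """Per-sample case weights compensating class imbalance.

    "inverse": w_i = 1/(k * n_class(i)) — each class's weights sum to
    1/k, so classes contribute equally however many samples they have.
    "proportional": w_i = n_class(i)/n (weights follow class size).
    """
    counts = labels.value_counts()
    k = len(counts)
    if mode == "inverse":
        return (1.0 / (k * counts[labels].to_numpy())).astype(float)
    return (counts[labels].to_numpy() / len(labels)).astype(float)


@dataclass
class RFModelBundle:
    model: RandomForestClassifier
    schema_id: str
    classes: list[str]
    params: RFParams
    oob_error: float
    oob_confusion: pd.DataFrame  # rows true, columns predicted
    manifest: dict
    table: FeatureTable  # retained so the bundle can be extended

    @property
    def bundle_hash(self) -> str:
        return stable_hash(self.manifest)


def _oob_stats(model: RandomForestClassifier, y: pd.Series,
               classes: list[str]) -> tuple[float, pd.DataFrame]:
    proba = model.oob_decision_function_
    has_votes = proba.sum(axis=1) > 0
    if not has_votes.all():
        warnings.warn(
            f"{int((~has_votes).sum())} sample(s) never out-of-bag; "
            "excluded from OOB statistics — increase n_trees"
        )
    pred = np.asarray(model.classes_)[np.argmax(proba, axis=1)]
    true = y.to_numpy()
    conf = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(true[has_votes], pred[has_votes]):
        conf.loc[t, p] += 1
    total = int(conf.to_numpy().sum())
    err = 1.0 - np.trace(conf.to_numpy()) / total if total else float("nan")
    conf.index.name = "true"
    conf.columns.name = "predicted"
    return float(err), conf


def train(table: FeatureTable, params: RFParams | None = None,
          allow_singleton: bool = False) -> RFModelBundle:
    """Grow a forest on a feature table with class-balancing case weights."""
    params = params or RFParams()
    counts = table.y.value_counts()
    if len(counts) < 2:
        raise UserInputError("training requires at least two classes")
    singletons = counts[counts < 2]
    if len(singletons):
        msg = f"singleton class(es) {sorted(singletons.index)}: OOB undefined"
        if not allow_singleton:
            raise UserInputError(msg + " (pass allow_singleton=True to keep them)")
        warnings.warn(msg + "; kept in the forest, excluded from OOB stats")
    w = case_weights(table.y, params.weight_mode)
    model = RandomForestClassifier(
        n_estimators=params.n_trees,
        max_features=params.resolve_mtry(table.X.shape[1]),
        min_samples_leaf=params.min_node_size,
        bootstrap=True,
        oob_score=True,
        random_state=params.seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Some inputs do not have OOB scores")
        model.fit(table.X.to_numpy(), table.y.to_numpy(), sample_weight=w)
    classes = table.classes
    non_singleton = table.y.isin(counts[counts >= 2].index).to_numpy()
    if non_singleton.all():
        oob_error, conf = _oob_stats(model, table.y, classes)
    else:
        # OOB stats over the non-singleton part only
        sub_y = table.y[non_singleton]
        proba = model.oob_decision_function_[non_singleton]
        pred = np.asarray(model.classes_)[np.argmax(proba, axis=1)]
        conf = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
        for t, p in zip(sub_y.to_numpy(), pred):
            conf.loc[t, p] += 1
        total = int(conf.to_numpy().sum())
        oob_error = 1.0 - np.trace(conf.to_numpy()) / total
        conf.index.name, conf.columns.name = "true", "predicted"
    manifest = {
        "sample_ids": list(map(str, table.X.index)),
        "labels": {str(k): str(v) for k, v in table.y.items()},
        "classes": classes,
        "schema_id": table.schema_id,
        "reference_hash": table.provenance.get("reference_hash"),
        "params": {"n_trees": params.n_trees, "mtry": params.resolve_mtry(table.X.shape[1]),
                   "min_node_size": params.min_node_size, "seed": params.seed,
                   "weight_mode": params.weight_mode},
        "parent_hash": None,
    }
    return RFModelBundle(model=model, schema_id=table.schema_id, classes=classes,
                         params=params, oob_error=oob_error, oob_confusion=conf,
                         manifest=manifest, table=table)


def predict(bundle: RFModelBundle, v: pd.Series,
            schema_id: Optional[str] = None) -> tuple[str, pd.Series]:
    """Classify one fused vector: majority-vote class + tree-vote fractions.

    The vector's schema id must equal the model's; there is no silent
    re-mapping of features between schemas.
    """
    if schema_id is not None and schema_id != bundle.schema_id:
        raise SchemaMismatchError(
            "prediction refused: schema ids differ\n"
            f"  model:  {bundle.schema_id}\n  sample: {schema_id}"
        )
    x = v.to_numpy(dtype=float).reshape(1, -1)
    if x.shape[1] != bundle.model.n_features_in_:
        raise SchemaMismatchError(
            f"vector has {x.shape[1]} features, model expects {bundle.model.n_features_in_}"
        )
    if float(np.abs(x).sum()) == 0.0:
        warnings.warn("all-zero feature vector: prediction carries no signal")
    votes = np.zeros(len(bundle.model.classes_))
    for est in bundle.model.estimators_:
        votes[int(est.predict(x)[0])] += 1
    votes /= votes.sum()
    fractions = pd.Series(votes, index=[str(c) for c in bundle.model.classes_],
                          name="vote_fraction")
    return str(fractions.idxmax()), fractions


def evaluate(bundle: RFModelBundle, table: FeatureTable) -> tuple[pd.DataFrame, float]:
    """Confusion matrix (rows true, columns predicted) and accuracy.

    Test samples of a class the model never saw appear as an extra row,
    never silently dropped.
    """
    if table.schema_id != bundle.schema_id:
        raise SchemaMismatchError(
            "evaluation refused: schema ids differ\n"
            f"  model: {bundle.schema_id}\n  table: {table.schema_id}"
        )
    pred = bundle.model.predict(table.X.to_numpy())
    true = table.y.to_numpy()
    rows = sorted(set(bundle.classes) | set(true))
    conf = pd.DataFrame(0, index=rows, columns=bundle.classes, dtype=int)
    for t, p in zip(true, pred):
        conf.loc[t, str(p)] += 1
    conf.index.name, conf.columns.name = "true", "predicted"
    correct = sum(conf.loc[c, c] for c in bundle.classes if c in conf.index)
    return conf, float(correct / len(true))


def extend_training(
    bundle: RFModelBundle,
    new_table: FeatureTable,
    params: RFParams | None = None,
) -> RFModelBundle:
    """Continuous-learning step: union the tables and retrain from scratch.

    Requires identical schema ids and reference hashes; records the
    parent bundle hash so model lineage is auditable.  With an empty
    ``new_table`` (0 rows is not representable, so pass the same seed
    and no overlapping rows) the retrained forest is identical.
    """
    if new_table.schema_id != bundle.schema_id:
        raise SchemaMismatchError(
            "extension refused: schema ids differ\n"
            f"  model: {bundle.schema_id}\n  new:   {new_table.schema_id}"
        )
    ref_old = bundle.manifest.get("reference_hash")
    ref_new = new_table.provenance.get("reference_hash")
    if ref_old is not None and ref_new is not None and ref_old != ref_new:
        raise SchemaMismatchError(
            "extension refused: runs were aligned against different references\n"
            f"  model: {ref_old}\n  new:   {ref_new}"
        )
    if len(new_table) == 0:
        union = bundle.table
    else:
        union = concat_tables(bundle.table, new_table)
    new_bundle = train(union, params or bundle.params)
    new_bundle.manifest["parent_hash"] = bundle.bundle_hash
    return new_bundle


# ---------------------------------------------------------------------------
# Persistence


def save_bundle(bundle: RFModelBundle, dirpath) -> Path:
    """Persist as a directory: forest.joblib + manifest.json + oob TSV."""
    d = Path(dirpath)
    d.mkdir(parents=True, exist_ok=True)
    joblib.dump(bundle.model, d / "forest.joblib")
    manifest = dict(bundle.manifest)
    manifest["oob_error"] = bundle.oob_error
    manifest["bundle_hash"] = bundle.bundle_hash
    (d / "manifest.json").write_text(json.dumps(manifest, indent=1))
    bundle.oob_confusion.to_csv(d / "oob_confusion.tsv", sep="\t")
    bundle.table.to_csv(d / "training_table.csv")
    return d


def load_bundle(dirpath) -> RFModelBundle:
    d = Path(dirpath)
    if not (d / "manifest.json").exists():
        raise UserInputError(f"no model bundle at {d} (manifest.json missing)")
    manifest = json.loads((d / "manifest.json").read_text())
    model = joblib.load(d / "forest.joblib")
    conf = pd.read_csv(d / "oob_confusion.tsv", sep="\t", index_col=0)
    table = FeatureTable.from_csv(d / "training_table.csv")
    p = manifest["params"]
    params = RFParams(n_trees=p["n_trees"], mtry=p["mtry"],
                      min_node_size=p["min_node_size"], seed=p["seed"],
                      weight_mode=p["weight_mode"])
    saved = {k: v for k, v in manifest.items() if k not in ("oob_error", "bundle_hash")}
    return RFModelBundle(model=model, schema_id=manifest["schema_id"],
                         classes=manifest["classes"], params=params,
                         oob_error=manifest["oob_error"], oob_confusion=conf,
                         manifest=saved, table=table)
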