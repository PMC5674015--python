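"""Random-forest classification with vote-margin confidence and active learning.

The classifier is a random forest over the K x F feature store. Confidence
for object i is the absolute tree-vote margin

    c_i = | sum_j t_j |,   t_j in {-1, +1},  j = 1..N trees,

which is 0 at a 50/50 vote split and N at unanimity. Active learning
iterates: train on the current labels, predict the whole store, present the
k least-confident unlabeled objects for labeling, and repeat — building a
training set concentrated near the decision boundary instead of wasting
annotator effort on redundant, confidently-classified objects.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .data_model import (
    IGNORE,
    NEGATIVE,
    POSITIVE,
    DataValidationError,
    FeatureStore,
    LabelSet,
    SlideMeta,
)

__all__ = [
    "ForestParams",
    "ForestModel",
    "PredictionResult",
    "Heatmap",
    "LoopHistory",
    "train_forest",
    "predict_confidence",
    "select_instances",
    "build_heatmap",
    "rank_slides",
    "run_learning_loop",
    "evaluate_auc",
    "trapezoidal_auc",
    "apply_label_edits",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ForestParams:
    """Random-forest configuration.

    Defaults are 100 trees of maximum depth 10 with mtry = round(sqrt(F))
    features considered per split — 7 for a 48-feature store.
    """

    n_trees: int = 100
    max_depth: int = 10
    mtry: int | None = None  # None -> round(sqrt(F)) at fit time
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.max_depth < 1:
            raise DataValidationError("n_trees and max_depth must be positive")
        if self.mtry is not None and self.mtry < 1:
            raise DataValidationError("mtry must be positive")

    def resolve_mtry(self, n_features: int) -> int:
        mtry = self.mtry if self.mtry is not None else round(math.sqrt(n_features))
        mtry = int(mtry)
        if not (1 <= mtry <= n_features):
            raise DataValidationError(
                f"mtry={mtry} outside [1, F={n_features}]"
            )
        return mtry


@dataclass
class ForestModel:
    """A trained ensemble plus the exact training snapshot that produced it."""

    params: ForestParams
    forest: RandomForestClassifier
    n_features: int
    training_snapshot: list[tuple[int, int]]  # (object_id, label), sorted

    @property
    def n_trees(self) -> int:
        return self.params.n_trees


@dataclass
class PredictionResult:
    """Per-object class and vote-margin confidence for one store."""

    object_ids: np.ndarray
    votes_pos: np.ndarray  # trees voting +1
    predicted: np.ndarray  # sign in {-1, +1}
    confidence: np.ndarray  # c_i = |2*votes_pos - N| in {0..N}
    n_trees: int

    @property
    def confidence_norm(self) -> np.ndarray:
        return self.confidence / self.n_trees

    @property
    def score(self) -> np.ndarray:
        """Continuous classification score: positive vote fraction in [0, 1]."""
        return self.votes_pos / self.n_trees

    def to_frame(self, store: FeatureStore | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "object_id": self.object_ids,
                "votes_pos": self.votes_pos,
                "predicted": self.predicted,
                "confidence": self.confidence,
                "confidence_norm": self.confidence_norm,
            }
        )
        if store is not None:
            df.insert(1, "slide_id", store.slide_ids)
        return df


def _effective_training(labels: LabelSet) -> tuple[list[int], np.ndarray]:
    ids = labels.labeled_ids()  # sorted, IGNORE excluded
    y = labels.labels_for(ids)
    return ids, y


def train_forest(
    store: FeatureStore, labels: LabelSet, params: ForestParams | None = None
) -> ForestModel:
    """Fit a random forest on the effective (non-IGNORE) labels.

    Deterministic given ``params.seed``; the model records its training
    snapshot so a run can be audited or reproduced exactly.
    """
    params = params or ForestParams()
    ids, y = _effective_training(labels)
    classes = set(int(v) for v in y)
    if classes != {NEGATIVE, POSITIVE}:
        raise DataValidationError(
            "training labels must include both classes (+1 and -1); "
            "label at least one object of each class"
        )
    rows = store.rows_of(ids)
    X = store.features[rows]
    mtry = params.resolve_mtry(store.n_features)
    forest = RandomForestClassifier(
        n_estimators=params.n_trees,
        max_depth=params.max_depth,
        max_features=mtry,
        random_state=params.seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return ForestModel(
        params=params,
        forest=forest,
        n_features=store.n_features,
        training_snapshot=[(int(o), int(l)) for o, l in zip(ids, y)],
    )


def _per_tree_votes_pos(model: ForestModel, X: np.ndarray) -> np.ndarray:
    """Count trees voting +1 for each row, from raw per-tree leaf classes.

    Uses forest.apply() to fetch each sample's leaf per tree, then maps the
    leaf to that tree's majority class — the individual tree's vote — rather
    than averaging probabilities across the ensemble.
    """
    leaves = model.forest.apply(X)  # (K, N) leaf indices
    # trees inside a forest predict indices into forest.classes_
    pos_index = int(np.flatnonzero(model.forest.classes_ == POSITIVE)[0])
    votes_pos = np.zeros(X.shape[0], dtype=np.int64)
    for j, est in enumerate(model.forest.estimators_):
        leaf_values = est.tree_.value[:, 0, :]  # (n_nodes, n_classes)
        leaf_votes_pos = np.argmax(leaf_values, axis=1) == pos_index
        votes_pos += leaf_votes_pos[leaves[:, j]]
    return votes_pos


def predict_confidence(
    model: ForestModel, store: FeatureStore, rows: np.ndarray | None = None
) -> PredictionResult:
    """Predict class and vote-margin confidence for every object (or a subset).

    The confidence is computed from raw per-tree votes: c_i = |2v_i - N|
    where v_i counts trees voting +1. A tie (even N, v = N/2) is predicted
    negative, reflecting that positives are rare in the motivating use;
    confidence is 0 there regardless.
    """
    if store.n_features != model.n_features:
        raise DataValidationError(
            f"store has F={store.n_features} features, model expects "
            f"{model.n_features}"
        )
    X = store.features if rows is None else store.features[rows]
    oids = store.object_ids if rows is None else store.object_ids[rows]
    n = model.n_trees
    votes_pos = _per_tree_votes_pos(model, X)
    confidence = np.abs(2 * votes_pos - n)
    predicted = np.where(votes_pos * 2 > n, POSITIVE, NEGATIVE)
    return PredictionResult(
        object_ids=np.asarray(oids),
        votes_pos=votes_pos,
        predicted=predicted,
        confidence=confidence,
        n_trees=n,
    )


def select_instances(
    pred: PredictionResult,
    labels: LabelSet,
    k: int = 8,
    candidates: set[int] | None = None,
) -> list[int]:
    """The k least-confident unlabeled objects, ties broken by object id.

    Objects already labeled — including IGNORE — are never returned. If
    ``candidates`` is given, selection is restricted to those ids (used to
    keep held-out validation slides out of training). Fewer than k unlabeled
    objects yields all of them with a warning.
    """
    if k < 1:
        raise DataValidationError("k must be positive")
    unlabeled = np.fromiter(
        (int(o) not in labels for o in pred.object_ids), dtype=bool,
        count=len(pred.object_ids),
    )
    if candidates is not None:
        in_cand = np.fromiter(
            (int(o) in candidates for o in pred.object_ids), dtype=bool,
            count=len(pred.object_ids),
        )
        unlabeled &= in_cand
    idx = np.flatnonzero(unlabeled)
    if len(idx) < k:
        warnings.warn(
            f"only {len(idx)} unlabeled objects available (requested {k})",
            stacklevel=2,
        )
    order = np.lexsort((pred.object_ids[idx], pred.confidence[idx]))
    return [int(o) for o in pred.object_ids[idx[order[:k]]]]


@dataclass
class Heatmap:
    """Per-slide grid of object, low-confidence and positive counts."""

    slide_id: str
    cell_size_px: int
    threshold_norm: float
    object_count: np.ndarray  # (rows, cols), rows index y
    low_confidence_count: np.ndarray
    positive_count: np.ndarray

    @property
    def n_objects(self) -> int:
        return int(self.object_count.sum())

    @property
    def n_low_confidence(self) -> int:
        return int(self.low_confidence_count.sum())

    def to_frame(self) -> pd.DataFrame:
        rows, cols = np.nonzero(self.object_count)
        return pd.DataFrame(
            {
                "row": rows,
                "col": cols,
                "object_count": self.object_count[rows, cols],
                "low_conf_count": self.low_confidence_count[rows, cols],
                "positive_count": self.positive_count[rows, cols],
            }
        )

    def save_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_heatmap(
    pred: PredictionResult,
    store: FeatureStore,
    slide: SlideMeta,
    cell_size_px: int = 512,
    threshold_norm: float = 0.25,
) -> Heatmap:
    """Bin one slide's objects into a grid of labeling-priority counts.

    Each object falls in cell (floor(x/cell), floor(y/cell)). A cell's
    low-confidence count uses ``confidence_norm <= threshold_norm``; hotspots
    enriched in low-confidence objects guide heatmap-based labeling, and the
    positive channel shows the density of positively classified objects.
    """
    if cell_size_px <= 0:
        raise DataValidationError("cell_size_px must be positive")
    mask = store.slide_mask(slide.slide_id)
    xy = store.centroids[mask]
    oids = store.object_ids[mask]
    pred_rows = np.flatnonzero(mask)
    # PredictionResult rows are store-aligned when predicted over the full store
    if len(pred.object_ids) != store.n_objects or not np.array_equal(
        pred.object_ids, store.object_ids
    ):
        raise DataValidationError("prediction must cover the full store, row-aligned")
    conf_norm = pred.confidence_norm[pred_rows]
    positive = pred.predicted[pred_rows] == POSITIVE

    out_of_bounds = (
        (xy[:, 0] < 0)
        | (xy[:, 0] >= slide.width_px)
        | (xy[:, 1] < 0)
        | (xy[:, 1] >= slide.height_px)
    )
    if out_of_bounds.any():
        bad = oids[out_of_bounds][0]
        raise DataValidationError(
            f"object {int(bad)} lies outside slide {slide.slide_id} bounds"
        )

    n_cols = math.ceil(slide.width_px / cell_size_px)
    n_rows = math.ceil(slide.height_px / cell_size_px)
    col = (xy[:, 0] // cell_size_px).astype(int)
    row = (xy[:, 1] // cell_size_px).astype(int)
    shape = (n_rows, n_cols)
    object_count = np.zeros(shape, dtype=np.int64)
    low_count = np.zeros(shape, dtype=np.int64)
    pos_count = np.zeros(shape, dtype=np.int64)
    np.add.at(object_count, (row, col), 1)
    np.add.at(low_count, (row, col), conf_norm <= threshold_norm)
    np.add.at(pos_count, (row, col), positive)
    return Heatmap(
        slide_id=slide.slide_id,
        cell_size_px=cell_size_px,
        threshold_norm=threshold_norm,
        object_count=object_count,
        low_confidence_count=low_count,
        positive_count=pos_count,
    )


def rank_slides(heatmaps: Sequence[Heatmap]) -> pd.DataFrame:
    """Order slides by their fraction of low-confidence objects, descending.

    Slides rich in low-confidence objects are where labeling effort pays
    off most; ties break lexically by slide id.
    """
    if not heatmaps:
        raise DataValidationError("need at least one heatmap")
    df = pd.DataFrame(
        {
            "slide_id": [h.slide_id for h in heatmaps],
            "n_objects": [h.n_objects for h in heatmaps],
            "n_low_confidence": [h.n_low_confidence for h in heatmaps],
        }
    )
    with np.errstate(invalid="ignore"):
        df["frac_low_confidence"] = np.where(
            df["n_objects"] > 0, df["n_low_confidence"] / df["n_objects"], 0.0
        )
    df = df.sort_values(
        ["frac_low_confidence", "slide_id"], ascending=[False, True]
    ).reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def trapezoidal_auc(
    y_true: np.ndarray, scores: np.ndarray
) -> tuple[float, np.ndarray]:
    """ROC AUC by trapezoidal integration over all score thresholds.

    Tied scores are grouped into a single threshold, which makes the area
    equal to the Mann–Whitney concordance probability with ties counted 1/2.
    Returns (auc, roc) where roc is an (m, 2) array of (fpr, tpr).
    """
    y_true = np.asarray(y_true)
    if len(set(np.unique(y_true))) < 2:
        raise DataValidationError("AUC needs both classes present")
    fpr, tpr, _ = _sk_roc_curve(y_true, scores, pos_label=POSITIVE)
    return float(_sk_auc(fpr, tpr)), np.column_stack([fpr, tpr])


def evaluate_auc(
    model: ForestModel, store: FeatureStore, validation: LabelSet
) -> tuple[float, np.ndarray]:
    """Held-out AUC of the model's continuous score (positive vote fraction)."""
    ids = validation.labeled_ids()
    if not ids:
        raise DataValidationError("validation set has no effective labels")
    y = validation.labels_for(ids)
    if set(int(v) for v in y) != {NEGATIVE, POSITIVE}:
        raise DataValidationError("validation set must include both classes")
    rows = store.rows_of(ids)
    pred = predict_confidence(model, store, rows=rows)
    return trapezoidal_auc(y, pred.score)


# ---------------------------------------------------------------------------
# The label-update-predict loop
# ---------------------------------------------------------------------------


@dataclass
class LoopHistory:
    """Per-iteration record of the active-learning loop."""

    records: list[dict] = field(default_factory=list)

    def append(
        self,
        iteration: int,
        added_ids: Sequence[int],
        sources: Sequence[str],
        train_size: int,
        auc: float | None,
    ) -> None:
        if self.records and train_size <= self.records[-1]["train_size"] and added_ids:
            raise DataValidationError("training-set size must strictly increase")
        self.records.append(
            {
                "iteration": iteration,
                "n_added": len(added_ids),
                "added_ids": "|".join(str(i) for i in added_ids),
                "sources": "|".join(sources),
                "train_size": train_size,
                "auc": float("nan") if auc is None else auc,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.records,
            columns=["iteration", "n_added", "added_ids", "sources", "train_size", "auc"],
        )

    def save_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    @property
    def final_auc(self) -> float:
        return self.records[-1]["auc"] if self.records else float("nan")


def run_learning_loop(
    store: FeatureStore,
    seed_labels: LabelSet,
    oracle: Callable[[int], int],
    params: ForestParams | None = None,
    k: int = 8,
    max_iterations: int | None = None,
    auc_target: float | None = None,
    validation: LabelSet | None = None,
    strategy: str = "uncertainty",
    candidates: set[int] | None = None,
    master_seed: int | None = None,
) -> tuple[ForestModel, LabelSet, LoopHistory]:
    """Run the closed label-update-predict cycle against a labeling oracle.

    Iteration 0 trains on the seed labels alone; each later iteration adds k
    oracle-labeled objects (least-confident under ``strategy='uncertainty'``,
    or uniformly random under ``'random'`` as a baseline), retrains from
    scratch, and records held-out AUC when a validation set is provided.
    Stops at ``max_iterations`` or when ``auc_target`` is reached. Fully
    reproducible: one master seed fans out to the forest seed and any
    sampling.

    Returns the final model, the accumulated label set, and the history.
    """
    if max_iterations is None and auc_target is None:
        raise DataValidationError("provide a stop criterion: max_iterations or auc_target")
    if strategy not in ("uncertainty", "random"):
        raise DataValidationError(f"unknown strategy {strategy!r}")
    if max_iterations is None:
        max_iterations = 200  # safety cap when only auc_target is given

    if master_seed is not None:
        ss = np.random.SeedSequence(master_seed)
        forest_seed, sample_seed = (
            int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)
        )
        params = ForestParams(
            n_trees=(params or ForestParams()).n_trees,
            max_depth=(params or ForestParams()).max_depth,
            mtry=(params or ForestParams()).mtry,
            seed=forest_seed,
        )
        rng = np.random.default_rng(sample_seed)
    else:
        params = params or ForestParams()
        rng = np.random.default_rng(params.seed)

    labels = seed_labels.copy()
    history = LoopHistory()

    def _evaluate(model: ForestModel) -> float | None:
        if validation is None:
            return None
        auc, _ = evaluate_auc(model, store, validation)
        return auc

    model = train_forest(store, labels, params)
    auc = _evaluate(model)
    history.append(0, sorted(labels.entries), ["seed"] * len(labels), labels.n_effective(), auc)

    for it in range(1, max_iterations + 1):
        if auc_target is not None and auc is not None and auc >= auc_target:
            break
        if strategy == "uncertainty":
            pred = predict_confidence(model, store)
            chosen = select_instances(pred, labels, k=k, candidates=candidates)
        else:
            pool = candidates if candidates is not None else set(
                int(o) for o in store.object_ids
            )
            avail = sorted(o for o in pool if o not in labels)
            if len(avail) < k:
                warnings.warn(f"only {len(avail)} unlabeled objects left", stacklevel=2)
            take = min(k, len(avail))
            chosen = [int(o) for o in rng.choice(avail, size=take, replace=False)]
        if not chosen:
            break
        for oid in chosen:
            labels.add(oid, oracle(oid), source="instance", iteration=it)
        model = train_forest(store, labels, params)
        auc = _evaluate(model)
        history.append(it, chosen, ["instance"] * len(chosen), labels.n_effective(), auc)

    return model, labels, history


def save_model(model: ForestModel, directory) -> None:
    """Export a model as a versioned archive directory.

    Contents: params.yaml (forest configuration + format version),
    snapshot.csv (the exact training labels used), ensemble.pkl (the
    serialized tree ensemble).
    """
    import pickle
    from pathlib import Path

    import yaml

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    with open(d / "params.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(
            {
                "format": "histolearn-forest",
                "version": 1,
                "n_trees": model.params.n_trees,
                "max_depth": model.params.max_depth,
                "mtry": model.params.mtry,
                "seed": model.params.seed,
                "n_features": model.n_features,
            },
            fh,
        )
    pd.DataFrame(model.training_snapshot, columns=["object_id", "label"]).to_csv(
        d / "snapshot.csv", index=False
    )
    with open(d / "ensemble.pkl", "wb") as fh:
        pickle.dump(model.forest, fh)


def load_model(directory) -> ForestModel:
    import pickle
    from pathlib import Path

    import yaml

    d = Path(directory)
    with open(d / "params.yaml", "r", encoding="utf-8") as fh:
        meta = yaml.safe_load(fh)
    if meta.get("format") != "histolearn-forest":
        raise DataValidationError(f"{d} is not a model archive")
    snapshot = pd.read_csv(d / "snapshot.csv")
    with open(d / "ensemble.pkl", "rb") as fh:
        forest = pickle.load(fh)
    params = ForestParams(
        n_trees=meta["n_trees"],
        max_depth=meta["max_depth"],
        mtry=meta["mtry"],
        seed=meta["seed"],
    )
    return ForestModel(
        params=params,
        forest=forest,
        n_features=meta["n_features"],
        training_snapshot=[
            (int(r.object_id), int(r.label)) for r in snapshot.itertuples(index=False)
        ],
    )


def apply_label_edits(
    labels: LabelSet, edits: Iterable[tuple[int, int]]
) -> LabelSet:
    """Apply review edits (relabel or IGNORE) to an existing label set.

    Each edit targets an already-labeled object; provenance becomes
    ``source='review'`` (iteration preserved). Idempotent for repeated
    identical edits, and a batch equals sequential application.
    """
    out = labels.copy()
    for oid, new_label in edits:
        oid = int(oid)
        if oid not in out.entries:
            raise KeyError(f"object_id {oid} has no existing label to edit")
        out.add(oid, int(new_label), source="review", iteration=out.iteration[oid])
    return out
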