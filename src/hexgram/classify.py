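"""Random-forest classification of hexapeptides and peptide-level calls.

A random forest is trained on the binary occurrence vectors of the
QuiPT-selected n-grams of hexapeptides.  A hexapeptide's amyloidogenicity
probability is the fraction of trees voting amyloid.  A peptide is then
scored by the *maximum* probability over its hexapeptides, and called
amyloid iff that score reaches the decision threshold -- equivalent to
the rule "amyloid iff at least one hexapeptide is amyloidogenic" at
every threshold.  A probability exactly at the threshold counts as
amyloid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .alphabets import Encoding
from .ngrams import FeatureMatrix, NGramFeature, extract_features
from .peptides import Hexapeptide, PeptideSet, extract_hexapeptides

_MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    """Forest hyperparameters.

    mtry (features tried per split) defaults to the rounded-down square
    root of the number of selected features when left as None.
    """

    seed: int
    n_trees: int = 500
    mtry: int | None = None
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")


@dataclass
class TrainedModel:
    """Fitted forest plus everything needed to re-featurize raw peptides."""

    forest: RandomForestClassifier
    feature_ids: tuple[str, ...]
    encoding: Encoding
    config: ModelConfig

    @property
    def oob_error(self) -> float:
        return 1.0 - float(self.forest.oob_score_)


@dataclass(frozen=True)
class PeptidePrediction:
    peptide_id: str
    hexapeptide_probs: tuple[float, ...]
    peptide_score: float
    call: int


def train_model(
    fm: FeatureMatrix, selected: Sequence[str], cfg: ModelConfig
) -> TrainedModel:
    """Fit a random forest on the selected feature columns.

    Deterministic given ``cfg.seed``.  Requires a non-empty selection
    (all ids present in the matrix) and both classes in the labels.
    """
    selected = list(selected)
    if not selected:
        raise ValueError("selected feature set is empty")
    missing = [f for f in selected if f not in fm.feature_ids]
    if missing:
        raise ValueError(f"selected features absent from matrix: {missing[:5]}")
    y = fm.labels
    if len(np.unique(y)) < 2:
        raise ValueError("training data contain a single class")
    sub = fm.subset(selected)
    mtry = cfg.mtry if cfg.mtry is not None else max(1, math.floor(math.sqrt(len(selected))))
    if mtry > len(selected):
        raise ValueError(f"mtry {mtry} exceeds number of selected features {len(selected)}")
    forest = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_features=mtry,
        random_state=cfg.seed,
        oob_score=True,
        n_jobs=1,
    )
    if fm.encoding is None:
        raise ValueError(
            "feature matrix carries no encoding; build it with extract_features"
        )
    forest.fit(sub.X, y)
    return TrainedModel(forest, tuple(selected), fm.encoding, cfg)


def vote_fractions(forest: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """Fraction of trees whose hard vote is the amyloid class."""
    classes = list(forest.classes_)
    pos = classes.index(1)
    votes = np.stack([tree.predict(X.astype(np.float32)) for tree in forest.estimators_])
    return (votes == forest.classes_[pos]).mean(axis=0)


def predict_hexapeptides(
    model: TrainedModel, hexes: Iterable[Hexapeptide]
) -> np.ndarray:
    """One amyloid probability (tree-vote fraction) per hexapeptide.

    Hexapeptides are re-featurized with the model's stored encoding and
    feature-id list, so prediction is self-contained.
    """
    hexes = list(hexes)
    if not hexes:
        return np.empty(0)
    features = [NGramFeature.from_id(fid) for fid in model.feature_ids]
    fm = extract_features(hexes, model.encoding, feature_space=features)
    return vote_fractions(model.forest, fm.X)


def aggregate_peptide(
    probs: Sequence[float], threshold: float = 0.5
) -> tuple[float, int]:
    """Peptide score = max hexapeptide probability; call = score >= threshold."""
    probs = list(probs)
    if not probs:
        raise ValueError("cannot aggregate an empty probability sequence")
    score = float(max(probs))
    return score, int(score >= threshold)


def predict_peptides(model: TrainedModel, ps: PeptideSet) -> list[PeptidePrediction]:
    """Full pipeline: extract hexapeptides, score them, aggregate per peptide."""
    hexes = extract_hexapeptides(ps)
    probs = predict_hexapeptides(model, hexes)
    by_parent: dict[str, list[float]] = {rec.id: [] for rec in ps}
    for h, p in zip(hexes, probs):
        by_parent[h.parent_id].append(float(p))
    out: list[PeptidePrediction] = []
    for rec in ps:
        score, call = aggregate_peptide(by_parent[rec.id], model.config.threshold)
        out.append(PeptidePrediction(rec.id, tuple(by_parent[rec.id]), score, call))
    return out


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize forest, encoding, feature ids and config as one archive."""
    joblib.dump(
        {
            "format_version": _MODEL_FORMAT_VERSION,
            "forest": model.forest,
            "feature_ids": list(model.feature_ids),
            "encoding_groups": list(model.encoding.groups),
            "config": {
                "seed": model.config.seed,
                "n_trees": model.config.n_trees,
                "mtry": model.config.mtry,
                "threshold": model.config.threshold,
            },
        },
        path,
    )


def load_model(path: str | Path) -> TrainedModel:
    blob = joblib.load(path)
    version = blob.get("format_version")
    if version != _MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {version!r}")
    return TrainedModel(
        forest=blob["forest"],
        feature_ids=tuple(blob["feature_ids"]),
        encoding=Encoding(blob["encoding_groups"]),
        config=ModelConfig(**blob["config"]),
    )
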