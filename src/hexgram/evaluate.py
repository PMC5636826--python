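"""Repeated peptide-level cross-validation, metrics and encoding ranking.

Cross-validation assigns *peptides* (never hexapeptides) to folds:
every hexapeptide inherits its parent's fold, so no sequence leaks
between training and test.  Feature selection (QuiPT) is refit inside
each training part.  Held-out test peptides are scored by the max-rule
aggregation and metrics are reported separately for each test length
stratum (6, 7-10, 11-15, 16-25, plus "all"); an optional set of long
peptides, never trained on, is split into the same folds and evaluated
alongside.

Encodings are compared by ranking their mean AUC within each test
stratum (rank 1 = best, midranks for ties) and summing ranks across
strata; the winner has the smallest rank sum, ties broken by grand-mean
AUC.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import quipt
from .alphabets import Encoding
from .classify import ModelConfig, aggregate_peptide, predict_hexapeptides, train_model
from .ngrams import extract_features, generate_feature_space
from .peptides import TEST_STRATA, PeptideSet, extract_hexapeptides

logger = logging.getLogger(__name__)

METRICS = ("auc", "mcc", "sensitivity", "specificity")


@dataclass(frozen=True)
class CVPlan:
    """Fold/repeat layout of a repeated cross-validation run."""

    seed: int
    n_folds: int = 5
    n_repeats: int = 15
    training_stratum: str | None = None  # recorded label, e.g. "6-10"

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")
        if self.n_repeats < 1:
            raise ValueError("need at least 1 repeat")


@dataclass
class EvaluationReport:
    """Tidy per-(repeat, fold, stratum) metric records for one encoding."""

    records: pd.DataFrame
    encoding: Encoding | None = None
    fold_assignments: dict[tuple[int, int], tuple[str, ...]] = field(default_factory=dict)

    def aggregate(self) -> pd.DataFrame:
        """Mean and SD of each metric per stratum, degenerate folds excluded."""
        ok = self.records[~self.records["degenerate"]]
        return ok.groupby("stratum")[list(METRICS)].agg(["mean", "std"])

    def mean_auc(self, stratum: str = "all") -> float:
        ok = self.records[
            (~self.records["degenerate"]) & (self.records["stratum"] == stratum)
        ]
        return float(ok["auc"].mean())


@dataclass(frozen=True)
class EncodingRanking:
    table: pd.DataFrame  # index: encoding name; per-stratum ranks, rank_sum, grand_mean_auc
    winner: str


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> dict[str, float | None]:
    """Sensitivity, specificity and MCC from a 2x2 confusion table.

    Undefined ratios (zero denominator) are returned as None rather than
    coerced to 0.
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    if tp + fp + tn + fn < 1:
        raise ValueError("empty confusion table")
    sens = tp / (tp + fn) if tp + fn else None
    spec = tn / (tn + fp) if tn + fp else None
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom else None
    return {"sensitivity": sens, "specificity": spec, "mcc": mcc}


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based (Mann-Whitney) AUC with midranks for ties."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-d and equally long")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _fold_assignment(
    ids: Sequence[str], n_folds: int, rng: np.random.Generator
) -> dict[str, int]:
    order = rng.permutation(len(ids))
    folds = np.arange(len(ids)) % n_folds
    return {ids[i]: int(folds[j]) for j, i in enumerate(order)}


def _stratum_of(length: int) -> str | None:
    for name, (lo, hi) in TEST_STRATA.items():
        if lo <= length <= hi:
            return name
    return None


def _evaluate_fold(
    test_records: list, scores: dict[str, float], threshold: float
) -> list[dict]:
    """Metric rows per length stratum (plus 'all') for one test fold."""
    rows = []
    by_stratum: dict[str, list] = {"all": []}
    for rec in test_records:
        by_stratum["all"].append(rec)
        st = _stratum_of(len(rec))
        if st is not None:
            by_stratum.setdefault(st, []).append(rec)
    for stratum, recs in by_stratum.items():
        y = np.array([r.label for r in recs])
        s = np.array([scores[r.id] for r in recs])
        n_pos = int((y == 1).sum())
        n_neg = int((y == 0).sum())
        row = {
            "stratum": stratum,
            "n_pos": n_pos,
            "n_neg": n_neg,
            "degenerate": n_pos == 0 or n_neg == 0,
        }
        if row["degenerate"]:
            row.update({m: np.nan for m in METRICS})
        else:
            calls = (s >= threshold).astype(int)
            tp = int(((calls == 1) & (y == 1)).sum())
            fp = int(((calls == 1) & (y == 0)).sum())
            tn = int(((calls == 0) & (y == 0)).sum())
            fn = int(((calls == 0) & (y == 1)).sum())
            cm = confusion_metrics(tp, fp, tn, fn)
            row["auc"] = auc(s, y)
            for m in ("mcc", "sensitivity", "specificity"):
                row[m] = np.nan if cm[m] is None else cm[m]
        rows.append(row)
    return rows


def crossvalidate(
    ps: PeptideSet,
    enc: Encoding,
    plan: CVPlan,
    cfg: ModelConfig,
    long_set: PeptideSet | None = None,
    alpha: float = 0.05,
) -> EvaluationReport:
    """Repeated k-fold CV of one encoding with per-fold QuiPT refit.

    Returns a tidy report with one row per (repeat, fold, stratum).
    Fold training parts lacking a class trigger a resampled assignment
    within the repeat (logged).  If QuiPT selects nothing at ``alpha``
    in some training part, the single smallest-p feature is used so the
    forest can still be fit (logged; only happens on near-null data).
    """
    if len(ps) < plan.n_folds:
        raise ValueError("fewer peptides than folds")
    labels = np.array(ps.labels)
    if labels.min() == labels.max():
        raise ValueError("cross-validation requires both classes")
    rng = np.random.default_rng(plan.seed)
    feature_space = generate_feature_space(enc)
    rows: list[dict] = []
    fold_assignments: dict[tuple[int, int], tuple[str, ...]] = {}

    for repeat in range(plan.n_repeats):
        for attempt in range(100):
            assign = _fold_assignment(ps.ids, plan.n_folds, rng)
            ok = all(
                len({r.label for r in ps if assign[r.id] != f}) == 2
                for f in range(plan.n_folds)
            )
            if ok:
                break
            logger.warning("repeat %d: single-class training fold, resampling", repeat)
        else:
            raise ValueError("could not build folds with two-class training parts")
        long_assign = (
            _fold_assignment(long_set.ids, plan.n_folds, rng) if long_set else {}
        )

        for f in range(plan.n_folds):
            train_recs = [r for r in ps if assign[r.id] != f]
            test_recs = [r for r in ps if assign[r.id] == f]
            if long_set:
                test_recs += [r for r in long_set if long_assign[r.id] == f]
            fold_assignments[(repeat, f)] = tuple(r.id for r in test_recs)

            fm = extract_features(
                extract_hexapeptides(train_recs), enc, feature_space=feature_space
            )
            hits = quipt.select_features(fm, alpha=alpha)
            if hits:
                selected = [h.feature_id for h in hits]
            else:
                table = quipt.score_features(fm, alpha=alpha)
                selected = [table.iloc[0]["feature_id"]]
                logger.warning(
                    "repeat %d fold %d: no feature below alpha=%.3g, "
                    "falling back to the smallest-p feature",
                    repeat, f, alpha,
                )
            rf_seed = (cfg.seed * 100003 + repeat * 101 + f) % (2**31)
            model = train_model(
                fm, selected, ModelConfig(rf_seed, cfg.n_trees, cfg.mtry, cfg.threshold)
            )

            scores: dict[str, float] = {}
            test_hexes = extract_hexapeptides(test_recs)
            probs = predict_hexapeptides(model, test_hexes)
            by_parent: dict[str, list[float]] = {r.id: [] for r in test_recs}
            for h, p in zip(test_hexes, probs):
                by_parent[h.parent_id].append(float(p))
            for r in test_recs:
                scores[r.id], _ = aggregate_peptide(by_parent[r.id], cfg.threshold)

            for row in _evaluate_fold(test_recs, scores, cfg.threshold):
                row.update({"repeat": repeat, "fold": f})
                rows.append(row)

    records = pd.DataFrame(rows)[
        ["repeat", "fold", "stratum", "n_pos", "n_neg", "degenerate", *METRICS]
    ]
    return EvaluationReport(records, encoding=enc, fold_assignments=fold_assignments)


def rank_encodings(
    reports: Mapping[str, EvaluationReport],
    strata: Sequence[str] | None = None,
) -> EncodingRanking:
    """Rank-sum selection of the best encoding across test strata.

    Within each stratum encodings are ranked by mean AUC descending
    (rank 1 = best, midranks for ties); the winner minimizes the rank
    sum, ties broken by grand-mean AUC.
    """
    if len(reports) < 2:
        raise ValueError("need at least two encodings to rank")
    names = list(reports)
    if strata is None:
        strata = sorted(
            set.intersection(
                *(set(r.records["stratum"]) for r in reports.values())
            )
            - {"all"}
        )
        if not strata:
            raise ValueError("no common evaluated stratum across encodings")
    mean_auc = pd.DataFrame(index=names, columns=list(strata), dtype=float)
    for name, rep in reports.items():
        evaluated = set(rep.records["stratum"])
        for st in strata:
            if st not in evaluated:
                raise ValueError(f"encoding {name!r} lacks stratum {st!r}")
            mean_auc.loc[name, st] = rep.mean_auc(st)
    ranks = mean_auc.apply(lambda col: rankdata(-col.to_numpy(), method="average"))
    table = ranks.copy()
    table["rank_sum"] = ranks.sum(axis=1)
    table["grand_mean_auc"] = mean_auc.mean(axis=1)
    winner = (
        table.sort_values(["rank_sum", "grand_mean_auc"], ascending=[True, False])
        .index[0]
    )
    return EncodingRanking(table=table, winner=str(winner))


def benchmark(
    predictions: Mapping[str, Mapping[str, float]],
    labels: PeptideSet,
    thresholds: Mapping[str, float] | None = None,
    lower_is_amyloid: Sequence[str] = (),
) -> pd.DataFrame:
    """Compare external per-peptide score files on a labelled set.

    Raw scores of each tool are min-max normalized to [0, 1] (after
    sign-flipping for tools where lower means more amyloidogenic), and
    the tool's decision threshold undergoes the same transform, so AUC
    is unchanged and the confusion metrics reflect the tool's own
    cutoff.  Tools without a threshold use 0.5 on the normalized scale.
    """
    thresholds = dict(thresholds or {})
    flip = set(lower_is_amyloid)
    y = np.array(labels.labels)
    rows = []
    for tool, scores in predictions.items():
        missing = [pid for pid in labels.ids if pid not in scores]
        if missing:
            raise ValueError(f"tool {tool!r}: missing score for peptide {missing[0]!r}")
        s = np.array([float(scores[pid]) for pid in labels.ids])
        t = thresholds.get(tool)
        if tool in flip:
            s = -s
            t = None if t is None else -t
        lo, hi = s.min(), s.max()
        span = hi - lo if hi > lo else 1.0
        s_norm = (s - lo) / span
        t_norm = 0.5 if t is None else (t - lo) / span
        calls = (s_norm >= t_norm).astype(int)
        tp = int(((calls == 1) & (y == 1)).sum())
        fp = int(((calls == 1) & (y == 0)).sum())
        tn = int(((calls == 0) & (y == 0)).sum())
        fn = int(((calls == 0) & (y == 1)).sum())
        cm = confusion_metrics(tp, fp, tn, fn)
        rows.append(
            {
                "tool": tool,
                "auc": auc(s_norm, y),
                "mcc": cm["mcc"],
                "sensitivity": cm["sensitivity"],
                "specificity": cm["specificity"],
                "threshold_norm": t_norm,
            }
        )
    return pd.DataFrame(rows).set_index("tool")
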