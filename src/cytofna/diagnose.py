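"""Slide-level Bethesda diagnosis.

Two-step decision process: a deterministic adequacy rule first labels
nondiagnostic slides (TBS I) from weighted epithelial-group counts,

    avg_a * (N-PTCA + N-TFECA) + avg_b * (N-PTCB + N-TFECB) < glob_cell,

with defaults 10 / 5 / 60 — the classical six-groups-of-ten follicular-cell
adequacy convention expressed over the detected group classes (large groups
weigh ``avg_a`` cells, small groups ``avg_b``). Slides that pass are
classified by a gradient-boosted tree model over the 104 slide features
(3-class II/V/VI, or 2-class II vs V+VI), tuned by grid search with
stratified 5-fold cross-validation. An optional cascade consults a binary
BRAF-mutation classifier whenever the image model outputs TBS V, resolving it
to TBS II (wild-type) or TBS VI (mutant). Evaluation metrics carry Wald
normal-approximation confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from xgboost import XGBClassifier

from .wsifeat import DecisionRuleParams, FeatureRegistry, registry_default

__all__ = [
    "DecisionRuleParams", "TbsResult", "ConfusionCounts", "MetricResult",
    "tbs1_rule", "train_wsi_gbt", "predict_tbs", "train_gene_gbt",
    "cascade_fuse", "metrics_from_counts", "WALD_Z", "DEFAULT_GRID",
]

WALD_Z = 1.959964

DEFAULT_GRID = {
    "max_depth": [3, 5, 7],
    "learning_rate": [0.05, 0.1, 0.3],
    "n_estimators": [100, 300],
    "subsample": [0.8, 1.0],
}


class DataError(ValueError):
    pass


class ContractError(ValueError):
    pass


# ---------------------------------------------------------------------------
# stage 1: adequacy rule

_RULE_COUNTS = ("N-PTCA", "N-TFECA", "N-PTCB", "N-TFECB")


def tbs1_rule(features: pd.Series,
              params: DecisionRuleParams | None = None) -> bool:
    """True when the slide is nondiagnostic (TBS I); strict inequality."""
    params = params or DecisionRuleParams()
    counts = {}
    for name in _RULE_COUNTS:
        v = float(features[name])
        if v < 0 or v != int(v):
            raise ContractError(f"{name} must be a non-negative integer")
        counts[name] = int(v)
    lhs = (params.avg_a * (counts["N-PTCA"] + counts["N-TFECA"])
           + params.avg_b * (counts["N-PTCB"] + counts["N-TFECB"]))
    return lhs < params.glob_cell


# ---------------------------------------------------------------------------
# classifiers

@dataclass
class WsiClassifier:
    booster: XGBClassifier
    classes: list
    registry_version: str
    best_params: dict
    fold_accuracies: list
    cv_accuracy: float
    n_invocations: int = 0

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        self.n_invocations += 1
        return self.booster.predict_proba(np.atleast_2d(x))


def _xgb(seed, n_classes, **kw):
    return XGBClassifier(tree_method="hist", n_jobs=1, random_state=seed,
                         objective=("multi:softprob" if n_classes > 2
                                    else "binary:logistic"), **kw)


def train_wsi_gbt(features: pd.DataFrame, labels, n_classes: int = 3,
                  search_budget: int | None = None, seed: int = 0,
                  grid: dict | None = None,
                  registry: FeatureRegistry | None = None) -> WsiClassifier:
    """Grid-searched, stratified-5-fold cross-validated classifier.

    ``n_classes=2`` merges V and VI into 'V+VI' before training. The best
    configuration is refit on all data; the report carries per-fold accuracy
    of the winner. Deterministic given ``seed``.
    """
    if n_classes not in (2, 3):
        raise ValueError("n_classes must be 2 or 3")
    registry = registry or registry_default()
    y = np.array(["V+VI" if n_classes == 2 and l in ("V", "VI") else l
                  for l in labels])
    classes, counts = np.unique(y, return_counts=True)
    for c, n in zip(classes, counts):
        if n < 5:
            raise DataError(f"class {c} has only {n} samples (< 5 folds)")
    yi = np.searchsorted(classes, y)
    grid = dict(grid or DEFAULT_GRID)
    if search_budget is not None:
        from sklearn.model_selection import ParameterGrid
        cfgs = list(ParameterGrid(grid))[:search_budget]
        grid = [dict((k, [v]) for k, v in c.items()) for c in cfgs]
    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    gs = GridSearchCV(_xgb(seed, len(classes)), grid, cv=cv,
                      scoring="accuracy", n_jobs=1, refit=True)
    x = features[list(registry.names)].to_numpy(dtype=float)
    gs.fit(x, yi)
    folds = [float(gs.cv_results_[f"split{i}_test_score"][gs.best_index_])
             for i in range(5)]
    return WsiClassifier(booster=gs.best_estimator_,
                         classes=list(classes),
                         registry_version=registry.version,
                         best_params=dict(gs.best_params_),
                         fold_accuracies=folds,
                         cv_accuracy=float(gs.best_score_))


@dataclass
class GeneClassifier:
    booster: XGBClassifier
    registry_version: str

    def predict(self, x: np.ndarray) -> int:
        return int(self.booster.predict(np.atleast_2d(x))[0])

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.booster.predict_proba(np.atleast_2d(x))


def train_gene_gbt(features: pd.DataFrame, braf_labels, seed: int = 0,
                   registry: FeatureRegistry | None = None,
                   n_estimators: int = 300, max_depth: int = 4,
                   learning_rate: float = 0.1) -> GeneClassifier:
    """Binary BRAF-status classifier on the same slide feature vectors."""
    registry = registry or registry_default()
    y = np.asarray(braf_labels, dtype=int)
    if len(set(y.tolist())) < 2:
        raise DataError("both BRAF labels (0 and 1) must be present")
    booster = _xgb(seed, 2, n_estimators=n_estimators, max_depth=max_depth,
                   learning_rate=learning_rate)
    booster.fit(features[list(registry.names)].to_numpy(dtype=float), y)
    return GeneClassifier(booster=booster, registry_version=registry.version)


# ---------------------------------------------------------------------------
# prediction and cascade fusion

@dataclass
class TbsResult:
    stage1: str                    # 'TBS_I' | 'PASS'
    wsi_pred: str | None           # 'II' | 'V' | 'VI' | 'V+VI' | None
    probs: dict = field(default_factory=dict)
    gene_pred: int | None = None
    final: str = "I"
    adeq_lhs: float = 0.0


def cascade_fuse(wsi_pred: str, gene_pred: int | None) -> str:
    """(V, 0) -> II; (V, 1) -> VI; everything else passes through."""
    if gene_pred not in (0, 1, None):
        raise ValueError("gene_pred must be 0, 1 or None")
    if wsi_pred == "V" and gene_pred == 0:
        return "II"
    if wsi_pred == "V" and gene_pred == 1:
        return "VI"
    return wsi_pred


def predict_tbs(features: pd.Series, wsi_model: WsiClassifier,
                rule_params: DecisionRuleParams | None = None,
                gene_model: GeneClassifier | None = None,
                registry: FeatureRegistry | None = None) -> TbsResult:
    """Stage-1 adequacy rule, then the image classifier, then the optional
    gene cascade. The classifier is never invoked on TBS I slides."""
    registry = registry or registry_default()
    if wsi_model.registry_version != registry.version:
        raise ContractError(
            f"registry version mismatch: model {wsi_model.registry_version} "
            f"vs features {registry.version}")
    rule_params = rule_params or DecisionRuleParams()
    lhs = float(features.get("ADEQ-LHS", 0.0))
    if tbs1_rule(features, rule_params):
        return TbsResult(stage1="TBS_I", wsi_pred=None, final="I",
                         adeq_lhs=lhs)
    x = features[[n for n in registry.names]].to_numpy(dtype=float)
    p = wsi_model.predict_proba(x)[0]
    wsi_pred = wsi_model.classes[int(np.argmax(p))]
    probs = {c: float(v) for c, v in zip(wsi_model.classes, p)}
    gene_pred = None
    if gene_model is not None and wsi_pred == "V":
        if gene_model.registry_version != registry.version:
            raise ContractError("gene model registry version mismatch")
        gene_pred = gene_model.predict(x)
    final = cascade_fuse(wsi_pred, gene_pred)
    return TbsResult(stage1="PASS", wsi_pred=wsi_pred, probs=probs,
                     gene_pred=gene_pred, final=final, adeq_lhs=lhs)


# ---------------------------------------------------------------------------
# evaluation metrics with Wald confidence intervals

@dataclass
class MetricResult:
    value: float | None
    ci: tuple | None
    n: int

    @property
    def percent(self):
        return None if self.value is None else 100.0 * self.value


class ConfusionCounts:
    """Integer table of predicted-label counts per true label."""

    def __init__(self, table):
        if isinstance(table, pd.DataFrame):
            self.table = table.astype(int)
        else:
            self.table = pd.DataFrame(table).T.fillna(0).astype(int)
        if (self.table.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_predictions(cls, truths, preds):
        df = pd.crosstab(pd.Series(truths, name="true"),
                         pd.Series(preds, name="pred"))
        return cls(df)

    def total(self) -> int:
        return int(self.table.to_numpy().sum())


def _wald(p: float, n: int, z: float = WALD_Z):
    half = z * np.sqrt(p * (1.0 - p) / n)
    return (float(np.clip(p - half, 0.0, 1.0)),
            float(np.clip(p + half, 0.0, 1.0)))


def _proportion(num: int, den: int, z: float = WALD_Z) -> MetricResult:
    if den == 0:
        return MetricResult(value=None, ci=None, n=0)
    p = num / den
    return MetricResult(value=float(p), ci=_wald(p, den, z), n=den)


def metrics_from_counts(counts: ConfusionCounts, positive_set,
                        positive_truth=None, alpha: float = 0.05) -> dict:
    """Binary screening metrics from a confusion table.

    Predictions in ``positive_set`` count as positive. ``positive_truth`` is
    the set of true labels considered disease-positive; by default every true
    label in the table is positive-eligible (the convention for evaluating
    indeterminate-category cohorts, where each sample counts toward
    sensitivity regardless of its row label). Each metric is a proportion
    with a Wald 1-alpha confidence interval; undefined metrics (denominator
    zero) are reported with value None.
    """
    if abs(alpha - 0.05) <= 1e-12:
        z = WALD_Z
    else:
        from scipy.stats import norm
        z = float(norm.ppf(1.0 - alpha / 2.0))
    t = counts.table
    pos_cols = [c for c in t.columns if c in set(positive_set)]
    truth = set(positive_truth) if positive_truth is not None \
        else set(t.index)
    pos_rows = [r for r in t.index if r in truth]
    neg_rows = [r for r in t.index if r not in truth]

    tp = int(t.loc[pos_rows, pos_cols].to_numpy().sum()) if pos_rows else 0
    fn = int(t.loc[pos_rows].to_numpy().sum()) - tp if pos_rows else 0
    fp = int(t.loc[neg_rows, pos_cols].to_numpy().sum()) if neg_rows else 0
    tn = int(t.loc[neg_rows].to_numpy().sum()) - fp if neg_rows else 0

    sens = _proportion(tp, tp + fn, z)
    spec = _proportion(tn, tn + fp, z)
    acc = _proportion(tp + tn, tp + fn + fp + tn, z)
    prec = _proportion(tp, tp + fp, z)
    if sens.value is not None and prec.value is not None \
            and (sens.value + prec.value) > 0:
        f1v = 2 * prec.value * sens.value / (prec.value + sens.value)
        f1 = MetricResult(value=f1v, ci=None, n=tp + fn + fp)
    else:
        f1 = MetricResult(value=None, ci=None, n=0)
    return {"sensitivity": sens, "specificity": spec, "accuracy": acc,
            "precision": prec, "recall": sens, "f1": f1,
            "counts": {"tp": tp, "fn": fn, "fp": fp, "tn": tn}}
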