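"""Slide-level aggregation of detections and cell calls into the 104-attribute
feature vector used by the diagnosis classifiers.

The default registry (version ``v1``) is composed of statistic families over
the 9-role reduction of the class schema:

* ``N-<role>`` (9): accepted-object counts;
* ``AVG-P-<role>`` / ``MEDI-P-<role>`` (18): mean/median classification
  probability of the called class;
* ``AVG-SC-<role>`` / ``MEDI-SC-<role>`` (18): mean/median detection score;
* ``AVG-NUCLEAR-<feat>`` / ``MEDI-NUCLEAR-<feat>`` (38): mean/median of each of
  the 19 nuclear morphometry features over all accepted nucleus-kind objects;
* ``AVG-AREA-<role>`` / ``MEDI-AREA-<role>`` (18): mean/median object pixel
  area per role;
* ``TOTAL-DET``, ``TOTAL-CLUSTER``, ``ADEQ-LHS`` (3): total accepted objects,
  cluster count, and the weighted epithelial-group adequacy sum.

Roles with no members use the sentinel 0 for AVG/MEDI statistics (documented
convention: tree models then need no missing-value handling). Cluster-kind
objects contribute to counts, scores and areas but not to the 19-feature
nuclear morphometry averages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema import DEFAULT_SCHEMA, REJECTED, ROLES, ClassSchema
from .segdetect import MORPHO_FEATURE_NAMES

__all__ = ["FeatureRegistry", "registry_default", "aggregate_slide_features",
           "DecisionRuleParams"]


@dataclass(frozen=True)
class DecisionRuleParams:
    """Adequacy-rule weights: cells per large epithelial group, cells per
    small epithelial group, and the minimum weighted cell count."""
    avg_a: float = 10.0
    avg_b: float = 5.0
    glob_cell: float = 60.0

    def __post_init__(self):
        if min(self.avg_a, self.avg_b, self.glob_cell) <= 0:
            raise ValueError("rule parameters must be strictly positive")


@dataclass(frozen=True)
class FeatureRegistry:
    names: tuple
    version: str = "v1"

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")

    def __len__(self):
        return len(self.names)

    def to_json(self):
        return {"version": self.version, "names": list(self.names)}


def registry_default() -> FeatureRegistry:
    """The stable, ordered 104-feature registry (version v1)."""
    names = []
    names += [f"N-{r}" for r in ROLES]
    names += [f"AVG-P-{r}" for r in ROLES]
    names += [f"MEDI-P-{r}" for r in ROLES]
    names += [f"AVG-SC-{r}" for r in ROLES]
    names += [f"MEDI-SC-{r}" for r in ROLES]
    for f in MORPHO_FEATURE_NAMES:
        names.append(f"AVG-NUCLEAR-{f.upper()}")
        names.append(f"MEDI-NUCLEAR-{f.upper()}")
    names += [f"AVG-AREA-{r}" for r in ROLES]
    names += [f"MEDI-AREA-{r}" for r in ROLES]
    names += ["TOTAL-DET", "TOTAL-CLUSTER", "ADEQ-LHS"]
    return FeatureRegistry(names=tuple(names))


def adequacy_lhs(counts: dict, params: DecisionRuleParams) -> float:
    """Weighted epithelial-group count entering the adequacy comparison."""
    return (params.avg_a * (counts.get("PTCA", 0) + counts.get("TFECA", 0))
            + params.avg_b * (counts.get("PTCB", 0) + counts.get("TFECB", 0)))


def aggregate_slide_features(calls, detections, morpho,
                             registry: FeatureRegistry | None = None,
                             rule_params: DecisionRuleParams | None = None,
                             schema: ClassSchema = DEFAULT_SCHEMA) -> pd.Series:
    """Aggregate one slide's accepted cell calls into the feature vector.

    ``calls`` reference detections by index via ``detection_id``;
    ``detections`` and ``morpho`` are parallel lists (``morpho[i]`` may be
    None for cluster-kind detections). REJECTED calls are skipped. The result
    is a named, ordered :class:`pandas.Series` of registry length.
    """
    registry = registry or registry_default()
    rule_params = rule_params or DecisionRuleParams()
    seen = set()
    for c in calls:
        if c.detection_id in seen:
            raise ValueError(f"duplicate detection reference {c.detection_id}")
        seen.add(c.detection_id)
    accepted = [c for c in calls if c.final_class not in (REJECTED, None)]

    per_role = {r: dict(p=[], sc=[], area=[]) for r in ROLES}
    nuclear_feats = []
    n_cluster = 0
    for c in accepted:
        det = detections[c.detection_id]
        role = schema.role(c.final_class)
        prob = float(np.max(c.prob_vector))
        per_role[role]["p"].append(prob)
        per_role[role]["sc"].append(det.score)
        per_role[role]["area"].append(det.area)
        if det.kind == "cluster":
            n_cluster += 1
        else:
            mv = morpho[c.detection_id]
            if mv is not None:
                nuclear_feats.append(np.asarray(mv, dtype=float))

    counts = {r: len(per_role[r]["p"]) for r in ROLES}

    def _avg(v):
        return float(np.mean(v)) if len(v) else 0.0

    def _med(v):
        return float(np.median(v)) if len(v) else 0.0

    values = {}
    for r in ROLES:
        values[f"N-{r}"] = counts[r]
        values[f"AVG-P-{r}"] = _avg(per_role[r]["p"])
        values[f"MEDI-P-{r}"] = _med(per_role[r]["p"])
        values[f"AVG-SC-{r}"] = _avg(per_role[r]["sc"])
        values[f"MEDI-SC-{r}"] = _med(per_role[r]["sc"])
        values[f"AVG-AREA-{r}"] = _avg(per_role[r]["area"])
        values[f"MEDI-AREA-{r}"] = _med(per_role[r]["area"])
    nf = np.vstack(nuclear_feats) if nuclear_feats else None
    for j, f in enumerate(MORPHO_FEATURE_NAMES):
        values[f"AVG-NUCLEAR-{f.upper()}"] = \
            float(nf[:, j].mean()) if nf is not None else 0.0
        values[f"MEDI-NUCLEAR-{f.upper()}"] = \
            float(np.median(nf[:, j])) if nf is not None else 0.0
    values["TOTAL-DET"] = sum(counts.values())
    values["TOTAL-CLUSTER"] = n_cluster
    values["ADEQ-LHS"] = adequacy_lhs(counts, rule_params)

    return pd.Series([values[n] for n in registry.names],
                     index=list(registry.names), dtype=float)
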