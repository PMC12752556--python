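"""Adequacy rule, cascade fusion, metrics arithmetic, and classifier
training contracts (the heavier cohort-level checks live in
test_acceptance.py)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cytofna.diagnose import (ConfusionCounts, ContractError, DataError,
                              DecisionRuleParams, cascade_fuse,
                              metrics_from_counts, predict_tbs, tbs1_rule,
                              train_gene_gbt, train_wsi_gbt)
from cytofna.wsifeat import registry_default


def _features(ptca=0, tfeca=0, ptcb=0, tfecb=0):
    v = pd.Series(0.0, index=list(registry_default().names))
    v["N-PTCA"], v["N-TFECA"] = ptca, tfeca
    v["N-PTCB"], v["N-TFECB"] = ptcb, tfecb
    v["ADEQ-LHS"] = 10.0 * (ptca + tfeca) + 5.0 * (ptcb + tfecb)
    return v


# ---------------------------------------------------------------------------
# adequacy rule

def test_zero_counts_is_nondiagnostic():
    assert tbs1_rule(_features()) is True


def test_six_large_groups_is_exactly_adequate():
    """60 < 60 is false: six large epithelial groups pass the strict rule."""
    assert tbs1_rule(_features(tfeca=6)) is False


def test_five_large_one_small_group_is_nondiagnostic():
    assert tbs1_rule(_features(tfeca=5, tfecb=1)) is True  # 55 < 60


def test_negative_count_is_a_contract_error():
    with pytest.raises(ContractError):
        tbs1_rule(_features(ptca=-1))


@given(st.integers(0, 40), st.integers(0, 40), st.integers(0, 40),
       st.integers(0, 40), st.integers(0, 3), st.integers(0, 3))
@settings(max_examples=300, deadline=None, derandomize=True)
def test_rule_is_monotone_in_every_count(a, b, c, d, bump_idx, bump):
    base = [a, b, c, d]
    bumped = list(base)
    bumped[bump_idx] += bump
    r0 = tbs1_rule(_features(*base))
    r1 = tbs1_rule(_features(*bumped))
    # increasing counts can only move a slide out of TBS I, never into it
    assert not (r0 is False and r1 is True)


def test_rule_parameters_are_config_exposed():
    params = DecisionRuleParams(avg_a=1, avg_b=1, glob_cell=2)
    assert tbs1_rule(_features(ptca=1), params) is True
    assert tbs1_rule(_features(ptca=2), params) is False


# ---------------------------------------------------------------------------
# cascade fusion

@pytest.mark.parametrize("wsi,gene,expected", [
    ("V", 0, "II"), ("V", 1, "VI"), ("V", None, "V"),
    ("II", 0, "II"), ("II", 1, "II"), ("II", None, "II"),
    ("VI", 0, "VI"), ("VI", 1, "VI"), ("VI", None, "VI"),
])
def test_cascade_mapping_exhaustive(wsi, gene, expected):
    assert cascade_fuse(wsi, gene) == expected


def test_cascade_rejects_invalid_gene_value():
    with pytest.raises(ValueError):
        cascade_fuse("V", 2)


# ---------------------------------------------------------------------------
# stage ordering with a stub classifier

class _StubWsi:
    registry_version = "v1"
    classes = ["II", "V", "VI"]

    def __init__(self):
        self.n_invocations = 0

    def predict_proba(self, x):
        self.n_invocations += 1
        return np.array([[0.1, 0.8, 0.1]])   # always TBS V


def test_inadequate_slide_never_reaches_the_classifier():
    stub = _StubWsi()
    r = predict_tbs(_features(), stub)
    assert r.final == "I"
    assert r.stage1 == "TBS_I"
    assert stub.n_invocations == 0


def test_adequate_slide_passes_through_stub_prediction():
    stub = _StubWsi()
    r = predict_tbs(_features(tfeca=10), stub)
    assert r.stage1 == "PASS"
    assert r.final == "V"          # no gene model: V passes through
    assert stub.n_invocations == 1


def test_registry_version_mismatch_is_a_contract_error():
    stub = _StubWsi()
    stub.registry_version = "v0"
    with pytest.raises(ContractError):
        predict_tbs(_features(tfeca=10), stub)


# ---------------------------------------------------------------------------
# training contracts (small synthetic tables)

def _toy_features(n, seed):
    rng = np.random.default_rng(seed)
    reg = registry_default()
    x = pd.DataFrame(rng.uniform(size=(n, 104)), columns=list(reg.names))
    frac = rng.uniform(size=n)
    x["N-PTCA"] = (20 * frac).astype(int)
    x["N-TFECA"] = (20 * (1 - frac)).astype(int)
    y = np.where(frac > 0.5, "VI", np.where(frac > 0.1, "V", "II"))
    return x, list(y)


def test_wsi_training_is_deterministic():
    x, y = _toy_features(80, 0)
    m1 = train_wsi_gbt(x, y, n_classes=3, seed=1, search_budget=4)
    m2 = train_wsi_gbt(x, y, n_classes=3, seed=1, search_budget=4)
    assert m1.best_params == m2.best_params
    assert m1.fold_accuracies == m2.fold_accuracies


def test_wsi_training_rejects_rare_class():
    x, y = _toy_features(80, 0)
    y = ["II"] * 3 + y[3:]
    y = [l if l != "II" or i < 3 else "V" for i, l in enumerate(y)]
    with pytest.raises(DataError):
        train_wsi_gbt(x, y, n_classes=3, seed=0, search_budget=1)


def test_two_class_merges_v_and_vi():
    x, y = _toy_features(80, 0)
    m = train_wsi_gbt(x, y, n_classes=2, seed=0, search_budget=2)
    assert set(m.classes) == {"II", "V+VI"}


def test_gene_training_requires_both_labels():
    x, _ = _toy_features(30, 0)
    with pytest.raises(DataError):
        train_gene_gbt(x, [0] * 30)


def test_gene_training_is_deterministic():
    x, _ = _toy_features(60, 2)
    rng = np.random.default_rng(0)
    braf = rng.integers(0, 2, 60)
    g1 = train_gene_gbt(x, braf, seed=3)
    g2 = train_gene_gbt(x, braf, seed=3)
    xv = x.iloc[0].to_numpy(dtype=float)
    assert np.array_equal(g1.predict_proba(xv), g2.predict_proba(xv))


# ---------------------------------------------------------------------------
# metrics

def _table1_tbs3():
    return ConfusionCounts({"TBS III": {
        "I": 8 + 0 + 8 + 0, "II": 27 + 0 + 17 + 34,
        "V": 122 + 2 + 82 + 56, "VI": 27 + 1 + 28 + 15}})


def _table1_tbs4():
    return ConfusionCounts({"TBS IV": {
        "I": 0, "II": 12 + 1 + 13 + 1,
        "V": 31 + 0 + 54 + 25, "VI": 57 + 1 + 91 + 6}})


def test_indeterminate_cohort_sensitivities():
    m3 = metrics_from_counts(_table1_tbs3(), {"V", "VI"})
    assert m3["sensitivity"].percent == pytest.approx(77.99, abs=0.005)
    m4 = metrics_from_counts(_table1_tbs4(), {"V", "VI"})
    assert m4["sensitivity"].percent == pytest.approx(90.75, abs=0.005)
    assert m4["sensitivity"].ci[0] == pytest.approx(0.8743, abs=5e-5)
    assert m4["sensitivity"].ci[1] == pytest.approx(0.9408, abs=5e-5)


def test_wald_interval_for_direct_proportion():
    """265 positives of 292 -> 90.75% with CI (0.8743, 0.9408)."""
    c = ConfusionCounts({"pos": {"pos": 265, "neg": 27}})
    m = metrics_from_counts(c, {"pos"})
    assert m["sensitivity"].value == pytest.approx(265 / 292)
    assert m["sensitivity"].ci == (pytest.approx(0.8743, abs=5e-5),
                                   pytest.approx(0.9408, abs=5e-5))


def test_zero_positives_clips_interval_to_zero():
    c = ConfusionCounts({"pos": {"pos": 0, "neg": 25}})
    m = metrics_from_counts(c, {"pos"})
    assert m["sensitivity"].value == 0.0
    assert m["sensitivity"].ci == (0.0, 0.0)


def test_undefined_metric_reported_as_missing():
    c = ConfusionCounts({"pos": {"pos": 5}})
    m = metrics_from_counts(c, {"pos"})   # no negative rows
    assert m["specificity"].value is None


def test_metrics_match_per_sample_recount(rng):
    """Brute-force oracle: rebuild each confusion table sample-by-sample and
    recount; 100 random tables."""
    labels = ["I", "II", "V", "VI"]
    for _ in range(100):
        table = {t: {p: int(rng.integers(0, 9)) for p in labels}
                 for t in rng.choice(labels, size=2, replace=False)}
        counts = ConfusionCounts(table)
        truth_pos = {"V", "VI"}
        m = metrics_from_counts(counts, {"V", "VI"},
                                positive_truth=truth_pos)
        # expand to individual samples
        samples = [(t, p) for t, row in table.items()
                   for p, k in row.items() for _ in range(k)]
        tp = sum(1 for t, p in samples if t in truth_pos and p in truth_pos)
        fn = sum(1 for t, p in samples if t in truth_pos and p not in truth_pos)
        fp = sum(1 for t, p in samples if t not in truth_pos and p in truth_pos)
        tn = sum(1 for t, p in samples if t not in truth_pos and p not in truth_pos)
        assert m["counts"] == {"tp": tp, "fn": fn, "fp": fp, "tn": tn}
        if tp + fn:
            assert m["sensitivity"].value == pytest.approx(tp / (tp + fn))
        if tn + fp:
            assert m["specificity"].value == pytest.approx(tn / (tn + fp))


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        ConfusionCounts({"a": {"a": -1}})
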