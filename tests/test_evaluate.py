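"""Metrics, retrospective ambiguity labeling, operating point, paired stats."""

import numpy as np
import pandas as pd
import pytest

from tactile_reject.evaluate import (
    accuracy,
    ambiguous_labeling,
    label_ambiguous,
    paired_tests,
    rejection_precision,
    rejection_rate,
    select_operating_point,
    summarize_session,
)
from tactile_reject.reject import REJECT


def _decisions(outputs, trues, category="target", mechanism="m", start_id=0):
    n = len(outputs)
    return pd.DataFrame(
        {
            "session_id": ["S"] * n,
            "trial_id": np.arange(start_id, start_id + n),
            "mechanism": [mechanism] * n,
            "output": outputs,
            "pred_noreject": [o if o != REJECT else t for o, t in zip(outputs, trues)],
            "true_motion": trues,
            "category": [category] * n,
        }
    )


def test_label_ambiguous_counts_misclassifications():
    d = _decisions(["A"] * 147 + ["B"] * 3, ["A"] * 150)
    assert label_ambiguous(d) == {147, 148, 149}
    assert label_ambiguous(_decisions(["A"] * 10, ["A"] * 10)) == set()


def test_label_ambiguous_guards():
    with pytest.raises(ValueError):
        label_ambiguous(_decisions(["A", REJECT], ["A", "A"]))
    with pytest.raises(ValueError):
        label_ambiguous(_decisions(["A"], ["A"], category="unknown"))


def test_accuracy_ratio_and_undefined():
    d = _decisions(["A"] * 135 + ["B"] * 15, ["A"] * 150)
    assert accuracy(d) == pytest.approx(0.90)
    assert np.isnan(accuracy(_decisions([REJECT] * 5, ["A"] * 5)))
    # rejecting exactly the misclassified trials yields perfect accuracy
    d = _decisions(["A"] * 10 + [REJECT] * 2, ["A"] * 12)
    assert accuracy(d) == 1.0


def test_removing_misclassified_never_lowers_accuracy():
    """Replacing any subset of wrong outputs with REJECT can only help."""
    rng = np.random.default_rng(0)
    for _ in range(25):
        trues = rng.choice(["A", "B", "C"], size=40).tolist()
        outputs = [
            t if rng.random() < 0.7 else rng.choice(["A", "B", "C"]) for t in trues
        ]
        base = accuracy(_decisions(outputs, trues))
        wrong = [i for i, (o, t) in enumerate(zip(outputs, trues)) if o != t]
        take = rng.choice(wrong, size=rng.integers(0, len(wrong) + 1),
                          replace=False) if wrong else []
        pruned = [REJECT if i in set(take) else o for i, o in enumerate(outputs)]
        assert accuracy(_decisions(pruned, trues)) >= base


def test_rejection_rate():
    d = _decisions([REJECT] * 21 + ["A"] * 29, ["A"] * 50, category="unknown")
    assert rejection_rate(d) == pytest.approx(0.42)
    assert rejection_rate(_decisions([REJECT] * 4, ["A"] * 4)) == 1.0
    assert np.isnan(rejection_rate(d.iloc[0:0]))


def test_rejection_precision():
    d = _decisions([REJECT] * 20 + ["A"] * 30, ["A"] * 50)
    assert rejection_precision(d, set(range(11))) == pytest.approx(11 / 20)
    assert rejection_precision(d, set(range(20))) == 1.0
    assert np.isnan(rejection_precision(_decisions(["A"] * 5, ["A"] * 5), {1}))


def test_operating_point_selection():
    assert select_operating_point([(0.3, 0.0, 1.0), (0.1, 0.2, 0.9)]) == 0.3
    # hand-computed: sqrt(.2^2+.4^2)=0.4472 vs sqrt(.4^2+.1^2)=0.4123
    assert select_operating_point([(1, 0.2, 0.6), (2, 0.4, 0.9)]) == 2
    assert select_operating_point([(9, 0.9, 0.1)]) == 9
    assert select_operating_point([(1, 0.5, 0.5), (2, 0.5, 0.5)]) == 1  # tie
    with pytest.raises(ValueError):
        select_operating_point([])


def _study_table(values: dict[str, list[float]]) -> pd.DataFrame:
    rows = []
    for mech, vals in values.items():
        for i, v in enumerate(vals):
            rows.append({"session_id": f"S{i}", "mechanism": mech, "accuracy": v})
    return pd.DataFrame(rows)


def test_paired_tests_null_case_and_ncomp():
    t = _study_table({"a": [0.9, 0.8, 0.7], "b": [0.9, 0.8, 0.7]})
    res = paired_tests(t, "accuracy")
    assert res.loc[0, "t_stat"] == 0.0 and res.loc[0, "p_value"] == 1.0
    assert res.loc[0, "mean_diff"] == 0.0

    four = _study_table({m: [0.9, 0.8, 0.7] for m in ["a", "b", "c", "d"]})
    res4 = paired_tests(four, "accuracy")
    assert len(res4) == 6  # four systems -> 6 pairwise comparisons
    assert res4["alpha_adj"].iloc[0] == pytest.approx(0.05 / 6)

    three = _study_table({m: [0.9, 0.8, 0.7] for m in ["a", "b", "c"]})
    res3 = paired_tests(three, "accuracy")
    assert len(res3) == 3
    assert res3["alpha_adj"].iloc[0] == pytest.approx(0.05 / 3)


def test_paired_tests_drop_undefined_pairwise():
    t = _study_table({"a": [0.9, np.nan, 0.7, 0.6], "b": [0.8, 0.5, np.nan, 0.5]})
    res = paired_tests(t, "accuracy")
    assert res.loc[0, "n_sessions"] == 2  # sessions with both defined


def test_count_conservation_in_session_report(tiny_decisions):
    """Accepted + rejected = total per category, exactly."""
    rep = summarize_session(tiny_decisions)
    for _, row in rep.iterrows():
        d = tiny_decisions[tiny_decisions["mechanism"] == row["mechanism"]]
        target = d[d["category"] == "target"]
        accepted = int((target["output"] != REJECT).sum())
        assert accepted + row["n_rejected_target"] == row["n_target"]


def test_mechanism_specific_ambiguity_labeling(tiny_decisions):
    """SVM-based mechanisms share the baseline labeling; entropy uses the net's."""
    lab = ambiguous_labeling(tiny_decisions)
    assert lab["baseline"] == lab["ocsvm"] == lab["ovr_ro"]
    target_ids = set(
        tiny_decisions.loc[tiny_decisions["category"] == "target", "trial_id"]
    )
    for ids in lab.values():
        assert ids <= target_ids
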