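"""Session-wise metrics, operating-point selection, and paired statistics.

Metrics follow the reject-option convention: accuracy is computed only over
*accepted* target trials; the rejection rate of a category is the fraction
of its trials withheld; rejection precision is the fraction of rejected
trials that were genuinely unintended.  "Ambiguous" trials are defined
retrospectively as target trials misclassified by the corresponding base
classifier on a no-rejection pass (the baseline SVM's labeling is shared by
all SVM-based mechanisms; entropy rejection uses the network's own).

Undefined ratios (zero denominators) propagate as NaN — never coerced to 0
or 1 — and are dropped pairwise by the paired t-tests, whose significance
level is Bonferroni-adjusted by the number of pairwise comparisons
(alpha_adj = 0.05 / N_comp).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .reject import REJECT
from .synthetic_data import NONTARGET, TARGET, UNKNOWN

#: Mechanisms whose no-reject pass is the baseline SVM's prediction.
SVM_BASED = ("baseline", "ocsvm", "ovr_ro")

METRIC_COLUMNS = (
    "accuracy", "rr_target", "rr_ambiguous", "rr_unknown", "rr_nontarget",
    "rp_ambiguous",
)


def label_ambiguous(decisions: pd.DataFrame) -> set[int]:
    """Trial ids of target trials misclassified on a no-rejection pass.

    ``decisions`` must hold exactly one row per target trial with a class
    output (no REJECT rows) and no rows from other categories.
    """
    if (decisions["category"] != TARGET).any():
        raise ValueError("ambiguity labeling is defined over target trials only")
    if (decisions["output"] == REJECT).any():
        raise ValueError("ambiguity labeling requires a no-rejection pass")
    wrong = decisions["output"] != decisions["true_motion"]
    return set(decisions.loc[wrong, "trial_id"].tolist())


def accuracy(decisions: pd.DataFrame) -> float:
    """Correct accepted / accepted over target trials; NaN if none accepted."""
    d = decisions[decisions["category"] == TARGET]
    accepted = d[d["output"] != REJECT]
    if len(accepted) == 0:
        return float("nan")
    return float((accepted["output"] == accepted["true_motion"]).mean())


def rejection_rate(decisions: pd.DataFrame) -> float:
    """Rejected / total over the given rows; NaN on an empty category."""
    if len(decisions) == 0:
        return float("nan")
    return float((decisions["output"] == REJECT).mean())


def rejection_precision(decisions: pd.DataFrame, unintended_ids: set[int]) -> float:
    """Rejected-and-unintended / rejected; NaN (rendered "-") if no rejections."""
    rejected = decisions[decisions["output"] == REJECT]
    if len(rejected) == 0:
        return float("nan")
    return float(rejected["trial_id"].isin(unintended_ids).mean())


def select_operating_point(candidates) -> object:
    """Pick the parameter closest to the ideal (RR_target, RR_unintended) = (0, 1).

    ``candidates`` is an iterable of (parameter, rr_target, rr_unintended);
    the parameter minimising sqrt(rr_target^2 + (1 - rr_unintended)^2) is
    returned, ties resolved toward the smaller parameter value.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("empty candidate grid")
    best = min(
        candidates,
        key=lambda c: (float(np.hypot(c[1], 1.0 - c[2])), c[0]),
    )
    return best[0]


def ambiguous_labeling(decisions: pd.DataFrame) -> dict[str, set[int]]:
    """Retrospective ambiguity sets per mechanism for one session's decisions.

    Built from each mechanism's ``pred_noreject`` column over target trials,
    so the labeling never depends on rejection behaviour.
    """
    labeling: dict[str, set[int]] = {}
    for mech, d in decisions.groupby("mechanism"):
        t = d[d["category"] == TARGET]
        noreject = t.assign(output=t["pred_noreject"])
        labeling[mech] = label_ambiguous(noreject)
    return labeling


def summarize_session(decisions: pd.DataFrame) -> pd.DataFrame:
    """Per-mechanism metric table for one session.

    Columns: accuracy over accepted target trials; rejection rates for the
    target, ambiguous (retrospective subset of target), unknown and
    non-target categories; rejection precision for ambiguous motions over
    target trials; plus the counts backing each ratio.
    """
    labeling = ambiguous_labeling(decisions)
    rows = []
    for mech, d in decisions.groupby("mechanism", sort=False):
        amb = labeling[mech]
        target = d[d["category"] == TARGET]
        row = {
            "session_id": d["session_id"].iloc[0],
            "mechanism": mech,
            "accuracy": accuracy(d),
            "rr_target": rejection_rate(target),
            "rr_ambiguous": rejection_rate(target[target["trial_id"].isin(amb)]),
            "rr_unknown": rejection_rate(d[d["category"] == UNKNOWN]),
            "rr_nontarget": rejection_rate(d[d["category"] == NONTARGET]),
            "rp_ambiguous": rejection_precision(target, amb),
            "n_target": len(target),
            "n_ambiguous": len(amb),
            "n_unknown": int((d["category"] == UNKNOWN).sum()),
            "n_nontarget": int((d["category"] == NONTARGET).sum()),
            "n_rejected_target": int((target["output"] == REJECT).sum()),
        }
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_study(session_reports: list[pd.DataFrame]) -> pd.DataFrame:
    """Stack per-session reports into one long table."""
    return pd.concat(session_reports, ignore_index=True)


@dataclass(frozen=True)
class PairedComparison:
    metric: str
    system_a: str
    system_b: str
    mean_diff: float  # percentage points, a - b
    t_stat: float
    p_value: float
    n_sessions: int
    n_comp: int
    alpha_adj: float
    significant: bool


def paired_tests(
    table: pd.DataFrame, metric: str, systems: list[str] | None = None
) -> pd.DataFrame:
    """Two-sided paired t-tests over session-wise metric values.

    ``table`` is a long study summary (rows = session x mechanism).  All
    unordered pairs of ``systems`` are tested; sessions with an undefined
    value for either member are dropped pairwise.  alpha_adj = 0.05 / N_comp
    (Bonferroni), N_comp = number of pairs tested: 6 when the four systems
    are compared on accuracy, 3 when the three rejection mechanisms are
    compared on rejection metrics.
    """
    wide = table.pivot(index="session_id", columns="mechanism", values=metric)
    systems = systems or [s for s in wide.columns]
    pairs = list(itertools.combinations(systems, 2))
    n_comp = len(pairs)
    alpha_adj = 0.05 / n_comp if n_comp else float("nan")
    rows = []
    for a, b in pairs:
        d = (wide[a] - wide[b]).dropna()
        if len(d) < 2:
            t_stat, p = float("nan"), float("nan")
        elif np.allclose(d, 0.0):
            t_stat, p = 0.0, 1.0  # identical columns: zero mean difference
        else:
            t_stat, p = stats.ttest_rel(
                wide.loc[d.index, a], wide.loc[d.index, b]
            )
        rows.append(
            PairedComparison(
                metric=metric,
                system_a=a,
                system_b=b,
                mean_diff=float(d.mean() * 100.0) if len(d) else float("nan"),
                t_stat=float(t_stat),
                p_value=float(p),
                n_sessions=int(len(d)),
                n_comp=n_comp,
                alpha_adj=alpha_adj,
                significant=bool(p < alpha_adj) if np.isfinite(p) else False,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def study_statistics(study: pd.DataFrame) -> pd.DataFrame:
    """The full statistical comparison of one study summary table.

    Accuracy compares all four systems (N_comp = 6); rejection rate and
    rejection precision compare only the three rejection mechanisms
    (N_comp = 3), the baseline having no reject option.
    """
    mechanisms = list(dict.fromkeys(study["mechanism"]))
    rejecting = [m for m in mechanisms if m != "baseline"]
    out = [paired_tests(study, "accuracy", mechanisms)]
    for metric in ("rr_target", "rr_ambiguous", "rr_unknown", "rr_nontarget",
                   "rp_ambiguous"):
        if len(rejecting) >= 2:
            out.append(paired_tests(study, metric, rejecting))
    return pd.concat(out, ignore_index=True)


def compact_summary(study: pd.DataFrame) -> pd.DataFrame:
    """Mean-per-mechanism overview (percent, one decimal in rendering).

    Rows are metrics per category, columns mechanisms; undefined session
    values are excluded from the mean (NaN-aware), and a metric undefined
    for a mechanism everywhere renders as NaN.
    """
    mechanisms = list(dict.fromkeys(study["mechanism"]))
    rows = []
    spec = [
        ("Target (incl. ambiguous)", "Accuracy [%]", "accuracy"),
        ("Target (incl. ambiguous)", "Rejection rate [%]", "rr_target"),
        ("Target (incl. ambiguous)", "Rejection precision [%]", "rp_ambiguous"),
        ("Unknown", "Rejection rate [%]", "rr_unknown"),
        ("Body movement", "Rejection rate [%]", "rr_nontarget"),
    ]
    for category, metric_name, col in spec:
        row: dict = {"category": category, "metric": metric_name}
        for mech in mechanisms:
            vals = study.loc[study["mechanism"] == mech, col].astype(float)
            mean = vals.mean()  # NaN-aware; all-undefined stays NaN
            row[mech] = round(100.0 * mean, 1) if np.isfinite(mean) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
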