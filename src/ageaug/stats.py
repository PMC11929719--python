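"""Macro-F1 metrics and the multi-run statistical comparison protocol.

Experiments are repeated several times with different seeds; each condition
(no erasing NE, random erasing RE, attention-guided erasing AGE) yields a
list of per-run macro F1 scores. Conditions are summarized as mean +/-
sample standard deviation and compared by a two-tailed unpaired Student
t-test (pooled variance; Welch's correction available behind a flag).
Significance markers follow the convention '*' for p < 0.0001 and '+' for
p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.metrics import f1_score

__all__ = [
    "macro_f1",
    "aggregate_runs",
    "unpaired_t_test",
    "compare_conditions",
    "EvalReport",
    "P_STRONG",
    "P_WEAK",
]

P_STRONG = 1e-4   # '*' marker
P_WEAK = 0.05     # '+' marker
_P_FLOOR = np.finfo(float).tiny


def macro_f1(labels, predictions, n_classes: int) -> float:
    """Unweighted mean of per-class F1 over all ``n_classes`` classes.

    A class with zero precision+recall denominator (absent from both labels
    and predictions, or never correctly predicted) contributes F1 = 0.
    """
    labels = np.asarray(labels, dtype=int)
    predictions = np.asarray(predictions, dtype=int)
    if labels.shape != predictions.shape or labels.ndim != 1 or labels.size < 1:
        raise ValueError("labels and predictions must be equal-length 1-D, nonempty")
    for arr in (labels, predictions):
        if (arr < 0).any() or (arr >= n_classes).any():
            raise ValueError("class index out of range")
    return float(f1_score(labels, predictions, labels=np.arange(n_classes),
                          average="macro", zero_division=0))


def aggregate_runs(f1_values) -> tuple[float, float]:
    """Mean and sample (n-1 denominator) standard deviation of per-run scores."""
    vals = np.asarray(list(f1_values), dtype=np.float64)
    if vals.size < 2:
        raise ValueError("need at least 2 runs for a standard deviation")
    return float(vals.mean()), float(vals.std(ddof=1))


def unpaired_t_test(a, b, welch: bool = False) -> tuple[float, float]:
    """Two-sample two-tailed t-test; Student pooled variance by default.

    Degenerate inputs with zero pooled variance return (0, 1) when the means
    agree and (+/-inf, minimal positive p) when they differ.
    """
    a = np.asarray(list(a), dtype=np.float64)
    b = np.asarray(list(b), dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), _P_FLOOR
    res = sps.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


@dataclass
class EvalReport:
    """Three-condition comparison: per-condition mean/std and AGE-vs-baseline tests."""

    condition_stats: dict[str, tuple[float, float, int]]  # name -> (mean, std, n)
    tests: dict[str, tuple[float, float]]                 # comparison -> (t, p)
    markers: dict[str, str] = field(default_factory=dict)  # comparison -> '', '+', '*'

    def age_marker(self) -> str:
        """Joint marker for the AGE row: the weakest of the two comparisons."""
        order = {"*": 2, "+": 1, "": 0}
        if not self.markers:
            return ""
        weakest = min(self.markers.values(), key=lambda m: order[m])
        return weakest

    def to_table(self) -> str:
        lines = ["condition\tmean_macro_f1 ± std\tn_runs"]
        label = {"NE": "No Erasing", "RE": "Random Erasing",
                 "AGE": "Attention-Guided Erasing"}
        for name in ("NE", "RE", "AGE"):
            mean, std, n = self.condition_stats[name]
            marker = self.age_marker() if name == "AGE" else ""
            lines.append(f"{label[name]}\t{mean:.4f} ± {std:.3f}{marker}\t{n}")
        for cmp_name, (t, p) in self.tests.items():
            lines.append(f"{cmp_name}\tt={t:.4f}\tp={p:.6g}{self.markers[cmp_name]}")
        return "\n".join(lines)


def _marker(p: float) -> str:
    if p < P_STRONG:
        return "*"
    if p < P_WEAK:
        return "+"
    return ""


def compare_conditions(ne_runs, re_runs, age_runs, welch: bool = False) -> EvalReport:
    """Aggregate the three conditions and test AGE against both baselines."""
    stats_by_cond = {}
    for name, runs in (("NE", ne_runs), ("RE", re_runs), ("AGE", age_runs)):
        runs = list(runs)
        mean, std = aggregate_runs(runs)
        stats_by_cond[name] = (mean, std, len(runs))
    tests = {
        "AGE_vs_NE": unpaired_t_test(age_runs, ne_runs, welch=welch),
        "AGE_vs_RE": unpaired_t_test(age_runs, re_runs, welch=welch),
    }
    markers = {k: _marker(p) for k, (_, p) in tests.items()}
    return EvalReport(condition_stats=stats_by_cond, tests=tests, markers=markers)
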