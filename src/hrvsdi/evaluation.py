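"""Per-case evaluation battery.

Each candidate depth-of-anaesthesia series (raw SDI, single-network
fit, ensemble fit, or an external index such as BIS) is scored against
the EACL gold standard case by case: Pearson correlation, mean absolute
error, and the ROC area for discriminating consciousness (EACL above
the clinical threshold of 65) from anaesthesia.  Methods are compared
with two-sided paired Student t-tests over the per-case metrics, and
everything is collected into a table mirroring the clinical reporting
layout (per-case rows, mean +/- SD summary, p-values).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .errors import InvalidArgumentError, UndefinedStatisticError

CONSCIOUSNESS_THRESHOLD = 65.0  # EACL above this scores as "conscious"


def pearson_r(a, b) -> float:
    """Product-moment correlation; constant input is undefined."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise InvalidArgumentError("series must share length")
    if a.size < 3:
        raise InvalidArgumentError("need >= 3 points for a correlation")
    if np.std(a) == 0 or np.std(b) == 0:
        raise UndefinedStatisticError("correlation undefined for a constant series")
    return float(stats.pearsonr(a, b).statistic)


def mae(a, b) -> float:
    """Mean absolute error, in score units."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise InvalidArgumentError("series must share length")
    if a.size == 0:
        raise InvalidArgumentError("need >= 1 point")
    return float(np.mean(np.abs(a - b)))


def roc_auc(scores, reference, threshold: float = CONSCIOUSNESS_THRESHOLD) -> float:
    """ROC area for consciousness discrimination.

    The reference series is binarised as conscious iff it exceeds
    ``threshold`` (strictly); higher predictor scores are taken to
    indicate consciousness.  Ties are handled by the rank/trapezoidal
    formulation.
    """
    scores = np.asarray(scores, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if scores.shape != reference.shape:
        raise InvalidArgumentError("series must share length")
    labels = reference > threshold
    if labels.all() or not labels.any():
        raise UndefinedStatisticError(
            f"reference has a single class at threshold {threshold}; AUC undefined")
    return float(roc_auc_score(labels, scores))


def paired_t_test(x, y):
    """Two-sided paired Student t-test on per-case metrics.

    Returns ``(t, p)``; identical series (all-zero differences) are a
    degenerate input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise InvalidArgumentError("need two equal-length series with n >= 2")
    if np.allclose(x - y, 0.0):
        raise UndefinedStatisticError("all paired differences are zero; t undefined")
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class EvalReport:
    """Per-case metric rows plus summary and paired-test results."""

    rows: pd.DataFrame                      # case, method, correlation, mae, auc
    summary: pd.DataFrame                   # method x metric: mean, sd
    paired_tests: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_text(self) -> str:
        """Plain-text rendering in the clinical-table style."""
        parts = ["Per-case metrics", self.rows.to_string(index=False), "",
                 "Summary (mean +/- SD)"]
        for method, grp in self.rows.groupby("method", sort=False):
            line = f"  {method}: "
            line += ", ".join(
                f"{m}={grp[m].mean():.4f} +/- {grp[m].std(ddof=1):.4f}"
                for m in ("correlation", "mae", "auc") if grp[m].notna().any())
            parts.append(line)
        if len(self.paired_tests):
            parts += ["", "Paired Student t-tests", self.paired_tests.to_string(index=False)]
        return "\n".join(parts)


def _case_metrics(pred, ref, threshold):
    row = {}
    try:
        row["correlation"] = pearson_r(pred, ref)
    except (InvalidArgumentError, UndefinedStatisticError):
        row["correlation"] = np.nan
    row["mae"] = mae(pred, ref)
    try:
        row["auc"] = roc_auc(pred, ref, threshold)
    except UndefinedStatisticError:
        row["auc"] = np.nan
    return row


def case_report(predictions_by_case: dict, eacl_by_case: dict,
                baseline_by_case: dict | None = None,
                method_name: str = "prediction", baseline_name: str = "baseline",
                threshold: float = CONSCIOUSNESS_THRESHOLD) -> EvalReport:
    """Score every case, summarise, and compare methods pairwise.

    ``predictions_by_case`` and optional ``baseline_by_case`` map case
    ids to score series aligned (same length and timestamps) with the
    EACL series in ``eacl_by_case``.
    """
    rows = []
    for cid in sorted(predictions_by_case, key=str):
        if cid not in eacl_by_case:
            continue
        ref = np.asarray(eacl_by_case[cid], dtype=float)
        rows.append({"case": cid, "method": method_name,
                     **_case_metrics(np.asarray(predictions_by_case[cid], dtype=float),
                                     ref, threshold)})
        if baseline_by_case is not None and cid in baseline_by_case:
            rows.append({"case": cid, "method": baseline_name,
                         **_case_metrics(np.asarray(baseline_by_case[cid], dtype=float),
                                         ref, threshold)})
    if not rows:
        raise InvalidArgumentError("no valid cases to report")
    df = pd.DataFrame(rows)

    summary = (df.groupby("method", sort=False)[["correlation", "mae", "auc"]]
               .agg(["mean", "std"]))  # pandas std is sample SD (ddof=1)
    summary.columns = ["_".join(col) for col in summary.columns]

    tests = []
    methods = list(df["method"].unique())
    if len(methods) == 2:
        a, b = methods
        merged = df[df.method == a].merge(df[df.method == b], on="case",
                                          suffixes=("_a", "_b"))
        for metric in ("correlation", "mae", "auc"):
            xa = merged[f"{metric}_a"].to_numpy()
            xb = merged[f"{metric}_b"].to_numpy()
            ok = np.isfinite(xa) & np.isfinite(xb)
            if ok.sum() < 2:
                continue
            try:
                t, p = paired_t_test(xa[ok], xb[ok])
            except UndefinedStatisticError:
                t, p = np.nan, 1.0  # no difference between the methods
            tests.append({"comparison": f"{a} vs {b}", "metric": metric,
                          "t": t, "p": p, "n": int(ok.sum())})
    return EvalReport(rows=df, summary=summary, paired_tests=pd.DataFrame(tests))
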