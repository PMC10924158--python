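"""Figures of merit and cohort summarization.

Two families are implemented side by side because their disagreement is
the phenomenon this package studies:

* task-agnostic FoMs — Dice and Jaccard overlap coefficients and the
  Hausdorff distance between a predicted and a reference mask;
* task-based FoMs — the signed and absolute normalized error of an
  estimated clinical quantity (MTV or TLG) against its true value, and
  the ensemble normalized bias, i.e. the normalized error averaged over
  the cohort's distribution of true values, reported in percent.

Cohort summaries report each FoM as mean with a 95% t-interval and
compare algorithm pairs with two-sided paired t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from petseval.core import SegmentationMask

#: columns of an EvaluationTable (one row per case x algorithm)
EVAL_COLUMNS = [
    "case_id",
    "algorithm",
    "dsc",
    "jsc",
    "hd_mm",
    "mtv_ml",
    "tlg_g",
    "true_mtv_ml",
    "true_tlg_g",
    "mtv_ne",
    "mtv_ane",
    "tlg_ne",
    "tlg_ane",
    "degenerate",
]


def _check_pair(truth: SegmentationMask, pred: SegmentationMask) -> None:
    if truth.shape != pred.shape:
        raise ValueError(f"mask grids differ: {truth.shape} vs {pred.shape}")


def dice_coefficient(truth: SegmentationMask, pred: SegmentationMask) -> float:
    """2|A∩B| / (|A|+|B|); 1.0 by convention when both masks are empty."""
    _check_pair(truth, pred)
    a = truth.values
    b = pred.values
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def jaccard_coefficient(truth: SegmentationMask, pred: SegmentationMask) -> float:
    """|A∩B| / |A∪B|; 1.0 by convention when both masks are empty."""
    _check_pair(truth, pred)
    a = truth.values
    b = pred.values
    union = int((a | b).sum())
    if union == 0:
        return 1.0
    return int((a & b).sum()) / union


def hausdorff_distance(truth: SegmentationMask, pred: SegmentationMask) -> float:
    """Symmetric Hausdorff distance between voxel-center point sets, in mm.

    The full (100th percentile) Hausdorff: max over the two directed
    max-min distances. Undefined (raises) if either mask is empty.
    """
    _check_pair(truth, pred)
    if truth.n_foreground == 0 or pred.n_foreground == 0:
        raise ValueError("Hausdorff distance is undefined for an empty mask")
    spacing = np.asarray(truth.spacing)
    pa = np.argwhere(truth.values) * spacing
    pb = np.argwhere(pred.values) * spacing
    d_ab = cKDTree(pb).query(pa)[0].max()
    d_ba = cKDTree(pa).query(pb)[0].max()
    return float(max(d_ab, d_ba))


def normalized_error(estimate: float, truth: float) -> tuple[float, float]:
    """Signed and absolute error relative to the true value."""
    if truth <= 0:
        raise ValueError("normalized error requires a positive true value")
    ne = (estimate - truth) / truth
    return ne, abs(ne)


def ensemble_normalized_bias(ne_values, absolute: bool = False) -> float:
    """Mean per-case normalized error across the cohort, in percent.

    With ``absolute=True`` returns |mean|, the absolute ensemble
    normalized bias (positive and negative per-case errors may cancel
    in the signed mean, which is why both variants are reported).
    """
    arr = np.asarray(list(ne_values), dtype=float)
    if arr.size == 0:
        raise ValueError("ensemble bias requires at least one record")
    bias = float(arr.mean()) * 100.0
    return abs(bias) if absolute else bias


@dataclass
class CohortSummary:
    """Per-FoM cohort statistics and paired-test results for (A, B)."""

    algorithms: tuple[str, str]
    n_cases: int
    means: dict = field(default_factory=dict)  # {algorithm: {fom: mean}}
    ci95: dict = field(default_factory=dict)  # {algorithm: {fom: (lo, hi)}}
    p_values: dict = field(default_factory=dict)  # {fom: P}
    degenerate_tests: list = field(default_factory=list)
    bias_pct: dict = field(default_factory=dict)  # {algorithm: {mtv,tlg: signed %}}
    abs_bias_pct: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "algorithms": list(self.algorithms),
            "n_cases": self.n_cases,
            "means": self.means,
            "ci95": self.ci95,
            "p_values": self.p_values,
            "degenerate_tests": self.degenerate_tests,
            "ensemble_normalized_bias_pct": self.bias_pct,
            "abs_ensemble_normalized_bias_pct": self.abs_bias_pct,
        }


def mean_ci95(values) -> tuple[float, tuple[float, float]]:
    """Sample mean and two-sided 95% t-interval (n-1 df)."""
    arr = np.asarray(list(values), dtype=float)
    n = arr.size
    if n < 2:
        raise ValueError("confidence interval requires n >= 2")
    m = float(arr.mean())
    sem = float(arr.std(ddof=1)) / np.sqrt(n)
    tcrit = float(stats.t.ppf(0.975, n - 1))
    return m, (m - tcrit * sem, m + tcrit * sem)


def paired_t_test(a, b) -> tuple[float, bool]:
    """Two-sided paired t-test P-value; flags the all-zero-difference case.

    Returns ``(p, degenerate)``; when every paired difference is exactly
    zero the test statistic is undefined and P is reported as 1.0 with
    the degenerate flag set.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired test requires equal-length samples")
    if a.size < 2:
        raise ValueError("paired test requires n >= 2")
    d = a - b
    if np.all(d == 0):
        return 1.0, True
    t = stats.ttest_rel(a, b)
    return float(t.pvalue), False


def summarize_and_test(
    table: pd.DataFrame,
    pair: tuple[str, str],
    foms: tuple[str, ...] = ("dsc", "jsc", "hd_mm"),
) -> CohortSummary:
    """Cohort means, 95% CIs, paired tests, and ensemble biases for a pair.

    ``table`` is an EvaluationTable (one row per case x algorithm). Both
    algorithms must cover the same case set; the paired test is aligned
    on ``case_id``.
    """
    alg_a, alg_b = pair
    sub = {a: table[table["algorithm"] == a].set_index("case_id") for a in pair}
    cases_a, cases_b = set(sub[alg_a].index), set(sub[alg_b].index)
    if cases_a != cases_b:
        missing = sorted(cases_a ^ cases_b)
        raise ValueError(f"algorithms cover different case sets; mismatched: {missing}")
    cases = sorted(cases_a)
    if len(cases) < 2:
        raise ValueError("cohort summary requires at least 2 cases")
    summary = CohortSummary(algorithms=(alg_a, alg_b), n_cases=len(cases))
    for alg in pair:
        df = sub[alg].loc[cases]
        summary.means[alg] = {}
        summary.ci95[alg] = {}
        for fom in foms:
            vals = df[fom].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            m, ci = mean_ci95(vals)
            summary.means[alg][fom] = m
            summary.ci95[alg][fom] = ci
        summary.bias_pct[alg] = {
            "mtv": ensemble_normalized_bias(df["mtv_ne"]),
            "tlg": ensemble_normalized_bias(df["tlg_ne"]),
        }
        summary.abs_bias_pct[alg] = {
            "mtv": ensemble_normalized_bias(df["mtv_ne"], absolute=True),
            "tlg": ensemble_normalized_bias(df["tlg_ne"], absolute=True),
        }
    for fom in foms:
        va = sub[alg_a].loc[cases, fom].to_numpy(dtype=float)
        vb = sub[alg_b].loc[cases, fom].to_numpy(dtype=float)
        ok = np.isfinite(va) & np.isfinite(vb)
        p, degenerate = paired_t_test(va[ok], vb[ok])
        summary.p_values[fom] = p
        if degenerate:
            summary.degenerate_tests.append(fom)
    return summary


def evaluate_case(
    truth: SegmentationMask,
    pred: SegmentationMask,
    volume,
    true_mtv: float,
    true_tlg: float,
    case_id: str,
    algorithm: str,
) -> dict:
    """One EvaluationTable row: overlap FoMs plus MTV/TLG errors.

    An empty prediction is scored as DSC/JSC 0 with an undefined (NaN)
    Hausdorff distance and MTV/TLG of 0, flagged degenerate rather than
    raised: algorithm failure is a legitimate study outcome.
    """
    from petseval.quantify import quantify  # local import avoids a cycle

    q = quantify(pred, volume)
    degenerate = pred.n_foreground == 0 or bool(pred.meta.get("degenerate", False))
    if pred.n_foreground == 0:
        dsc, jsc, hd = 0.0, 0.0, float("nan")
    else:
        dsc = dice_coefficient(truth, pred)
        jsc = jaccard_coefficient(truth, pred)
        hd = hausdorff_distance(truth, pred)
    mtv_ne, mtv_ane = normalized_error(q.mtv, true_mtv)
    tlg_ne, tlg_ane = normalized_error(q.tlg, true_tlg)
    return {
        "case_id": case_id,
        "algorithm": algorithm,
        "dsc": dsc,
        "jsc": jsc,
        "hd_mm": hd,
        "mtv_ml": q.mtv,
        "tlg_g": q.tlg,
        "true_mtv_ml": true_mtv,
        "true_tlg_g": true_tlg,
        "mtv_ne": mtv_ne,
        "mtv_ane": mtv_ane,
        "tlg_ne": tlg_ne,
        "tlg_ane": tlg_ane,
        "degenerate": degenerate,
    }
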