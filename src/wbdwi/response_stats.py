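"""Response statistics: normality gate, two-group tests, ROC rows.

For each candidate feature the cohort analysis mirrors the clinical study
design: complete metabolic responders (CMR) are compared against partial
responders (PMR) at the relevant timepoint; stable/progressive patients are
excluded from the comparison.  A Lilliefors-corrected Kolmogorov-Smirnov
test decides between the Welch t-test (both groups normal) and the
two-sided Mann-Whitney U test; for features significant at alpha an
empirical ROC curve is built and an operating cutoff chosen by Youden's J.

The positive class for ROC purposes is PMR (poor response: the event worth
detecting), but orientation is chosen per feature so that the reported AUC
is >= 0.5 and is always stated explicitly, since whether PMR sits above or
below CMR genuinely varies by feature (e.g. diffusion volume is higher in
poor responders while ADC percentiles are lower).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

from .config import AnalysisConfig
from .errors import ParameterError, SingleClassError, UndersizeError
from .volumes import CohortManifest

# ---------------------------------------------------------------------------
# normality gate


@dataclass
class NormalityResult:
    p_value: float
    is_normal: bool


def ks_normality(values: Sequence[float], alpha: float = 0.05) -> NormalityResult:
    """Kolmogorov-Smirnov normality test with Lilliefors correction.

    The correction is needed because the normal's mean and sd are estimated
    from the sample.  A zero-variance sample is declared non-normal by
    convention; n < 4 raises (the null distribution is not tabulated there).
    """
    x = np.asarray(values, dtype=np.float64)
    if x.size < 4:
        raise UndersizeError(f"normality test needs n >= 4, got {x.size}")
    if np.ptp(x) == 0:
        return NormalityResult(p_value=0.0, is_normal=False)
    _, p = lilliefors(x, dist="norm", pvalmethod="table")
    return NormalityResult(p_value=float(p), is_normal=bool(p >= alpha))


# ---------------------------------------------------------------------------
# two-group location test


@dataclass
class TestResult:
    test_used: str  # "mann_whitney" | "t_test"
    p_value: float
    statistic: float


def two_group_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    is_normal: bool,
    exact_max_n: int = 14,
) -> TestResult:
    """Welch t-test if both groups passed normality, else Mann-Whitney U.

    The Mann-Whitney p-value is exact (full null enumeration) when the
    combined sample size is at most ``exact_max_n`` and there are no ties —
    the regime of small clinical cohorts, where the normal approximation is
    least trustworthy — and tie-corrected asymptotic otherwise.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise UndersizeError(f"both groups need n >= 2, got {a.size} and {b.size}")
    if is_normal:
        stat, p = sps.ttest_ind(a, b, equal_var=False)
        return TestResult("t_test", float(p), float(stat))
    combined = np.concatenate([a, b])
    if np.ptp(combined) == 0:  # all values identical: no evidence either way
        u = a.size * b.size / 2.0
        return TestResult("mann_whitney", 1.0, u)
    tie_free = np.unique(combined).size == combined.size
    method = "exact" if (combined.size <= exact_max_n and tie_free) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult("mann_whitney", float(res.pvalue), float(res.statistic))


# ---------------------------------------------------------------------------
# ROC analysis


@dataclass
class RocResult:
    auc: float
    cutoff: float
    sensitivity: float  # percent, unrounded
    specificity: float
    accuracy: float
    orientation: str  # "ge": positive class called when score >= cutoff; "le" otherwise
    n_pos: int
    n_neg: int

    @property
    def rounded(self) -> tuple[int, int, int]:
        """(Sen, Spec, Acc) as displayed: nearest integer percent."""
        return (
            int(round(self.sensitivity)),
            int(round(self.specificity)),
            int(round(self.accuracy)),
        )


def auc_from_scores(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """Empirical AUC for the 'positive scores are higher' orientation.

    Equals U/(n1*n2) from the Mann-Whitney statistic: the fraction of
    (positive, negative) pairs ranked concordantly, ties counting 1/2.
    """
    pos = np.asarray(pos_scores, dtype=np.float64)[:, None]
    neg = np.asarray(neg_scores, dtype=np.float64)[None, :]
    greater = (pos > neg).sum()
    ties = (pos == neg).sum()
    return float((greater + 0.5 * ties) / (pos.size * neg.size))


def roc_analysis(
    scores: Sequence[float],
    labels: Sequence[str],
    positive_label: str = "PMR",
) -> RocResult:
    """Empirical ROC over all distinct cutoffs, with a Youden-J cutoff.

    Orientation is flipped when needed so the reported AUC is >= 0.5.
    Candidate cutoffs are midpoints between consecutive distinct scores (plus
    the extreme value itself), so the cutoff is expressed in feature units
    and classifies identically to any value in the same gap.  Ties in J are
    broken toward higher specificity, then toward the more conservative
    (fewer-positives) cutoff.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    y = labels == positive_label
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise SingleClassError(
            f"ROC needs both classes; got {n_pos} positive / {n_neg} negative"
        )
    if not np.all(np.isfinite(scores)):
        raise ParameterError("ROC scores must be finite")

    auc_ge = auc_from_scores(scores[y], scores[~y])
    orientation = "ge" if auc_ge >= 0.5 else "le"
    auc = auc_ge if orientation == "ge" else 1.0 - auc_ge

    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    if orientation == "ge":
        candidates = np.concatenate([[uniq[0]], mids])  # uniq[0] -> everyone positive
        pred = scores[None, :] >= candidates[:, None]
        conservative_order = np.argsort(-candidates, kind="stable")
    else:
        candidates = np.concatenate([mids, [uniq[-1]]])
        pred = scores[None, :] <= candidates[:, None]
        conservative_order = np.argsort(candidates, kind="stable")

    tp = (pred & y[None, :]).sum(axis=1)
    tn = (~pred & ~y[None, :]).sum(axis=1)
    sens = tp / n_pos
    spec = tn / n_neg
    j = sens + spec - 1.0

    # max J -> max specificity -> most conservative cutoff, deterministically
    best = None
    for idx in conservative_order:
        key = (j[idx], spec[idx])
        if best is None or key > best[0]:
            best = (key, idx)
    idx = best[1]

    acc = (tp[idx] + tn[idx]) / (n_pos + n_neg)
    return RocResult(
        auc=auc,
        cutoff=float(candidates[idx]),
        sensitivity=100.0 * float(sens[idx]),
        specificity=100.0 * float(spec[idx]),
        accuracy=100.0 * float(acc),
        orientation=orientation,
        n_pos=n_pos,
        n_neg=n_neg,
    )


def confusion_accuracy(tp: int, fn: int, tn: int, fp: int) -> dict[str, float]:
    """Sensitivity/specificity/accuracy (percent) from confusion counts.

    Accuracy is the prevalence-weighted mean of sensitivity and specificity:
    (TP + TN) / N.  ``*_rounded`` fields carry the displayed integer percent.
    """
    n_pos, n_neg = tp + fn, tn + fp
    if n_pos == 0 or n_neg == 0:
        raise SingleClassError("confusion matrix needs both classes")
    sens = 100.0 * tp / n_pos
    spec = 100.0 * tn / n_neg
    acc = 100.0 * (tp + tn) / (n_pos + n_neg)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "accuracy": acc,
        "sensitivity_rounded": int(round(sens)),
        "specificity_rounded": int(round(spec)),
        "accuracy_rounded": int(round(acc)),
    }


# ---------------------------------------------------------------------------
# cohort-level comparison runner


#: mode -> (label timepoint, candidate feature sets). A candidate set is
#: ("f", timepoint) for raw features or ("d", pair tag) for percentage changes.
COMPARISON_MODES: dict[str, tuple[int, tuple[tuple[str, object], ...]]] = {
    "predict_interim": (1, (("f", 0),)),
    "predict_eot": (2, (("f", 0), ("f", 1), ("d", "01"))),
    "assess_interim": (1, (("f", 1), ("d", "01"))),
    "assess_eot": (2, (("f", 2), ("d", "02"), ("d", "12"))),
}


@dataclass
class ComparisonPlan:
    """Which feature sets may be compared for a given clinical question."""

    mode: str
    label_timepoint: int = field(init=False)
    candidate_sets: tuple[tuple[str, object], ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.mode not in COMPARISON_MODES:
            raise ParameterError(
                f"unknown mode {self.mode!r}; expected one of {sorted(COMPARISON_MODES)}"
            )
        self.label_timepoint, self.candidate_sets = COMPARISON_MODES[self.mode]


def _feature_key(name: str, th: float, tag: str, kind: str) -> str:
    prefix = "d" if kind == "d" else ""
    return f"{prefix}{name}{th:g}%{tag}"


@dataclass
class ComparisonReport:
    """Results table plus the completeness report of skipped features."""

    mode: str
    results: pd.DataFrame
    skipped: pd.DataFrame
    n_cmr: int
    n_pmr: int

    @property
    def significant(self) -> pd.DataFrame:
        return self.results[self.results["significant"]].reset_index(drop=True)


RESULT_COLUMNS = [
    "feature", "feature_name", "threshold_percent", "source", "tag",
    "n_cmr", "n_pmr",
    "median_cmr", "q1_cmr", "q3_cmr", "median_pmr", "q1_pmr", "q3_pmr",
    "test_used", "p_value", "q_value", "significant",
    "auc", "cutoff", "orientation",
    "sensitivity", "specificity", "accuracy",
    "sensitivity_pct", "specificity_pct", "accuracy_pct",
]


def run_comparisons(
    features: pd.DataFrame,
    deltas: pd.DataFrame,
    manifest: CohortManifest,
    plan: ComparisonPlan | str,
    config: AnalysisConfig | None = None,
) -> ComparisonReport:
    """CMR-vs-PMR comparison of every candidate feature of a plan.

    For each feature: normality gate per group -> Welch t or Mann-Whitney;
    medians and interquartile ranges always reported; ROC row added only when
    p < alpha.  Patients labelled SMD/PMD at the plan's timepoint are
    excluded.  Features missing (or undefined) for any included patient are
    skipped and listed in the completeness report.  Benjamini-Hochberg
    q-values are reported as a supplementary column; significance is gated on
    the raw p-value alone, matching the single-threshold convention of small
    exploratory cohorts.
    """
    config = config or AnalysisConfig()
    if isinstance(plan, str):
        plan = ComparisonPlan(plan)

    labels = manifest.labels(plan.label_timepoint)
    cmr_ids = [pid for pid, lab in labels.items() if lab == "CMR"]
    pmr_ids = [pid for pid, lab in labels.items() if lab == "PMR"]
    if len(cmr_ids) < 2 or len(pmr_ids) < 2:
        raise UndersizeError(
            f"{plan.mode}: need >= 2 patients per group, got "
            f"{len(cmr_ids)} CMR / {len(pmr_ids)} PMR"
        )
    included = set(cmr_ids) | set(pmr_ids)

    rows: list[dict] = []
    skipped: list[dict] = []
    for kind, tag in plan.candidate_sets:
        if kind == "f":
            sub = features[features["timepoint"] == tag]
            tag_str = str(tag)
        else:
            sub = deltas[deltas["pair"] == tag]
            tag_str = str(tag)
        sub = sub[sub["patient_id"].isin(included)]
        for (th, name), grp in sub.groupby(["threshold_percent", "feature_name"], sort=True):
            key = _feature_key(name, th, tag_str, kind)
            values = grp.set_index("patient_id")["value"]
            missing = sorted(included - set(values.index[np.isfinite(values)]))
            if missing:
                skipped.append(
                    {"feature": key, "reason": "missing_or_undefined", "patients": ";".join(missing)}
                )
                continue
            g_cmr = values.loc[cmr_ids].to_numpy(dtype=np.float64)
            g_pmr = values.loc[pmr_ids].to_numpy(dtype=np.float64)

            def _normal(g: np.ndarray) -> bool:
                if g.size < 4:
                    return False  # too small to certify normality; use ranks
                return ks_normality(g, config.alpha).is_normal

            is_normal = _normal(g_cmr) and _normal(g_pmr)
            test = two_group_test(g_cmr, g_pmr, is_normal, config.exact_mw_max_n)
            row = {
                "feature": key,
                "feature_name": name,
                "threshold_percent": th,
                "source": "feature" if kind == "f" else "delta",
                "tag": tag_str,
                "n_cmr": g_cmr.size,
                "n_pmr": g_pmr.size,
                "median_cmr": float(np.median(g_cmr)),
                "q1_cmr": float(np.percentile(g_cmr, 25)),
                "q3_cmr": float(np.percentile(g_cmr, 75)),
                "median_pmr": float(np.median(g_pmr)),
                "q1_pmr": float(np.percentile(g_pmr, 25)),
                "q3_pmr": float(np.percentile(g_pmr, 75)),
                "test_used": test.test_used,
                "p_value": test.p_value,
                "significant": bool(test.p_value < config.alpha),
            }
            if row["significant"]:
                roc = roc_analysis(
                    np.concatenate([g_cmr, g_pmr]),
                    np.array(["CMR"] * g_cmr.size + ["PMR"] * g_pmr.size),
                    positive_label="PMR",
                )
                sen_r, spec_r, acc_r = roc.rounded
                row.update(
                    auc=roc.auc, cutoff=roc.cutoff, orientation=roc.orientation,
                    sensitivity=roc.sensitivity, specificity=roc.specificity,
                    accuracy=roc.accuracy,
                    sensitivity_pct=sen_r, specificity_pct=spec_r, accuracy_pct=acc_r,
                )
            rows.append(row)

    results = pd.DataFrame(rows)
    if not results.empty:
        results["q_value"] = multipletests(results["p_value"], method="fdr_bh")[1]
        results = results.reindex(columns=RESULT_COLUMNS)
    else:
        results = pd.DataFrame(columns=RESULT_COLUMNS)
    skipped_df = pd.DataFrame(skipped, columns=["feature", "reason", "patients"])
    return ComparisonReport(
        mode=plan.mode,
        results=results,
        skipped=skipped_df,
        n_cmr=len(cmr_ids),
        n_pmr=len(pmr_ids),
    )
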