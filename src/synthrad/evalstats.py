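"""Evaluation statistics: ROC/AUC, DeLong, NRI/IDI, calibration, decision
curves, confusion metrics, and reader-study tabulation.

Positive-class conventions (fixed by enum-like constants rather than left
implicit): tumor-consistency models score "fibrous" as the positive class;
the real-versus-synthetic reader study scores "synthetic" as positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve
from statsmodels.stats.proportion import proportion_confint

POSITIVE_CONSISTENCY = "fibrous"
POSITIVE_READER = "synthetic"

N_BOOTSTRAP = 2000


# ----------------------------------------------------------------------
# ROC / AUC


@dataclass
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    roc_points: np.ndarray = field(repr=False)  # columns fpr, tpr
    n_pos: int
    n_neg: int

    def trapezoid_auc(self) -> float:
        fpr, tpr = self.roc_points[:, 0], self.roc_points[:, 1]
        return float(np.trapezoid(tpr, fpr))


def _binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "OUS":
        y = (y == POSITIVE_CONSISTENCY).astype(int)
    y = y.astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary (0/1 or soft/fibrous)")
    return y


def mann_whitney_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Concordance probability with half credit for ties."""
    r = stats.rankdata(scores)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    return float((r[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def auc(scores, labels, n_boot: int = N_BOOTSTRAP, seed: int = 0) -> ROCResult:
    """AUC (Mann-Whitney form) with a stratified-bootstrap 95% CI."""
    s = np.asarray(scores, dtype=float)
    y = _binary(labels)
    point = mann_whitney_auc(s, y)
    fpr, tpr, _ = roc_curve(y, s)
    pos, neg = np.where(y == 1)[0], np.where(y == 0)[0]
    rng = np.random.default_rng([seed, 440_001])
    reps = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate([rng.choice(pos, pos.size), rng.choice(neg, neg.size)])
        reps[b] = mann_whitney_auc(s[idx], y[idx])
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return ROCResult(auc=point, ci_low=float(lo), ci_high=float(hi),
                     roc_points=np.column_stack([fpr, tpr]),
                     n_pos=int(y.sum()), n_neg=int(y.size - y.sum()))


# ----------------------------------------------------------------------
# DeLong's test


def _structural_components(scores: np.ndarray, y: np.ndarray):
    pos = scores[y == 1]
    neg = scores[y == 0]
    v10 = np.empty(pos.size)
    v01 = np.empty(neg.size)
    for i, x in enumerate(pos):
        v10[i] = ((x > neg).sum() + 0.5 * (x == neg).sum()) / neg.size
    for j, x in enumerate(neg):
        v01[j] = ((pos > x).sum() + 0.5 * (pos == x).sum()) / pos.size
    return v10, v01


def delong_test(pred_a, pred_b, labels) -> tuple[float, float]:
    """Paired comparison of two correlated AUCs.

    Returns ``(z, two-sided p)``; identical predictions give (0, 1).
    """
    a = np.asarray(pred_a, dtype=float)
    b = np.asarray(pred_b, dtype=float)
    y = _binary(labels)
    if a.shape != b.shape or a.shape[0] != y.shape[0]:
        raise ValueError("predictions must be paired on the same cases")
    v10a, v01a = _structural_components(a, y)
    v10b, v01b = _structural_components(b, y)
    auc_a, auc_b = v10a.mean(), v10b.mean()
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]))
    s01 = np.cov(np.vstack([v01a, v01b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0:
        return 0.0, 1.0
    z = float((auc_a - auc_b) / np.sqrt(var))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return z, p


def delong_variance(scores, labels) -> float:
    """Variance of a single AUC from the structural components."""
    y = _binary(labels)
    v10, v01 = _structural_components(np.asarray(scores, dtype=float), y)
    return float(np.var(v10, ddof=1) / v10.size + np.var(v01, ddof=1) / v01.size)


# ----------------------------------------------------------------------
# reclassification


@dataclass
class ReclassificationResult:
    nri: float
    idi: float
    nri_ci: tuple[float, float]
    idi_ci: tuple[float, float]
    nri_p: float
    idi_p: float
    p_up_event: float
    p_down_event: float
    p_up_nonevent: float
    p_down_nonevent: float


def nri_idi(p_old, p_new, labels) -> ReclassificationResult:
    """Category-free NRI and IDI of a new risk model over an old one.

    NRI = [P(up|event) - P(down|event)] + [P(down|nonevent) - P(up|nonevent)];
    IDI = discrimination-slope(new) - discrimination-slope(old).  CIs and
    p-values use the asymptotic normal forms.
    """
    po = np.asarray(p_old, dtype=float)
    pn = np.asarray(p_new, dtype=float)
    y = _binary(labels)
    if po.shape != pn.shape or po.shape[0] != y.shape[0]:
        raise ValueError("probability vectors must be paired")
    if ((po < 0) | (po > 1) | (pn < 0) | (pn > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    ev, ne = y == 1, y == 0
    n_e, n_ne = int(ev.sum()), int(ne.sum())
    if n_e == 0 or n_ne == 0:
        raise ValueError("both outcome classes must be present")
    up, down = pn > po, pn < po
    pue, pde = up[ev].mean(), down[ev].mean()
    pun, pdn = up[ne].mean(), down[ne].mean()
    nri = (pue - pde) + (pdn - pun)
    se_nri = np.sqrt((pue + pde - (pue - pde) ** 2) / n_e
                     + (pun + pdn - (pdn - pun) ** 2) / n_ne)
    d = pn - po
    idi = d[ev].mean() - d[ne].mean()
    se_idi = np.sqrt(d[ev].var(ddof=1) / n_e + d[ne].var(ddof=1) / n_ne) \
        if n_e > 1 and n_ne > 1 else 0.0

    def ptail(est, se):
        return float(2.0 * stats.norm.sf(abs(est) / se)) if se > 0 else 1.0

    zq = stats.norm.ppf(0.975)
    return ReclassificationResult(
        nri=float(nri), idi=float(idi),
        nri_ci=(float(nri - zq * se_nri), float(nri + zq * se_nri)),
        idi_ci=(float(idi - zq * se_idi), float(idi + zq * se_idi)),
        nri_p=ptail(nri, se_nri), idi_p=ptail(idi, se_idi),
        p_up_event=float(pue), p_down_event=float(pde),
        p_up_nonevent=float(pun), p_down_nonevent=float(pdn))


# ----------------------------------------------------------------------
# confusion metrics


def confusion_metrics(pred_labels, true_labels,
                      positive=POSITIVE_CONSISTENCY) -> dict:
    """Accuracy, sensitivity, specificity with Wilson 95% intervals."""
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape:
        raise ValueError("prediction/label length mismatch")
    pos = true == positive if true.dtype.kind in "OUS" else true.astype(bool)
    ppos = pred == positive if pred.dtype.kind in "OUS" else pred.astype(bool)
    tp = int((ppos & pos).sum())
    tn = int((~ppos & ~pos).sum())
    fp = int((ppos & ~pos).sum())
    fn = int((~ppos & pos).sum())
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("a class is empty; metrics undefined")

    def with_ci(count, nobs):
        lo, hi = proportion_confint(count, nobs, method="wilson")
        return {"value": count / nobs, "ci_low": float(lo), "ci_high": float(hi)}

    return {
        "accuracy": with_ci(tp + tn, tp + tn + fp + fn),
        "sensitivity": with_ci(tp, tp + fn),
        "specificity": with_ci(tn, tn + fp),
        "counts": {"tp": tp, "fp": fp, "tn": tn, "fn": fn},
    }


# ----------------------------------------------------------------------
# reader study


@dataclass
class ReaderStudyTable:
    """Tidy counts of the real-or-fake test.

    One row per (reader, modality, truth) with the number of images called
    real and called synthetic; each row must sum to the per-arm presented
    count when ``arm_size`` is given.
    """

    table: pd.DataFrame = field(repr=False)
    arm_size: int | None = None

    REQUIRED = ("reader", "modality", "truth", "called_real", "called_synthetic")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"reader-study table missing columns: {missing}")
        bad = set(self.table["truth"]) - {"real", "synthetic"}
        if bad:
            raise ValueError(f"unknown truth values: {bad}")
        sums = self.table["called_real"] + self.table["called_synthetic"]
        if self.arm_size is not None and not (sums == self.arm_size).all():
            raise ValueError(
                f"cell sums {sorted(set(sums))} inconsistent with arm size "
                f"{self.arm_size}")

    @classmethod
    def from_csv(cls, path, arm_size: int | None = None) -> "ReaderStudyTable":
        return cls(pd.read_csv(path), arm_size=arm_size)


def reader_study_summary(table: ReaderStudyTable,
                         printed_values: dict | None = None) -> dict:
    """Per-reader pooled metrics and per-arm detection proportions.

    "Synthetic" is the positive class: sensitivity is the proportion of
    synthetic images called synthetic.  Pooling sums counts across
    modalities per reader.  ``mean_synthetic_detection`` averages, over
    every (reader, modality) cell, the proportion of synthetic images
    correctly called synthetic.  When ``printed_values`` supplies
    externally reported per-reader numbers, any disagreement with the
    table-derived values (> 0.005) is listed under ``discrepancies``.
    """
    t = table.table
    readers = {}
    for reader, grp in t.groupby("reader"):
        syn = grp[grp["truth"] == "synthetic"]
        real = grp[grp["truth"] == "real"]
        tp = int(syn["called_synthetic"].sum())
        fn = int(syn["called_real"].sum())
        tn = int(real["called_real"].sum())
        fp = int(real["called_synthetic"].sum())
        readers[reader] = {
            "sensitivity": tp / (tp + fn),
            "specificity": tn / (tn + fp),
            "accuracy": (tp + tn) / (tp + tn + fp + fn),
        }
    syn_cells = t[t["truth"] == "synthetic"]
    props = (syn_cells["called_synthetic"]
             / (syn_cells["called_synthetic"] + syn_cells["called_real"]))
    result = {
        "per_reader": readers,
        "mean_synthetic_detection": float(props.mean()),
        "discrepancies": [],
    }
    if printed_values:
        for reader, metrics in printed_values.items():
            for metric, printed in metrics.items():
                derived = readers.get(reader, {}).get(metric)
                if derived is not None and abs(derived - printed) > 0.005:
                    result["discrepancies"].append(
                        f"{reader} {metric}: printed {printed:.3f} vs "
                        f"table-derived {derived:.3f}")
    return result


# ----------------------------------------------------------------------
# calibration and decision curves


def calibration_curve(pred, labels, n_bins: int = 10) -> dict:
    """Equal-frequency reliability curve plus logistic recalibration.

    Returns bin mean predicted probability, bin event rate, and the slope
    and intercept of the logistic recalibration of outcomes on logit(p).
    """
    p = np.asarray(pred, dtype=float)
    y = _binary(labels)
    if p.size < n_bins:
        raise ValueError(f"need >= {n_bins} cases for {n_bins} bins")
    order = np.argsort(p, kind="stable")
    bins = np.array_split(order, n_bins)
    bin_p, bin_rate = [], []
    for idx in bins:
        if idx.size == 0:
            raise ValueError("degenerate (empty) calibration bin")
        bin_p.append(float(p[idx].mean()))
        bin_rate.append(float(y[idx].mean()))
    eps = 1e-6
    logit = np.log(np.clip(p, eps, 1 - eps) / np.clip(1 - p, eps, 1 - eps))
    import statsmodels.api as sm

    try:
        fit = sm.GLM(y, sm.add_constant(logit),
                     family=sm.families.Binomial()).fit()
        intercept, slope = float(fit.params[0]), float(fit.params[1])
    except Exception:  # perfect separation on tiny inputs
        intercept, slope = float("nan"), float("nan")
    return {"bin_mean_p": bin_p, "bin_event_rate": bin_rate,
            "slope": slope, "intercept": intercept}


def decision_curve(pred, labels, threshold_grid) -> pd.DataFrame:
    """Net benefit of the model versus treat-all and treat-none.

    ``net_benefit = TP/n - (FP/n) * t/(1-t)`` at each threshold ``t``;
    treat-none is 0 and treat-all follows from prevalence in closed form.
    """
    p = np.asarray(pred, dtype=float)
    y = _binary(labels)
    t_grid = np.asarray(threshold_grid, dtype=float)
    if ((t_grid <= 0) | (t_grid >= 1)).any():
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    n = y.size
    prev = y.mean()
    rows = []
    for t in t_grid:
        treat = p >= t
        tp = int((treat & (y == 1)).sum())
        fp = int((treat & (y == 0)).sum())
        odds = t / (1.0 - t)
        rows.append({
            "threshold": t,
            "net_benefit_model": tp / n - fp / n * odds,
            "net_benefit_treat_all": prev - (1.0 - prev) * odds,
            "net_benefit_treat_none": 0.0,
        })
    return pd.DataFrame(rows)
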