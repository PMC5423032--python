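"""Antibody/serum microarray signal extraction, group comparison and ROC.

Lectin/glyco-antibody microarrays (LGAMs) immobilize antibodies against
candidate glycoproteins, capture them from serum, and read their
glycosylation with a labelled lectin; serum microarrays immobilize the serum
itself and probe it with the labelled lectin. Both reduce to the same spot
arithmetic: background-filter replicate spots (the ±2 SD rule shared with the
lectin-array module), take the per-sample per-probe median of the effective
net values, compare groups, and evaluate a candidate biomarker by an
empirical ROC curve with an operating point chosen by Youden's J.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import DEFAULT_CONTROL_PROBES, ValidationError
from .lectin_array import filter_effective_spots

logger = logging.getLogger(__name__)


def lgam_signals(spots: pd.DataFrame, metadata: pd.DataFrame,
                 control_probes: frozenset[str] = DEFAULT_CONTROL_PROBES) -> pd.DataFrame:
    """Per-sample, per-antibody median of background-filtered net intensities.

    Spots are filtered block-wise with the ±2 SD background rule, then the
    median is taken over all effective replicate spots of an antibody across
    the sample's blocks. Pairs whose spots were all rejected are reported
    with ``median_signal`` NaN and ``missing`` True (never imputed as zero).
    Control probes are excluded.
    """
    groups = metadata.set_index("sample_id")["group"]
    rows = []
    for (sample_id, _block), block in spots.groupby(["sample_id", "block_id"], sort=False):
        effective, _ = filter_effective_spots(block)
        for probe, nets in effective.items():
            if probe in control_probes:
                continue
            for v in nets:
                rows.append((sample_id, probe, v))
    eff = pd.DataFrame(rows, columns=["sample_id", "antibody", "net"])
    medians = eff.groupby(["sample_id", "antibody"])["net"].median()
    antibodies = sorted(set(spots.loc[~spots["is_control"], "probe"]))
    full_index = pd.MultiIndex.from_product(
        [sorted(set(spots["sample_id"])), antibodies], names=["sample_id", "antibody"])
    out = medians.reindex(full_index).rename("median_signal").reset_index()
    out["missing"] = out["median_signal"].isna()
    out["group"] = out["sample_id"].map(groups)
    return out


@dataclass
class GroupComparison:
    fold: float          # case mean / control mean
    p_value: float
    mode: str            # "paired" or "welch"
    degenerate: bool = False  # paired differences had zero variance


def group_compare(control_values, case_values, paired: bool = True) -> GroupComparison:
    """Two-sided t-test between groups plus the case/control fold estimate.

    ``paired`` matches samples by position (requires equal sizes); otherwise
    a Welch unequal-variance test is used. All-zero paired differences make
    the paired statistic undefined; this is flagged (``degenerate``) with
    p = NaN rather than silently reported.
    """
    ctrl = np.asarray(list(control_values), float)
    case = np.asarray(list(case_values), float)
    ctrl, case_nan = ctrl[~np.isnan(ctrl)], case[~np.isnan(case)]
    case = case_nan
    if len(ctrl) < 2 or len(case) < 2:
        raise ValidationError("each group needs ≥2 non-missing samples")
    fold = float(case.mean() / ctrl.mean()) if ctrl.mean() != 0 else float("inf")
    if paired:
        if len(ctrl) != len(case):
            raise ValidationError("paired mode requires equal group sizes")
        diffs = case - ctrl
        if np.allclose(diffs.std(ddof=1), 0.0):
            return GroupComparison(fold, float("nan"), "paired", degenerate=True)
        p = float(stats.ttest_rel(case, ctrl).pvalue)
        return GroupComparison(fold, p, "paired")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.ttest_ind(case, ctrl, equal_var=False)
    p = float(res.pvalue)
    if math.isnan(p) and np.array_equal(case, ctrl):
        p = 1.0  # identical groups: no evidence of difference
    return GroupComparison(fold, p, "welch")


@dataclass
class RocResult:
    """Empirical ROC curve with AUC and a Youden-optimal operating point."""

    auc: float
    points: list[tuple[float, float]]            # (1 − specificity, sensitivity)
    thresholds: list[float] = field(repr=False, default_factory=list)
    threshold_star: float = float("nan")
    sensitivity_star: float = float("nan")
    specificity_star: float = float("nan")

    def as_dict(self) -> dict:
        return {"auc": self.auc, "threshold_star": self.threshold_star,
                "sensitivity_star": self.sensitivity_star,
                "specificity_star": self.specificity_star}


def roc_curve(scores, labels, positive_label: str = "ASD",
              auto_flip: bool = False) -> RocResult:
    """Empirical ROC over all distinct thresholds of a continuous score.

    AUC uses the Mann–Whitney identity (probability a random positive
    outscores a random negative, ties counting ½), so it equals exhaustive
    pair counting exactly. The operating point maximizes Youden's
    J = sensitivity + specificity − 1; ties go to the higher-specificity
    threshold. ``auto_flip`` negates the score orientation when AUC < 0.5
    (off by default) and is recorded via a negative ``threshold_star`` sign
    convention being avoided — flipped results are recomputed on −score.
    """
    scores = np.asarray(list(scores), float)
    labels = np.asarray(list(labels))
    pos = scores[labels == positive_label]
    neg = scores[labels != positive_label]
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("both groups must be nonempty for ROC analysis")

    # Mann–Whitney AUC via midranks (ties count 1/2)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    auc = (ranks[:len(pos)].sum() - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg))
    if auto_flip and auc < 0.5:
        warnings.warn("AUC < 0.5; score orientation flipped")
        flipped = roc_curve(-scores, labels, positive_label, auto_flip=False)
        return flipped

    # curve: classify positive when score >= threshold, thresholds descending
    thresholds = np.unique(scores)[::-1]
    sens = [(pos >= t).mean() for t in thresholds]
    fpr = [(neg >= t).mean() for t in thresholds]
    points = [(0.0, 0.0)] + list(zip(fpr, sens))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))

    j_best, star = -np.inf, None
    for t, s, f in zip(thresholds, sens, fpr):
        j = s + (1 - f) - 1
        if j > j_best + 1e-12 or (abs(j - j_best) <= 1e-12 and star is not None and (1 - f) > star[2]):
            j_best, star = j, (float(t), float(s), float(1 - f))
    return RocResult(float(auc), points, [float(t) for t in thresholds],
                     threshold_star=star[0], sensitivity_star=star[1],
                     specificity_star=star[2])


def serum_array_compare(spots: pd.DataFrame, metadata: pd.DataFrame, probe: str,
                        paired: bool = True, case_group: str = "ASD",
                        control_group: str = "TD"
                        ) -> tuple[pd.DataFrame, GroupComparison]:
    """Serum-microarray comparison of one labelled-lectin probe across samples.

    Same filtering/median pipeline as :func:`lgam_signals` restricted to one
    probe, followed by a TD-vs-ASD test of the per-sample medians.
    """
    signals = lgam_signals(spots, metadata)
    sub = signals[signals["antibody"] == probe].dropna(subset=["median_signal"])
    ctrl = sub.loc[sub["group"] == control_group].sort_values("sample_id")["median_signal"]
    case = sub.loc[sub["group"] == case_group].sort_values("sample_id")["median_signal"]
    if len(ctrl) < 2 or len(case) < 2:
        raise ValidationError("need ≥2 samples per group for serum-array comparison")
    cmp_res = group_compare(ctrl, case, paired=paired)
    return sub.reset_index(drop=True), cmp_res
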