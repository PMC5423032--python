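"""Label-free relative quantification from spectral counts.

Raw spectral counts R_i of a protein in run i are placed on a common depth
scale by ``N_i = R_i · C̄ / C_i``, where ``C_i`` is the total spectral count
of run i and ``C̄`` the average total over *all* runs under comparison (both
groups jointly). The per-group spectral index (SI) of a protein is the mean
of its normalized counts over that group's runs; the case/control abundance
ratio is ``SI_case / SI_control`` and proteins are classified as up-regulated
(ratio ≥ 1.5), down-regulated (ratio ≤ 0.67), group-specific (the other SI is
0) or unchanged. Identification accounting reports the usual
inclusion–exclusion set sizes with the common fraction as a percentage of the
union.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Collection, Iterable

import numpy as np
import pandas as pd

from .io import CountMatrix, ValidationError

logger = logging.getLogger(__name__)

RATIO_UP = 1.5
RATIO_DOWN = 0.67


@dataclass
class RunNormalization:
    run_id: str
    total: int            # C_i
    mean_total: float     # C̄ over all runs under comparison
    scale: float          # C̄ / C_i


@dataclass
class IdentificationAccounting:
    """Inclusion–exclusion accounting of two identification sets."""

    n_control: int
    n_case: int
    n_common: int
    n_control_only: int
    n_case_only: int
    n_union: int
    common_pct_of_union: float  # rounded to one decimal

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def normalize_runs(cm: CountMatrix) -> tuple[list[RunNormalization], pd.DataFrame]:
    """Depth-normalize a count matrix: ``N_i = R_i · C̄ / C_i``.

    After normalization every run's total equals C̄.
    """
    if cm.counts.shape[1] < 2:
        raise ValidationError("normalization requires ≥2 runs under comparison")
    totals = cm.counts.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValidationError(f"run {zero[0]!r} has total spectral count 0")
    c_bar = float(totals.mean())
    scales = c_bar / totals
    normalized = cm.counts * scales
    norms = [RunNormalization(str(r), int(totals[r]), c_bar, float(scales[r]))
             for r in cm.counts.columns]
    return norms, normalized


def spectral_index(normalized_counts: pd.Series | np.ndarray,
                   group_runs: Iterable[str] | None = None) -> float:
    """Per-group spectral index: mean normalized count over the group's runs.

    Zero iff the protein is absent from every run of the group. Runs where
    the protein was not observed contribute zeros to the mean.
    """
    if group_runs is not None:
        normalized_counts = pd.Series(normalized_counts).loc[list(group_runs)]
    vals = np.asarray(normalized_counts, float)
    if vals.size == 0:
        raise ValidationError("spectral index over an empty run set")
    return float(vals.mean())


def classify_regulation(si_control: float, si_case: float,
                        ratio_up: float = RATIO_UP,
                        ratio_down: float = RATIO_DOWN) -> tuple[str, float]:
    """Regulation label and case/control ratio from the two spectral indices.

    Boundary ratios are inclusive (1.5 → up, 0.67 → down). A protein seen in
    only one group is labelled ``case_only``/``control_only`` with ratio
    ``inf``/``0``.
    """
    if si_control < 0 or si_case < 0:
        raise ValidationError("spectral indices must be non-negative")
    if si_control == 0 and si_case == 0:
        raise ValidationError("protein absent from both groups")
    if si_control == 0:
        return "case_only", float("inf")
    if si_case == 0:
        return "control_only", 0.0
    ratio = si_case / si_control
    # inclusive boundaries, robust to floating rounding of the quotient
    if ratio >= ratio_up * (1 - 1e-12):
        return "up", ratio
    if ratio <= ratio_down * (1 + 1e-12):
        return "down", ratio
    return "unchanged", ratio


def quantify(cm: CountMatrix, case_group: str = "ASD", control_group: str = "TD",
             ratio_up: float = RATIO_UP, ratio_down: float = RATIO_DOWN,
             min_peptides: int = 1,
             peptide_counts: dict[str, int] | None = None) -> pd.DataFrame:
    """Full quantification table: SI per group, ratio and regulation label.

    ``peptide_counts`` (protein → distinct peptides) supports flagging
    single-peptide identifications; proteins below ``min_peptides`` are
    retained but flagged in the ``low_evidence`` column.
    """
    case_runs = [r for r, g in cm.groups.items() if g == case_group]
    ctrl_runs = [r for r, g in cm.groups.items() if g == control_group]
    if not case_runs or not ctrl_runs:
        raise ValidationError("both groups need at least one run")
    _, normalized = normalize_runs(cm)
    si_ctrl = normalized[ctrl_runs].mean(axis=1)
    si_case = normalized[case_runs].mean(axis=1)
    rows = []
    for pid in cm.proteins:
        c, a = float(si_ctrl[pid]), float(si_case[pid])
        if c == 0 and a == 0:
            label, ratio = "absent", float("nan")
        else:
            label, ratio = classify_regulation(c, a, ratio_up, ratio_down)
        npep = (peptide_counts or {}).get(pid)
        rows.append({"protein_id": pid, "si_control": c, "si_case": a,
                     "ratio": ratio, "regulation": label,
                     "low_evidence": bool(npep is not None and npep < min_peptides)})
    logger.info("quantify: thresholds ratio_up=%s ratio_down=%s", ratio_up, ratio_down)
    return pd.DataFrame(rows).set_index("protein_id")


def accounting(control_ids: Collection, case_ids: Collection) -> IdentificationAccounting:
    """Set accounting of identifications (works for proteins or peptides)."""
    ctrl, case = set(control_ids), set(case_ids)
    common = ctrl & case
    union = ctrl | case
    pct = round(100.0 * len(common) / len(union), 1) if union else 0.0
    return IdentificationAccounting(
        n_control=len(ctrl), n_case=len(case), n_common=len(common),
        n_control_only=len(ctrl - case), n_case_only=len(case - ctrl),
        n_union=len(union), common_pct_of_union=pct)
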