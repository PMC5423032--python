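"""Lectin-microarray processing: spot filtering, per-block normalization,
replicate aggregation, differential glycopattern analysis, and clustering.

The processing chain mirrors standard lectin-array practice:

1. Per block, spots whose foreground falls below ``mean(background) +
   2·SD(background)`` are discarded as noise-level; kept spots are background
   subtracted (``net = foreground − mean(background)``).
2. Per block, each lectin's median net value is divided by the sum of all
   lectins' medians, giving normalized fluorescence intensities (NFIs) that
   sum to 1 within the block.
3. NFIs are averaged over replicate blocks per sample (typically 9 = 3 blocks
   × 3 slides) with the SD recorded.
4. Group comparison uses fold change (case-group mean over control-group
   mean) gated at ≥1.5 / ≤0.67, plus a paired two-sided t-test over
   subgroup-matched means.

Sample SD (``ddof=1``) is used throughout; a single observation gives SD 0.
Medians of an even number of spots are the mean of the two central values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import (DEFAULT_CONTROL_PROBES, DegenerateBlockError,
                 InsufficientReplicatesError, ValidationError)

logger = logging.getLogger(__name__)

FOLD_UP = 1.5
FOLD_DOWN = 0.67
ALPHA = 0.05


@dataclass
class BlockNFIProfile:
    """Per-block normalized fluorescence intensities; values sum to 1."""

    block_id: str
    nfi: dict[str, float]


@dataclass
class SampleLectinProfile:
    """Per-sample lectin NFIs aggregated over replicate blocks."""

    sample_id: str
    mean_nfi: dict[str, float]
    sd_nfi: dict[str, float]
    n_blocks: int
    coverage: dict[str, int]  # blocks in which each lectin was effective


def filter_effective_spots(block: pd.DataFrame,
                           clamp_negative: bool = True
                           ) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Background-filter one block's spots and background-subtract the rest.

    The cutoff is ``mean(background) + 2·SD(background)`` over every spot of
    the block (controls included — they measure the same local background).
    Returns per-probe arrays of net values for kept spots and a rejection
    report (probe, replicate, foreground, cutoff).
    """
    if block.empty:
        raise ValidationError("empty block")
    bg = block["background"].to_numpy(float)
    mean_bg = float(bg.mean())
    sd_bg = float(bg.std(ddof=1)) if len(bg) > 1 else 0.0
    cutoff = mean_bg + 2.0 * sd_bg
    fg = block["foreground"].to_numpy(float)
    keep = fg >= cutoff
    net = fg - mean_bg
    if clamp_negative and (net[keep] < 0).any():
        warnings.warn("negative net intensity after background subtraction; clamped to 0")
        net = np.clip(net, 0.0, None)
    effective: dict[str, np.ndarray] = {}
    for probe in block["probe"].unique():
        mask = keep & (block["probe"] == probe).to_numpy()
        if mask.any():
            effective[str(probe)] = net[mask]
    rejected = block.loc[~keep, ["probe", "replicate", "foreground"]].copy()
    rejected["cutoff"] = cutoff
    rejected["reason"] = "foreground below background cutoff"
    return effective, rejected


def normalize_block(effective: dict[str, np.ndarray], block_id: str = "",
                    control_probes: frozenset[str] = DEFAULT_CONTROL_PROBES
                    ) -> BlockNFIProfile:
    """Median-sum normalization of one block's effective net values.

    ``nfi(l) = median(net_l) / Σ_l' median(net_l')`` over non-control probes.
    Lectins with no effective spots are simply absent from the result.
    """
    medians = {probe: float(np.median(vals))
               for probe, vals in effective.items()
               if probe not in control_probes and len(vals)}
    denom = sum(medians.values())
    if denom <= 0:
        raise DegenerateBlockError(f"block {block_id!r}: sum of lectin medians is {denom}")
    return BlockNFIProfile(block_id, {l: m / denom for l, m in medians.items()})


def aggregate_sample(blocks: list[BlockNFIProfile], sample_id: str = "") -> SampleLectinProfile:
    """Average per-lectin NFIs over replicate blocks (SD with ddof=1).

    A lectin present in only some blocks is averaged over those blocks and
    its coverage count recorded.
    """
    if not blocks:
        raise ValidationError("no blocks to aggregate")
    values: dict[str, list[float]] = {}
    for b in blocks:
        for lectin, v in b.nfi.items():
            values.setdefault(lectin, []).append(v)
    mean_nfi = {l: float(np.mean(v)) for l, v in values.items()}
    sd_nfi = {l: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0 for l, v in values.items()}
    coverage = {l: len(v) for l, v in values.items()}
    return SampleLectinProfile(sample_id, mean_nfi, sd_nfi, len(blocks), coverage)


def nfi_table(spots: pd.DataFrame) -> pd.DataFrame:
    """Vectorized filter → normalize over a whole spot table.

    Equivalent to running :func:`filter_effective_spots` +
    :func:`normalize_block` per (sample, block); returns a long frame with
    columns ``sample_id``, ``block_id``, ``probe``, ``nfi``.
    """
    grp = spots.groupby(["sample_id", "block_id"], sort=False)["background"]
    mean_bg = grp.transform("mean")
    sd_bg = grp.transform("std").fillna(0.0)
    keep = spots["foreground"] >= mean_bg + 2.0 * sd_bg
    net = (spots["foreground"] - mean_bg).clip(lower=0.0)
    eff = spots.loc[keep & ~spots["is_control"]].assign(net=net[keep & ~spots["is_control"]])
    med = eff.groupby(["sample_id", "block_id", "probe"], sort=False)["net"].median()
    denom = med.groupby(level=["sample_id", "block_id"], sort=False).transform("sum")
    if (denom <= 0).any():
        bad = denom.index[denom <= 0][0]
        raise DegenerateBlockError(f"block {bad[1]!r} of sample {bad[0]!r}: zero median sum")
    return (med / denom).rename("nfi").reset_index()


def sample_profiles(spots: pd.DataFrame) -> dict[str, SampleLectinProfile]:
    """Full per-sample aggregation of a spot table (filter → NFI → average)."""
    table = nfi_table(spots)
    profiles: dict[str, SampleLectinProfile] = {}
    for sample_id, sub in table.groupby("sample_id", sort=False):
        blocks = [BlockNFIProfile(str(b), dict(zip(g["probe"], g["nfi"])))
                  for b, g in sub.groupby("block_id", sort=False)]
        profiles[str(sample_id)] = aggregate_sample(blocks, str(sample_id))
    return profiles


def mean_nfi_matrix(profiles: dict[str, SampleLectinProfile]) -> pd.DataFrame:
    """Samples × lectins matrix of mean NFIs (absent lectins → 0)."""
    return pd.DataFrame({s: p.mean_nfi for s, p in profiles.items()}).T.fillna(0.0).sort_index(axis=1)


def differential_lectins(nfi_means: pd.DataFrame, metadata: pd.DataFrame,
                         case_group: str = "ASD", control_group: str = "TD",
                         fold_up: float = FOLD_UP, fold_down: float = FOLD_DOWN,
                         alpha: float = ALPHA, bh_correct: bool = False) -> pd.DataFrame:
    """Differential glycopattern analysis between paired subgroup profiles.

    ``nfi_means`` is a samples × lectins matrix of mean NFIs; ``metadata``
    supplies group labels and the ``subgroup_index`` pairing key (control
    subgroup k is paired with case subgroup k). Per lectin:

    * ``fold_change`` = case mean / control mean (infinite, flagged, when the
      control mean is 0);
    * ``p_value`` from a paired two-sided t-test over subgroup-matched means;
    * ``direction`` = up if fold ≥ ``fold_up`` and p < ``alpha``, down if
      fold ≤ ``fold_down`` and p < ``alpha``, else unchanged.

    With ``bh_correct`` a Benjamini–Hochberg ``q_value`` column is added and
    used for the direction gate instead of the raw p-value (off by default).
    """
    meta = metadata.set_index("sample_id")
    if "subgroup_index" not in meta.columns:
        raise ValidationError("metadata lacks subgroup_index pairing key")

    def group_matrix(group: str) -> pd.DataFrame:
        ids = meta.index[meta["group"] == group]
        m = nfi_means.loc[nfi_means.index.intersection(ids)]
        m = m.set_index(meta.loc[m.index, "subgroup_index"].astype(int))
        return m.sort_index()

    ctrl = group_matrix(control_group)
    case = group_matrix(case_group)
    if len(ctrl) != len(case) or not (ctrl.index == case.index).all():
        raise ValidationError("case/control subgroup indices do not pair up")
    if len(ctrl) < 2:
        raise InsufficientReplicatesError("paired t-test requires ≥2 subgroup pairs")

    lectins = sorted(set(ctrl.columns) | set(case.columns))
    ctrl = ctrl.reindex(columns=lectins, fill_value=0.0)
    case = case.reindex(columns=lectins, fill_value=0.0)

    ctrl_mean = ctrl.mean(axis=0)
    case_mean = case.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = case_mean / ctrl_mean
    ctrl_zero = ctrl_mean == 0
    fold[ctrl_zero] = np.inf

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-variance pairs yield nan p
        p = stats.ttest_rel(case.to_numpy(), ctrl.to_numpy(), axis=0).pvalue
    out = pd.DataFrame({"lectin": lectins,
                        "fold_change": fold.to_numpy(),
                        "p_value": p,
                        "control_mean_zero": ctrl_zero.to_numpy()})
    gate_p = out["p_value"]
    if bh_correct:
        from statsmodels.stats.multitest import multipletests
        finite = out["p_value"].fillna(1.0).to_numpy()
        out["q_value"] = multipletests(finite, method="fdr_bh")[1]
        gate_p = out["q_value"]
    sig = gate_p < alpha
    out["direction"] = "unchanged"
    out.loc[sig & (out["fold_change"] >= fold_up), "direction"] = "up"
    out.loc[sig & (out["fold_change"] <= fold_down), "direction"] = "down"
    logger.info("differential_lectins: thresholds fold_up=%s fold_down=%s alpha=%s",
                fold_up, fold_down, alpha)
    return out


# ---------------------------------------------------------------------------
# hierarchical clustering (1 − Pearson distance, average linkage)
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """Agglomerative clustering result.

    ``merges`` holds ``(i, j, height, new_index)`` tuples where leaf indices
    are ``0..n−1`` in input order and internal nodes are numbered from ``n``
    upward (as in scipy linkage matrices).
    """

    labels: list[str]
    merges: list[tuple[int, int, float, int]]

    def to_newick(self) -> str:
        """Ultrametric Newick rendering: leaf-to-node depth = height / 2."""
        n = len(self.labels)
        height = {i: 0.0 for i in range(n)}
        node = {i: self.labels[i] for i in range(n)}
        for i, j, h, new in self.merges:
            bl_i = h / 2 - height[i] / 2
            bl_j = h / 2 - height[j] / 2
            node[new] = f"({node[i]}:{bl_i:.6g},{node[j]}:{bl_j:.6g})"
            height[new] = h
        root = self.merges[-1][3] if self.merges else 0
        return node[root] + ";"


def correlation_distance(matrix: np.ndarray) -> np.ndarray:
    """1 − Pearson correlation between rows; zero-variance rows get r = 0."""
    x = np.asarray(matrix, float)
    sd = x.std(axis=1)
    if (sd == 0).any():
        warnings.warn("constant profile: correlations involving it set to 0")
    centered = x - x.mean(axis=1, keepdims=True)
    norm = np.where(sd > 0, sd * np.sqrt(x.shape[1]), 1.0)
    z = centered / norm[:, None]
    r = z @ z.T
    r[sd == 0, :] = 0.0
    r[:, sd == 0] = 0.0
    np.fill_diagonal(r, 1.0)
    return 1.0 - r


def hierarchical_cluster(matrix: pd.DataFrame) -> Dendrogram:
    """Average-linkage agglomerative clustering of the rows of ``matrix``.

    Distance is 1 − Pearson correlation. Deterministic: among tied minimum
    distances the pair with the lowest indices (in current merge order)
    merges first.
    """
    labels = [str(i) for i in matrix.index]
    if len(labels) < 2:
        raise ValidationError("clustering requires ≥2 profiles")
    d = correlation_distance(matrix.to_numpy())
    n = len(labels)
    active: list[int] = list(range(n))
    sizes = {i: 1 for i in range(n)}
    dist: dict[tuple[int, int], float] = {
        (i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    while len(active) > 1:
        best = None
        for a_pos, i in enumerate(active):
            for j in active[a_pos + 1:]:
                key = (min(i, j), max(i, j))
                if best is None or dist[key] < best[0] - 1e-15:
                    best = (dist[key], i, j)
        h, i, j = best
        merges.append((i, j, h, next_id))
        # average linkage: size-weighted mean of member distances
        for k in active:
            if k in (i, j):
                continue
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            dist[(k, next_id)] = (sizes[i] * dik + sizes[j] * djk) / (sizes[i] + sizes[j])
        sizes[next_id] = sizes[i] + sizes[j]
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1
    return Dendrogram(labels, merges)
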