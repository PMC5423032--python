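"""Iterative position-specific binomial motif extraction around glycosites.

Candidate glycosites are expanded into fixed-width residue windows (default
half-width k = 13, i.e. 27-mers, padded with ``X`` at protein termini). Given
a foreground window set (sites of interest) and a background set, motifs are
grown greedily, motif-x style:

1. For every (offset ≠ 0, residue) pair compute the exact binomial tail
   probability P(X ≥ c) with X ~ Binomial(n_fg, q), where c is the foreground
   count of the residue at the offset and q its current background frequency.
2. Fix the most significant pair (subject to a minimum foreground occurrence
   and a p-value threshold), reduce both sets to the windows matching it, and
   repeat until no pair qualifies.
3. The fixed pairs form one motif; its *fold increase* is the ratio of match
   fractions on the ORIGINAL (unreduced) foreground vs background sets, and
   its score is Σ −log10(p) over the steps (p floored at 1e-16). Matching
   foreground windows are removed and the search restarts for further
   nonredundant motifs.

``X`` padding never matches a fixed position and never supports enrichment.
Ties in step selection are broken deterministically: larger foreground count,
then smaller |offset|, then alphabetical residue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .io import AMINO_ACIDS, ValidationError

logger = logging.getLogger(__name__)

P_THRESHOLD = 1e-6
MIN_OCCURRENCES = 20
MIN_FOLD_INCREASE = 30.0
P_FLOOR = 1e-16  # keeps motif scores finite when a tail underflows to 0


@dataclass
class PeptideWindowSet:
    """Fixed-width residue windows centered on a candidate glycosite."""

    windows: list[str]
    center_residue: str
    role: str = "foreground"

    def __post_init__(self) -> None:
        if not self.windows:
            raise ValidationError("empty window set")
        w = len(self.windows[0])
        if w % 2 != 1:
            raise ValidationError("window width must be odd (2k+1)")
        k = w // 2
        for win in self.windows:
            if len(win) != w:
                raise ValidationError("windows of unequal width")
            if win[k] != self.center_residue:
                raise ValidationError(
                    f"window {win!r} does not hold {self.center_residue!r} at its center")

    @property
    def width(self) -> int:
        return len(self.windows[0])

    @property
    def k(self) -> int:
        return self.width // 2

    def to_array(self) -> np.ndarray:
        return np.array([list(w) for w in self.windows], dtype="<U1")


def build_windows(sequences: Mapping[str, str], sites: Mapping[str, Sequence[int]],
                  k: int = 13, center_residue: str = "N",
                  role: str = "foreground") -> PeptideWindowSet:
    """Cut a (2k+1)-wide window around each 1-based site position.

    Windows running past a terminus are padded with ``X``. Every site must
    hold ``center_residue``; duplicates (repeated sites) are retained.
    """
    windows = []
    for pid, positions in sites.items():
        seq = sequences[pid]
        for pos in positions:
            if not 1 <= pos <= len(seq) or seq[pos - 1] != center_residue:
                raise ValidationError(
                    f"protein {pid!r} position {pos}: expected {center_residue!r}, "
                    f"found {seq[pos - 1] if 1 <= pos <= len(seq) else 'out of range'!r}")
            lo, hi = pos - 1 - k, pos + k
            left = "X" * max(0, -lo)
            right = "X" * max(0, hi - len(seq))
            windows.append(left + seq[max(lo, 0):min(hi, len(seq))] + right)
    return PeptideWindowSet(windows, center_residue, role)


def position_frequencies(ws: PeptideWindowSet) -> pd.DataFrame:
    """Residue × offset relative frequencies, excluding ``X`` padding.

    Columns are offsets −k..k; at each offset frequencies over observed
    (non-``X``) residues sum to 1. An offset where every window is padding is
    returned as all-NaN (undefined).
    """
    arr = ws.to_array()
    k = ws.k
    offsets = list(range(-k, k + 1))
    out = pd.DataFrame(0.0, index=list(AMINO_ACIDS), columns=offsets)
    for col, off in enumerate(offsets):
        residues = arr[:, col]
        valid = residues != "X"
        n = int(valid.sum())
        if n == 0:
            out[off] = np.nan
            continue
        letters, counts = np.unique(residues[valid], return_counts=True)
        for letter, c in zip(letters, counts):
            out.loc[letter, off] = c / n
    return out


def binomial_enrichment(n: int, c: int, q: float) -> float:
    """Exact upper binomial tail P(X ≥ c), X ~ Binomial(n, q).

    ``c = 0`` gives 1 by convention; ``q = 0`` with ``c > 0`` gives 0 (the
    caller floors it before taking logs).
    """
    if not 0.0 <= q <= 1.0:
        raise ValidationError(f"background frequency {q} outside [0, 1]")
    if c <= 0:
        return 1.0
    if q == 0.0:
        return 0.0
    return float(binom.sf(c - 1, n, q))


@dataclass
class MotifStep:
    offset: int
    residue: str
    p_value: float
    fg_before: int
    fg_after: int
    bg_before: int
    bg_after: int


@dataclass
class Motif:
    """One extracted motif: fixed (offset, residue) steps plus statistics."""

    steps: list[MotifStep]
    k: int
    center_residue: str
    fold_increase: float = float("nan")
    fg_matches: int = 0
    fg_total: int = 0
    bg_matches: int = 0
    bg_total: int = 0

    @property
    def fixed(self) -> dict[int, str]:
        return {s.offset: s.residue for s in self.steps}

    @property
    def motif_score(self) -> float:
        return float(sum(-np.log10(max(s.p_value, P_FLOOR)) for s in self.steps))

    def pattern(self, half_width: int | None = None) -> str:
        """Render the consensus with ``x`` wildcards.

        ``half_width`` trims the rendering symmetrically (e.g. 6 → the
        13-position form often printed); fixed steps outside the trim are
        still part of the motif statistics.
        """
        hw = self.k if half_width is None else half_width
        fixed = self.fixed
        out = []
        for off in range(-hw, hw + 1):
            if off == 0:
                out.append(self.center_residue)
            else:
                out.append(fixed.get(off, "x"))
        return "".join(out)


def _match_mask(arr: np.ndarray, k: int, fixed: Mapping[int, str]) -> np.ndarray:
    mask = np.ones(arr.shape[0], dtype=bool)
    for off, residue in fixed.items():
        mask &= arr[:, off + k] == residue
    return mask


def fold_increase(fixed: Mapping[int, str], fg: PeptideWindowSet,
                  bg: PeptideWindowSet) -> tuple[float, int, int]:
    """Fold increase of a motif: fg match fraction over bg match fraction.

    Computed on the full (unreduced) sets. Zero background matches with a
    nonzero foreground fraction is reported as ``inf``.
    """
    fg_arr, bg_arr = fg.to_array(), bg.to_array()
    fg_m = int(_match_mask(fg_arr, fg.k, fixed).sum())
    bg_m = int(_match_mask(bg_arr, bg.k, fixed).sum())
    fg_frac = fg_m / len(fg.windows)
    bg_frac = bg_m / len(bg.windows)
    if bg_frac == 0.0:
        return (float("inf") if fg_frac > 0 else 0.0), fg_m, bg_m
    return fg_frac / bg_frac, fg_m, bg_m


def _best_step(fg_arr: np.ndarray, bg_arr: np.ndarray, k: int,
               free_offsets: list[int], p_threshold: float,
               min_occurrences: int) -> tuple[int, str, float, int] | None:
    """Most significant qualifying (offset, residue) pair, or None.

    Tie-break: smallest p, then largest fg count, then smallest |offset|,
    then alphabetical residue (offset sign breaks exact |offset| ties,
    negative first).
    """
    n_fg, n_bg = fg_arr.shape[0], bg_arr.shape[0]
    letters = np.array(list(AMINO_ACIDS), dtype="<U1")
    best = None
    for off in free_offsets:
        col_fg = fg_arr[:, off + k]
        col_bg = bg_arr[:, off + k]
        c = (col_fg[:, None] == letters).sum(axis=0)
        q = (col_bg[:, None] == letters).sum(axis=0) / n_bg
        with np.errstate(divide="ignore"):
            p = np.where(c > 0, binom.sf(c - 1, n_fg, np.clip(q, 1e-300, 1.0)), 1.0)
        p = np.where((q == 0) & (c > 0), 0.0, p)
        ok = (c >= min_occurrences) & (p < p_threshold)
        for idx in np.flatnonzero(ok):
            key = (float(p[idx]), -int(c[idx]), abs(off), off, str(letters[idx]))
            if best is None or key < best[0]:
                best = (key, (off, str(letters[idx]), float(p[idx]), int(c[idx])))
    return None if best is None else best[1]


def extract_motifs(fg: PeptideWindowSet, bg: PeptideWindowSet,
                   p_threshold: float = P_THRESHOLD,
                   min_fold_increase: float = MIN_FOLD_INCREASE,
                   min_occurrences: int = MIN_OCCURRENCES) -> list[Motif]:
    """Greedy iterative extraction of nonredundant motifs.

    Deterministic given input order. Motifs whose fold increase (measured on
    the original sets) does not exceed ``min_fold_increase`` are dropped, but
    their matching foreground windows are still removed before the restart so
    the search always terminates.
    """
    if fg.width != bg.width or fg.center_residue != bg.center_residue:
        raise ValidationError("foreground and background window sets are incompatible")
    k = fg.k
    fg_orig, bg_orig = fg.to_array(), bg.to_array()
    remaining = np.ones(fg_orig.shape[0], dtype=bool)
    motifs: list[Motif] = []
    while remaining.sum() >= min_occurrences:
        cur_fg = fg_orig[remaining]
        cur_bg = bg_orig.copy()
        free = [o for o in range(-k, k + 1) if o != 0]
        steps: list[MotifStep] = []
        while True:
            found = _best_step(cur_fg, cur_bg, k, free, p_threshold, min_occurrences)
            if found is None:
                break
            off, residue, p, c = found
            fgb, bgb = cur_fg.shape[0], cur_bg.shape[0]
            cur_fg = cur_fg[cur_fg[:, off + k] == residue]
            cur_bg = cur_bg[cur_bg[:, off + k] == residue]
            steps.append(MotifStep(off, residue, p, fgb, cur_fg.shape[0],
                                   bgb, cur_bg.shape[0]))
            free.remove(off)
        if not steps:
            break
        motif = Motif(steps, k, fg.center_residue)
        fixed = motif.fixed
        fi, fg_m, bg_m = fold_increase(fixed, fg, bg)
        motif.fold_increase = fi
        motif.fg_matches, motif.fg_total = fg_m, fg_orig.shape[0]
        motif.bg_matches, motif.bg_total = bg_m, bg_orig.shape[0]
        matched_remaining = _match_mask(fg_orig, k, fixed) & remaining
        remaining &= ~matched_remaining
        if fi > min_fold_increase:
            motifs.append(motif)
        logger.info("motif %s: score=%.2f fold_increase=%.2f (%s)",
                    motif.pattern(), motif.motif_score, fi,
                    "kept" if fi > min_fold_increase else "dropped")
    return motifs


def motif_table(motifs: list[Motif], trim_half_width: int | None = 6) -> pd.DataFrame:
    """Flat report of extracted motifs (one row per motif)."""
    rows = []
    for m in motifs:
        row = {"pattern": m.pattern(),
               "motif_score": m.motif_score,
               "fold_increase": m.fold_increase,
               "fg_matches": m.fg_matches, "fg_total": m.fg_total,
               "bg_matches": m.bg_matches, "bg_total": m.bg_total,
               "steps": ";".join(f"{s.offset}{s.residue}:p={s.p_value:.3g}" for s in m.steps)}
        if trim_half_width is not None:
            row["pattern_trimmed"] = m.pattern(trim_half_width)
        rows.append(row)
    return pd.DataFrame(rows)


def merge_consensus(motifs: list[Motif]) -> list[str]:
    """Presentation-only merge of motifs differing at exactly one position.

    Motifs sharing the same fixed offsets whose residues differ at a single
    offset are rendered as one consensus with a bracketed residue class
    (e.g. ``[KR]``); statistics remain per-motif in :func:`motif_table`.
    """
    groups: list[dict[int, set[str]]] = []
    for m in motifs:
        fixed = {o: {r} for o, r in m.fixed.items()}
        merged = False
        for g in groups:
            if set(g) != set(fixed):
                continue
            diff = [o for o in g if fixed[o] - g[o]]
            if len(diff) <= 1:
                for o in fixed:
                    g[o] |= fixed[o]
                merged = True
                break
        if not merged:
            groups.append(fixed)
    if not motifs:
        return []
    k, center = motifs[0].k, motifs[0].center_residue
    patterns = []
    for g in groups:
        out = []
        for off in range(-k, k + 1):
            if off == 0:
                out.append(center)
            elif off in g:
                res = sorted(g[off])
                out.append(res[0] if len(res) == 1 else "[" + "".join(res) + "]")
            else:
                out.append("x")
        patterns.append("".join(out))
    return patterns
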