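"""Synthetic-data generators with known ground truth for every pipeline stage.

The generators emulate the study design end to end: 37-lectin microarrays
read on pooled serum subgroups (five per group, nine replicate blocks each),
Poisson spectral counts from triplicate LC-MS/MS runs per group with unequal
depths, fixed-width residue windows with planted position-specific
enrichments, and two-group continuous biomarker scores under a binormal
model. Each generator returns plain tables (the same dialects the readers in
:mod:`glycoserum.io` accept) plus a truth table.

One master seed drives independent per-generator streams (spawned from a
single :class:`numpy.random.SeedSequence`), so adding or rerunning one
generator never perturbs another's draws; identical configs produce
byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io import AMINO_ACIDS, CountMatrix, ValidationError
from .motif_enrichment import PeptideWindowSet

#: The five lectins the study design contrasts, with their reported group
#: fold changes (case vs control); the remaining probes are padded to the
#: 37-lectin panel and left at fold 1.
DEFAULT_LECTIN_FOLDS = {"MAL-II": 3.33, "MAL-I": 2.20, "ACA": 1.65,
                        "PNA": 1.90, "STL": 0.54}

DEFAULT_PROTEIN_RATIOS = {"P001": 1.5, "P002": 2.0, "P003": 3.0,
                          "P004": 0.67, "P005": 0.5}

_STREAMS = {"lectin": 0, "spectral": 1, "windows": 2, "biomarker": 3, "serum": 4}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with the study design as defaults.

    Noise defaults: spot-level multiplicative noise CV 0.15, additive
    background Normal(200, 20) truncated at 0, lognormal σ 0.5 for baseline
    lectin signals (median 2000 fluorescence units) and σ 0.8 for baseline
    protein abundances (median 50 expected counts per unit depth).
    """

    seed: int = 0
    # lectin arrays
    n_lectins: int = 37
    n_subgroups_per_group: int = 5
    blocks_per_sample: int = 9
    spots_per_lectin: int = 3
    planted_lectin_folds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LECTIN_FOLDS))
    spot_noise_cv: float = 0.15
    background_mean: float = 200.0
    background_sd: float = 20.0
    baseline_median: float = 2000.0
    baseline_sigma: float = 0.5
    # spectral counts
    n_proteins: int = 100
    planted_protein_ratios: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROTEIN_RATIOS))
    runs_per_group: int = 3
    run_depth_multipliers: Sequence[float] = (1.0, 0.7, 1.3, 0.8, 1.2, 1.0)
    protein_baseline_median: float = 50.0
    protein_baseline_sigma: float = 0.8
    # motif windows
    motif_plants: Sequence[tuple[int, str, float]] = ((-1, "K", 0.7), (2, "Y", 0.7))
    fg_windows: int = 200
    bg_windows: int = 2000
    window_halfwidth: int = 13
    center_residue: str = "N"
    # biomarker scores / serum-style arrays
    biomarker_delta: float = 1.664
    n_samples_per_group: int = 15
    antibodies: Sequence[str] = ("C8B", "TF", "C1QA", "APOD")
    planted_antibody_folds: dict[str, float] = field(
        default_factory=lambda: {"APOD": 2.0})
    sample_noise_cv: float = 0.5  # biological between-sample variability
    spots_per_antibody: int = 5
    blocks_per_slide: int = 3
    case_group: str = "ASD"
    control_group: str = "TD"

    def __post_init__(self) -> None:
        counts = (self.n_lectins, self.n_subgroups_per_group, self.blocks_per_sample,
                  self.spots_per_lectin, self.n_proteins, self.runs_per_group,
                  self.fg_windows, self.bg_windows, self.window_halfwidth,
                  self.n_samples_per_group)
        if any(c < 1 for c in counts):
            raise ValidationError("all design counts must be ≥ 1")
        for _, residue, pen in self.motif_plants:
            if not 0.0 < pen <= 1.0:
                raise ValidationError("plant penetrance must be in (0, 1]")
            if residue not in AMINO_ACIDS:
                raise ValidationError(f"plant residue {residue!r} is not a standard residue")
        if len(self.run_depth_multipliers) < 2 * self.runs_per_group:
            raise ValidationError("need a depth multiplier per run (both groups)")

    def rng(self, stream: str) -> np.random.Generator:
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return np.random.default_rng(children[_STREAMS[stream]])

    def lectin_names(self) -> list[str]:
        named = list(DEFAULT_LECTIN_FOLDS)
        extra = [f"LEC{i:02d}" for i in range(len(named) + 1, self.n_lectins + 1)]
        return (named + extra)[: self.n_lectins]


def _lognormal(rng: np.random.Generator, median: float, sigma: float, size) -> np.ndarray:
    return rng.lognormal(mean=np.log(median), sigma=sigma, size=size)


def _noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative lognormal noise with unit mean and the given CV."""
    sigma = np.sqrt(np.log1p(cv ** 2))
    return rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma, size=size)


def simulate_lectin_arrays(config: SimulationConfig
                           ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Spot table, sample metadata and truth table for the lectin arrays.

    Per (sample, block, lectin, spot): ``foreground = baseline_lectin ×
    fold(group) × noise + local_background`` and the recorded background is
    an independent draw from the same background distribution, so the net
    value after block-level background subtraction is unbiased for the
    signal.
    """
    rng = config.rng("lectin")
    lectins = config.lectin_names()
    folds = {l: config.planted_lectin_folds.get(l, 1.0) for l in lectins}
    baselines = dict(zip(lectins, _lognormal(rng, config.baseline_median,
                                             config.baseline_sigma, len(lectins))))
    samples = ([(f"{config.control_group}-{i}", config.control_group, i)
                for i in range(1, config.n_subgroups_per_group + 1)]
               + [(f"{config.case_group}-{i}", config.case_group, i)
                  for i in range(1, config.n_subgroups_per_group + 1)])
    rows = []
    for sample_id, group, _sub in samples:
        is_case = group == config.case_group
        for b in range(1, config.blocks_per_sample + 1):
            for lectin in lectins:
                signal = baselines[lectin] * (folds[lectin] if is_case else 1.0)
                n = config.spots_per_lectin
                noise = _noise(rng, config.spot_noise_cv, n)
                local_bg = np.clip(rng.normal(config.background_mean,
                                              config.background_sd, n), 0, None)
                meas_bg = np.clip(rng.normal(config.background_mean,
                                             config.background_sd, n), 0, None)
                for r in range(n):
                    rows.append((sample_id, f"B{b}", lectin, r + 1,
                                 signal * noise[r] + local_bg[r], meas_bg[r]))
    spots = pd.DataFrame(rows, columns=["sample_id", "block_id", "probe",
                                        "replicate", "foreground", "background"])
    spots["is_control"] = False
    metadata = pd.DataFrame([{"sample_id": s, "group": g, "subgroup_index": i}
                             for s, g, i in samples])
    truth = pd.DataFrame({"lectin": lectins,
                          "true_fold": [folds[l] for l in lectins],
                          "baseline": [baselines[l] for l in lectins]})
    return spots, metadata, truth


def simulate_spectral_counts(config: SimulationConfig
                             ) -> tuple[CountMatrix, pd.DataFrame]:
    """Count matrix (with run groups) and per-protein truth ratios.

    Expected count of protein p in run i is ``baseline_p × ratio_p(group) ×
    depth_i``; observed counts are Poisson. All-zero proteins are dropped
    (they were never identified).
    """
    rng = config.rng("spectral")
    proteins = [f"P{i:03d}" for i in range(1, config.n_proteins + 1)]
    ratios = {p: config.planted_protein_ratios.get(p, 1.0) for p in proteins}
    baselines = _lognormal(rng, config.protein_baseline_median,
                           config.protein_baseline_sigma, len(proteins))
    runs, groups, depth = [], {}, []
    for g_idx, group in enumerate((config.control_group, config.case_group)):
        for r in range(config.runs_per_group):
            run_id = f"{group}_run{r + 1}"
            runs.append(run_id)
            groups[run_id] = group
            depth.append(config.run_depth_multipliers[g_idx * config.runs_per_group + r])
    depth_arr = np.array(depth)
    is_case = np.array([groups[r] == config.case_group for r in runs])
    ratio_arr = np.array([ratios[p] for p in proteins])
    lam = baselines[:, None] * np.where(is_case[None, :], ratio_arr[:, None], 1.0) * depth_arr[None, :]
    counts = rng.poisson(lam)
    df = pd.DataFrame(counts, index=proteins, columns=runs)
    nonzero = df.sum(axis=1) > 0
    df = df.loc[nonzero]
    truth = pd.DataFrame({"protein_id": proteins,
                          "true_ratio": ratio_arr,
                          "baseline": baselines}).set_index("protein_id").loc[nonzero]
    return CountMatrix(df, groups), truth.reset_index()


def simulate_windows(config: SimulationConfig
                     ) -> tuple[PeptideWindowSet, PeptideWindowSet, pd.DataFrame]:
    """Foreground/background window sets with planted enrichments.

    Background windows are i.i.d. uniform over the 20 residues with the fixed
    center residue; each planted (offset, residue, penetrance) is imposed
    independently on that fraction of foreground windows.
    """
    rng = config.rng("windows")
    k = config.window_halfwidth
    w = 2 * k + 1
    letters = np.array(list(AMINO_ACIDS), dtype="<U1")

    def draw(n: int) -> np.ndarray:
        arr = letters[rng.integers(0, len(letters), size=(n, w))]
        arr[:, k] = config.center_residue
        return arr

    bg = draw(config.bg_windows)
    fg = draw(config.fg_windows)
    for offset, residue, penetrance in config.motif_plants:
        mask = rng.random(config.fg_windows) < penetrance
        fg[mask, offset + k] = residue
    truth = pd.DataFrame(list(config.motif_plants),
                         columns=["offset", "residue", "penetrance"])
    to_set = lambda arr, role: PeptideWindowSet(["".join(r) for r in arr],
                                                config.center_residue, role)
    return to_set(fg, "foreground"), to_set(bg, "background"), truth


def simulate_biomarker_scores(config: SimulationConfig
                              ) -> tuple[pd.DataFrame, float]:
    """Binormal biomarker scores: control ~ N(0,1), case ~ N(δ,1).

    The true AUC is Φ(δ/√2).
    """
    rng = config.rng("biomarker")
    n = config.n_samples_per_group
    ctrl = rng.normal(0.0, 1.0, n)
    case = rng.normal(config.biomarker_delta, 1.0, n)
    df = pd.DataFrame({
        "sample_id": [f"{config.control_group}-{i+1}" for i in range(n)]
                     + [f"{config.case_group}-{i+1}" for i in range(n)],
        "score": np.concatenate([ctrl, case]),
        "group": [config.control_group] * n + [config.case_group] * n})
    true_auc = float(norm.cdf(config.biomarker_delta / np.sqrt(2)))
    return df, true_auc


def simulate_serum_spots(config: SimulationConfig
                         ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Spot table for an antibody-microarray validation experiment.

    Each antibody is printed in quintuplicate per block with triplicate
    blocks per sample; per-sample antibody signals are lognormal around an
    antibody baseline, multiplied by the planted fold for case samples, with
    the same spot noise and background model as the lectin arrays. BSA and
    dilution-buffer spots are included as negative controls (background-level
    foreground).
    """
    rng = config.rng("serum")
    n = config.n_samples_per_group
    antibodies = list(config.antibodies)
    baselines = dict(zip(antibodies, _lognormal(rng, config.baseline_median,
                                                config.baseline_sigma, len(antibodies))))
    samples = ([(f"{config.control_group}-{i+1}", config.control_group, i + 1) for i in range(n)]
               + [(f"{config.case_group}-{i+1}", config.case_group, i + 1) for i in range(n)])
    rows = []
    for sample_id, group, _idx in samples:
        is_case = group == config.case_group
        # per-sample biological variability around the antibody baseline
        sample_level = _noise(rng, config.sample_noise_cv, len(antibodies))
        for b in range(1, config.blocks_per_slide + 1):
            for a_idx, ab in enumerate(antibodies):
                fold = config.planted_antibody_folds.get(ab, 1.0) if is_case else 1.0
                signal = baselines[ab] * fold * sample_level[a_idx]
                nspot = config.spots_per_antibody
                noise = _noise(rng, config.spot_noise_cv, nspot)
                local = np.clip(rng.normal(config.background_mean,
                                           config.background_sd, nspot), 0, None)
                meas = np.clip(rng.normal(config.background_mean,
                                          config.background_sd, nspot), 0, None)
                for r in range(nspot):
                    rows.append((sample_id, f"B{b}", ab, r + 1,
                                 signal * noise[r] + local[r], meas[r]))
            for ctrl_probe in ("BSA", "buffer"):
                for r in range(config.spots_per_antibody):
                    fgv = np.clip(rng.normal(config.background_mean,
                                             config.background_sd), 0, None)
                    bgv = np.clip(rng.normal(config.background_mean,
                                             config.background_sd), 0, None)
                    rows.append((sample_id, f"B{b}", ctrl_probe, r + 1, fgv, bgv))
    spots = pd.DataFrame(rows, columns=["sample_id", "block_id", "probe",
                                        "replicate", "foreground", "background"])
    spots["is_control"] = spots["probe"].isin({"BSA", "buffer"})
    metadata = pd.DataFrame([{"sample_id": s, "group": g, "subgroup_index": i}
                             for s, g, i in samples])
    truth = pd.DataFrame({"antibody": antibodies,
                          "true_fold": [config.planted_antibody_folds.get(a, 1.0)
                                        for a in antibodies]})
    return spots, metadata, truth
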