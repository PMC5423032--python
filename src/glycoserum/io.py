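"""Readers and writers for the tabular formats used across the pipeline.

All inputs are plain UTF-8 tab-separated text (or standard FASTA):

* **spot table** — one row per microarray spot, columns ``sample_id``,
  ``block_id``, ``probe``, ``replicate``, ``foreground``, ``background``.
  This is the minimal post-extraction table produced by spot-quantification
  software; vendor-specific extended headers are not modelled.
* **count matrix** — spectral counts, proteins in rows, LC-MS/MS runs in
  columns; a sidecar metadata table maps run id to group.
* **sample metadata** — ``sample_id``, ``group`` (TD/ASD) and an optional
  ``subgroup_index`` used as the pairing key for pooled subgroups.
* **annotation flags** — per-protein 0/1 glycosylation annotation flags
  (``known_N``, ``known_O``, ``predicted_N``, ``predicted_O``).
* **FASTA** — protein sequences over the 20 standard residues plus ``X``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """A file does not have the expected structure (missing columns, empty)."""


class ValidationError(ValueError):
    """A file parses but violates a content invariant (negative counts, ...)."""


class DegenerateBlockError(ValueError):
    """A microarray block has no usable signal to normalize against."""


class InsufficientReplicatesError(ValueError):
    """Fewer replicates/pairs than the statistical test requires."""


#: Probe names treated as negative controls and excluded from normalization
#: denominators and downstream statistics.
DEFAULT_CONTROL_PROBES = frozenset({"BSA", "buffer"})

SPOT_COLUMNS = ("sample_id", "block_id", "probe", "replicate", "foreground", "background")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")


# ---------------------------------------------------------------------------
# spot tables
# ---------------------------------------------------------------------------

def read_spot_table(path: str | Path,
                    control_probes: frozenset[str] = DEFAULT_CONTROL_PROBES) -> pd.DataFrame:
    """Read a spot table; returns rows sorted/grouped by sample.

    The returned frame carries an extra boolean ``is_control`` column marking
    negative-control probes. Raises :class:`FormatError` if a required column
    is missing and :class:`ValidationError` on negative or non-finite
    intensities (the message cites the 1-based data row).
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "block_id": str, "probe": str})
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty spot table")
    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    for col in ("foreground", "background"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[~np.isfinite(vals)]
        if len(bad):
            raise ValidationError(f"{path}: non-numeric {col} at row {bad[0] + 1}")
        neg = vals.index[vals < 0]
        if len(neg):
            raise ValidationError(f"{path}: negative {col} at row {neg[0] + 1}")
        df[col] = vals.astype(float)
    rep = pd.to_numeric(df["replicate"], errors="coerce")
    if (~np.isfinite(rep)).any() or (rep < 1).any() or (rep % 1 != 0).any():
        raise ValidationError(f"{path}: replicate must be a positive integer")
    df["replicate"] = rep.astype(int)
    dup = df.duplicated(subset=["sample_id", "block_id", "probe", "replicate"])
    if dup.any():
        row = int(df.index[dup][0]) + 1
        raise ValidationError(f"{path}: duplicate (block, probe, replicate) within a sample at row {row}")
    df["is_control"] = df["probe"].isin(control_probes)
    return df.sort_values("sample_id", kind="stable").reset_index(drop=True)


def write_spot_table(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, list(SPOT_COLUMNS)].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata (sample_id, group, optional subgroup_index)."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty metadata table")
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column(s) {col}")
    if df["sample_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate sample_id")
    if "subgroup_index" in df.columns:
        sub = df.dropna(subset=["subgroup_index"])
        if sub.duplicated(subset=["group", "subgroup_index"]).any():
            raise ValidationError(f"{path}: subgroup_index repeated within a group")
        df["subgroup_index"] = df["subgroup_index"].astype("Int64")
    return df


def write_sample_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Spectral counts per (protein, run) plus run group labels.

    ``counts`` is a proteins × runs integer frame; ``groups`` maps run id to
    its group label (e.g. TD/ASD).
    """

    counts: pd.DataFrame
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValidationError(f"duplicate protein id {dup!r}")
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValidationError("negative spectral count")
        if not np.issubdtype(arr.dtype, np.integer):
            frac = arr % 1
            if (frac != 0).any():
                i, j = np.argwhere(frac != 0)[0]
                raise ValidationError(
                    f"non-integer count {arr[i, j]} for protein "
                    f"{self.counts.index[i]!r}, run {self.counts.columns[j]!r}")
            self.counts = self.counts.astype(int)
        for run, total in self.counts.sum(axis=0).items():
            if total == 0:
                raise ValidationError(f"run {run!r} has no nonzero count")

    @property
    def proteins(self) -> list[str]:
        return list(self.counts.index)

    @property
    def runs(self) -> list[str]:
        return list(self.counts.columns)


def read_count_matrix(path: str | Path, metadata_path: str | Path | None = None) -> CountMatrix:
    """Read a protein × run spectral-count matrix (+ optional run metadata)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty count matrix")
    if df.shape[1] == 0:
        raise FormatError(f"{path}: count matrix has no run columns")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = df.index[vals.isna()][0]
            raise ValidationError(f"{path}: non-numeric count for protein {row!r}, run {col!r}")
        df[col] = vals
    df.index = df.index.astype(str)
    df.index.name = None
    groups = read_run_metadata(metadata_path) if metadata_path is not None else {}
    return CountMatrix(df, groups)


def write_count_matrix(cm: CountMatrix, path: str | Path,
                       metadata_path: str | Path | None = None) -> None:
    cm.counts.rename_axis("protein_id").to_csv(path, sep="\t")
    if metadata_path is not None:
        pd.DataFrame({"run_id": list(cm.groups), "group": list(cm.groups.values())}
                     ).to_csv(metadata_path, sep="\t", index=False)


def read_run_metadata(path: str | Path) -> dict[str, str]:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty run metadata")
    for col in ("run_id", "group"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column(s) {col}")
    if df["run_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate run_id")
    return dict(zip(df["run_id"], df["group"]))


# ---------------------------------------------------------------------------
# FASTA and annotation flags
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein FASTA into an id → uppercased-sequence mapping.

    Only the 20 standard residue letters plus ``X`` are accepted.
    """
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ValidationError(f"{path}: duplicate sequence id {rec.id!r}")
        seq = str(rec.seq).upper()
        illegal = set(seq) - VALID_RESIDUES
        if illegal:
            raise ValidationError(
                f"{path}: illegal residue letter {sorted(illegal)[0]!r} in {rec.id!r}")
        sequences[rec.id] = seq
    return sequences


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=i, description="") for i, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


FLAG_COLUMNS = ("known_N", "known_O", "predicted_N", "predicted_O")


def read_annotation_flags(path: str | Path) -> pd.DataFrame:
    """Read per-protein glycosylation flags; absent columns default to False."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty annotation table")
    if "protein_id" not in df.columns:
        raise FormatError(f"{path}: missing column(s) protein_id")
    if df["protein_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate protein_id")
    for col in FLAG_COLUMNS:
        if col in df.columns:
            df[col] = df[col].fillna(0).astype(int).astype(bool)
        else:
            df[col] = False
    return df.set_index("protein_id")[list(FLAG_COLUMNS)]


def write_annotation_flags(df: pd.DataFrame, path: str | Path) -> None:
    df.astype(int).rename_axis("protein_id").to_csv(path, sep="\t")
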