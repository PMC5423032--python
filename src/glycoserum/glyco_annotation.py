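"""Glycosylation-category assignment for identified proteins.

Proteins are partitioned using database annotation flags plus a built-in
N-sequon scanner:

* ``N_Y`` / ``O_Y`` — database-known N-/O-glycoproteins (flag ``known_N`` /
  ``known_O``); percentages are reported over the database-known proteins.
* ``N_P`` / ``O_P`` — proteins without known glyco annotation that carry a
  predicted site: an N-sequon found by the scanner (or a supplied
  ``predicted_N`` flag), or a supplied ``predicted_O`` flag; percentages are
  reported over this novel subset.
* ``nonglyco`` — no known or predicted glycosylation evidence.
* ``unknown_protein`` — neither annotation record nor sequence available.

O-glycosite prediction is not reimplemented (there is no comparably simple
sequence rule); ``predicted_O`` must be supplied as an input flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

CATEGORY_ORDER = ("N_Y", "O_Y", "N_P", "O_P", "nonglyco", "unknown_protein")


def scan_n_sequons(sequence: str) -> list[int]:
    """1-based positions of N-glycosylation sequons N-X-S/T (X ≠ P).

    Overlapping sequons are all reported. Positions closer than 3 residues to
    the C-terminus cannot complete the motif and never match.
    """
    seq = sequence.upper()
    hits = []
    for i in range(len(seq) - 2):
        if seq[i] == "N" and seq[i + 1] != "P" and seq[i + 2] in "ST":
            hits.append(i + 1)
    return hits


@dataclass
class CategoryTally:
    label: str
    count: int
    denominator_name: str
    denominator: int

    @property
    def pct(self) -> float:
        return round(100.0 * self.count / self.denominator, 1) if self.denominator else 0.0

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        d["pct"] = self.pct
        return d


def categorize(flags: pd.DataFrame | None,
               sequences: Mapping[str, str] | None = None,
               proteins: list[str] | None = None
               ) -> tuple[pd.DataFrame, list[CategoryTally]]:
    """Assign glyco categories per protein and tally them.

    ``flags`` is the annotation table (index protein_id, boolean columns
    known_N/known_O/predicted_N/predicted_O); a protein with a row there is
    treated as database-known (even if all flags are false, i.e. "unproven").
    Proteins appearing only in ``sequences`` are novel and classified by the
    sequon scanner plus any predicted flags. ``proteins`` optionally fixes
    the protein universe; otherwise it is the union of both inputs.

    Returns the per-protein table (all applicable labels plus a primary
    ``category`` by precedence known > predicted > nonglyco) and tallies with
    explicit denominators: known categories over database-known proteins,
    predicted categories over the novel subset.
    """
    sequences = sequences or {}
    flag_index = set(flags.index) if flags is not None else set()
    if proteins is None:
        proteins = sorted(flag_index | set(sequences))
    rows = []
    for pid in proteins:
        in_db = pid in flag_index
        f = flags.loc[pid] if in_db else None
        seq = sequences.get(pid)
        known_n = bool(f["known_N"]) if in_db else False
        known_o = bool(f["known_O"]) if in_db else False
        sequons = scan_n_sequons(seq) if seq is not None else []
        predicted_n = bool(sequons) or (bool(f["predicted_N"]) if in_db else False)
        predicted_o = bool(f["predicted_O"]) if in_db else False
        labels = []
        if known_n:
            labels.append("N_Y")
        if known_o:
            labels.append("O_Y")
        if predicted_n:
            labels.append("N_P")
        if predicted_o:
            labels.append("O_P")
        if not labels:
            labels.append("nonglyco" if (in_db or seq is not None) else "unknown_protein")
        rows.append({"protein_id": pid, "in_database": in_db,
                     "known_N": known_n, "known_O": known_o,
                     "predicted_N": predicted_n, "predicted_O": predicted_o,
                     "sequon_positions": sequons,
                     "labels": labels, "category": labels[0]})
    table = pd.DataFrame(rows).set_index("protein_id")

    known = table.index[table["in_database"]]
    novel = table.index[~table["in_database"] | ~(table["known_N"] | table["known_O"])]
    novel = novel.difference(table.index[table["category"] == "unknown_protein"])
    tallies = [
        CategoryTally("N_Y", int(table.loc[known, "known_N"].sum()), "known_proteins", len(known)),
        CategoryTally("O_Y", int(table.loc[known, "known_O"].sum()), "known_proteins", len(known)),
        CategoryTally("N_P", int(table.loc[novel, "predicted_N"].sum()), "novel_proteins", len(novel)),
        CategoryTally("O_P", int(table.loc[novel, "predicted_O"].sum()), "novel_proteins", len(novel)),
        CategoryTally("nonglyco", int((table["category"] == "nonglyco").sum()),
                      "all_proteins", len(table)),
        CategoryTally("unknown_protein", int((table["category"] == "unknown_protein").sum()),
                      "all_proteins", len(table)),
    ]
    return table, tallies
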