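"""Motif extraction at anchor-numbered sites and per-clade frequency tables.

Functionally important residues are read out at bovine-rhodopsin-anchored
positions -- the retinal-binding K296, the E/DRY triad at 134-136, the
NPxxY motif at 302-306, a configurable extracellular-loop tripeptide and
the counterion positions (113 and 181 by default) -- through one shared
pairwise alignment per sequence.  Deleted columns yield "-"; extractions
containing gaps are excluded from allele counts but reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._seq import anchor_record
from .screening import map_anchor_positions


@dataclass
class MotifDefinition:
    name: str
    positions: tuple               # 1-based anchor coordinates, strictly increasing
    expected_alleles: tuple = ()

    def __post_init__(self):
        self.positions = tuple(self.positions)
        if list(self.positions) != sorted(set(self.positions)):
            raise ValueError("motif positions must be strictly increasing")


def default_motifs(ec_positions=(280, 281, 282),
                   counterion_positions=(113, 181)) -> list:
    return [
        MotifDefinition("K296", (296,), ("K",)),
        MotifDefinition("E/DRY", (134, 135, 136), ("DRY", "DRF", "DRC")),
        MotifDefinition("NPxxY", (302, 303, 304, 305, 306)),
        MotifDefinition("EC_tripeptide", tuple(ec_positions), ("NKQ", "HPK", "NSR", "NST")),
        MotifDefinition("counterions", tuple(counterion_positions)),
    ]


def extract_motifs(protein: str, motifs: list, anchor: str | None = None) -> dict:
    """Extract every motif through one shared query-anchor alignment."""
    if anchor is None:
        anchor = anchor_record()[1]
    all_positions = sorted({p for m in motifs for p in m.positions})
    try:
        mapped = map_anchor_positions(protein, anchor, all_positions)
    except ValueError:
        mapped = [None] * len(all_positions)
    lookup = dict(zip(all_positions, mapped))
    out = {}
    for m in motifs:
        residues = []
        for p in m.positions:
            q = lookup.get(p)
            residues.append(protein[q - 1] if q else "-")
        out[m.name] = "".join(residues)
    return out


def extract_motif(protein: str, motif: MotifDefinition, anchor: str | None = None) -> str:
    return extract_motifs(protein, [motif], anchor)[motif.name]


def extract_motifs_from_row(row: str, anchor_map, motifs: list) -> dict:
    """Extract motifs from a master-alignment row via the panel's anchor map.

    For queries already merged into the reference panel's column system
    this shares one alignment across all positions and all sequences, and
    is exact wherever the master columns are; positions outside the map or
    gapped in the row yield "-".
    """
    col_of = {p: i for i, p in enumerate(anchor_map) if p is not None}
    out = {}
    for m in motifs:
        residues = []
        for p in m.positions:
            i = col_of.get(p)
            residues.append(row[i] if i is not None and i < len(row)
                            and row[i] != "-" else "-")
        out[m.name] = "".join(residues)
    return out


@dataclass
class MotifTable:
    per_sequence: pd.DataFrame      # seq_id, clade, motif, allele
    allele_counts: pd.DataFrame     # clade, motif, allele, count, fraction
    position_abundance: pd.DataFrame  # clade, motif, offset, residue, count, rank
    excluded: pd.DataFrame          # gap-containing extractions


def motif_frequency_table(clades: dict, extractions: dict) -> MotifTable:
    """Per-clade allele counts/fractions and ranked residue abundances.

    ``clades``: seq_id -> clade label; ``extractions``: seq_id ->
    {motif name -> residue string}.  Gap-containing extractions are
    excluded from allele counts (and fractions) but listed in ``excluded``.
    """
    seq_rows, excl_rows = [], []
    for sid in sorted(extractions):
        clade = clades.get(sid, "unclassified")
        for motif, allele in sorted(extractions[sid].items()):
            row = {"seq_id": sid, "clade": clade, "motif": motif, "allele": allele}
            if "-" in allele:
                excl_rows.append(row)
            else:
                seq_rows.append(row)
    per_seq = pd.DataFrame(seq_rows, columns=["seq_id", "clade", "motif", "allele"])
    excluded = pd.DataFrame(excl_rows, columns=["seq_id", "clade", "motif", "allele"])

    if len(per_seq):
        counts = (per_seq.groupby(["clade", "motif", "allele"]).size()
                  .rename("count").reset_index())
        totals = counts.groupby(["clade", "motif"])["count"].transform("sum")
        counts["fraction"] = counts["count"] / totals
    else:
        counts = pd.DataFrame(columns=["clade", "motif", "allele", "count", "fraction"])

    pos_rows = []
    for (clade, motif), grp in per_seq.groupby(["clade", "motif"]) if len(per_seq) else []:
        width = len(grp["allele"].iloc[0])
        for off in range(width):
            residues = grp["allele"].str[off]
            vc = residues.value_counts()
            for rank, (res, cnt) in enumerate(
                    sorted(vc.items(), key=lambda kv: (-kv[1], kv[0])), start=1):
                pos_rows.append({"clade": clade, "motif": motif, "offset": off,
                                 "residue": res, "count": int(cnt), "rank": rank})
    position_abundance = pd.DataFrame(
        pos_rows, columns=["clade", "motif", "offset", "residue", "count", "rank"])
    return MotifTable(per_seq, counts, position_abundance, excluded)
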