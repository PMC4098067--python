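"""Genome-size-ordered positional profiles and motif windows.

The anchor profile is a species-by-position matrix of residue classes
({R, K, S/T, other, absent}) at positions specified either from the
N-terminus (R3 is N-anchored) or as fold-anchored offsets (R11-, R17-
and R20-equivalents at offsets 12, 6, 3; the yeast S10/S15-equivalent
serines at offsets 14 and 9). Rows are ordered by ascending genome
size. Motif windows summarize the residues flanking a focal anchor as
per-column relative frequencies, the input to sequence-logo rendering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from histevo.domains import (
    DomainPartition,
    residue_at_n_position,
    residue_at_offset,
)
from histevo.sequence_io import AMINO_ACIDS, SpeciesRecord


@dataclass(frozen=True)
class Anchor:
    """A named NTD position in one of the two coordinate systems."""

    label: str
    system: str  # "n" (from N-terminus) or "fold" (offset before fold)
    position: int

    def __post_init__(self) -> None:
        if self.system not in ("n", "fold"):
            raise ValueError(f"unknown coordinate system {self.system!r}")
        if self.position < 1:
            raise ValueError("anchor positions/offsets are >= 1")


# Default anchors for the H2A NTD: human numbering for the arginines,
# yeast numbering for the serines, all but R3 expressed fold-anchored.
DEFAULT_ANCHORS = (
    Anchor("R3", "n", 3),
    Anchor("S10eq", "fold", 14),
    Anchor("R11eq", "fold", 12),
    Anchor("S15eq", "fold", 9),
    Anchor("R17eq", "fold", 6),
    Anchor("R20eq", "fold", 3),
)

RESIDUE_CLASSES = ("R", "K", "S/T", "other", "absent")


def classify_residue(residue: str | None) -> str:
    if residue is None:
        return "absent"
    if residue == "R":
        return "R"
    if residue == "K":
        return "K"
    if residue in ("S", "T"):
        return "S/T"
    return "other"


def _lookup(partition: DomainPartition, anchor: Anchor) -> str | None:
    if anchor.system == "n":
        return residue_at_n_position(partition, anchor.position)
    return residue_at_offset(partition, anchor.position)


def build_anchor_matrix(partitions: Mapping[str, DomainPartition],
                        species: Sequence[SpeciesRecord],
                        anchors: Iterable[Anchor] = DEFAULT_ANCHORS,
                        ) -> pd.DataFrame:
    """Species-by-anchor residue-class matrix ordered by genome size.

    ``partitions`` maps species_id to that species' H2A partition. Rows
    follow ascending genome size (ties broken by species_id) regardless
    of input order; a ``genome_size_mbp`` column is included for
    reference.
    """
    anchors = tuple(anchors)
    meta = {s.species_id: s for s in species}
    missing = set(partitions) - set(meta)
    if missing:
        raise ValueError(f"species missing from metadata: {sorted(missing)[:5]}")
    ordered = sorted(
        (s for s in species if s.species_id in partitions),
        key=lambda s: (s.genome_size_mbp, s.species_id),
    )
    rows = []
    for sp in ordered:
        part = partitions[sp.species_id]
        row = {"species_id": sp.species_id,
               "genome_size_mbp": sp.genome_size_mbp,
               "size_class": sp.size_class}
        for anchor in anchors:
            row[anchor.label] = classify_residue(_lookup(part, anchor))
        rows.append(row)
    return pd.DataFrame(rows).set_index("species_id")


@dataclass
class MotifMatrix:
    """Per-column amino-acid frequencies around a focal anchor."""

    anchor: Anchor
    k: int
    stratum: str
    frequencies: pd.DataFrame  # index: 20 amino acids; columns: -k..k
    n_sequences: int
    column_n: dict[int, int]


def motif_window(partitions: Mapping[str, DomainPartition],
                 anchor: Anchor, k: int = 1,
                 species: Sequence[SpeciesRecord] | None = None,
                 stratum: str = "all") -> MotifMatrix:
    """Frequency matrix of the residues at relative positions -k..+k.

    Negative relative positions are N-terminal of the focal anchor. A
    sequence contributes only if the focal position itself resolves;
    flanking positions that run off the tail are skipped per column, so
    every column with contributors sums to 1.
    """
    if k < 1:
        raise ValueError("window half-width k must be >= 1")
    keep = set(partitions)
    if stratum != "all":
        if species is None:
            raise ValueError("species metadata required to stratify")
        keep = {s.species_id for s in species if s.size_class == stratum} & keep
    offsets = list(range(-k, k + 1))
    counts = {d: {} for d in offsets}
    column_n = {d: 0 for d in offsets}
    n_sequences = 0
    for sid in sorted(keep):
        part = partitions[sid]
        focal = _lookup(part, anchor)
        if focal is None:
            continue
        n_sequences += 1
        if anchor.system == "n":
            focal_pos = anchor.position
        else:
            focal_pos = part.fold_start - anchor.position
        for d in offsets:
            pos = focal_pos + d
            if pos < 1 or pos > len(part.ntd):
                continue
            res = part.ntd[pos - 1]
            if res == "X":
                continue
            counts[d][res] = counts[d].get(res, 0) + 1
            column_n[d] += 1
    freq = pd.DataFrame(0.0, index=list(AMINO_ACIDS), columns=offsets)
    for d in offsets:
        if column_n[d]:
            for res, c in counts[d].items():
                freq.loc[res, d] = c / column_n[d]
    return MotifMatrix(anchor=anchor, k=k, stratum=stratum, frequencies=freq,
                       n_sequences=n_sequences, column_n=column_n)


def consensus_motif(matrix: MotifMatrix, plurality_threshold: float = 0.5,
                    pool_st: bool = True) -> str:
    """Render a motif matrix as a consensus string.

    Per column: the most frequent residue if it reaches the plurality
    threshold, else ``x``; columns with no contributors render as ``-``.
    With ``pool_st``, serine and threonine frequencies are pooled and a
    pooled winner renders as ``(S/T)``.
    """
    parts = []
    for d in matrix.frequencies.columns:
        if matrix.column_n.get(d, 0) == 0:
            parts.append("-")
            continue
        col = matrix.frequencies[d]
        candidates = {aa: col[aa] for aa in col.index}
        if pool_st:
            st = candidates.pop("S") + candidates.pop("T")
            candidates["(S/T)"] = st
        winner = max(sorted(candidates), key=lambda aa: candidates[aa])
        parts.append(winner if candidates[winner] >= plurality_threshold else "x")
    return "".join(parts)
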