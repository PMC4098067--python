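"""NTD / fold / CTD partitioning and the fold-anchored coordinate system.

All coordinates are 1-based and inclusive. The fold-anchored offset of
an NTD position is the number of residues between it and the first fold
residue: ``offset = fold_start - n_position``, so the residue
immediately N-terminal to the fold has offset 1 and the first fold
residue has offset 0. In the human H2A reference (fold_start 23) the
four NTD arginines at N-positions 3, 11, 17 and 20 sit at offsets 20,
12, 6 and 3.
"""

from __future__ import annotations

from dataclasses import dataclass

from histevo.sequence_io import HistoneSequence


@dataclass
class DomainPartition:
    """A histone split into tail / fold / tail substrings."""

    seq_id: str
    species_id: str
    ntd: str
    fold: str
    ctd: str
    fold_start: int
    fold_end: int

    @property
    def full(self) -> str:
        return self.ntd + self.fold + self.ctd


def partition_domains(seq: HistoneSequence | str,
                      fold_span: tuple[int, int],
                      species_id: str = "",
                      seq_id: str = "") -> DomainPartition:
    """Split a sequence at a 1-based inclusive fold span.

    The concatenation ntd + fold + ctd always reconstructs the input;
    empty NTD or CTD are permitted.
    """
    if isinstance(seq, HistoneSequence):
        residues, seq_id = seq.residues, seq.seq_id
        species_id = species_id or seq.species_id
    else:
        residues = str(seq)
    start, end = fold_span
    if not (1 <= start <= end <= len(residues)):
        raise ValueError(
            f"fold span ({start}, {end}) outside sequence of length "
            f"{len(residues)} ({seq_id!r})"
        )
    return DomainPartition(
        seq_id=seq_id,
        species_id=species_id,
        ntd=residues[: start - 1],
        fold=residues[start - 1 : end],
        ctd=residues[end:],
        fold_start=start,
        fold_end=end,
    )


def fold_anchored_offset(n_position: int, fold_start: int) -> int:
    """Residues between an N-terminal position and the first fold residue."""
    if n_position < 1:
        raise ValueError(f"n_position is 1-based, got {n_position}")
    if n_position > fold_start:
        raise ValueError(
            f"position {n_position} lies C-terminal of fold start {fold_start}"
        )
    return fold_start - n_position


def residue_at_offset(partition: DomainPartition, fold_offset: int) -> str | None:
    """NTD residue at a fold-anchored offset, or None if the tail is shorter."""
    if fold_offset < 1:
        raise ValueError(f"fold_offset must be >= 1 (NTD), got {fold_offset}")
    n_position = partition.fold_start - fold_offset
    if n_position < 1:
        return None
    return partition.ntd[n_position - 1]


def residue_at_n_position(partition: DomainPartition, n_position: int) -> str | None:
    """NTD residue at a 1-based position from the N-terminus, or None."""
    if n_position < 1:
        raise ValueError(f"n_position is 1-based, got {n_position}")
    if n_position > len(partition.ntd):
        return None
    return partition.ntd[n_position - 1]
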