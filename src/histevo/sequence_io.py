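"""Sequence and metadata IO, packaged references, genome-size classes.

FASTA headers follow the ``seq_id|FAMILY|species_id`` dialect; fields
beyond the first are optional. Species metadata is a tab-separated table
with columns ``species_id``, ``kingdom``, ``genome_size_mbp``. Genome
sizes are classified as small (< 100 Mbp), medium (100-1000 Mbp,
boundaries inclusive) or large (> 1000 Mbp).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("histevo")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUOUS = set("BZXUJO*")
FAMILIES = ("H2A", "H2B", "H3", "H4")
KINGDOMS = ("protozoa", "fungi", "plants", "animals", "other")
SIZE_CLASSES = ("small", "medium", "large")


class FastaParseError(ValueError):
    """Raised for a malformed FASTA record; names the offending entry."""


@dataclass
class SpeciesRecord:
    """One species with its genome size (Mbp) and derived size class."""

    species_id: str
    kingdom: str
    genome_size_mbp: float
    size_class: str = field(init=False)

    def __post_init__(self) -> None:
        if self.genome_size_mbp <= 0:
            raise ValueError(
                f"genome_size_mbp must be positive, got {self.genome_size_mbp}"
                f" for {self.species_id!r}"
            )
        if self.kingdom not in KINGDOMS:
            self.kingdom = "other"
        self.size_class = assign_size_class(self.genome_size_mbp)


@dataclass
class HistoneSequence:
    """A candidate histone protein tied to a species and family.

    ``flags`` accumulates provenance decisions made by the classifier:
    ``duplicate``, ``variant``, ``canonical``.
    """

    seq_id: str
    species_id: str
    family: str
    residues: str
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"empty residue string for {self.seq_id!r}")
        bad = set(self.residues) - set(AMINO_ACIDS) - {"X"}
        if bad:
            raise ValueError(
                f"{self.seq_id!r}: residues outside the amino-acid alphabet: "
                f"{sorted(bad)}"
            )
        if self.family not in FAMILIES:
            self.family = "unknown"

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class FamilyReference:
    """Canonical human/yeast sequences and fold spans for one family."""

    family: str
    human: str
    human_fold_span: tuple[int, int]
    yeast: str
    yeast_fold_span: tuple[int, int]
    variants: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for seq, (start, end) in (
            (self.human, self.human_fold_span),
            (self.yeast, self.yeast_fold_span),
        ):
            if not (1 <= start <= end <= len(seq)):
                raise ValueError(
                    f"fold span ({start}, {end}) outside reference of length "
                    f"{len(seq)} for family {self.family}"
                )

    @property
    def human_fold(self) -> str:
        start, end = self.human_fold_span
        return self.human[start - 1 : end]

    @property
    def yeast_fold(self) -> str:
        start, end = self.yeast_fold_span
        return self.yeast[start - 1 : end]


@dataclass
class ReferenceSet:
    """Packaged canonical references, one :class:`FamilyReference` per family."""

    families: dict[str, FamilyReference]

    def __getitem__(self, family: str) -> FamilyReference:
        return self.families[family]

    def __contains__(self, family: str) -> bool:
        return family in self.families


def assign_size_class(genome_size_mbp: float, small_max: float = 100.0,
                      large_min: float = 1000.0) -> str:
    """Map a genome size in Mbp onto {small, medium, large}.

    medium is the closed interval [small_max, large_min]; small and large
    are the open tails. Non-positive sizes are rejected.
    """
    g = float(genome_size_mbp)
    if g <= 0:
        raise ValueError(f"genome size must be positive, got {g}")
    if g < small_max:
        return "small"
    if g <= large_min:
        return "medium"
    return "large"


def _parse_header(header: str) -> tuple[str, str, str]:
    fields = header.split("|")
    seq_id = fields[0].strip()
    family = fields[1].strip().upper() if len(fields) > 1 and fields[1].strip() else "unknown"
    species_id = fields[2].strip() if len(fields) > 2 else ""
    return seq_id, family, species_id


def strip_initiator_met(residues: str) -> str:
    """Drop a leading initiator methionine (mature-form convention)."""
    return residues[1:] if residues.startswith("M") and len(residues) > 1 else residues


def read_fasta(path: str | Path, *, ambiguous: str = "reject",
               keep_met: bool = False) -> list[HistoneSequence]:
    """Read candidate histones from a protein FASTA file.

    Headers are parsed as ``seq_id|FAMILY|species_id``. Records containing
    ambiguous residues (B, Z, X, U, J, O) are rejected with a logged
    warning by default, or masked to ``X`` with ``ambiguous="mask"``
    (masked positions are never counted as specific residues downstream).
    Unless ``keep_met`` is set, a leading initiator methionine is stripped
    so coordinates refer to the mature protein.
    """
    path = Path(path)
    if ambiguous not in ("reject", "mask"):
        raise ValueError(f"unknown ambiguity policy {ambiguous!r}")
    records: list[HistoneSequence] = []
    try:
        entries = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        raise FastaParseError(f"{path}: {exc}") from exc
    if not entries:
        # distinguish empty file from a file with no FASTA headers
        text = path.read_text().strip()
        if text:
            raise FastaParseError(f"{path}: no FASTA records found in non-empty file")
        logger.warning("%s: empty FASTA file", path)
        return []
    for entry in entries:
        seq_id, family, species_id = _parse_header(entry.description)
        residues = str(entry.seq).upper().replace("-", "").replace(".", "")
        if not residues:
            raise FastaParseError(f"{path}: record {seq_id!r} has no residues")
        if not keep_met:
            residues = strip_initiator_met(residues)
        bad = {c for c in residues if c not in AMINO_ACIDS}
        if bad:
            if bad - AMBIGUOUS:
                raise FastaParseError(
                    f"{path}: record {seq_id!r} contains non-amino-acid "
                    f"characters {sorted(bad - AMBIGUOUS)}"
                )
            if ambiguous == "reject":
                logger.warning(
                    "rejecting %s: ambiguous residues %s", seq_id, sorted(bad)
                )
                continue
            residues = "".join("X" if c in AMBIGUOUS else c for c in residues)
        records.append(HistoneSequence(seq_id, species_id, family, residues))
    return records


def write_fasta(records: Iterable[HistoneSequence], path: str | Path) -> None:
    """Write sequences with ``seq_id|FAMILY|species_id`` headers."""
    out = [
        SeqRecord(Seq(r.residues), id=f"{r.seq_id}|{r.family}|{r.species_id}",
                  description="")
        for r in records
    ]
    SeqIO.write(out, str(path), "fasta")


def read_species_table(path: str | Path) -> list[SpeciesRecord]:
    """Read the tab-separated species metadata table.

    Required columns: species_id, kingdom, genome_size_mbp. Unknown
    kingdoms map to "other"; non-numeric or non-positive genome sizes
    raise a row-level error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"species_id": str, "kingdom": str})
    missing = {"species_id", "kingdom", "genome_size_mbp"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        try:
            g = float(row["genome_size_mbp"])
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"{path}: row {i} ({row['species_id']!r}): non-numeric genome size"
            ) from exc
        try:
            records.append(SpeciesRecord(str(row["species_id"]),
                                         str(row["kingdom"]).lower(), g))
        except ValueError as exc:
            raise ValueError(f"{path}: row {i}: {exc}") from exc
    return records


def write_species_table(species: Iterable[SpeciesRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "species_id": s.species_id,
                "kingdom": s.kingdom,
                "genome_size_mbp": s.genome_size_mbp,
            }
            for s in species
        ]
    ).to_csv(path, sep="\t", index=False)


def load_reference_set(path: str | Path | None = None) -> ReferenceSet:
    """Load the packaged (or a user-supplied) reference histone set."""
    if path is None:
        source = resources.files("histevo.data").joinpath("reference_histones.yaml")
        raw = yaml.safe_load(source.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    families = {}
    for family, entry in raw.items():
        families[family] = FamilyReference(
            family=family,
            human=entry["human"],
            human_fold_span=tuple(entry["human_fold_span"]),
            yeast=entry["yeast"],
            yeast_fold_span=tuple(entry["yeast_fold_span"]),
            variants=dict(entry.get("variants") or {}),
        )
    return ReferenceSet(families)
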