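"""Canonical-histone classification by fold alignment.

A candidate counts as a true hit for a family when a local alignment
against that family's histone fold exceeds 35% identity and 90% fold
coverage (both strict, thresholds configurable). Hits are deduplicated
within species, H2A/H3 variants are removed by comparison against
packaged variant references, and one canonical sequence per (species,
family) is selected by highest global similarity to the human or yeast
canonical reference.

Alignments use BLOSUM62 with gap open/extend 11/1 (Smith-Waterman for
fold-hit detection, Needleman-Wunsch for similarity ranking). Identity
for hit detection is counted over aligned (non-gap) columns; global
similarity for ranking is counted over all alignment columns, so length
outliers such as variant tails score against a record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from histevo.sequence_io import FamilyReference, HistoneSequence, ReferenceSet

logger = logging.getLogger("histevo")


@dataclass
class ClassifierConfig:
    identity_threshold: float = 0.35
    overlap_threshold: float = 0.90
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        for name in ("identity_threshold", "overlap_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


@dataclass
class FoldAlignmentResult:
    """Identity/overlap of a candidate against a family's fold domain."""

    candidate_id: str
    family: str
    identity: float
    overlap: float
    fold_span_on_candidate: tuple[int, int] | None
    aligned_columns: int


DEFAULT_CONFIG = ClassifierConfig()

_ALIGNER_CACHE: dict[tuple, Align.PairwiseAligner] = {}


def _aligner(mode: str, config: ClassifierConfig) -> Align.PairwiseAligner:
    key = (mode, config.matrix, config.gap_open, config.gap_extend)
    if key not in _ALIGNER_CACHE:
        aligner = Align.PairwiseAligner()
        aligner.mode = mode
        aligner.substitution_matrix = substitution_matrices.load(config.matrix)
        aligner.open_gap_score = -config.gap_open
        aligner.extend_gap_score = -config.gap_extend
        _ALIGNER_CACHE[key] = aligner
    return _ALIGNER_CACHE[key]


def align_to_fold(candidate: HistoneSequence | str, reference_fold: str,
                  config: ClassifierConfig = DEFAULT_CONFIG,
                  family: str = "unknown") -> FoldAlignmentResult:
    """Locally align a candidate against a reference fold domain.

    identity = identical aligned residue pairs / aligned (non-gap)
    columns; overlap = fraction of reference-fold positions covered by
    the alignment; fold_span_on_candidate = first-to-last candidate
    position (1-based, inclusive) aligned to the fold.
    """
    if isinstance(candidate, HistoneSequence):
        seq, cid, family = candidate.residues, candidate.seq_id, candidate.family
    else:
        seq, cid = str(candidate), "<anonymous>"
    if not reference_fold:
        raise ValueError("empty reference fold")
    if not seq:
        raise ValueError("empty candidate sequence")
    aligner = _aligner("local", config)
    alignments = aligner.align(reference_fold.replace("X", "A"),
                               seq.replace("X", "A"))
    try:
        best = alignments[0]
    except IndexError:
        return FoldAlignmentResult(cid, family, 0.0, 0.0, None, 0)
    ref_blocks, cand_blocks = best.aligned
    if len(ref_blocks) == 0:
        return FoldAlignmentResult(cid, family, 0.0, 0.0, None, 0)
    matches = 0
    aligned_cols = 0
    covered = 0
    for (rs, re), (cs, ce) in zip(ref_blocks, cand_blocks):
        aligned_cols += re - rs
        covered += re - rs
        matches += sum(
            1 for a, b in zip(reference_fold[rs:re], seq[cs:ce]) if a == b
        )
    span = (int(cand_blocks[0][0]) + 1, int(cand_blocks[-1][1]))
    identity = matches / aligned_cols if aligned_cols else 0.0
    overlap = covered / len(reference_fold)
    return FoldAlignmentResult(cid, family, identity, overlap, span, aligned_cols)


def is_canonical_hit(result: FoldAlignmentResult,
                     config: ClassifierConfig = DEFAULT_CONFIG) -> bool:
    """Strict thresholds: identity > 35% AND fold overlap > 90%."""
    return (result.identity > config.identity_threshold
            and result.overlap > config.overlap_threshold)


def global_similarity(a: str, b: str,
                      config: ClassifierConfig = DEFAULT_CONFIG) -> float:
    """Global percent identity over all alignment columns (gaps count)."""
    aligner = _aligner("global", config)
    best = aligner.align(a.replace("X", "G"), b.replace("X", "G"))[0]
    a_blocks, b_blocks = best.aligned
    matches = sum(
        sum(1 for x, y in zip(a[rs:re], b[cs:ce]) if x == y)
        for (rs, re), (cs, ce) in zip(a_blocks, b_blocks)
    )
    return matches / best.length if best.length else 0.0


def deduplicate(records: list[HistoneSequence]) -> list[HistoneSequence]:
    """Keep the first of identical sequences within a (species, family).

    Later identical records are flagged ``duplicate`` in place and
    dropped from the returned list; identical sequences in *different*
    species are all retained (each species contributes its own copy).
    """
    seen: set[tuple[str, str, str]] = set()
    retained = []
    for rec in records:
        key = (rec.species_id, rec.family, rec.residues)
        if key in seen:
            rec.flags.add("duplicate")
        else:
            seen.add(key)
            retained.append(rec)
    return retained


def filter_variants(records: list[HistoneSequence], reference_set: ReferenceSet,
                    config: ClassifierConfig = DEFAULT_CONFIG,
                    ) -> list[HistoneSequence]:
    """Flag H2A/H3 records closer to a variant reference than to canonical.

    Each record is scored by global similarity against the canonical
    human and yeast references (the better of the two) and against each
    packaged variant reference; records *strictly* closer to a variant
    are flagged ``variant`` and dropped from the returned list. Ties
    favor canonical. Families without variant references pass through.
    """
    retained = []
    for rec in records:
        if rec.family not in reference_set:
            retained.append(rec)
            continue
        ref = reference_set[rec.family]
        if not ref.variants:
            if rec.family in ("H2A", "H3"):
                logger.warning("no variant references for %s; pass-through",
                               rec.family)
            retained.append(rec)
            continue
        can_sim = max(global_similarity(rec.residues, ref.human, config),
                      global_similarity(rec.residues, ref.yeast, config))
        var_sim = max(global_similarity(rec.residues, v, config)
                      for v in ref.variants.values())
        if var_sim > can_sim:
            rec.flags.add("variant")
        else:
            retained.append(rec)
    return retained


def select_canonical_per_species(records: list[HistoneSequence],
                                 reference_set: ReferenceSet,
                                 config: ClassifierConfig = DEFAULT_CONFIG,
                                 ) -> dict[tuple[str, str], HistoneSequence]:
    """Pick the single canonical sequence per (species, family).

    Among unflagged hits, the record with the highest global similarity
    to either the human or the yeast canonical reference wins; exact
    score ties break toward the longer sequence, then the
    lexicographically smaller seq_id. The winner is flagged
    ``canonical``.
    """
    groups: dict[tuple[str, str], list[HistoneSequence]] = {}
    for rec in records:
        if rec.flags & {"duplicate", "variant"}:
            continue
        groups.setdefault((rec.species_id, rec.family), []).append(rec)
    selected = {}
    for key, members in groups.items():
        family = key[1]
        if family not in reference_set:
            continue
        ref = reference_set[family]
        scored = []
        for rec in members:
            sim = max(global_similarity(rec.residues, ref.human, config),
                      global_similarity(rec.residues, ref.yeast, config))
            scored.append((sim, len(rec.residues), rec))
        scored.sort(key=lambda t: (-t[0], -t[1], t[2].seq_id))
        winner = scored[0][2]
        winner.flags.add("canonical")
        selected[key] = winner
    return selected


def classify_records(records: list[HistoneSequence], reference_set: ReferenceSet,
                     config: ClassifierConfig = DEFAULT_CONFIG,
                     families: tuple[str, ...] = ("H2A",),
                     ) -> tuple[list[dict], dict[tuple[str, str], HistoneSequence]]:
    """Full classification pass: align, threshold, dedup, filter, select.

    Records with family ``unknown`` are tried against every requested
    family's fold and assigned to the best-overlap one that passes.
    Returns (per-record rows, canonical selection). Each row carries
    seq_id, species_id, family, identity, overlap, fold span and flags.
    """
    rows = []
    hits: list[HistoneSequence] = []
    spans: dict[str, tuple[int, int]] = {}
    for rec in records:
        tried = [rec.family] if rec.family in reference_set.families else list(families)
        best: FoldAlignmentResult | None = None
        best_family = None
        for family in tried:
            ref = reference_set[family]
            res = align_to_fold(rec, ref.human_fold, config, family=family)
            if best is None or (res.identity * res.overlap
                                > best.identity * best.overlap):
                best, best_family = res, family
        assert best is not None
        hit = is_canonical_hit(best, config)
        rows.append({
            "seq_id": rec.seq_id,
            "species_id": rec.species_id,
            "family": best_family,
            "identity": round(best.identity, 4),
            "overlap": round(best.overlap, 4),
            "fold_start": best.fold_span_on_candidate[0]
            if best.fold_span_on_candidate else None,
            "fold_end": best.fold_span_on_candidate[1]
            if best.fold_span_on_candidate else None,
            "hit": hit,
        })
        if hit:
            if rec.family == "unknown":
                rec.family = best_family
            spans[rec.seq_id] = best.fold_span_on_candidate
            hits.append(rec)
    kept = deduplicate(hits)
    kept = filter_variants(kept, reference_set, config)
    selected = select_canonical_per_species(kept, reference_set, config)
    flag_lookup = {rec.seq_id: rec.flags for rec in records}
    for row in rows:
        row["flags"] = ",".join(sorted(flag_lookup.get(row["seq_id"], set()))) or "-"
    return rows, selected
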