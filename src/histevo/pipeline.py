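"""End-to-end run orchestration: classify -> partition -> compose ->
compare -> positions -> motifs, with a reproducible run manifest."""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from histevo import positions as pos_mod
from histevo.classify import ClassifierConfig, classify_records
from histevo.domains import partition_domains
from histevo.residue_stats import (
    composition_table,
    compare_size_classes,
)
from histevo.sequence_io import (
    load_reference_set,
    read_fasta,
    read_species_table,
    write_fasta,
)

logger = logging.getLogger("histevo")

STAGES = ("classify", "partition", "compose", "compare", "positions", "motifs")


@dataclass
class RunConfig:
    """Validated run parameters; defaults reproduce the study settings."""

    identity_threshold: float = 0.35
    overlap_threshold: float = 0.90
    small_max_mbp: float = 100.0
    large_min_mbp: float = 1000.0
    exact_limit: int = 100
    families: tuple[str, ...] = ("H2A",)
    motif_k: int = 1
    seed: int = 0
    outdir: Path = Path("histevo_out")
    comparisons: tuple[tuple[str, ...], ...] = (("R",), ("K",), ("S", "T"))

    def __post_init__(self) -> None:
        if not 0 < self.identity_threshold < 1:
            raise ValueError("identity_threshold must be in (0, 1)")
        if not 0 < self.overlap_threshold < 1:
            raise ValueError("overlap_threshold must be in (0, 1)")
        if not 0 < self.small_max_mbp < self.large_min_mbp:
            raise ValueError("size-class edges must satisfy 0 < small < large")
        self.outdir = Path(self.outdir)

    def classifier(self) -> ClassifierConfig:
        return ClassifierConfig(self.identity_threshold, self.overlap_threshold)


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, fasta_path: str | Path,
                 species_path: str | Path) -> dict:
    """Execute every stage and write tab-separated outputs + manifest.

    Sequences whose species is missing from the metadata table are
    skipped with a warning and counted in the manifest. Identical
    inputs and config produce byte-identical outputs.
    """
    fasta_path, species_path = Path(fasta_path), Path(species_path)
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    reference_set = load_reference_set()
    cconfig = config.classifier()

    records = read_fasta(fasta_path)
    species = read_species_table(species_path)
    known = {s.species_id for s in species}
    skipped = [r.seq_id for r in records if r.species_id not in known]
    for seq_id in skipped:
        logger.warning("skipping %s: species not in metadata", seq_id)
    records = [r for r in records if r.species_id in known]

    completed = []
    # classify
    rows, selected = classify_records(records, reference_set, cconfig,
                                      families=config.families)
    class_df = pd.DataFrame(rows)
    class_df.to_csv(outdir / "classified.tsv", sep="\t", index=False)
    write_fasta(sorted(selected.values(), key=lambda r: r.seq_id),
                outdir / "canonical.fasta")
    completed.append("classify")

    # partition (fold span from the classifier's alignment)
    span_lookup = {
        row["seq_id"]: (row["fold_start"], row["fold_end"])
        for row in rows if row["fold_start"] is not None
    }
    partitions = {}
    for (species_id, family), rec in selected.items():
        if family != "H2A":
            continue
        span = span_lookup.get(rec.seq_id)
        if span is None:
            continue
        partitions[species_id] = partition_domains(rec, span)
    part_df = pd.DataFrame([
        {"seq_id": p.seq_id, "species_id": sid, "ntd": p.ntd,
         "fold_start": p.fold_start, "fold_end": p.fold_end,
         "ntd_length": len(p.ntd)}
        for sid, p in sorted(partitions.items())
    ])
    part_df.to_csv(outdir / "partitions.tsv", sep="\t", index=False)
    completed.append("partition")

    # compose
    comp = composition_table(partitions.values())
    comp.to_csv(outdir / "composition.tsv", sep="\t", index=False)
    completed.append("compose")

    # compare
    comparisons = []
    for residue_set in config.comparisons:
        for ga, gb in (("small", "medium"), ("small", "large"),
                       ("medium", "large")):
            try:
                c = compare_size_classes(comp, species, residue_set,
                                         group_a=ga, group_b=gb,
                                         exact_limit=config.exact_limit)
            except ValueError as exc:
                logger.warning("comparison skipped: %s", exc)
                continue
            comparisons.append({
                "residue_set": "".join(residue_set), "group_a": ga,
                "group_b": gb, "n_a": c.n_a, "n_b": c.n_b, "U": c.U,
                "p_two_sided": c.p_two_sided, "method": c.method,
            })
    pd.DataFrame(comparisons).to_csv(outdir / "comparisons.tsv", sep="\t",
                                     index=False)
    completed.append("compare")

    # positions
    anchor_df = pos_mod.build_anchor_matrix(partitions, species)
    anchor_df.to_csv(outdir / "positions.tsv", sep="\t")
    completed.append("positions")

    # motifs (per stratum around each default arginine anchor)
    motif_rows = []
    for anchor in pos_mod.DEFAULT_ANCHORS:
        for stratum in ("small", "medium", "large"):
            m = pos_mod.motif_window(partitions, anchor, k=config.motif_k,
                                     species=species, stratum=stratum)
            consensus = pos_mod.consensus_motif(m) if m.n_sequences else ""
            motif_rows.append({
                "anchor": anchor.label, "stratum": stratum,
                "n_sequences": m.n_sequences, "consensus": consensus,
            })
    pd.DataFrame(motif_rows).to_csv(outdir / "motifs.tsv", sep="\t",
                                    index=False)
    completed.append("motifs")

    manifest = {
        "stages_completed": completed,
        "parameters": {
            "identity_threshold": config.identity_threshold,
            "overlap_threshold": config.overlap_threshold,
            "small_max_mbp": config.small_max_mbp,
            "large_min_mbp": config.large_min_mbp,
            "exact_limit": config.exact_limit,
            "families": list(config.families),
            "motif_k": config.motif_k,
        },
        "seed": config.seed,
        "inputs": {
            "fasta": {"path": str(fasta_path), "sha256": _sha256(fasta_path)},
            "species": {"path": str(species_path),
                        "sha256": _sha256(species_path)},
        },
        "n_input_records": len(records) + len(skipped),
        "n_skipped_no_species": len(skipped),
        "skipped_seq_ids": sorted(skipped),
        "n_canonical": len(selected),
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
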