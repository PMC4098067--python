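# histevo

Comparative analysis of histone H2A N-terminal tail (NTD) evolution
across eukaryotic genome sizes, built around a fold-anchored coordinate
system, plus the small statistical toolkit used for chromatin-compaction
phenotype measurements.

## The scientific problem

Core histones are among the most conserved proteins known, yet their
N-terminal tails vary across eukaryotes. When candidate H2A sequences
from many species are classified against the conserved histone fold,
partitioned into NTD / fold / C-terminal domain, and stratified by
genome size — small (< 100 Mbp), medium (100–1000 Mbp), large
(> 1000 Mbp) — a striking pattern emerges: the number of NTD arginines
rises with genome size while serines/threonines fall, and the acquired
arginines sit at *fixed distances from the histone fold* rather than at
fixed positions from the N-terminus.

The key coordinate is the **fold-anchored offset**

```
offset = fold_start − n_position
```

so the residue immediately N-terminal to the first fold residue has
offset 1. In the human H2A NTD (`SGRGKQGGKTRAKAKSRSSRAG`, 22 residues,
fold starting at position 23) the four arginines R3/R11/R17/R20 sit at
offsets 20, 12, 6 and 3; in the yeast NTD the single arginine sits at
offset 6 — the same anchor as human R17 — while yeast S10 and S15 occupy
offsets 14 and 9. This package implements:

- **sequence IO & references** — FASTA/TSV readers, packaged canonical
  human/yeast histones with fold spans, genome-size classes;
- **canonical classification** — local alignment against the family
  fold (BLOSUM62, gap 11/1) with strict > 35 % identity and > 90 % fold
  overlap thresholds, per-species deduplication, variant filtering
  against decoy references, and per-species canonical selection;
- **domain partitioning** — NTD/fold/CTD splits and both coordinate
  systems (N-anchored and fold-anchored);
- **residue statistics** — per-domain composition tables and an
  in-package two-sided Mann–Whitney U test (exact enumeration for small
  tie-free samples, tie-corrected normal approximation otherwise);
- **positional profiles** — genome-size-ordered heat-map matrices of
  residue classes {R, K, S/T, other, absent} at the six standard
  anchors, and motif frequency windows (e.g. VKG → ARA at the
  R11-equivalent offset 12);
- **compaction statistics** — intensity-weighted probe centroids,
  inter-probe distances in nm, percent change of medians, Welch-t /
  Mann–Whitney comparisons and elliptical nuclear area
  `(D1/2)·(D2/2)·π`;
- **a synthetic-evolution generator** — cohorts of independent species
  whose H2A features follow logistic acquisition curves in log10 genome
  size, with ground-truth labels and decoy contaminants, so the whole
  pipeline is testable without any network retrieval.

## Worked example

Generate a 60-species synthetic cohort (with decoy duplicates, variants
and shuffled non-histones), run the full pipeline, and compare NTD
arginine counts between small and large genomes:

```bash
$ histevo simulate --n 60 --seed 7 --outdir synthetic
60 species, 75 sequences -> synthetic/

$ histevo run --fasta synthetic/sequences.fasta --species synthetic/species.tsv --outdir out
6 stages completed -> out/manifest.yaml

$ histevo compare --partitions out/partitions.tsv --species synthetic/species.tsv \
      --residues R --groups small,large
residues=R small (n=24) vs large (n=16): U=18.0 p=6.97e-07 [normal_approx]
```

The 75 generated records contain 60 true canonical H2As plus 15 decoys;
the classifier recovers exactly the 60 (see `out/classified.tsv`). The
rank test says small-genome species have far fewer NTD arginines than
large-genome species (U = 18 of a possible 24 × 16 = 384; two-sided
p ≈ 7e-07). `out/positions.tsv` holds the genome-size-ordered anchor
matrix and `out/motifs.tsv` the per-stratum consensus motifs — with the
default model the offset-12 anchor reads `VKG` in medium and `ARA` in
large genomes.

Compaction toolkit (one measurement per line):

```bash
$ histevo compaction --wt wt.txt --mut mut.txt --test t
% change (median) = -40.0%  p = 1.68e-10  [t_test]  medians 100 -> 60
```

i.e. the mutant's median inter-probe distance is 40 % below wild type —
the sign convention used for compaction phenotypes throughout.

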