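"""Synthetic cohorts with programmed genome-size-dependent H2A evolution.

The generator emulates the comparative pattern under study: starting
from a yeast-like H2A (a 23-residue NTD with a single arginine at fold
offset 6, followed by a fixed fold/CTD), each species independently
acquires or loses NTD features with probabilities that follow a
logistic curve in log10 genome size,

    p_f(g) = 1 / (1 + exp(-s_f * (log10 g - m_f))),

with steepness s_f (per decade) and midpoint m_f (log10 Mbp). The
default features reproduce the qualitative program: gain of R3
(N-anchored insertion), gain of K then conversion K->R at fold offset
12 (with VKG -> ARA flank motifs), K->R at offset 3 (AKA -> SRA
flanks), loss of the serines at fold offsets 14 (G/S deletion) and 9
(S->A substitution), and two compensating lysine gains (offsets 8 and
19) whose curves are tied to the lysine-removing features so that the
expected NTD lysine count stays flat across genome sizes while
arginines rise and serines/threonines fall.

Indels preserve the fold-anchored offsets of every programmed feature:
the G/S deletion sits N-terminal of all substitution anchors (its
removal shifts nothing C-terminal of it), substitutions are applied at
their final offsets after any deletion, and the R3 insertion comes
last and changes no fold offset. Species are independent draws (no
phylogenetic covariance); all randomness flows from a single integer
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from histevo.sequence_io import HistoneSequence, SpeciesRecord

# Yeast-like base template: NTD with R at fold offset 6 only, then the
# fixed fold + CTD shared by every synthetic H2A.
TEMPLATE_NTD = "SGGKGGKAGSAAKASQSRSAKAG"
TEMPLATE_FOLD_CTD = (
    "LTFPVGRVHRLLRRGNYAQRIGSGAPVYLTAVLEYLAAEILELAGNAARDNKKTRIIPRHLQLAIRNDDELN"
    "KLLGNVTIAQGGVLPNIHQNLLPKKSAKATKASQEL"
)
# 40-residue acidic extension used to build variant-like decoys.
ACIDIC_TAIL = "EDEEDSEDEEGDESDGEKDEDSEEDGEDEESEDDEGSEDE"

FEATURES = (
    "r3_gain",      # insert R at N-position 3
    "s10_loss",     # delete G/S at fold offsets 15, 14
    "s15_loss",     # S->A at fold offset 9
    "k11_gain",     # A->K at offset 12 with V..G flanks (VKG motif)
    "k11_to_r11",   # K->R at offset 12 with A..A flanks (ARA motif)
    "k20_to_r20",   # K->R at offset 3 with S flank ((S/T)RA motif)
    "k8_gain",      # Q->K at offset 8 (balances the K lost at offset 3)
    "k19_gain",     # G->K at offset 19 (balances the K lost at offset 12)
)


@dataclass(frozen=True)
class FeatureCurve:
    """Logistic acquisition curve in log10 genome size."""

    steepness: float
    midpoint: float  # log10 Mbp

    def probability(self, genome_size_mbp: float) -> float:
        x = self.steepness * (math.log10(genome_size_mbp) - self.midpoint)
        if x >= 0:
            return 1.0 / (1.0 + math.exp(-x))
        return math.exp(x) / (1.0 + math.exp(x))


@dataclass
class EvolutionModel:
    """Per-feature acquisition curves; defaults emulate the study pattern.

    Midpoints: the early features (R3, K at offset 12, K->R at offset
    3) switch around 100 Mbp (midpoint 2.0); the serine losses shortly
    after (2.3); the late conversion K->R at offset 12 around 1000 Mbp
    (3.0). The compensating lysine gains share the curves of the
    lysine-removing features they offset.
    """

    curves: dict[str, FeatureCurve] = field(default_factory=lambda: {
        "r3_gain": FeatureCurve(3.0, 2.0),
        "s10_loss": FeatureCurve(3.0, 2.3),
        "s15_loss": FeatureCurve(3.0, 2.3),
        "k11_gain": FeatureCurve(3.0, 2.0),
        "k11_to_r11": FeatureCurve(3.0, 3.0),
        "k20_to_r20": FeatureCurve(3.0, 2.0),
        "k8_gain": FeatureCurve(3.0, 2.0),
        "k19_gain": FeatureCurve(3.0, 3.0),
    })

    def __post_init__(self) -> None:
        missing = set(FEATURES) - set(self.curves)
        if missing:
            raise ValueError(f"model missing curves for {sorted(missing)}")

    def null(self) -> "EvolutionModel":
        """Copy with all steepness 0: p = 0.5 regardless of genome size."""
        return EvolutionModel({
            name: replace(curve, steepness=0.0)
            for name, curve in self.curves.items()
        })

    @classmethod
    def from_yaml(cls, path) -> "EvolutionModel":
        raw = yaml.safe_load(open(path))
        return cls({name: FeatureCurve(float(v["steepness"]), float(v["midpoint"]))
                    for name, v in raw.items()})

    def to_yaml(self, path) -> None:
        raw = {name: {"steepness": c.steepness, "midpoint": c.midpoint}
               for name, c in self.curves.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh)


@dataclass
class SyntheticCohort:
    """A reproducible simulated species set with ground-truth labels."""

    species: list[SpeciesRecord]
    sequences: list[HistoneSequence]
    truth: dict[str, dict[str, bool]]  # species_id -> feature -> present
    labels: dict[str, str]  # seq_id -> {canonical, duplicate, variant, nonhistone}
    seed: int


DEFAULT_KINGDOM_PROPS = {"protozoa": 0.15, "fungi": 0.25, "plants": 0.2,
                         "animals": 0.4}


def simulate_species(n: int, seed: int,
                     size_range: tuple[float, float] = (8.0, 5600.0),
                     kingdom_props: dict[str, float] | None = None,
                     ) -> list[SpeciesRecord]:
    """Draw n species with log-uniform genome sizes on ``size_range``."""
    lo, hi = size_range
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 < lo < hi):
        raise ValueError(f"invalid size range ({lo}, {hi})")
    props = kingdom_props or DEFAULT_KINGDOM_PROPS
    kingdoms = list(props)
    weights = np.array([props[k] for k in kingdoms], dtype=float)
    weights /= weights.sum()
    rng = np.random.default_rng(seed)
    sizes = 10 ** rng.uniform(math.log10(lo), math.log10(hi), size=n)
    chosen = rng.choice(kingdoms, size=n, p=weights)
    return [
        SpeciesRecord(f"sp{i:04d}", str(chosen[i]), float(sizes[i]))
        for i in range(n)
    ]


def _offset_index(ntd: list[str], offset: int) -> int:
    """0-based index of the residue at a fold-anchored offset."""
    return len(ntd) - offset


def _apply_features(truth: dict[str, bool]) -> str:
    """Build an NTD from the template given a feature presence map.

    Deletions are applied first so that every substitution lands at its
    stated *final* fold-anchored offset; the N-anchored R3 insertion
    comes last and leaves all fold offsets untouched.
    """
    ntd = list(TEMPLATE_NTD)
    if truth["s10_loss"]:
        i = _offset_index(ntd, 14)
        del ntd[i]       # the serine at offset 14
        del ntd[i - 1]   # the glycine immediately N-terminal of it
    if truth["s15_loss"]:
        ntd[_offset_index(ntd, 9)] = "A"
    if truth["k19_gain"]:
        ntd[_offset_index(ntd, 19)] = "K"
    if truth["k8_gain"]:
        ntd[_offset_index(ntd, 8)] = "K"
    if truth["k11_gain"]:
        ntd[_offset_index(ntd, 13)] = "V"
        ntd[_offset_index(ntd, 12)] = "K"
        ntd[_offset_index(ntd, 11)] = "G"
    if truth["k11_to_r11"]:
        ntd[_offset_index(ntd, 13)] = "A"
        ntd[_offset_index(ntd, 12)] = "R"
        ntd[_offset_index(ntd, 11)] = "A"
    if truth["k20_to_r20"]:
        ntd[_offset_index(ntd, 4)] = "S"
        ntd[_offset_index(ntd, 3)] = "R"
    # N-anchored insertion last, N-terminal of all fold-anchored features
    if truth["r3_gain"]:
        ntd.insert(2, "R")
    return "".join(ntd)


def simulate_h2a(species: SpeciesRecord, model: EvolutionModel,
                 seed: int | np.random.Generator) -> tuple[HistoneSequence,
                                                           dict[str, bool]]:
    """Draw one synthetic H2A for a species; returns (sequence, truth).

    Feature presence is Bernoulli with probability p_f(g); the
    conversion at offset 12 (k11_to_r11) only applies on top of a
    gained lysine, and its truth entry records the effective state.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    g = species.genome_size_mbp
    truth = {
        name: bool(rng.random() < model.curves[name].probability(g))
        for name in FEATURES
    }
    truth["k11_to_r11"] = truth["k11_to_r11"] and truth["k11_gain"]
    residues = _apply_features(truth) + TEMPLATE_FOLD_CTD
    seq = HistoneSequence(
        seq_id=f"{species.species_id}_H2A",
        species_id=species.species_id,
        family="H2A",
        residues=residues,
    )
    return seq, truth


def simulate_cohort(n: int = 160, seed: int = 0,
                    model: EvolutionModel | None = None,
                    size_range: tuple[float, float] = (8.0, 5600.0),
                    ) -> SyntheticCohort:
    """Full cohort: species metadata, sequences and ground truth."""
    model = model or EvolutionModel()
    species = simulate_species(n, seed, size_range)
    rng = np.random.default_rng([seed, 1])
    sequences = []
    truth = {}
    labels = {}
    for sp in species:
        seq, t = simulate_h2a(sp, model, rng)
        sequences.append(seq)
        truth[sp.species_id] = t
        labels[seq.seq_id] = "canonical"
    return SyntheticCohort(species=species, sequences=sequences, truth=truth,
                           labels=labels, seed=seed)


def inject_decoys(cohort: SyntheticCohort,
                  rates: dict[str, float] | None = None,
                  seed: int = 0) -> SyntheticCohort:
    """Add labelled contaminants: duplicates, variant-like, shuffled.

    Per species, each decoy type is added independently with its rate:
    an exact duplicate of the species' H2A; a variant-like sequence
    (the H2A plus the packaged acidic C-terminal extension); and a
    shuffled sequence (same composition, order destroyed) that must
    fail fold-identity thresholds. Originals precede decoys in the
    output order, so deduplication retains the originals.
    """
    rates = {"duplicate": 0.1, "variant": 0.1, "shuffle": 0.1, **(rates or {})}
    for name, rate in rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"rate for {name!r} must be in [0, 1]")
    rng = np.random.default_rng([seed, 2])
    sequences = list(cohort.sequences)
    labels = dict(cohort.labels)
    by_species = {seq.species_id: seq for seq in cohort.sequences}
    for sp in cohort.species:
        base = by_species[sp.species_id]
        if rng.random() < rates["duplicate"]:
            dup = HistoneSequence(base.seq_id + "_dup", sp.species_id, "H2A",
                                  base.residues)
            sequences.append(dup)
            labels[dup.seq_id] = "duplicate"
        if rng.random() < rates["variant"]:
            var = HistoneSequence(base.seq_id + "_var", sp.species_id, "H2A",
                                  base.residues + ACIDIC_TAIL)
            sequences.append(var)
            labels[var.seq_id] = "variant"
        if rng.random() < rates["shuffle"]:
            shuffled = "".join(rng.permutation(list(base.residues)))
            shuf = HistoneSequence(base.seq_id + "_shuf", sp.species_id, "H2A",
                                   shuffled)
            sequences.append(shuf)
            labels[shuf.seq_id] = "nonhistone"
    return SyntheticCohort(species=cohort.species, sequences=sequences,
                           truth=cohort.truth, labels=labels, seed=cohort.seed)


def truth_table(cohort: SyntheticCohort):
    """Ground-truth feature presence as a species-by-feature table."""
    import pandas as pd

    rows = [{"species_id": sid, **feats} for sid, feats in cohort.truth.items()]
    if not rows:
        return pd.DataFrame(columns=["species_id", *FEATURES]).set_index("species_id")
    return pd.DataFrame(rows).set_index("species_id")


def template_fold_start(ntd: str) -> int:
    """Fold start of a synthetic sequence (1 + its NTD length)."""
    return len(ntd) + 1


def known_fold_span(seq: HistoneSequence) -> tuple[int, int]:
    """Exact fold span of a generator-produced sequence.

    The synthetic fold+CTD block is fixed, so the span follows from the
    sequence length; the fold proper is the first 73 residues of the
    block (mirroring the packaged yeast H2A fold span).
    """
    ntd_len = len(seq.residues) - len(TEMPLATE_FOLD_CTD)
    if ntd_len < 0 or not seq.residues.endswith(TEMPLATE_FOLD_CTD):
        raise ValueError(f"{seq.seq_id!r} is not a generator-produced sequence")
    return (ntd_len + 1, ntd_len + 73)
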