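# Methods

## Coordinate conventions

All sequence coordinates are 1-based and inclusive. A histone is split
into NTD, fold and CTD with `ntd + fold + ctd` reconstructing the input
exactly; `fold_start = len(ntd) + 1`. The fold-anchored offset of an
NTD position is `fold_start − n_position`, so offset 1 is the residue
immediately before the fold and offset 0 is the first fold residue.
Packaged fold spans follow the convention that the fold begins
immediately after the mature NTD: position 23 for human H2A (22-residue
NTD) and position 24 for yeast H2A (23-residue NTD). Under this
convention the human NTD arginines at positions 3/11/17/20 have offsets
20/12/6/3, and the yeast serines S10/S15 have offsets 14/9 — these
offsets define the cross-species "equivalent" anchor columns
(`S10eq=14, R11eq=12, S15eq=9, R17eq=6, R20eq=3`, with R3 anchored to
the N-terminus instead because its position is conserved from that
end). Sequences beginning with an initiator methionine are stripped to
the mature form on input (`keep_met` disables this), since all
reference coordinates refer to mature proteins.

## Canonical classification

Candidates are aligned locally (Smith–Waterman) against the family's
fold domain using BLOSUM62 with gap open 11 / extend 1, keeping the
aligner in-process rather than shelling out to an external search
binary; the thresholds operate on identity and coverage, not bit
scores, so the substitution model only shapes the alignment path. A record is a true hit when identity
(identical pairs / aligned non-gap columns) exceeds 0.35 **and** fold
coverage (reference fold positions aligned / fold length) exceeds 0.90,
both strictly. The fold span on the candidate — first to last aligned
candidate position — becomes its `fold_start` for partitioning, so NTD
lengths are free to vary across species.

Within a (species, family), records with identical residue strings are
deduplicated (first by input order wins); identical sequences in
different species are retained, because selection is per species.

Variant filtering (H2A and H3) scores each record by **global** percent
identity against the canonical human and yeast references (the better
of the two) and against each packaged variant reference; a record
strictly closer to a variant reference is flagged and excluded. Global
identity here counts matches over *all* alignment columns, gaps
included. This is deliberate: with gap-free-column identity, a
canonical sequence carrying a long variant tail (e.g. a macroH2A-like
acidic extension) scores the same as the untailed canonical against the
canonical reference — the tail is simply gapped out at no cost to the
ratio — and variant filtering and canonical selection both collapse.
Counting gap columns makes length outliers pay for their extensions,
which is what a variant filter needs. The same gap-inclusive score
ranks candidates for canonical selection (highest similarity to the
human or yeast canonical wins). All ties break deterministically:
unflagged over flagged, then longer sequence, then lexicographically
smaller id.

Packaged variant references are editable data: the H2A.Z-like entry
follows the human H2A.Z N-terminal architecture; the macroH2A-like and
H3-variant-like entries are synthetic decoys (canonical sequence plus a
40-residue acidic C-terminal extension / a diverged N-terminal
extension) built for specificity testing rather than copies of natural
variants.

## Rank statistics

The Mann–Whitney U test is implemented in-package. U is computed from
midranks (ties averaged) for the first sample, so `U_a + U_b = n_a·n_b`
always. When both samples are tie-free and `n_a·n_b ≤ 100` the exact
null distribution is built by the standard partition-counting
recurrence `c(u; n, m) = c(u−m; n−1, m) + c(u; n, m−1)` and one-sided
p-values are exact tail sums; otherwise a normal approximation with
tie-corrected variance and a 0.5 continuity correction is used (this
path reproduces the asymptotic p-values of scipy's implementation to
machine precision, which the tests verify as an independent
cross-check, alongside a complete enumeration sweep of every tie-free
configuration with n, m ≤ 4). Two-sided p is `min(1, 2·min(p_less,
p_greater))`, floored at the smallest positive normal float so p stays
in (0, 1] even for extreme separation. Raw p-values are reported
without multiple-testing correction, matching how such comparisons are
conventionally presented; the composition sweep is small and the
comparisons are pre-specified.

Genome-size classes are small (< 100 Mbp), medium ([100, 1000] Mbp,
closed interval — the boundary membership is a package choice since
"100–1000" leaves edges unspecified) and large (> 1000 Mbp). Class
comparisons require at least two species per group; the
presence/absence test (genome sizes of species lacking vs possessing a
feature) requires non-empty groups.

## Compaction toolkit

Probe positions are intensity-weighted centroids of (x, y) pixel
clouds; inter-probe distance is the Euclidean centroid distance times a
user-supplied nm-per-pixel factor (the factor is instrument-specific
and has no default). Distances are 2-D, matching measurement in single
projections. Percent change is `100·(center(mut) − center(wt)) /
center(wt)` with the median as default center (mean available; both are
always reported). The t path uses Welch's unequal-variance two-sided
test; the rank path delegates to the in-package Mann–Whitney. Nuclear
cross-sectional area is the ellipse formula `(D1/2)·(D2/2)·π` from the
long and short orthogonal axes (validated as `d1 ≥ d2 > 0`).

## Synthetic cohorts

The generator emulates the comparative structure the analysis assumes,
not any real phylogeny. Species are independent draws: genome sizes
log-uniform on [8, 5600] Mbp (the studied range), kingdoms drawn with
proportions protozoa 0.15 / fungi 0.25 / plants 0.20 / animals 0.40 —
a rough nod to how sequenced eukaryotes distribute, not a calibrated
quantity. Default cohort size is 160 species.

Each H2A starts from a yeast-like template (23-residue NTD, single
arginine at offset 6, fixed fold+CTD). Each feature f fires with
probability `p_f(g) = 1/(1 + exp(−s_f·(log10 g − m_f)))` — logistic in
log10 genome size, the minimal monotone curve with an interpretable
midpoint and steepness. Defaults use steepness 3 per decade throughout;
midpoints place the early features (R3 insertion, K gain at offset 12,
K→R at offset 3) at 100 Mbp (m = 2.0), the serine losses slightly later
(m = 2.3), and the late K→R conversion at offset 12 at 1000 Mbp
(m = 3.0). Flank templates give the motif program: VKG when the
offset-12 slot is K, ARA when it has converted to R, and AKA → (S/T)RA
around offset 3.

Feature mechanics preserve every stated anchor: the S10 loss is a G/S
double deletion at offsets 15/14, N-terminal of all substitution
anchors; the S15 loss is an S→A substitution at offset 9 (a deletion
there would sit C-terminal of the offset-11..13 motif cluster and drag
those anchors by one — substitution loss keeps all anchors exact);
substitutions are applied at their final offsets after any deletion;
the R3 insertion comes last and changes no fold offset. Two
compensating lysine gains (Q→K at offset 8, G→K at offset 19) share the
curves of the two K-removing features so the expected NTD lysine count
stays flat in genome size (residual imbalance ≤ ~0.035 K), mirroring
the empirical negative result for lysines; with all features on, the
template converges to the human configuration (22-residue NTD, R at
position 3 and offsets 12/6/3, four lysines).

Decoy injection adds, per species and independently at configurable
rates, an exact duplicate, a variant-like sequence (the species' H2A
plus the packaged 40-residue acidic tail) and a shuffled sequence (same
composition, order destroyed — shuffling reliably breaks the joint
identity/coverage threshold, verified over repeated shuffles). Ground
truth (feature presence per species, role label per sequence) travels
with the cohort.

What passing tests on these cohorts do **not** show: real cohorts have
phylogenetic covariance (related species are not independent draws),
ragged NTD boundaries beyond the programmed indels, annotation noise,
and histone variants far more diverse than the packaged decoys. The
generator demonstrates that the pipeline recovers effects it was told
to plant and stays calibrated when none exist; transfer to real data
rides on the classifier thresholds and the fold-anchoring argument, not
on these simulations.

## Calibration and problem sizes

The null calibration check runs 500 cohorts of 160 species with all
steepness set to 0 (every feature fires with p = 0.5 regardless of
genome size, seeds 0–499) and asserts the small-vs-large arginine
comparison rejects at α = 0.05 at a rate inside the binomial 95 % CI
around 0.05 (measured: 0.052). These replicates partition by the
generator's known fold spans — it is the statistical path being
calibrated, and this keeps 500 replicates to a few seconds. Pattern
recovery (one 160-species cohort, seed 7) runs the full
alignment-based path: classification, partitioning from alignment
spans, composition, rank tests and stratified motifs. Cohort sizes in
the tests (30–160) keep the complete suite under a minute while leaving
every group comfortably above the rank test's small-sample regime.

## Known limitations

- Variant filtering is only as good as the packaged decoy references;
  a variant family with no nearby decoy passes as canonical.
- The classifier assigns `unknown`-family records to the best-scoring
  requested family; genuinely ambiguous fusion proteins are out of
  scope.
- The exact Mann–Whitney path requires tie-free data; counts data
  (heavily tied) always take the tie-corrected normal path, which is
  mildly conservative for tiny samples.
- No phylogenetic correction anywhere: species are treated as
  exchangeable, in the simulations and in the rank tests alike.
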