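# Methods

## The model

Two lineages (a focal, mapped species and a sequenced reference) descend
from a common ancestor that underwent a whole-genome duplication (WGD) at
`t_wgd` My and split at `t_spec` My, with `t_spec < t_wgd`. Times run
backwards from the present in My; the substitution rate `r` is per site
per **year**. The 10⁶ unit conversion appears in exactly two places: the
simulator's branch-length computation and the `dating` module
(`r = K/(2T·10⁶)`, `T = K/(2r)/10⁶`); everywhere else times are My and
distances are substitutions/site.

Under a constant rate, the expected pairwise divergence is `2·r·t` for a
pair separated `t` years: orthologs (same WGD copy, different lineages)
show `2·r·t_spec`, and all paralog pairs (different WGD copies, whether
within or across lineages) show `2·r·t_wgd`, because every paralog pair
coalesces at the duplication. With the default study conditions
(`t_wgd = 150`, `t_spec = 45`, `r = 1.3e-9`) these are 0.117 and 0.39 —
the "paralogs about three times more diverged" regime.

## The simulator and what it does (not) emulate

An ancestral gene set (19 chromosomes × 35 genes by default, one intron
sequence of 500–1000 bp per gene, genes every 1 Mb) is duplicated in whole
at `t_wgd`; copy-2 chromosomes are appended unchanged (no diploidization
rearrangements, so effects stay isolated). Sequences evolve along the
genealogy `ancestor → (copy 1, copy 2) → split → four terminal copies`
under a continuous-time Markov model: the default is equal-frequency
single-rate (Jukes–Cantor); a two-transition-class unequal-frequency
(Tamura–Nei) mode with separate purine and pyrimidine transition
multipliers exercises the distance estimator off its null. Branch
transition matrices are exact matrix exponentials of the unit-scaled rate
matrix, so realized divergence is calibrated to `2rt` by construction
(tests check the realized mismatch fraction against the closed-form
expectation within binomial error).

Rearrangements accrue only on the two post-split branches:
`Poisson(event_rate × t_spec)` events per lineage, typed by `event_mix`.
The defaults are `event_rate = 0.14`/My/genome/lineage with mix
1:1:5:6 over fission:fusion:inversion:translocation — the proportions of
the thirteen events observed between the two Salicaceae karyotypes over
45 My. Fissions cut a chromosome at a uniform gene boundary; fusions
concatenate two chromosomes; inversions reverse 3–8 consecutive genes
(default `inversion_size_range`), flipping strands; translocations move a
single gene to another chromosome. Every event is logged with its lineage,
time and affected gene identities (the truth log), and gene counts are
conserved (chromosome count changes by ±1 only for fission/fusion).

Marker panels take one marker per gene (an optional spacing filter thins
them); the fragment is the gene's whole intron. With
`paralog_amplification_rate > 0` a fraction of markers emulates erroneous
paralog amplification: the fragment is drawn from, and the marker
segregates (hence maps) at, the WGD counterpart locus, while the recorded
design target stays at copy 1. This is the mechanism behind the published
"best homology to paralog 2" cases: the genotyped SNP lives in the
paralogous copy, so its linkage position is the paralog's position.

Linkage maps use a single genome-wide density (default 5 cM/Mb, which
reproduces the published ~5 cM mean interval at 1 Mb marker spacing) with
optional Gaussian cM jitter; no per-chromosome recombination landscape is
attempted. Full-sib (CP) genotypes assign each marker maternal-only
(`lmxll`), paternal-only (`nnxnp`) or biparental (`hkxhk`) status in the
proportions of the published SNP set (75:158:74), with random phase per
parent. Gametes follow a Markov (no-interference) crossover chain whose
per-interval recombination fraction is the inverse Kosambi transform of
the map distance, keeping the generative process consistent with the
Kosambi convention of the maps it feeds. The simulator has no selection,
no indel evolution (indels appear only in alignment test fixtures), no
genotyping error, no null alleles and no repeat/heterochromatin structure
— so passing tests demonstrate correctness of the estimators and
detectors under the neutral clock model, not robustness to assembly
artefacts, alignment error from indels, or segregation-distorting
selection, all of which affect real data.

## Homology search and classification

The reference is a closed set of located sequences (`>chrom:start-end`
FASTA). Candidate loci for a fragment are nominated by a banded infix
edit-distance screen (edlib) on both strands: unrelated random DNA sits
near 0.49 normalized edit distance while true homologs up to the paralog
regime (~30–34% mismatch) stay below ~0.38, so the default cutoff of 0.42
separates them with no appreciable miss probability — unlike exact k-mer
seeding, which can find zero intact 11-mers between short introns at that
divergence. Surviving candidates are extended by local alignment with the
classic BLASTN scores (+2 match, −3 mismatch, −5 gap open, −2 gap extend);
this scheme keeps a positive expected per-column score down to ~60%
identity, which a +1/−2 scheme does not. Significance is a raw-score
threshold (default 40) — with a closed, desk-sized reference there is no
need for an E-value model. Ties are broken deterministically
(lower/shorter chromosome label, then lower start).

`find_paralog2` re-searches the expected target's own sequence and returns
the best hit that does not overlap the query locus — the WGD partner if
one exists. Classification then applies, in order: (a) best hit overlaps
the expected anchor → `ortholog_expected` (overlap means ≥ 1 shared bp on
1-based inclusive intervals; the sequenced fragment is a sub-interval of
the gene span, so exact coordinate equality would be wrong); (b) best hit
overlaps the known paralog-2 locus → `ortholog_of_paralog2` if the
marker's linkage group is a synteny partner of that chromosome, else
`discordant_anomaly`; (b′) if no paralog 2 is known but the off-anchor
best hit lies on a partner chromosome of the marker's linkage group, the
hit itself is taken as the paralog-2 locus (this covers markers whose
duplicate copy was never independently located); (d) anything else →
`other_region`. Markers without a map position can only receive (a)/(d).
Chromosome-only anchors (published rows that give just the chromosome)
overlap anything on that chromosome.

## Rearrangement detection

The correspondence table is restricted to confidently classified markers
(`ortholog_expected` at the anchor locus, `ortholog_of_paralog2` at the
paralog-2 locus), each carrying (linkage group, cM) and (chromosome, bp
midpoint of the ortholog locus).

*Partnerships*: a chromosome partners a linkage group when it carries at
least `min_markers = 3` of its markers — three because isolated or
closely-spaced markers at group ends are the least reliably placed.

*Fission-or-fusion*: one event per chromosome split over ≥ 2 groups and
per group joining ≥ 2 chromosomes, deduplicated by member set. Direction
is never assigned: without an outgroup, a fission in one lineage is
indistinguishable from a fusion in the other. Unplaced scaffolds (labels
starting `scaff`) are excluded from event calling — linking an unplaced
assembly fragment to a group documents the assembly, not a rearrangement —
but still count for partnerships and translocation screening.

*Inversions*: within each (group, chromosome) pair with ≥ 2·`min_inv`
markers, markers are taken in cM order and maximal strictly descending bp
runs with ≥ `min_inv = 3` markers are reported. The bp axis orientation
is a convention; it is chosen by breakpoint parsimony (the orientation
with fewer descending runs), with the Kendall-correlation sign only as a
tie-break. Pure correlation-sign orientation misfires when one long
inversion dominates the pair counts; parsimony does not, and it keeps
detection invariant under reversing a group's cM axis. Tied cM positions
form unordered blocks and contribute no breakpoints. Spans are reported
between the outermost discordant markers — breakpoints between flanking
concordant markers cannot be located more precisely from map data.

*Single-marker translocations*: markers anchored to a chromosome that is
not a partner of their linkage group, excluding members of multi-marker
events. Two such markers merge into one event when they are consecutive
in bp order among all mapped markers of the source chromosome and within
one intervening marker on their shared linkage group — physically and
genetically adjacent strays almost surely moved together.

The rate is `n_events/(2·t)`: the factor 2 counts both lineages' branch
length (13 events over 45 My → 0.14 events/My/genome). Coverage sums, per
chromosome, the bp span between outermost anchored markers.

## Distances, summaries, tests, dating

Triplets (focal fragment, paralog 1, paralog 2) are aligned by two global
pairwise alignments against the focal sequence, merged on the focal
coordinate with "once a gap, always a gap"; where both paralogs insert at
the same focal position, paralog-1 columns come first (deterministic).
Scores of the embedded pairs stay within the gap-merge penalty bound of
the optimal pairwise scores (tested against a full Gotoh dynamic program
on small fixtures).

K<sub>i</sub> is the closed-form ML distance of the Tamura–Nei model:
from the observed purine-transition, pyrimidine-transition and
transversion proportions and the pooled base frequencies of the pair,
restricted to masked intron sites with **pairwise** gap deletion (a site
is dropped only for pairs gapped at it, maximizing usable sites). Where
the fragment carries no annotation the whole fragment is treated as
intron, since fragments are designed to span introns. With uniform
composition and balanced classes the formula reduces exactly to
−¾·ln(1 − 4p/3); the implementation agrees with an independent
implementation (R, ape) to 10⁻⁹ on fixtures. This closed-form pairwise
estimator stands in for composite-likelihood variants that pool pattern
counts across all pairs; the difference is negligible at these divergences
and the closed form is directly testable. A non-positive logarithm
argument marks the pair saturated; the distance is computed with the
argument clipped to 10⁻¹² (large but finite). Summaries (mean, SEM =
sd/√n, median, 0.1-wide histogram from 0) keep saturated and extreme
(> 1) values by default — they are part of the empirical distributions —
with a filter switch that drops them.

The rank-sum test reports W (rank sum of the first group under pooled
mid-ranks), U = W − n₁(n₁+1)/2, and a two-sided p: full enumeration of
all rank assignments when the smaller group has < 8 observations (ties
handled through mid-ranks), otherwise a tie-corrected normal approximation
with continuity correction. The two branches agree within ~10% relative p
at the crossover size, and the test holds its nominal 5% size under the
null (both tested).

Dating anchors one event on a calibration and dates the other: a
speciation anchor (fossil co-occurrence, default 45 My) turns the ortholog
median K<sub>i</sub> into a rate and dates the WGD from the paralog
median; a WGD anchor (Eurosid I/II split, default 110 My) does the
converse. Medians are the default point estimate (robust to the saturated
tail); means sit behind a flag. Presentation rounding: rates to 3
significant figures, approximate dates to the nearest 10 My.

## Linkage statistics

Kosambi: x(r) = 25·ln((1+2r)/(1−2r)) cM with inverse r = ½·tanh(x/50)
(round-trip exact to 10⁻¹²); Haldane provided for comparison (Kosambi ≤
Haldane for r > 0). Segregation tests use 1:1 (df 1) for single-parent
informative markers, 1:2:1 (df 2) for biparental shared-allele markers,
and 1:1:1:1 (df 3) for fully informative four-allele configurations
(supported, not default); the flag counts crossed thresholds on the
asterisk scale 0.1 … 0.0001, with exclusion at p < 10⁻⁵. Two-point
recombination fractions maximize the CP transmission likelihood (both
meioses share one rf; relative phase of each doubly heterozygous parent is
maximized over, equivalent to choosing the phase minimizing rf); pairs
informative in disjoint parents carry no linkage information and return
rf = 0.5, LOD = 0. Groups are connected components of the LOD graph at the
threshold (transitive by construction); marker **ordering** within groups
is deliberately not implemented. Mean map interval is total length divided
by marker count (not interval count) — the convention that reproduces both
published values (2477/495 = 5.0, 1793/221 = 8.1).

## Bundled published tables

`salicoid.data/published_markers.tsv` transcribes the published tables of
anomalous markers (20 paralog-2 cases, 4 other-region cases, 7 putative
translocations) with their printed coordinates; one row (I-3_sa) prints
reversed coordinates, which the loader normalizes. cM positions are not
printed in the source (they appear only in figures), so the
correspondence builder places these markers, and a synthetic backbone of
three concordant markers per published partnership, at synthetic cM
positions consistent with the stated ordering (II-23_sa and II_37_sa_pI
adjacent on LG XVII). The backbone is labelled `bb_*` and exists solely to
establish the published partner structure at the detector's
`min_markers`.

## Numerical and procedural choices

- All randomness flows from a single integer seed through named
  sub-streams (`numpy` `default_rng([seed, stream])`); identical
  parameters give byte-identical outputs, which the pipeline manifest
  (SHA-256 per artifact) makes checkable.
- Two-pass classification in the pipeline: partnerships are first derived
  from unambiguous expected-ortholog calls, then all markers are
  reclassified with synteny checks enabled.
- Degenerate inputs: empty fragment, empty reference, zero usable aligned
  sites, zero genotype totals, non-positive times/rates all raise typed
  errors; no-hit markers are classified `other_region` with a flag rather
  than erroring.
- Problem sizes in the test and acceptance runs (4–6 chromosomes,
  6–26 genes each, 200 replicates of 600 sites, 1000 null simulations)
  were chosen as the smallest at which the binomial/Poisson error bands in
  the checks are comfortably tighter than the effects being verified.

## Known limitations

- Fission/fusion events whose smaller product carries fewer than
  `min_markers` markers, chained events on one chromosome, and reciprocal
  events in the two lineages are not resolvable from a correspondence
  table; the detectors report the observable signature.
- Orientation of a group/chromosome pair is ambiguous when genetic and
  physical order are uncorrelated (τ = 0 and equal run counts); the
  forward orientation is then preferred deterministically.
- The two-point likelihood ignores genotyping error and null alleles.
- Saturated K<sub>i</sub> values are magnitudes, not estimates; dating
  from medians limits their influence but distributions containing many
  saturated pairs should be filtered explicitly.
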