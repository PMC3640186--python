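# Methods

This note documents the models, conventions and numerical choices behind
`landuse16s`, in the order data flows through the pipeline.

## Reference taxonomy and lineage algebra

A lineage is an ordered prefix of the seven ranks domain → species; a rank may
be present only if all shallower ranks are, and the empty lineage means
"unclassified".  The lowest common ancestor (LCA) of lineages is their longest
common prefix, which makes `lca` commutative, associative and idempotent — the
properties the property tests assert.  Reference FASTA headers use a
single-line bracket-numbered dialect
(`>ID [0]domain;[1]phylum;…;[6]species`): self-contained, lossless for seven
ranks, and strict (a missing slot is a parse error naming the line; missing
intermediate ranks are rejected rather than padded so the prefix invariant
stays testable).  The species slot is an opaque label.

## Read model and trimming

Forward reads carry an inline 8-base sample barcode followed by an 11-base
primer region; reverse mates are reverse-complemented 3′ windows with no
barcode.  Demultiplexing requires an exact barcode match (no error
correction — any mismatch discards the pair), so barcode-region sequencing
errors surface as demultiplexing losses, which the conservation logging
accounts for (input = assigned + discarded).

Trimming first removes a fixed 11-base primer prefix from each mate
regardless of content, then keeps the contiguous segment maximizing
Σ(qᵢ − floor) with floor 20; ties resolve to the leftmost, then longest
segment, and mates whose kept segment is shorter than 50 nt are rejected.
This is the standard maximum-scoring-segment family of quality trimmers,
chosen because it is exactly checkable against an O(n²) all-substrings
oracle.  A pair survives only if both mates survive; the per-sample count of
surviving pairs is the denominator for all relative abundances.  We
demultiplex before trimming to protect the barcode prefix.

## Alignment and identity

Each mate is aligned to every reference by local dynamic programming with
match +1, mismatch −1, gap −2 (linear).  Both read and reference ends clip
free.  This realizes the two quantities the classifier filters on:
`identity` = matches / alignment columns (gap columns count in the
denominator — a deliberately strict definition) and `length_fraction` = read
bases inside the alignment / read length.  A read-global ("semi-global")
formulation would force length_fraction ≡ 1 and make the 80% coverage filter
vacuous, so the local formulation is the one that makes both filters
meaningful; it also mirrors how read mappers with a length-fraction parameter
behave.  Determinism: among co-optimal alignments the endpoint with the
smallest read index then smallest reference index wins, and traceback prefers
diagonal > read-consuming gap > reference-consuming gap; ties among equally
good references resolve by reference id.  Score-0 alignments are reported
empty (identity 0, length fraction 0).

Two shortcuts accelerate classification without changing any result, and the
suite asserts on/off equivalence:

* **Exact-substring path.**  A mate contained verbatim in a reference attains
  the maximum possible score (all-match, full-length), so the containing
  references *are* the best-hit set — unless some other reference shares a
  common substring of ≥ ⌈0.8·m⌉ bases (the only way to tie identity 1.0 while
  covering 80% of the read), in which case the exhaustive path runs.
* **k-mer screen.**  A reference sharing no 14-mer with the mate cannot
  contain a run of 14 match columns; covering R₀ = ⌈0.8·m⌉ read bases then
  forces at least E = ⌈(R₀−13)/14⌉ error columns and at most (E+1)·13
  matches, bounding identity by (E+1)·13 / ((E+1)·13 + E) ≈ 0.936 for
  m ≈ 139.  When a screened candidate already exceeds that bound, unscreened
  references are provably out of the running; otherwise the exhaustive path
  runs.

## Pair classification

Per mate, hits must cover ≥ 80% of the read and only hits tying the maximal
identity are kept.  If the mates' hit sets share a reference the pair is
*concordant* (ties → LCA over the shared references); otherwise, if both
mates have hits, the pair takes the LCA of all hit lineages (*lca* status);
otherwise it is *unclassified* — a single-mate hit does not classify a pair.
The pair's effective identity is the minimum identity over the hits used
(conservative), and the lineage is truncated to the deepest rank whose floor
it meets: domain/phylum 0.80, class/order/family 0.90, genus 0.95, species
0.99.  A truncation to depth 0 is reported unclassified.  Counting is
rank-monotone: a pair counted at genus is counted at every shallower rank.
Normalization divides counts by the sample's trimmed-pair total, so column
sums equal classified/trimmed ratios and never exceed 1.

## Soil chemistry

Measured NH4⁺-N (KCl extraction recovers both species) is treated as total
ammoniacal N and partitioned by Henderson–Hasselbalch with pKa 9.23:
f(pH) = 10^(pH−9.23)/(1+10^(pH−9.23)), NH3-N = NH4-N·f(pH), all in mg N per
kg soil — no molar or solution-phase conversion, because that is the
convention under which the published KBS non-agricultural plot means (pH 5.2,
NH4⁺-N 6.18) reproduce the published log10[NH3] = −3.24 exactly.  Table
printing rounds half away from zero to two decimals.  The published BRR and
EAA plot-level logs do not reproduce from their printed means under any
simple speciation convention; they are consistent with averaging per-sample
logs, whose raw inputs are not available, so the module derives but does not
force those rows (see `analysis/03_soil_speciation.py`).  SOM = 1.72 × %OC.

## Statistics

Spearman rho is the product-moment correlation of average ranks.  The
two-sided p is computed by exhaustive permutation enumeration for n ≤ 8
(feasible: ≤ 40,320 permutations; handles ties correctly because ranks are
permuted as-is) and by the t approximation with df = n−2 otherwise.
Proportions are arcsine-square-root transformed before ANOVA only; Spearman
runs on raw proportions since it is invariant to monotone transforms.
One-way ANOVA is the classical between/within decomposition (zero within-group
variance with distinct means reports F = ∞, p = 0).  Two-way ANOVA requires a
balanced complete design — with balance, type-I/II/III sums of squares
coincide, so the unspecified choice is moot; unbalanced input is rejected with
an instruction to subsample rather than silently reweighted.  Each sample,
including pseudoreplicates, is one observation.  No multiple-testing
correction is applied beyond the p ≤ 0.001 screen itself.  Land use is coded
binary (agricultural = 1).

A genus is a signature iff it passes the 0.05% site-wide abundance floor at
*all* sites and meets |ρ| ≥ 0.5, p ≤ 0.001 with a consistent sign at every
site.  Fold changes report larger/smaller mean with direction separate, and
the integer fold rounds half away from zero.

## Synthetic study design

The generator's defaults are the study conditions the tests exercise:

* **Reference**: 12 genera across 3 phyla (an archaeal ammonia-oxidizer clade
  and two bacterial phyla), 300-nt records.  Sequences descend from random
  phylum roots with per-base mutation rates 0.065 (family vs root) and 0.0385
  (genus vs family), then are regenerated (bounded, seed-deterministic
  retries) until within-family inter-genus Hamming identity lies in
  [0.90, 0.95) and cross-phylum identity is < 0.80 — placing every rank
  threshold on a decisive boundary: a clean read beats 0.95 only against its
  own genus, and discordant same-family mates truncate at family.
* **Soils**: 3 sites × 2 land uses × 16 samples.  pH ~ N(7.4, 0.3) on
  agricultural and N(5.6, 0.3) on non-agricultural plots (small site
  offsets), NH4⁺-N lognormal within the published 1.3–9.6 mg/kg range, other
  covariates within published ranges; NH3 always derived by the speciation
  module, so nh3 ≤ nh4 holds by construction.
* **Communities**: focal weights base·exp(β·(pH−6.5)+ε) with β = +1
  (archaeal ammonia oxidizer), −1 (*Bradyrhizobium*), base weight 0.02,
  lognormal noise σ = 0.3; the other ten genera share a symmetric
  Dirichlet(1) bulk.  The ±1.8 pH contrast between land uses then yields
  roughly 5–7× abundance contrasts, matching the 2–7× range reported for
  real soils, while the symmetric bulk keeps null genera uncorrelated with
  land use.
* **Reads**: 150 nt, 400 pairs/sample by default; forward = barcode +
  11-base primer proxy (the first 11 bases of the 515F primer) + 5′ window,
  reverse = reverse complement of the 3′ window, uniform substitution errors
  at 0.5%/base (a realistic short-read error magnitude), constant Q40
  qualities with an optional low-quality 3′ tail to exercise trimming.  The
  11-base primer proxy matches the 11-base trim exactly, so primer removal is
  lossless by construction.  The reverse mate carries no primer, so the fixed
  11-base cut removes 11 template bases there — the cost of applying the
  stated rule verbatim to both mates.

What the generator does **not** emulate: position-dependent error profiles,
indels, chimeras, PCR/GC bias, variable amplicon lengths, overdispersed
(compositional) count noise beyond the Dirichlet bulk, and real phylogenetic
sequence structure.  Passing tests therefore demonstrate correctness of the
pipeline's rules and statistics under controlled conditions, not classifier
performance on real amplicon data.

## Problem sizes in the test suite

The committed acceptance checks run the study design at 3 sites × 2 land
uses × 16 samples with 400 read pairs per sample across 12 seeds (signature
recovery), 500+ randomized classifier-oracle instances over databases of
4–13 references with reads ≤ 120 nt, 1,000 random reads for the trimming
oracle, and permutation enumeration up to n = 8.  Detection power for the
signature screen comes from the 32-samples-per-site correlation design —
read depth beyond a few hundred pairs adds little — and at these sizes both
planted signatures were recovered with zero false positives in every seed
tried.

## Known limitations

* The aligner is exact but O(m·n) per reference; the fast paths assume
  substitution-dominated reads and fall back to the exhaustive scan
  otherwise.  Databases far beyond toy size would need a real seeded mapper.
* Effective pair identity as the minimum of mate identities is conservative;
  other pair-merging conventions would shift the rank at which borderline
  pairs truncate.
* Spearman's t approximation is inaccurate in the far tail for n just above
  8; the signature screen at n = 32 is well inside its valid range.
* The Venn partition is defined for exactly three sites; studies with a
  different site count skip it.
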