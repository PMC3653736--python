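# Methods

This note documents the models, parameter choices, and numerical decisions
behind `rnrscape`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Scoring model

Each RNR gene family (nrdA, nrdB, nrdE, nrdF, nrdH, nrdI, nrdJ, nrdD,
nrdG) is represented by a position-specific scoring matrix (PSSM) rather
than a full profile hidden Markov model. Columns of the seed alignment with
a gap fraction strictly above 0.5 are discarded as non-match columns; a
retained column scores residue *a* as
`log2((c_a + α·b_a) / (n + α) / b_a)` bits, with pseudocount mass α = 1 and
background *b* (flat 1/20 unless a frequency file is supplied). Sequences
are aligned to the profile by Smith–Waterman local dynamic programming with
affine gaps; both gap directions use the same penalties (open 7 bits,
extend 1 bit — chosen so that a single gap costs roughly two good match
columns, which behaves sensibly on the synthetic fixtures). Ambiguity
codes (X and friends) score the column minimum, i.e. as a worst-case
mismatch.

The DP is verified against an independent oracle that enumerates every
monotone set of matched (residue, column) pairs with per-dimension affine
gap charges — exact on instances up to 5 columns × 8 residues.

Besides the single best local alignment, the engine reports non-overlapping
suboptimal local hits scoring at least 60% of the best, found by hard
masking of the best hit's query span and re-running. This is what lets a
split gene produce one hit per coding fragment when fragments share one
reading frame.

## E-values

Significance is empirical: for each profile, 200 background-sampled decoys
of length 400 are scored and a Gumbel (type-I extreme value) null is fitted
by method of moments (`β = sd·√6/π`, `μ = mean − γ·β`). The E-value of a
score *s* is `N·P(S ≥ s)` with `N` the number of protein × profile
comparisons in the search at hand. Decoy length is fixed; no length
correction is applied to query proteins, which is adequate at the scales
the package targets (the Gumbel location shifts only logarithmically with
sequence length). A decoy score distribution with zero variance (a
degenerate profile) is an error, not a silent pass. The fit is validated
two ways: recovery of known Gumbel parameters from simulated draws, and
near-uniformity of null P-values (count with P ≤ 0.1 out of 500 fresh
decoys inside the binomial 99% band [25, 85]).

One known limitation: because E = N·p and N grows with the search size, a
fixed E-value cut-off is effectively stricter in larger searches. Hits far
above threshold are unaffected, but ORFs that only graze a gene (short
overlaps at read ends) can flip between counted and not counted as the
comparison count changes.

## Curation rules

* E-value cut-off 1e-4, boundary inclusive (E = 1e-4 passes); the
  inclusivity is a documented convention.
* When hits to different families overlap the same locus (reciprocal
  overlap ≥ 50% of the shorter interval; connected components of that
  relation), only the lowest E-value survives, with ties broken by higher
  bit score, then lexicographic family name — a total order, so curation is
  invariant to input order.
* nrdH and nrdG calls require genomic context: an accepted call of a
  different, unambiguous family within 5 000 nt or with at most 3 annotated
  genes in between. Both windows are configurable; the confusion of nrdH
  with thioredoxins/glutaredoxins and of nrdG with formate-lyase activases
  is handled entirely by this rule rather than by extra profiles.
* Manual overrides: forced inclusions are appended (idempotently) with
  their own reason code; forced exclusions flip matching calls. Every input
  hit leaves the chain exactly once with a status and a reason.

For searches over annotated genomes, the curated call's locus is the
annotated CDS interval, while the hit retains its local-alignment envelope.
This makes gene-order strings and split-gene junctions exact properties of
the annotation (integers such as a 40-nt overlap or a 41-nt spacer) instead
of fuzzy properties of alignment end-trimming.

## Gene organization and split genes

Gene order is the family sequence sorted by genomic start on the deposited
orientation, written with the `nrd` prefix stripped (`GDBA`). Operon groups
are maximal same-strand runs with inter-call gaps ≤ 200 nt. Split genes are
same-family call clusters within 20 kb whose profile intervals are
quasi-disjoint — pairwise overlap < 20% of the shorter fragment; heavier
overlap is treated as duplicate hits, not a split. Fragments are labeled
-a, -b, … by ascending profile start, and junctions are computed in
transcription orientation so labels read 5'→3' on either strand; a negative
junction is exactly minus the fragment overlap. Positive junctions are
scanned for six-frame ORFs (≥ 30 codons, no start-codon requirement) and
each ORF translation is matched against the packaged motif patterns
(HNH / GIY-YIG / LAGLIDADG endonuclease and intein termini). The patterns
are illustrative, versioned regular expressions shipped with the package —
they are stand-ins, not a curated motif database, and reports name motif
classes only, never intron-vs-intein verdicts.

## Metagenome branch

Reads are de-replicated by exact, case-insensitive full-length identity
(prefix-duplicate removal is available behind a flag, off by default, since
the de-replication criterion of mixed published datasets is not knowable).
"Metagenome size" is the total nucleotide count after de-replication —
robust to read-length heterogeneity, unlike read counts. Six-frame ORFs of
≥ 30 residues (edge-truncated runs allowed) are scored against all
profiles; each ORF contributes to at most one family — its lowest-E-value
family, same tie-breaks as curation — when E ≤ 1e-4. Abundance is
`C/(size_nt·L)·1e9`, with gene length L the profile match-column count in
residues; the fixed 1e9 scale keeps typical values O(0.1–100). Class
aggregate columns are exact sums over member genes. Metagenomes with ≤ 5
total hits are flagged excluded but their values are retained.

## Distance phylogenetics

Protein distances are Poisson-corrected p-distances over mutually non-gap
columns (`d = −ln(1−p)`); saturated pairs are an error naming the pair.
Neighbor joining is the standard agglomeration with two deliberate
determinism choices: the Q-matrix argmin is tie-broken lexicographically on
the sorted label pair, and negative branch-length estimates are clamped to
zero. NJ is exact on additive matrices, which the tests exploit (100/100
recovery of random 6–10-leaf trees). Congruence between two gene families
is the Robinson–Foulds distance between their NJ trees restricted to
genomes carrying accepted calls of both families, reported raw and
normalized by 2(n−3); no "congruent/incongruent" verdict threshold is
imposed — the number is the report. Distance-plus-NJ deliberately replaces
maximum-likelihood search with model selection and bootstrapping: the
package tests the structural co-inheritance claim, not exact tree
reconstruction.

## Synthetic data: what it emulates and what it does not

Generators are pure functions of (configuration, seed) — identical seeds
give byte-identical outputs.

* **Seed alignments**: a background-sampled ancestor, rows derived by
  i.i.d. per-site substitution to one of the other 19 residues (probability
  = divergence, default 0.15), with ~5% of columns converted to
  majority-gap columns to exercise the match-column rule. Under this model
  the expected pairwise p-distance is `2d − d²·20/19`, which the tests
  check. Family lengths (70–260 residues) are scaled down from real RNR
  genes while preserving relative lengths.
* **Genomes**: genes drawn from the family ancestor at the configured
  divergence (default 0.15; recovery suites use 0.25), reverse-translated
  with uniform synonymous codon choice (codon bias is irrelevant to a
  protein-space search), placed by gene-order template with 100-nt
  intergenic gaps, plus 3 random decoy genes and 300-nt flanks at
  background GC 0.5. Stratum defaults tie environment and host oxygen to
  class combinations (marine→I/II, sewage→I and I+III, soil→II and I+II,
  anaerobe hosts→III); the II+III combination is never generated by
  default. Split specs excise a gene into fragments with configured signed
  junctions. For a negative junction the later fragment's nucleotides take
  precedence in the overlap and the earlier fragment's stored /translation
  is authoritative for its locus; truth validation therefore checks
  sequence/translation consistency outside recorded overlaps. Non-coding
  spacers are built around stop cassettes that interrupt all six frames at
  least every ~25 codons, so a "210-nt non-coding spacer" really contains
  no ORF at the caller's 30-codon threshold; motif-bearing spacers embed a
  reverse-translated ORF carrying a literal motif exemplar.
* **Reads**: lengths `round(Normal(334, 0.15·334))` clipped to [60, 668],
  drawn from genomes proportional to depth, strand-random, with i.i.d.
  substitution errors (default 1%) and optional exact-duplicate injection.
* **Gene trees**: random binary topologies with branch lengths U(0.08,
  0.3); sequences of 400 residues evolved with per-site substitution
  probability `1 − exp(−t)` per branch. Discordant pairs resample the
  second topology until its RF distance from the first is positive.

What passing these tests shows: the pipeline's rules are implemented
exactly (junction arithmetic, tie-breaks, boundaries), its statistics are
calibrated under the generator's null, and planted signal at moderate
divergence is recovered through the full chain. What they do not show:
performance on real phage genomes, whose RNR genes did not evolve by
i.i.d. substitution from a single consensus, whose confounders
(thioredoxins, formate-lyase activases) are real sequences rather than
random decoys, and whose metagenomes carry platform-specific artifacts
(indels, quality structure, chimeras) the read model omits.

## Problem sizes

Suites are sized for a single CPU: planted-truth recovery uses 100 genomes
at divergence 0.25; null calibration 500 decoys; the DP/oracle sweep 100
tiny instances; NJ recovery 100 trees of 6–10 leaves. The depth-bias check
compares one metagenome of 4 800 reads against one of 14 400 from the same
three-genome pool — depths chosen so per-class Poisson counting noise is
comfortably below the 25% agreement band being tested (the shortest gene,
nrdG at 90 residues, dominates the class III variance through its 1/L
normalization weight).

## Known limitations

* The PSSM + affine-gap model has no position-specific insert/delete
  states; real profile HMMs will discriminate better at high divergence.
* The Gumbel fit is by moments on 200 decoys; extreme-tail E-values (far
  below ~1e-6/decoy-set) are extrapolations.
* Six-frame ORF calling has no sequencing-error model; a frameshift error
  truncates fragments rather than being corrected.
* De-replication is exact-identity only by default.
* GenBank parsing is a minimal dialect (LOCUS, CDS with /gene, /product,
  /translation, ORIGIN); joins import as separate parts sharing a gene id.
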