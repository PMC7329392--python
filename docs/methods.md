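# Methods

`kepmine` mines fungal proteomes for Kex2-processed repeat proteins (KEPs):
secretory precursors that carry an ER signal peptide and tandem-repeated
internal peptides excised by the Golgi protease Kex2 at dibasic motifs (KR,
KK, RK, RR). KEPs include peptide-pheromone precursors (yeast α-mating
factor, filamentous-fungus α-pheromones) and the precursors of
ustiloxin-type cyclic RiPPs, whose maturation additionally requires
DUF3328-domain "cyclization factor" proteins encoded near the precursor
gene. The pipeline detects KEPs, groups them into types and their repeat
units into sub-types, quantifies domain co-occurrence in the gene
neighborhood, and annotates pheromone-like precursors.

## Detection funnel

A protein passes through ordered stages, and the first failing stage is
recorded as its single rejection reason:

1. **Signal peptide** (`NO_SIGNAL`). Predictions are normally consumed from
   a SignalP 4.1 short-format table; the reported cleavage site is the first
   mature residue, so `cleavage_pos` (last signal residue) is that value
   minus one. A built-in heuristic exists so that simulations and tests need
   no external predictor: within the first 45 residues it requires a K/R at
   positions 1–6 (n-region charge), a run of ≥ 8 hydrophobic residues
   (ACFILMVW) starting at positions 2–15 (h-region), and a small-residue
   motif `[AGSTC]-x-[AGSTC]` ending at the smallest position p with
   hEnd + 2 ≤ p ≤ 40 (c-region, the classic A-X-A site); p is the cleavage
   position. The synthetic generator constructs signals to exactly these
   rules; the heuristic is a caricature for testing, not a SignalP
   replacement, and real-data runs should use the file path.
2. **Length** (`TOO_SHORT`): mature sequences under 16 aa cannot be scored.
3. **Tandem repetitiveness** (`NOT_REPETITIVE`) — the repeat scorer below.
4. **Kex2 sites** (`NO_KEX2_SITE`): dibasic motifs are found by a
   leftmost-greedy non-overlapping scan (cleavage after the motif), and the
   mature sequence splits into inter-site fragments with site residues
   excluded and empty fragments dropped.
5. **Fragment size** (`FRAGMENT_TOO_LONG`): any fragment over 100 aa
   disqualifies the protein (the exclusion applies to every fragment, not
   only repeat units).
6. **Repeat units** (`TOO_FEW_UNITS` / `UNITS_TOO_SHORT`): a fragment is a
   repeat unit when at least half of its positions are repeat-masked and its
   length is 8–100 aa; at least 3 units are required. When most of the
   masked fragments are shorter than 8 aa the rejection is labeled
   `UNITS_TOO_SHORT`, otherwise `TOO_FEW_UNITS`.

## Repeat scoring: coherence-gated seed-sliding identity voting

Every length-40 window of the mature sequence (a *seed*; all windows at
stride 1, `n_seeds = L - 39`) is slid over the sequence at every gapless
offset, partial end-overlap allowed, excluding the seed's own source
placement. Under a placement, a position whose residue equals the seed
residue overlaid on it earns one vote, **provided the match is coherent**:
at that placement's shift, at least 2/3 of the 12 shifted-self-comparison
columns around the position must match, and the match must extend to at
least one adjacent column. The score of a position is its votes divided by
`n_seeds`; positions with score > 0.6 are masked as repeated. `X` never
matches anything, including another `X`.

The coherence gate is essential. Ungated, the vote count decomposes into a
composition statistic — every same-residue coincidence between a seed and
the sequence votes — giving a uniform-random sequence an expected score of
seed_length/20 = 2.0 at every position, far above the 0.6 threshold; no
threshold can then separate repeats from background. Gated, a random
sequence scores zero almost surely (8 of 12 chance matches at 1/20 each:
~2×10⁻⁸ per site), while in tandem arrays the period-multiple shifts align
copy onto copy in long conserved stretches, and every position accumulates
several votes per overlapping seed. The window tolerates 4 mismatches per
12 columns, so ~5% per-copy substitution leaves coherence intact; the
di-residue requirement suppresses isolated chance matches that would
otherwise bleed mask across the repeat-region boundary. Both knobs
(`coherence_window` = 12, `min_local_identity` = 2/3) are exposed in
`PipelineParams`.

Scoring is O(L²): placements are grouped by source-to-placement shift d, so
all their match columns come from the single comparison
`mature[i] == mature[i+d]`, and the votes a position receives through
partner m equal the number of seeds containing m. The test suite checks the
optimized scorer vote-for-vote against a direct (seed, placement, position)
enumeration.

A sequence is *tandem repetitive* when cutting at every mask flip yields
more than 2 blocks. A mature sequence that is one solid masked block plus a
tail has only 2 blocks and does not qualify; real precursors carry a
non-repeated pro-region and tail around the repeat array, giving ≥ 3.

Sequences shorter than 41 aa use a reduced seed of max(8, L/2) (flagged on
the output track) so that minimal legal precursors (~30 aa mature) remain
scorable.

## Similarity, typing and sub-typing

Pairwise similarity is optimal Smith–Waterman local alignment under
BLOSUM62 with affine gaps (a gap of length g costs 11 + (g−1)·1), computed
with Biopython's `PairwiseAligner` and checked in the tests against an
independent Gotoh dynamic program. Identity counts exact matches over
aligned columns (gap columns included in the denominator); coverage is the
aligned span over the full sequence length, per sequence. E-values follow
Karlin–Altschul, E = K·m·n·exp(−λS), with the standard gapped-BLOSUM62
constants λ = 0.267, K = 0.041; in database mode n is the database residue
total. The downstream thresholds (10⁻³⁰, 10⁻¹⁰) are so extreme that modest
constant error cannot flip a decision; composition-based statistics and
low-complexity filtering are deliberately not emulated, which is a known
fidelity gap relative to BLAST-derived E-values.

Two KEPs are *linked* when, in both search directions, E < 10⁻³⁰ (database
mode over all KEP sequences) and the query's coverage exceeds 70%. Types
are single-linkage components of the link graph (union-find, cross-checked
against a brute-force transitive closure); components are labeled `#1, #2,
…` by descending size with ties broken by smallest member id, and
singletons are stand-alone (`0`). Repeat units within a type are grouped
into sub-types with identity > 65% and coverage > 70% (no E-value
threshold); sub-types with ≤ 2 members are flagged small and excluded from
profile reporting. Cross-study set comparison uses the same reciprocal rule
at 95%/95%.

Sub-type profiles use a center-star multiple alignment (center = member
with maximal summed pairwise scores; "once a gap, always a gap" merging on
center coordinates) and a per-column residue frequency matrix with a total
pseudocount mass of 0.05 per column split over the 20 residues. This
replaces an external MSA + profile-HMM tool chain: no insert/delete states,
but the consensus and composition quantities used downstream are preserved.

## Gene neighborhood

Genes on a contig are ranked by start coordinate; gene distance is the
absolute rank difference (adjacent = 1), strand ignored, undefined across
contigs. Around each KEP gene, the survey covers distance 1..15 on *each*
side (truncated at contig ends). For a domain label (DUF3328 = PF11807,
Tyrosinase = PF00264, MFS_1, or "another KEP") the module reports the
per-distance hit histogram, the fraction of KEPs with ≥ 1 hit in the
radius, the mean over KEPs of the nearest-hit distance, and the mean
distance of all hits within 10 genes. Both means are emitted because a
published "average distance" can be read either way; the nearest-hit mean
is the headline statistic. Conditional histograms stratify KEPs by the
presence of a second label in the radius (e.g. Tyrosinase given DUF3328),
and the two strata partition the KEPs exactly.

## Annotation and census tables

A KEP is flagged as a yeast α-mating factor when it carries an MF_alpha
(PF04648) and/or MF_alpha_N (PF05436) domain hit at E ≤ 10⁻⁵ (domain
tables are consumed from hmmscan `--domtblout`). It is flagged as a fungal
(or Basidiomycota) pheromone when its best local alignment against a
user-supplied FASTA of validated precursor peptides reaches E < 10⁻¹⁰ in
database mode over the query set; query sets are configuration, not
embedded data. Motif content rates report the fraction of repeat units
(8–100 aa) containing a substring motif (Y, HH, W) — the Y rate tracks the
tyrosine-ether cyclization chemistry of ustiloxin-type compounds.

The per-phylum census counts surveyed strains, strains with ≥ 1 KEP
("found"), genera, KEPs (and the DUF3328-accompanied subset), and the mean
and SD of per-strain counts. The mean divides total KEPs by *found*
strains and the SD is the sample (n−1) SD over found strains — the
convention that reproduces a two-strain phylum with counts {5, 7} printing
6.00 ± 1.41.

## Synthetic data

The generator plants every structure the pipeline measures and emits both
the files (FASTA, SignalP short table, gene-order TSV, domtblout, truth
JSON) and an exact ground truth; everything derives from one seed.

* **KEP precursors**: signal (built to the heuristic's rules) + spacer
  pro-region (10–16 aa) + Kex2 site + k × (unit + site) + tail (4–8 aa),
  k ∈ 3..12, units mutated from a family ancestor (8–30 aa, ancestors
  pairwise < 30% identical by rejection sampling) at 5% per residue by
  default. Substitutions that would create K/R adjacencies at unit
  boundaries or inside units are resampled, so planted unit intervals equal
  the detector's fragments exactly. The Kex2 motif is drawn once per
  precursor by default (real precursors conserve their processing motif
  across repeats); per-junction sampling is available. The spacer/tail
  flank the repeat region so the mask yields > 2 parts. Family experiments
  additionally share one unit count and one ancestral spacer/tail per
  family (orthologs inherit the whole precursor architecture, and
  independently drawn flanks would structurally break the 70% reciprocal
  coverage rule for small precursors).
* **Decoys**, one class per rejection mode: bad N-terminus (`no_signal`),
  random mature (`no_repeat`), units concatenated without dibasic
  separators in an entirely K/R-free mature (`no_kex2`), a planted
  101–150 aa inter-site fragment on an otherwise valid 6-unit precursor
  (`long_fragment`), 5–7 aa units (`short_units`), and k = 2
  (`few_units`). Decoy repeat units are exact copies: each class isolates
  a single rejection mode.
* **Gene orders**: one contig per strain; KEP genes placed ≥ 32 ranks
  apart and ≥ 16 from contig ends so the 15-gene windows of distinct KEPs
  never overlap and planted distances are recovered exactly. Each KEP gets
  a DUF3328 gene with probability 0.22 at a distance drawn from a
  truncated-geometric distribution on 1..15 with mean 3.09 (the decay
  ratio is solved by bisection); DUF3328-positive KEPs get a Tyrosinase
  gene at distance 2 with probability 0.5; 5% of the remaining genes carry
  a background transporter-like label.

What the generator does **not** emulate — and hence what green tests do not
show about real data: real signal-peptide sequence statistics (the file
path exists for real SignalP output), homology between decoys and KEPs,
overlapping gene neighborhoods and multi-contig assemblies, insertions and
deletions within repeat units (substitutions only), and the taxonomic
correlation structure of real strain collections.

## Validation battery and problem sizes

The seeded experiments in `kepmine.experiments` (run by the test suite and
by `scripts/acceptance.py`) use: 20 strains × (5 KEPs + 36 decoys) for
detection recovery at mutation 0 and 0.05; 6 families × 10 members for
type recovery (adjusted Rand index against truth, computed in-package and
cross-checked against scikit-learn, with stand-alones counted as
singletons); 500 KEP genes over 50 contigs for neighborhood recovery; and
200 random sequences plus tandem/50 alignment pairs for the two
oracle-equivalence checks. These sizes give tight binomial bounds (e.g.
SD ≈ 0.019 on the recovered DUF3328 fraction) while the whole battery runs
in well under a minute.

## Numerical and degenerate-input choices

* Mask comparisons are strict (`score > 0.6`), matching "greater than";
  the coherence count uses `cnt ≥ (2/3)·w − 1e−9` to keep the integer
  boundary (8 of 12) exact under floating point.
* Alignment tie-breaking among co-optimal alignments follows the
  deterministic enumeration order of the aligner; scores, identities and
  coverages are tie-invariant in all decisions the pipeline makes.
* Empty local alignments (best score ≤ 0) get identity 0, coverage 0,
  E = ∞.
* Sample SD of a single strain is reported as 0; motif rates of an empty
  unit list as 0; vicinity means are absent (`None`/empty cells) when no
  hits exist.
* Mature sequences shorter than 16 aa produce a degenerate all-false track
  with `n_seeds = 0` rather than an error.

## Known limitations

* The E-value model ignores composition bias and low-complexity masking;
  absolute E-values can differ from BLAST by orders of magnitude (decision
  thresholds are far from the regime where this matters on these data).
* The heuristic signal predictor is a rule mirror for simulation, not a
  predictor; its agreement with the generator is by construction.
* Repeat detection is gapless: indel-diverged repeats score only through
  their conserved frames and may be missed.
* Sub-type profiles are frequency matrices, not profile HMMs; they carry
  no position-specific gap model.
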