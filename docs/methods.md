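# Methods

## Scope and data model

`lcrevol` analyses one ortholog family at a time: an `OrthologGroup` holds
equal-length aligned sequences for a subset of a fixed ten-species panel
(human, chimpanzee, mouse, rat, Tasmanian devil, chicken, green anole,
tropical clawed frog, zebrafish, fugu — in that order, always). The panel
order is part of the data contract: every conservation profile string is
written and parsed in it. All user-facing coordinates are 1-based inclusive;
0-based half-open indexing exists only at numpy boundaries. The gap
character is `-` (`.` normalized on read), and an aligned sequence's
`CoordinateMap` is the strictly increasing bijection between its ungapped
positions and its non-gap columns.

## Detectors

**polyX.** A residue-type-specific sliding window: every window of
`polyx_window = 10` positions holding at least `polyx_min_count = 8` copies
of residue X is a candidate; candidates for the same X that overlap by one
position or abut are merged; the merged span is trimmed to the first/last X
inside it, so a reported homorepeat always starts and ends on its residue.
Sequences shorter than the window are scanned as one truncated window when
at least 8 residues long — a totality choice for degenerate input, not a
biological claim. Different residue types may produce overlapping regions;
there is no cross-type merging.

**CBR (CAST-style).** For each residue type X, the sequence is scored
position-wise against a homopolymer of X with BLOSUM62 and the
maximal-scoring segment is found with the running-sum-reset (Kadane) rule;
ties go to the leftmost segment. Segments scoring at least
`cast_threshold = 40` are emitted (ten alanines at +4, or eight glutamates
at +5, sit exactly at threshold), all copies of X inside the emitted
interval are replaced by a neutral symbol that scores 0 against every
target, and the scan repeats. Masking guarantees strictly decreasing
attainable score, hence termination — with one guard this implementation
adds: a threshold-reaching segment containing *no* copy of X (possible
because some residues score positively against X, e.g. S vs A or Q vs E) is
not an X-rich region, cannot be reduced by masking, and ends the iteration
for that residue type instead of being emitted. Masking is performed
independently per residue type (each type scans a fresh copy of the
sequence); a single progressively masked pass would couple overlapping
biases of different types in an order-dependent way.

**IDR.** Disorder calls consume a per-residue score profile in [0, 1]:
maximal runs of scores ≥ `idr_score_threshold = 0.5` that are at least
`idr_min_length = 30` residues long. The intended score source is an
external long-disorder predictor, ingested through a 3-column
(position, residue, score) adapter that cross-checks residues against the
sequence. The bundled fallback is explicitly *not* a disorder predictor
re-implementation: it maps the TOP-IDP propensity scale affinely from the
scale's range onto [0, 1] (per-sequence min–max normalization would
degenerate on homopolymers) and smooths with a centered 21-residue moving
average truncated at the ends. It exists so pipelines are testable without
an external tool; any fidelity claim about real disorder calls requires the
adapter. The 0.5 cutoff is the conventional disorder threshold of
[0, 1]-scaled predictors; sources that document a different operating point
should override it.

**CC.** Coiled coils are ingested as interval annotations and passed
through; no heptad-repeat prediction is attempted.

## Consolidation and conservation profiles

Per group and per feature kind, every feature is mapped to alignment
columns (interior gap columns are spanned, keeping intervals contiguous in
column space) and the union of covered columns is split into maximal
contiguous runs. Each run is one consolidated feature with a profile over
`{1, 0, -}`: `1` where the species has a feature of that kind overlapping
the run by at least one column, `0` where the species is present without
overlap, `-` where the species is absent from the group. One shared column
suffices for a `1` — the simplest reading of "the interval contains the
feature" — and runs separated by even a single uncovered column stay
separate. Kinds are consolidated independently; overlaps between kinds
(polyQ inside a Q-rich CBR inside an IDR) are preserved, since such
nesting is itself a finding. Consolidated coordinates are alignment
coordinates and are never back-projected onto the human sequence.

## Enrichment

The enrichment of feature-containing proteins in a foreground set against
a background proteome is the one-sided Fisher exact test: the inclusive
hypergeometric upper tail P(X ≥ k) with the background including the
foreground. The tail is accumulated as `logsumexp` of log-pmf terms, so
p-values far below double-precision pmf products (1e-30 and smaller) are
exact to machine precision; tails below the double range saturate at the
smallest positive float rather than underflowing to zero. Values are
cross-checked in the test suite against exhaustive rational-arithmetic
enumeration. Raw p-values are reported (matching how such scans are usually
published); a Benjamini–Hochberg column is written as optional extra
output but drives nothing.

## Co-occurrence and the HAP40-likeness cascade

Presence vectors are built from *raw per-sequence* features — one binary
entry per (kind, individual sequence), orthologs included — because
co-occurrence asks whether two kinds appear in the same molecules, not in
the same consolidated regions. The 42 kinds (IDR, CC, 20 CBR types, 20
polyX types) are compared all-against-all by the Jaccard score, with an
empty union defined as 0.

The cascade mines consolidated tables for the HAP40 signature:
(s1) any A-rich CBR; (s2) one conserved in at least
`min_conserved_species = 4` species, counting `1`s of the profile with the
human sequence included; (s3) at least one such region not overlapping any
consolidated polyA by a single column — a diffuse alanine bias explained by
a pure run is disqualified regardless of how conserved the polyA is;
(s4) the group also carries a consolidated polyP, regardless of its
conservation and position. Bordering of the polyP on the A-rich region is
deliberately *not* a filter: it is an observation to make on the survivors.
A group survives s3 if *any* of its qualifying regions is diffuse.

## IDR co-evolution

Each aligned sequence is reduced to a binary vector over columns — 1 at
columns holding a residue inside an IDR, 0 at ordered residues and gaps —
and every unordered species pair is scored by the Jaccard overlap of the
two vectors, giving a 45-entry profile per protein. A pair is
non-informative (serialized `NA`) exactly when a species is absent or both
vectors are all-zero; one empty side against a non-empty one is an
informative 0. Large proteins can be split into fragments specified in the
leading (human) sequence's coordinates and mapped to column ranges; IDRs
are predicted full-length and their column profiles sliced, so a disordered
run crossing a boundary contributes to both fragments, and fully gapped
slices stay in the group as empty profiles. The default Huntingtin
fragmentation (1–402, 403–970, 971–1330, 1331–2080, 2081–3142) follows the
disorder-bounded domain decomposition of the protein.

Profiles are clustered by complete linkage. The distance between two
profiles is Euclidean over the coordinates informative in both, rescaled by
`sqrt(45 / n_shared)` — the standard pairwise-deletion convention, chosen
over zero-filling because zero-filling makes missingness look like
dissimilarity. Rescaling leaves fully informative pairs untouched and is a
pseudo-metric there. A pair with no shared informative coordinate gets the
maximal attainable distance `sqrt(45)` (scores live in [0, 1]) with a
warning. Profiles are sorted by identifier before linkage so results are
input-order invariant; the number of flat clusters is a user parameter (no
principled cut rule is imposed). Dendrograms are exported as Newick.

## Synthetic data

The generator builds alignments in a shared column frame: plants and indels
are specified in columns, indels become per-species gap blocks, and no
aligner runs — removing aligner nondeterminism from tests. Plants are
deterministic patterns; only the background is random (uniform over the 20
residues by default, a human-like composition optionally):

- polyX plants are pure runs (purity 1.0) or runs diluted by
  negative-scoring fillers (purity < 1, for recall sweeps);
- CBR plants intersperse the biased residue at a Bresenham-even fraction
  ≤ 0.7 — never 8-in-10, so a diffuse bias cannot masquerade as a
  homorepeat — with fillers scoring exactly −1 against the residue, making
  the planted segment score an exact function of the bias;
- IDR plants only touch the emitted disorder score files (0.9 inside, 0.1
  outside by default); CC plants only touch the annotation table.

Two conditioning steps make planted truth exact rather than approximate:
plant flanks are insulated (no residue scoring ≥ 0 against the planted
residue within 10 columns), and the background is rejection-resampled until
the scanners find nothing outside the plants — random sequence genuinely
contains compositional bias at useful rates (four tryptophans within five
positions already score 41), and an un-scrubbed background would
contaminate precision measurements. Both steps are deterministic under the
plan seed; generation is byte-reproducible.

The truth table (expected per-sequence features, consolidated intervals and
profiles, presence entries, cascade stage) is derived from the plan by
column arithmetic, never by calling the detectors; implied features are
accounted for (a pure polyX run of length ℓ is also a CAST-detectable CBR
when ℓ × diag ≥ 40). Plan validation enforces ≥ 20 columns between
residue-touching plants of the same species so planted signals stay
independent. Recovery metrics match intervals at reciprocal overlap ≥ 0.9,
require exact profile strings, and score clusterings by the plain Rand
index.

What the generator does *not* emulate: phylogenetic substitution processes,
tree-correlated indels, sequencing/annotation artifacts, and the real
covariance structure of LCR occurrence across a proteome. Passing recovery
tests therefore demonstrates the correctness of the pipeline's bookkeeping
and statistics on controlled input, not detector accuracy on real
proteomes.

## Problem sizes and numerical choices

The bundled demo corpus is six 10-species groups of 400 alignment columns —
enough to exercise every cascade stage and all feature kinds while keeping
the default test suite in seconds. Oracle-equivalence tests cover every
sequence length up to 50 exhaustively for the polyX scanner, quadratic
substring enumeration for the maximal-segment rule, and rational-arithmetic
enumeration for hypergeometric tails up to population 60. Presence-matrix
targets are validated at 2000 columns (±0.03 sampling tolerance for a
Jaccard target of 0.25). Kadane ties break leftmost; feature tables are
sorted on (group, sequence, kind, start) so every output file is
deterministic byte-for-byte under a fixed config and seed.

## Known limitations

- CAST region boundaries follow the maximal-segment formulation; the
  original tool's exact boundary conventions are not publicly specified, so
  region-level counts on real corpora may differ slightly even where calls
  agree.
- The per-type masking choice (vs one progressive pass) can differ from the
  original tool on sequences where biases of different types overlap.
- Enrichment p-values computed from published contingency tables can
  disagree with published values when the underlying proteome snapshot
  differed; the exact test here is the auditable ground truth for the
  counts it is given (see the test suite for a worked instance).
- The disorder fallback is a smoothed propensity scale; its calls correlate
  with, but do not reproduce, energy-model predictors.
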