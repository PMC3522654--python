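# Methods

This note records the models, conventions and parameter choices behind
`retrohome`, in the order the pipeline applies them.

## Sequence model and coordinates

All genomic intervals are 0-based half-open on the forward strand of a
named replicon; GFF3 output converts to 1-based inclusive. Input sequences
are uppercased and every non-ACGT letter (IUPAC ambiguity codes included)
collapses to `N`. `N` is treated conservatively everywhere: it never
counts as an identical site in alignments and never satisfies a consensus
position, including a consensus `N` (which accepts only real bases).
Circular replicons are handled by appending the first *L*−1 bases
(*L* = query or motif length) before scanning; hits are reported with the
start normalised into `[0, replicon length)` and duplicates from the
wrapped region removed, including fragments of a wrapped hit re-surfacing
at the origin.

## Local alignment search

Detection and flank comparison use one engine: exact k-mer seeding
followed by affine-gap Smith–Waterman restricted to the seeded windows.
The contract is identity-over-length rather than e-value based: a hit is a
maximal local alignment with identity ≥ `min_identity` over ≥ `min_length`
subject bases.

Scoring: match +1, mismatch −2, gap open −5 (cost of the first gap
column), gap extend −2 for nucleotides; BLOSUM62 with gap open −11 /
extend −1 for proteins. "Similarity" of a hit is identical columns over
all aligned columns (gaps in the denominator), matching the BLAST notion
of identity; the gap-excluded identity (identical / substitution columns)
is kept separately and drives the 10%-divergence naming rule.

Determinism and tie-breaks, shared verbatim by the pure-Python validator
in `retrohome.validation`: the reported alignment ends at the
highest-scoring DP cell, ties broken by smallest subject end then smallest
query end; traceback prefers diagonal over the subject-consuming gap over
the query-consuming gap. Non-overlapping secondary hits come from
iterating: report the optimum, mask its subject footprint, re-run until
the best score drops below `min_score`.

Two performance devices preserve exact agreement with full-matrix DP:

* a score-only rolling pass locates the best cell first; the traceback
  matrix is then built only over a window of 3×(query length)+64 subject
  bases ending at that cell. With these penalties any positive-scoring
  local alignment spans < 1.5× query length of subject, and every cell a
  traceback can visit or consult lies within twice that of the end cell,
  so the windowed pass reproduces the full-matrix alignment exactly;
* oversized seeded windows are split into 8 kb chunks overlapping by twice
  the query length, and duplicate hits from the overlaps removed.

Defaults: k = 8 (k ≥ 8 enforced), `min_identity` 0.60, `min_length` 50 bp,
`min_score` 20 for the raw search — deliberately permissive so that the
100 bp / 75% detection filters, not the search, decide what is reported.
Flank comparisons use k = 16: flank matches of interest are ≥ 80%
identical over ≥ 500 bp, where 16-mer seeds are abundant, and longer seeds
make genomes with no shared flanks essentially free to reject. The
protein search translates all six frames and projects hits back through
the reference ORF to genomic and reference-nucleotide coordinates.

The second detection round re-screens with round-one copies as queries.
Known copy footprints are N-masked first: hits fully contained in
detected copies would be dropped anyway, and masking avoids re-aligning
every query to every known locus. Identical copy sequences are queried
once. Copies found only in round two have their identity to the original
reference measured by re-alignment, since their hit statistics refer to
the round-two query.

## Detection filters and classification

Overlapping detections (nucleotide and protein pooled) are clustered by
single-linkage on ≥ 1 bp genomic overlap, strand-agnostic; the hit with
the most identical sites is kept (ties: higher similarity, then leftmost
start) and the rule recurses on the non-overlapping remainder. Detections
shorter than 100 bp of genomic footprint are discarded, as are nucleotide
detections below 75% similarity — both strict inequalities, so a 100 bp or
exactly-75% detection survives; protein detections are exempt from the
similarity rule.

A copy is FULL_LENGTH when its merged alignment reaches within
`edge_slack` = 15 bp of both reference ends, or when both boundaries are
confirmed by its immediate flanks aligning contiguously (gap ≤ 15 bp)
across the insertion point of an intron-free homologous locus. Retained
same-reference, same-strand hits closer than 200 bp merge into one locus.

ORF integrity (full-length copies only): the copy must contain an
uninterrupted reading frame (ATG/GTG/TTG start to stop) overlapping at
least 90% of the reference ORF's projection and reaching at least 90% of
the reference ORF length. A frameshift or premature stop fails both.

Names: a copy within 10% nucleotide divergence (gap-excluded) of its
reference keeps the reference name; beyond that it receives
`<strain>.I<n>` with a per-genome counter, assigned deterministically and
idempotently in detection order.

## Orthology

Both 3 kbp flanks of each copy (genomic forward orientation; truncated at
linear replicon ends, wrapped on circular ones) are aligned against every
other genome of the same genus/complex at ≥ 80% identity over ≥ 500 bp.
A pair is ORTHOLOGOUS when a flank covering its junction-proximal end
(within 20 bp) lands within 20 bp of a subject copy's junction;
RETROHOMED when both flanks land adjacently (gap within ±20 bp, absorbing
target-site duplications) with no intron copy between; UNRESOLVED
otherwise. Orthologous calls take precedence, and the 20 bp values are
declared choices — the underlying studies quantify none of them.

Orthology is closed transitively: connected components (union-find) of
the orthologous relation partition each genus's copies into distinct
elements; copies without orthologous calls are singletons. Manual synteny
inspection of large mobile elements is replaced by an explicit override
table (genome, replicon, position, subject genome) that reclassifies
listed pairs as DISTINCT_MGE before collapsing.

## Homing-site models

All consensus models live on a window around the insertion point,
default −25..+10 (35 columns, no position zero; the insertion point falls
after column 24). The −25..+10 default follows the figure-level
definition; the window is configurable where sources disagree.

* **EBS consensus**: IBS1 occupies the columns immediately 5′ of the
  insertion point (reverse complement of EBS1 under Watson–Crick pairing),
  IBS2 immediately 5′ of IBS1, IBS3 the first column 3′. Pairing accepts
  G·U wobble: EBS G pairs target T as well as C, EBS U/T pairs target G as
  well as A. Each EBS column takes the wobble-consistent majority base of
  the observed flank windows (ties → N; no consistent base → strict
  Watson–Crick complement). When a reference flank is supplied, non-EBS
  columns identical across *all* windows and the reference are fixed too;
  everything else is N.
* **Conservation consensus** (unknown EBS): with ≥ 5 windows, a column is
  fixed to its modal base when its frequency reaches 0.8, else N.
* **Class C**: EBS1/EBS3 only; matches count only when gated by a
  Rho-independent terminator (below). The reference-flank extension rule
  is applied to class C too when a reference flank is available — the
  terminator gate stays the biological filter, the extension pins the
  site numerically.
* **IS-context similarity**: the 90 bp around a known insertion site
  (45 bp each side — the split is a declared choice) is re-found by local
  alignment at ≥ 90% identity over ≥ 72 bp (80% of 90), counting only hits
  that cover the integration junction.

Consensus scanning requires a perfect match at every fixed position, both
strands, wrapping circular origins; an all-N consensus is rejected.

## Terminator finder

A Rho-independent terminator is an inverted repeat with stem 5–18 bp
(Watson–Crick or G·T wobble rungs, at most one other mismatch), loop
3–10 nt, followed within 3 nt by a U-rich tract (≥ 5 T in the next 8
bases; the best window over the allowed gaps defines the tail score).
Every stem/loop/start combination is tested (vectorised per combination);
hits strictly contained in a same-strand hit are dropped unless maximality
is disabled. Class C sites must start (first fixed consensus column)
0–20 nt 3′ of a stem-loop end on the same strand. User-supplied terminator
intervals can stand in for or extend the detector. The detector is
deliberately permissive; in random sequence it fires often, which is why
class C gating is paired with the extended consensus above.

## Occupancy

Each detected copy of a model's intron contributes one OCCUPIED record at
its 5′ junction. A scanned candidate whose insertion point falls within
3 bp of such a junction merges into it; candidates strictly inside any
intron copy are removed; the rest are AVAILABLE. The full-length occupancy
row for (intron, genome) is `full-length copies / (full-length copies +
available)`, in percent, rounded half-up (forced by the printed tables:
1/(1+7) → 13). The fragment table uses sites available *at the time of
fragment acquisition*: current available plus sites now occupied by
full-length copies. Zero sites overall → an UNDEFINED cell, printed
blank. One published fragment row (1 occupied / 4 available printed as
50%) contradicts the formula that reproduces all other rows; it is
excluded from regression and flagged, never corrected.

The strains-vs-abundance test is a chi-square goodness-of-fit of observed
copy (or distinct-element) counts per genus against expectations
proportional to sequenced-strain counts, df = genera − 1. The published
analysis names only "Chi square test"; since the exact table the authors
built is not recoverable, p-values are reported but never asserted against
the published ones. MLST divergence is the mean over unordered strain
pairs of the p-distance on third codon positions of the concatenated
aligned genes, skipping columns with a gap or ambiguity in either
sequence (complete pairwise deletion — the deletion mode is a declared
choice), with outgroup strains excluded before averaging.

## Synthetic populations

The generator emulates exactly the structures the pipeline must recover:
i.i.d. background chromosomes at a configurable GC content; planted
full-length copies sitting precisely at site insertion points (the 35 bp
site context, whose IBS columns pair with the intron's EBS); free sites as
intact contexts; class C sites and copies placed 8 nt behind a canonical
planted terminator (GC-rich 8 bp stem, 4 nt loop, 8 T tail); IS elements
carrying the 90 bp context of IS-targeting introns; orthologous copies
sharing identical 3 kb flanks across strains; intron-free counterpart loci
for retrohoming calls; 7 kb islands planted at different loci in two
strains for the override scenario; and decoy terminators. Divergence is
substitution-only with an exact count of changed positions, which keeps
identity arithmetic exact; the outer 3 bp of planted elements are left
unmutated and fragments get mismatching guard bases so local alignment
cannot trim or extend a planted boundary by chance. Site contexts are
identical across the planted occurrences of an intron, so the consensus
builders recover the full 35-column motif and genome scans are specific
(a 35-fixed-base motif has no chance matches at these genome sizes).

What the generator does *not* emulate — and passing tests therefore do not
demonstrate on real data: phylogenetic background divergence between
strains, repeat families beyond the declared IS specs, indels, gene
conversion between copies, compositional bias around real terminators,
and degraded sites. The false-discovery check (zero detections in a 1 Mb
intron-free random genome) is meaningful precisely because the background
is repeat-free.

Default study conditions used by the tests and the acceptance script: one
150 kb strain with 26 full-length copies and 17 free sites (EBS scheme);
one 120 kb strain with 2 class C copies and 17 terminator-gated sites plus
5 decoy terminators; six 80 kb strains with orthology groups of sizes
3/2/2/2, three retrohoming loci and one island transfer. These sizes keep
each survey in tens of seconds while leaving every planted structure
individually resolvable.

## Known limitations

* No e-value statistics; sensitivity at high divergence (> ~25% from the
  nearest query) depends on exact k-mer seeding and is not guaranteed.
* Protein-level search ignores frameshifts within one hit (each frame is
  searched independently).
* Orthology is pairwise-evidence-based and made transitive by components;
  conflicting evidence inside a component is not re-examined.
* The terminator model is a motif detector, not a thermodynamic one; no
  RNA secondary-structure free energies are computed.
* The W3110-style inconsistency handling, the chi-square construction and
  the −25..+10 window are declared conventions where the sources are
  silent or self-contradictory; each is configurable.
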