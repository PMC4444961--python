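# Methods

## The presence criterion

A mature miRNA is scored **present** in an assembly iff the genome contains
a full-length exact match of the mature sequence on either strand. This is
a deliberately strict criterion: mature miRNAs of 18–24 nt are often
perfectly conserved over long phylogenetic distances, so an exact match is
a meaningful homology signal at this length scale, and exactness makes the
call binary and reproducible. The scanner therefore does not use a local
aligner: all queries (and their reverse complements) of a given length are
packed into 2-bit integer codes, every contig window is packed the same way
with numpy, and membership is a set lookup. Windows containing any
non-ACGT character are invalid — an `N` can never support presence, even
when an ambiguity code would be compatible with the query (a config-level
choice: "exact" is read literally). Soft-masked lowercase sequence is
scanned normally, because assembly masking marks repeats, not absence.
Overlapping and self-overlapping occurrences are all reported; minus-strand
hits carry forward-contig 0-based half-open coordinates. An optional
`max_mismatches` (default 0) adds Hamming-distance matches for sensitivity
analyses only; the default reproduces the strict criterion.

## Catalog construction

miRBase mature FASTA stores RNA; genomes store DNA, so queries are
converted U→T at load — the exact-match criterion is only meaningful in one
alphabet. Sequences outside 16–30 nt or with non-RNA/DNA characters are
rejected loudly, naming the record. Identical matures pooled from several
source species (or from paralogous loci with identical products) collapse
to one query; genomic multiplicity is recovered from hit counts, not from
catalog duplication. The canonical name of a merged entry follows a species
precedence list (default `ame > nvi > dme`, honey bee first, because
candidates are conventionally reported under `ame-` names). Family
assignment is regex-based on miRBase naming (strip species prefix, `-5p/-3p`
arm, trailing paralog letters and duplicate-locus numerals); unrecognized
dialects raise rather than silently mis-group.

## Profile matrix conventions

The central object is a complete miRNA × genome 0/1 matrix with hit counts
retained as cell provenance. Display and screening use two conventions:

* **Informativeness filter** — rows present in every genome of the panel,
  or in at most one, carry no grouping signal and are dropped. The filter
  is applied per panel: a row uninformative on a seven-genome panel can be
  informative on the 24-genome panel.
* **Tree ordering** — columns are fixed to the species tree's left-to-right
  leaf order and rows are sorted lexicographically by their presence
  pattern (presence sorting first, ties broken by name). This
  "clustering by phylogeny" is a deterministic convention, not a
  distance-based clustering: fixing the species axis to the phylogeny is
  the point of the display, and determinism makes runs reproducible.

## Parsimony reconstruction

Each matrix row is a binary character on the rooted species tree
(polytomies allowed). Three reconstructions are computed:

* **Fitch** (`fitch_min_changes`) — minimum number of state changes over
  all ancestral assignments, regain after loss allowed. Implemented as
  unit-cost dynamic programming rather than set-based Fitch because the DP
  is exact on polytomies without binarization. The root state is free and
  changes are counted on tree branches only, so a constant character costs
  zero. Among co-optimal assignments the reported one keeps the parent's
  state on ties (DELTRAN-like: events pushed toward the tips, i.e. gains as
  late as possible); nodes whose state differs between optima are flagged
  ambiguous via an exact second pass over achievable states.
* **Dollo** (`dollo_reconstruct`) — exactly one gain, placed on the branch
  entering the MRCA of all present leaves (the virtual root stem when that
  MRCA is the root), plus the minimal loss set: below the origin a node is
  present iff some descendant leaf is present, which yields one loss per
  maximal absent subtree and is provably minimal. All-absent characters
  are rejected (no origin to place).
* **Independent gain count** (`count_independent_gains`) — weighted
  Sankoff-style DP with the **root prior fixed to absent** and a virtual
  root-stem branch: these catalogs are lineage-annotated miRNAs, so
  presence at the base of the panel is itself an origin worth counting
  (an all-present character counts one gain on the root stem). The count
  reported is the minimum number of gains among all minimum-total-cost
  assignments, computed by tracking (cost, gains) lexicographically per
  node and state; it is independent of event tie-breaking. Unit costs by
  default; `gain_cost`/`loss_cost` are configurable and must be positive.

The two root conventions coexist on purpose: Fitch answers "how many
changes at minimum" in the classical sense (and its trivial cases — e.g.
constant characters at cost 0 — behave as practitioners expect), while the
gain count and Dollo place origination events explicitly. A consequence to
be aware of: Dollo's cost includes the origin, so Dollo cost ≥ Fitch cost
always holds, with equality impossible for constant-present characters.

## Trait screens

Trait labels are three-valued: positive (eusocial), negative (solitary),
**neutral** for facultatively social species. The neutral label exists
because a facultative species neither confirms nor refutes an association
with obligate trait expression: trait-exclusive candidates must have zero
presences in negative genomes and at least `min_positive` (default 1; the
informativeness filter already removes singletons) in positive genomes,
while neutral cells are ignored entirely — the screen's output is invariant
under arbitrary rewriting of neutral columns, and a test asserts exactly
that. Clade screens intersect clade membership with the panel at hand,
since a panel may sample only part of a clade. `clade_universal` demands
presence in at least (clade size − tolerance) members and absence outside;
tolerance 0 is the strict "present in all, absent elsewhere" criterion.
The convergence summary reports, per miRNA, the minimum independent gain
count, the Fitch loss count, and how many Fitch gain branches lead into
subtrees whose labeled leaves are all positive-or-neutral; no significance
test is attached — the screens are combinatorial filters, not hypothesis
tests.

## The packaged fixture

Re-running the original 24-assembly scan requires genome downloads, so the
package ships a matrix fixture encoding the published distribution facts
for the eleven candidate miRNAs, plus eight interpolated background rows
(deeply conserved, outgroup-restricted, and clade-concordant patterns) that
keep the screens non-trivial. Every cell carries a provenance tag:
`reported: <fact>` when it follows from a stated distribution, or
`interpolated` when filled phylogeny-concordantly — the two are
machine-distinguishable and a test checks the packaged TSVs stay in sync
with the in-code builder. Three interpolation choices are worth noting:

* miR-281, miR-306 and miR-279c are categorized as unique to Hymenoptera
  but, unlike miR-6065, not unique to Aculeata; each therefore needs at
  least one presence in a non-aculeate hymenopteran. The two non-starred
  parasitoid sister species (*N. longicornis*, *N. giraulti*) are the
  phylogeny-concordant choice, and they lie outside the starred panel, so
  the initial-panel screens are unaffected.
* The trait-exclusive screen reproduces the five candidates on the
  **starred (initial) seven-genome panel**, where the only non-hymenopteran
  column is *D. melanogaster*. On the extended panel miR-279d is present in
  non-dipteran outgroups (all solitary), so it cannot be trait-exclusive
  there; the extended panel contributes the refinement facts
  (Hymenoptera-uniqueness, the *P. dominula* losses, the *L. albipes*
  presences) rather than the screen itself.
* The species phylogeny is encoded with an outgroup ladder and a
  vespid + formicoid + apoid structure inside Aculeata; internal resolution
  beyond the three clade handles the screens use (Hymenoptera, Aculeata,
  Vespidae) does not affect any screened quantity.

Trait labels follow the species table: 11 eusocial-positive species,
*L. albipes* neutral, 12 negative.

## Synthetic data

The simulator emulates exactly the structure the analysis assumes and
nothing more:

* **Presence evolution** — per miRNA, a root state drawn with
  `root_presence_prob` (default 0.5), then a two-state continuous-time
  gain/loss process down each branch using the closed-form transition
  probabilities (`gain_rate`, `loss_rate` per unit branch length, defaults
  0.5/0.5 on trees with mean branch length 0.5 — enough turnover that
  characters are informative but not randomized). A root drawn present is
  logged as a root-stem gain so the event log alone determines every leaf
  state.
* **Genomes** — one contig per species of i.i.d. nucleotides at
  `gc_content` (default 0.42, a typical insect genome-wide value), with
  each truly-present mature (fixed random 22-mers, collision-checked
  against each other and their reverse complements) planted once at a
  uniform non-overlapping position and strand. Backgrounds are
  rejection-sampled: each genome is re-scanned and redrawn in the
  astronomically unlikely event a catalog sequence arises by chance or by a
  planting junction, so recovery tests are exact rather than probabilistic
  (the per-panel chance-collision probability is also reported).
* **False negatives** — `fn_rate` vetoes planting per (miRNA, genome)
  cell, not per occurrence, matching the genome-level concern that a
  low-coverage assembly simply lacks the locus. Vetoed cells are recorded
  so calibration is testable: at `fn_rate` 0.2 the recovered miss fraction
  must sit within binomial error of 0.2.

What the simulator does **not** model: repeat content, isochores, assembly
gaps with positional structure, sequence divergence of the matures
themselves, or correlated loss across related species. Passing recovery
tests therefore demonstrates the scanner/caller machinery is exact on the
stated generative model — not that real assemblies have no false negatives
(they do, which is why `fn_rate` exists and why the screens tolerate
configurable thresholds).

All randomness flows from a mandatory integer seed through numpy
`SeedSequence` spawning; identical seeds give byte-identical panels.

## Problem sizes and determinism

The test and acceptance workloads are sized for a laptop-class single CPU:
1,000 randomized scanner trials against a naive oracle; exhaustive
parsimony enumeration on all characters of a fixed 8-leaf tree and 100
random topologies of ≤ 8 leaves (polytomies included); 10,000 random
characters for the Dollo/Fitch dominance check; and 20 simulation seeds of
50 miRNAs × 10 species × 200 kb genomes for end-to-end recovery, run at
false-negative rates 0 and 0.2. Pipeline outputs contain no timestamps
(the human-readable summary isolates its timestamp to one header line), so
two runs on identical inputs are hash-identical.

## Known limitations

* Presence calling is purely sequence-exact; a single substitution in an
  otherwise conserved mature scores absent. This understates presence in
  distant species and is the main reason the profile should be read
  together with the false-negative caveat.
* Absence is two-state; low-coverage assemblies arguably deserve a third
  "unknown" state. A three-state matrix is deferred by design.
* The parsimony layer is rate-free: the simulator uses branch lengths, but
  reconstruction deliberately does not, matching the narrative style of
  gain/loss arguments the screens support. No likelihood model of gain/loss
  and no formal phylogenetic comparative test (e.g. correlated-evolution
  likelihood ratio) is included; the convergence summary is descriptive.
* The fixture encodes printed distribution facts, with unconstrained cells
  interpolated; it is a worked example and regression anchor, not a
  substitute for rescanning the underlying assemblies.
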