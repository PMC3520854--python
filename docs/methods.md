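# Methods

## Classifier

The classifier is the classical word-presence naive Bayes model for rRNA
taxonomy.  A sequence contributes the *set* of overlapping words it
contains — multiplicity is deliberately ignored, both in training and in
scoring, because presence/absence statistics are what make the model
robust to the wildly varying copy numbers of short motifs in rRNA.  Words
overlapping any non-ACGT character are skipped rather than expanded into
their IUPAC possibilities; ambiguity codes are rare in curated references
and expansion would let a single `N` inject spurious word mass.

With `N` training sequences, of which `n(w)` contain word `w`, and `m(w)`
of the `M` sequences of genus `G` containing `w`:

- word prior: `prior(w) = (n(w) + 0.5) / (N + 1)`
- genus conditional: `P(w|G) = (m(w) + prior(w)) / (M + 1)`
- read score: `score(G) = Σ log P(w|G)` over the read's distinct words.

The pseudo-counts keep every conditional strictly positive, so a genus
whose training sequences share no word with a read still receives a
finite (very negative) score and no comparison ever involves `-inf`.
Genera are identified by their Genus-rank display label; training
validates that a genus label never appears with two different lineages.
All argmax ties break toward the lexicographically smallest genus
identifier, which costs nothing and makes every result reproducible.

Parameters: `word_size` defaults to 8 (the standard choice for this model
family; 4 is used in tests where brute-force enumeration must stay cheap).
The scoring matrix is held dense over all `4^w` words (`G x 65536`
float64 at the default), which keeps classification a single fancy-index
and sum.

## Bootstrap confidence

Each of `trials` (default 100) bootstrap trials draws `max(1, V // 8)` of
the read's `V` distinct words uniformly *with replacement* and classifies
on that subsample.  The reported genus is the one winning the most trials
(ties lexicographic).  Confidence at rank `r` is 100 x the fraction of
trials whose winner shares the reported genus's ancestral path down to
`r` — counted on full path prefixes, not bare labels, so that a family
label reachable through two different orders cannot inflate family
confidence, and ancestor confidence ≥ descendant confidence holds by
construction.  The subsample-of-one-eighth-with-replacement scheme is the
published convention for this classifier family; the seed is a required
parameter everywhere randomness enters.

The reporting threshold (default 60%) scans Domain to Genus and replaces
the first rank with confidence strictly below the cutoff, and every
deeper rank, with the sentinel `unclassified` (confidence equal to the
cutoff passes).  Confidences are retained after truncation so aggregate
statistics remain recomputable from the classification table alone.

## Custom-database construction

The pipeline is length filter → dereplication → nearest-cultured-hit →
placement rule.

- The length filter keeps candidates of ungapped length ≥ 1250 bp
  (inclusive — "at least").
- Pairwise identity is computed from a global Needleman–Wunsch alignment
  with match +1, mismatch −1, linear gap −2, as matches over alignment
  columns after trimming terminal gap columns; this lets a short fragment
  score 100% against a full-length sequence it matches exactly.  Any
  consistent metric would serve; this one is simple, symmetric, and
  recorded in the provenance report.
- Dereplication (99%) and OTU generation (97%) share one greedy centroid
  clustering: sequences are processed longest-first (ties lexicographic by
  id, favouring full-length representatives), each joining the first
  representative in founding order with identity ≥ the threshold.  In the
  well-separated regime (cluster margins ≥ 2% from the threshold) this
  reproduces the all-pairs connected-components partition; near the
  threshold the greedy result is order-dependent and only determinism is
  promised.
- Placement: a cultured hit strictly above 95% identity lends its full
  genus-level lineage.  At or below 95% the candidate is placed in the
  hit's domain and phylum with the user-supplied class, and everything
  below Class is flagged *incertae sedis*: a supplied clade name (e.g.
  `gamma-1`, `firm-4`) occupies Family, a retained prior genus name (as
  for a named isolate inside a habitat-specific clade) occupies Genus,
  and remaining ranks take placeholders named after the deepest assigned
  label.  Clade membership is an input (`clade_map` TSV), not computed:
  it encodes a phylogenetic analysis and taxonomic judgement that no
  algorithm here should pretend to make.

Incertae-sedis serialization: in memory the flag is a boolean and labels
never carry the `_incertae_sedis` suffix; the taxonomy writer appends the
suffix for flagged ranks and the reader strips it back, so files are
byte-stable across write/read/write and in-memory objects round-trip
exactly.  Taxonomy lines with fewer than six ranks are padded downward
with flagged placeholders named after the deepest named label; more than
six ranks is an error (sub-ranks are not modelled).

## Congruence evaluation

A `ClassificationTable` holds every (query, training set) classification
at one cutoff.  For the congruence and pairwise-agreement statistics, the
taxon a set reports at rank `r` is its full ancestral path down to `r`: a
genus name reached through different higher ranks is a different
classification.  This is the only reading under which "congruent at a
deeper rank" implies "congruent at every shallower rank", making the
congruent count non-increasing from Domain to Genus a theorem rather than
an empirical observation.  The `unclassified` sentinel collapses to a
single distinct label: two sets both reporting it are equal as labels
(which matters for the all-mutually-different count) but never count as
agreement.  Per query and rank the three categories — all sets agree on a
non-unclassified taxon / all pairwise differ / anything else — partition
the query set exactly.

A read counts as unclassified *overall* for a set when even its Domain
rank is below the cutoff; since every scenario here is single-domain,
that count is structurally zero and the per-rank unclassified counts
(Family in particular) are the informative ones — they are what the
augmentation experiment reports.  Mean bootstrap confidence per family
groups each set's reads by that set's own family display label (heat-map
style rows), not by any reference truth.

## Synthetic scenarios

The generator emulates the statistical structure of a hypervariable-region
amplicon study, not its biochemistry.  A uniform-random root sequence is
mutated down the hierarchy with per-rank substitution fractions (defaults:
2% within genus, 8% between genera, 15% between families, 25% between
phyla — strictly increasing with rank distance, giving mean pairwise
identities that separate cleanly at every rank).  Class is 1:1 with phylum
and Order 1:1 with family, so the branching ranks are Phylum, Family and
Genus.  Defaults: 4 phyla x 2 families x 2 genera (16 genera), 5
references of 1300 bp per genus, 500 reads of 250 bp excised from
positions 20–340 (a V1/V2-like forward-oriented window), 0.5% per-base
substitution error.  Evolution is substitution-only: no indels, no
chimeras, no homopolymer error model, no abundance skew.  Passing tests on
these data therefore demonstrate the correctness of the pipeline's logic
and the qualitative training-set effects, not classifier accuracy on real
pyrosequencing reads.

The novel-clade scenario removes four of the sixteen genera and offers
them as the custom database.  The default choice is all four genera of one
seeded-chosen phylum: holding out genera that leave same-family or
same-phylum siblings behind does not model an under-characterized habitat
— the nearest surviving family absorbs the reads confidently and
augmentation has nothing to fix.  Each of the three base sets drops a
distinct third of every remaining genus's references (per-genus
round-robin after a seeded shuffle, with the uneven remainder rotated
across genera so set sizes balance and every genus stays represented), and
renames all labels above genus through its own recorded, invertible
dialect map (`label@dbA` etc.), emulating the disagreeing taxonomic
frameworks of independently curated databases.  Reads are drawn with 50%
enrichment for holdout genera.  All streams (references, reads, holdout
bookkeeping) derive from the one scenario seed through independent
`SeedSequence` spawns, and identical configurations produce byte-identical
outputs.

## Problem sizes

The standard experiments run at their full configured sizes: 500 reads
against the complete 80-reference training set for the recovery
experiment, and 500 reads against six training sets (three base, three
augmented) for the augmentation experiment — about 3,500 bootstrap
classifications in total, a few seconds end to end.  Test oracles use
word size 4 and reads of 30–60 bp so that brute-force enumeration stays
exact and cheap; the Monte-Carlo check of the bootstrap compares against
an independent 100,000-trial re-simulation on a toy model.

## Known limitations

- No reverse-complement scanning: reads are assumed primer-oriented.
- No alignment-based or phylogenetic-placement classification; clade
  membership for the database builder must be supplied.
- The identity metric is one fixed global-alignment convention; identities
  near a clustering threshold can differ from other tools' metrics.
- Greedy clustering is order-dependent near the threshold (deterministic,
  but not the unique optimal partition).
- The read simulator's error model is uniform substitution only.
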