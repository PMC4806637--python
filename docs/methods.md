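# Methods

This note documents the models, conventions and numerical choices behind
`metevent`, and what its synthetic benchmarks do and do not demonstrate.

## Annotation schema and standoff dialect

Documents are abstracts/titles with two entity types — gene-or-protein
(`GP`) and `Metabolite` — and four trigger-anchored event types:
production, consumption and reaction (Theme: metabolite, Cause: enzyme)
and positive regulation (Theme: another event, Cause: enzyme).  Substrates,
products, co-factors and co-enzymes are all treated as metabolites; GP
mentions acting as event causes (or listed in an enzyme gazetteer) are
treated as enzymes.  Causes may be absent on any event: texts frequently
describe a transformation without naming its catalyst.

Standoff offsets are counted in Unicode code points, 0-based and
end-exclusive, which keeps spans stable through write/read round trips
regardless of multibyte characters.  Multiple arguments of one role use
numbered slots (`Theme`, `Theme2`, ...).  Event triggers are written as T
lines typed with the event type; on input, any non-entity T type is
accepted as a trigger (some corpora type triggers with dedicated names),
because the E line carries the event type.  The downloadable corpora in
this domain do not document their exact multi-theme dialect, so the
encoding above is declared rather than inferred.

For `Metabolic_reaction` events with exactly two themes, theme order is
meaningful by convention: first product, then substrate — the "formation
of X from Y" reading.  The schema itself does not distinguish substrate
and product themes, so this positional convention is this package's
design choice; it is produced by the extractor's reaction pattern and
consumed by the network module's role assignment.

## Entity tagging

Gazetteer matching is case-insensitive after whitespace collapsing, and a
match may not begin or end inside an alphanumeric run — an entry `PL`
never fires inside `PLP`, which guards against the abbreviated-metabolite
false positives that plague dictionary taggers.  Overlaps are resolved
longest-match-first, then leftmost, GP winning exact ties: a deterministic
single pass.  This dictionary stage is a transparent stand-in for a
machine-learned named-entity tagger; enzyme selection (Cause of an event,
or enzyme-gazetteer membership after normalization) replaces a manual
curation step and is therefore an automated approximation of it.

## Event extraction

The baseline extractor is deliberately simple and fully deterministic:

1. **Sentence splitting** — rule-based: a terminator run (`.!?`) ends a
   sentence when followed by whitespace plus an uppercase letter, digit or
   opening bracket/quote, unless the preceding word is a known abbreviation
   or a lone letter (so "E. coli K-12" stays intact).
2. **Long-sentence skip** — sentences with more than 100 tokens are
   dropped.  Tokens are whitespace-split; the original procedure counted
   parser tokens, which are unrecoverable without the parser, so the
   whitespace convention is a documented divergence.
3. **Trigger detection** — case-insensitive whole-word lexicon lookup.
   The shipped lexicon covers the small set of generic event words that
   dominate metabolic event descriptions (catalyzes/catalysis,
   biosynthesis/synthesis, formation, conversion, utilization, metabolism,
   plus morphological variants, production/degradation/amination) with a
   default event type per word.  Default types for ambiguous nouns
   ("synthesis" as production, "formation" as production unless the
   reaction pattern fires) are declared conventions, user-overridable via
   a TSV lexicon.
4. **Argument attachment** — pattern templates in precedence order
   (most specific first):
   - P1 `trigger of MetA from MetB [by GP]` → reaction, themes
     (product, substrate), optional cause;
   - P2 `Met trigger by GP` → trigger's default type, theme Met, cause GP;
   - P3 `trigger of Met by GP` → as P2;
   - P4 `GP trigger` for regulation triggers with a later event in the
     sentence → positive regulation, theme = nearest following event,
     cause GP; with no preceding GP the regulation is emitted cause-less
     (nominalizations such as "catalysis of ..." name no enzyme);
   - P5 fallback: nearest preceding metabolite as theme, no cause.
   A trigger with no candidate theme yields no event — the extractor never
   emits a schema-invalid annotation.  Adjacency is enforced through gap
   patterns (the text between anchor and argument must be exactly
   "of/from/by" plus optional articles), so an intervening mention breaks
   a pattern rather than mis-attaching.

The optional trailing cause on P1 and the cause-less P4 variant extend the
minimal template set; they are needed for reaction events with three
arguments and regulation events without a named enzyme, both of which occur
at known rates in real corpora (arguments-per-event means of 2.12 and 1.76).

The machine-learned event classifier used in the original workflow is not
reimplemented; the extractor sits behind a replaceable stage interface
(`run` accepts `--use-gold-entities`/`--use-gold-events`), so gold
annotations or an external system's standoff output can be substituted at
any stage.

## Network reconstruction

Each document's events become an *event interaction graph* (entities and
events as nodes, one edge per Theme/Cause slot).  Conversion rules R1–R5
distill interaction pairs: production → `produces` (role product),
consumption → `consumes` (role substrate), reaction → one `reaction` pair
per theme (roles from the product/substrate convention when exactly two
themes); positive regulation contributes no pair itself but propagates its
Cause into the regulated event, recursively through nested regulations,
*alongside* any explicit cause of the inner event (both enzymes yield
pairs).  A rule firing with no cause at all allocates a proxy enzyme
`PROXY_<k>`, numbered in first-appearance order across the run, so
bipartiteness is preserved and output is deterministic.  No published
pseudocode for this event-graph-to-interaction transformation is
available; rules R1–R5 are this package's own formulation of it.

Merging canonicalizes names (casefold, collapse whitespace, strip edge
punctuation, then a user-supplied synonym map — the replacement for
database-backed name resolution), pools provenance sorted and de-duplicated
(hence idempotent and order-insensitive), and keeps a role only when all
merged occurrences agree.  Proxy ids are never normalized or merged across
documents.  The bipartite network has one node per distinct enzyme
(including proxies) and metabolite and one labelled edge per merged pair;
an identical name on both sides raises a naming-collision error to be
resolved via the synonym map.  Conversions are the cross product, per
enzyme, of consumed × produced metabolites (substrate ≠ product).

## Evaluation

Entity matching is *sloppy* by default: same type and ≥ 1 shared
character.  The criterion is cited in the literature without a minimal
overlap threshold, so the weakest reading is used and the exact-span mode
is available as a flag.  Event matching requires identical type, trigger
span overlap, and at-least-one (`any`) or all (`all`) argument
correspondence; entity arguments compare sloppily, nested event arguments
recursively, and `all` demands a perfect one-to-one correspondence of the
argument lists.  Counting uses maximum-cardinality one-to-one matching
(Hopcroft–Karp) rather than first-come greedy: it is order-independent and
equals the brute-force optimum, which the test suite verifies exhaustively
on small span universes.

Micro-averages apply P/R/F to summed TP/FP/FN.  All-zero counts yield
(0, 0, 0) by convention.  Interaction sets compare on canonical
(enzyme, metabolite) keys, direction-insensitive by default (the curated
reference lists in this domain do not consistently orient interactions);
a direction-sensitive flag exists.

Cohen's kappa needs a shared item universe, which free-span annotation
does not define; the convention here is: unify the two annotators'
annotations by sloppy span overlap via maximum matching (entities by span,
events by trigger span), label matched items with each annotator's type
and unmatched items with type vs. `"none"`.  Published kappa values for
the original corpus are not reproducible without the original annotator
files and their (unstated) universe convention; only the formula and this
declared convention are testable.  When chance agreement is 1, kappa is
reported as 1 if observed agreement is 1 and is an error otherwise.

K-fold splitting shuffles the sorted document ids with a seeded
Fisher–Yates pass and deals round-robin, giving fold sizes within one of
each other (271 documents, k = 5 → 55/54/54/54/54).

## Synthetic corpus generator

The generator's defaults are the reference corpus profile: Poisson
per-document counts with means 7.00 metabolites and 9.27 GP mentions,
Poisson events per document with mean 1.77, the event-type mix
115 : 132 : 134 : 99 (production : consumption : reaction : regulation),
and per-type cause probabilities (0.10, 0.22, 0.12, 0.76) chosen so the
arguments-per-event means approach 1.10, 1.22, 2.12 and 1.76.  Because a
regulation sentence plants two events (the regulation and its nested core
event), sentence types are sampled from an analytically compensated
distribution (`q_pr = p_pr/(1−p_pr)`, core types scaled by
`(1−2p_pr)/(1−p_pr)²`) so the realized event totals and mix match the
configured proportions in expectation.  Entity totals are realized as
`max(Poisson target, entities used by event sentences)` with filler
sentences supplying the remainder; the truncation bias is ≪ 1 SE at the
default rates.  Nested core events always appear cause-less (their enzyme
arrives via regulation propagation), which pulls the core-type argument
means slightly below their configured targets; the means are validated by
sampling checks, not asserted exactly.

Every event sentence instantiates one of the extractor's own pattern
templates over synthetic name pools ("Alvanase", "belvinate", ... —
chosen to avoid gazetteer collisions and trigger words; a flag substitutes
real enzyme/metabolite names).  This makes the generator a *closed-loop
oracle*: the extractor provably recovers 100 % of planted events, and the
pipeline reproduces the generator's gold network exactly.  Passing these
checks demonstrates internal consistency of extraction, conversion,
merging and network assembly — not performance on real prose, whose
syntactic variety the templates deliberately do not model.  Corpus-scale
published F-scores (cross-validated event extraction, learning curves,
large-scale extraction counts) require the original corpus and trained
NER/event models and are out of reach at desk scale; the closed-loop,
brute-force-matching, parameter-recovery and invariant suites stand in
for them.

`perturb_annotations` deletes each annotation independently with
`p_miss` (cascading through dangling references), injects spurious
entities at word spans disjoint from all original annotations (so they are
guaranteed false positives), and shifts surviving spans whole by 1–3
characters with `p_shift` (all pool names are ≥ 7 characters, so sloppy
overlap is preserved while exact matching breaks).  Planted rates are
recovered as measured recall/precision within ±3 SE in the tests.

## Determinism and problem sizes

All randomness flows through explicit integer seeds (NumPy generators for
simulation, a seeded Fisher–Yates shuffle for folds); identical inputs,
configuration and seed give byte-identical outputs, including proxy
numbering and sorted TSV/SIF exports.  The test and acceptance runs use
deliberately small problem sizes — e.g. 100 generator seeds × 6 documents
for the closed loop, 200 documents for parameter recovery, exhaustive
matching oracles on ≤ 8 annotations — chosen because the checked
properties are size-independent (exact identities and invariants) or reach
sub-percent standard errors at those sizes.

## Known limitations

- The extractor handles the pattern inventory above; coordination
  ("... and also by the aspC- and avtA-encoded transaminases") attaches
  only the first enzyme, and implicit or precedence-dependent events are
  out of reach of surface patterns.
- Dictionary tagging cannot find names absent from the gazetteers and does
  not disambiguate species or abbreviations.
- Name normalization is purely orthographic plus the synonym map; no
  database-backed normalization is attempted.
- Stoichiometry, compartments, reversibility and flux are out of scope;
  the network is a qualitative evidence graph, not a metabolic model.
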