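# metevent

Text mining of **metabolic events** and reconstruction of **bipartite
enzyme–metabolite interaction networks** from biomedical abstracts.

Curating which enzyme produces, consumes or converts which metabolite is a
bottleneck of metabolic network reconstruction: the evidence is scattered
across thousands of abstracts, and generic relation-extraction tools do not
speak the vocabulary of metabolism.  `metevent` is a toolkit for the whole
workflow around trigger-anchored *metabolic events*:

- **Annotation I/O** — read/write/validate BRAT standoff (`.txt`/`.ann`)
  restricted to a metabolic schema: two entity types (gene-or-protein `GP`,
  `Metabolite`) and four event types (`Metabolic_production`,
  `Metabolic_consumption`, `Metabolic_reaction`, `Positive_regulation`),
  with Theme (affected metabolite, or nested event) and Cause (enzyme)
  argument roles.
- **Entity tagging** — deterministic gazetteer matching for GP/metabolite
  mentions, plus enzyme selection among GP mentions (event Cause or enzyme
  gazetteer membership).
- **Event extraction** — a transparent rule-based baseline: sentence
  splitting, a >100-token sentence skip rule, trigger-word detection
  ("catalyzes", "synthesis", "formation", ...), and pattern-template
  argument attachment.  The stage is replaceable: any system that emits the
  standoff schema (including gold annotations) can be substituted.
- **Network reconstruction** — events become an event interaction graph,
  then directed interaction pairs *(enzyme, metabolite, produces | consumes
  | reaction)* with provenance; pairs are merged across documents under
  name normalization and a synonym map and assembled into a strictly
  bipartite network (proxy enzyme nodes fill in when no enzyme is named).
  Enzymes with both a consumed and a produced metabolite yield inferred
  conversions *substrate → enzyme → product*.
- **Evaluation** — sloppy span matching for entities (same type, any span
  overlap), approximated boundary matching for events (same type, trigger
  overlap, at-least-one or all arguments), one-to-one counting by maximum
  matching, micro-averaged precision/recall/F-score, interaction-set
  scoring, Cohen's kappa for inter-annotator agreement, and seeded k-fold
  splits.
- **Synthetic corpora** — a generator that emulates realistic corpus
  statistics (entities and events per abstract, event-type mix,
  arguments per event) with known gold events, pairs and network, plus
  controlled perturbations for parameter-recovery testing.

The core quantities are the standard retrieval metrics over matched
annotation counts,

P = TP/(TP+FP),  R = TP/(TP+FN),  F = 2PR/(P+R),

micro-averaged by summing TP/FP/FN across categories, and Cohen's
kappa = (p_o − p_e)/(1 − p_e) over a span-unified item universe.

## Worked example

Three one-sentence documents — two describing leucine transamination and
one describing the phosphoglucosamine mutase reaction — with small
gazetteers and a synonym map identifying the tyrosine-repressible
transaminase with the tyrB-encoded transaminase:

```sh
metevent run --in corpus --out out \
    --gp-gazetteer gp.tsv --met-gazetteer met.tsv --synonym-map syn.tsv
cut -f1-4 out/pairs.tsv
cat out/conversions.tsv
```

prints

```
enzyme	direction	metabolite	role
glmm	reaction	glucosamine-1-phosphate	product
glmm	reaction	glucosamine-6-phosphate	substrate
tyrb-encoded transaminase	consumes	2-kic	substrate
tyrb-encoded transaminase	produces	leucine	product

substrate	enzyme	product
2-kic	tyrb-encoded transaminase	leucine
```

Reading: GlmM's "catalyzes the formation of glucosamine-1-phosphate from
glucosamine-6-phosphate" is extracted as a positive regulation over a
two-theme reaction; the regulating enzyme propagates into both reaction
pairs with product/substrate roles.  The production event ("leucine
synthesis by the tyrosine-repressible transaminase") and the consumption
event ("2-KIC amination by the tyrB-encoded transaminase") merge under the
synonym map onto one enzyme, so the network module infers that 2-KIC is
converted to leucine by that transaminase.  `out/` also contains the
intermediate standoff annotations, the SIF/GraphML network exports and a
run report.

Other subcommands: `tag`, `extract`, `map`, `reconstruct` (individual
stages), `evaluate`, `agreement`, `crossval`, `stats`, `simulate`.

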