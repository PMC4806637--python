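"""Evaluation machinery: span matching, P/R/F, agreement, cross-validation.

Entity comparison uses *sloppy span matching*: a predicted and a gold
entity are compatible when they have the same type and their spans share at
least one character (an ``exact`` mode requiring identical spans is also
provided).  Event comparison uses *approximated boundary matching*: same
event type, sloppy trigger-span overlap, and at-least-one or all matching
arguments, where entity arguments are compared sloppily and nested event
arguments recursively.

Counting is a maximum-cardinality one-to-one matching over compatible
pred/gold pairs — deterministic and order-independent, and equal by
construction to the brute-force optimum.  Micro-averages pool the summed
true positives, false positives and false negatives across categories.

Inter-annotator agreement offers consensus F-scores (each annotator scored
against a consensus annotation) and Cohen's kappa,
``kappa = (p_o - p_e) / (1 - p_e)``, computed over an item universe built
by unifying the two annotators' annotations under sloppy span overlap, with
category "none" for items only one annotator produced.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import networkx as nx

from .network import InteractionPair, normalize_name
from .standoff import AnnotatedDocument, Entity, MetabolicEvent

SLOPPY = "sloppy"
EXACT = "exact"
ANY = "any"
ALL = "all"


@dataclass
class EvalCounts:
    """True/false positive and false negative tallies for one category."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    category: str = ""

    def __add__(self, other: "EvalCounts") -> "EvalCounts":
        return EvalCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn,
                          self.category if self.category == other.category else "")


@dataclass(frozen=True)
class MatchConfig:
    entity_mode: str = SLOPPY
    event_arg_mode: str = ANY

    def __post_init__(self) -> None:
        if self.entity_mode not in (SLOPPY, EXACT):
            raise ValueError(f"entity_mode must be 'sloppy' or 'exact', got {self.entity_mode!r}")
        if self.event_arg_mode not in (ANY, ALL):
            raise ValueError(f"event_arg_mode must be 'any' or 'all', got {self.event_arg_mode!r}")


def spans_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _entities_compatible(p: Entity, g: Entity, mode: str) -> bool:
    if p.etype != g.etype:
        return False
    if mode == EXACT:
        return p.span == g.span
    return spans_overlap(p.span, g.span)


def _max_matching_count(
    preds: Sequence, golds: Sequence, compatible
) -> int:
    """Maximum-cardinality one-to-one matching size (Hopcroft–Karp)."""
    g = nx.Graph()
    top = [("p", i) for i in range(len(preds))]
    g.add_nodes_from(top, bipartite=0)
    g.add_nodes_from((("g", j) for j in range(len(golds))), bipartite=1)
    for i, p in enumerate(preds):
        for j, q in enumerate(golds):
            if compatible(p, q):
                g.add_edge(("p", i), ("g", j))
    if g.number_of_edges() == 0:
        return 0
    matching = nx.bipartite.maximum_matching(g, top_nodes=top)
    return len(matching) // 2


def match_entities(
    pred: Sequence[Entity], gold: Sequence[Entity], cfg: MatchConfig | None = None
) -> dict[str, EvalCounts]:
    """Per-entity-type counts under one-to-one sloppy/exact span matching."""
    cfg = cfg or MatchConfig()
    counts: dict[str, EvalCounts] = {}
    for etype in sorted({e.etype for e in pred} | {e.etype for e in gold}):
        p_t = [e for e in pred if e.etype == etype]
        g_t = [e for e in gold if e.etype == etype]
        tp = _max_matching_count(
            p_t, g_t, lambda a, b: _entities_compatible(a, b, cfg.entity_mode)
        )
        counts[etype] = EvalCounts(tp, len(p_t) - tp, len(g_t) - tp, etype)
    return counts


class _DocIndex:
    def __init__(self, entities: Sequence[Entity], events: Sequence[MetabolicEvent]):
        self.entities = {e.id: e for e in entities}
        self.events = {e.id: e for e in events}

    def resolve(self, ref: str):
        if ref in self.entities:
            return self.entities[ref]
        if ref in self.events:
            return self.events[ref]
        raise KeyError(ref)


def _events_compatible(
    p: MetabolicEvent, g: MetabolicEvent, pi: _DocIndex, gi: _DocIndex,
    cfg: MatchConfig, memo: dict[tuple[str, str], bool],
) -> bool:
    key = (p.id, g.id)
    if key in memo:
        return memo[key]
    memo[key] = False  # guard against reference cycles
    ok = p.evtype == g.evtype and (
        p.trigger_span == g.trigger_span
        if cfg.entity_mode == EXACT
        else spans_overlap(p.trigger_span, g.trigger_span)
    )
    if ok:
        p_args = [(role, pi.resolve(ref)) for role, ref in p.arguments]
        g_args = [(role, gi.resolve(ref)) for role, ref in g.arguments]

        def arg_eq(pa, ga) -> bool:
            (pr, po), (gr, go) = pa, ga
            if pr != gr:
                return False
            if isinstance(po, Entity) and isinstance(go, Entity):
                return _entities_compatible(po, go, SLOPPY)
            if isinstance(po, MetabolicEvent) and isinstance(go, MetabolicEvent):
                return _events_compatible(po, go, pi, gi, cfg, memo)
            return False

        if not p_args and not g_args:
            ok = True
        elif cfg.event_arg_mode == ANY:
            ok = any(arg_eq(pa, ga) for pa in p_args for ga in g_args)
        else:  # ALL: a perfect one-to-one correspondence of the argument lists
            if len(p_args) != len(g_args):
                ok = False
            else:
                m = _max_matching_count(p_args, g_args, arg_eq)
                ok = m == len(g_args)
    memo[key] = ok
    return ok


def match_events(
    pred: Sequence[MetabolicEvent],
    gold: Sequence[MetabolicEvent],
    pred_entities: Sequence[Entity],
    gold_entities: Sequence[Entity],
    cfg: MatchConfig | None = None,
) -> dict[str, EvalCounts]:
    """Per-event-type counts under approximated boundary matching."""
    cfg = cfg or MatchConfig()
    pi = _DocIndex(pred_entities, pred)
    gi = _DocIndex(gold_entities, gold)
    memo: dict[tuple[str, str], bool] = {}
    counts: dict[str, EvalCounts] = {}
    for evtype in sorted({e.evtype for e in pred} | {e.evtype for e in gold}):
        p_t = [e for e in pred if e.evtype == evtype]
        g_t = [e for e in gold if e.evtype == evtype]
        tp = _max_matching_count(
            p_t, g_t, lambda a, b: _events_compatible(a, b, pi, gi, cfg, memo)
        )
        counts[evtype] = EvalCounts(tp, len(p_t) - tp, len(g_t) - tp, evtype)
    return counts


def prf(c: EvalCounts) -> tuple[float, float, float]:
    """Precision, recall and F-score in [0, 1]; all-zero counts give
    (0, 0, 0) by convention."""
    if c.tp < 0 or c.fp < 0 or c.fn < 0:
        raise ValueError("counts must be non-negative")
    p = c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0
    r = c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


def micro_average(counts: Iterable[EvalCounts]) -> tuple[float, float, float]:
    """P/R/F of the element-wise summed counts across categories."""
    counts = list(counts)
    if not counts:
        raise ValueError("micro_average needs at least one category")
    total = EvalCounts()
    for c in counts:
        total = total + c
    return prf(total)


def evaluate_interactions(
    pred: Iterable[InteractionPair | tuple],
    gold: Iterable[InteractionPair | tuple],
    synonym_map: Mapping[str, str] | None = None,
    *,
    direction_sensitive: bool = False,
) -> EvalCounts:
    """Set comparison of enzyme–metabolite pairs on canonical names.

    Direction-insensitive by default: pairs compare on (enzyme, metabolite)
    keys; with ``direction_sensitive`` the direction label must agree too.
    """

    def canon(item) -> tuple:
        if isinstance(item, InteractionPair):
            enz, met, direction = item.enzyme, item.metabolite, item.direction
        else:
            enz, met = item[0], item[1]
            direction = item[2] if len(item) > 2 and direction_sensitive else None
        key = (normalize_name(enz, synonym_map), normalize_name(met, synonym_map))
        if direction_sensitive:
            key += (direction if not isinstance(item, InteractionPair) else item.direction,)
        return key

    pred_keys = {canon(p) for p in pred}
    gold_keys = {canon(g) for g in gold}
    tp = len(pred_keys & gold_keys)
    return EvalCounts(tp, len(pred_keys) - tp, len(gold_keys) - tp, "interaction")


@dataclass
class KappaResult:
    kappa: float
    p_observed: float
    p_expected: float
    per_category: dict[str, float] = field(default_factory=dict)
    n_items: int = 0


def cohens_kappa(
    labels_a: Sequence[Hashable], labels_b: Sequence[Hashable]
) -> KappaResult:
    """Cohen's kappa over two parallel label sequences.

    Per-category kappas are one-vs-rest binary collapses.  When chance
    agreement ``p_e`` is 1 (a single shared category), kappa is 1.0 if the
    annotators agree everywhere, otherwise the value is undefined and a
    :class:`ValueError` is raised.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError("label sequences differ in length")
    n = len(labels_a)
    if n == 0:
        raise ValueError("empty item universe")

    def _kappa(a: Sequence, b: Sequence) -> tuple[float, float, float]:
        po = sum(x == y for x, y in zip(a, b)) / n
        cats = set(a) | set(b)
        pe = sum((list(a).count(c) / n) * (list(b).count(c) / n) for c in cats)
        if pe >= 1.0 - 1e-12:
            if po >= 1.0 - 1e-12:
                return 1.0, po, pe
            raise ValueError("kappa undefined: chance agreement is 1 but observed is not")
        return (po - pe) / (1 - pe), po, pe

    kappa, po, pe = _kappa(labels_a, labels_b)
    per_cat = {}
    for cat in sorted(set(labels_a) | set(labels_b), key=str):
        a_bin = [x == cat for x in labels_a]
        b_bin = [x == cat for x in labels_b]
        try:
            per_cat[str(cat)] = _kappa(a_bin, b_bin)[0]
        except ValueError:
            per_cat[str(cat)] = float("nan")
    return KappaResult(kappa, po, pe, per_cat, n)


def agreement_labels(
    docs_a: Sequence[AnnotatedDocument],
    docs_b: Sequence[AnnotatedDocument],
    kind: str = "entities",
) -> tuple[list[str], list[str]]:
    """Build the kappa item universe for two annotators.

    Annotations are unified across annotators by sloppy span overlap
    (entity spans, or event trigger spans) using a maximum matching; each
    unified item yields the pair of type labels, and unmatched annotations
    pair their type with ``"none"``.
    """
    a_by_id = {d.doc_id: d for d in docs_a}
    b_by_id = {d.doc_id: d for d in docs_b}
    if set(a_by_id) != set(b_by_id):
        raise ValueError("annotator document sets differ")
    labels_a: list[str] = []
    labels_b: list[str] = []
    for doc_id in sorted(a_by_id):
        if kind == "entities":
            items_a = [(e.span, e.etype) for e in a_by_id[doc_id].entities]
            items_b = [(e.span, e.etype) for e in b_by_id[doc_id].entities]
        elif kind == "events":
            items_a = [(e.trigger_span, e.evtype) for e in a_by_id[doc_id].events]
            items_b = [(e.trigger_span, e.evtype) for e in b_by_id[doc_id].events]
        else:
            raise ValueError(f"kind must be 'entities' or 'events', got {kind!r}")
        g = nx.Graph()
        top = [("a", i) for i in range(len(items_a))]
        g.add_nodes_from(top, bipartite=0)
        g.add_nodes_from((("b", j) for j in range(len(items_b))), bipartite=1)
        for i, (sa, _) in enumerate(items_a):
            for j, (sb, _) in enumerate(items_b):
                if spans_overlap(sa, sb):
                    g.add_edge(("a", i), ("b", j))
        matching = (
            nx.bipartite.maximum_matching(g, top_nodes=top) if g.number_of_edges() else {}
        )
        matched_a = set()
        matched_b = set()
        for node, partner in matching.items():
            if node[0] == "a":
                matched_a.add(node[1])
                matched_b.add(partner[1])
                labels_a.append(items_a[node[1]][1])
                labels_b.append(items_b[partner[1]][1])
        for i, (_, t) in enumerate(items_a):
            if i not in matched_a:
                labels_a.append(t)
                labels_b.append("none")
        for j, (_, t) in enumerate(items_b):
            if j not in matched_b:
                labels_a.append("none")
                labels_b.append(t)
    return labels_a, labels_b


def interannotator_kappa(
    docs_a: Sequence[AnnotatedDocument], docs_b: Sequence[AnnotatedDocument]
) -> dict[str, KappaResult]:
    """Entity and event kappa between two annotators' document sets."""
    out = {}
    for kind in ("entities", "events"):
        la, lb = agreement_labels(docs_a, docs_b, kind)
        if la:
            out[kind] = cohens_kappa(la, lb)
    return out


def consensus_fscore(
    annotator: Sequence[AnnotatedDocument],
    consensus: Sequence[AnnotatedDocument],
    cfg: MatchConfig | None = None,
) -> dict[str, tuple[float, float, float]]:
    """Per-category (P, R, F) of one annotator against the consensus."""
    cfg = cfg or MatchConfig()
    a_by_id = {d.doc_id: d for d in annotator}
    c_by_id = {d.doc_id: d for d in consensus}
    if set(a_by_id) != set(c_by_id):
        raise ValueError("annotator and consensus document ids differ")
    totals: dict[str, EvalCounts] = {}
    for doc_id in sorted(a_by_id):
        a, c = a_by_id[doc_id], c_by_id[doc_id]
        per_doc = match_entities(a.entities, c.entities, cfg)
        per_doc.update(match_events(a.events, c.events, a.entities, c.entities, cfg))
        for cat, counts in per_doc.items():
            totals[cat] = totals.get(cat, EvalCounts(category=cat)) + counts
    return {cat: prf(counts) for cat, counts in sorted(totals.items())}


def kfold_split(
    doc_ids: Sequence[str], k: int = 5, seed: int = 0
) -> list[list[str]]:
    """Random partition into k approximately equal, disjoint folds.

    Deterministic for a fixed seed: the sorted ids are shuffled by a seeded
    Fisher–Yates pass and dealt round-robin, so fold sizes differ by at most
    one.
    """
    ids = sorted(doc_ids)
    if k < 1 or k > len(ids):
        raise ValueError(f"k must be between 1 and {len(ids)}, got {k}")
    rng = random.Random(seed)
    rng.shuffle(ids)  # Fisher–Yates
    return [ids[i::k] for i in range(k)]
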