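"""Synthetic annotated-corpus generator with known gold standards.

The generator emits corpora whose statistical shape follows the reference
corpus profile: per-document entity counts are Poisson with means 7.00
(metabolites) and 9.27 (GP mentions), events per document are Poisson with
mean 1.77, the event-type mix follows the 115:132:134:99 proportions of
production : consumption : reaction : positive regulation, and per-type
cause probabilities are chosen to approach the published
arguments-per-event means (1.10, 1.22, 2.12, 1.76).

Every event sentence is realized from one of the extractor's own pattern
templates, so the rule-based extractor provably recovers all planted events
(a closed-loop oracle); the gold interaction pairs and gold bipartite
network are derived from the planted events with the standard conversion
rules, so the full pipeline can be validated end to end without any
download.  Names are synthetic by default ("Alvanase", "belvinate", ...) to
avoid accidental gazetteer collisions; ``realistic_names`` substitutes a
small pool of real enzyme/metabolite names.

``perturb_annotations`` produces controlled corruptions (deletions,
spurious entities, span shifts) for parameter-recovery tests of the
evaluation machinery.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError
from .network import (
    BipartiteNetwork,
    InteractionPair,
    build_network,
    documents_to_interactions,
    merge_interactions,
)
from .standoff import (
    CONSUMPTION,
    GP,
    METABOLITE,
    POSITIVE_REGULATION,
    PRODUCTION,
    REACTION,
    AnnotatedDocument,
    Entity,
    MetabolicEvent,
)

_CORE_TYPES = (PRODUCTION, CONSUMPTION, REACTION)
_ALL_TYPES = _CORE_TYPES + (POSITIVE_REGULATION,)

_ENZ_PRE = ["Alv", "Brx", "Cud", "Dorn", "Elb", "Fren", "Gil", "Hap", "Jor", "Kel"]
_ENZ_MID = ["an", "el", "or", "ud"]
_MET_PRE = ["belv", "cort", "dex", "fulm", "gart", "hexin", "junt", "kelv", "lorn", "mirv"]
_MET_MID = ["in", "ox", "ur", "ell", "ap", "id"]

_REAL_ENZYMES = [
    "GlmM", "phosphoglucosamine mutase", "tyrB-encoded transaminase",
    "tyrosine-repressible transaminase", "aspC-encoded transaminase",
    "avtA-encoded transaminase", "branched-chain amino acid aminotransferase",
    "acetolactate synthase",
]
_REAL_METABOLITES = [
    "leucine", "2-KIC", "glucosamine-1-phosphate", "glucosamine-6-phosphate",
    "valine", "isoleucine", "pyridoxal 5'-phosphate", "pyridoxine",
    "2-ketoisovalerate", "threonine",
]


def enzyme_pool(n: int, realistic: bool = False) -> list[str]:
    if realistic:
        return list(_REAL_ENZYMES)[: max(1, n)]
    names = [f"{p}{m}ase" for p in _ENZ_PRE for m in _ENZ_MID]
    return names[: max(1, min(n, len(names)))]


def metabolite_pool(n: int, realistic: bool = False) -> list[str]:
    if realistic:
        return list(_REAL_METABOLITES)[: max(1, n)]
    names = [f"{p}{m}ate" for p in _MET_PRE for m in _MET_MID]
    return names[: max(1, min(n, len(names)))]


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic corpus."""

    n_docs: int = 271
    seed: int = 0
    metabolite_rate: float = 7.00      # mean metabolite mentions per document
    gp_rate: float = 9.27              # mean GP mentions per document
    events_per_doc: float = 1.77
    event_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            PRODUCTION: 115 / 480,
            CONSUMPTION: 132 / 480,
            REACTION: 134 / 480,
            POSITIVE_REGULATION: 99 / 480,
        }
    )
    # probability an event sentence names its enzyme; tuned to the
    # arguments-per-event means (production 1.10, consumption 1.22,
    # reaction 2.12, positive regulation 1.76)
    cause_prob: Mapping[str, float] = field(
        default_factory=lambda: {
            PRODUCTION: 0.10,
            CONSUMPTION: 0.22,
            REACTION: 0.12,
            POSITIVE_REGULATION: 0.76,
        }
    )
    trigger_words: Mapping[str, Sequence[tuple[str, float]]] = field(
        default_factory=lambda: {
            PRODUCTION: (("synthesis", 0.5), ("biosynthesis", 0.3), ("formation", 0.2)),
            CONSUMPTION: (("utilization", 0.5), ("metabolism", 0.3), ("amination", 0.2)),
            REACTION: (("formation", 0.6), ("conversion", 0.4)),
            POSITIVE_REGULATION: (("catalyzes", 0.7), ("catalyzed", 0.3)),
        }
    )
    n_enzymes: int = 40
    n_metabolites: int = 60
    realistic_names: bool = False

    def validate(self) -> None:
        if self.n_docs < 1:
            raise ConfigurationError("n_docs must be >= 1")
        if min(self.metabolite_rate, self.gp_rate, self.events_per_doc) < 0:
            raise ConfigurationError("rates must be non-negative")
        total = sum(self.event_mix.values())
        if abs(total - 1.0) > 1e-6:
            raise ConfigurationError(f"event_mix proportions must sum to 1, got {total}")
        for t, p in self.cause_prob.items():
            if not 0 <= p <= 1:
                raise ConfigurationError(f"cause_prob[{t}] out of [0, 1]")


@dataclass
class GoldBundle:
    """A generated corpus plus the gold it was built from."""

    corpus: list[AnnotatedDocument]
    gold_pairs: list[InteractionPair]
    gold_network: BipartiteNetwork


class _SentenceBuilder:
    """Accumulates one sentence while tracking entity/trigger offsets."""

    def __init__(self) -> None:
        self.parts: list[str] = []
        self.length = 0
        self.entities: list[dict] = []
        self.triggers: list[dict] = []

    def lit(self, s: str) -> None:
        self.parts.append(s)
        self.length += len(s)

    def entity(self, name: str, etype: str) -> dict:
        rec = {"etype": etype, "start": self.length, "end": self.length + len(name), "text": name}
        self.entities.append(rec)
        self.lit(name)
        return rec

    def trigger(self, word: str, capitalize: bool = False) -> dict:
        surface = word[0].upper() + word[1:] if capitalize else word
        rec = {"start": self.length, "end": self.length + len(surface), "text": surface}
        self.triggers.append(rec)
        self.lit(surface)
        return rec

    def text(self) -> str:
        return "".join(self.parts)


def _pick(rng: np.random.Generator, table: Sequence[tuple[str, float]]) -> str:
    words = [w for w, _ in table]
    weights = np.array([p for _, p in table], dtype=float)
    weights = weights / weights.sum()
    return words[int(rng.choice(len(words), p=weights))]


def _sample_names(rng: np.random.Generator, pool: Sequence[str], k: int) -> list[str]:
    idx = rng.choice(len(pool), size=min(k, len(pool)), replace=False)
    return [pool[int(i)] for i in idx]


def _core_phrase(
    b: _SentenceBuilder, rng: np.random.Generator, cfg: GeneratorConfig,
    etype: str, mets: list[str],
) -> dict:
    """Append a core-event phrase ("<met> <trig>" or "<trig> of A from B");
    returns the planted event record (without cause)."""
    word = _pick(rng, cfg.trigger_words[etype])
    if etype == REACTION:
        trig = b.trigger(word)
        b.lit(" of ")
        a = b.entity(mets[0], METABOLITE)
        b.lit(" from ")
        s = b.entity(mets[1], METABOLITE)
        themes = [("ent", a), ("ent", s)]
    else:
        m = b.entity(mets[0], METABOLITE)
        b.lit(" ")
        trig = b.trigger(word)
        themes = [("ent", m)]
    return {"evtype": etype, "trigger": trig, "themes": themes, "causes": []}


def _sentence_type_distribution(cfg: GeneratorConfig) -> tuple[list[float], float]:
    """Sentence-type probabilities compensating for nesting.

    A regulation sentence plants two events (the regulation plus its nested
    core event), so sampling sentence types directly from the event mix
    would inflate core-event counts and depress the regulation share.
    Solving for the sentence distribution q that realizes the configured
    event-type proportions p in expectation gives ``q_pr = p_pr/(1-p_pr)``
    and ``q_t = p_t (1-2 p_pr)/(1-p_pr)^2`` for core types, with
    ``1 + q_pr`` planted events per sentence on average.
    """
    p_pr = cfg.event_mix[POSITIVE_REGULATION]
    if p_pr >= 0.5:
        raise ConfigurationError(
            "positive-regulation proportion must be < 0.5 (each regulation nests a core event)"
        )
    q_pr = p_pr / (1 - p_pr)
    q = [cfg.event_mix[t] * (1 - 2 * p_pr) / (1 - p_pr) ** 2 for t in _CORE_TYPES]
    q.append(q_pr)
    total = sum(q)
    return [x / total for x in q], 1 + q_pr


def _event_sentence(
    rng: np.random.Generator, cfg: GeneratorConfig, etype: str,
    enzymes: list[str], mets: list[str],
) -> tuple[str, list[dict], list[dict]]:
    """One template-realized sentence; returns (text, entities, events)."""
    b = _SentenceBuilder()
    events: list[dict] = []
    with_cause = rng.random() < cfg.cause_prob[etype]
    if etype == POSITIVE_REGULATION:
        core_p = np.array([cfg.event_mix[t] for t in _CORE_TYPES])
        inner_type = _CORE_TYPES[int(rng.choice(len(_CORE_TYPES), p=core_p / core_p.sum()))]
        verb = _pick(rng, cfg.trigger_words[POSITIVE_REGULATION])
        if with_cause:
            enz = b.entity(enzymes[0], GP)
            b.lit(" ")
            trig = b.trigger(verb)
            b.lit(" the ")
            inner = _core_phrase(b, rng, cfg, inner_type, mets)
            b.lit(".")
            causes = [("ent", enz)]
        else:
            trig = b.trigger("catalysis", capitalize=True)
            b.lit(" of the ")
            inner = _core_phrase(b, rng, cfg, inner_type, mets)
            b.lit(" was reported.")
            causes = []
        events.append(inner)
        events.append(
            {"evtype": POSITIVE_REGULATION, "trigger": trig,
             "themes": [("ev", inner)], "causes": causes}
        )
    elif etype == REACTION:
        b.lit("The ")
        ev = _core_phrase(b, rng, cfg, REACTION, mets)
        if with_cause:
            b.lit(" by the ")
            enz = b.entity(enzymes[0], GP)
            ev["causes"] = [("ent", enz)]
        b.lit(" was observed.")
        events.append(ev)
    else:
        b.lit("The ")
        ev = _core_phrase(b, rng, cfg, etype, mets)
        if with_cause:
            b.lit(" by the ")
            enz = b.entity(enzymes[0], GP)
            ev["causes"] = [("ent", enz)]
        b.lit(" was reported.")
        events.append(ev)
    return b.text(), b.entities, events


def _filler_sentence(names: list[tuple[str, str]]) -> tuple[str, list[dict]]:
    b = _SentenceBuilder()
    b.lit("Additional assays detected ")
    for i, (name, etype) in enumerate(names):
        if i > 0:
            b.lit(" and " if i == len(names) - 1 else ", ")
        b.entity(name, etype)
    b.lit(".")
    return b.text(), b.entities


def _assemble_document(
    doc_id: str, sentences: list[tuple[str, list[dict], list[dict]]]
) -> AnnotatedDocument:
    text_parts: list[str] = []
    offset = 0
    all_ents: list[dict] = []
    all_evts: list[dict] = []
    for sent_text, ents, evts in sentences:
        for rec in ents:
            rec["start"] += offset
            rec["end"] += offset
        for ev in evts:
            ev["trigger"]["start"] += offset
            ev["trigger"]["end"] += offset
        text_parts.append(sent_text)
        all_ents.extend(ents)
        all_evts.extend(evts)
        offset += len(sent_text) + 1  # single space joins sentences
    text = " ".join(text_parts)
    all_ents.sort(key=lambda r: (r["start"], r["end"]))
    entities = []
    for i, rec in enumerate(all_ents):
        rec["id"] = f"T{i + 1}"
        entities.append(Entity(rec["id"], rec["etype"], rec["start"], rec["end"], rec["text"]))
    all_evts.sort(key=lambda ev: ev["trigger"]["start"])
    for i, ev in enumerate(all_evts):
        ev["id"] = f"E{i + 1}"
    events = []
    for ev in all_evts:
        themes = tuple(
            ref["id"] if kind == "ent" else ref["id"] for kind, ref in ev["themes"]
        )
        causes = tuple(ref["id"] for _, ref in ev["causes"])
        trig = ev["trigger"]
        events.append(
            MetabolicEvent(
                ev["id"], ev["evtype"], trig["start"], trig["end"], trig["text"],
                themes, causes,
            )
        )
    return AnnotatedDocument(doc_id, text, entities, events)


def generate_corpus(cfg: GeneratorConfig | None = None) -> GoldBundle:
    """Generate a corpus and its gold pairs/network; byte-identical per seed."""
    cfg = cfg or GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    enzymes = enzyme_pool(cfg.n_enzymes, cfg.realistic_names)
    mets = metabolite_pool(cfg.n_metabolites, cfg.realistic_names)
    stype_p, events_per_sentence = _sentence_type_distribution(cfg)
    docs: list[AnnotatedDocument] = []
    for i in range(cfg.n_docs):
        doc_id = f"SYN{i:04d}"
        n_sentences = int(rng.poisson(cfg.events_per_doc / events_per_sentence))
        target_met = int(rng.poisson(cfg.metabolite_rate))
        target_gp = int(rng.poisson(cfg.gp_rate))
        sentences: list[tuple[str, list[dict], list[dict]]] = []
        used_met = used_gp = 0
        for _ in range(n_sentences):
            etype = _ALL_TYPES[int(rng.choice(len(_ALL_TYPES), p=stype_p))]
            enz_names = _sample_names(rng, enzymes, 1)
            met_names = _sample_names(rng, mets, 2)
            sent = _event_sentence(rng, cfg, etype, enz_names, met_names)
            sentences.append(sent)
            used_met += sum(1 for r in sent[1] if r["etype"] == METABOLITE)
            used_gp += sum(1 for r in sent[1] if r["etype"] == GP)
        extra: list[tuple[str, str]] = []
        n_extra_met = max(0, target_met - used_met)
        n_extra_gp = max(0, target_gp - used_gp)
        extra += [(n, METABOLITE) for n in _sample_names(rng, mets, n_extra_met)]
        extra += [(n, GP) for n in _sample_names(rng, enzymes, n_extra_gp)]
        while n_extra_met > len(mets) or n_extra_gp > len(enzymes):
            # pools exhausted for extreme draws; repeat names in a second list
            n_extra_met = max(0, n_extra_met - len(mets))
            n_extra_gp = max(0, n_extra_gp - len(enzymes))
            extra += [(n, METABOLITE) for n in _sample_names(rng, mets, n_extra_met)]
            extra += [(n, GP) for n in _sample_names(rng, enzymes, n_extra_gp)]
        if extra:
            text, ents = _filler_sentence(extra)
            sentences.append((text, ents, []))
        if not sentences:
            sentences.append(("No metabolic activity was reported.", [], []))
        docs.append(_assemble_document(doc_id, sentences))
    pairs = merge_interactions(documents_to_interactions(docs))
    return GoldBundle(docs, pairs, build_network(pairs))


_WORD = re.compile(r"[0-9A-Za-z][0-9A-Za-z'-]{2,}")


def perturb_annotations(
    doc: AnnotatedDocument,
    p_miss: float = 0.0,
    p_spurious: float = 0.0,
    p_shift: float = 0.0,
    seed: int = 0,
) -> AnnotatedDocument:
    """Controlled corruption of a gold document.

    Each annotation is deleted independently with probability ``p_miss``
    (events also cascade-delete when an argument disappears); spurious
    entities are injected at word spans that overlap no original annotation,
    at a Poisson rate of ``p_spurious`` per document; surviving spans are
    shifted whole by 1–3 characters in either direction with probability
    ``p_shift``, clamped to the document bounds.  Deterministic per seed.
    """
    for name, p in (("p_miss", p_miss), ("p_spurious", p_spurious), ("p_shift", p_shift)):
        if not 0 <= p <= (1 if name != "p_spurious" else float("inf")):
            raise ConfigurationError(f"{name} out of range")
    rng = np.random.default_rng(seed)
    n = len(doc.text)

    kept_entities = [e for e in doc.entities if rng.random() >= p_miss]
    dropped_ids = {e.id for e in doc.entities} - {e.id for e in kept_entities}
    own_drop = {ev.id for ev in doc.events if rng.random() < p_miss}
    removed = set(dropped_ids) | own_drop
    changed = True
    while changed:  # cascade through nested references
        changed = False
        for ev in doc.events:
            if ev.id in removed:
                continue
            if any(r in removed for r in ev.themes + ev.causes):
                removed.add(ev.id)
                changed = True
    kept_events = [ev for ev in doc.events if ev.id not in removed]

    # spurious entities at untouched word spans
    blocked = [e.span for e in doc.entities] + [ev.trigger_span for ev in doc.events]
    candidates = [
        m.span()
        for m in _WORD.finditer(doc.text)
        if not any(m.start() < b_end and m.end() > b_start for b_start, b_end in blocked)
    ]
    n_spurious = int(rng.poisson(p_spurious)) if p_spurious else 0
    spurious: list[Entity] = []
    if n_spurious and candidates:
        chosen = rng.choice(len(candidates), size=min(n_spurious, len(candidates)), replace=False)
        max_t = max((int(m.group(1)) for e in doc.entities for m in [re.fullmatch(r"T(\d+)", e.id)] if m), default=0)
        for k, ci in enumerate(sorted(int(c) for c in chosen)):
            start, end = candidates[ci]
            etype = GP if rng.random() < 0.5 else METABOLITE
            spurious.append(
                Entity(f"T{max_t + k + 1}", etype, start, end, doc.text[start:end])
            )

    def shift_span(start: int, end: int) -> tuple[int, int]:
        if rng.random() >= p_shift:
            return start, end
        delta = int(rng.integers(1, 4)) * (1 if rng.random() < 0.5 else -1)
        length = end - start
        new_start = min(max(0, start + delta), n - length)
        return new_start, new_start + length

    shifted_entities = []
    for e in kept_entities:
        s, t = shift_span(e.start, e.end)
        shifted_entities.append(replace(e, start=s, end=t, text=doc.text[s:t]))
    shifted_events = []
    for ev in kept_events:
        s, t = shift_span(ev.trigger_start, ev.trigger_end)
        shifted_events.append(
            replace(ev, trigger_start=s, trigger_end=t, trigger_text=doc.text[s:t])
        )
    return AnnotatedDocument(
        doc.doc_id, doc.text, shifted_entities + spurious, shifted_events
    )


def corpus_from_counts(
    n_docs: int,
    entity_totals: Mapping[str, int],
    event_totals: Mapping[str, int] | None = None,
) -> list[AnnotatedDocument]:
    """Deterministic corpus realizing exact per-type annotation totals.

    Counts are dealt round-robin (document *i* receives one extra unit while
    ``i < total mod n_docs``), which is the layout used to recompute
    published per-document means from printed totals.
    """
    if n_docs < 1:
        raise ConfigurationError("n_docs must be >= 1")
    event_totals = dict(event_totals or {})
    trig_word = {
        PRODUCTION: "synthesis", CONSUMPTION: "utilization",
        REACTION: "conversion", POSITIVE_REGULATION: "catalyzes",
    }
    docs = []
    for i in range(n_docs):
        def share(total: int) -> int:
            return total // n_docs + (1 if i < total % n_docs else 0)

        b = _SentenceBuilder()
        met_ids: list[dict] = []
        first = True
        for etype in sorted(entity_totals):
            for j in range(share(entity_totals[etype])):
                if not first:
                    b.lit(" ")
                first = False
                rec = b.entity(f"{etype.lower()}{j}", etype)
                if etype == METABOLITE:
                    met_ids.append(rec)
        events: list[dict] = []
        core_events: list[dict] = []
        for evtype in sorted(event_totals):
            for _ in range(share(event_totals[evtype])):
                if not first:
                    b.lit(" ")
                first = False
                trig = b.trigger(trig_word.get(evtype, "synthesis"))
                if evtype == POSITIVE_REGULATION:
                    if not core_events:
                        raise ConfigurationError(
                            "positive regulation requires a core event in the same document"
                        )
                    ev = {"evtype": evtype, "trigger": trig,
                          "themes": [("ev", core_events[0])], "causes": []}
                else:
                    if not met_ids:
                        raise ConfigurationError("events require a metabolite in the document")
                    ev = {"evtype": evtype, "trigger": trig,
                          "themes": [("ent", met_ids[0])], "causes": []}
                    core_events.append(ev)
                events.append(ev)
        if first:
            b.lit("empty")
        docs.append(_assemble_document(f"CNT{i:04d}", [(b.text(), b.entities, events)]))
    return docs
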