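"""Shared fixtures: worked-example documents and a random-document strategy."""

from __future__ import annotations

import pytest
from hypothesis import strategies as st

import metevent as me

GLMM_TEXT = (
    "GlmM catalyzes the formation of glucosamine-1-phosphate from glucosamine-6-phosphate."
)

EX1_TEXT = "leucine synthesis by the tyrosine-repressible transaminase in Escherichia coli K-12."
EX2_TEXT = (
    "2-KIC amination by the tyrB-encoded transaminase and also by the aspC- and "
    "avtA-encoded transaminases."
)


@pytest.fixture
def glmm_doc() -> me.AnnotatedDocument:
    """The nested-regulation worked annotation: GlmM catalyzes a reaction
    forming glucosamine-1-phosphate (product) from glucosamine-6-phosphate
    (substrate)."""
    entities = [
        me.Entity("T1", me.GP, 0, 4, "GlmM"),
        me.Entity("T2", me.METABOLITE, 32, 55, "glucosamine-1-phosphate"),
        me.Entity("T3", me.METABOLITE, 61, 84, "glucosamine-6-phosphate"),
    ]
    events = [
        me.MetabolicEvent("E1", me.POSITIVE_REGULATION, 5, 14, "catalyzes", ("E2",), ("T1",)),
        me.MetabolicEvent("E2", me.REACTION, 19, 28, "formation", ("T2", "T3")),
    ]
    return me.AnnotatedDocument("glmm", GLMM_TEXT, entities, events)


@pytest.fixture
def worked_gazetteers() -> tuple[me.Gazetteer, me.Gazetteer]:
    gaz_gp = me.Gazetteer.from_terms(
        me.GP,
        ["GlmM", "phosphoglucosamine mutase", "tyrosine-repressible transaminase",
         "tyrB-encoded transaminase"],
    )
    gaz_met = me.Gazetteer.from_terms(
        me.METABOLITE,
        ["glucosamine-1-phosphate", "glucosamine-6-phosphate", "glucosamine",
         "leucine", "2-KIC"],
    )
    return gaz_gp, gaz_met


def make_doc(text: str, gaz_gp: me.Gazetteer, gaz_met: me.Gazetteer, doc_id: str = "doc"):
    """Tag + extract helper used by pipeline-level tests."""
    entities = me.tag_entities(text, gaz_gp, gaz_met)
    events = me.extract_events(text, entities)
    return me.AnnotatedDocument(doc_id, text, entities, events)


@st.composite
def annotated_documents(draw) -> me.AnnotatedDocument:
    """Random schema-valid documents for round-trip/property tests."""
    n_words = draw(st.integers(min_value=4, max_value=14))
    words = [
        draw(st.text(alphabet="abcdefgh", min_size=2, max_size=6)) or "aa"
        for _ in range(n_words)
    ]
    text = " ".join(words) + "."
    spans = []
    pos = 0
    for w in words:
        spans.append((pos, pos + len(w)))
        pos += len(w) + 1

    indices = list(range(n_words))
    n_entities = draw(st.integers(min_value=0, max_value=min(5, n_words)))
    picked = draw(st.permutations(indices))[:n_entities]
    entities = []
    for k, idx in enumerate(sorted(picked)):
        etype = draw(st.sampled_from([me.GP, me.METABOLITE]))
        s, e = spans[idx]
        entities.append(me.Entity(f"T{k + 1}", etype, s, e, text[s:e]))
    mets = [e for e in entities if e.etype == me.METABOLITE]
    gps = [e for e in entities if e.etype == me.GP]
    free = [i for i in indices if i not in picked]

    events = []
    if mets and free:
        n_events = draw(st.integers(min_value=0, max_value=min(3, len(free))))
        for k in range(n_events):
            idx = free[k]
            s, e = spans[idx]
            evtype = draw(st.sampled_from([me.PRODUCTION, me.CONSUMPTION, me.REACTION]))
            n_themes = draw(st.integers(min_value=1, max_value=min(2, len(mets))))
            themes = tuple(m.id for m in draw(st.permutations(mets))[:n_themes])
            causes = ()
            if gps and draw(st.booleans()):
                causes = (draw(st.sampled_from(gps)).id,)
            events.append(
                me.MetabolicEvent(f"E{k + 1}", evtype, s, e, text[s:e], themes, causes)
            )
        # optionally a regulation over the first core event
        if events and len(free) > n_events and draw(st.booleans()):
            idx = free[n_events]
            s, e = spans[idx]
            causes = (draw(st.sampled_from(gps)).id,) if gps else ()
            events.append(
                me.MetabolicEvent(
                    f"E{len(events) + 1}", me.POSITIVE_REGULATION, s, e, text[s:e],
                    (events[0].id,), causes,
                )
            )
    return me.AnnotatedDocument("rand", text, entities, events)
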