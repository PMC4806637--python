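"""BRAT standoff I/O restricted to the metabolic annotation schema.

A document is a pair of UTF-8 files, ``<doc_id>.txt`` (raw text) and
``<doc_id>.ann`` (annotations).  The schema comprises two entity types —
gene-or-protein mentions (``GP``) and ``Metabolite`` — and four
trigger-anchored event types: ``Metabolic_production``,
``Metabolic_consumption``, ``Metabolic_reaction`` and
``Positive_regulation``.  Production, consumption and reaction events take
Metabolite themes and optional GP (enzyme) causes; positive regulation takes
another event as its theme.

Offsets are 0-based, end-exclusive and counted in Unicode code points (the
usual BRAT convention), so writing and re-reading a document never shifts
spans regardless of multibyte content.

Standoff dialect notes:

* entity lines: ``Tn<TAB>Type start end<TAB>text``;
* event lines: ``En<TAB>EventType:Ttrig Theme:Ref [Theme2:Ref ...]
  [Cause:Ref ...]`` — multiple arguments of one role use the numbered-slot
  convention (``Theme``, ``Theme2``, ...);
* event triggers are ordinary T lines; on write they are typed with the
  event type, on read any non-entity T type is accepted as a trigger (some
  corpora use dedicated trigger type names), since the event type is carried
  by the E line.

For ``Metabolic_reaction`` events with exactly two themes the theme order is
meaningful by convention: the first theme is the product, the second the
substrate (the "formation of <product> from <substrate>" reading).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .errors import (
    DanglingReferenceError,
    SchemaError,
    SpanIntegrityError,
    StandoffParseError,
)

logger = logging.getLogger(__name__)

GP = "GP"
METABOLITE = "Metabolite"
ENTITY_TYPES = frozenset({GP, METABOLITE})

PRODUCTION = "Metabolic_production"
CONSUMPTION = "Metabolic_consumption"
REACTION = "Metabolic_reaction"
POSITIVE_REGULATION = "Positive_regulation"
EVENT_TYPES = frozenset({PRODUCTION, CONSUMPTION, REACTION, POSITIVE_REGULATION})

#: event types whose themes are metabolite entities
CORE_EVENT_TYPES = frozenset({PRODUCTION, CONSUMPTION, REACTION})


@dataclass(frozen=True)
class Entity:
    """A typed text span with 0-based, end-exclusive code-point offsets."""

    id: str
    etype: str
    start: int
    end: int
    text: str

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class MetabolicEvent:
    """A typed, trigger-anchored event with role-labelled arguments.

    ``themes``/``causes`` hold annotation ids.  Themes of production,
    consumption and reaction events reference Metabolite entities; the theme
    of a Positive_regulation references another event.  Causes reference GP
    entities and may be empty.
    """

    id: str
    evtype: str
    trigger_start: int
    trigger_end: int
    trigger_text: str
    themes: tuple[str, ...]
    causes: tuple[str, ...] = ()

    @property
    def trigger_span(self) -> tuple[int, int]:
        return (self.trigger_start, self.trigger_end)

    @property
    def arguments(self) -> tuple[tuple[str, str], ...]:
        """(role, ref) pairs, themes first."""
        return tuple(("Theme", t) for t in self.themes) + tuple(
            ("Cause", c) for c in self.causes
        )


def _id_key(ann_id: str) -> tuple[str, int, str]:
    m = re.fullmatch(r"([A-Za-z]+)(\d+)", ann_id)
    if m:
        return (m.group(1), int(m.group(2)), "")
    return (ann_id, -1, ann_id)


@dataclass
class AnnotatedDocument:
    """One abstract/title with its entity and event annotations.

    Annotation lists are kept in a canonical order (entities by span, events
    by id) so that documents parsed from reordered ``.ann`` lines compare
    equal.
    """

    doc_id: str
    text: str
    entities: list[Entity] = field(default_factory=list)
    events: list[MetabolicEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.entities = sorted(self.entities, key=lambda e: (e.start, e.end, _id_key(e.id)))
        self.events = sorted(self.events, key=lambda e: _id_key(e.id))

    def annotation_ids(self) -> set[str]:
        return {e.id for e in self.entities} | {e.id for e in self.events}

    def entity_map(self) -> dict[str, Entity]:
        return {e.id: e for e in self.entities}

    def event_map(self) -> dict[str, MetabolicEvent]:
        return {e.id: e for e in self.events}

    def get(self, ann_id: str) -> Entity | MetabolicEvent:
        for e in self.entities:
            if e.id == ann_id:
                return e
        for ev in self.events:
            if ev.id == ann_id:
                return ev
        raise DanglingReferenceError(f"{self.doc_id}: unknown annotation id {ann_id!r}")


@dataclass(frozen=True)
class Violation:
    """One schema violation: the annotation at fault and the rule broken."""

    ann_id: str
    rule: str
    message: str


_ROLE_RE = re.compile(r"(Theme|Cause)(\d*)")


def read_standoff(
    text_content: str,
    ann_content: str,
    doc_id: str = "doc",
    *,
    permissive: bool = False,
    validate: bool = True,
) -> AnnotatedDocument:
    """Parse paired text/annotation content into an :class:`AnnotatedDocument`.

    Unknown annotation types and line kinds are rejected unless
    ``permissive`` is set, in which case they are skipped with a warning.
    Span/text disagreements raise :class:`SpanIntegrityError`; unresolved
    references raise :class:`DanglingReferenceError`; schema violations (with
    ``validate=True``) raise :class:`SchemaError`.
    """
    entities: list[Entity] = []
    triggers: dict[str, tuple[str, int, int, str]] = {}
    raw_events: list[tuple[int, str, str, str, list[tuple[str, str]]]] = []
    seen_ids: set[str] = set()
    n = len(text_content)

    for lineno, line in enumerate(ann_content.splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("#"):
            continue  # BRAT comment line
        fields = line.split("\t")
        tag = fields[0]
        if tag.startswith("T"):
            if len(fields) < 3:
                raise StandoffParseError("T line needs 3 tab-separated fields", lineno)
            header = fields[1].split()
            if len(header) != 3:
                raise StandoffParseError(
                    f"malformed T header {fields[1]!r} (expected 'Type start end')", lineno
                )
            ttype, s_start, s_end = header
            try:
                start, end = int(s_start), int(s_end)
            except ValueError:
                raise StandoffParseError(f"non-integer offsets in {fields[1]!r}", lineno)
            surface = fields[2]
            if tag in seen_ids:
                raise StandoffParseError(f"duplicate annotation id {tag!r}", lineno)
            if not (0 <= start < end <= n):
                raise SpanIntegrityError(
                    f"{doc_id}/{tag}: span ({start}, {end}) outside document of length {n}"
                )
            if text_content[start:end] != surface:
                raise SpanIntegrityError(
                    f"{doc_id}/{tag}: annotated text {surface!r} != document text "
                    f"{text_content[start:end]!r} at ({start}, {end})"
                )
            if ttype in ENTITY_TYPES:
                seen_ids.add(tag)
                entities.append(Entity(tag, ttype, start, end, surface))
            else:
                # candidate event trigger (typed with the event type or a
                # corpus-specific trigger type)
                seen_ids.add(tag)
                triggers[tag] = (ttype, start, end, surface)
        elif tag.startswith("E"):
            if len(fields) < 2:
                raise StandoffParseError("E line needs 2 tab-separated fields", lineno)
            parts = fields[1].split()
            if not parts or ":" not in parts[0]:
                raise StandoffParseError(f"malformed E header {fields[1]!r}", lineno)
            evtype, trig_ref = parts[0].split(":", 1)
            if evtype not in EVENT_TYPES:
                if permissive:
                    logger.warning("%s line %d: skipping unknown event type %r", doc_id, lineno, evtype)
                    continue
                raise StandoffParseError(f"unknown event type {evtype!r}", lineno)
            if tag in seen_ids:
                raise StandoffParseError(f"duplicate annotation id {tag!r}", lineno)
            seen_ids.add(tag)
            args: list[tuple[str, str]] = []
            for tok in parts[1:]:
                if ":" not in tok:
                    raise StandoffParseError(f"malformed argument {tok!r}", lineno)
                role, ref = tok.split(":", 1)
                m = _ROLE_RE.fullmatch(role)
                if not m:
                    if permissive:
                        logger.warning("%s line %d: skipping unknown role %r", doc_id, lineno, role)
                        continue
                    raise StandoffParseError(f"unknown argument role {role!r}", lineno)
                args.append((m.group(1), ref))
            raw_events.append((lineno, tag, evtype, trig_ref, args))
        else:
            if permissive:
                logger.warning("%s line %d: skipping unsupported line %r", doc_id, lineno, tag)
                continue
            raise StandoffParseError(f"unsupported annotation line {tag!r}", lineno)

    entity_ids = {e.id for e in entities}
    event_ids = {tag for _, tag, _, _, _ in raw_events}
    events: list[MetabolicEvent] = []
    for lineno, tag, evtype, trig_ref, args in raw_events:
        trig = triggers.get(trig_ref)
        if trig is None:
            raise DanglingReferenceError(
                f"{doc_id}/{tag}: trigger reference {trig_ref!r} does not resolve"
            )
        _, t_start, t_end, t_text = trig
        themes = tuple(ref for role, ref in args if role == "Theme")
        causes = tuple(ref for role, ref in args if role == "Cause")
        for ref in themes + causes:
            if ref not in entity_ids and ref not in event_ids:
                raise DanglingReferenceError(
                    f"{doc_id}/{tag}: argument reference {ref!r} does not resolve"
                )
        events.append(MetabolicEvent(tag, evtype, t_start, t_end, t_text, themes, causes))

    # unreferenced non-entity T lines carry unknown types
    referenced = {trig_ref for _, _, _, trig_ref, _ in raw_events}
    for tid, (ttype, *_rest) in triggers.items():
        if tid not in referenced:
            if permissive:
                logger.warning("%s: skipping unreferenced annotation %s of type %r", doc_id, tid, ttype)
            else:
                raise StandoffParseError(
                    f"unknown entity type {ttype!r} for unreferenced annotation {tid}"
                )

    doc = AnnotatedDocument(doc_id, text_content, entities, events)
    if validate:
        violations = validate_schema(doc)
        if violations:
            raise SchemaError(violations)
    return doc


def validate_schema(doc: AnnotatedDocument) -> list[Violation]:
    """Check all schema constraints; violations are returned, not raised."""
    violations: list[Violation] = []
    n = len(doc.text)
    seen: set[str] = set()
    for e in doc.entities:
        if e.id in seen:
            violations.append(Violation(e.id, "duplicate-id", f"id {e.id} used more than once"))
        seen.add(e.id)
        if e.etype not in ENTITY_TYPES:
            violations.append(Violation(e.id, "entity-type", f"unknown entity type {e.etype!r}"))
        if not (0 <= e.start < e.end <= n):
            violations.append(
                Violation(e.id, "span-bounds", f"span {e.span} outside document of length {n}")
            )
        elif doc.text[e.start:e.end] != e.text:
            violations.append(
                Violation(e.id, "span-text", f"text {e.text!r} != document substring at {e.span}")
            )
    entity_map = {e.id: e for e in doc.entities}
    event_map = {e.id: e for e in doc.events}
    for ev in doc.events:
        if ev.id in seen:
            violations.append(Violation(ev.id, "duplicate-id", f"id {ev.id} used more than once"))
        seen.add(ev.id)
        if ev.evtype not in EVENT_TYPES:
            violations.append(Violation(ev.id, "event-type", f"unknown event type {ev.evtype!r}"))
            continue
        if not (0 <= ev.trigger_start < ev.trigger_end <= n):
            violations.append(
                Violation(ev.id, "span-bounds", f"trigger span {ev.trigger_span} out of bounds")
            )
        elif doc.text[ev.trigger_start:ev.trigger_end] != ev.trigger_text:
            violations.append(
                Violation(ev.id, "span-text", "trigger text != document substring")
            )
        for ref in ev.themes:
            if ref not in entity_map and ref not in event_map:
                violations.append(
                    Violation(ev.id, "dangling-ref", f"theme {ref!r} does not resolve")
                )
            elif ev.evtype in CORE_EVENT_TYPES:
                ent = entity_map.get(ref)
                if ent is None or ent.etype != METABOLITE:
                    violations.append(
                        Violation(
                            ev.id,
                            "theme-type",
                            f"theme of {ev.evtype} must be a Metabolite entity, got {ref!r}",
                        )
                    )
            else:  # Positive_regulation
                if ref not in event_map:
                    violations.append(
                        Violation(
                            ev.id,
                            "theme-type",
                            f"theme of {POSITIVE_REGULATION} must be an event, got {ref!r}",
                        )
                    )
        for ref in ev.causes:
            ent = entity_map.get(ref)
            if ref not in entity_map and ref not in event_map:
                violations.append(
                    Violation(ev.id, "dangling-ref", f"cause {ref!r} does not resolve")
                )
            elif ent is None or ent.etype != GP:
                violations.append(
                    Violation(ev.id, "cause-type", f"cause must be a GP entity, got {ref!r}")
                )
    # acyclicity of event -> event references
    children = {
        ev.id: [r for r in ev.themes + ev.causes if r in event_map] for ev in doc.events
    }
    state: dict[str, int] = {}

    def visit(node: str) -> bool:
        state[node] = 1
        for nxt in children.get(node, ()):
            st = state.get(nxt, 0)
            if st == 1:
                return True
            if st == 0 and visit(nxt):
                return True
        state[node] = 2
        return False

    for ev in doc.events:
        if state.get(ev.id, 0) == 0 and visit(ev.id):
            violations.append(
                Violation(ev.id, "cycle", "argument reference graph contains a cycle")
            )
    return violations


def write_standoff(doc: AnnotatedDocument, *, validate: bool = True) -> tuple[str, str]:
    """Serialize a document to ``(text_content, ann_content)``.

    Annotation ids are preserved; event triggers are emitted as T lines typed
    with the event type, numbered after the highest existing T id.  Round
    trip identity holds: ``read_standoff(*write_standoff(d)) == d``.
    """
    if validate:
        violations = validate_schema(doc)
        if violations:
            raise SchemaError(violations)
    lines: list[str] = []
    max_t = 0
    for e in doc.entities:
        m = re.fullmatch(r"T(\d+)", e.id)
        if m:
            max_t = max(max_t, int(m.group(1)))
    for e in doc.entities:
        lines.append(f"{e.id}\t{e.etype} {e.start} {e.end}\t{e.text}")
    next_t = max_t + 1
    for ev in doc.events:
        trig_id = f"T{next_t}"
        next_t += 1
        lines.append(
            f"{trig_id}\t{ev.evtype} {ev.trigger_start} {ev.trigger_end}\t{ev.trigger_text}"
        )
        args = [f"{ev.evtype}:{trig_id}"]
        for i, t in enumerate(ev.themes):
            slot = "Theme" if i == 0 else f"Theme{i + 1}"
            args.append(f"{slot}:{t}")
        for i, c in enumerate(ev.causes):
            slot = "Cause" if i == 0 else f"Cause{i + 1}"
            args.append(f"{slot}:{c}")
        lines.append(f"{ev.id}\t" + " ".join(args))
    ann = "\n".join(lines)
    if ann:
        ann += "\n"
    return doc.text, ann


def read_corpus(directory: str | Path, **kwargs) -> list[AnnotatedDocument]:
    """Read all ``.txt``/``.ann`` pairs in a directory, sorted by doc id.

    A missing ``.ann`` file is treated as an unannotated document.
    """
    directory = Path(directory)
    docs = []
    for txt_path in sorted(directory.glob("*.txt")):
        doc_id = txt_path.stem
        ann_path = txt_path.with_suffix(".ann")
        text = txt_path.read_text(encoding="utf-8")
        ann = ann_path.read_text(encoding="utf-8") if ann_path.exists() else ""
        docs.append(read_standoff(text, ann, doc_id, **kwargs))
    return docs


def write_corpus(docs: Iterable[AnnotatedDocument], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for doc in docs:
        text, ann = write_standoff(doc)
        (directory / f"{doc.doc_id}.txt").write_text(text, encoding="utf-8")
        (directory / f"{doc.doc_id}.ann").write_text(ann, encoding="utf-8")


def iter_entities(docs: Iterable[AnnotatedDocument]) -> Iterator[Entity]:
    for doc in docs:
        yield from doc.entities
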