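"""Rule-based baseline metabolic event extractor.

The extractor is a deterministic, transparent stage: sentence splitting
(rule-based with an abbreviation exception list), a >100-token sentence skip
rule (whitespace tokens), trigger detection against a small lexicon of event
words, and pattern-template argument attachment.  It is deliberately exposed
behind small composable functions so that gold annotations or an external
event classifier can be substituted for any stage.

Argument-attachment pattern templates, in precedence order (most specific
first); Met = metabolite entity, GP = gene/protein entity:

P1  ``<trigger> of <MetA> from <MetB> [by <GP>]`` -> Metabolic_reaction with
    themes (MetA = product, MetB = substrate) and optional Cause GP.
P2  ``<Met> <trigger> by <GP>`` -> event of the trigger's default type with
    Theme Met, Cause GP.
P3  ``<trigger> of <Met> by <GP>`` -> same as P2.
P4  ``<GP> <trigger>`` where the trigger maps to Positive_regulation and a
    later trigger in the sentence produced an event -> Positive_regulation
    with Theme = nearest following event and Cause GP.  Without a preceding
    GP the regulation event is still emitted, cause-less (nominalized
    phrasings such as "catalysis of ..." name no enzyme).
P5  fallback: nearest preceding Met as Theme, no Cause.

A trigger with no candidate theme produces no event (logged) — never a
schema-invalid one.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ConfigurationError
from .standoff import (
    CONSUMPTION,
    EVENT_TYPES,
    GP,
    METABOLITE,
    POSITIVE_REGULATION,
    PRODUCTION,
    REACTION,
    AnnotatedDocument,
    Entity,
    MetabolicEvent,
)

logger = logging.getLogger(__name__)

#: words never split on when followed by a period
ABBREVIATIONS = frozenset(
    {
        "al", "approx", "ca", "cf", "dr", "e", "e.g", "eq", "etc", "fig",
        "figs", "i.e", "mr", "mrs", "no", "sp", "spp", "st", "vs",
    }
)

DEFAULT_MAX_TOKENS = 100

#: event-word lexicon shipped by default: the nine generic keywords that
#: dominate metabolic event descriptions, plus morphological variants and a
#: few reaction-class nouns, each mapped to a default event type.
DEFAULT_TRIGGERS: dict[str, str] = {
    # positive regulation (catalysis vocabulary)
    "catalyzes": POSITIVE_REGULATION,
    "catalyze": POSITIVE_REGULATION,
    "catalyzed": POSITIVE_REGULATION,
    "catalyzing": POSITIVE_REGULATION,
    "catalysis": POSITIVE_REGULATION,
    # production
    "biosynthesis": PRODUCTION,
    "synthesis": PRODUCTION,
    "synthesized": PRODUCTION,
    "synthesizes": PRODUCTION,
    "synthesize": PRODUCTION,
    "formation": PRODUCTION,
    "formed": PRODUCTION,
    "production": PRODUCTION,
    "produced": PRODUCTION,
    "produces": PRODUCTION,
    # consumption
    "utilization": CONSUMPTION,
    "utilized": CONSUMPTION,
    "utilizes": CONSUMPTION,
    "utilize": CONSUMPTION,
    "metabolism": CONSUMPTION,
    "metabolized": CONSUMPTION,
    "degradation": CONSUMPTION,
    "degraded": CONSUMPTION,
    "amination": CONSUMPTION,
    # reaction
    "conversion": REACTION,
    "converted": REACTION,
    "converts": REACTION,
}


@dataclass(frozen=True)
class SentenceSpan:
    """A sentence interval into the document text (whitespace-trimmed)."""

    start: int
    end: int
    n_tokens: int

    def slice(self, text: str) -> str:
        return text[self.start : self.end]


@dataclass(frozen=True)
class Trigger:
    start: int
    end: int
    text: str
    evtype: str


@dataclass
class TriggerLexicon:
    """Mapping from casefolded event word to its default event type."""

    entries: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {t for t in self.entries.values() if t not in EVENT_TYPES}
        if bad:
            raise ConfigurationError(f"unknown event types in lexicon: {sorted(bad)}")
        self.entries = {w.casefold(): t for w, t in self.entries.items()}

    @classmethod
    def default(cls) -> "TriggerLexicon":
        return cls(dict(DEFAULT_TRIGGERS))

    @classmethod
    def from_tsv(cls, content: str) -> "TriggerLexicon":
        """Parse ``word<TAB>event_type`` lines."""
        entries = {}
        for line in content.splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            word, evtype = line.split("\t")[:2]
            entries[word] = evtype.strip()
        return cls(entries)

    @classmethod
    def from_file(cls, path: str | Path) -> "TriggerLexicon":
        return cls.from_tsv(Path(path).read_text(encoding="utf-8"))

    def __len__(self) -> int:
        return len(self.entries)


_TERMINATOR = re.compile(r"[.!?]+")
_LAST_WORD = re.compile(r"(\S+)$")


def split_sentences(text: str) -> list[SentenceSpan]:
    """Split text into sentence spans.

    A terminator run ends a sentence when it is at end of text or followed
    by whitespace and an uppercase letter, digit or opening quote/bracket,
    and the word before it is not a known abbreviation or a lone letter.
    Spans are trimmed of surrounding whitespace, so their concatenation plus
    the inter-sentence whitespace reconstructs the text.
    """
    boundaries: list[int] = []
    for m in _TERMINATOR.finditer(text):
        end = m.end()
        if end < len(text) and not text[end].isspace():
            continue
        j = end
        while j < len(text) and text[j].isspace():
            j += 1
        if j < len(text):
            nxt = text[j]
            if not (nxt.isupper() or nxt.isdigit() or nxt in "(\"'“["):
                continue
        wm = _LAST_WORD.search(text, 0, m.start())
        if wm:
            word = wm.group(1).lstrip("([\"'“").rstrip(".")
            if word.casefold() in ABBREVIATIONS or (len(word) == 1 and word.isalpha()):
                continue
        boundaries.append(end)
    if not boundaries or boundaries[-1] != len(text):
        boundaries.append(len(text))
    spans: list[SentenceSpan] = []
    prev = 0
    for b in boundaries:
        seg = text[prev:b]
        stripped = seg.strip()
        if stripped:
            start = prev + (len(seg) - len(seg.lstrip()))
            end = start + len(stripped)
            spans.append(SentenceSpan(start, end, len(stripped.split())))
        prev = b
    return spans


def filter_long_sentences(
    sentences: Sequence[SentenceSpan], max_tokens: int = DEFAULT_MAX_TOKENS
) -> list[SentenceSpan]:
    """Drop sentences with more than ``max_tokens`` whitespace tokens."""
    kept = [s for s in sentences if s.n_tokens <= max_tokens]
    skipped = len(sentences) - len(kept)
    if skipped:
        logger.info("skipped %d sentence(s) longer than %d tokens", skipped, max_tokens)
    return kept


def detect_triggers(
    text: str, sentence: SentenceSpan, lexicon: TriggerLexicon
) -> list[Trigger]:
    """Case-insensitive whole-word lexicon matches inside one sentence."""
    if len(lexicon) == 0:
        raise ConfigurationError("trigger lexicon is empty")
    chunk = sentence.slice(text)
    found: list[Trigger] = []
    for word, evtype in lexicon.entries.items():
        pat = re.compile(rf"(?<![0-9A-Za-z]){re.escape(word)}(?![0-9A-Za-z])", re.IGNORECASE)
        for m in pat.finditer(chunk):
            found.append(
                Trigger(sentence.start + m.start(), sentence.start + m.end(), m.group(0), evtype)
            )
    found.sort(key=lambda t: (t.start, t.end))
    return found


# gap patterns between a trigger/entity and the next argument; the whole gap
# text must match, so an intervening entity mention breaks adjacency
_GAP_OF = re.compile(r"\s+of(?:\s+(?:the|a|an))?\s+", re.IGNORECASE)
_GAP_FROM = re.compile(r"\s+from(?:\s+(?:the|a|an))?\s+", re.IGNORECASE)
_GAP_BY = re.compile(r"\s*,?\s*(?:and\s+)?by(?:\s+(?:the|a|an|its))?\s+", re.IGNORECASE)
_GAP_ADJ = re.compile(r"\s+")


def _first_after(
    pos: int, entities: Sequence[Entity], etype: str, gap: re.Pattern[str], text: str
) -> Entity | None:
    for e in sorted(entities, key=lambda e: e.start):
        if e.start < pos or e.etype != etype:
            continue
        if gap.fullmatch(text[pos : e.start]):
            return e
    return None


def _last_before(
    pos: int, entities: Sequence[Entity], etype: str, gap: re.Pattern[str] | None, text: str
) -> Entity | None:
    best = None
    for e in sorted(entities, key=lambda e: e.start):
        if e.end > pos or e.etype != etype:
            continue
        if gap is not None and not gap.fullmatch(text[e.end : pos]):
            continue
        best = e
    return best


def attach_arguments(
    text: str,
    trigger: Trigger,
    entities: Sequence[Entity],
    following_events: Sequence[MetabolicEvent] = (),
    event_id: str = "E1",
) -> MetabolicEvent | None:
    """Apply the pattern templates to one detected trigger.

    ``entities`` are the (gold or tagged) entities of the sentence holding
    the trigger; ``following_events`` are already-built events later in the
    sentence, used only for Positive_regulation triggers.  Returns ``None``
    when no pattern yields a schema-valid event.
    """
    if trigger.evtype == POSITIVE_REGULATION:
        # P4: nearest following event as theme; adjacent preceding GP as cause
        nxt = min(
            (ev for ev in following_events if ev.trigger_start > trigger.start),
            key=lambda ev: ev.trigger_start,
            default=None,
        )
        if nxt is None:
            logger.debug("regulation trigger %r has no following event", trigger.text)
            return None
        gp = _last_before(trigger.start, entities, GP, _GAP_ADJ, text)
        causes = (gp.id,) if gp else ()
        return MetabolicEvent(
            event_id, POSITIVE_REGULATION, trigger.start, trigger.end, trigger.text,
            themes=(nxt.id,), causes=causes,
        )

    # P1: "<trigger> of <MetA> from <MetB> [by <GP>]" -> reaction
    met_a = _first_after(trigger.end, entities, METABOLITE, _GAP_OF, text)
    if met_a is not None:
        met_b = _first_after(met_a.end, entities, METABOLITE, _GAP_FROM, text)
        if met_b is not None:
            gp = _first_after(met_b.end, entities, GP, _GAP_BY, text)
            return MetabolicEvent(
                event_id, REACTION, trigger.start, trigger.end, trigger.text,
                themes=(met_a.id, met_b.id), causes=(gp.id,) if gp else (),
            )

    # P2: "<Met> <trigger> by <GP>"
    met = _last_before(trigger.start, entities, METABOLITE, _GAP_ADJ, text)
    if met is not None:
        gp = _first_after(trigger.end, entities, GP, _GAP_BY, text)
        if gp is not None:
            return MetabolicEvent(
                event_id, trigger.evtype, trigger.start, trigger.end, trigger.text,
                themes=(met.id,), causes=(gp.id,),
            )

    # P3: "<trigger> of <Met> by <GP>"
    if met_a is not None:
        gp = _first_after(met_a.end, entities, GP, _GAP_BY, text)
        if gp is not None:
            return MetabolicEvent(
                event_id, trigger.evtype, trigger.start, trigger.end, trigger.text,
                themes=(met_a.id,), causes=(gp.id,),
            )

    # P5: fallback — nearest preceding metabolite, no cause; then nearest
    # following "of"-attached metabolite
    theme = met if met is not None else _last_before(trigger.start, entities, METABOLITE, None, text)
    if theme is None:
        theme = met_a
    if theme is None:
        logger.debug("trigger %r has no candidate theme; no event emitted", trigger.text)
        return None
    return MetabolicEvent(
        event_id, trigger.evtype, trigger.start, trigger.end, trigger.text,
        themes=(theme.id,), causes=(),
    )


def extract_events(
    text: str,
    entities: Sequence[Entity],
    lexicon: TriggerLexicon | None = None,
    *,
    max_tokens: int = DEFAULT_MAX_TOKENS,
    id_start: int = 1,
) -> list[MetabolicEvent]:
    """Run the full extractor over a document.

    Event ids are assigned in trigger order (``E<id_start>`` onward), so
    extraction is deterministic and re-running on identical input yields
    identical annotations.
    """
    if lexicon is None:
        lexicon = TriggerLexicon.default()
    sentences = filter_long_sentences(split_sentences(text), max_tokens)
    collected: list[MetabolicEvent] = []
    tmp = 0
    for sent in sentences:
        sent_entities = [e for e in entities if e.start >= sent.start and e.end <= sent.end]
        triggers = detect_triggers(text, sent, lexicon)
        sent_events: list[MetabolicEvent] = []
        for trig in triggers:
            if trig.evtype == POSITIVE_REGULATION:
                continue
            tmp += 1
            ev = attach_arguments(text, trig, sent_entities, (), f"tmp{tmp}")
            if ev is not None:
                sent_events.append(ev)
        for trig in triggers:
            if trig.evtype != POSITIVE_REGULATION:
                continue
            tmp += 1
            ev = attach_arguments(text, trig, sent_entities, sent_events, f"tmp{tmp}")
            if ev is not None:
                sent_events.append(ev)
        collected.extend(sent_events)
    # renumber by trigger position, rewriting nested-event references
    collected.sort(key=lambda ev: (ev.trigger_start, ev.trigger_end))
    rename = {ev.id: f"E{id_start + i}" for i, ev in enumerate(collected)}
    final = [
        MetabolicEvent(
            rename[ev.id], ev.evtype, ev.trigger_start, ev.trigger_end, ev.trigger_text,
            themes=tuple(rename.get(r, r) for r in ev.themes),
            causes=ev.causes,
        )
        for ev in collected
    ]
    return final


def run_extractor(
    doc: AnnotatedDocument, lexicon: TriggerLexicon | None = None, **kwargs
) -> AnnotatedDocument:
    """Return a copy of ``doc`` whose events are re-extracted from its text
    and (gold or tagged) entities."""
    events = extract_events(doc.text, doc.entities, lexicon, **kwargs)
    return AnnotatedDocument(doc.doc_id, doc.text, list(doc.entities), events)
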