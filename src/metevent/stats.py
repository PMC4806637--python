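"""Descriptive corpus statistics and event-word rankings.

For a corpus of annotated abstracts/titles this module reports, per entity
type and per event type: the total count, the mean and standard deviation
of the per-document counts, and (for events) the mean number of arguments
(themes + causes) per event — the layout of a standard corpus statistics
table.  It also ranks trigger words by frequency and measures what fraction
of all events a designated set of generic event words covers.

The standard deviation is the population SD by default (``sample_sd=True``
switches to the n-1 denominator); trigger words are casefolded but not
stemmed, so inflected forms rank separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .extraction import split_sentences
from .standoff import ENTITY_TYPES, EVENT_TYPES, AnnotatedDocument


@dataclass(frozen=True)
class TypeStats:
    total: int
    mean_per_doc: float
    sd_per_doc: float


@dataclass(frozen=True)
class EventTypeStats(TypeStats):
    mean_args: float


@dataclass
class CorpusStats:
    n_documents: int
    n_sentences: int
    entities: dict[str, TypeStats] = field(default_factory=dict)
    entity_total: TypeStats | None = None
    events: dict[str, EventTypeStats] = field(default_factory=dict)
    event_total: EventTypeStats | None = None


def _type_stats(per_doc: np.ndarray, sample_sd: bool) -> TypeStats:
    ddof = 1 if sample_sd and per_doc.size > 1 else 0
    return TypeStats(
        total=int(per_doc.sum()),
        mean_per_doc=float(per_doc.mean()),
        sd_per_doc=float(per_doc.std(ddof=ddof)),
    )


def corpus_statistics(
    corpus: Sequence[AnnotatedDocument], *, sample_sd: bool = False
) -> CorpusStats:
    """Compute corpus statistics; permutation-invariant over documents."""
    if not corpus:
        raise ValueError("corpus_statistics needs a non-empty corpus")
    n = len(corpus)
    n_sentences = sum(len(split_sentences(d.text)) for d in corpus)
    stats = CorpusStats(n_documents=n, n_sentences=n_sentences)

    ent_counts = {t: np.zeros(n) for t in sorted(ENTITY_TYPES)}
    for i, doc in enumerate(corpus):
        for e in doc.entities:
            if e.etype in ent_counts:
                ent_counts[e.etype][i] += 1
    for t, arr in ent_counts.items():
        stats.entities[t] = _type_stats(arr, sample_sd)
    stats.entity_total = _type_stats(sum(ent_counts.values()), sample_sd)

    ev_counts = {t: np.zeros(n) for t in sorted(EVENT_TYPES)}
    ev_args: dict[str, list[int]] = {t: [] for t in ev_counts}
    for i, doc in enumerate(corpus):
        for ev in doc.events:
            if ev.evtype in ev_counts:
                ev_counts[ev.evtype][i] += 1
                ev_args[ev.evtype].append(len(ev.themes) + len(ev.causes))
    all_args: list[int] = []
    for t, arr in ev_counts.items():
        base = _type_stats(arr, sample_sd)
        args = ev_args[t]
        all_args.extend(args)
        stats.events[t] = EventTypeStats(
            base.total, base.mean_per_doc, base.sd_per_doc,
            mean_args=float(np.mean(args)) if args else 0.0,
        )
    base = _type_stats(sum(ev_counts.values()), sample_sd)
    stats.event_total = EventTypeStats(
        base.total, base.mean_per_doc, base.sd_per_doc,
        mean_args=float(np.mean(all_args)) if all_args else 0.0,
    )
    return stats


def top_event_words(
    corpus: Iterable[AnnotatedDocument], n: int | None = 10
) -> list[tuple[str, int, float]]:
    """Rank casefolded trigger words by count (ties alphabetical).

    Returns ``(word, count, fraction of total events)`` rows; when ``n``
    exceeds the vocabulary the full ranking is returned.
    """
    counts: dict[str, int] = {}
    total = 0
    for doc in corpus:
        for ev in doc.events:
            word = ev.trigger_text.casefold()
            counts[word] = counts.get(word, 0) + 1
            total += 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if n is not None:
        ranked = ranked[:n]
    return [(w, c, c / total if total else 0.0) for w, c in ranked]


def generic_word_fraction(
    corpus: Iterable[AnnotatedDocument], words: Iterable[str]
) -> float:
    """Fraction of all events whose trigger word is in ``words``."""
    wordset = {w.casefold() for w in words}
    total = 0
    hit = 0
    for doc in corpus:
        for ev in doc.events:
            total += 1
            if ev.trigger_text.casefold() in wordset:
                hit += 1
    return hit / total if total else 0.0


def format_stats_text(stats: CorpusStats) -> str:
    """Human-readable report mirroring the standard table layout."""
    lines = [
        "Corpus statistics",
        f"Documents\t{stats.n_documents}",
        f"Sentences\t{stats.n_sentences}",
        "",
        "Entity type\ttotal (mean/doc, SD)",
    ]
    for t, s in stats.entities.items():
        lines.append(f"{t}\t{s.total} ({s.mean_per_doc:.2f}, {s.sd_per_doc:.2f})")
    s = stats.entity_total
    lines.append(f"Total\t{s.total} ({s.mean_per_doc:.2f}, {s.sd_per_doc:.2f})")
    lines += ["", "Event type\ttotal (mean/doc, SD) (args/event)"]
    for t, e in stats.events.items():
        lines.append(
            f"{t}\t{e.total} ({e.mean_per_doc:.2f}, {e.sd_per_doc:.2f}) ({e.mean_args:.2f})"
        )
    e = stats.event_total
    lines.append(
        f"Total\t{e.total} ({e.mean_per_doc:.2f}, {e.sd_per_doc:.2f}) ({e.mean_args:.2f})"
    )
    return "\n".join(lines) + "\n"


def stats_to_tsv(stats: CorpusStats) -> str:
    rows = ["category\tkind\ttotal\tmean_per_doc\tsd_per_doc\tmean_args"]
    for t, s in stats.entities.items():
        rows.append(f"{t}\tentity\t{s.total}\t{s.mean_per_doc:.4f}\t{s.sd_per_doc:.4f}\t")
    s = stats.entity_total
    rows.append(f"Total\tentity\t{s.total}\t{s.mean_per_doc:.4f}\t{s.sd_per_doc:.4f}\t")
    for t, e in stats.events.items():
        rows.append(
            f"{t}\tevent\t{e.total}\t{e.mean_per_doc:.4f}\t{e.sd_per_doc:.4f}\t{e.mean_args:.4f}"
        )
    e = stats.event_total
    rows.append(
        f"Total\tevent\t{e.total}\t{e.mean_per_doc:.4f}\t{e.sd_per_doc:.4f}\t{e.mean_args:.4f}"
    )
    return "\n".join(rows) + "\n"
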