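"""Gazetteer-based entity tagging and enzyme selection.

Dictionary matching stands in for a machine-learned named-entity tagger: a
GP gazetteer and a metabolite gazetteer are matched against the text
case-insensitively, whole multi-word entries tolerate arbitrary internal
whitespace, and matches may not start or end inside an alphanumeric run (so
an entry ``PL`` never fires inside ``PLP``).  Overlaps are resolved
longest-match-first, then leftmost, with GP winning ties — a deterministic
single pass.

Enzyme selection among GP mentions follows the event-word + enzyme-name
rule: a GP entity counts as an enzyme iff it is the Cause of some event or
its normalized surface form appears in an enzyme gazetteer.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .errors import ConfigurationError
from .standoff import GP, METABOLITE, AnnotatedDocument, Entity


def normalize_surface(s: str) -> str:
    """Casefold and collapse internal whitespace."""
    return " ".join(s.split()).casefold()


@dataclass
class Gazetteer:
    """A dictionary of surface strings mapping to canonical names.

    ``entries`` keys are normalized surfaces; values are canonical names
    (the surface itself when no canonical was given).
    """

    etype: str
    entries: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_terms(cls, etype: str, terms: Iterable[str | tuple[str, str]]) -> "Gazetteer":
        entries = {}
        for t in terms:
            if isinstance(t, tuple):
                surface, canonical = t
            else:
                surface, canonical = t, t
            entries[normalize_surface(surface)] = canonical
        return cls(etype, entries)

    @classmethod
    def from_tsv(cls, content: str, etype: str) -> "Gazetteer":
        """Parse ``surface<TAB>canonical`` lines (canonical optional)."""
        terms: list[tuple[str, str]] = []
        for line in content.splitlines():
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            surface = parts[0]
            canonical = parts[1] if len(parts) > 1 and parts[1].strip() else surface
            terms.append((surface, canonical))
        return cls.from_terms(etype, terms)

    @classmethod
    def from_file(cls, path: str | Path, etype: str) -> "Gazetteer":
        return cls.from_tsv(Path(path).read_text(encoding="utf-8"), etype)

    def __contains__(self, surface: str) -> bool:
        return normalize_surface(surface) in self.entries

    def canonical(self, surface: str) -> str | None:
        return self.entries.get(normalize_surface(surface))

    def __len__(self) -> int:
        return len(self.entries)


def _entry_pattern(surface: str) -> re.Pattern[str]:
    tokens = [re.escape(tok) for tok in surface.split()]
    body = r"\s+".join(tokens)
    return re.compile(rf"(?<![0-9A-Za-z]){body}(?![0-9A-Za-z])", re.IGNORECASE)


def _candidates(text: str, gaz: Gazetteer) -> list[tuple[int, int, str]]:
    out = []
    for surface in gaz.entries:
        for m in _entry_pattern(surface).finditer(text):
            out.append((m.start(), m.end(), gaz.etype))
    return out


def tag_entities(
    text: str,
    gaz_gp: Gazetteer,
    gaz_met: Gazetteer,
    *,
    id_start: int = 1,
) -> list[Entity]:
    """Tag GP and metabolite mentions; returns non-overlapping entities
    sorted by start offset with ids ``T<id_start>``, ``T<id_start+1>``, ...
    """
    if len(gaz_gp) == 0 or len(gaz_met) == 0:
        raise ConfigurationError("gazetteers must be non-empty for tagging")
    candidates = _candidates(text, gaz_gp) + _candidates(text, gaz_met)
    # longest first, then leftmost; GP beats Metabolite on full ties
    candidates.sort(key=lambda c: (-(c[1] - c[0]), c[0], 0 if c[2] == GP else 1))
    accepted: list[tuple[int, int, str]] = []
    for start, end, etype in candidates:
        if any(start < a_end and end > a_start for a_start, a_end, _ in accepted):
            continue
        accepted.append((start, end, etype))
    accepted.sort(key=lambda c: c[0])
    return [
        Entity(f"T{id_start + i}", etype, start, end, text[start:end])
        for i, (start, end, etype) in enumerate(accepted)
    ]


def select_enzymes(doc: AnnotatedDocument, enzyme_gaz: Gazetteer | None = None) -> set[str]:
    """Ids of GP entities treated as enzymes.

    A GP entity is selected iff (a) it appears as the Cause of any event, or
    (b) its normalized surface form is in ``enzyme_gaz``.  Monotone in the
    gazetteer: adding entries never removes selections.
    """
    cause_refs = {ref for ev in doc.events for ref in ev.causes}
    selected = set()
    for e in doc.entities:
        if e.etype != GP:
            continue
        if e.id in cause_refs:
            selected.add(e.id)
        elif enzyme_gaz is not None and e.text in enzyme_gaz:
            selected.add(e.id)
    return selected
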