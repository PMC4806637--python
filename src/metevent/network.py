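"""Event-to-interaction mapping and bipartite network reconstruction.

Extracted events are first converted to a per-document *event interaction
graph* (entities and events as nodes, Theme/Cause argument edges), then
distilled into directed enzyme–metabolite :class:`InteractionPair` records,
merged across documents under name normalization and a synonym map, and
finally assembled into a strictly bipartite metabolic network.  Where an
event names no enzyme, a deterministic ``PROXY_<k>`` node preserves
bipartiteness.

Conversion rules (applied exhaustively):

R1  production(Theme M, Cause E)  -> (E, M, produces), role product
R2  consumption(Theme M, Cause E) -> (E, M, consumes), role substrate
R3  reaction(Themes {Mi}, Cause E) -> one (E, Mi, reaction) pair per theme;
    with exactly two themes the first carries role product and the second
    substrate (the "formation of X from Y" convention)
R4  Positive_regulation(Theme = event X, Cause E) -> rules R1–R3 applied to
    X with E added as a cause, recursively through nested regulations; an
    explicit cause on X is kept alongside (both yield pairs)
R5  a rule firing with no cause at all -> enzyme = fresh proxy id
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .errors import DanglingReferenceError, MetEventError, NamingCollisionError
from .standoff import (
    CONSUMPTION,
    CORE_EVENT_TYPES,
    POSITIVE_REGULATION,
    PRODUCTION,
    REACTION,
    AnnotatedDocument,
)

PRODUCES = "produces"
CONSUMES = "consumes"
REACTION_DIR = "reaction"
DIRECTIONS = (PRODUCES, CONSUMES, REACTION_DIR)

_DIRECTION_OF = {PRODUCTION: PRODUCES, CONSUMPTION: CONSUMES, REACTION: REACTION_DIR}
_ROLE_OF = {PRODUCES: "product", CONSUMES: "substrate"}

_STRIP_CHARS = " \t\n.,;:()[]{}\"'"


def normalize_name(name: str, synonym_map: Mapping[str, str] | None = None) -> str:
    """Canonicalize an entity name for merging.

    Casefold, collapse internal whitespace, strip leading/trailing
    punctuation, then apply the synonym map (whose keys and values are
    normalized the same way).
    """
    s = " ".join(name.split()).casefold().strip(_STRIP_CHARS)
    if synonym_map:
        s = synonym_map.get(s, s)
    return s


def load_synonym_map(content: str) -> dict[str, str]:
    """Parse ``surface<TAB>canonical`` lines into a normalized synonym map."""
    out: dict[str, str] = {}
    for line in content.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            continue
        out[normalize_name(parts[0])] = normalize_name(parts[1])
    return out


@dataclass(frozen=True)
class InteractionPair:
    """A directed enzyme–metabolite relation with provenance.

    ``provenance`` is a tuple of ``(doc_id, event_ids)`` records naming the
    events each occurrence was distilled from.
    """

    enzyme: str
    metabolite: str
    direction: str
    role: str | None = None
    is_proxy: bool = False
    provenance: tuple[tuple[str, tuple[str, ...]], ...] = ()

    def key(self) -> tuple[str, str, str]:
        return (self.enzyme, self.metabolite, self.direction)


class ProxyAllocator:
    """Deterministic ``PROXY_<k>`` ids in first-appearance order."""

    def __init__(self, start: int = 1):
        self._next = start

    def new(self) -> str:
        pid = f"PROXY_{self._next}"
        self._next += 1
        return pid


def build_event_graph(doc: AnnotatedDocument) -> nx.DiGraph:
    """Per-document event interaction graph.

    Nodes are annotation ids with ``kind`` ("entity"/"event"), type and
    surface-name attributes; each argument slot becomes one directed edge
    from the event to its argument, labelled with its role.
    """
    g = nx.DiGraph(doc_id=doc.doc_id)
    for e in doc.entities:
        g.add_node(e.id, kind="entity", etype=e.etype, name=e.text)
    for ev in doc.events:
        g.add_node(ev.id, kind="event", evtype=ev.evtype, name=ev.trigger_text)
    ids = doc.annotation_ids()
    for ev in doc.events:
        for i, t in enumerate(ev.themes):
            if t not in ids:
                raise DanglingReferenceError(f"{doc.doc_id}/{ev.id}: theme {t!r} unresolved")
            g.add_edge(ev.id, t, role="Theme", order=i)
        for i, c in enumerate(ev.causes):
            if c not in ids:
                raise DanglingReferenceError(f"{doc.doc_id}/{ev.id}: cause {c!r} unresolved")
            g.add_edge(ev.id, c, role="Cause", order=i)
    return g


def _propagated_causes(
    graph: nx.DiGraph, regulators: Mapping[str, list[str]], node: str,
    memo: dict[str, list[tuple[str, str]]],
) -> list[tuple[str, str]]:
    """(enzyme entity id, regulating event id) pairs inherited through
    Positive_regulation ancestors of ``node``."""
    if node in memo:
        return memo[node]
    memo[node] = []  # cycle guard; documents are validated acyclic anyway
    out: list[tuple[str, str]] = []
    for reg in regulators.get(node, ()):
        for _, tgt, data in graph.out_edges(reg, data=True):
            if data["role"] == "Cause":
                out.append((tgt, reg))
        out.extend(_propagated_causes(graph, regulators, reg, memo))
    memo[node] = out
    return out


def to_interactions(
    graph: nx.DiGraph, proxies: ProxyAllocator | None = None
) -> list[InteractionPair]:
    """Distill an event interaction graph into enzyme–metabolite pairs."""
    if proxies is None:
        proxies = ProxyAllocator()
    doc_id = graph.graph.get("doc_id", "doc")
    nodes = graph.nodes
    event_ids = [n for n in nodes if nodes[n].get("kind") == "event"]
    event_ids.sort(key=lambda n: (len(n), n))
    regulators: dict[str, list[str]] = {}
    for ev in event_ids:
        if nodes[ev]["evtype"] != POSITIVE_REGULATION:
            continue
        for _, tgt, data in graph.out_edges(ev, data=True):
            if data["role"] == "Theme":
                regulators.setdefault(tgt, []).append(ev)
    memo: dict[str, list[tuple[str, str]]] = {}
    pairs: list[InteractionPair] = []
    for ev in event_ids:
        evtype = nodes[ev]["evtype"]
        if evtype not in CORE_EVENT_TYPES:
            continue
        themes = sorted(
            (
                (data["order"], tgt)
                for _, tgt, data in graph.out_edges(ev, data=True)
                if data["role"] == "Theme" and nodes[tgt].get("kind") == "entity"
            ),
        )
        theme_names = [nodes[t]["name"] for _, t in themes]
        own_causes = [
            (tgt, None)
            for _, tgt, data in sorted(
                graph.out_edges(ev, data=True), key=lambda e: e[2].get("order", 0)
            )
            if data["role"] == "Cause"
        ]
        inherited = [(c, reg) for c, reg in _propagated_causes(graph, regulators, ev, memo)]
        causes: list[tuple[str | None, str | None]] = []
        seen: set[str] = set()
        for cid, reg in own_causes + inherited:
            if cid not in seen:
                seen.add(cid)
                causes.append((cid, reg))
        if not causes:
            causes = [(None, None)]  # R5: proxy
        direction = _DIRECTION_OF[evtype]
        if evtype == REACTION and len(theme_names) == 2:
            roles: list[str | None] = ["product", "substrate"]
        elif evtype in (PRODUCTION, CONSUMPTION):
            roles = [_ROLE_OF[direction]] * len(theme_names)
        else:
            roles = [None] * len(theme_names)
        for cid, reg in causes:
            if cid is None:
                enzyme, is_proxy = proxies.new(), True
            else:
                enzyme, is_proxy = nodes[cid]["name"], False
            ev_ids = (ev,) if reg is None else (ev, reg)
            for name, role in zip(theme_names, roles):
                pairs.append(
                    InteractionPair(
                        enzyme=enzyme,
                        metabolite=name,
                        direction=direction,
                        role=role,
                        is_proxy=is_proxy,
                        provenance=((doc_id, ev_ids),),
                    )
                )
    return pairs


def documents_to_interactions(
    docs: Iterable[AnnotatedDocument], proxies: ProxyAllocator | None = None
) -> list[InteractionPair]:
    """Convenience: event graphs + :func:`to_interactions` over a corpus,
    sharing one proxy allocator so proxies never merge across documents."""
    if proxies is None:
        proxies = ProxyAllocator()
    pairs: list[InteractionPair] = []
    for doc in docs:
        pairs.extend(to_interactions(build_event_graph(doc), proxies))
    return pairs


def merge_interactions(
    pairs: Iterable[InteractionPair], synonym_map: Mapping[str, str] | None = None
) -> list[InteractionPair]:
    """Merge pairs under name canonicalization.

    The result contains no two pairs with the same (enzyme, metabolite,
    direction); provenance records are pooled, sorted and de-duplicated, so
    the operation is idempotent and order-insensitive.  Proxy enzyme ids are
    left untouched.  A role is kept only when all merged occurrences agree.
    """
    groups: dict[tuple[str, str, str], list[InteractionPair]] = {}
    for p in pairs:
        enzyme = p.enzyme if p.is_proxy else normalize_name(p.enzyme, synonym_map)
        metabolite = normalize_name(p.metabolite, synonym_map)
        q = replace(p, enzyme=enzyme, metabolite=metabolite)
        groups.setdefault(q.key(), []).append(q)
    merged = []
    for key in sorted(groups):
        members = groups[key]
        roles = {m.role for m in members if m.role is not None}
        provenance = tuple(sorted({rec for m in members for rec in m.provenance}))
        merged.append(
            replace(
                members[0],
                role=roles.pop() if len(roles) == 1 else None,
                provenance=provenance,
            )
        )
    return merged


def infer_conversions(
    pairs: Iterable[InteractionPair],
) -> list[tuple[str, str, str]]:
    """(substrate, enzyme, product) triples from consumes/produces pairs.

    For every enzyme with at least one consumed and one produced metabolite,
    all substrate × product combinations are emitted (substrate != product).
    """
    consumed: dict[str, set[str]] = {}
    produced: dict[str, set[str]] = {}
    for p in pairs:
        if p.direction == CONSUMES:
            consumed.setdefault(p.enzyme, set()).add(p.metabolite)
        elif p.direction == PRODUCES:
            produced.setdefault(p.enzyme, set()).add(p.metabolite)
    out = []
    for enzyme in sorted(set(consumed) & set(produced)):
        for ms in sorted(consumed[enzyme]):
            for mp in sorted(produced[enzyme]):
                if ms != mp:
                    out.append((ms, enzyme, mp))
    return out


@dataclass
class BipartiteNetwork:
    """Strictly bipartite enzyme–metabolite network.

    Backed by a :class:`networkx.MultiGraph`; nodes carry ``part``
    ("enzyme"/"metabolite") and ``is_proxy`` attributes, edges are keyed by
    direction and carry role and provenance.
    """

    graph: nx.MultiGraph = field(default_factory=nx.MultiGraph)

    @property
    def enzymes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["part"] == "enzyme"}

    @property
    def metabolites(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["part"] == "metabolite"}

    @property
    def proxies(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d.get("is_proxy")}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def is_bipartite(self) -> bool:
        return all(
            {self.graph.nodes[u]["part"], self.graph.nodes[v]["part"]}
            == {"enzyme", "metabolite"}
            for u, v in self.graph.edges()
        )

    def pairs(self) -> list[InteractionPair]:
        out = []
        for u, v, key, data in self.graph.edges(keys=True, data=True):
            enz, met = (u, v) if self.graph.nodes[u]["part"] == "enzyme" else (v, u)
            out.append(
                InteractionPair(
                    enzyme=enz,
                    metabolite=met,
                    direction=key,
                    role=data.get("role"),
                    is_proxy=bool(self.graph.nodes[enz].get("is_proxy")),
                    provenance=data.get("provenance", ()),
                )
            )
        out.sort(key=lambda p: p.key())
        return out


def build_network(pairs: Iterable[InteractionPair]) -> BipartiteNetwork:
    """Assemble merged pairs into a bipartite network.

    Node count = distinct enzymes (including proxies) + distinct
    metabolites; edge count = number of pairs.  An enzyme whose name equals
    a metabolite name cannot be represented bipartitely and raises
    :class:`NamingCollisionError` (resolve via the synonym map).
    """
    pairs = list(pairs)
    enzymes = {p.enzyme for p in pairs}
    metabolites = {p.metabolite for p in pairs}
    clash = enzymes & metabolites
    if clash:
        raise NamingCollisionError(
            f"name(s) used as both enzyme and metabolite: {sorted(clash)}"
        )
    net = BipartiteNetwork()
    for p in pairs:
        net.graph.add_node(p.enzyme, part="enzyme", is_proxy=p.is_proxy)
        net.graph.add_node(p.metabolite, part="metabolite", is_proxy=False)
        net.graph.add_edge(
            p.enzyme, p.metabolite, key=p.direction,
            direction=p.direction, role=p.role, provenance=p.provenance,
        )
    return net


def _provenance_to_str(prov: tuple[tuple[str, tuple[str, ...]], ...]) -> str:
    return json.dumps([[doc, list(evs)] for doc, evs in prov])


def _provenance_from_str(s: str) -> tuple[tuple[str, tuple[str, ...]], ...]:
    if not s:
        return ()
    return tuple((doc, tuple(evs)) for doc, evs in json.loads(s))


def export_network(net: BipartiteNetwork, fmt: str) -> str:
    """Serialize to ``sif``, ``tsv`` or ``graphml`` text."""
    if fmt == "sif":
        lines = sorted(f"{p.enzyme}\t{p.direction}\t{p.metabolite}" for p in net.pairs())
        return "\n".join(lines) + ("\n" if lines else "")
    if fmt == "tsv":
        return pairs_to_tsv(net.pairs())
    if fmt == "graphml":
        g = nx.MultiGraph()
        for n, d in net.graph.nodes(data=True):
            g.add_node(n, part=d["part"], is_proxy=bool(d.get("is_proxy")))
        for u, v, key, d in net.graph.edges(keys=True, data=True):
            g.add_edge(
                u, v, key=key, direction=d["direction"], role=d.get("role") or "",
                provenance=_provenance_to_str(d.get("provenance", ())),
            )
        return "\n".join(nx.generate_graphml(g)) + "\n"
    raise MetEventError(f"unknown export format {fmt!r} (expected sif, tsv or graphml)")


def import_network(content: str, fmt: str) -> BipartiteNetwork:
    """Re-import ``tsv`` or ``graphml`` content written by
    :func:`export_network`."""
    if fmt == "tsv":
        return build_network(pairs_from_tsv(content))
    if fmt == "graphml":
        g = nx.parse_graphml(content, force_multigraph=True)
        net = BipartiteNetwork()
        for n, d in g.nodes(data=True):
            net.graph.add_node(
                n, part=d["part"], is_proxy=d.get("is_proxy") in (True, "true", "True", "1")
            )
        for u, v, key, d in g.edges(keys=True, data=True):
            net.graph.add_edge(
                u, v, key=d.get("direction", key),
                direction=d.get("direction", key),
                role=d.get("role") or None,
                provenance=_provenance_from_str(d.get("provenance", "")),
            )
        return net
    raise MetEventError(f"unknown import format {fmt!r} (expected tsv or graphml)")


_TSV_HEADER = "enzyme\tdirection\tmetabolite\trole\tis_proxy\tdoc_ids\tprovenance"


def pairs_to_tsv(pairs: Iterable[InteractionPair]) -> str:
    """Byte-stable, lexicographically sorted pair table."""
    rows = []
    for p in sorted(pairs, key=lambda p: p.key()):
        doc_ids = ",".join(sorted({doc for doc, _ in p.provenance}))
        rows.append(
            "\t".join(
                [
                    p.enzyme, p.direction, p.metabolite, p.role or "",
                    "1" if p.is_proxy else "0", doc_ids,
                    _provenance_to_str(p.provenance),
                ]
            )
        )
    return "\n".join([_TSV_HEADER] + rows) + "\n"


def pairs_from_tsv(content: str) -> list[InteractionPair]:
    pairs = []
    lines = [ln for ln in content.splitlines() if ln.strip()]
    for line in lines:
        if line.startswith("enzyme\t"):
            continue
        cols = line.split("\t")
        enzyme, direction, metabolite = cols[0], cols[1], cols[2]
        role = cols[3] or None if len(cols) > 3 else None
        is_proxy = len(cols) > 4 and cols[4] == "1"
        provenance = _provenance_from_str(cols[6]) if len(cols) > 6 else ()
        pairs.append(
            InteractionPair(enzyme, metabolite, direction, role, is_proxy, provenance)
        )
    return pairs
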