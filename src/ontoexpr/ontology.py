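"""Ontologies, controlled vocabularies and taxon constraints.

The anatomy axis of a condition is annotated against a single multispecies
ontology (an Uberon-like composite that merges the cell ontology and
species-specific anatomies), the developmental axis against a stage
ontology, and sex/strain against flat controlled vocabularies whose members
all hang directly under one root label.

Only a restricted OBO dialect is honored: ``[Term]`` stanzas with ``id``,
``name``, ``is_a``, ``relationship: part_of`` and ``is_obsolete``.  Every
other tag is silently ignored.  Parsing is delegated to :mod:`obonet`; this
module layers validation (dangling parents, cycles) and DAG traversal on
top of the resulting graph.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import obonet

from .errors import (
    CycleDetected,
    DanglingParent,
    EmptyOntology,
    MalformedStanza,
    UnknownTerm,
)

#: relations traversed by default when propagating conditions
DEFAULT_RELATIONS = frozenset({"is_a", "part_of"})


@dataclass(frozen=True)
class OntologyTerm:
    """One ontology term: a CURIE, a human label and its typed parent edges."""

    id: str
    name: str
    parents: tuple[tuple[str, str], ...] = ()  # (relation, parent CURIE)
    obsolete: bool = False


class Ontology:
    """A DAG of terms over typed edges ``is_a`` and ``part_of``.

    The internal graph stores one edge child -> parent per (relation,
    parent); traversal results are memoized per (term, relation set).
    """

    def __init__(self, terms: Mapping[str, OntologyTerm]):
        self.terms: dict[str, OntologyTerm] = dict(terms)
        g = nx.MultiDiGraph()
        g.add_nodes_from(self.terms)
        for t in self.terms.values():
            for rel, parent in t.parents:
                if parent not in self.terms:
                    raise DanglingParent(
                        f"term {t.id!r} references missing parent {parent!r}"
                    )
                g.add_edge(t.id, parent, key=rel)
        if not nx.is_directed_acyclic_graph(nx.DiGraph(g)):
            cyc = nx.find_cycle(nx.DiGraph(g))
            raise CycleDetected(f"cycle over is_a/part_of: {cyc}")
        self.graph = g
        self.roots: frozenset[str] = frozenset(
            n for n in g.nodes if g.out_degree(n) == 0
        )
        self._closure_cache: dict[tuple[str, frozenset, bool], frozenset] = {}

    # -- basics ---------------------------------------------------------

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)

    def _check(self, term: str) -> None:
        if term not in self.terms:
            raise UnknownTerm(f"unknown term {term!r}")

    # -- traversal ------------------------------------------------------

    def _reach(self, term: str, relations: frozenset, up: bool) -> frozenset:
        key = (term, relations, up)
        hit = self._closure_cache.get(key)
        if hit is not None:
            return hit
        seen: set[str] = set()
        stack = [term]
        while stack:
            node = stack.pop()
            edges = (
                self.graph.out_edges(node, keys=True)
                if up
                else self.graph.in_edges(node, keys=True)
            )
            for u, v, rel in edges:
                nxt = v if up else u
                if rel in relations and nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        out = frozenset(seen)
        self._closure_cache[key] = out
        return out

    def ancestors(
        self, term: str, relations: Iterable[str] = DEFAULT_RELATIONS
    ) -> frozenset[str]:
        """Transitive ancestors of *term* over *relations*, excluding itself."""
        self._check(term)
        return self._reach(term, frozenset(relations), up=True)

    def descendants(
        self, term: str, relations: Iterable[str] = DEFAULT_RELATIONS
    ) -> frozenset[str]:
        """Transitive descendants of *term* over *relations* (inverse edges)."""
        self._check(term)
        return self._reach(term, frozenset(relations), up=False)

    def depth(self, term: str, relations: Iterable[str] = DEFAULT_RELATIONS) -> int:
        """Longest path length from *term* up to any root (0 for a root)."""
        self._check(term)
        rels = frozenset(relations)
        best = 0
        stack = [(term, 0)]
        while stack:
            node, d = stack.pop()
            parents = [
                v for _, v, rel in self.graph.out_edges(node, keys=True) if rel in rels
            ]
            if not parents:
                best = max(best, d)
            for p in parents:
                stack.append((p, d + 1))
        return best

    # -- taxon filtering ------------------------------------------------

    def filter_by_taxon(
        self, species, tc: "TaxonConstraints", permissive: bool = False
    ) -> "Ontology":
        """Sub-ontology of terms existing in *species*.

        Children of removed terms are re-wired to each nearest retained
        ancestor, carrying over the relation of the child's original edge,
        so reachability among retained terms is preserved.
        """
        kept = {t for t in self.terms if tc.exists(t, species, permissive)}
        if not kept:
            raise EmptyOntology(f"no term exists for species {species!r}")

        def nearest_kept(start: str) -> set[str]:
            # walk upward through removed terms until a kept one is met
            found: set[str] = set()
            seen: set[str] = set()
            stack = [start]
            while stack:
                node = stack.pop()
                if node in kept:
                    found.add(node)
                    continue
                for _, v, _rel in self.graph.out_edges(node, keys=True):
                    if v not in seen:
                        seen.add(v)
                        stack.append(v)
            return found

        new_terms: dict[str, OntologyTerm] = {}
        for tid in kept:
            parents: list[tuple[str, str]] = []
            for rel, parent in self.terms[tid].parents:
                targets = {parent} if parent in kept else nearest_kept(parent)
                for tgt in sorted(targets):
                    if (rel, tgt) not in parents:
                        parents.append((rel, tgt))
            old = self.terms[tid]
            new_terms[tid] = OntologyTerm(old.id, old.name, tuple(parents))
        return Ontology(new_terms)


def parse_obo(stream) -> Ontology:
    """Parse a restricted OBO 1.2 text stream into an :class:`Ontology`.

    Obsolete terms are dropped; edges pointing to obsolete terms are
    removed with them (obsolete terms carry no children).  A parent
    reference to a term never defined raises :class:`DanglingParent`; a
    cycle over is_a/part_of raises :class:`CycleDetected`; a stanza without
    an id raises :class:`MalformedStanza`.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    try:
        # obonet logs header chatter on the root logger; keep it quiet
        logging.disable(logging.WARNING)
        try:
            g = obonet.read_obo(stream, ignore_obsolete=False)
        finally:
            logging.disable(logging.NOTSET)
    except KeyError as exc:  # obonet raises KeyError('id') on id-less stanzas
        raise MalformedStanza(f"stanza missing tag {exc}") from exc

    obsolete = {
        n
        for n, data in g.nodes(data=True)
        if str(data.get("is_obsolete", "")).lower() == "true"
    }
    # nodes created only as edge targets carry no attributes at all
    dangling = {
        n for n, data in g.nodes(data=True) if not data and n not in obsolete
    }

    terms: dict[str, OntologyTerm] = {}
    for node, data in g.nodes(data=True):
        if node in obsolete or node in dangling:
            continue
        parents = []
        for _, parent, rel in g.out_edges(node, keys=True):
            if rel not in DEFAULT_RELATIONS:
                continue  # unsupported relationship types ignored
            if parent in obsolete:
                continue
            if parent in dangling:
                raise DanglingParent(
                    f"term {node!r} references undefined parent {parent!r}"
                )
            parents.append((rel, parent))
        terms[node] = OntologyTerm(
            id=node, name=data.get("name", node), parents=tuple(parents)
        )
    if dangling:
        # dangling nodes referenced by retained terms raise above; any left
        # here were referenced only by obsolete terms and can be ignored,
        # unless some retained term points at them (handled above).
        pass
    return Ontology(terms)


@dataclass(frozen=True)
class ControlledVocabulary:
    """Flat vocabulary: every member's sole parent is the root label."""

    root: str
    members: frozenset[str]

    def __contains__(self, label: str) -> bool:
        return label == self.root or label in self.members

    def parent(self, label: str) -> str | None:
        if label == self.root:
            return None
        if label not in self.members:
            raise UnknownTerm(f"{label!r} not in vocabulary rooted at {self.root!r}")
        return self.root


@dataclass
class TaxonConstraints:
    """Per-(term, species) existence flags for a multispecies ontology.

    In strict mode (default), a pair absent from the table counts as
    non-existent; ``permissive=True`` inverts the default.
    """

    _table: dict[tuple[str, object], bool] = field(default_factory=dict)

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, object, bool]]):
        tc = cls()
        for term, species, flag in records:
            tc._table[(term, species)] = bool(flag)
        return tc

    def exists(self, term: str, species, permissive: bool = False) -> bool:
        return self._table.get((term, species), permissive)

    def set(self, term: str, species, flag: bool) -> None:
        self._table[(term, species)] = bool(flag)

    def __len__(self) -> int:
        return len(self._table)
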