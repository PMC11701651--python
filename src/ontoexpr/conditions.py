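"""Post-composed conditions and the condition graph.

A condition is the intersection of five independently-maintained axes:
anatomical entity, cell type, developmental stage, sex and strain, for one
species.  Anatomy and cell type are post-composed — stored as two separate
term fields from the same merged multispecies ontology, never fused into a
pre-composed CURIE.  Annotations are propagated to every combination of
per-axis ancestors, yielding a DAG of conditions ordered by the product of
the per-axis ontology orders; data attached to a condition are therefore
visible from all of its ancestral conditions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import networkx as nx

from .errors import (
    GraphSizeExceeded,
    NoSpeciesOrExperiment,
    TermNotInSpecies,
    UnknownTerm,
)
from .ontology import (
    DEFAULT_RELATIONS,
    ControlledVocabulary,
    Ontology,
    TaxonConstraints,
)

AXES = ("anat", "cell_type", "stage", "sex", "strain")

#: conventional vocabulary roots
ANY_SEX = "any sex"
WILD_TYPE = "wild type"


@dataclass(frozen=True, order=True)
class Condition:
    """A post-composed annotation condition for one species."""

    anat: str
    cell_type: str
    stage: str
    sex: str
    strain: str
    species: object

    def axis(self, name: str) -> str:
        return getattr(self, name)

    def key(self) -> tuple:
        return (self.anat, self.cell_type, self.stage, self.sex, self.strain,
                str(self.species))


@dataclass(frozen=True)
class Annotation:
    """One curated library or cell population.

    The author's verbatim free-text label is always retained next to the
    ontology mapping; it may be empty only for bulk libraries.
    """

    library_id: str
    experiment_id: str
    condition: Condition
    free_text_label: str = ""
    data_type: str = "bulk"  # bulk | sc_droplet | sc_full_length
    integrated: bool = True


@dataclass
class ConditionContext:
    """Ontologies, vocabularies, constraints and axis roots for one dataset.

    ``anatomy`` serves both the anatomical-entity and the cell-type axes
    (the composite ontology merges the cell ontology into the anatomy
    ontology).  ``stage_relations`` is exposed separately because stage
    ontologies may be traversed over is_a only.
    """

    anatomy: Ontology
    stages: Ontology
    sex: ControlledVocabulary
    strain: ControlledVocabulary
    taxon_constraints: TaxonConstraints
    anat_root: str
    cell_root: str
    stage_root: str
    anat_relations: frozenset = DEFAULT_RELATIONS
    stage_relations: frozenset = DEFAULT_RELATIONS
    permissive_taxa: bool = False

    def root_condition(self, species) -> Condition:
        return Condition(self.anat_root, self.cell_root, self.stage_root,
                         self.sex.root, self.strain.root, species)

    def axis_root(self, axis: str) -> str:
        return {
            "anat": self.anat_root,
            "cell_type": self.cell_root,
            "stage": self.stage_root,
            "sex": self.sex.root,
            "strain": self.strain.root,
        }[axis]

    def _exists(self, term: str, species) -> bool:
        return self.taxon_constraints.exists(term, species, self.permissive_taxa)

    def axis_ancestors(self, axis: str, value: str, species) -> frozenset[str]:
        """Ancestors of *value* along one axis, valid for *species*."""
        if axis in ("anat", "cell_type"):
            onto, rels = self.anatomy, self.anat_relations
        elif axis == "stage":
            onto, rels = self.stages, self.stage_relations
        else:
            vocab = self.sex if axis == "sex" else self.strain
            return frozenset() if value == vocab.root else frozenset({vocab.root})
        anc = onto.ancestors(value, rels)
        return frozenset(a for a in anc if self._exists(a, species))

    def axis_descendants(self, axis: str, value: str, species=None) -> frozenset[str]:
        if axis in ("anat", "cell_type"):
            desc = self.anatomy.descendants(value, self.anat_relations)
        elif axis == "stage":
            desc = self.stages.descendants(value, self.stage_relations)
        else:
            vocab = self.sex if axis == "sex" else self.strain
            return frozenset(vocab.members) if value == vocab.root else frozenset()
        if species is None:
            return desc
        return frozenset(d for d in desc if self._exists(d, species))

    def is_axis_ancestor_or_equal(self, axis: str, a: str, b: str, species) -> bool:
        return a == b or a in self.axis_ancestors(axis, b, species)


def compose_condition(
    anat: str,
    cell_type: str,
    stage: str,
    sex: str,
    strain: str,
    species,
    ctx: ConditionContext,
) -> Condition:
    """Validate axis terms and build a :class:`Condition`.

    Ontology terms must exist in their ontology and pass the taxon
    constraints for *species*; sex/strain must belong to their vocabulary.
    """
    for axis, term, onto in (
        ("anat", anat, ctx.anatomy),
        ("cell_type", cell_type, ctx.anatomy),
        ("stage", stage, ctx.stages),
    ):
        if term not in onto:
            raise UnknownTerm(f"{axis} term {term!r} not in ontology")
        if not ctx._exists(term, species):
            raise TermNotInSpecies(
                f"{axis} term {term!r} does not exist for species {species!r}"
            )
    for axis, label, vocab in (("sex", sex, ctx.sex), ("strain", strain, ctx.strain)):
        if label not in vocab:
            raise UnknownTerm(f"{axis} label {label!r} not in vocabulary")
    return Condition(anat, cell_type, stage, sex, strain, species)


def collapse_condition(c: Condition, axes: Iterable[str], ctx: ConditionContext) -> Condition:
    """Keep only *axes*; every other axis is replaced by its root sentinel.

    Idempotent: collapsing an already-collapsed condition is a no-op.
    """
    keep = set(axes)
    if not keep:
        raise ValueError("axes must be a non-empty subset of " + str(AXES))
    unknown = keep - set(AXES)
    if unknown:
        raise ValueError(f"unknown axes {sorted(unknown)}")
    updates = {a: ctx.axis_root(a) for a in AXES if a not in keep}
    return replace(c, **updates) if updates else c


def condition_ancestors(c: Condition, ctx: ConditionContext) -> set[Condition]:
    """All ancestral conditions of *c*: the Cartesian product of per-axis
    {self union ancestors}, minus *c* itself."""
    per_axis = [
        sorted({c.axis(a)} | set(ctx.axis_ancestors(a, c.axis(a), c.species)))
        for a in AXES
    ]
    out = set()
    for combo in itertools.product(*per_axis):
        cond = Condition(*combo, species=c.species)
        if cond != c:
            out.add(cond)
    return out


def iter_condition_ancestors(c: Condition, ctx: ConditionContext):
    """Streamed variant of :func:`condition_ancestors` (lazy product)."""
    per_axis = [
        sorted({c.axis(a)} | set(ctx.axis_ancestors(a, c.axis(a), c.species)))
        for a in AXES
    ]
    for combo in itertools.product(*per_axis):
        cond = Condition(*combo, species=c.species)
        if cond != c:
            yield cond


class ConditionGraph:
    """DAG over annotated conditions and their inferred ancestors.

    Edges are the transitive reduction of the ancestor relation restricted
    to the node set; reachability queries go through the per-axis ontology
    indexes (:meth:`is_ancestor`), not the stored edges.
    """

    def __init__(self, nodes: set[Condition], edges: nx.DiGraph,
                 annotated: set[Condition], ctx: ConditionContext):
        self.nodes = nodes
        self.edges = edges  # parent -> child
        self.annotated = annotated
        self.ctx = ctx

    def is_ancestor(self, a: Condition, b: Condition) -> bool:
        """True iff *a* is a strict ancestor of *b* in the product order."""
        if a == b or a.species != b.species:
            return False
        return all(
            self.ctx.is_axis_ancestor_or_equal(ax, a.axis(ax), b.axis(ax), b.species)
            for ax in AXES
        )

    def ancestors_of(self, c: Condition) -> set[Condition]:
        return set(nx.ancestors(self.edges, c)) if c in self.edges else set()

    def descendants_of(self, c: Condition) -> set[Condition]:
        return set(nx.descendants(self.edges, c)) if c in self.edges else set()

    def parents_of(self, c: Condition) -> set[Condition]:
        return set(self.edges.predecessors(c))

    def children_of(self, c: Condition) -> set[Condition]:
        return set(self.edges.successors(c))

    def depth(self, c: Condition) -> int:
        """Longest path from any root node of the graph down to *c*."""
        return self._depths[c]

    def __contains__(self, c: Condition) -> bool:
        return c in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)


def build_condition_graph(
    annotations: Sequence[Annotation],
    ctx: ConditionContext,
    max_nodes: int = 1_000_000,
) -> ConditionGraph:
    """Build the condition graph for a set of validated annotations.

    Nodes are the annotated conditions plus every ancestral combination;
    the stored edge set is the transitive reduction (covering relation) of
    the ancestor order on the node set.  Raises
    :class:`GraphSizeExceeded` when inference would create more than
    *max_nodes* conditions.
    """
    annotated = {a.condition for a in annotations}
    nodes: set[Condition] = set(annotated)
    for c in annotated:
        for anc in iter_condition_ancestors(c, ctx):
            nodes.add(anc)
            if len(nodes) > max_nodes:
                raise GraphSizeExceeded(
                    f"condition graph exceeds {max_nodes} inferred nodes"
                )

    full = nx.DiGraph()
    full.add_nodes_from(nodes)
    node_list = sorted(nodes)
    # ancestor relation restricted to the node set; reduced below
    tmp_graph = ConditionGraph(nodes, full, annotated, ctx)
    for a in node_list:
        for b in node_list:
            if a is not b and tmp_graph.is_ancestor(a, b):
                full.add_edge(a, b)
    reduced = nx.transitive_reduction(full)
    reduced.add_nodes_from(nodes)

    graph = ConditionGraph(nodes, reduced, annotated, ctx)
    # longest-path depths (roots at 0), memoized once: DAG topological pass
    depths: dict[Condition, int] = {}
    for n in nx.topological_sort(reduced):
        preds = list(reduced.predecessors(n))
        depths[n] = 0 if not preds else 1 + max(depths[p] for p in preds)
    graph._depths = depths
    return graph


# --- annotation queries ------------------------------------------------------


@dataclass
class QueryFilters:
    """Raw-data query: AND across axes, OR within an axis term list.

    ``include_children`` applies to the ontology-backed axes only (anatomy,
    cell type, stage); sex and strain are flat vocabularies with no child
    expansion.  Either *species* or *experiment_id* must be given.
    """

    species: object = None
    experiment_id: str | None = None
    anat: Sequence[str] = ()
    cell_type: Sequence[str] = ()
    stage: Sequence[str] = ()
    sex: Sequence[str] = ()
    strain: Sequence[str] = ()
    include_children: bool = False
    data_type: Sequence[str] = ()
    integrated_only: bool = False


@dataclass
class QueryResult:
    annotations: list[Annotation]
    observed: dict[str, list[str]] = field(default_factory=dict)


def _axis_match(ctx, axis, value, wanted, include_children, species) -> bool:
    if not wanted:
        return True
    if value in wanted:
        return True
    if include_children and axis in ("anat", "cell_type", "stage"):
        for w in wanted:
            try:
                if value in ctx.axis_descendants(axis, w, species):
                    return True
            except UnknownTerm:
                continue
    return False


def query_annotations(
    annotations: Sequence[Annotation],
    filters: QueryFilters,
    ctx: ConditionContext,
) -> QueryResult:
    """Ontology-reasoned retrieval of annotations.

    A record matches when every supplied axis matches; a term list matches
    when the annotation's term is listed, or — with ``include_children`` —
    is a descendant of a listed term.  The result also reports the distinct
    per-axis values observed in the matching records, for post-filter
    display.
    """
    if filters.species is None and filters.experiment_id is None:
        raise NoSpeciesOrExperiment("select a species or an experiment first")

    out: list[Annotation] = []
    for ann in annotations:
        c = ann.condition
        if filters.species is not None and c.species != filters.species:
            continue
        if filters.experiment_id is not None and ann.experiment_id != filters.experiment_id:
            continue
        if filters.data_type and ann.data_type not in filters.data_type:
            continue
        if filters.integrated_only and not ann.integrated:
            continue
        ok = all(
            _axis_match(ctx, axis, c.axis(axis), getattr(filters, axis),
                        filters.include_children, c.species)
            for axis in AXES
        )
        if ok:
            out.append(ann)

    observed = {
        axis: sorted({a.condition.axis(axis) for a in out}) for axis in AXES
    }
    return QueryResult(annotations=out, observed=observed)
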