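"""Synthetic dataset bundles with known ground truth.

The generator emulates the data model the pipeline consumes: a small
multispecies anatomy+cell-type ontology (balanced trees), a stage chain,
flat sex/strain vocabularies, bulk libraries annotated to anatomy leaves
(two replicates each), and droplet single-cell libraries whose clusters are
annotated to cell-type leaves.  Abundances follow a log-normal noise floor
(mu=0, sigma=1 on the log2 scale) for intergenic regions and non-expressed
genes; expressed genes and planted dubious intergenic regions are drawn
from the same law scaled by ``effect_size`` (default 8x the reference
median).  Single-cell counts are multinomial per cell from per-cluster
profiles, with intergenic features carried in the matrix so pseudo-bulk
samples have their own background null.

The default ``expressed_fraction`` is 0.95: the stringent intergenic
selection thresholds regions at the q-th percentile (q=5) of genic
expression, a rule that presupposes that at most ~q% of the genic reference
sits at noise level; the generator's never-expressed fraction is therefore
set equal to q so the threshold falls at the noise/expressed boundary, as
it does for real protein-coding gene sets.

Everything is deterministic given the seed; each component (ontology
layout, expression levels, single-cell sampling) consumes its own RNG
stream so changing one knob does not shift the others' draws.
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .calls import generate_calls
from .conditions import (
    ANY_SEX,
    WILD_TYPE,
    Annotation,
    Condition,
    ConditionGraph,
    build_condition_graph,
)
from .errors import InvalidConfig, KeyMismatch
from .io_formats import (
    DatasetBundle,
    SingleCellLibrary,
    write_annotation_table,
    write_matrix_tsv,
)
from .ontology import ControlledVocabulary, Ontology, OntologyTerm, TaxonConstraints
from .conditions import ConditionContext

ANAT_ROOT = "ANAT:0000000"
CELL_ROOT = "CELL:0000000"
STAGE_ROOT = "STAGE:0000000"
STAGE_ADULT = "STAGE:0000001"


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one simulated bundle (seed is mandatory)."""

    seed: int
    n_genes: int = 2000
    n_intergenic: int = 1000
    n_dubious_intergenic: int = 100
    n_bulk_samples: int = 8
    n_cells: int = 200  # per single-cell library
    n_clusters: int = 4
    n_sc_libraries: int = 2
    expressed_fraction: float = 0.95
    effect_size: float = 8.0
    depth: int = 3  # anatomy tree depth
    branching: int = 2  # anatomy tree branching factor
    log2_sigma: float = 1.0
    umi_per_cell: int = 5000
    species_id: int = 9606

    def validate(self) -> None:
        checks = [
            (self.n_genes >= 10, "n_genes >= 10"),
            (self.n_intergenic >= 10, "n_intergenic >= 10"),
            (0 <= self.n_dubious_intergenic < self.n_intergenic,
             "0 <= n_dubious_intergenic < n_intergenic"),
            (self.n_bulk_samples >= 1, "n_bulk_samples >= 1"),
            (self.n_clusters >= 1, "n_clusters >= 1"),
            (self.n_sc_libraries >= 0, "n_sc_libraries >= 0"),
            (self.n_cells >= self.n_clusters or self.n_sc_libraries == 0,
             "n_cells >= n_clusters"),
            (0.0 <= self.expressed_fraction <= 1.0,
             "expressed_fraction in [0, 1]"),
            (self.effect_size > 0, "effect_size > 0"),
            (self.depth >= 1 and self.branching >= 1, "depth, branching >= 1"),
            (self.log2_sigma > 0, "log2_sigma > 0"),
            (self.umi_per_cell >= 1, "umi_per_cell >= 1"),
            (isinstance(self.seed, (int, np.integer)), "seed must be an int"),
        ]
        bad = [msg for ok, msg in checks if not ok]
        if bad:
            raise InvalidConfig("; ".join(bad))


@dataclass
class GroundTruth:
    """Planted truth of a simulated bundle.

    The generator makes a gene's expression status condition-independent
    (an expressed gene is expressed in every sample), so the truth is
    stored per gene; :meth:`per_condition` materializes the per
    gene-x-condition view when needed.
    """

    expressed_genes: frozenset[str]
    dubious_regions: frozenset[str]
    all_genes: frozenset[str]
    all_regions: frozenset[str]

    def truly_expressed(self, gene: str, condition: Condition | None = None) -> bool:
        if gene not in self.all_genes:
            raise KeyMismatch(f"gene {gene!r} unknown to the ground truth")
        return gene in self.expressed_genes

    def truly_dubious(self, region: str) -> bool:
        if region not in self.all_regions:
            raise KeyMismatch(f"region {region!r} unknown to the ground truth")
        return region in self.dubious_regions

    def per_condition(self, conditions: Iterable[Condition]) -> dict:
        return {
            (g, c): (g in self.expressed_genes)
            for c in conditions
            for g in sorted(self.all_genes)
        }


# --- ontology scaffolding -----------------------------------------------------


def _balanced_tree(prefix: str, root_name: str, depth: int, branching: int) -> dict[str, OntologyTerm]:
    """Balanced is_a tree with BFS-numbered CURIEs under one root."""
    terms = {f"{prefix}:0000000": OntologyTerm(f"{prefix}:0000000", root_name)}
    counter = 1
    level = [f"{prefix}:0000000"]
    for d in range(depth):
        nxt = []
        for parent in level:
            for b in range(branching):
                tid = f"{prefix}:{counter:07d}"
                counter += 1
                terms[tid] = OntologyTerm(
                    tid,
                    f"{root_name} {d + 1}.{counter}",
                    parents=(("is_a", parent),),
                )
                nxt.append(tid)
        level = nxt
    return terms


def _toy_context(cfg: SynthConfig) -> tuple[ConditionContext, list[str], list[str]]:
    anat = _balanced_tree("ANAT", "anatomical structure", cfg.depth, cfg.branching)
    cell = {CELL_ROOT: OntologyTerm(CELL_ROOT, "cell")}
    for j in range(cfg.n_clusters):
        tid = f"CELL:{j + 1:07d}"
        cell[tid] = OntologyTerm(tid, f"cell type {j}", parents=(("is_a", CELL_ROOT),))
    anatomy = Ontology({**anat, **cell})
    stages = Ontology(
        {
            STAGE_ROOT: OntologyTerm(STAGE_ROOT, "life cycle"),
            STAGE_ADULT: OntologyTerm(
                STAGE_ADULT, "adult stage", parents=(("is_a", STAGE_ROOT),)
            ),
        }
    )
    tc = TaxonConstraints.from_records(
        (t, cfg.species_id, True)
        for t in list(anatomy.terms) + list(stages.terms)
    )
    ctx = ConditionContext(
        anatomy=anatomy,
        stages=stages,
        sex=ControlledVocabulary(ANY_SEX, frozenset({"female", "male", "hermaphrodite"})),
        strain=ControlledVocabulary(WILD_TYPE, frozenset({"wild isolate"})),
        taxon_constraints=tc,
        anat_root=ANAT_ROOT,
        cell_root=CELL_ROOT,
        stage_root=STAGE_ROOT,
    )
    anat_leaves = sorted(
        t for t in anat if not anatomy.descendants(t) and t != ANAT_ROOT
    ) or [ANAT_ROOT]
    cell_leaves = sorted(t for t in cell if t != CELL_ROOT)
    return ctx, anat_leaves, cell_leaves


# --- abundance models ---------------------------------------------------------


def _lognoise(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """The intergenic noise floor: 2**N(0, sigma) on the abundance scale."""
    return np.exp2(rng.normal(0.0, sigma, size=shape))


def simulate_bundle(cfg: SynthConfig) -> tuple[DatasetBundle, GroundTruth]:
    """Generate a complete, validated bundle plus its planted truth."""
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    rng_assign, rng_expr, rng_sc = (np.random.default_rng(s) for s in ss.spawn(3))

    ctx, anat_leaves, cell_leaves = _toy_context(cfg)
    genes = [f"G{i:06d}" for i in range(cfg.n_genes)]
    regions = [f"IG{i:06d}" for i in range(cfg.n_intergenic)]

    n_expr = int(round(cfg.expressed_fraction * cfg.n_genes))
    expressed = frozenset(
        rng_assign.choice(genes, size=n_expr, replace=False)
    ) if n_expr else frozenset()
    dubious = frozenset(
        rng_assign.choice(regions, size=cfg.n_dubious_intergenic, replace=False)
    ) if cfg.n_dubious_intergenic else frozenset()

    # bulk libraries: two replicates per anatomy leaf, round-robin
    bulk_cols = [f"BULK{i:03d}" for i in range(cfg.n_bulk_samples)]
    gene_scale = np.where([g in expressed for g in genes], cfg.effect_size, 1.0)
    region_scale = np.where([r in dubious for r in regions], cfg.effect_size, 1.0)
    bulk = pd.DataFrame(
        gene_scale[:, None]
        * _lognoise(rng_expr, (cfg.n_genes, cfg.n_bulk_samples), cfg.log2_sigma),
        index=genes,
        columns=bulk_cols,
    )
    intergenic = pd.DataFrame(
        region_scale[:, None]
        * _lognoise(rng_expr, (cfg.n_intergenic, cfg.n_bulk_samples), cfg.log2_sigma),
        index=regions,
        columns=bulk_cols,
    )
    bulk.index.name = intergenic.index.name = "feature_id"

    annotations: list[Annotation] = []
    for i, lib in enumerate(bulk_cols):
        leaf = anat_leaves[(i // 2) % len(anat_leaves)]
        annotations.append(
            Annotation(
                library_id=lib,
                experiment_id="EXPBULK1",
                condition=Condition(
                    leaf, CELL_ROOT, STAGE_ADULT, ANY_SEX, WILD_TYPE, cfg.species_id
                ),
                free_text_label="",
                data_type="bulk",
            )
        )

    # droplet libraries: authors' clusters map onto cell-type leaves, all
    # sampled from one anatomical site (the first child of the anatomy root)
    sc_anat = sorted(ctx.anatomy.descendants(ANAT_ROOT) & {
        t for t in ctx.anatomy.terms
        if ("is_a", ANAT_ROOT) in ctx.anatomy.terms[t].parents
    })
    sc_site = sc_anat[0] if sc_anat else ANAT_ROOT
    features = genes + regions
    feat_scale = np.concatenate([gene_scale, region_scale])
    single_cell: list[SingleCellLibrary] = []
    for lib_idx in range(cfg.n_sc_libraries):
        lib_id = f"SC{lib_idx + 1:02d}"
        profiles = feat_scale[:, None] * _lognoise(
            rng_sc, (len(features), cfg.n_clusters), cfg.log2_sigma
        )
        profiles /= profiles.sum(axis=0, keepdims=True)
        barcodes = [f"{lib_id}-BC{i:05d}" for i in range(cfg.n_cells)]
        cluster_of = {
            bc: f"{lib_id}_c{i % cfg.n_clusters}" for i, bc in enumerate(barcodes)
        }
        counts = np.empty((len(features), cfg.n_cells), dtype=np.int64)
        for i in range(cfg.n_cells):
            counts[:, i] = rng_sc.multinomial(
                cfg.umi_per_cell, profiles[:, i % cfg.n_clusters]
            )
        single_cell.append(
            SingleCellLibrary(
                library_id=lib_id,
                counts=sp.csc_matrix(counts),
                feature_ids=list(features),
                barcode_ids=barcodes,
                barcode_to_cluster=cluster_of,
            )
        )
        for j in range(cfg.n_clusters):
            annotations.append(
                Annotation(
                    library_id=f"{lib_id}_c{j}",
                    experiment_id="EXPSC1",
                    condition=Condition(
                        sc_site, cell_leaves[j % len(cell_leaves)], STAGE_ADULT,
                        ANY_SEX, WILD_TYPE, cfg.species_id,
                    ),
                    free_text_label=f"author cluster {j}",
                    data_type="sc_droplet",
                )
            )

    bundle = DatasetBundle(
        species=cfg.species_id,
        context=ctx,
        annotations=annotations,
        bulk=bulk,
        intergenic=intergenic,
        single_cell=single_cell,
        config={"synth": asdict(cfg)},
    )
    truth = GroundTruth(
        expressed_genes=expressed,
        dubious_regions=dubious,
        all_genes=frozenset(genes),
        all_regions=frozenset(regions),
    )
    return bundle, truth


# --- on-disk bundle -----------------------------------------------------------


def _write_obo(onto: Ontology, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\n")
        for tid in sorted(onto.terms):
            term = onto.terms[tid]
            fh.write(f"\n[Term]\nid: {term.id}\nname: {term.name}\n")
            for rel, parent in term.parents:
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: {rel} {parent}\n")


def _write_vocab(vocab: ControlledVocabulary, path) -> None:
    pd.DataFrame(
        {"member": sorted(vocab.members), "root": vocab.root}
    ).to_csv(path, sep="\t", index=False)


def write_bundle(bundle: DatasetBundle, truth: GroundTruth | None, outdir) -> str:
    """Write a bundle (and optional truth table) as a loadable on-disk tree.

    Returns the path of the written ``config.yaml``.
    """
    os.makedirs(outdir, exist_ok=True)
    ctx = bundle.context
    _write_obo(ctx.anatomy, os.path.join(outdir, "anatomy.obo"))
    _write_obo(ctx.stages, os.path.join(outdir, "stages.obo"))
    _write_vocab(ctx.sex, os.path.join(outdir, "sex.tsv"))
    _write_vocab(ctx.strain, os.path.join(outdir, "strain.tsv"))
    tc_rows = sorted(
        (term, str(species), "1" if flag else "0")
        for (term, species), flag in ctx.taxon_constraints._table.items()
    )
    pd.DataFrame(tc_rows, columns=["term_id", "species_id", "exists"]).to_csv(
        os.path.join(outdir, "taxon_constraints.tsv"), sep="\t", index=False
    )
    write_annotation_table(bundle.annotations, os.path.join(outdir, "annotations.tsv"))
    write_matrix_tsv(bundle.bulk, os.path.join(outdir, "bulk.tsv"))
    write_matrix_tsv(bundle.intergenic, os.path.join(outdir, "intergenic.tsv"))

    sc_entries = []
    for lib in bundle.single_cell:
        d = os.path.join(outdir, lib.library_id)
        os.makedirs(d, exist_ok=True)
        scipy.io.mmwrite(os.path.join(d, "matrix.mtx"), sp.coo_matrix(lib.counts))
        with open(os.path.join(d, "features.tsv"), "w", encoding="utf-8") as fh:
            fh.write("\n".join(lib.feature_ids) + "\n")
        with open(os.path.join(d, "barcodes.tsv"), "w", encoding="utf-8") as fh:
            fh.write("\n".join(lib.barcode_ids) + "\n")
        pd.DataFrame(
            sorted(lib.barcode_to_cluster.items()), columns=["barcode", "cluster_id"]
        ).to_csv(os.path.join(d, "clusters.tsv"), sep="\t", index=False)
        sc_entries.append(
            {
                "library_id": lib.library_id,
                "mtx": f"{lib.library_id}/matrix.mtx",
                "features": f"{lib.library_id}/features.tsv",
                "barcodes": f"{lib.library_id}/barcodes.tsv",
                "clusters": f"{lib.library_id}/clusters.tsv",
            }
        )

    if truth is not None:
        rows = [(g, "1" if g in truth.expressed_genes else "0") for g in sorted(truth.all_genes)]
        rows += [(r, "dubious" if r in truth.dubious_regions else "clean") for r in sorted(truth.all_regions)]
        pd.DataFrame(rows, columns=["feature_id", "truth"]).to_csv(
            os.path.join(outdir, "truth.tsv"), sep="\t", index=False
        )

    config = {
        "species_id": bundle.species,
        "anatomy_obo": "anatomy.obo",
        "stage_obo": "stages.obo",
        "sex_vocab": "sex.tsv",
        "strain_vocab": "strain.tsv",
        "taxon_constraints": "taxon_constraints.tsv",
        "annotations": "annotations.tsv",
        "bulk_matrix": "bulk.tsv",
        "intergenic_matrix": "intergenic.tsv",
        "single_cell": sc_entries,
        "roots": {
            "anat": ctx.anat_root,
            "cell_type": ctx.cell_root,
            "stage": ctx.stage_root,
        },
    }
    cfg_path = os.path.join(outdir, "config.yaml")
    with open(cfg_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return cfg_path


# --- recovery metrics ---------------------------------------------------------


@dataclass
class RecoveryMetrics:
    sensitivity: float
    specificity: float
    false_present_rate: float
    n_calls: int
    confusion: dict[str, int] = field(default_factory=dict)
    by_depth: dict[int, dict[str, float]] = field(default_factory=dict)


def evaluate_recovery(
    calls: Sequence,
    truth: GroundTruth,
    graph: ConditionGraph | None = None,
) -> RecoveryMetrics:
    """Confusion counts of present/absent calls against the planted truth.

    ``false_present_rate`` is FP / (FP + TN) over truly-non-expressed
    gene x condition pairs.  With *graph* given, rates are additionally
    stratified by condition depth to expose propagation artifacts.
    """
    tp = fp = tn = fn = 0
    per_depth: dict[int, list[int]] = {}
    for call in calls:
        truly = truth.truly_expressed(call.gene, call.condition)
        called = call.state == "present"
        tp += truly and called
        fn += truly and not called
        fp += (not truly) and called
        tn += (not truly) and not called
        if graph is not None:
            d = graph.depth(call.condition)
            cell = per_depth.setdefault(d, [0, 0, 0, 0])
            cell[0] += truly and called
            cell[1] += truly and not called
            cell[2] += (not truly) and called
            cell[3] += (not truly) and not called

    def _rate(num, den):
        return num / den if den else float("nan")

    by_depth = {
        d: {
            "sensitivity": _rate(v[0], v[0] + v[1]),
            "false_present_rate": _rate(v[2], v[2] + v[3]),
            "n": sum(v),
        }
        for d, v in sorted(per_depth.items())
    }
    return RecoveryMetrics(
        sensitivity=_rate(tp, tp + fn),
        specificity=_rate(tn, tn + fp),
        false_present_rate=_rate(fp, fp + tn),
        n_calls=tp + fp + tn + fn,
        confusion={"tp": tp, "fp": fp, "tn": tn, "fn": fn},
        by_depth=by_depth,
    )


def null_calibration(
    seed: int,
    n_genes: int = 2000,
    n_intergenic: int = 1000,
    alpha: float = 0.05,
    method: str = "fisher",
    **overrides,
) -> float:
    """Present-call rate when no gene is expressed (should track *alpha*).

    The bundle is generated with ``expressed_fraction=0`` and no planted
    dubious regions, and p-values are computed against the full clean
    region set: with no expressed genes there is no genic distribution to
    anchor the percentile selection rule, so the harness isolates the
    estimator and integration machinery it is meant to calibrate.
    """
    cfg = SynthConfig(
        seed=seed,
        n_genes=n_genes,
        n_intergenic=n_intergenic,
        n_dubious_intergenic=0,
        expressed_fraction=0.0,
        **overrides,
    )
    bundle, truth = simulate_bundle(cfg)
    graph = build_condition_graph(bundle.annotations, bundle.context)
    samples = bundle.build_samples()
    calls = generate_calls(
        graph, samples, frozenset(truth.all_regions), alpha=alpha, method=method
    )
    present = sum(1 for c in calls if c.state == "present")
    return present / len(calls)
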