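"""Readers and writers for every on-disk format the pipeline touches.

All tabular files are UTF-8 TSVs; output files start with ``#``-comment
header lines carrying the tool version and the parameters of the run, then
one header row with a fixed, documented column order.  Gene x sample
matrices are plain TSVs (first column = feature id); droplet single-cell
counts are MatrixMarket triplets with sidecar ``features.tsv`` /
``barcodes.tsv`` files (H5AD accepted as an optional alternative input).
Barcodes are matched case-sensitively.

A *dataset bundle* groups everything one species' analysis needs:
ontologies, vocabularies, taxon constraints, annotations, bulk and
intergenic abundance matrices, and single-cell libraries with their
barcode-to-cluster maps.  :func:`load_bundle` validates referential
integrity across all of them and reports every violation at once.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from . import __version__
from .calls import ExpressionCall, Sample, pseudobulk
from .conditions import (
    Annotation,
    Condition,
    ConditionContext,
    compose_condition,
)
from .errors import OntoexprError, SchemaMismatch, ValidationError
from .ontology import ControlledVocabulary, Ontology, TaxonConstraints, parse_obo

FLOAT_FMT = "%.12g"

CALLS_COLUMNS = [
    "gene_id",
    "anat_id",
    "cell_type_id",
    "stage_id",
    "sex",
    "strain",
    "species_id",
    "p_integrated",
    "state",
    "quality",
    "data_types",
    "n_samples_self",
    "n_samples_descendant",
    "source_samples",
    "mean_normalized_rank",
    "score",
]

ANNOTATION_COLUMNS = [
    "experiment_id",
    "library_id",
    "species_id",
    "anat_id",
    "cell_type_id",
    "stage_id",
    "sex",
    "strain",
    "free_text_label",
    "data_type",
    "integrated",
]

ENRICHMENT_COLUMNS = ["term", "k", "K", "n", "N", "p", "fdr", "method"]


def _fmt(x: float) -> str:
    return FLOAT_FMT % x


def _parse_species(raw: str):
    raw = str(raw)
    return int(raw) if raw.lstrip("-").isdigit() else raw


# --- simple readers -----------------------------------------------------------


def read_ontology(path) -> Ontology:
    with open(path, encoding="utf-8") as fh:
        return parse_obo(fh)


def read_vocabulary(path) -> ControlledVocabulary:
    """Two-column TSV ``member<TAB>root`` (with that header)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if list(df.columns) != ["member", "root"]:
        raise SchemaMismatch(
            f"{path}: expected columns ['member', 'root'], got {list(df.columns)}"
        )
    roots = set(df["root"])
    if len(roots) != 1:
        raise SchemaMismatch(f"{path}: vocabulary must have exactly one root")
    return ControlledVocabulary(root=roots.pop(), members=frozenset(df["member"]))


def read_taxon_constraints(path) -> TaxonConstraints:
    """TSV with header ``term_id<TAB>species_id<TAB>exists`` (0/1 flags)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if list(df.columns)[:3] != ["term_id", "species_id", "exists"]:
        raise SchemaMismatch(
            f"{path}: expected columns term_id/species_id/exists, "
            f"got {list(df.columns)}"
        )
    return TaxonConstraints.from_records(
        (row.term_id, _parse_species(row.species_id), row.exists in ("1", "true", "True"))
        for row in df.itertuples()
    )


def read_matrix_tsv(path) -> pd.DataFrame:
    """Feature x sample abundance matrix; first column holds feature ids."""
    df = pd.read_csv(path, sep="\t", comment="#")
    df = df.set_index(df.columns[0])
    df.index.name = "feature_id"
    return df.astype(float)


def write_matrix_tsv(df: pd.DataFrame, path, index_label="feature_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format=FLOAT_FMT)


def read_annotation_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    if list(df.columns) != ANNOTATION_COLUMNS:
        raise SchemaMismatch(
            f"{path}: expected columns {ANNOTATION_COLUMNS}, got {list(df.columns)}"
        )
    return df


def write_annotation_table(annotations: Sequence[Annotation], path) -> None:
    rows = []
    for a in annotations:
        c = a.condition
        rows.append(
            dict(
                experiment_id=a.experiment_id,
                library_id=a.library_id,
                species_id=str(c.species),
                anat_id=c.anat,
                cell_type_id=c.cell_type,
                stage_id=c.stage,
                sex=c.sex,
                strain=c.strain,
                free_text_label=a.free_text_label,
                data_type=a.data_type,
                integrated="1" if a.integrated else "0",
            )
        )
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_cluster_map(path) -> dict[str, str]:
    """TSV ``barcode<TAB>cluster_id`` (with that header)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if list(df.columns) != ["barcode", "cluster_id"]:
        raise SchemaMismatch(
            f"{path}: expected columns ['barcode', 'cluster_id'], "
            f"got {list(df.columns)}"
        )
    return dict(zip(df["barcode"], df["cluster_id"]))


def read_id_list(path) -> list[str]:
    """One id per line; blank lines and '#' comments ignored.

    Multi-column sidecars (e.g. CellRanger-style features.tsv) contribute
    their first column.
    """
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            out.append(line.split("\t")[0])
    return out


# --- single-cell libraries ----------------------------------------------------


@dataclass
class SingleCellLibrary:
    """One droplet library: counts, sidecars and the authors' clustering."""

    library_id: str
    counts: sp.spmatrix  # features x barcodes, raw counts
    feature_ids: list[str]
    barcode_ids: list[str]
    barcode_to_cluster: dict[str, str]


def read_mtx_library(library_id, mtx, features, barcodes, clusters) -> SingleCellLibrary:
    counts = sp.csc_matrix(scipy.io.mmread(mtx))
    return SingleCellLibrary(
        library_id=library_id,
        counts=counts,
        feature_ids=read_id_list(features),
        barcode_ids=read_id_list(barcodes),
        barcode_to_cluster=read_cluster_map(clusters),
    )


def read_h5ad_library(library_id, path, cluster_key) -> SingleCellLibrary:
    """Optional H5AD input: obs = cells, var = features, X = raw counts."""
    import anndata  # deferred: only needed when the flag is used

    ad = anndata.read_h5ad(path)
    x = ad.X
    counts = sp.csc_matrix(x.T if sp.issparse(x) else np.asarray(x).T)
    clusters = {
        str(bc): str(cl) for bc, cl in zip(ad.obs_names, ad.obs[cluster_key])
    }
    return SingleCellLibrary(
        library_id=library_id,
        counts=counts,
        feature_ids=[str(v) for v in ad.var_names],
        barcode_ids=[str(o) for o in ad.obs_names],
        barcode_to_cluster=clusters,
    )


# --- the bundle ---------------------------------------------------------------


@dataclass
class DatasetBundle:
    """Everything needed to compute calls and scores for one species."""

    species: object
    context: ConditionContext
    annotations: list[Annotation]
    bulk: pd.DataFrame  # genes x bulk libraries
    intergenic: pd.DataFrame  # regions x bulk libraries
    single_cell: list[SingleCellLibrary] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.bulk.index)

    @property
    def region_ids(self) -> list[str]:
        return list(self.intergenic.index)

    def build_samples(self) -> list[Sample]:
        """Materialize bulk samples and pseudo-bulked cell populations.

        Bulk samples merge the genic and intergenic abundances of their
        library column; single-cell libraries are pseudo-bulked per cluster
        (intergenic features quantified in the matrix ride along, so every
        sample carries its own background null).
        """
        by_library = {a.library_id: a for a in self.annotations}
        genes = frozenset(self.gene_ids)
        samples: list[Sample] = []
        for lib in self.bulk.columns:
            ann = by_library.get(lib)
            if ann is None:
                continue
            abundance = dict(self.bulk[lib])
            abundance.update(dict(self.intergenic[lib]))
            samples.append(
                Sample(
                    sample_id=lib,
                    annotation=ann,
                    abundance=abundance,
                    detectable_genes=genes,
                    origin="bulk",
                )
            )
        for sclib in self.single_cell:
            cluster_annotations = {
                cl: by_library[cl]
                for cl in set(sclib.barcode_to_cluster.values())
                if cl in by_library
            }
            samples.extend(
                pseudobulk(
                    sclib.counts,
                    sclib.feature_ids,
                    sclib.barcode_ids,
                    sclib.barcode_to_cluster,
                    cluster_annotations,
                    gene_ids=genes,
                )
            )
        return samples


def _build_context(cfg: dict, base: str) -> ConditionContext:
    def p(key):
        return os.path.join(base, cfg[key])

    anatomy = read_ontology(p("anatomy_obo"))
    stages = read_ontology(p("stage_obo"))
    roots = cfg.get("roots", {})
    return ConditionContext(
        anatomy=anatomy,
        stages=stages,
        sex=read_vocabulary(p("sex_vocab")),
        strain=read_vocabulary(p("strain_vocab")),
        taxon_constraints=read_taxon_constraints(p("taxon_constraints")),
        anat_root=roots["anat"],
        cell_root=roots["cell_type"],
        stage_root=roots["stage"],
        permissive_taxa=bool(cfg.get("permissive_taxa", False)),
    )


def load_bundle(config_path) -> DatasetBundle:
    """Load and cross-validate a dataset bundle from a YAML config.

    Every referential-integrity violation found — unresolvable ontology
    terms, annotations without matrix columns, cluster-map barcodes missing
    from the barcode sidecar, gene/region id collisions — is collected and
    reported together in one :class:`ValidationError`.
    """
    with open(config_path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    base = os.path.dirname(os.path.abspath(config_path))
    species = _parse_species(cfg["species_id"])
    issues: list[str] = []

    ctx = _build_context(cfg, base)
    bulk = read_matrix_tsv(os.path.join(base, cfg["bulk_matrix"]))
    intergenic = read_matrix_tsv(os.path.join(base, cfg["intergenic_matrix"]))

    overlap = set(bulk.index) & set(intergenic.index)
    if overlap:
        issues.append(
            f"{len(overlap)} ids shared between genes and intergenic regions "
            f"(e.g. {sorted(overlap)[:3]})"
        )
    if list(bulk.columns) != list(intergenic.columns):
        issues.append("bulk and intergenic matrices list different sample columns")

    ann_df = read_annotation_table(os.path.join(base, cfg["annotations"]))
    annotations: list[Annotation] = []
    for row in ann_df.itertuples():
        try:
            condition = compose_condition(
                row.anat_id, row.cell_type_id, row.stage_id, row.sex, row.strain,
                _parse_species(row.species_id), ctx,
            )
        except OntoexprError as exc:
            issues.append(f"annotation {row.library_id!r}: {exc}")
            continue
        if condition.species != species:
            issues.append(
                f"annotation {row.library_id!r}: species {condition.species!r} "
                f"differs from bundle species {species!r}"
            )
        annotations.append(
            Annotation(
                library_id=row.library_id,
                experiment_id=row.experiment_id,
                condition=condition,
                free_text_label=row.free_text_label,
                data_type=row.data_type,
                integrated=row.integrated in ("1", "true", "True"),
            )
        )

    by_library = {a.library_id: a for a in annotations}
    single_cell: list[SingleCellLibrary] = []
    for entry in cfg.get("single_cell", []):
        lib_id = entry["library_id"]
        if "h5ad" in entry:
            lib = read_h5ad_library(
                lib_id, os.path.join(base, entry["h5ad"]), entry["cluster_key"]
            )
        else:
            lib = read_mtx_library(
                lib_id,
                os.path.join(base, entry["mtx"]),
                os.path.join(base, entry["features"]),
                os.path.join(base, entry["barcodes"]),
                os.path.join(base, entry["clusters"]),
            )
        if lib.counts.shape != (len(lib.feature_ids), len(lib.barcode_ids)):
            issues.append(
                f"library {lib_id!r}: matrix shape {lib.counts.shape} does not "
                f"match {len(lib.feature_ids)} features x "
                f"{len(lib.barcode_ids)} barcodes"
            )
            continue
        known = set(lib.barcode_ids)
        for barcode in lib.barcode_to_cluster:
            if barcode not in known:
                issues.append(
                    f"library {lib_id!r}: clustered barcode {barcode!r} "
                    "missing from barcodes.tsv"
                )
        for cluster in sorted(set(lib.barcode_to_cluster.values())):
            if cluster not in by_library:
                issues.append(
                    f"library {lib_id!r}: cluster {cluster!r} has no "
                    "annotation row"
                )
        single_cell.append(lib)

    annotated_bulk = {
        a.library_id for a in annotations if a.data_type == "bulk"
    }
    for lib in annotated_bulk - set(bulk.columns):
        issues.append(f"bulk annotation {lib!r} has no column in the bulk matrix")

    if issues:
        raise ValidationError(issues)

    return DatasetBundle(
        species=species,
        context=ctx,
        annotations=annotations,
        bulk=bulk,
        intergenic=intergenic,
        single_cell=single_cell,
        config=cfg,
    )


# --- calls TSV ----------------------------------------------------------------


def _header_comments(params: Mapping | None) -> str:
    lines = [f"# ontoexpr {__version__}"]
    for key, val in sorted((params or {}).items()):
        lines.append(f"# {key}={val}")
    return "\n".join(lines) + "\n"


def write_calls(
    calls: Sequence[ExpressionCall],
    scores: Mapping | None,
    path,
    params: Mapping | None = None,
) -> None:
    """Write the per-species calls TSV (scores appended as two columns).

    Rows are sorted by gene then condition axes so files are diffable
    across runs; floats are printed with 12 significant digits.
    """
    rows = []
    for call in calls:
        c = call.condition
        sc = scores.get((call.gene, c)) if scores else None
        rows.append(
            dict(
                gene_id=call.gene,
                anat_id=c.anat,
                cell_type_id=c.cell_type,
                stage_id=c.stage,
                sex=c.sex,
                strain=c.strain,
                species_id=str(c.species),
                p_integrated=_fmt(call.p_integrated),
                state=call.state,
                quality=call.quality,
                data_types=",".join(sorted(call.data_types)),
                n_samples_self=call.n_samples_self,
                n_samples_descendant=call.n_samples_descendant,
                source_samples=",".join(call.sample_ids),
                mean_normalized_rank="" if sc is None else _fmt(sc.mean_normalized_rank),
                score="" if sc is None else _fmt(sc.score),
            )
        )
    df = pd.DataFrame(rows, columns=CALLS_COLUMNS)
    df = df.sort_values(CALLS_COLUMNS[:7], kind="mergesort")
    buf = io.StringIO()
    buf.write(_header_comments(params))
    df.to_csv(buf, sep="\t", index=False)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def read_calls(path):
    """Read a calls TSV back into (calls, scores).

    The column order must match :data:`CALLS_COLUMNS` exactly; any
    deviation raises :class:`SchemaMismatch`.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    if list(df.columns) != CALLS_COLUMNS:
        raise SchemaMismatch(
            f"{path}: expected columns {CALLS_COLUMNS}, got {list(df.columns)}"
        )
    from .scores import ExpressionScore  # local import to avoid a cycle

    calls: list[ExpressionCall] = []
    scores: dict[tuple[str, Condition], ExpressionScore] = {}
    for row in df.itertuples():
        condition = Condition(
            anat=row.anat_id,
            cell_type=row.cell_type_id,
            stage=row.stage_id,
            sex=row.sex,
            strain=row.strain,
            species=_parse_species(row.species_id),
        )
        calls.append(
            ExpressionCall(
                gene=row.gene_id,
                condition=condition,
                p_integrated=float(row.p_integrated),
                state=row.state,
                quality=row.quality,
                data_types=frozenset(
                    t for t in row.data_types.split(",") if t
                ),
                n_samples_self=int(row.n_samples_self),
                n_samples_descendant=int(row.n_samples_descendant),
                sample_ids=tuple(s for s in row.source_samples.split(",") if s),
            )
        )
        if row.score != "":
            scores[(row.gene_id, condition)] = ExpressionScore(
                gene=row.gene_id,
                condition=condition,
                mean_normalized_rank=float(row.mean_normalized_rank),
                score=float(row.score),
            )
    return calls, scores


def write_enrichment(results, path, params: Mapping | None = None) -> None:
    rows = [
        dict(
            term=r.term, k=r.k, K=r.K, n=r.n, N=r.N,
            p=_fmt(r.p), fdr=_fmt(r.fdr), method=r.method,
        )
        for r in results
    ]
    df = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_comments(params))
        df.to_csv(fh, sep="\t", index=False)


def write_scores(scores: Mapping, path, params: Mapping | None = None) -> None:
    """Standalone score TSV: gene, condition axes, mean rank, score."""
    rows = []
    for (gene, c), sc in scores.items():
        rows.append(
            dict(
                gene_id=gene,
                anat_id=c.anat,
                cell_type_id=c.cell_type,
                stage_id=c.stage,
                sex=c.sex,
                strain=c.strain,
                species_id=str(c.species),
                mean_normalized_rank=_fmt(sc.mean_normalized_rank),
                score=_fmt(sc.score),
            )
        )
    cols = CALLS_COLUMNS[:7] + ["mean_normalized_rank", "score"]
    df = pd.DataFrame(rows, columns=cols).sort_values(cols[:7], kind="mergesort")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_comments(params))
        df.to_csv(fh, sep="\t", index=False)
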