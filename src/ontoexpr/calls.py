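"""Present/absent expression calls from an intergenic background null.

The expression state of a gene in a sample is tested against the null
hypothesis that its abundance belongs to the distribution of abundances of
a stringent set of intergenic regions — genome regions free of annotated
(and of dubious unannotated) genes — quantified in the same sample.  The
per-sample empirical p-value uses the add-one estimator ``(k+1)/(n+1)``
with ties counted conservatively, which guarantees ``p > 0`` and a
super-uniform null.  Per-gene p-values from all samples annotated to a
condition or to any of its descendant conditions are then combined into a
single integrated p-value per gene and condition; the gene is called
*present* in the condition when the integrated p-value is at most ``alpha``
and *absent* otherwise.

Droplet single-cell libraries are pseudo-bulked first: raw counts of all
cells belonging to one author-annotated population are summed and the sum
is library-normalized, after which the sample behaves like a bulk library.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .conditions import Annotation, Condition, ConditionGraph
from .errors import (
    AllRegionsDubious,
    EmptyCluster,
    EmptyList,
    EmptyReference,
    GeneNotDetectable,
    NoData,
    OutOfRange,
    TooFewRegions,
    UnknownBarcode,
)

logger = logging.getLogger(__name__)

MIN_REFERENCE_REGIONS = 10
COMBINE_METHODS = ("fisher", "stouffer", "bh_best")


@dataclass
class Sample:
    """One bulk library or one pseudo-bulked cell population.

    ``abundance`` maps every quantified feature — genes *and* intergenic
    regions — to a library-normalized, TPM-like value.  ``detectable_genes``
    is the subset of gene ids the protocol can in principle measure (e.g.
    polyA selection misses non-polyadenylated transcripts); it bounds the
    rank denominator downstream and never includes intergenic regions.
    """

    sample_id: str
    annotation: Annotation
    abundance: dict[str, float]
    detectable_genes: frozenset[str]
    origin: str = "bulk"  # bulk | pseudo_bulk

    def __post_init__(self):
        self.detectable_genes = frozenset(self.detectable_genes)
        missing = self.detectable_genes - self.abundance.keys()
        if missing:
            raise ValueError(
                f"sample {self.sample_id!r}: {len(missing)} detectable genes "
                "missing from the abundance map"
            )
        vals = np.fromiter(self.abundance.values(), dtype=float,
                           count=len(self.abundance))
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise ValueError(
                f"sample {self.sample_id!r}: abundances must be finite and >= 0"
            )

    @property
    def condition(self) -> Condition:
        return self.annotation.condition


@dataclass(frozen=True)
class GenePValue:
    gene: str
    sample_id: str
    p: float


@dataclass(frozen=True)
class ExpressionCall:
    """Integrated present/absent call for one gene in one condition."""

    gene: str
    condition: Condition
    p_integrated: float
    state: str  # present | absent
    quality: str  # gold | silver | bronze
    data_types: frozenset[str]
    n_samples_self: int
    n_samples_descendant: int
    sample_ids: tuple[str, ...] = ()


# --- reference intergenic selection ------------------------------------------


def select_reference_intergenic(
    intergenic: pd.DataFrame,
    genic: pd.DataFrame,
    q: float = 5.0,
) -> frozenset[str]:
    """Select the stringent intergenic reference set from bulk data.

    Both inputs are abundance matrices (rows = region ids / gene ids,
    columns = bulk sample ids).  A region is discarded as dubious when its
    mean ``log2(abundance + 1)`` across bulk samples exceeds the *q*-th
    percentile of the genes' mean ``log2(abundance + 1)`` — i.e. when it is
    expressed like the annotated gene population rather than like noise.
    """
    if intergenic.shape[0] < MIN_REFERENCE_REGIONS:
        raise TooFewRegions(
            f"need >= {MIN_REFERENCE_REGIONS} intergenic regions, "
            f"got {intergenic.shape[0]}"
        )
    if intergenic.shape[1] < 1 or genic.shape[1] < 1:
        raise TooFewRegions("need at least one bulk sample")
    region_means = np.log2(intergenic.to_numpy(dtype=float) + 1.0).mean(axis=1)
    genic_means = np.log2(genic.to_numpy(dtype=float) + 1.0).mean(axis=1)
    threshold = np.percentile(genic_means, q)
    keep = intergenic.index.to_numpy()[region_means <= threshold]
    if keep.size == 0:
        raise AllRegionsDubious(
            "every intergenic region exceeds the genic expression threshold"
        )
    return frozenset(keep)


# --- per-sample p-values -----------------------------------------------------


def _reference_values(sample: Sample, reference: Iterable[str]) -> np.ndarray:
    vals = [sample.abundance[r] for r in reference if r in sample.abundance]
    if len(vals) < MIN_REFERENCE_REGIONS:
        raise EmptyReference(
            f"sample {sample.sample_id!r}: only {len(vals)} reference regions "
            f"quantified (need >= {MIN_REFERENCE_REGIONS})"
        )
    return np.sort(np.asarray(vals, dtype=float))


def present_pvalue(sample: Sample, gene: str, reference: Iterable[str]) -> GenePValue:
    """Right-tail empirical p-value of one gene against the intergenic null.

    ``p = (k+1)/(n+1)`` where *k* counts reference regions whose abundance
    in this sample is >= the gene's abundance (ties count toward *k*).
    """
    if gene not in sample.detectable_genes:
        raise GeneNotDetectable(
            f"gene {gene!r} not detectable in sample {sample.sample_id!r}"
        )
    ref = _reference_values(sample, reference)
    n = ref.size
    g = sample.abundance[gene]
    k = n - int(np.searchsorted(ref, g, side="left"))
    return GenePValue(gene=gene, sample_id=sample.sample_id, p=(k + 1) / (n + 1))


def sample_pvalues(
    sample: Sample, genes: Sequence[str], reference: Iterable[str]
) -> pd.Series:
    """Vectorized :func:`present_pvalue` over *genes*.

    Genes not detectable in the sample get NaN (they contribute no
    evidence, rather than an error, on the batch path).
    """
    ref = _reference_values(sample, reference)
    n = ref.size
    out = np.full(len(genes), np.nan)
    for i, gene in enumerate(genes):
        if gene in sample.detectable_genes:
            k = n - int(np.searchsorted(ref, sample.abundance[gene], side="left"))
            out[i] = (k + 1) / (n + 1)
    return pd.Series(out, index=list(genes), name=sample.sample_id)


# --- pseudo-bulking ----------------------------------------------------------


def pseudobulk(
    counts: sp.spmatrix,
    feature_ids: Sequence[str],
    barcode_ids: Sequence[str],
    barcode_to_cluster: Mapping[str, str],
    cluster_annotations: Mapping[str, Annotation],
    gene_ids: Iterable[str] | None = None,
    strict: bool = True,
    normalize: str = "cpm",
) -> list[Sample]:
    """Aggregate droplet single-cell counts into per-population samples.

    *counts* is a feature x barcode matrix of raw counts.  Cell populations
    are the authors' original clusters (no re-clustering); all reads of the
    cells of one cluster are summed, then library-normalized (counts per
    million over all features).  Barcodes present in the matrix but not in
    the cluster map are ignored with a logged count; a clustered barcode
    missing from the matrix raises :class:`UnknownBarcode` in strict mode.
    Per-gene raw counts over assigned barcodes are conserved exactly across
    the returned samples.
    """
    feature_ids = list(feature_ids)
    barcode_ids = list(barcode_ids)
    mat = sp.csc_matrix(counts)
    if mat.shape != (len(feature_ids), len(barcode_ids)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match "
            f"{len(feature_ids)} features x {len(barcode_ids)} barcodes"
        )
    col_of = {b: j for j, b in enumerate(barcode_ids)}

    members: dict[str, list[int]] = {c: [] for c in cluster_annotations}
    for barcode, cluster in barcode_to_cluster.items():
        j = col_of.get(barcode)
        if j is None:
            if strict:
                raise UnknownBarcode(f"barcode {barcode!r} not in count matrix")
            logger.warning("barcode %r not in count matrix; skipped", barcode)
            continue
        members.setdefault(cluster, []).append(j)

    n_unassigned = len(set(barcode_ids) - set(barcode_to_cluster))
    if n_unassigned:
        logger.info("pseudobulk: %d unassigned barcodes ignored", n_unassigned)

    gene_set = frozenset(gene_ids) if gene_ids is not None else frozenset(feature_ids)

    samples: list[Sample] = []
    for cluster in sorted(members):
        cols = members[cluster]
        if not cols:
            raise EmptyCluster(f"cluster {cluster!r} has no member barcodes")
        raw = np.asarray(mat[:, cols].sum(axis=1)).ravel().astype(float)
        total = raw.sum()
        if normalize == "cpm" and total > 0:
            abund = raw * (1e6 / total)
        else:
            abund = raw
        annotation = cluster_annotations.get(cluster)
        if annotation is None:
            logger.info("pseudobulk: cluster %r has no annotation; skipped", cluster)
            continue
        samples.append(
            Sample(
                sample_id=cluster,
                annotation=annotation,
                abundance=dict(zip(feature_ids, abund)),
                detectable_genes=gene_set & frozenset(feature_ids),
                origin="pseudo_bulk",
            )
        )
    return samples


def pseudobulk_raw_counts(
    counts: sp.spmatrix,
    feature_ids: Sequence[str],
    barcode_ids: Sequence[str],
    barcode_to_cluster: Mapping[str, str],
) -> pd.DataFrame:
    """Raw summed counts per cluster (features x clusters), unnormalized."""
    mat = sp.csc_matrix(counts)
    col_of = {b: j for j, b in enumerate(barcode_ids)}
    clusters = sorted(set(barcode_to_cluster.values()))
    out = {}
    for cluster in clusters:
        cols = [col_of[b] for b, c in barcode_to_cluster.items()
                if c == cluster and b in col_of]
        out[cluster] = np.asarray(mat[:, cols].sum(axis=1)).ravel()
    return pd.DataFrame(out, index=list(feature_ids))


# --- p-value combination -----------------------------------------------------


def _validate_ps(ps: Sequence[float]) -> np.ndarray:
    arr = np.asarray(list(ps), dtype=float)
    if arr.size == 0:
        raise EmptyList("no p-values to combine")
    if np.any(arr <= 0) or np.any(arr > 1) or not np.all(np.isfinite(arr)):
        raise OutOfRange("p-values must lie in (0, 1]")
    return arr


def combine_pvalues(ps: Sequence[float], method: str = "fisher") -> float:
    """Combine per-sample p-values into one integrated p-value.

    ``fisher``: chi-square tail of ``-2 * sum(log p)`` with ``2k`` df;
    ``stouffer``: normal tail of the mean z-score;
    ``bh_best``: the best Benjamini-Hochberg-adjusted p,
    ``min_i p_(i) * k / i`` capped at 1.
    """
    arr = _validate_ps(ps)
    if method not in COMBINE_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {COMBINE_METHODS}")
    if arr.size == 1:
        return float(arr[0])
    if method == "bh_best":
        k = arr.size
        srt = np.sort(arr)
        return float(min(1.0, np.min(srt * k / np.arange(1, k + 1))))
    res = stats.combine_pvalues(arr, method=method)
    return float(min(1.0, res.pvalue))


def _combine_matrix(P: np.ndarray, method: str) -> np.ndarray:
    """Column-wise combination of a samples x genes p-value matrix.

    NaN entries mark samples where the gene is not detectable and are
    ignored; columns with no finite p yield NaN.
    """
    k = np.sum(np.isfinite(P), axis=0)
    out = np.full(P.shape[1], np.nan)
    any_data = k > 0
    if method == "fisher":
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = -2.0 * np.nansum(np.log(P), axis=0)
        out[any_data] = stats.chi2.sf(stat[any_data], 2 * k[any_data])
    elif method == "stouffer":
        z = stats.norm.isf(P)
        zsum = np.nansum(z, axis=0)
        with np.errstate(invalid="ignore"):
            out[any_data] = stats.norm.sf(zsum[any_data] / np.sqrt(k[any_data]))
    elif method == "bh_best":
        for j in np.nonzero(any_data)[0]:
            col = P[:, j]
            vals = np.sort(col[np.isfinite(col)])
            out[j] = min(1.0, np.min(vals * vals.size / np.arange(1, vals.size + 1)))
    else:
        raise ValueError(f"unknown method {method!r}")
    return np.minimum(out, 1.0, where=np.isfinite(out), out=out)


# --- integrated calls --------------------------------------------------------


def _contributing_samples(
    condition: Condition, graph: ConditionGraph, samples: Sequence[Sample]
) -> tuple[list[Sample], int, int]:
    desc = graph.descendants_of(condition)
    self_s, desc_s = [], []
    for s in samples:
        if s.condition == condition:
            self_s.append(s)
        elif s.condition in desc:
            desc_s.append(s)
    return self_s + desc_s, len(self_s), len(desc_s)


def _quality(state: str, p_int: float, per_sample: np.ndarray, alpha: float) -> str:
    """Confidence tier for a call.

    Present: gold when >= 2 samples are individually significant, silver
    otherwise.  Absent: bronze when the integrated p is marginal (in
    ``(alpha, 2*alpha]``), gold when >= 2 samples are individually
    non-significant, silver otherwise.
    """
    per_sample = per_sample[np.isfinite(per_sample)]
    if state == "present":
        return "gold" if int(np.sum(per_sample <= alpha)) >= 2 else "silver"
    if p_int <= 2 * alpha:
        return "bronze"
    return "gold" if int(np.sum(per_sample > alpha)) >= 2 else "silver"


def call_expression(
    gene: str,
    condition: Condition,
    graph: ConditionGraph,
    samples: Sequence[Sample],
    reference: Iterable[str],
    alpha: float = 0.05,
    method: str = "fisher",
) -> ExpressionCall:
    """Integrated present/absent call for one gene in one condition.

    Collects the gene's per-sample p-values from samples annotated to
    *condition* or to any of its descendant conditions, combines them, and
    classifies the call as present iff the integrated p-value is <= *alpha*.
    """
    contrib, n_self, n_desc = _contributing_samples(condition, graph, samples)
    ps, used = [], []
    for s in contrib:
        if gene in s.detectable_genes:
            ps.append(present_pvalue(s, gene, reference).p)
            used.append(s)
    if not ps:
        raise NoData(
            f"no sample contributes data for gene {gene!r} in condition {condition}"
        )
    p_int = combine_pvalues(ps, method=method)
    state = "present" if p_int <= alpha else "absent"
    return ExpressionCall(
        gene=gene,
        condition=condition,
        p_integrated=p_int,
        state=state,
        quality=_quality(state, p_int, np.asarray(ps), alpha),
        data_types=frozenset(s.annotation.data_type for s in used),
        n_samples_self=n_self,
        n_samples_descendant=n_desc,
        sample_ids=tuple(s.sample_id for s in used),
    )


def generate_calls(
    graph: ConditionGraph,
    samples: Sequence[Sample],
    reference: Iterable[str],
    genes: Sequence[str] | None = None,
    alpha: float = 0.05,
    method: str = "fisher",
) -> list[ExpressionCall]:
    """All calls for every condition node of the graph (vectorized).

    Equivalent to :func:`call_expression` per (gene, condition) but
    computes each sample's p-value vector once.  Conditions or genes
    without any contributing sample are skipped silently.
    """
    if genes is None:
        genes = sorted(set().union(*(s.detectable_genes for s in samples)))
    genes = list(genes)
    pmat = {s.sample_id: sample_pvalues(s, genes, reference) for s in samples}

    calls: list[ExpressionCall] = []
    for condition in sorted(graph.nodes):
        contrib, n_self, n_desc = _contributing_samples(condition, graph, samples)
        if not contrib:
            continue
        P = np.vstack([pmat[s.sample_id].to_numpy() for s in contrib])
        p_int = _combine_matrix(P, method)
        for j, gene in enumerate(genes):
            if not np.isfinite(p_int[j]):
                continue
            col = P[:, j]
            has = np.isfinite(col)
            state = "present" if p_int[j] <= alpha else "absent"
            used = [s for s, h in zip(contrib, has) if h]
            calls.append(
                ExpressionCall(
                    gene=gene,
                    condition=condition,
                    p_integrated=float(p_int[j]),
                    state=state,
                    quality=_quality(state, float(p_int[j]), col, alpha),
                    data_types=frozenset(s.annotation.data_type for s in used),
                    n_samples_self=n_self,
                    n_samples_descendant=n_desc,
                    sample_ids=tuple(s.sample_id for s in used),
                )
            )
    return calls
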