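"""Nonparametric 0-100 expression scores.

Expression levels are made comparable across protocols and data types
through ranks rather than through the abundances themselves.  Per sample,
detectable genes are ranked by decreasing abundance (fractional ranks, ties
sharing the mean of their tied positions).  Ranks are then normalized by
``rank * global_max / sample_max`` to account for protocols that can only
measure part of the transcriptome (a polyA library ranks fewer genes than a
ribo-depleted one).  Normalized ranks of all samples annotated to a
condition or its descendant conditions are averaged, and the mean rank is
inverted and renormalized to a score in ``(0, 100]``:

    score = 100 * (M + 1 - mean_rank) / M

with ``M`` the condition's maximum normalized rank, so the top-ranked gene
of a condition scores exactly 100 and the bottom one ``100 / M > 0``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calls import ExpressionCall, Sample
from .conditions import Condition, ConditionGraph
from .errors import EmptySample, NoData, OutOfRange, UnknownGene


@dataclass
class RankedSample:
    """Fractional ranks of one sample's detectable genes (1 = most expressed)."""

    sample_id: str
    rank: pd.Series  # gene -> fractional rank
    max_rank: float  # number of rankable positions in the sample
    condition: Condition


@dataclass(frozen=True)
class ExpressionScore:
    gene: str
    condition: Condition
    mean_normalized_rank: float
    score: float


def rank_sample(sample: Sample) -> RankedSample:
    """Rank the sample's detectable genes by decreasing abundance.

    Non-detectable genes (and intergenic regions) are absent from the rank
    map; the rank denominator is the detectable-gene count.
    """
    genes = sorted(sample.detectable_genes)
    if not genes:
        raise EmptySample(f"sample {sample.sample_id!r} has no detectable gene")
    abund = np.array([sample.abundance[g] for g in genes], dtype=float)
    ranks = stats.rankdata(-abund, method="average")
    return RankedSample(
        sample_id=sample.sample_id,
        rank=pd.Series(ranks, index=genes),
        max_rank=float(len(genes)),
        condition=sample.condition,
    )


def normalize_rank(r: float, sample_max: float, global_max: float) -> float:
    """Scale a within-sample rank onto the species-wide rank axis."""
    if not (1.0 <= r <= sample_max + 1e-9):
        raise OutOfRange(f"rank {r} outside [1, {sample_max}]")
    if sample_max > global_max + 1e-9:
        raise OutOfRange(f"sample_max {sample_max} exceeds global_max {global_max}")
    return r * global_max / sample_max


def _contributing(
    condition: Condition, graph: ConditionGraph, ranked: Sequence[RankedSample]
) -> list[RankedSample]:
    desc = graph.descendants_of(condition)
    return [r for r in ranked if r.condition == condition or r.condition in desc]


def integrate_rank(
    gene: str,
    condition: Condition,
    graph: ConditionGraph,
    ranked_samples: Sequence[RankedSample],
    global_max: float | None = None,
) -> float:
    """Unweighted mean of the gene's normalized ranks over the condition's
    own samples and those of its descendant conditions."""
    if global_max is None:
        global_max = max(r.max_rank for r in ranked_samples)
    contrib = _contributing(condition, graph, ranked_samples)
    vals = [
        normalize_rank(float(r.rank[gene]), r.max_rank, global_max)
        for r in contrib
        if gene in r.rank.index
    ]
    if not vals:
        raise NoData(f"no ranked sample for gene {gene!r} in condition {condition}")
    return float(np.mean(vals))


def expression_score(mean_rank: float, condition_max_rank: float) -> float:
    """Invert and renormalize a mean rank to the (0, 100] score scale."""
    if condition_max_rank < 1:
        raise OutOfRange("condition_max_rank must be >= 1")
    if not (1.0 - 1e-9 <= mean_rank <= condition_max_rank + 1e-9):
        raise OutOfRange(
            f"mean_rank {mean_rank} outside [1, {condition_max_rank}]"
        )
    return 100.0 * (condition_max_rank + 1.0 - mean_rank) / condition_max_rank


def compute_scores(
    graph: ConditionGraph,
    samples: Sequence[Sample],
    genes: Sequence[str] | None = None,
    global_max: float | None = None,
) -> dict[tuple[str, Condition], ExpressionScore]:
    """Scores for every (gene, condition) with data, vectorized per condition.

    ``global_max`` defaults to the largest sample max-rank across all
    samples (one normalization axis per species); each condition's maximum
    rank is the largest normalized sample max among its contributing
    samples, which equals ``global_max``.
    """
    ranked = [rank_sample(s) for s in samples]
    if global_max is None:
        global_max = max(r.max_rank for r in ranked)
    if genes is None:
        genes = sorted(set().union(*(set(r.rank.index) for r in ranked)))
    genes = list(genes)

    norm_rows = {}
    for r in ranked:
        row = np.full(len(genes), np.nan)
        aligned = r.rank.reindex(genes).to_numpy() * (global_max / r.max_rank)
        row[:] = aligned
        norm_rows[r.sample_id] = row

    out: dict[tuple[str, Condition], ExpressionScore] = {}
    for condition in sorted(graph.nodes):
        contrib = _contributing(condition, graph, ranked)
        if not contrib:
            continue
        M = np.vstack([norm_rows[r.sample_id] for r in contrib])
        with np.errstate(invalid="ignore"):
            mean_rank = np.nanmean(M, axis=0)
        cond_max = max(
            normalize_rank(r.max_rank, r.max_rank, global_max) for r in contrib
        )
        for j, gene in enumerate(genes):
            if not np.isfinite(mean_rank[j]):
                continue
            out[(gene, condition)] = ExpressionScore(
                gene=gene,
                condition=condition,
                mean_normalized_rank=float(mean_rank[j]),
                score=expression_score(float(mean_rank[j]), cond_max),
            )
    return out


def gene_expression_pattern(
    gene: str,
    calls: Iterable[ExpressionCall],
    scores: Mapping[tuple[str, Condition], ExpressionScore],
    data_types: Iterable[str] | None = None,
) -> list[tuple[Condition, float, str, frozenset[str], tuple[str, ...]]]:
    """Gene-page view: present conditions ordered by score, highest first.

    Ties break on the condition's lexicographic key.  ``data_types``
    restricts results to conditions supported by at least one sample of the
    listed types; each row carries the contributing sample ids so the
    source data of every entry can be identified.
    """
    wanted = frozenset(data_types) if data_types is not None else None
    rows = []
    seen_gene = False
    for call in calls:
        if call.gene != gene:
            continue
        seen_gene = True
        if call.state != "present":
            continue
        if wanted is not None and not (call.data_types & wanted):
            continue
        sc = scores.get((gene, call.condition))
        if sc is None:
            continue
        rows.append(
            (call.condition, sc.score, call.state, call.data_types, call.sample_ids)
        )
    if not seen_gene:
        raise UnknownGene(f"gene {gene!r} has no expression call")
    rows.sort(key=lambda r: (-r[1], r[0].key()))
    return rows
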