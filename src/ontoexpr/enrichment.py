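"""Anatomical and cell-type enrichment of gene lists (TopAnat-style).

Instead of functional annotations, genes are mapped to ontology terms by
their expression patterns: a gene is attached to every anatomy/cell-type
term in which it has a *present* expression call, and to all ancestors of
those terms.  A gene list is then tested per term for over-representation
against a background list with the upper-tail hypergeometric test, either
independently per term (``classic``) or with the bottom-up ``elim``
decorrelation scheme in which genes of significant descendant terms are
removed from their ancestors before the ancestors are tested, so that broad
terms do not merely echo their most specific children.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping

from scipy import stats
from statsmodels.stats.multitest import multipletests

from .calls import ExpressionCall
from .errors import EmptyForeground, ForegroundNotInBackground, InvalidCounts
from .ontology import Ontology

logger = logging.getLogger(__name__)

TermGeneMap = dict[str, set[str]]


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int  # foreground genes at term
    K: int  # background genes at term
    n: int  # foreground size
    N: int  # background size
    p: float
    fdr: float
    method: str  # classic | elim


def map_genes_to_terms(
    calls: Iterable[ExpressionCall], ontology: Ontology
) -> TermGeneMap:
    """Attach each gene to its present-call terms and all their ancestors.

    Both the anatomy and the cell-type axis of each present call
    contribute; axis values not found in *ontology* (e.g. the cell-type
    root sentinel of a bulk sample) are skipped.
    """
    out: TermGeneMap = defaultdict(set)
    for call in calls:
        if call.state != "present":
            continue
        for term in (call.condition.anat, call.condition.cell_type):
            if term not in ontology:
                continue
            out[term].add(call.gene)
            for anc in ontology.ancestors(term):
                out[anc].add(call.gene)
    return dict(out)


def hypergeom_test(k: int, n: int, K: int, N: int) -> float:
    """Exact upper-tail hypergeometric probability P(X >= k).

    *k* foreground genes at the term, *n* foreground genes total, *K*
    background genes at the term, *N* background genes total.
    """
    if not (0 <= k <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise InvalidCounts(f"inconsistent counts k={k} n={n} K={K} N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def topanat(
    foreground: Iterable[str],
    background: Iterable[str] | None,
    term_map: Mapping[str, set[str]],
    ontology: Ontology,
    method: str = "elim",
    fdr_alpha: float = 0.05,
    elim_threshold: float = 0.01,
    min_background: int = 2,
    strict: bool = False,
) -> list[EnrichmentResult]:
    """Term enrichment of *foreground* against *background*.

    When *background* is None it defaults to every gene with at least one
    present call (the union of the term map); a genome-wide universe can be
    passed explicitly instead.  Foreground genes outside the background are
    dropped with a warning (or raise in strict mode).  Terms with fewer
    than *min_background* background genes are untestable and skipped.
    Reported p-values are BH-adjusted across the tested terms; results are
    sorted by ascending p, ties by term id.
    """
    if background is None:
        background = set().union(*term_map.values()) if term_map else set()
    background = set(background)
    fg_in = set(foreground)
    outside = fg_in - background
    if outside:
        if strict:
            raise ForegroundNotInBackground(
                f"{len(outside)} foreground genes not in background"
            )
        logger.warning(
            "topanat: dropping %d foreground genes not in background", len(outside)
        )
    fg = fg_in & background
    if not fg:
        raise EmptyForeground("foreground is empty after background intersection")
    n, N = len(fg), len(background)

    terms = sorted(t for t in term_map if t in ontology)
    results: list[tuple[str, int, int, float]] = []

    if method == "classic":
        for term in terms:
            genes_t = term_map[term] & background
            K = len(genes_t)
            if K < min_background:
                continue
            k = len(genes_t & fg)
            results.append((term, k, K, hypergeom_test(k, n, K, N)))
    elif method == "elim":
        # leaves first: deeper terms tested before their ancestors
        order = sorted(terms, key=lambda t: (-ontology.depth(t), t))
        removed: dict[str, set[str]] = defaultdict(set)
        for term in order:
            genes_t = (term_map[term] & background) - removed[term]
            K = len(genes_t)
            if K < min_background:
                continue
            k = len(genes_t & fg)
            p = hypergeom_test(k, n, K, N)
            results.append((term, k, K, p))
            if p <= elim_threshold:
                for anc in ontology.ancestors(term):
                    removed[anc] |= genes_t
    else:
        raise ValueError(f"unknown method {method!r}; choose 'classic' or 'elim'")

    if not results:
        return []
    ps = [r[3] for r in results]
    fdr = multipletests(ps, alpha=fdr_alpha, method="fdr_bh")[1]
    out = [
        EnrichmentResult(term=t, k=k, K=K, n=n, N=N, p=p, fdr=float(q), method=method)
        for (t, k, K, p), q in zip(results, fdr)
    ]
    out.sort(key=lambda r: (r.p, r.term))
    return out
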