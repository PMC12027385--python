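"""Local over-representation analysis (ORA) of ceNET gene sets.

Re-implements the usual annotation-server workflow offline: for each
annotation term the overlap with the query gene set is scored with a
one-sided hypergeometric test, adjusted per annotation category with
Benjamini–Hochberg, filtered on an effect-size floor
(``strength = log10(observed/expected)``) and a minimum number of
query hits, and finally clustered into groups of mutually similar
terms by single-linkage on Jaccard similarity of their query members.

Default thresholds: FDR <= 0.05, strength >= 0.01, >= 2 query genes
per term, grouping at Jaccard >= 0.2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import DomainError, UsageError
from .io_tables import AnnotationSet

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentTerm:
    """One annotation term's over-representation result.

    ``k`` query genes hit the term, out of ``K`` background genes in
    the term, ``n`` query genes in the background and ``N`` background
    genes overall. ``strength`` is ``log10((k/n)/(K/N))``, the log
    observed/expected ratio. ``group_id`` is assigned by
    :func:`group_terms` (0 = ungrouped).
    """

    term_id: str
    term_name: str
    category: str
    k: int
    K: int
    n: int
    N: int
    p_hyper: float
    fdr_bh: float
    strength: float
    members: frozenset[str] = field(default_factory=frozenset)
    group_id: int = 0


def hypergeom_upper_tail(k, K, n, N):
    """Upper-tail hypergeometric probability P(X >= k) for X ~
    Hypergeom(N, K, n): drawing ``n`` items without replacement from a
    universe of ``N`` containing ``K`` marked items.

    Accepts scalars or broadcastable arrays; computed through the
    survival function of :class:`scipy.stats.hypergeom`, which works
    on log-scale internally and is stable far into the tail.
    """
    k_arr, K_arr, n_arr, N_arr = np.broadcast_arrays(
        np.asarray(k), np.asarray(K), np.asarray(n), np.asarray(N))
    if np.any(K_arr > N_arr) or np.any(n_arr > N_arr):
        raise DomainError("need K <= N and n <= N")
    if np.any(k_arr < 0) or np.any(k_arr > np.minimum(K_arr, n_arr)):
        raise DomainError("need 0 <= k <= min(K, n)")
    p = stats.hypergeom.sf(k_arr - 1, N_arr, K_arr, n_arr)
    if np.ndim(k) == 0 and np.isscalar(k):
        return float(p)
    return p if p.shape else float(p)


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, order-aligned with
    the input and capped at 1."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise DomainError("p-values must lie in (0, 1]")
    return np.minimum(stats.false_discovery_control(p, method="bh"),
                      1.0).tolist()


def strength_score(k: int, K: int, n: int, N: int) -> float:
    """log10 observed/expected term-hit ratio; -inf when k = 0."""
    if k == 0:
        return -math.inf
    return math.log10((k / n) / (K / N))


def enrich(
    query: Iterable[str],
    annotations: Sequence[AnnotationSet],
    background: Iterable[str],
    *,
    fdr_max: float = 0.05,
    strength_min: float = 0.01,
    min_hits: int = 2,
) -> list[EnrichmentTerm]:
    """Test every annotation term for over-representation in ``query``.

    Query genes outside the background are dropped with a warning, as
    are term genes outside the background (the background defines the
    universe N). BH adjustment runs separately within each annotation
    category over *all* tested terms of that category; the returned
    list keeps only terms passing all three thresholds, sorted by
    (category, fdr, -strength).
    """
    background = set(background)
    if not background:
        raise UsageError("background universe is empty")
    query = set(query)
    outside = query - background
    if outside:
        logger.warning("%d query genes outside background dropped: %s",
                       len(outside), ", ".join(sorted(outside)[:10]))
    query &= background
    n, N = len(query), len(background)

    by_category: dict[str, list[tuple[AnnotationSet, frozenset[str]]]] = {}
    for ann in annotations:
        genes = frozenset(ann.genes & background)
        lost = len(ann.genes) - len(genes)
        if lost:
            logger.warning("term %s: %d genes outside background dropped",
                           ann.term_id, lost)
        if not genes:
            logger.warning("term %s: empty after background restriction; "
                           "skipped", ann.term_id)
            continue
        by_category.setdefault(ann.category, []).append((ann, genes))

    results: list[EnrichmentTerm] = []
    for category in sorted(by_category):
        tested = by_category[category]
        ks = [len(query & genes) for _, genes in tested]
        ps = [float(hypergeom_upper_tail(k, len(genes), n, N))
              for k, (_, genes) in zip(ks, tested)]
        fdrs = bh_adjust(ps)
        for (ann, genes), k, p, fdr in zip(tested, ks, ps, fdrs):
            if k < min_hits or fdr > fdr_max:
                continue
            strength = strength_score(k, len(genes), n, N)
            if strength < strength_min:
                continue
            results.append(EnrichmentTerm(
                term_id=ann.term_id, term_name=ann.term_name,
                category=category, k=k, K=len(genes), n=n, N=N,
                p_hyper=p, fdr_bh=fdr, strength=strength,
                members=frozenset(query & genes)))
    results.sort(key=lambda t: (t.category, t.fdr_bh, -t.strength, t.term_id))
    return results


def jaccard(a: frozenset[str], b: frozenset[str]) -> float:
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def group_terms(
    results: Sequence[EnrichmentTerm], similarity_min: float = 0.2
) -> list[EnrichmentTerm]:
    """Assign ``group_id`` by single-linkage clustering on Jaccard
    similarity of the terms' query-member sets.

    Terms connected by any chain of pairwise links with similarity >=
    ``similarity_min`` share a group. Each group's representative is
    its lowest-FDR term; group ids are 1-based in representative order
    (ties broken by term_id). Returns the input order with group ids
    filled in.
    """
    n = len(results)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if jaccard(results[i].members, results[j].members) >= similarity_min:
                parent[find(i)] = find(j)

    components: dict[int, list[int]] = {}
    for i in range(n):
        components.setdefault(find(i), []).append(i)
    reps = sorted(
        (min(idxs, key=lambda i: (results[i].fdr_bh, results[i].p_hyper,
                                  results[i].term_id)), idxs)
        for rep, idxs in components.items())
    reps.sort(key=lambda t: (results[t[0]].fdr_bh, results[t[0]].p_hyper,
                             results[t[0]].term_id))
    out = [EnrichmentTerm(**vars(t)) for t in results]
    for gid, (_, idxs) in enumerate(reps, start=1):
        for i in idxs:
            out[i].group_id = gid
    return out
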