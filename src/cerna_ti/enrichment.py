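"""Stage 5: offline hypergeometric functional enrichment.

For a query gene set of size ``n`` drawn from a universe of size ``N``, a
term annotating ``K`` universe genes and ``k`` query genes has upper-tail
p-value ``P(X >= k)`` for ``X ~ Hypergeometric(N, K, n)``. The tail is
computed with exact integer arithmetic (binomial coefficients and a
rational sum) so small worked examples are reproduced exactly; the
Benjamini-Hochberg adjusted ``q`` is always reported alongside, but the
significance call mirrors the classical raw ``p < alpha`` convention of
web enrichment tools.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from math import comb

import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io_formats import AnnotationMap, ValidationError

logger = logging.getLogger("cerna_ti")


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact upper-tail ``P(X >= k)``, ``X ~ Hypergeometric(N, K, n)``."""
    if not 0 <= K <= N or not 0 <= n <= N:
        raise ValidationError(f"invalid hypergeometric parameters N={N}, K={K}, n={n}")
    if k <= max(0, n + K - N):
        return 1.0
    hi = min(K, n)
    if k > hi:
        return 0.0
    num = sum(comb(K, j) * comb(N - K, n - j) for j in range(k, hi + 1))
    return float(Fraction(num, comb(N, n)))


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int   # query genes annotated with the term
    K: int   # universe genes annotated with the term
    n: int   # query size (within universe)
    N: int   # universe size
    p: float
    q: float

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def hypergeom_enrich(
    query: set[str],
    annot: AnnotationMap,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Test every annotated term for over-representation in ``query``.

    Query genes outside the universe are logged and dropped. Results are
    sorted by p (ties by term id); ``q`` is the Benjamini-Hochberg adjusted
    p over all tested terms.
    """
    if not annot.universe:
        raise ValidationError("annotation universe is empty")
    if not query:
        raise ValidationError("query gene set is empty")
    stray = query - set(annot.universe)
    if stray:
        logger.warning("dropping %d query gene(s) outside the universe", len(stray))
    q_in = query & set(annot.universe)
    if not q_in:
        raise ValidationError("no query gene lies in the annotation universe")
    N, n = len(annot.universe), len(q_in)
    rows = []
    for term_id in sorted(annot.terms):
        name, members = annot.terms[term_id]
        K = len(members)
        k = len(members & q_in)
        rows.append((term_id, name, k, K, hypergeom_tail(N, K, n, k)))
    pvals = [r[4] for r in rows]
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    results = [
        EnrichmentResult(term_id=tid, term_name=name, k=k, K=K, n=n, N=N,
                         p=p, q=float(qv))
        for (tid, name, k, K, p), qv in zip(rows, qvals)
    ]
    results.sort(key=lambda r: (r.p, r.term_id))
    n_sig = sum(r.p < alpha for r in results)
    logger.info("enrichment: %d/%d terms at p < %g (query %d of universe %d)",
                n_sig, len(results), alpha, n, N)
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"term_id": r.term_id, "term_name": r.term_name, "k": r.k, "K": r.K,
          "n": r.n, "N": r.N, "p": r.p, "q": r.q} for r in results]
    )
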