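"""Over-representation analysis of a gene list against gene-set
libraries.

Per term the module reports the Fisher exact (hypergeometric
upper-tail) p value, a Benjamini-Hochberg adjusted p, a rank-deviation
z obtained from seeded random queries, the combined score
ln(p) * z_rank, and the gene ratio k / K.

The Fisher p is computed in exact rational arithmetic and converted to
float once, so it agrees bit-for-bit with a brute-force enumeration of
the hypergeometric tail.
"""

from __future__ import annotations

import logging
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

logger = logging.getLogger(__name__)


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """Exact P(X >= k) for X ~ Hypergeometric(N, K, n).

    Computed as a single rational number (sum of binomial products over
    the tail) and rounded to float once.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValidationError(f"invalid hypergeometric parameters N={N}, K={K}, n={n}")
    if k <= max(0, n + K - N):
        return 1.0
    if k > min(n, K):
        return 0.0
    numerator = sum(comb(K, j) * comb(N - K, n - j) for j in range(k, min(n, K) + 1))
    return float(Fraction(numerator, comb(N, n)))


def _prepare(query, universe) -> tuple[set[str], set[str]]:
    universe_set = {g.upper() for g in universe}
    if not universe_set:
        raise ValidationError("empty universe")
    query_set = {g.upper() for g in query}
    outside = query_set - universe_set
    if outside:
        logger.warning("enrichment: dropped %d query gene(s) outside the universe", len(outside))
    return query_set & universe_set, universe_set


def fisher_enrich(query, term_genes, universe) -> tuple[int, float]:
    """Overlap count and Fisher exact upper-tail p of a term in a query.

    The term is restricted to the universe (K = |term ∩ universe|);
    query genes outside the universe are dropped with a logged count.
    """
    query_set, universe_set = _prepare(query, universe)
    term_set = {g.upper() for g in term_genes} & universe_set
    k = len(query_set & term_set)
    p = hypergeom_tail(k, len(universe_set), len(term_set), len(query_set))
    return k, p


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, clipped to 1.

    Input order is preserved in the output.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def _term_pvalues_fast(member_matrix, K_vec, query_idx, N):
    """Vectorised per-term upper-tail p for one query (permutation scoring)."""
    k_vec = member_matrix[:, query_idx].sum(axis=1)
    return stats.hypergeom.sf(k_vec - 1, N, K_vec, len(query_idx))


def rank_z(
    term: str,
    query,
    library: dict[str, list[str]],
    universe,
    n_permutations: int = 1000,
    seed: int = 0,
) -> float:
    """Deviation of a term's p-value rank from its expected rank, as z.

    The observed rank of ``term`` (terms ranked by ascending p over the
    real query) is compared against ranks of the same term when scoring
    seeded random queries of identical size:
    z = (observed rank - mean null rank) / sd(null ranks).
    Negative z means the term ranks better than expected by chance.
    """
    if n_permutations < 100:
        raise ValidationError("n_permutations must be >= 100")
    results = enrich(
        query, library, universe, n_permutations=n_permutations, seed=seed
    )
    row = results[results["term"] == term]
    if row.empty:
        raise ValidationError(f"term {term!r} not in library")
    return float(row["z_rank"].iloc[0])


def _rank_statistics(
    library: dict[str, list[str]],
    universe_sorted: list[str],
    n_query: int,
    observed_p: np.ndarray,
    n_permutations: int,
    seed: int,
) -> np.ndarray:
    """z of observed rank vs. seeded random-query null ranks, per term."""
    rng = np.random.default_rng(seed)
    N = len(universe_sorted)
    gene_index = {g: i for i, g in enumerate(universe_sorted)}
    terms = list(library)
    member_matrix = np.zeros((len(terms), N), dtype=bool)
    for t, name in enumerate(terms):
        for g in library[name]:
            idx = gene_index.get(g.upper())
            if idx is not None:
                member_matrix[t, idx] = True
    K_vec = member_matrix.sum(axis=1)

    observed_rank = stats.rankdata(observed_p, method="average")
    if n_query == 0 or n_permutations == 0:
        return np.zeros(len(terms))
    null_ranks = np.empty((n_permutations, len(terms)))
    for b in range(n_permutations):
        qidx = rng.choice(N, size=n_query, replace=False)
        pvals = _term_pvalues_fast(member_matrix, K_vec, qidx, N)
        null_ranks[b] = stats.rankdata(pvals, method="average")
    mean_rank = null_ranks.mean(axis=0)
    sd_rank = null_ranks.std(axis=0, ddof=1)
    z = np.zeros(len(terms))
    nonzero = sd_rank > 0
    z[nonzero] = (observed_rank[nonzero] - mean_rank[nonzero]) / sd_rank[nonzero]
    if (~nonzero).any():
        logger.warning("rank_z: %d term(s) with degenerate null rank SD, z set to 0",
                       int((~nonzero).sum()))
    return z


def enrich(
    query,
    library: dict[str, list[str]],
    universe,
    alpha: float = 0.05,
    n_permutations: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Score every term of a library against a query gene list.

    Returns one row per term with k, n, K, N, p, p_adj (BH), z_rank,
    combined_score = ln(p) * z_rank (plus its absolute value),
    gene_ratio = k / K, overlap genes, and a ``significant`` flag
    (p_adj < alpha, strict). Rows are sorted by combined score
    descending (ties broken by p, then term name) so the most enriched
    terms come first.
    """
    if not library:
        raise ValidationError("empty gene-set library")
    if not 0 <= alpha <= 1:
        raise ValidationError("alpha must be in [0, 1]")
    query_set, universe_set = _prepare(query, universe)
    universe_sorted = sorted(universe_set)
    N, n = len(universe_set), len(query_set)

    rows = []
    pvals = []
    for term, genes in library.items():
        term_set = {g.upper() for g in genes} & universe_set
        overlap = sorted(query_set & term_set)
        k, K = len(overlap), len(term_set)
        p = hypergeom_tail(k, N, K, n)
        pvals.append(p)
        rows.append(
            {
                "term": term,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p": p,
                "gene_ratio": k / K if K else 0.0,
                "overlap_genes": ",".join(overlap),
            }
        )
    table = pd.DataFrame(rows)
    observed_p = np.array(pvals)
    table["p_adj"] = bh_adjust(observed_p)
    table["z_rank"] = _rank_statistics(
        library, universe_sorted, n, observed_p, n_permutations, seed
    )
    logp = np.log(observed_p)  # p > 0 always (upper tail includes k)
    table["combined_score"] = logp * table["z_rank"]
    table["abs_combined_score"] = np.abs(table["combined_score"])
    table["significant"] = table["p_adj"] < alpha
    table = table.sort_values(
        ["combined_score", "p", "term"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    return table[
        ["term", "k", "n", "K", "N", "p", "p_adj", "z_rank", "combined_score",
         "abs_combined_score", "gene_ratio", "significant", "overlap_genes"]
    ]
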