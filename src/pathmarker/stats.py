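"""Gene-set overlap, enrichment and functional-similarity statistics.

Over-representation is tested one-sided with the hypergeometric upper tail
(equivalent to one-sided Fisher's exact test on the 2x2 table). Term
enrichment reports per-term count, percentage of the query set, raw p and
Benjamini-Hochberg adjusted p against an explicit chip background.
Functional profiles are vectors of -log10 hypergeometric p over a term
universe; two gene sets are compared by the Pearson correlation of their
profiles.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .containers import GeneSetCollection

logger = logging.getLogger(__name__)


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``k`` observed overlap, ``n`` query size, ``K`` annotated genes,
    ``N`` background size. k = 0 gives p = 1 (the tail includes 0).
    """
    if not (0 <= k <= min(n, K) and max(n, K) <= N):
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def overlap_test(set_a: set[str], set_b: set[str],
                 background: set[str]) -> tuple[set[str], float]:
    """Overlap of two gene sets and its hypergeometric upper-tail p.

    Genes outside the background are dropped with a warning.
    """
    background = set(background)
    a = set(set_a) & background
    b = set(set_b) & background
    dropped = (len(set_a) - len(a)) + (len(set_b) - len(b))
    if dropped:
        logger.warning("%d gene(s) outside the background were dropped",
                       dropped)
    overlap = a & b
    p = hypergeom_upper_tail(len(overlap), len(a), len(b), len(background))
    return overlap, p


def bh_adjust(pvalues: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def term_enrichment(query: set[str], annotations: GeneSetCollection,
                    background: set[str]) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of every term hit by the query.

    Columns: term, count, percentage (of the background-intersected query,
    in %), p_value, adjusted_p (BH); one row per term with at least one
    query gene, sorted by p then term name.
    """
    background = set(background)
    q = set(query) & background
    if not q:
        raise ValueError("query set is empty after background intersection")
    rows = []
    for name in annotations.names():
        members = annotations[name] & background
        hits = q & members
        if not hits:
            continue
        p = hypergeom_upper_tail(len(hits), len(q), len(members),
                                 len(background))
        rows.append((name, len(hits), 100.0 * len(hits) / len(q), p))
    df = pd.DataFrame(rows, columns=["term", "count", "percentage",
                                     "p_value"])
    df["adjusted_p"] = bh_adjust(df["p_value"].to_numpy())
    return df.sort_values(["p_value", "term"], ignore_index=True)


def functional_profile(genes: set[str], annotations: GeneSetCollection,
                       background: set[str], cap: float = 320.0
                       ) -> pd.Series:
    """-log10 hypergeometric upper-tail p per term, over all terms.

    Returned as a Series indexed by the (name-ordered) term universe;
    values are capped at ``cap`` so underflowing p-values stay finite.
    """
    background = set(background)
    q = set(genes) & background
    if not q:
        raise ValueError("gene set is empty after background intersection")
    terms = sorted(annotations.names())
    vals = []
    for name in terms:
        members = annotations[name] & background
        k = len(q & members)
        p = hypergeom_upper_tail(k, len(q), len(members), len(background))
        with np.errstate(divide="ignore"):
            v = -np.log10(p) if p > 0 else np.inf
        vals.append(min(float(v), cap))
    return pd.Series(vals, index=terms, name="neglog10_p")


def profile_similarity(p1: pd.Series, p2: pd.Series) -> float:
    """Pearson correlation of two functional profiles on one universe."""
    if list(p1.index) != list(p2.index):
        raise ValueError("profiles must share the same term universe")
    x = p1.to_numpy(dtype=float)
    y = p2.to_numpy(dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for a zero-variance profile")
    return float(sps.pearsonr(x, y).statistic)


def proportion_compare(k1: int, n1: int, k2: int, n2: int,
                       method: str = "chi2") -> float:
    """Two-sample proportion test p-value for k1/n1 vs k2/n2.

    ``method`` "chi2" is the two-proportion chi-square test with Yates
    continuity correction (as in R's prop.test); "ztest" is the pooled
    normal-approximation z-test.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if not 0 <= k <= n or n == 0:
            raise ValueError("need 0 <= k <= n with n > 0")
    if method == "chi2":
        table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
        if table.sum(axis=0).min() == 0:  # degenerate margin: no signal
            return 1.0
        return float(sps.chi2_contingency(table, correction=True).pvalue)
    if method == "ztest":
        p_pool = (k1 + k2) / (n1 + n2)
        se = np.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
        if se == 0:
            return 1.0
        z = (k1 / n1 - k2 / n2) / se
        return float(2 * sps.norm.sf(abs(z)))
    raise ValueError(f"unknown method {method!r}")
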