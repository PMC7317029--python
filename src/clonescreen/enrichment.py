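"""Annotation-term over-representation by the exact hypergeometric upper tail.

Terms are opaque labels; no ontology structure is consulted.  Raw p-values are
adjusted with Benjamini-Hochberg across the tested terms.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InvalidArgumentError


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    if n == 0:
        return p
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ hypergeometric(N population, K marked, n drawn)."""
    return float(min(stats.hypergeom.sf(k - 1, N, K, n), 1.0))


def enrich(gene_set, universe, annotation: dict, min_term_size: int = 2) -> pd.DataFrame:
    """Hypergeometric over-representation of annotation terms in ``gene_set``.

    Parameters
    ----------
    gene_set
        Genes of interest (must be a subset of ``universe``).
    universe
        Background gene set (e.g. all screened genes).
    annotation
        Mapping ``gene -> iterable of terms``; genes outside the universe are
        ignored.
    min_term_size
        Terms annotating fewer universe genes are skipped (count reported in
        the ``skipped_small_terms`` DataFrame attribute).

    Returns a DataFrame of rows ``term, k, K, n, N, p, q`` sorted by p, where
    p = P(X >= k) for X hypergeometric(N, K, n).
    """
    universe = set(universe)
    if not universe:
        raise InvalidArgumentError("empty universe")
    gene_set = set(gene_set)
    outside = gene_set - universe
    if outside:
        raise InvalidArgumentError(
            f"gene_set not contained in universe: {sorted(outside)[:5]}")
    term_genes: dict[str, set] = {}
    for gene, terms in annotation.items():
        if gene not in universe:
            continue
        for t in terms:
            term_genes.setdefault(t, set()).add(gene)
    N, n = len(universe), len(gene_set)
    rows = []
    skipped = 0
    for term, members in sorted(term_genes.items()):
        K = len(members)
        if K < min_term_size:
            skipped += 1
            continue
        k = len(members & gene_set)
        p = hypergeom_upper_tail(k, N, K, n)
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N, "p": p})
    out = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    out = out.sort_values(["p", "term"], kind="stable").reset_index(drop=True)
    out.attrs["skipped_small_terms"] = skipped
    return out


def read_annotation(path) -> dict:
    """Read a ``gene<TAB>term`` annotation table into gene -> set of terms."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns[:2])
    out: dict[str, set] = {}
    for g, t in zip(df[cols[0]], df[cols[1]]):
        out.setdefault(g, set()).add(t)
    return out
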