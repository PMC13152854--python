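"""Hypergeometric over-representation tests with Benjamini-Hochberg FDR.

A gene set (e.g. a trajectory module) is tested for over-representation of
every annotation term it overlaps, against a universe of expressed genes.
P-values are upper tails of the hypergeometric distribution; FDR control is
applied within each annotation layer separately (GO vs KEGG and so on have
different term granularities, so pooling would distort the correction).
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import AnnotationTable


def hypergeom_pvalue(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    ``N`` universe size, ``K`` term size, ``n`` set size, ``k`` overlap.
    Uses log-gamma arithmetic (stable for N up to 1e6).
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(f"inconsistent counts N={N} K={K} n={n} k={k}")
    if k == 0:
        return 1.0
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 0.0), 1.0)


def bh_fdr(pvalues: Iterable[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted values, input order preserved."""
    p = list(pvalues)
    if not p:
        return []
    if any(not (0 < x <= 1) for x in p):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in q]


def enrich_geneset(genes: Iterable[str], annotation: AnnotationTable,
                   universe: Iterable[str], alpha: float = 0.05) -> pd.DataFrame:
    """Test every overlapping term for over-representation in ``genes``.

    Terms with zero overlap are not tested (this reduces the number of
    hypotheses m and therefore changes q-values).  BH correction is applied
    within each annotation layer.  Results are sorted by (q, p, term);
    ``significant`` marks q < ``alpha``.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    genes = set(genes)
    if not genes <= universe:
        raise ValueError("gene set must be a subset of the universe")
    gt = annotation.gene_terms
    gt = gt[gt["gene"].isin(universe)]
    N = len(universe)
    n = len(genes)
    rows = []
    for (layer, term), sub in gt.groupby(["layer", "term"], sort=True):
        members = set(sub["gene"])
        k = len(members & genes)
        if k == 0:
            continue
        K = len(members)
        rows.append({"layer": layer, "term": term, "N": N, "K": K, "n": n,
                     "k": k, "p": hypergeom_pvalue(N, K, n, k)})
    if not rows:
        return pd.DataFrame(columns=["layer", "term", "N", "K", "n", "k",
                                     "p", "q", "significant"])
    out = pd.DataFrame(rows)
    out["q"] = 1.0
    for layer, sub in out.groupby("layer"):
        out.loc[sub.index, "q"] = bh_fdr(sub["p"])
    out["significant"] = out["q"] < alpha
    return out.sort_values(["q", "p", "term"], kind="stable").reset_index(drop=True)


def enrich_clusters(labels: pd.Series, annotation: AnnotationTable,
                    universe: Iterable[str], alpha: float = 0.05) -> pd.DataFrame:
    """Run ``enrich_geneset`` for every cluster; adds a ``cluster`` column."""
    universe = set(universe)
    frames = []
    for cluster in sorted(labels.unique()):
        genes = set(labels.index[labels == cluster]) & universe
        res = enrich_geneset(genes, annotation, universe, alpha=alpha)
        res.insert(0, "cluster", cluster)
        frames.append(res)
    return pd.concat(frames, ignore_index=True)
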