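"""Stage-residualized co-expression networks, WGCNA-style modules with
eigengene-trait models, and the cross-cultivar consensus network.

Developmental stage dominates dormancy transcriptomes, so correlations are
computed on stage-residualized log2(TPM+1): per gene, the mean over all
samples of the same stage is subtracted, leaving genotype- and replicate-
level covariation.  The module layer follows WGCNA's construction —
unsigned adjacency |r|^beta, topological-overlap similarity, average-
linkage clustering of 1-TOM with a static tree cut, size-ranked colour
names — and each module is summarized by its eigengene (first principal
component across samples).  The consensus network keeps only edges whose
correlation sign agrees, at sufficient magnitude, in at least k of n
per-cultivar networks, suppressing single-genotype artefacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
import statsmodels.api as sm

#: WGCNA's size-ranked module colour order.
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
)

UNASSIGNED = "grey"


def residualize_by_stage(log_values: pd.DataFrame, design: pd.DataFrame,
                         within_cultivar: bool = False) -> pd.DataFrame:
    """Subtract per-stage sample means from every gene.

    With ``within_cultivar=True`` the means are taken per (cultivar, stage)
    cell instead, which additionally removes genotype baselines; this is the
    residualization used for the per-cultivar networks.
    """
    cols = ["cultivar", "stage"] if within_cultivar else ["stage"]
    keys = pd.MultiIndex.from_frame(design[cols].astype(object))
    mat = log_values.copy()
    mat.columns = keys
    resid = mat - mat.T.groupby(level=list(range(len(cols))), sort=False
                                ).transform("mean").T
    resid.columns = log_values.columns
    counts = design.groupby(cols, observed=False).size()
    if (counts == 0).any():
        raise ValueError(f"empty {cols} cell: {list(counts[counts == 0].index)}")
    return resid


def _drop_zero_variance(values: pd.DataFrame) -> pd.DataFrame:
    sds = values.std(axis=1, ddof=1)
    flat = sds[sds == 0].index
    if len(flat):
        warnings.warn(f"dropping {len(flat)} zero-variance genes from network")
        values = values.drop(index=flat)
    return values


def correlation_matrix(values: pd.DataFrame) -> pd.DataFrame:
    """Gene x gene Pearson correlations across samples (rows = genes)."""
    if values.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    values = _drop_zero_variance(values)
    corr = np.corrcoef(values.to_numpy())
    return pd.DataFrame(corr, index=values.index, columns=values.index)


def correlation_network(values: pd.DataFrame, min_abs_r: float = 0.8) -> nx.Graph:
    """Threshold graph: an edge for every gene pair with |r| >= min_abs_r.

    Edge attributes: ``weight`` (signed r), ``sign``.  Nodes carry their
    degree after construction.
    """
    corr = correlation_matrix(values)
    g = nx.Graph(kind="correlation", min_abs_r=min_abs_r)
    g.add_nodes_from(corr.index)
    r = corr.to_numpy()
    iu, ju = np.triu_indices(len(corr), k=1)
    keep = np.abs(r[iu, ju]) >= min_abs_r
    for i, j in zip(iu[keep], ju[keep]):
        val = float(r[i, j])
        g.add_edge(corr.index[i], corr.index[j], weight=val,
                   sign=1 if val > 0 else -1)
    nx.set_node_attributes(g, dict(g.degree()), "degree")
    return g


def adjacency_from_corr(corr: pd.DataFrame, beta: int = 6) -> pd.DataFrame:
    """Unsigned WGCNA adjacency |r|^beta with a zero diagonal."""
    a = np.abs(corr.to_numpy()) ** beta
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=corr.index, columns=corr.columns)


def tom_similarity(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap:  TOM_ij = (sum_u a_iu a_uj + a_ij) /
    (min(k_i, k_j) + 1 - a_ij), with TOM_ii = 1.

    Two nodes are similar when they share neighbourhoods, not merely when
    they are directly connected.  Requires adjacency in [0, 1] with zero
    diagonal.
    """
    a = adjacency.to_numpy(dtype=float)
    if (a < 0).any() or (a > 1).any():
        raise ValueError("adjacency must lie in [0, 1]")
    if np.abs(np.diag(a)).max() > 1e-12:
        raise ValueError("adjacency diagonal must be zero")
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def detect_modules(tom: pd.DataFrame, min_module_size: int = 20,
                   cut_height: float = 0.8) -> pd.Series:
    """Average-linkage hierarchical clustering of 1-TOM with a static cut.

    Clusters below ``min_module_size`` become ``grey`` (unassigned); the
    rest are named by size-ranked WGCNA colour order (turquoise largest).
    """
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    genes = tom.index
    if len(genes) < 2:
        return pd.Series(UNASSIGNED, index=genes, name="module")
    dist = 1.0 - tom.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    link = average(squareform(dist, checks=False))
    raw = fcluster(link, t=cut_height, criterion="distance")
    sizes = pd.Series(raw).value_counts()
    ranked = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    names: dict[int, str] = {}
    color_i = 0
    for c in ranked:
        if sizes[c] >= min_module_size and color_i < len(MODULE_COLORS):
            names[c] = MODULE_COLORS[color_i]
            color_i += 1
        else:
            names[c] = UNASSIGNED
    return pd.Series([names[c] for c in raw], index=genes, name="module")


def module_eigengene(log_values: pd.DataFrame,
                     module_genes: list[str] | pd.Index
                     ) -> tuple[pd.Series, float]:
    """First principal component of the gene-standardized module submatrix.

    Returns the per-sample eigengene scaled to unit variance (ddof=1) and
    sign-aligned to correlate positively with the module's mean standardized
    expression, plus the fraction of variance PC1 explains.
    """
    module_genes = list(module_genes)
    if not module_genes:
        raise ValueError("module is empty")
    sub = log_values.loc[module_genes].to_numpy(dtype=float)
    if sub.shape[1] < 2:
        raise ValueError("eigengene needs at least 2 samples")
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (sub - mu) / sd
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    pc1 = vt[0]
    explained = float(s[0] ** 2 / (s ** 2).sum())
    mean_profile = z.mean(axis=0)
    if np.dot(pc1, mean_profile) < 0:
        pc1 = -pc1
    pc1 = pc1 / pc1.std(ddof=1)
    return pd.Series(pc1, index=log_values.columns, name="eigengene"), explained


def module_eigengenes(log_values: pd.DataFrame, modules: pd.Series
                      ) -> tuple[pd.DataFrame, pd.Series]:
    """Eigengene per non-grey module; returns (samples x modules, explained)."""
    mes = {}
    explained = {}
    for color in sorted(modules.unique()):
        if color == UNASSIGNED:
            continue
        genes = modules.index[modules == color]
        mes[f"ME{color}"], explained[f"ME{color}"] = module_eigengene(
            log_values, genes)
    return pd.DataFrame(mes), pd.Series(explained, name="pc1_var_explained")


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p for a Pearson correlation via t = r sqrt((n-2)/(1-r^2))."""
    if n < 3:
        return float("nan")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def trait_frame(design: pd.DataFrame, hormones_wide: pd.DataFrame) -> pd.DataFrame:
    """Per-sample trait table: numeric stage (1..n), 0/1 CR group, cultivar
    (categorical), and the hormone concentrations."""
    traits = pd.DataFrame(index=pd.Index(design["sample_id"], name="sample_id"))
    traits["stage_num"] = (design["stage"].cat.codes + 1).to_numpy()
    traits["cr_group_num"] = (design["cr_group"] == "High").astype(int).to_numpy()
    traits["cultivar"] = design["cultivar"].to_numpy()
    for h in hormones_wide.columns:
        traits[h] = hormones_wide[h].reindex(traits.index).to_numpy()
    return traits


@dataclass
class TraitModelFit:
    params: pd.Series
    pvalues: pd.Series
    aliased: list[str]
    r_squared: float


def module_trait_association(eigengenes: pd.DataFrame, traits: pd.DataFrame
                             ) -> tuple[pd.DataFrame, pd.DataFrame,
                                        dict[str, TraitModelFit]]:
    """Eigengene-trait statistics.

    (a) Pairwise Pearson r (with two-sided t-test p) between every module
    eigengene and every numeric trait.  (b) An OLS fit per module,
    ME ~ stage_num + cultivar + cr_group_num + ABA + GA3 + GA7; in the
    reference design the CR group is collinear with the cultivar dummies,
    so the aliased term is dropped from the fit and flagged.
    """
    numeric = traits.select_dtypes(include=[np.number])
    n = len(traits)
    corr = pd.DataFrame(index=eigengenes.columns, columns=numeric.columns,
                        dtype=float)
    pval = corr.copy()
    for me in eigengenes.columns:
        for tr in numeric.columns:
            r = float(np.corrcoef(eigengenes[me], numeric[tr])[0, 1])
            corr.loc[me, tr] = r
            pval.loc[me, tr] = correlation_pvalue(r, n)

    X_parts = [pd.Series(1.0, index=traits.index, name="const")]
    X_parts.append(numeric["stage_num"])
    if "cultivar" in traits:
        dummies = pd.get_dummies(traits["cultivar"], prefix="cultivar",
                                 drop_first=True, dtype=float)
        X_parts.append(dummies)
    for tr in numeric.columns:
        if tr != "stage_num":
            X_parts.append(numeric[tr])
    X = pd.concat(X_parts, axis=1)

    aliased: list[str] = []
    base_cols = [c for c in X.columns if c != "cr_group_num"]
    if "cr_group_num" in X.columns:
        rank_without = np.linalg.matrix_rank(X[base_cols].to_numpy())
        if np.linalg.matrix_rank(X.to_numpy()) == rank_without:
            aliased.append("cr_group_num")
            X = X[base_cols]

    fits = {}
    for me in eigengenes.columns:
        res = sm.OLS(eigengenes[me].to_numpy(), X.to_numpy()).fit()
        fits[me] = TraitModelFit(
            params=pd.Series(res.params, index=X.columns),
            pvalues=pd.Series(res.pvalues, index=X.columns),
            aliased=list(aliased),
            r_squared=float(res.rsquared),
        )
    return corr, pval, fits


def per_cultivar_correlations(log_values: pd.DataFrame, design: pd.DataFrame
                              ) -> dict[str, pd.DataFrame]:
    """Per-cultivar gene-gene correlations on within-cultivar stage-
    residualized data (each cultivar contributes its own samples only)."""
    resid = residualize_by_stage(log_values, design, within_cultivar=True)
    out = {}
    for cultivar, sub in design.groupby("cultivar", sort=False):
        cols = list(sub["sample_id"])
        out[str(cultivar)] = correlation_matrix(resid[cols])
    return out


def consensus_network(per_cultivar_corrs: dict[str, pd.DataFrame],
                      k_of_n: int = 3, min_abs_r: float = 0.5) -> nx.Graph:
    """Consensus edges across per-cultivar networks.

    An edge survives iff at least ``k_of_n`` cultivars show the same
    correlation sign with |r| >= ``min_abs_r`` each.  The consensus weight
    is the signed minimum |r| among the supporting cultivars; the support
    count and per-cultivar correlations are stored on the edge.  Raising
    ``k_of_n`` or ``min_abs_r`` can only remove edges.
    """
    cultivars = list(per_cultivar_corrs)
    if k_of_n > len(cultivars):
        raise ValueError(f"k_of_n={k_of_n} exceeds {len(cultivars)} cultivars")
    genes = per_cultivar_corrs[cultivars[0]].index
    for c in cultivars[1:]:
        if not genes.equals(per_cultivar_corrs[c].index):
            # zero-variance drops may differ between cultivars
            genes = genes.intersection(per_cultivar_corrs[c].index)
    R = np.stack([per_cultivar_corrs[c].loc[genes, genes].to_numpy()
                  for c in cultivars])
    strong = np.abs(R) >= min_abs_r
    pos = ((R > 0) & strong).sum(axis=0)
    neg = ((R < 0) & strong).sum(axis=0)

    g = nx.Graph(kind="consensus", k_of_n=k_of_n, min_abs_r=min_abs_r,
                 cultivars=",".join(cultivars))
    g.add_nodes_from(genes)
    iu, ju = np.triu_indices(len(genes), k=1)
    keep = (pos[iu, ju] >= k_of_n) | (neg[iu, ju] >= k_of_n)
    for i, j in zip(iu[keep], ju[keep]):
        rs = R[:, i, j]
        sign = 1 if pos[i, j] >= k_of_n else -1
        support_mask = (np.sign(rs) == sign) & (np.abs(rs) >= min_abs_r)
        weight = sign * float(np.abs(rs[support_mask]).min())
        attrs = {f"r_{c}": float(rs[ci]) for ci, c in enumerate(cultivars)}
        g.add_edge(genes[i], genes[j], weight=weight, sign=sign,
                   support=int(support_mask.sum()), **attrs)
    nx.set_node_attributes(g, dict(g.degree()), "degree")
    return g


def node_centrality(graph: nx.Graph) -> pd.DataFrame:
    """Degree and normalized betweenness (bridge score) per node."""
    if graph.number_of_nodes() == 0:
        return pd.DataFrame(columns=["degree", "betweenness"])
    degree = dict(graph.degree())
    betweenness = nx.betweenness_centrality(graph, normalized=True)
    return pd.DataFrame({"degree": pd.Series(degree),
                         "betweenness": pd.Series(betweenness)}).sort_index()


def connected_subgraph(graph: nx.Graph) -> nx.Graph:
    """Induced subgraph of nodes with degree > 0 (the displayed core)."""
    keep = [n for n, d in graph.degree() if d > 0]
    return graph.subgraph(keep).copy()


def edges_frame(graph: nx.Graph) -> pd.DataFrame:
    """Edge list as a DataFrame (gene1, gene2 sorted, plus attributes)."""
    rows = []
    for u, v, data in graph.edges(data=True):
        a, b = sorted((u, v))
        rows.append({"gene1": a, "gene2": b, **data})
    cols = ["gene1", "gene2"]
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=cols + ["weight", "sign"])
    return df.sort_values(cols, kind="stable").reset_index(drop=True)


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, path)


def write_sif(graph: nx.Graph, path: str | Path,
              interaction: str = "coexp") -> None:
    """Cytoscape simple-interaction format: ``gene1 <interaction> gene2``."""
    with open(path, "w", encoding="utf-8") as fh:
        for u, v, data in sorted(graph.edges(data=True)):
            tag = f"{interaction}{'+' if data.get('sign', 1) > 0 else '-'}"
            fh.write(f"{u}\t{tag}\t{v}\n")
        for node in sorted(n for n, d in graph.degree() if d == 0):
            fh.write(f"{node}\n")
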