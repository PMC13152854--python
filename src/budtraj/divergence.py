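"""Chilling-requirement divergence statistics and candidate selection.

Divergence between the High-CR and Low-CR cultivar groups is measured per
gene and per stage as the difference of the group means of log2(TPM+1)
cultivar-stage replicate means — cultivars, not libraries, are the
independent units.  Genes whose High-minus-Low difference changes sign
across stages are directionally discordant; clusters with a substantial
discordant fraction are the CR-divergent trajectory modules.  Candidate
regulators must additionally show a temporally concordant trend across
cultivars, pass a basal-abundance gate, and carry a regulatory-plausible
functional class.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import PLAUSIBLE_CLASSES, cr_group_of_cultivar
from .trajectory import ClusterAssignment


def group_stage_means(log_rep_means: pd.DataFrame,
                      design: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-CR-group stage means: for each stage, average the (cultivar,
    stage) replicate means over the group's cultivars."""
    group_of = cr_group_of_cultivar(design)
    stages = list(design["stage"].cat.categories)
    out = {}
    for grp in ("Low", "High"):
        cultivars = [c for c in group_of.index if group_of[c] == grp]
        if not cultivars:
            raise ValueError(f"CR group {grp!r} has no cultivars")
        stage_means = {
            s: log_rep_means.loc[:, [(c, s) for c in cultivars]].mean(axis=1)
            for s in stages
        }
        out[grp] = pd.DataFrame(stage_means)
    return out


def stage_group_difference(log_rep_means: pd.DataFrame,
                           design: pd.DataFrame) -> pd.DataFrame:
    """Per-gene signed High-minus-Low difference d_s at every stage."""
    groups = group_stage_means(log_rep_means, design)
    return groups["High"] - groups["Low"]


def module_stage_divergence(d: pd.DataFrame,
                            assignment: ClusterAssignment) -> pd.DataFrame:
    """Cluster x stage divergence D(c, s) = mean over the cluster's genes of
    |d_s|, with the peak stage (argmax; ties broken toward the earliest
    stage)."""
    rows = []
    for cluster in assignment.centroids.index:
        genes = assignment.genes_in(cluster)
        if len(genes) == 0:
            raise ValueError(f"cluster {cluster} is empty")
        D = d.reindex(genes).abs().mean(axis=0)
        peak = D.index[int(np.argmax(D.to_numpy()))]  # argmax takes first max
        rows.append(pd.Series({**D.to_dict(), "peak_stage": peak}, name=cluster))
    out = pd.DataFrame(rows)
    out.index.name = "cluster"
    return out


def discordance_flag(d: pd.DataFrame, eps: float = 0.05) -> pd.Series:
    """Directional discordance: the signs of the stage differences with
    |d_s| >= eps are not all equal.  Genes with every |d_s| < eps are not
    discordant."""
    vals = d.to_numpy()
    big = np.abs(vals) >= eps
    pos = (vals > 0) & big
    neg = (vals < 0) & big
    flag = pos.any(axis=1) & neg.any(axis=1)
    return pd.Series(flag, index=d.index, name="discordant")


def cultivar_concordance(log_rep_means: pd.DataFrame, eps: float = 0.05,
                         k_of_n: int = 3
                         ) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Cross-cultivar temporal-trend concordance.

    Per cultivar the trend sign is sign(x_last_stage - x_first_stage) on the
    log scale (0 when |delta| < eps).  ``concordance_count`` is the size of
    the largest set of cultivars sharing the same non-zero sign; the filter
    passes when that count reaches ``k_of_n``.

    Returns (trend signs gene x cultivar, counts, pass flags).
    """
    cultivars = list(dict.fromkeys(log_rep_means.columns.get_level_values(0)))
    n_stages = len(log_rep_means.columns) // len(cultivars)
    if n_stages < 2:
        raise ValueError("need at least 2 stages")
    signs = {}
    for c in cultivars:
        block = log_rep_means[c]
        delta = block.iloc[:, -1] - block.iloc[:, 0]
        s = np.sign(delta.to_numpy())
        s[np.abs(delta.to_numpy()) < eps] = 0
        signs[c] = s.astype(int)
    trend = pd.DataFrame(signs, index=log_rep_means.index)
    n_pos = (trend.to_numpy() > 0).sum(axis=1)
    n_neg = (trend.to_numpy() < 0).sum(axis=1)
    count = pd.Series(np.maximum(n_pos, n_neg), index=trend.index,
                      name="concordance_count")
    passes = pd.Series(count >= k_of_n, index=trend.index,
                       name="concordance_pass")
    return trend, count, passes


def abundance_gate(tpm_values: pd.DataFrame, min_mean: float = 0.5,
                   min_max: float = 1.0) -> pd.Series:
    """Basal abundance gate: mean TPM >= ``min_mean`` and max TPM >=
    ``min_max`` over all libraries, boundaries inclusive."""
    mean_ok = tpm_values.mean(axis=1) >= min_mean
    max_ok = tpm_values.max(axis=1) >= min_max
    return pd.Series(mean_ok & max_ok, index=tpm_values.index,
                     name="abundance_pass")


def select_candidates(assignment: ClusterAssignment, flagged_clusters: set[str],
                      discordant: pd.Series, concordance_pass: pd.Series,
                      abundance_pass: pd.Series, classes: pd.Series,
                      plausible: frozenset[str] | set[str] = PLAUSIBLE_CLASSES,
                      ) -> tuple[pd.Index, pd.Series]:
    """Candidate = member of a flagged CR-divergent cluster AND discordant
    AND trend-concordant AND abundance-passing AND regulatory-plausible
    class.  Returns the candidate gene index and per-cluster counts."""
    if not plausible:
        raise ValueError("plausibility class set must be non-empty")
    labels = assignment.labels
    in_flagged = labels.isin(flagged_clusters)
    genes = labels.index
    ok = (
        in_flagged
        & discordant.reindex(genes).fillna(False).astype(bool)
        & concordance_pass.reindex(genes).fillna(False).astype(bool)
        & abundance_pass.reindex(genes).fillna(False).astype(bool)
        & classes.reindex(genes).isin(list(plausible))
    )
    candidates = genes[ok]
    counts = labels.loc[candidates].value_counts().reindex(
        assignment.centroids.index, fill_value=0)
    counts.name = "n_candidates"
    return candidates, counts


def build_divergence_table(d: pd.DataFrame,
                           groups: dict[str, pd.DataFrame],
                           discordant: pd.Series,
                           trend: pd.DataFrame,
                           concordance_count: pd.Series,
                           concordance_pass: pd.Series,
                           abundance_pass: pd.Series,
                           classes: pd.Series,
                           labels: pd.Series) -> pd.DataFrame:
    """Assemble the per-gene divergence table (one row per gene)."""
    out = pd.DataFrame(index=d.index)
    out["cluster"] = labels.reindex(d.index)
    for s in d.columns:
        out[f"high_{s}"] = groups["High"][s]
        out[f"low_{s}"] = groups["Low"][s]
        out[f"d_{s}"] = d[s]
    out["discordant"] = discordant
    for c in trend.columns:
        out[f"trend_{c}"] = trend[c]
    out["concordance_count"] = concordance_count
    out["concordance_pass"] = concordance_pass
    out["abundance_pass"] = abundance_pass.reindex(d.index)
    out["class"] = classes.reindex(d.index).fillna("other")
    return out
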