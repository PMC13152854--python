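"""Integrated evidence scoring and ranked candidate tables.

Every gene in a CR-divergent trajectory cluster that passes the basal
expression filter is eligible for ranking.  Five evidence components, each
in [0, 1], are combined by a weighted sum:

* ``div``       — peak stage divergence max_s |d_s|, rescaled by the 99th
                  percentile over eligible genes and capped at 1;
* ``hub``       — degree in the candidate network / max degree (0 when the
                  gene is not in the network);
* ``bridge``    — normalized betweenness centrality;
* ``support``   — cross-cultivar concordance count / number of cultivars;
* ``abundance`` — the basal abundance gate as 0/1.

The functional class gates candidacy upstream and labels the output but
does not enter the score (avoids double counting).  The weights are part
of the configuration and are echoed into the output header.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .qc import log2p1

DEFAULT_WEIGHTS = {
    "div": 0.4,
    "hub": 0.2,
    "bridge": 0.1,
    "support": 0.2,
    "abundance": 0.1,
}

COMPONENTS = tuple(DEFAULT_WEIGHTS)


def evidence_components(eligible: pd.Index, d: pd.DataFrame,
                        centrality: pd.DataFrame,
                        concordance_count: pd.Series, n_cultivars: int,
                        abundance_pass: pd.Series,
                        labels: pd.Series, classes: pd.Series) -> pd.DataFrame:
    """Per-gene evidence component table for the eligible genes.

    ``centrality`` is the degree/betweenness table of the candidate network;
    genes absent from it score 0 on hub and bridge but remain rankable.
    Also records the cluster, the stage of maximum |d_s| and the class.
    """
    if len(eligible) == 0:
        raise ValueError("no eligible genes")
    d_el = d.reindex(eligible)
    max_abs = d_el.abs().max(axis=1)
    p99 = float(np.percentile(max_abs.to_numpy(), 99))
    div = (max_abs / p99).clip(upper=1.0) if p99 > 0 else max_abs * 0.0

    degree = centrality["degree"].reindex(eligible).fillna(0.0) \
        if len(centrality) else pd.Series(0.0, index=eligible)
    max_deg = float(degree.max())
    hub = degree / max_deg if max_deg > 0 else degree * 0.0
    bridge = (centrality["betweenness"].reindex(eligible).fillna(0.0)
              if len(centrality) else pd.Series(0.0, index=eligible))

    support = concordance_count.reindex(eligible).fillna(0) / n_cultivars
    abundance = abundance_pass.reindex(eligible).fillna(False).astype(float)

    abs_vals = d_el.abs().to_numpy()
    peak_idx = np.argmax(abs_vals, axis=1)      # first max -> earliest stage
    peak_stage = [d_el.columns[i] for i in peak_idx]

    return pd.DataFrame({
        "cluster": labels.reindex(eligible),
        "peak_stage": peak_stage,
        "div": div.astype(float),
        "hub": hub.astype(float),
        "bridge": bridge.astype(float),
        "support": support.astype(float),
        "abundance": abundance,
        "class": classes.reindex(eligible).fillna("other"),
    }, index=eligible)


def priority_score(components: pd.DataFrame,
                   weights: dict[str, float] | None = None) -> pd.Series:
    """Weighted sum of the evidence components; weights must be
    non-negative and sum to 1 (tolerance 1e-9)."""
    w = dict(DEFAULT_WEIGHTS if weights is None else weights)
    if set(w) != set(COMPONENTS):
        raise ValueError(f"weights must cover exactly {COMPONENTS}")
    if any(v < 0 for v in w.values()):
        raise ValueError("weights must be non-negative")
    if abs(sum(w.values()) - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {sum(w.values())}")
    score = sum(w[c] * components[c] for c in COMPONENTS)
    return pd.Series(score, index=components.index, name="score")


def rank_candidates(components: pd.DataFrame, scores: pd.Series,
                    top_n: int = 20) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full table sorted by descending score (ties by gene id) with unique
    ranks, plus the annotated top-``top_n`` panel."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    table = components.copy()
    table["score"] = scores
    table = table.sort_values(["score"], ascending=False, kind="stable")
    # stable sort keeps the index order for ties; pre-sort index for
    # deterministic lexicographic tie-breaking
    table = table.loc[
        sorted(table.index, key=lambda g: (-table.at[g, "score"], g))]
    table["rank"] = np.arange(1, len(table) + 1)
    top = table.head(top_n)[["rank", "score", "cluster", "peak_stage", "class"]]
    return table, top


def stage_profiles_report(tpm_values: pd.DataFrame, design: pd.DataFrame,
                          genes: list[str] | pd.Index) -> pd.DataFrame:
    """Low/High group means +/- s.e.m. per stage on the log2(TPM+1) scale.

    The s.e.m. is sd(ddof=1)/sqrt(n) over the group's libraries at that
    stage (6 in the reference design); reported as missing when a group has
    fewer than 2 libraries.
    """
    logx = log2p1(tpm_values.loc[list(genes)])
    rows = []
    for (grp, stage), cell in design.groupby(["cr_group", "stage"],
                                             observed=True, sort=False):
        ids = list(cell["sample_id"])
        sub = logx[ids]
        mean = sub.mean(axis=1)
        if len(ids) >= 2:
            sem = sub.std(axis=1, ddof=1) / np.sqrt(len(ids))
        else:
            sem = pd.Series(np.nan, index=sub.index)
        for gene in sub.index:
            rows.append({"gene": gene, "cr_group": grp, "stage": stage,
                         "n_libraries": len(ids), "mean": float(mean[gene]),
                         "sem": float(sem[gene])})
    return pd.DataFrame(rows)
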