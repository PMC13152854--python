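"""Quality-control layer: expression filtering, log transform, replicate
means, sample-correlation structure, and a PCA summary.

The working scale throughout the package is log2(TPM+1); replicate means
can be taken on either the TPM or the log scale because different downstream
statistics require different scales (trajectory z-scores use TPM-scale
means, divergence contrasts use log-scale means).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix


@dataclass
class QCReport:
    n_genes_total: int
    n_genes_expressed: int
    within_group_correlation_range: tuple[float, float]
    pc_variance_fractions: list[float]


def filter_expressed(em: ExpressionMatrix, min_tpm: float = 1.0,
                     min_libraries: int = 3) -> ExpressionMatrix:
    """Keep genes with TPM >= ``min_tpm`` in at least ``min_libraries``
    libraries (boundary inclusive).  Idempotent; preserves gene order."""
    if min_libraries > em.n_samples:
        raise ValueError(
            f"min_libraries={min_libraries} exceeds sample count {em.n_samples}")
    n_expressed = (em.values >= min_tpm).sum(axis=1)
    keep = n_expressed >= min_libraries
    return ExpressionMatrix(em.values.loc[keep], em.design)


def log2p1(values: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2(x + 1); rejects negative input."""
    if (values.to_numpy() < 0).any():
        raise ValueError("log2p1 requires non-negative values")
    return np.log2(values + 1.0)


def replicate_means(values: pd.DataFrame, design: pd.DataFrame,
                    scale: str = "tpm") -> pd.DataFrame:
    """Mean over replicates per (cultivar, stage) cell.

    ``values`` must be a TPM matrix in design column order.  ``scale='tpm'``
    averages TPM directly; ``scale='log'`` averages log2(TPM+1).  Returns a
    gene x (cultivar, stage) matrix with a two-level column MultiIndex.
    """
    if scale not in ("tpm", "log"):
        raise ValueError(f"unknown scale {scale!r}")
    mat = log2p1(values) if scale == "log" else values
    cols = pd.MultiIndex.from_frame(design[["cultivar", "stage"]].astype(
        {"stage": object}))
    mat = mat.copy()
    mat.columns = cols
    out = mat.T.groupby(level=["cultivar", "stage"], sort=False).mean().T
    # keep design order of cells
    order = list(dict.fromkeys(zip(design["cultivar"], design["stage"])))
    return out.loc[:, order]


def sample_correlations(log_values: pd.DataFrame,
                        design: pd.DataFrame) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Sample-to-sample Pearson correlation matrix on log2(TPM+1).

    Returns the symmetric unit-diagonal matrix and the (min, max) of the
    mean within-(cultivar, stage)-group correlations, the replicate-
    concordance summary.  Rejects zero-variance samples.
    """
    if log_values.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    sds = log_values.std(axis=0, ddof=1)
    if (sds == 0).any():
        bad = sds.index[sds == 0][0]
        raise ValueError(f"zero-variance sample {bad!r}")
    corr = log_values.corr(method="pearson")
    group_means = []
    for _, cell in design.groupby(["cultivar", "stage"], observed=True):
        ids = list(cell["sample_id"])
        if len(ids) < 2:
            continue
        sub = corr.loc[ids, ids].to_numpy()
        iu = np.triu_indices(len(ids), k=1)
        group_means.append(float(sub[iu].mean()))
    rng = (min(group_means), max(group_means)) if group_means else (np.nan, np.nan)
    return corr, rng


def pca_variance(log_values: pd.DataFrame, design: pd.DataFrame,
                 n_top_genes: int = 2000,
                 n_components: int = 10) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on the most variable genes.

    Genes are ranked by variance of log2(TPM+1) and the top ``n_top_genes``
    retained; each gene is centred but not scaled.  Returns per-sample
    scores (samples x PCs, annotated with the design) and the variance
    fractions (non-increasing, summing to <= 1).
    """
    if n_top_genes < 2:
        raise ValueError("n_top_genes must be >= 2")
    if log_values.shape[0] < 2 or log_values.shape[1] < 3:
        raise ValueError("need at least 2 genes and 3 samples")
    variances = log_values.var(axis=1, ddof=1)
    top = variances.sort_values(ascending=False, kind="stable").index[:n_top_genes]
    X = log_values.loc[top].to_numpy().T          # samples x genes
    X = X - X.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    n_components = min(n_components, len(s))
    total_var = (X ** 2).sum()
    fractions = (s ** 2 / total_var)[:n_components]
    scores = pd.DataFrame(
        (u * s)[:, :n_components],
        index=log_values.columns,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    scores = pd.concat(
        [design.set_index("sample_id").loc[scores.index], scores], axis=1)
    return scores, fractions


def qc_report(em: ExpressionMatrix, min_tpm: float = 1.0, min_libraries: int = 3,
              n_top_genes: int = 2000) -> tuple[QCReport, pd.DataFrame, pd.DataFrame]:
    """Run the full QC layer; returns the report, the correlation matrix and
    the PCA score table."""
    expressed = filter_expressed(em, min_tpm=min_tpm, min_libraries=min_libraries)
    logx = log2p1(expressed.values)
    corr, within = sample_correlations(logx, em.design)
    scores, fractions = pca_variance(logx, em.design, n_top_genes=n_top_genes)
    report = QCReport(
        n_genes_total=em.n_genes,
        n_genes_expressed=expressed.n_genes,
        within_group_correlation_range=within,
        pc_variance_fractions=[float(f) for f in fractions],
    )
    return report, corr, scores
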