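"""Intra-cultivar standardized temporal profiles and trajectory modules.

Each gene's stage trajectory is z-scored within every cultivar, removing
baseline expression differences between genotypes so that clustering groups
genes by the direction and timing of change rather than by expression level.
The standardized profiles (one block of stages per cultivar, concatenated)
are partitioned with k-means into k trajectory modules, labelled C1..Ck in
decreasing size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .io import cr_group_of_cultivar


@dataclass
class TrajectoryMatrix:
    """Gene x (cultivar, stage) z-scores plus a per-gene validity flag.

    Genes with zero stage variance in any cultivar are flagged invalid (z
    undefined there) and excluded from clustering; their rows are NaN.
    """

    z: pd.DataFrame
    valid: pd.Series

    @property
    def valid_z(self) -> pd.DataFrame:
        return self.z.loc[self.valid]


@dataclass
class ClusterAssignment:
    labels: pd.Series            # valid gene -> "C1".."Ck"
    k: int
    seed: int
    centroids: pd.DataFrame      # cluster x (cultivar, stage)
    inertia: float

    def genes_in(self, cluster: str) -> pd.Index:
        return self.labels.index[self.labels == cluster]

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index(
            key=lambda idx: idx.str.removeprefix("C").astype(int))


def zscore_trajectories(mean_matrix: pd.DataFrame) -> TrajectoryMatrix:
    """Z-score each gene's stage profile within each cultivar block.

    ``mean_matrix`` is a gene x (cultivar, stage) replicate-mean matrix
    (columns: two-level MultiIndex).  Uses sd with denominator n-1.  The
    result is invariant to any positive affine rescaling applied per
    cultivar block of the input.
    """
    cultivars = list(dict.fromkeys(mean_matrix.columns.get_level_values(0)))
    n_stages = len(mean_matrix.columns) // len(cultivars)
    if n_stages < 2:
        raise ValueError("need at least 2 stages per cultivar")
    z = mean_matrix.astype(float).copy()
    valid = pd.Series(True, index=mean_matrix.index)
    for c in cultivars:
        block = mean_matrix[c].to_numpy(dtype=float)
        mu = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, ddof=1, keepdims=True)
        flat = sd[:, 0] == 0
        valid &= ~pd.Series(flat, index=mean_matrix.index)
        with np.errstate(invalid="ignore", divide="ignore"):
            zb = (block - mu) / sd
        zb[flat] = np.nan
        z.loc[:, pd.IndexSlice[c, :]] = zb
    return TrajectoryMatrix(z=z, valid=valid)


def cluster_kmeans(traj: TrajectoryMatrix, k: int = 8, seed: int = 0,
                   n_restarts: int = 10) -> ClusterAssignment:
    """Lloyd's k-means with k-means++ initialization, best of ``n_restarts``
    by within-cluster sum of squares; deterministic given ``seed``.

    Clusters are relabelled C1..Ck in decreasing size (ties broken by the
    internal label for determinism).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    X = traj.valid_z
    if X.shape[0] < k:
        raise ValueError(f"only {X.shape[0]} valid genes for k={k}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts,
                random_state=seed, algorithm="lloyd")
    raw = km.fit_predict(X.to_numpy())
    sizes = np.bincount(raw, minlength=k)
    order = sorted(range(k), key=lambda j: (-sizes[j], j))
    rename = {old: f"C{rank + 1}" for rank, old in enumerate(order)}
    labels = pd.Series([rename[r] for r in raw], index=X.index, name="cluster")
    centroids = pd.DataFrame(km.cluster_centers_[order],
                             index=[f"C{i + 1}" for i in range(k)],
                             columns=X.columns)
    return ClusterAssignment(labels=labels, k=k, seed=seed,
                             centroids=centroids, inertia=float(km.inertia_))


def cluster_group_profiles(assignment: ClusterAssignment, traj: TrajectoryMatrix,
                           design: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster mean z-profile over stages for each CR group.

    For each cluster and stage, averages the z-scores over the cluster's
    genes and the cultivars of each CR group.  Indexed by (cluster,
    cr_group), columns are stages.
    """
    group_of = cr_group_of_cultivar(design)
    stages = list(design["stage"].cat.categories)
    rows = {}
    for cluster in assignment.centroids.index:
        genes = assignment.genes_in(cluster)
        if len(genes) == 0:
            raise ValueError(f"cluster {cluster} is empty")
        zsub = traj.z.loc[genes]
        for grp in ("Low", "High"):
            cultivars = [c for c in group_of.index if group_of[c] == grp]
            if not cultivars:
                continue
            prof = np.zeros(len(stages))
            for si, s in enumerate(stages):
                cells = zsub.loc[:, [(c, s) for c in cultivars]]
                prof[si] = float(cells.to_numpy().mean())
            rows[(cluster, grp)] = prof
    out = pd.DataFrame.from_dict(rows, orient="index", columns=stages)
    out.index = pd.MultiIndex.from_tuples(out.index, names=["cluster", "cr_group"])
    return out


def flag_cr_divergent_clusters(assignment: ClusterAssignment,
                               discordant: pd.Series,
                               tau_discordant: float = 0.5
                               ) -> tuple[set[str], pd.DataFrame]:
    """Flag clusters whose fraction of directionally discordant genes is at
    least ``tau_discordant`` (boundary inclusive; tau=0 flags everything).

    Returns the flagged cluster ids and a per-cluster summary table
    (n_genes, n_discordant, fraction, flagged).
    """
    if len(assignment.labels) == 0:
        raise ValueError("empty cluster assignment")
    rows = []
    for cluster in assignment.centroids.index:
        genes = assignment.genes_in(cluster)
        n = len(genes)
        n_disc = int(discordant.reindex(genes).fillna(False).sum())
        frac = n_disc / n if n else 0.0
        rows.append({"cluster": cluster, "n_genes": n, "n_discordant": n_disc,
                     "fraction_discordant": frac,
                     "flagged": bool(n > 0 and frac >= tau_discordant)})
    table = pd.DataFrame(rows).set_index("cluster")
    flagged = set(table.index[table["flagged"]])
    return flagged, table
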