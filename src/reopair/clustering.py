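"""Sample clustering on a pyroptosis gene panel and survival separation.

Samples are clustered by Ward-linkage agglomerative clustering on
Euclidean distance over per-gene z-scored log2(TPM+1) panel rows — the
conventional heatmap-clustering setup — and the resulting groups are
compared by a two-sample log-rank test. Cluster labels are made
deterministic by calling the larger cluster "1".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines.statistics import multivariate_logrank_test
from scipy.cluster.hierarchy import fcluster, linkage

from .containers import ExpressionMatrix, ReopairError, SurvivalTable


@dataclass
class PanelClustering:
    """Ward clustering of samples over a gene panel."""

    panel_ids: list
    labels: pd.Series            # per-sample cluster label, 1 = larger cluster
    linkage: np.ndarray          # scipy condensed linkage matrix
    k: int


def ward_cluster(expr: ExpressionMatrix, panel_ids: Sequence[str], k: int = 2) -> PanelClustering:
    """Cluster samples by Ward linkage on z-scored log2 panel expression.

    Panel genes missing from the matrix are dropped with a warning, as are
    zero-variance genes (which carry no clustering information and would
    break z-scoring). Labels are renumbered by decreasing cluster size so
    that label 1 is always the larger cluster.
    """
    if k < 2:
        raise ReopairError("k must be at least 2")
    if expr.values.shape[1] < k:
        raise ReopairError(f"fewer than k={k} samples to cluster")
    panel_ids = list(panel_ids)
    present = [g for g in panel_ids if g in expr.values.index]
    missing = sorted(set(panel_ids) - set(present))
    if missing:
        warnings.warn(f"panel genes missing from expression matrix, dropped: {missing}")
    if not present:
        raise ReopairError("no panel genes present in the expression matrix")
    mat = expr.subset_transcripts(present).log2p1().values
    sd = mat.std(axis=1, ddof=1)
    zero_var = sd.index[sd == 0]
    if len(zero_var):
        warnings.warn(f"zero-variance panel genes excluded from z-scoring: {zero_var.tolist()}")
        mat = mat.drop(index=zero_var)
        sd = sd.drop(index=zero_var)
    if mat.shape[0] == 0:
        raise ReopairError("no informative panel genes after variance filtering")
    z = mat.sub(mat.mean(axis=1), axis=0).div(sd, axis=0)
    # samples as observations (columns -> rows)
    link = linkage(z.to_numpy().T, method="ward", metric="euclidean")
    raw = fcluster(link, t=k, criterion="maxclust")
    # relabel by decreasing size (ties broken by raw label for determinism)
    sizes = pd.Series(raw).value_counts()
    order = sorted(sizes.index, key=lambda lab: (-sizes[lab], lab))
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = pd.Series([remap[v] for v in raw], index=expr.values.columns, name="cluster")
    return PanelClustering(present, labels, link, k)


def cluster_logrank(clustering: PanelClustering, surv: SurvivalTable) -> dict:
    """Log-rank test of survival separation between the clusters.

    Returns ``{'statistic', 'p', 'df'}``; for two clusters this is the
    standard two-sample log-rank chi-square with 1 degree of freedom.
    """
    ids = [s for s in clustering.labels.index if s in surv.data.index]
    if not ids:
        raise ReopairError("no overlap between clustered samples and survival table")
    labels = clustering.labels.loc[ids]
    time, event = surv.times_events(ids)
    for lab in np.unique(labels):
        if event[labels.to_numpy() == lab].sum() == 0:
            warnings.warn(f"cluster {lab} has zero events; log-rank p may be unstable")
    res = multivariate_logrank_test(time, labels.to_numpy(), event)
    return {
        "statistic": float(res.test_statistic),
        "p": float(res.p_value),
        "df": int(res.degrees_of_freedom) if hasattr(res, "degrees_of_freedom") else len(np.unique(labels)) - 1,
    }
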