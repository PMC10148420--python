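"""Moderated two-group differential expression of lncRNAs.

A limma-style empirical-Bayes moderated t-test on log2(TPM+1): per-gene
two-group linear models whose residual variances are shrunk toward a
common prior estimated by moment matching on the log sample variances.
If s2_g ~ s2_true_g * chi2_d / d and 1/s2_true_g is scaled chi-square with
d0 degrees of freedom, then z_g = log(s2_g) satisfies

    Var(z) = trigamma(d/2) + trigamma(d0/2)
    E(z)   = log(s0^2) + digamma(d/2) - log(d/2) - digamma(d0/2) + log(d0/2)

so d0 and the prior variance s0^2 follow from the observed mean and
variance of z. The moderated statistic replaces s2_g by
(d0 s0^2 + d s2_g) / (d0 + d) and gains d0 extra degrees of freedom.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, ReopairError


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (x > 0); returns inf for x <= 0."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    # Newton iteration as used for this inversion in practice
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _fit_variance_prior(s2: np.ndarray, d: float) -> tuple[float, float]:
    """Moment-match (prior df d0, prior variance s0^2) from sample variances."""
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e_z = z.mean()
    v_z = z.var(ddof=1)
    resid_var = v_z - special.polygamma(1, d / 2.0)
    if resid_var <= 0:
        d0 = np.inf
        log_s0 = e_z - special.polygamma(0, d / 2.0) + np.log(d / 2.0)
    else:
        d0 = 2.0 * _trigamma_inverse(resid_var)
        log_s0 = (e_z - special.polygamma(0, d / 2.0) + np.log(d / 2.0)
                  + special.polygamma(0, d0 / 2.0) - np.log(d0 / 2.0))
    return d0, float(np.exp(log_s0))


def moderated_de(
    expr: ExpressionMatrix,
    labels: pd.Series,
    prior_df: Optional[float] = None,
) -> pd.DataFrame:
    """Moderated-t differential expression between two sample groups.

    Parameters
    ----------
    expr
        Expression matrix; log2(TPM+1) is applied if not already on that scale.
    labels
        Per-sample group label with exactly two levels; the contrast is
        group 1 minus group 2 where the levels are sorted ascending (with
        cluster labels from :func:`~reopair.clustering.ward_cluster`, the
        larger cluster minus the smaller).
    prior_df
        Override the estimated prior degrees of freedom. ``0`` disables
        shrinkage (ordinary per-gene pooled-variance t); ``numpy.inf``
        collapses every gene's variance to the common prior.

    Returns a DataFrame indexed by transcript id with columns
    ``log2FC``, ``t``, ``p``, ``fdr``.
    """
    mat = expr.log2p1().values
    labels = labels.reindex(mat.columns)
    if labels.isna().any():
        raise ReopairError("labels missing for some samples")
    levels = sorted(labels.unique())
    if len(levels) != 2:
        raise ReopairError(f"expected exactly two groups, got {levels}")
    g1 = mat.columns[labels == levels[0]]
    g2 = mat.columns[labels == levels[1]]
    n1, n2 = len(g1), len(g2)
    if n1 < 2 or n2 < 2:
        raise ReopairError("each group needs at least 2 samples")

    x1 = mat[g1].to_numpy()
    x2 = mat[g2].to_numpy()
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    lfc = m1 - m2
    d = n1 + n2 - 2
    ss = x1.var(axis=1, ddof=1) * (n1 - 1) + x2.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / d
    if prior_df is None:
        d0, s02 = _fit_variance_prior(s2, d)
    else:
        d0 = float(prior_df)
        _, s02 = _fit_variance_prior(s2, d)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2
        df_total = d
    else:
        s2_post = (d0 * s02 + d * s2) / (d0 + d)
        df_total = d0 + d
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame(
        {"log2FC": lfc, "t": t, "p": p, "fdr": fdr},
        index=mat.index,
    ).assign(prior_df=d0, prior_var=s02)


def select_prlncrnas(
    de: pd.DataFrame,
    lfc_min: float = 1.0,
    fdr_max: float = 0.05,
) -> list:
    """Select differentially expressed lncRNAs at |log2FC| > lfc_min and FDR < fdr_max.

    Both inequalities are strict, so a gene at exactly the fold-change
    threshold is excluded. Returns the selected ids in the table's order;
    warns if the selection is empty.
    """
    mask = (de["log2FC"].abs() > lfc_min) & (de["fdr"] < fdr_max)
    ids = de.index[mask].tolist()
    if not ids:
        warnings.warn("no lncRNAs pass the differential-expression thresholds")
    return ids
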