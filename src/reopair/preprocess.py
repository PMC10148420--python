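"""Cohort and expression preprocessing.

Reproduces the standard preparation of a bulk RNA-seq survival cohort:
drop samples with under 30 days of follow-up or missing survival,
length-normalise counts to TPM, drop transcripts below detection in every
sample (count < 1 for mRNAs, < 0.5 for lncRNAs), filter and RPM-normalise
miRNA counts, and split the cohort into training and validation arms with a
covariate-balance report.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    CohortSplit,
    EmptyCohortError,
    ExpressionMatrix,
    ReopairError,
    SurvivalTable,
)

MIN_FOLLOWUP_DAYS = 30.0


def filter_samples(surv: SurvivalTable, min_days: float = MIN_FOLLOWUP_DAYS) -> SurvivalTable:
    """Drop samples with missing survival or follow-up under ``min_days``.

    Samples with exactly ``min_days`` of follow-up are retained (the removal
    rule is strictly "less than"). Order is preserved. Raises
    :class:`EmptyCohortError` if nothing survives.
    """
    df = surv.data
    keep = df["os_days"].notna() & (df["os_days"] >= min_days)
    if not keep.any():
        raise EmptyCohortError(
            f"no samples with known survival of at least {min_days} days"
        )
    return SurvivalTable(df.loc[keep])


def tpm_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Length-normalise raw counts to transcripts per million.

    TPM_g = (count_g / length_g) / sum_h (count_h / length_h) * 1e6 per
    sample, with lengths in kilobases. Requires ``scale='counts'`` and
    per-transcript lengths.
    """
    if expr.scale != "counts":
        raise ReopairError(f"tpm_normalize requires counts, got scale={expr.scale!r}")
    if expr.lengths_kb is None:
        raise ReopairError("tpm_normalize requires per-transcript effective lengths")
    lengths = expr.lengths_kb
    bad = lengths.index[lengths.isna() | (lengths <= 0)]
    if len(bad):
        raise ReopairError(f"missing or non-positive length for transcripts: {bad.tolist()[:5]}")
    rates = expr.values.div(lengths, axis=0)
    totals = rates.sum(axis=0)
    zero = totals.index[totals <= 0]
    if len(zero):
        raise ReopairError(f"zero total length-normalised rate in samples: {zero.tolist()[:5]}")
    tpm = rates.div(totals, axis=1) * 1e6
    return ExpressionMatrix(tpm, expr.biotype, "TPM", expr.lengths_kb)


def filter_low_expression(expr_counts: ExpressionMatrix) -> pd.Index:
    """Return transcript ids passing the detection floor.

    An mRNA is excluded iff its count is below 1 in *every* sample; a lncRNA
    iff below 0.5 in every sample (one sample at or above the threshold
    rescues the transcript). Other biotypes are kept unconditionally.
    """
    if expr_counts.scale != "counts":
        raise ReopairError("filter_low_expression operates on raw counts")
    values = expr_counts.values
    bt = expr_counts.biotype
    threshold = pd.Series(np.nan, index=values.index)
    threshold[bt == "mRNA"] = 1.0
    threshold[bt == "lncRNA"] = 0.5
    max_count = values.max(axis=1)
    drop = threshold.notna() & (max_count < threshold)
    return values.index[~drop]


def preprocess_mirna(mirna_counts: ExpressionMatrix, max_zero_frac: float = 0.5) -> ExpressionMatrix:
    """Filter sparse miRNAs and normalise to reads per million.

    Drops miRNAs with a zero count in strictly more than ``max_zero_frac``
    of samples (exactly 50% zeros is retained), then scales each sample to
    RPM over the retained miRNAs.
    """
    if mirna_counts.scale != "counts":
        raise ReopairError("preprocess_mirna operates on raw counts")
    values = mirna_counts.values
    zero_frac = (values == 0).mean(axis=1)
    keep = values.index[zero_frac <= max_zero_frac]
    if len(keep) == 0:
        raise ReopairError("all miRNAs removed by the zero-fraction filter")
    kept = values.loc[keep]
    totals = kept.sum(axis=0)
    zero = totals.index[totals <= 0]
    if len(zero):
        raise ReopairError(f"zero total miRNA count in samples: {zero.tolist()[:5]}")
    rpm = kept.div(totals, axis=1) * 1e6
    return ExpressionMatrix(rpm, mirna_counts.biotype.loc[keep], "RPM")


def _balance_report(df: pd.DataFrame, in_train: pd.Series) -> pd.DataFrame:
    """Per-covariate two-arm balance test: rank-sum for numeric columns,
    chi-square for categorical. Degenerate covariates are flagged, not failed."""
    rows = []
    for col in df.columns:
        if col in ("os_days", "event"):
            continue
        x = df[col]
        a, b = x[in_train], x[~in_train]
        if x.nunique(dropna=True) < 2:
            rows.append({"covariate": col, "test": "degenerate", "p": np.nan,
                         "note": "constant across cohort"})
            continue
        if pd.api.types.is_numeric_dtype(x):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                stat, p = stats.mannwhitneyu(a.dropna(), b.dropna())
            rows.append({"covariate": col, "test": "rank-sum", "p": p, "note": ""})
        else:
            tab = pd.crosstab(in_train, x)
            if tab.shape[1] < 2 or (tab.sum(axis=0) == 0).any():
                rows.append({"covariate": col, "test": "degenerate", "p": np.nan,
                             "note": "insufficient categories"})
                continue
            _, p, _, _ = stats.chi2_contingency(tab)
            rows.append({"covariate": col, "test": "chi-square", "p": p, "note": ""})
    return pd.DataFrame(rows)


def split_cohort(
    surv: SurvivalTable,
    train_fraction: float,
    seed: int,
) -> tuple[CohortSplit, pd.DataFrame]:
    """Seeded random train/validation partition plus a balance report.

    ``|train| = round(train_fraction * n)``; e.g. 343 samples at
    ``train_fraction = 240/343`` gives arms of 240 and 103. Returns the
    split and a per-covariate balance table (rank-sum / chi-square p-values
    between arms).
    """
    if not (0.0 < train_fraction < 1.0):
        raise ReopairError("train_fraction must lie in (0, 1)")
    ids = np.asarray(surv.sample_ids)
    n_train = int(round(train_fraction * len(ids)))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    train = set(ids[perm[:n_train]])
    train_ids = [i for i in ids if i in train]             # preserve cohort order
    valid_ids = [i for i in ids if i not in train]
    split = CohortSplit(train_ids, valid_ids, seed)
    in_train = pd.Series(surv.data.index.isin(train), index=surv.data.index)
    report = _balance_report(surv.data, in_train)
    return split, report
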