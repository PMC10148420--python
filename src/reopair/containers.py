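"""Core data containers shared across the pipeline.

Expression is carried as a transcripts x samples :class:`pandas.DataFrame`
annotated with per-transcript biotypes and an explicit abundance scale, so
that scale-sensitive operations (TPM normalisation, log transforms) can
refuse inputs on the wrong scale instead of silently producing nonsense.
Survival data is a per-sample table of overall-survival time in days, an
event indicator and optional clinical covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

VALID_SCALES = ("counts", "TPM", "RPM", "log2p1")
VALID_BIOTYPES = ("lncRNA", "mRNA", "miRNA", "other")

#: days per year used for all survival horizons
DAYS_PER_YEAR = 365.25


class ReopairError(ValueError):
    """Base class for user-facing errors raised by this package."""


class EmptyCohortError(ReopairError):
    """A filter removed every sample."""


@dataclass
class ExpressionMatrix:
    """Transcripts x samples abundance matrix with biotype annotation.

    Parameters
    ----------
    values
        Non-negative abundances; index = transcript ids, columns = sample ids.
        For ``scale='log2p1'`` the values are log2(x+1) of a non-negative
        quantity and hence still >= 0.
    biotype
        Per-transcript label, one of ``lncRNA``, ``mRNA``, ``miRNA``, ``other``.
    scale
        One of ``counts``, ``TPM``, ``RPM``, ``log2p1``.
    lengths_kb
        Optional per-transcript effective length in kilobases; required by
        TPM normalisation when ``scale='counts'``.
    """

    values: pd.DataFrame
    biotype: pd.Series
    scale: str = "counts"
    lengths_kb: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if self.scale not in VALID_SCALES:
            raise ReopairError(
                f"unknown expression scale {self.scale!r}; expected one of {VALID_SCALES}"
            )
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ReopairError(f"duplicated transcript ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            raise ReopairError("duplicated sample ids in expression matrix")
        self.biotype = self.biotype.reindex(self.values.index)
        if self.biotype.isna().any():
            missing = self.biotype.index[self.biotype.isna()].tolist()
            raise ReopairError(f"missing biotype for transcripts: {missing[:5]}")
        bad = set(self.biotype.unique()) - set(VALID_BIOTYPES)
        if bad:
            raise ReopairError(f"unknown biotypes: {sorted(bad)}")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise ReopairError("expression values must be finite")
        if (arr < 0).any():
            raise ReopairError("expression values must be non-negative")
        if self.lengths_kb is not None:
            self.lengths_kb = self.lengths_kb.reindex(self.values.index)

    # -- convenience accessors -------------------------------------------------

    @property
    def transcript_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def subset_transcripts(self, ids: Iterable[str]) -> "ExpressionMatrix":
        ids = pd.Index(ids)
        missing = ids.difference(self.values.index)
        if len(missing):
            raise ReopairError(f"transcripts not in matrix: {missing.tolist()[:5]}")
        return ExpressionMatrix(
            self.values.loc[ids],
            self.biotype.loc[ids],
            self.scale,
            None if self.lengths_kb is None else self.lengths_kb.loc[ids],
        )

    def subset_samples(self, ids: Iterable[str]) -> "ExpressionMatrix":
        ids = pd.Index(ids)
        missing = ids.difference(self.values.columns)
        if len(missing):
            raise ReopairError(f"samples not in matrix: {missing.tolist()[:5]}")
        return ExpressionMatrix(self.values[ids], self.biotype, self.scale, self.lengths_kb)

    def by_biotype(self, biotype: str) -> "ExpressionMatrix":
        keep = self.biotype.index[self.biotype == biotype]
        return self.subset_transcripts(keep)

    def log2p1(self) -> "ExpressionMatrix":
        """Return log2(x+1)-transformed copy (identity if already log2p1)."""
        if self.scale == "log2p1":
            return self
        return ExpressionMatrix(
            np.log2(self.values + 1.0), self.biotype, "log2p1", self.lengths_kb
        )

    # -- I/O -------------------------------------------------------------------

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="transcript_id")

    @classmethod
    def from_tsv(
        cls,
        path,
        biotype_map: pd.Series | dict,
        scale: str = "counts",
        lengths_kb: Optional[pd.Series] = None,
    ) -> "ExpressionMatrix":
        """Read a TSV/CSV with transcript ids in the first column.

        ``biotype_map`` maps transcript id -> biotype (e.g. read from a
        two-column TSV replacing GENCODE annotation).
        """
        sep = "," if str(path).endswith(".csv") else "\t"
        values = pd.read_csv(path, sep=sep, index_col=0)
        biotype = pd.Series(biotype_map)
        return cls(values, biotype, scale, lengths_kb)


@dataclass
class SurvivalTable:
    """Per-sample overall survival with optional clinical covariates.

    ``data`` is indexed by sample id and must contain columns ``os_days``
    (non-negative, possibly missing) and ``event`` (0/1 whenever ``os_days``
    is present). Optional clinical columns: ``age``, ``gender``, ``stage``,
    ``grade``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ReopairError("duplicated sample ids in survival table")
        for col in ("os_days", "event"):
            if col not in self.data.columns:
                raise ReopairError(f"survival table missing required column {col!r}")
        present = self.data["os_days"].notna()
        ev = self.data.loc[present, "event"]
        if not ev.isin([0, 1]).all():
            raise ReopairError("event indicator must be 0 or 1 where os_days is present")
        if (self.data.loc[present, "os_days"] < 0).any():
            raise ReopairError("os_days must be non-negative")

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    def subset(self, ids: Iterable[str]) -> "SurvivalTable":
        ids = pd.Index(ids)
        missing = ids.difference(self.data.index)
        if len(missing):
            raise ReopairError(f"samples not in survival table: {missing.tolist()[:5]}")
        return SurvivalTable(self.data.loc[ids])

    def times_events(self, ids: Optional[Iterable[str]] = None):
        """Return (time, event) float arrays, optionally for a sample subset."""
        df = self.data if ids is None else self.data.loc[pd.Index(ids)]
        return df["os_days"].to_numpy(float), df["event"].to_numpy(float)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path) -> "SurvivalTable":
        sep = "," if str(path).endswith(".csv") else "\t"
        return cls(pd.read_csv(path, sep=sep, index_col="sample_id"))


@dataclass
class CohortSplit:
    """Disjoint train / validation sample-id partition."""

    train_ids: list = field(default_factory=list)
    validation_ids: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.validation_ids)
        if overlap:
            raise ReopairError(f"train/validation overlap: {sorted(overlap)[:5]}")
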