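"""Within-sample relative expression orderings (REOs) of lncRNA pairs.

The core screen: every unordered pair of candidate lncRNAs defines a binary
within-sample feature X[i, j] = 1 iff the first member's abundance is
strictly below the second's in sample j (ties count as ">=", state 0).
Because only the ordering matters, X is invariant to any strictly monotone
per-sample transform of the expression values — the property that makes
pair signatures portable across normalisations and platforms.

Pairs whose "1" state is rare (< 20%) or near-universal (> 80%) across
samples are uninformative for stratification and are removed; the
survivors are screened one at a time by univariate Cox regression of
overall survival on the binary state, keeping pairs with Wald p < 0.005.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, ReopairError, SurvivalTable
from .coxph import cox_screen_binary


@dataclass(frozen=True, order=True)
class LncPair:
    """An unordered lncRNA pair in canonical (lexicographic) orientation."""

    a_id: str
    b_id: str

    def __post_init__(self) -> None:
        if self.a_id == self.b_id:
            raise ReopairError(f"pair members must differ: {self.a_id}")
        if self.a_id > self.b_id:
            raise ReopairError(
                f"pair not in canonical orientation: ({self.a_id}, {self.b_id}); "
                "use LncPair.make()"
            )

    @classmethod
    def make(cls, x: str, y: str) -> "LncPair":
        """Construct in canonical orientation regardless of argument order."""
        return cls(min(x, y), max(x, y))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.a_id}|{self.b_id}"


@dataclass
class REOMatrix:
    """Binary pairs x samples ordering matrix."""

    pairs: list                 # list[LncPair], row order
    X: np.ndarray               # (n_pairs, n_samples) uint8
    sample_ids: list

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.uint8)
        if self.X.shape != (len(self.pairs), len(self.sample_ids)):
            raise ReopairError("REO matrix shape does not match pairs/samples")
        if not np.isin(self.X, (0, 1)).all():
            raise ReopairError("REO matrix must be binary")

    @property
    def prevalence(self) -> np.ndarray:
        """Fraction of samples in state 1, per pair."""
        return self.X.mean(axis=1)

    def subset_pairs(self, keep: Sequence[int]) -> "REOMatrix":
        keep = list(keep)
        return REOMatrix([self.pairs[i] for i in keep], self.X[keep], self.sample_ids)

    def subset_samples(self, ids: Sequence[str]) -> "REOMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise ReopairError(f"samples not in REO matrix: {missing[:5]}")
        cols = [pos[s] for s in ids]
        return REOMatrix(self.pairs, self.X[:, cols], list(ids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=[str(p) for p in self.pairs],
                            columns=self.sample_ids)


def enumerate_pairs(lnc_ids: Sequence[str]) -> list:
    """All C(k, 2) unordered pairs in deterministic lexicographic order."""
    lnc_ids = list(lnc_ids)
    ids = sorted(set(lnc_ids))
    if len(ids) < len(lnc_ids):
        raise ReopairError("duplicate lncRNA ids in pair enumeration")
    if len(ids) < 2:
        raise ReopairError("need at least 2 lncRNAs to form pairs")
    return [LncPair(a, b) for a, b in combinations(ids, 2)]


def reo_states(expr: ExpressionMatrix, a_ids: Sequence[str], b_ids: Sequence[str]) -> np.ndarray:
    """Binary ordering states for explicitly oriented (a, b) pairs.

    Row i is 1 in sample j iff expr[a_ids[i], j] < expr[b_ids[i], j]
    (ties -> 0). Used both for canonical pair matrices and for scoring a
    model whose stored orientation differs from the canonical one.
    """
    idx = expr.values.index
    missing = [g for g in {*a_ids, *b_ids} if g not in idx]
    if missing:
        raise ReopairError(f"lncRNAs missing from expression matrix: {sorted(missing)[:10]}")
    va = expr.values.loc[list(a_ids)].to_numpy()
    vb = expr.values.loc[list(b_ids)].to_numpy()
    return (va < vb).astype(np.uint8)


def build_reo_matrix(expr: ExpressionMatrix, pairs: Sequence[LncPair]) -> REOMatrix:
    """Materialise the binary REO matrix for canonical pairs."""
    pairs = list(pairs)
    X = reo_states(expr, [p.a_id for p in pairs], [p.b_id for p in pairs])
    return REOMatrix(pairs, X, list(expr.values.columns))


def prevalence_filter(reo: REOMatrix, low: float = 0.20, high: float = 0.80) -> REOMatrix:
    """Drop pairs whose state-1 prevalence is < low or > high (boundaries kept)."""
    if not (0.0 <= low < high <= 1.0):
        raise ReopairError("need 0 <= low < high <= 1")
    prev = reo.prevalence
    keep = np.nonzero((prev >= low) & (prev <= high))[0]
    if keep.size == 0:
        warnings.warn("prevalence filter removed every pair")
    return reo.subset_pairs(keep)


def univariate_cox_screen(
    reo: REOMatrix,
    surv: SurvivalTable,
    alpha: float = 0.005,
    low: float = 0.20,
    high: float = 0.80,
) -> pd.DataFrame:
    """Prevalence filter plus per-pair univariate Cox screen.

    Fits a Cox model with the single binary covariate X per pair (Breslow
    ties) and keeps pairs with Wald p < ``alpha``. Pairs failing the
    prevalence window are not fitted; pairs whose fit does not converge
    (e.g. complete separation) are flagged and not kept, and the screen
    continues.

    Returns a DataFrame with one row per input pair: ``pair``, ``a_id``,
    ``b_id``, ``prevalence``, ``beta``, ``hr``, ``z``, ``p``,
    ``kept_after_prevalence``, ``kept_after_cox``.
    """
    time, event = surv.times_events(reo.sample_ids)
    if np.isnan(time).any():
        raise ReopairError("survival times missing for some samples; filter first")
    if event.sum() == 0:
        raise ReopairError("no events in survival data")
    prev = reo.prevalence
    kept_prev = (prev >= low) & (prev <= high)
    out = pd.DataFrame({
        "pair": [str(p) for p in reo.pairs],
        "a_id": [p.a_id for p in reo.pairs],
        "b_id": [p.b_id for p in reo.pairs],
        "prevalence": prev,
        "beta": np.nan,
        "hr": np.nan,
        "z": np.nan,
        "p": np.nan,
        "kept_after_prevalence": kept_prev,
        "kept_after_cox": False,
    })
    idx = np.nonzero(kept_prev)[0]
    if idx.size:
        fits = cox_screen_binary(reo.X[idx], time, event)
        out.loc[idx, ["beta", "hr", "z", "p"]] = fits[["beta", "hr", "z", "p"]].to_numpy()
        out["converged"] = True
        out.loc[idx, "converged"] = fits["converged"].to_numpy()
        out.loc[idx, "kept_after_cox"] = (
            fits["converged"].to_numpy() & (fits["p"].to_numpy() < alpha)
        )
    else:
        out["converged"] = True
    return out
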