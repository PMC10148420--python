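"""Downstream analyses: set-overlap enrichment and ceRNA axis assembly.

The overlap test asks whether two sample (or gene) sets drawn from a
common population of size N share more members than chance: the upper-tail
hypergeometric probability P(X >= k) of observing at least the seen
overlap. The ceRNA (competing endogenous RNA) assembly threads
lncRNA -> miRNA -> mRNA paths through user-supplied interaction edge
tables (e.g. miRNet and TargetScan exports), keeping only paths whose
miRNA and mRNA are themselves prognostic by univariate Cox regression on
their log2 expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, ReopairError, SurvivalTable
from .coxph import ConvergenceError, cox_fit
from .risk_model import RiskModel


@dataclass
class OverlapTest:
    """Upper-tail hypergeometric overlap between two subsets of a population."""

    N: int      # population size
    K: int      # size of set A
    n: int      # size of set B
    k: int      # observed overlap
    p_upper: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (f"overlap {self.k} of |A|={self.K}, |B|={self.n} in N={self.N}: "
                f"P(X >= {self.k}) = {self.p_upper:.3g}")


def hypergeometric_overlap(N: int, K: int, n: int, k: int) -> OverlapTest:
    """Exact upper-tail hypergeometric probability of an overlap of at least k.

    X counts the overlap when a set of size n is drawn without replacement
    from a population of N containing K marked members;
    ``p_upper = P(X >= k)``.
    """
    for name, v in (("N", N), ("K", K), ("n", n), ("k", k)):
        if int(v) != v or v < 0:
            raise ReopairError(f"{name} must be a non-negative integer")
    if K > N or n > N:
        raise ReopairError("set sizes cannot exceed the population size")
    lo, hi = max(0, n + K - N), min(n, K)
    if not (lo <= k <= hi):
        raise ReopairError(f"overlap k={k} outside the feasible range [{lo}, {hi}]")
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return OverlapTest(int(N), int(K), int(n), int(k), min(p, 1.0))


@dataclass
class CeRNAAxis:
    """One lncRNA - miRNA - mRNA competing-endogenous-RNA path."""

    lncrna: str
    mirna: str
    mrna: str
    p_mirna: float
    p_mrna: float


def _read_edges(edges) -> pd.DataFrame:
    if isinstance(edges, pd.DataFrame):
        df = edges.iloc[:, :2].copy()
    else:
        df = pd.read_csv(edges, sep="\t", usecols=[0, 1])
    df.columns = ["source", "target"]
    return df.astype(str)


def _univariate_cox_p(values: pd.Series, surv: SurvivalTable) -> float:
    """Wald p for a continuous log2(x+1) expression covariate."""
    x = np.log2(values.to_numpy(float) + 1.0)
    time, event = surv.times_events(values.index)
    fit = cox_fit(x[:, None], time, event, ties="breslow")
    return float(fit.summary()["p"].iloc[0])


def build_cerna_axes(
    model: RiskModel,
    lnc_mir_edges,
    mir_prg_edges,
    mirna_expr: ExpressionMatrix,
    prg_expr: ExpressionMatrix,
    surv: SurvivalTable,
    alpha: float = 0.05,
) -> list:
    """Assemble prognostic lncRNA-miRNA-mRNA axes.

    Steps: restrict lncRNAs to the model's members; take their target
    miRNAs from ``lnc_mir_edges``; keep miRNAs that also target a supplied
    mRNA in ``mir_prg_edges``; test each candidate miRNA and mRNA by
    univariate Cox on log2 expression and keep nodes with p < ``alpha``;
    emit every path whose two edges exist and whose miRNA and mRNA both
    survive. Nodes without expression are skipped with a warning.
    """
    lnc_mir = _read_edges(lnc_mir_edges)
    mir_prg = _read_edges(mir_prg_edges)
    if lnc_mir.empty or mir_prg.empty:
        raise ReopairError("interaction edge tables must be nonempty")
    model_lnc = set(model.lncrna_ids)
    lnc_mir = lnc_mir[lnc_mir["source"].isin(model_lnc)]
    candidate_mirnas = set(lnc_mir["target"]) & set(mir_prg["source"])
    candidate_prgs = set(mir_prg.loc[mir_prg["source"].isin(candidate_mirnas), "target"])

    def node_p(node: str, expr: ExpressionMatrix) -> float | None:
        if node not in expr.values.index:
            warnings.warn(f"no expression for {node}; skipped")
            return None
        try:
            return _univariate_cox_p(expr.values.loc[node, surv.sample_ids], surv)
        except (ConvergenceError, ReopairError) as err:
            warnings.warn(f"Cox fit failed for {node} ({err}); skipped")
            return None

    mirna_p = {m: p for m in sorted(candidate_mirnas)
               if (p := node_p(m, mirna_expr)) is not None}
    prg_p = {g: p for g in sorted(candidate_prgs)
             if (p := node_p(g, prg_expr)) is not None}
    keep_mirnas = {m for m, p in mirna_p.items() if p < alpha}
    keep_prgs = {g for g, p in prg_p.items() if p < alpha}

    axes = []
    mir_targets = mir_prg.groupby("source")["target"].apply(set).to_dict()
    for _, row in lnc_mir.drop_duplicates().sort_values(["source", "target"]).iterrows():
        lnc, mir = row["source"], row["target"]
        if mir not in keep_mirnas:
            continue
        for prg in sorted(mir_targets.get(mir, ()) & keep_prgs):
            axes.append(CeRNAAxis(lnc, mir, prg, mirna_p[mir], prg_p[prg]))
    return axes


def axes_to_frame(axes: list) -> pd.DataFrame:
    """Tabulate axes as a TSV-ready DataFrame."""
    return pd.DataFrame(
        [(a.lncrna, a.mirna, a.mrna, a.p_mirna, a.p_mrna) for a in axes],
        columns=["lncRNA", "miRNA", "mRNA", "p_miRNA", "p_mRNA"],
    )
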