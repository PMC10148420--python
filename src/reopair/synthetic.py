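"""Synthetic HCC-like cohorts with planted pair-ordering prognostic structure.

The generator emulates the statistical structure the pipeline assumes in a
bulk RNA-seq survival cohort:

* two latent tumour subtypes with distinct mean profiles over a pyroptosis
  gene panel (so panel-based Ward clustering can recover them);
* a set of lncRNAs differentially expressed between the subtypes
  (|log2 fold change| > 1);
* planted prognostic lncRNA *pairs*: for each pair (a, b) a latent binary
  state Z decides the within-sample ordering (a < b iff Z = 1), built with a
  deterministic expression margin so recomputing the ordering from the
  expression values reproduces Z exactly, with no ties;
* survival times from an exponential proportional-hazards model whose
  linear predictor is the sum of true log-hazard coefficients over the
  planted pair states, with independent uniform censoring calibrated to a
  requested censoring fraction;
* a small fraction of samples with follow-up under 30 days or missing
  survival, to exercise the cohort filter.

Everything is driven by one integer seed; the same seed yields a
bit-identical cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .containers import ExpressionMatrix, ReopairError, SurvivalTable


@dataclass
class SimConfig:
    """Parameters of a simulated cohort.

    Defaults mirror a TCGA-LIHC-sized study: 343 tumour samples, a 40-gene
    pyroptosis panel, heavy right-censoring and log2-scale abundance noise.
    """

    n_samples: int = 343
    n_lnc: int = 200
    n_prg: int = 40
    n_de_lnc: int = 30
    n_planted_pairs: int = 5
    beta_true: Sequence[float] = field(default_factory=lambda: (1.0, -1.0, 1.2, -1.2, 1.0))
    prevalence_range: tuple = (0.3, 0.7)
    baseline_hazard: float = 1.0 / 1500.0   # events per day
    censor_rate: float = 0.65
    subtype_prob: float = 0.5
    noise_sd: float = 0.5                    # log2-scale abundance noise
    short_followup_frac: float = 0.05        # survival < 30 d or missing
    seed: int = 0

    def __post_init__(self) -> None:
        self.beta_true = tuple(float(b) for b in self.beta_true)
        for name in ("n_samples", "n_lnc", "n_prg"):
            if getattr(self, name) <= 0:
                raise ReopairError(f"{name} must be positive")
        if self.n_planted_pairs < 0 or self.n_de_lnc < 0:
            raise ReopairError("counts must be non-negative")
        if len(self.beta_true) != self.n_planted_pairs:
            raise ReopairError(
                f"beta_true has {len(self.beta_true)} entries for "
                f"{self.n_planted_pairs} planted pairs"
            )
        if 2 * self.n_planted_pairs > self.n_lnc:
            raise ReopairError("n_planted_pairs must be <= n_lnc / 2")
        lo, hi = self.prevalence_range
        if not (0.0 < lo < hi < 1.0):
            raise ReopairError("prevalence_range must be a nonempty subinterval of (0, 1)")
        if not (0.0 <= self.censor_rate < 1.0):
            raise ReopairError("censor_rate must lie in [0, 1)")
        if not (0.0 < self.subtype_prob < 1.0):
            raise ReopairError("subtype_prob must lie in (0, 1)")
        if self.baseline_hazard <= 0 or self.noise_sd <= 0:
            raise ReopairError("baseline_hazard and noise_sd must be positive")
        if not (0.0 <= self.short_followup_frac < 0.5):
            raise ReopairError("short_followup_frac must lie in [0, 0.5)")


@dataclass
class SimCohort:
    """A generated cohort plus its ground truth."""

    expression: ExpressionMatrix          # log2-scale abundances (lncRNA + panel rows)
    survival: SurvivalTable
    truth: dict
    config: SimConfig

    @property
    def planted_pairs(self) -> list:
        return [tuple(t["pair"]) for t in self.truth["planted_pairs"]]


def _censor_tmax(hazards: np.ndarray, target: float) -> float:
    """Upper bound of Uniform(0, c) censoring giving the requested censor rate.

    For exponential event time with rate h and C ~ U(0, c) the probability of
    censoring is (1 - exp(-h c)) / (h c); we average over the cohort's hazards
    and solve for c.
    """
    def frac(c):
        x = hazards * c
        return float(np.mean(np.where(x > 1e-12, (1.0 - np.exp(-x)) / np.where(x > 0, x, 1.0), 1.0)))
    # frac is 1 at c -> 0 and decreases toward 0; bracket then solve
    hi = 1.0 / np.median(hazards)
    while frac(hi) > target:
        hi *= 2.0
        if hi > 1e12:
            break
    return brentq(lambda c: frac(c) - target, 1e-9, hi, xtol=1e-6)


def generate_cohort(config: SimConfig) -> SimCohort:
    """Draw a full synthetic cohort (expression, survival, truth) from ``config``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = [f"S{i:04d}" for i in range(n)]
    subtype = 1 + (rng.random(n) >= config.subtype_prob).astype(int)  # 1 or 2

    # ---- pyroptosis panel genes: subtype-separated means ---------------------
    prg_ids = [f"PRG{i:03d}" for i in range(config.n_prg)]
    prg_base = rng.normal(5.0, 1.0, size=config.n_prg)
    # per-gene offset with |delta| = 2 * noise_sd, random sign
    delta = 2.0 * config.noise_sd * rng.choice([-1.0, 1.0], size=config.n_prg)
    prg_mean = prg_base[:, None] + np.where(subtype[None, :] == 1, 0.0, delta[:, None])
    prg = prg_mean + rng.normal(0.0, config.noise_sd, size=(config.n_prg, n))

    # ---- lncRNAs -------------------------------------------------------------
    lnc_ids = [f"LNC{i:04d}" for i in range(config.n_lnc)]
    base = rng.lognormal(mean=1.2, sigma=0.5, size=config.n_lnc)  # log2-scale baselines
    lnc = base[:, None] + rng.normal(0.0, config.noise_sd, size=(config.n_lnc, n))

    # planted prognostic pairs occupy the first 2 * n_planted_pairs ids
    planted = []
    margin = 3.0 * config.noise_sd
    for k in range(config.n_planted_pairs):
        ia, ib = 2 * k, 2 * k + 1
        p = rng.uniform(*config.prevalence_range)
        z = (rng.random(n) < p).astype(int)
        # moderately expressed baseline so the subtype shift and ordering
        # margin never push a member against the zero-abundance floor
        pair_base = rng.uniform(4.5, 6.0)
        # members co-vary through a shared per-sample level (co-regulation);
        # the within-pair ordering, not either member's level, carries Z
        centre = pair_base + rng.normal(0.0, 3.0 * config.noise_sd, size=n)
        # planted members are also subtype-differential (the pipeline builds
        # pairs from the DE pool); the shared shift leaves the ordering intact
        pair_shift = rng.choice([-1.0, 1.0]) * rng.uniform(1.25, 2.0)
        centre = centre + np.where(subtype == 2, pair_shift, 0.0)
        half = 0.5 * (margin + rng.uniform(0.0, config.noise_sd, size=n))
        centre = np.maximum(centre, half + 0.05)  # keep both members positive
        # Z = 1  <=>  expr(a) < expr(b); margin >= 3 * noise_sd guarantees no ties
        sign = np.where(z == 1, 1.0, -1.0)
        lnc[ia] = centre - sign * half
        lnc[ib] = centre + sign * half
        planted.append({
            "pair": (lnc_ids[ia], lnc_ids[ib]),
            "beta": config.beta_true[k],
            "prevalence": p,
            "z": z,
        })

    # subtype-differential lncRNAs follow the planted ones
    de_start = 2 * config.n_planted_pairs
    if de_start + config.n_de_lnc > config.n_lnc:
        raise ReopairError("n_de_lnc + 2*n_planted_pairs exceeds n_lnc")
    de_ids = lnc_ids[de_start:de_start + config.n_de_lnc]
    de_shift = rng.choice([-1.0, 1.0], size=config.n_de_lnc) * rng.uniform(
        1.25, 2.0, size=config.n_de_lnc
    )
    lnc[de_start:de_start + config.n_de_lnc, :] += np.where(
        subtype[None, :] == 2, de_shift[:, None], 0.0
    )

    values = pd.DataFrame(
        np.vstack([np.clip(lnc, 0.0, None), np.clip(prg, 0.0, None)]),
        index=lnc_ids + prg_ids,
        columns=sample_ids,
    )
    biotype = pd.Series(
        ["lncRNA"] * config.n_lnc + ["mRNA"] * config.n_prg, index=values.index
    )
    expr = ExpressionMatrix(values, biotype, scale="log2p1")

    # ---- survival under exponential proportional hazards ---------------------
    lp = np.zeros(n)
    for t in planted:
        lp += t["beta"] * t["z"]
    hazards = config.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / hazards)
    if config.censor_rate > 0:
        tmax = _censor_tmax(hazards, config.censor_rate)
        t_cens = rng.uniform(0.0, tmax, size=n)
    else:
        t_cens = np.full(n, np.inf)
    os_days = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    os_days = np.maximum(os_days, 1e-3)  # event times strictly positive

    os_days = os_days.astype(object)
    n_short = int(round(config.short_followup_frac * n))
    short_idx = rng.choice(n, size=n_short, replace=False)
    for j, i in enumerate(short_idx):
        if j % 2 == 0:
            os_days[i] = float(rng.uniform(0.5, 29.5))
            event[i] = int(rng.random() < 0.5)
        else:
            os_days[i] = np.nan  # missing survival

    age = rng.normal(60.0, 10.0, size=n).round(1)
    gender = rng.choice(["male", "female"], size=n, p=[0.7, 0.3])
    stage = rng.choice(["I", "II", "III", "IV"], size=n, p=[0.4, 0.25, 0.25, 0.1])
    grade = rng.choice(["G1", "G2", "G3", "G4"], size=n, p=[0.15, 0.45, 0.3, 0.1])
    surv = SurvivalTable(pd.DataFrame(
        {
            "os_days": pd.array([float(x) if x == x else np.nan for x in os_days], dtype=float),
            "event": event,
            "age": age,
            "gender": gender,
            "stage": stage,
            "grade": grade,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    ))

    truth = {
        "planted_pairs": planted,
        "subtype": pd.Series(subtype, index=sample_ids),
        "de_lnc_ids": de_ids,
        "prg_ids": prg_ids,
        "linear_predictor": lp,
        "short_followup_ids": [sample_ids[i] for i in short_idx],
    }
    return SimCohort(expr, surv, truth, config)


def write_cohort(cohort: SimCohort, out_dir) -> dict:
    """Write the standard input tables (expression TSV, clinical TSV, truth JSON).

    Returns the mapping of table name -> written path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "biotypes": out / "biotypes.tsv",
        "clinical": out / "clinical.tsv",
        "truth": out / "truth.json",
    }
    cohort.expression.to_tsv(paths["expression"])
    cohort.expression.biotype.rename("biotype").to_csv(
        paths["biotypes"], sep="\t", index_label="transcript_id"
    )
    cohort.survival.to_tsv(paths["clinical"])
    truth = {
        "planted_pairs": [
            {
                "pair": list(t["pair"]),
                "beta": t["beta"],
                "prevalence": t["prevalence"],
                "z": [int(v) for v in t["z"]],
            }
            for t in cohort.truth["planted_pairs"]
        ],
        "subtype": cohort.truth["subtype"].tolist(),
        "de_lnc_ids": list(cohort.truth["de_lnc_ids"]),
        "short_followup_ids": cohort.truth["short_followup_ids"],
    }
    paths["truth"].write_text(json.dumps(truth, indent=1))
    return {k: str(v) for k, v in paths.items()}
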