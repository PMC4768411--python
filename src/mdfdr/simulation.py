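"""Operating-characteristics study: mdFDR and average power by simulation.

Datasets mimic a multi-group microarray experiment: p groups (the last one
the reference) of n chips each, m genes per chip, expression values normal
with unit variance. Null genes have mean 0 in every group; each non-null
gene draws an independent U(0, 2.5) mean for every experimental group, so
every non-null gene is truly non-null (and up-regulated) in all q
comparisons. Three noise-correlation patterns are supported:

* ``independent`` — all values independent;
* ``within_sample`` — within one chip, any two genes have correlation rho;
* ``within_gene`` — for one gene, any two chips have correlation rho.

Equicorrelation is generated exactly by the shared-factor identity
X = sqrt(rho) * Z_shared + sqrt(1 - rho) * Z_own.

Each replication runs all requested pipelines on the same dataset and
records the realized mixed-directional false discovery proportion (false or
wrong-signed calls over all calls) and power (correctly signed calls over
non-null pairs); cell averages over replications estimate mdFDR and average
power.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data import DirectionalDecisions, ExpressionMatrix, GroupDesign, SimulationTruth
from .dunnett import (
    DunnettNullModel,
    dunnett_statistics,
    max_abs_t_tail,
    screening_pvalue,
    two_sided_t_pvalues,
)
from .model import PROCEDURES, pairwise_stage
from .multitest import bh_select, bonferroni_screening_pvalue

__all__ = [
    "SimulationConfig",
    "RunMetrics",
    "generate_dataset",
    "score_run",
    "estimate_operating_characteristics",
]

STRUCTURES = ("independent", "within_sample", "within_gene")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulation cell.

    Defaults are the study configuration: p = 4 groups (reference last) of
    n = 10 samples, m = 1000 features, unit-variance normal noise, non-null
    means uniform on (0, 2.5), nominal level alpha = 0.05.
    """

    m: int = 1000
    n: int = 10
    p: int = 4
    pi1: float = 0.3
    effect_low: float = 0.0
    effect_high: float = 2.5
    sigma: float = 1.0
    rho: float = 0.0
    structure: str = "independent"
    n_reps: int = 200
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.pi1 <= 1.0:
            raise ValueError("pi1 must be in [0, 1]")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0, 1)")
        if self.structure not in STRUCTURES:
            raise ValueError(
                f"unknown structure {self.structure!r}; choose from {STRUCTURES}"
            )
        if min(self.m, self.n, self.p - 1, self.n_reps) < 1:
            raise ValueError("m, n, p-1 and n_reps must be positive")

    @property
    def q(self) -> int:
        return self.p - 1

    @property
    def m0(self) -> int:
        """Number of null features (nearest-integer rounding)."""
        return int(round(self.m * (1.0 - self.pi1)))

    def design(self) -> GroupDesign:
        labels = [
            f"group_{g + 1}" for g in range(self.q) for _ in range(self.n)
        ] + ["reference"] * self.n
        return GroupDesign(labels, "reference")


@dataclass(frozen=True)
class RunMetrics:
    """Realized error and power of one pipeline on one dataset."""

    fdp: float
    power: float

    def __post_init__(self):
        if not (0.0 <= self.fdp <= 1.0 and 0.0 <= self.power <= 1.0):
            raise ValueError("fdp and power must be in [0, 1]")


def _rep_rng(config: SimulationConfig, rep_index: int) -> np.random.Generator:
    # independent substream per (seed, structure, pi1-cell, replication)
    return np.random.default_rng(
        np.random.SeedSequence(
            entropy=config.seed,
            spawn_key=(
                STRUCTURES.index(config.structure),
                int(round(config.pi1 * 10_000)),
                rep_index,
            ),
        )
    )


def generate_dataset(
    config: SimulationConfig, rep_index: int = 0
) -> tuple[ExpressionMatrix, GroupDesign, SimulationTruth]:
    """Draw one dataset under the configured correlation structure."""
    rng = _rep_rng(config, rep_index)
    m, n, q = config.m, config.n, config.q
    N = n * config.p

    mu = np.zeros((m, q))
    m1 = m - config.m0
    if m1 > 0:
        mu[config.m0 :, :] = rng.uniform(
            config.effect_low, config.effect_high, size=(m1, q)
        )

    noise = rng.standard_normal((m, N))
    if config.rho > 0.0 and config.structure != "independent":
        r = config.rho
        if config.structure == "within_sample":
            shared = rng.standard_normal((1, N))  # one factor per chip
        else:  # within_gene
            shared = rng.standard_normal((m, 1))  # one factor per gene
        noise = np.sqrt(r) * shared + np.sqrt(1.0 - r) * noise
    values = config.sigma * noise
    # experimental groups occupy the first q*n columns, reference the last n
    for i in range(q):
        values[:, i * n : (i + 1) * n] += mu[:, i : i + 1]

    matrix = ExpressionMatrix(values, [f"gene_{j + 1}" for j in range(m)])
    return matrix, config.design(), SimulationTruth(mu=mu)


def score_run(decisions: DirectionalDecisions, truth: SimulationTruth) -> RunMetrics:
    """Per-pair accounting of one run's directional calls.

    A call is false if its (feature, comparison) pair is truly null or its
    sign disagrees with the true sign; fdp is false calls over all calls
    (0 when there are none). Power is the fraction of truly non-null pairs
    called with the correct sign.
    """
    calls = decisions.calls
    made = calls != 0
    correct = made & truth.nonnull & (calls == truth.signs)
    n_calls = int(made.sum())
    n_false = n_calls - int(correct.sum())
    fdp = n_false / max(1, n_calls)
    power = int(correct.sum()) / max(1, truth.n_nonnull_pairs)
    return RunMetrics(fdp=fdp, power=power)


def _run_all_procedures(
    config: SimulationConfig, rep_index: int, procedures: list[str]
) -> dict[str, RunMetrics]:
    """One replication: shared dataset, all pipelines, scored."""
    matrix, design, truth = generate_dataset(config, rep_index)
    null_model = DunnettNullModel.from_design(design)
    stats_ = dunnett_statistics(matrix, design)
    raw_p = two_sided_t_pvalues(stats_)

    screening_cache: dict[str, np.ndarray] = {}
    adjusted_p = None
    out = {}
    for name in procedures:
        screening, pairwise, pairwise_pvalues = PROCEDURES[name]
        if screening not in screening_cache:
            if screening == "dunnett":
                screening_cache[screening] = screening_pvalue(stats_, null_model)
            else:
                screening_cache[screening] = bonferroni_screening_pvalue(raw_p)
        if pairwise_pvalues == "dunnett" and adjusted_p is None:
            # adjusted p-values are shared by every joint-screening pipeline
            adjusted_p = np.ones_like(stats_.t)
            ok = np.isfinite(stats_.t)
            adjusted_p[ok] = max_abs_t_tail(np.abs(stats_.t[ok]), null_model)
        screen = bh_select(screening_cache[screening], config.alpha)
        decisions = pairwise_stage(
            stats_, raw_p, null_model, screen, config.alpha, pairwise,
            pairwise_pvalues, adjusted_p=adjusted_p,
        )
        out[name] = score_run(decisions, truth)
    return out


def estimate_operating_characteristics(
    config: SimulationConfig,
    procedures: list[str] | None = None,
    pi1_values: list[float] | None = None,
) -> pd.DataFrame:
    """Estimate mdFDR and average power over replications.

    All procedures are evaluated on identical datasets within a replication
    (shared seed substreams) so procedure contrasts are paired. Returns a
    long-format table with one row per (procedure, pi1) cell: mean fdp
    (the mdFDR estimate), mean power, and their Monte-Carlo standard errors.
    """
    if procedures is None:
        procedures = list(PROCEDURES)
    unknown = [p for p in procedures if p not in PROCEDURES]
    if unknown:
        raise ValueError(f"unknown procedures: {unknown}")
    if pi1_values is None:
        pi1_values = [config.pi1]

    rows = []
    for pi1 in pi1_values:
        cell = replace(config, pi1=pi1)
        fdp = {name: np.empty(cell.n_reps) for name in procedures}
        power = {name: np.empty(cell.n_reps) for name in procedures}
        for rep in range(cell.n_reps):
            metrics = _run_all_procedures(cell, rep, procedures)
            for name, rm in metrics.items():
                fdp[name][rep] = rm.fdp
                power[name][rep] = rm.power
        for name in procedures:
            if cell.n_reps > 1:
                se_f = fdp[name].std(ddof=1) / np.sqrt(cell.n_reps)
                se_p = power[name].std(ddof=1) / np.sqrt(cell.n_reps)
            else:
                se_f = se_p = 0.0
            rows.append(
                {
                    "procedure": name,
                    "structure": cell.structure,
                    "rho": cell.rho,
                    "pi1": pi1,
                    "mdfdr": fdp[name].mean(),
                    "power": power[name].mean(),
                    "se_mdfdr": se_f,
                    "se_power": se_p,
                    "n_reps": cell.n_reps,
                }
            )
    return pd.DataFrame(rows)
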