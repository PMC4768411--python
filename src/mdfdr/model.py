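"""The three-step directional testing procedure as a Model/Results pair.

Step 1 (screening): a global p-value per feature — from the joint
distribution of the many-to-one statistics ("dunnett") or the Bonferroni
global test ("bonferroni") — is fed to the Benjamini-Hochberg step-up rule
at level alpha; R features are selected.

Step 2 (pairwise): for each selected feature, the q pairwise comparisons
are tested at the data-dependent level R*alpha/m. The main method
thresholds each single-step adjusted p-value directly at R*alpha/m; the
Holm/Hochberg/Bonferroni variants apply the named mdFWER procedure to the
same adjusted p-values at that level. The Guo-style comparator instead
pairs Bonferroni screening with a Bonferroni rule on the raw two-sided
pooled-t p-values.

Step 3 (direction): every rejected comparison is called up or down by the
sign of its statistic. This three-step scheme controls the mixed
directional FDR — the expected fraction of directional calls that are
either on a truly null pair or carry the wrong sign — at level alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import (
    CALL_LABELS,
    NONE,
    DirectionalDecisions,
    ExpressionMatrix,
    FeatureStats,
    GroupDesign,
    ScreeningResult,
    validate_inputs,
)
from .dunnett import (
    DunnettNullModel,
    dunnett_statistics,
    max_abs_t_tail,
    screening_pvalue,
    two_sided_t_pvalues,
)
from .multitest import apply_rows, bh_select, bonferroni_screening_pvalue

__all__ = [
    "MdFDRModel",
    "MdFDRResults",
    "PROCEDURES",
    "run_procedure",
    "decisions_to_table",
]

SCREENING_METHODS = ("dunnett", "bonferroni")
PAIRWISE_METHODS = ("dunnett", "holm", "hochberg", "bonferroni")
PAIRWISE_PVALUES = ("dunnett", "raw")

#: The five pipelines compared in the operating-characteristics study:
#: (screening method, pairwise method, pairwise p-value source) by name.
#: The holm/hochberg/bonferroni variants keep the joint-distribution
#: screening and adjusted pairwise p-values and only swap the mdFWER rule;
#: "guo" is the Bonferroni-screening comparator whose Bonferroni rule acts
#: on raw two-sided t p-values.
PROCEDURES = {
    "dunnett": ("dunnett", "dunnett", "dunnett"),
    "holm": ("dunnett", "holm", "dunnett"),
    "hochberg": ("dunnett", "hochberg", "dunnett"),
    "bonferroni": ("dunnett", "bonferroni", "dunnett"),
    "guo": ("bonferroni", "bonferroni", "raw"),
}


class MdFDRModel:
    """Many-to-one directional testing model for a features x samples matrix.

    Parameters
    ----------
    matrix : ExpressionMatrix or array-like
        m x N numeric expression values (features in rows).
    design : GroupDesign
        Sample-to-group assignment naming the reference group.
    feature_ids : sequence of str, optional
        Required when ``matrix`` is a bare array.

    Examples
    --------
    >>> model = MdFDRModel.from_dataframe(df, groups, reference="normal")
    >>> res = model.fit(alpha=0.05)
    >>> print(res.summary())
    """

    def __init__(self, matrix, design: GroupDesign, feature_ids=None):
        if not isinstance(matrix, ExpressionMatrix):
            values = np.asarray(matrix, dtype=float)
            if feature_ids is None:
                feature_ids = [f"feature_{j}" for j in range(values.shape[0])]
            matrix = ExpressionMatrix(values, feature_ids)
        self.matrix, self.design = validate_inputs(matrix, design)
        self.null_model = DunnettNullModel.from_design(self.design)
        self._stats: FeatureStats | None = None

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, groups, reference: str) -> "MdFDRModel":
        """Build from a features x samples DataFrame and a sample->group map.

        ``groups`` may be a mapping or a Series indexed by sample id, or a
        sequence aligned with the frame's columns.
        """
        if isinstance(groups, (dict, pd.Series)):
            groups = pd.Series(groups)
            missing = [c for c in frame.columns if c not in groups.index]
            if missing:
                raise ValueError(f"samples without a group label: {missing}")
            labels = groups.loc[frame.columns].tolist()
        else:
            labels = list(groups)
        matrix = ExpressionMatrix(frame.to_numpy(dtype=float), frame.index)
        return cls(matrix, GroupDesign(labels, reference))

    @property
    def stats(self) -> FeatureStats:
        """Per-feature statistics T_ij (computed once, then cached)."""
        if self._stats is None:
            self._stats = dunnett_statistics(self.matrix, self.design)
        return self._stats

    def fit(
        self,
        alpha: float = 0.05,
        screening: str = "dunnett",
        pairwise: str = "dunnett",
        pairwise_pvalues: str = "dunnett",
    ) -> "MdFDRResults":
        """Run the three-step procedure at mdFDR level ``alpha``.

        ``pairwise_pvalues`` selects what the pairwise rule consumes:
        single-step adjusted p-values from the joint null ("dunnett", the
        default) or raw two-sided pooled-t p-values ("raw", used by the
        Guo-style comparator).
        """
        if not 0 < alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if screening not in SCREENING_METHODS:
            raise ValueError(f"unknown screening method {screening!r}")
        if pairwise not in PAIRWISE_METHODS:
            raise ValueError(f"unknown pairwise method {pairwise!r}")
        if pairwise_pvalues not in PAIRWISE_PVALUES:
            raise ValueError(f"unknown pairwise p-value source {pairwise_pvalues!r}")
        if pairwise == "dunnett" and pairwise_pvalues == "raw":
            raise ValueError(
                "the plain-threshold pairwise rule is only valid on "
                "adjusted p-values"
            )
        stats_ = self.stats
        raw_p = two_sided_t_pvalues(stats_)
        if screening == "dunnett":
            sp = screening_pvalue(stats_, self.null_model)
        else:
            sp = bonferroni_screening_pvalue(raw_p)
        screen = bh_select(sp, alpha)
        decisions = pairwise_stage(
            stats_, raw_p, self.null_model, screen, alpha, pairwise,
            pairwise_pvalues,
        )
        return MdFDRResults(self, decisions, alpha, screening, pairwise)


def pairwise_stage(
    stats_: FeatureStats,
    raw_p: np.ndarray,
    null_model: DunnettNullModel,
    screen: ScreeningResult,
    alpha: float,
    pairwise: str,
    pairwise_pvalues: str = "dunnett",
    adjusted_p: np.ndarray | None = None,
) -> DirectionalDecisions:
    """Steps 2-3: directional decisions for the screened features.

    The pairwise level is R*alpha/m with the realized R; when R = 0 the
    stage is skipped entirely and no calls are made. ``adjusted_p`` lets a
    caller that evaluates several pipelines on the same data supply the
    precomputed (m, q) single-step adjusted p-values.
    """
    m, q = stats_.t.shape
    calls = np.full((m, q), NONE, dtype=int)
    pairwise_p = np.full((m, q), np.nan)
    level = screen.R * alpha / m
    if screen.R > 0:
        sel = screen.selected
        t_sel = stats_.t[sel]
        signs = np.sign(np.nan_to_num(t_sel)).astype(int)
        if pairwise_pvalues == "dunnett":
            if adjusted_p is not None:
                p_sel = adjusted_p[sel]
            else:
                p_sel = np.ones_like(t_sel)
                ok = np.isfinite(t_sel)
                if ok.any():
                    p_sel[ok] = max_abs_t_tail(np.abs(t_sel[ok]), null_model)
        else:
            p_sel = raw_p[sel]
        if pairwise == "dunnett":
            # already-adjusted p-values: plain threshold, no further division
            reject = p_sel <= level
            sub = np.where(reject, signs, NONE)
        else:
            sub = apply_rows(pairwise, p_sel, signs, level)
        calls[sel] = sub
        pairwise_p[sel] = p_sel
    return DirectionalDecisions(
        pairwise_p=pairwise_p, calls=calls, screening=screen, level=level
    )


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run."""

    alpha: float = 0.05
    screening_method: str = "dunnett"
    pairwise_method: str = "dunnett"
    pairwise_pvalues: str = "dunnett"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def run_procedure(
    matrix: ExpressionMatrix, design: GroupDesign, config: PipelineConfig
) -> DirectionalDecisions:
    """Functional entry point: run the full procedure, return the decisions."""
    model = MdFDRModel(matrix, design)
    res = model.fit(
        alpha=config.alpha,
        screening=config.screening_method,
        pairwise=config.pairwise_method,
        pairwise_pvalues=config.pairwise_pvalues,
    )
    return res.decisions


class MdFDRResults:
    """Fitted results: selection, directional calls and audit quantities.

    Attributes
    ----------
    decisions : DirectionalDecisions
        Calls and pairwise p-values per (feature, comparison).
    R : int
        Number of features selected by BH in the screening step.
    level : float
        The realized pairwise testing level R*alpha/m.
    """

    def __init__(self, model, decisions, alpha, screening, pairwise):
        self.model = model
        self.decisions = decisions
        self.alpha = alpha
        self.screening_method = screening
        self.pairwise_method = pairwise

    @property
    def R(self) -> int:
        return self.decisions.screening.R

    @property
    def level(self) -> float:
        return self.decisions.level

    @property
    def screening_p(self) -> np.ndarray:
        return self.decisions.screening.screening_p

    @property
    def calls(self) -> np.ndarray:
        return self.decisions.calls

    @property
    def n_undirected(self) -> int:
        """Features selected in screening but with no pairwise rejection.

        Declared not differentially expressed overall; kept in the table.
        """
        return int(self.decisions.undirected_selected.sum())

    def to_frame(self) -> pd.DataFrame:
        """Long-format decision table, one row per (feature, comparison)."""
        return decisions_to_table(
            self.decisions, self.model.matrix.feature_ids, self.model
        )

    def summary(self) -> str:
        d = self.model.design
        lines = [
            "Mixed-directional FDR procedure",
            f"  features (m):        {self.model.matrix.m}",
            f"  comparisons (q):     {d.q}  [{', '.join(d.experimental_labels)}"
            f" vs {d.reference_label}]",
            f"  pooled df:           {d.df}",
            f"  alpha:               {self.alpha}",
            f"  screening method:    {self.screening_method}",
            f"  pairwise method:     {self.pairwise_method}",
            f"  selected (R):        {self.R}",
            f"  pairwise level:      {self.level:.6g}  (R*alpha/m)",
        ]
        for i, g in enumerate(d.experimental_labels):
            up = int(np.sum(self.calls[:, i] > 0))
            down = int(np.sum(self.calls[:, i] < 0))
            lines.append(f"  {g} vs {d.reference_label}: {up} up, {down} down")
        lines.append(
            f"  selected but undirected: {self.n_undirected} "
            "(declared not differentially expressed)"
        )
        return "\n".join(lines)


def decisions_to_table(
    decisions: DirectionalDecisions, feature_ids, model: MdFDRModel | None = None
) -> pd.DataFrame:
    """Flatten decisions into one record per (feature, comparison).

    Columns: feature_id, comparison, T, screening_p, pairwise_p, call,
    selected, undirected (the selected-but-no-pairwise-rejection flag).
    """
    calls = decisions.calls
    m, q = calls.shape
    if model is not None:
        comp = [
            f"{g}_vs_{model.design.reference_label}"
            for g in model.design.experimental_labels
        ]
        t = model.stats.t
    else:
        comp = [f"comparison_{i + 1}" for i in range(q)]
        t = np.full((m, q), np.nan)
    undirected = decisions.undirected_selected
    records = pd.DataFrame(
        {
            "feature_id": np.repeat(list(feature_ids), q),
            "comparison": np.tile(comp, m),
            "T": t.ravel(),
            "screening_p": np.repeat(decisions.screening.screening_p, q),
            "pairwise_p": decisions.pairwise_p.ravel(),
            "call": [CALL_LABELS[c] for c in calls.ravel()],
            "selected": np.repeat(decisions.screening.selected, q),
            "undirected": np.repeat(undirected, q),
        }
    )
    return records
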