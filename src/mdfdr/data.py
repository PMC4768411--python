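"""Shared domain types, index conventions and input validation.

Conventions used throughout the package:

* Features (genes, probe sets, CpG sites, ...) are rows; samples are columns.
* Comparison ``i`` (``i = 0..q-1``) always means "experimental group ``i``
  minus the reference group", so a positive statistic / an ``up`` call means
  the feature is higher in the experimental group.
* After canonicalization the reference group's samples are stored last and
  experimental groups appear in order of first appearance in the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GroupDesign",
    "ExpressionMatrix",
    "FeatureStats",
    "ScreeningResult",
    "DirectionalDecisions",
    "SimulationTruth",
    "validate_inputs",
    "UP",
    "DOWN",
    "NONE",
]

# Directional call codes: sign of the declared direction, 0 = no call.
UP: int = 1
DOWN: int = -1
NONE: int = 0

CALL_LABELS = {UP: "up", DOWN: "down", NONE: "none"}
CALL_CODES = {v: k for k, v in CALL_LABELS.items()}


@dataclass(frozen=True)
class GroupDesign:
    """Sample-to-group assignment with a designated reference group.

    Parameters
    ----------
    group_labels : sequence of str
        One group label per sample column, in column order.
    reference_label : str
        The label of the reference (control) group. All ``q`` experimental
        groups are compared against it; with ``q`` experimental groups there
        are ``p = q + 1`` groups in total.
    """

    group_labels: tuple
    reference_label: str

    def __init__(self, group_labels, reference_label):
        object.__setattr__(self, "group_labels", tuple(str(g) for g in group_labels))
        object.__setattr__(self, "reference_label", str(reference_label))
        self._validate()

    def _validate(self) -> None:
        labels = self.group_labels
        if self.reference_label not in labels:
            raise ValueError(
                f"reference group {self.reference_label!r} has no samples"
            )
        counts = self.group_sizes
        if len(counts) < 2:
            raise ValueError("need at least one experimental group (q >= 1)")
        small = {g: c for g, c in counts.items() if c < 2}
        if small:
            raise ValueError(
                f"every group needs >= 2 samples for a pooled variance; got {small}"
            )
        if self.df <= 0:
            raise ValueError("pooled degrees of freedom must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.group_labels)

    @property
    def group_sizes(self) -> dict:
        sizes: dict = {}
        for g in self.group_labels:
            sizes[g] = sizes.get(g, 0) + 1
        return sizes

    @property
    def experimental_labels(self) -> tuple:
        """Experimental group labels in order of first appearance."""
        seen = []
        for g in self.group_labels:
            if g != self.reference_label and g not in seen:
                seen.append(g)
        return tuple(seen)

    @property
    def q(self) -> int:
        """Number of experimental groups (= number of pairwise comparisons)."""
        return len(self.experimental_labels)

    @property
    def p(self) -> int:
        """Total number of groups, q + 1."""
        return self.q + 1

    @property
    def df(self) -> int:
        """Pooled within-group degrees of freedom, sum(n_g) - p."""
        return self.n_samples - self.p

    def indices(self, label: str) -> np.ndarray:
        """Column indices of the samples belonging to ``label``."""
        return np.flatnonzero(np.asarray(self.group_labels) == label)


@dataclass(frozen=True)
class ExpressionMatrix:
    """A features x samples numeric matrix with unique feature identifiers."""

    values: np.ndarray
    feature_ids: tuple

    def __init__(self, values, feature_ids):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValueError("expression matrix must be 2-dimensional")
        feature_ids = tuple(str(f) for f in feature_ids)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "feature_ids", feature_ids)
        self._validate()

    def _validate(self) -> None:
        m, _ = self.values.shape
        if m < 1:
            raise ValueError("need at least one feature")
        if len(self.feature_ids) != m:
            raise ValueError(
                f"{len(self.feature_ids)} feature ids for {m} matrix rows"
            )
        if len(set(self.feature_ids)) != m:
            raise ValueError("duplicate feature ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(
                "matrix contains missing or non-finite values; "
                "missing data are rejected, not imputed"
            )

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class FeatureStats:
    """Per-feature many-to-one statistics T_ij and the shared null model.

    Attributes
    ----------
    t : (m, q) ndarray
        Statistic for feature j, comparison i (experimental i minus
        reference). Rows of a feature with zero pooled variance are NaN.
    df : int
        Pooled degrees of freedom, sum(n_g) - p.
    rho : (q, q) ndarray
        Null correlation matrix of the statistics within a feature.
    """

    t: np.ndarray
    df: int
    rho: np.ndarray

    def __post_init__(self):
        rho = np.asarray(self.rho, dtype=float)
        if not np.allclose(rho, rho.T):
            raise ValueError("rho must be symmetric")
        if not np.allclose(np.diag(rho), 1.0):
            raise ValueError("rho must have unit diagonal")
        # PSD up to numerical noise
        if np.linalg.eigvalsh(rho).min() < -1e-10:
            raise ValueError("rho must be positive semi-definite")


@dataclass(frozen=True)
class ScreeningResult:
    """Outcome of the screening step: per-feature p-values and BH selection."""

    screening_p: np.ndarray
    selected: np.ndarray  # boolean mask over features
    R: int


@dataclass(frozen=True)
class DirectionalDecisions:
    """Per (feature, comparison) directional calls with their p-values.

    ``calls`` holds UP/DOWN/NONE codes; rows of non-selected features are all
    NONE. ``pairwise_p`` is meaningful only for selected features (NaN
    elsewhere is allowed).
    """

    pairwise_p: np.ndarray
    calls: np.ndarray
    screening: ScreeningResult
    level: float  # the data-dependent pairwise level R*alpha/m

    def __post_init__(self):
        if np.any(self.calls[~self.screening.selected] != NONE):
            raise ValueError("non-selected features must have no calls")

    @property
    def n_calls(self) -> int:
        return int(np.count_nonzero(self.calls))

    @property
    def undirected_selected(self) -> np.ndarray:
        """Mask of features selected in screening but with no pairwise call.

        These are reported as not differentially expressed overall, but kept
        in the audit table.
        """
        return self.screening.selected & ~np.any(self.calls != NONE, axis=1)


@dataclass(frozen=True)
class SimulationTruth:
    """True means and non-null status for a simulated dataset.

    ``mu`` is (m, q): the true mean of feature j in experimental group i
    (the reference mean is always 0). ``nonnull`` marks pairs with mu != 0;
    ``signs`` carries the true direction for those pairs (0 on null pairs).
    """

    mu: np.ndarray
    nonnull: np.ndarray = field(init=False)
    signs: np.ndarray = field(init=False)

    def __post_init__(self):
        mu = np.asarray(self.mu, dtype=float)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "nonnull", mu != 0.0)
        object.__setattr__(self, "signs", np.sign(mu).astype(int))

    @property
    def n_nonnull_pairs(self) -> int:
        return int(np.count_nonzero(self.nonnull))


def validate_inputs(
    matrix: ExpressionMatrix, design: GroupDesign
) -> tuple[ExpressionMatrix, GroupDesign]:
    """Validate a matrix/design pair and canonicalize the column order.

    Columns are reordered so experimental groups come first (in order of
    first appearance) and the reference group last; this operation is
    idempotent and does not change any downstream statistic.
    """
    if matrix.n_samples != design.n_samples:
        raise ValueError(
            f"matrix has {matrix.n_samples} samples but design has "
            f"{design.n_samples} group labels"
        )
    order = np.concatenate(
        [design.indices(g) for g in design.experimental_labels]
        + [design.indices(design.reference_label)]
    )
    if np.array_equal(order, np.arange(matrix.n_samples)):
        return matrix, design
    labels = np.asarray(design.group_labels)[order]
    return (
        ExpressionMatrix(matrix.values[:, order], matrix.feature_ids),
        GroupDesign(labels, design.reference_label),
    )
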