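"""BH step-up selection and directional mdFWER procedures.

The screening stage selects features with the Benjamini-Hochberg step-up
rule. Within each selected feature, a mixed-directional familywise error
(mdFWER) controlling procedure — Holm, Hochberg or Bonferroni, augmented
with sign-based directional decisions — is applied to the q pairwise
p-values at the data-dependent level R*alpha/m. The Bonferroni global test
(q times the smallest raw p-value) gives the screening p-value of the
comparator pipeline.
"""

from __future__ import annotations

import numpy as np

from .data import DOWN, NONE, UP, ScreeningResult

__all__ = [
    "bh_select",
    "holm_directional",
    "hochberg_directional",
    "bonferroni_directional",
    "bonferroni_screening_pvalue",
    "MDFWER_PROCEDURES",
]


def bh_select(pvalues: np.ndarray, alpha: float) -> ScreeningResult:
    """Benjamini-Hochberg step-up selection at level ``alpha``.

    Rejects the k smallest p-values where k = max{ i : p_(i) <= i*alpha/m }
    (k = 0 when the set is empty). Ties are resolved stably by original
    index; tied p-values share a threshold so the outcome is
    order-independent.
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    thresholds = alpha * np.arange(1, m + 1) / m
    below = p[order] <= thresholds
    k = int(np.max(np.nonzero(below)[0]) + 1) if below.any() else 0
    selected = np.zeros(m, dtype=bool)
    selected[order[:k]] = True
    return ScreeningResult(screening_p=p, selected=selected, R=k)


def _directions(signs: np.ndarray, reject: np.ndarray) -> np.ndarray:
    calls = np.full(reject.shape, NONE, dtype=int)
    calls[reject & (np.asarray(signs) > 0)] = UP
    calls[reject & (np.asarray(signs) <= 0)] = DOWN
    return calls


def holm_directional(pvals, signs, level: float) -> np.ndarray:
    """Holm step-down with directional decisions.

    Order p ascending and reject while p_(i) <= level/(q-i+1); the first
    failure stops the procedure. Rejected comparisons are called up/down by
    the sign of their statistic.
    """
    p = np.asarray(pvals, dtype=float)
    q = p.size
    order = np.argsort(p, kind="stable")
    thresholds = level / (q - np.arange(q))
    below = p[order] <= thresholds
    n_reject = int(np.argmin(below)) if not below.all() else q
    reject = np.zeros(q, dtype=bool)
    reject[order[:n_reject]] = True
    return _directions(signs, reject)


def hochberg_directional(pvals, signs, level: float) -> np.ndarray:
    """Hochberg step-up with directional decisions.

    Find the largest i with p_(i) <= level/(q-i+1); reject it and every
    smaller p-value.
    """
    p = np.asarray(pvals, dtype=float)
    q = p.size
    order = np.argsort(p, kind="stable")
    thresholds = level / (q - np.arange(q))
    below = p[order] <= thresholds
    k = int(np.max(np.nonzero(below)[0]) + 1) if below.any() else 0
    reject = np.zeros(q, dtype=bool)
    reject[order[:k]] = True
    return _directions(signs, reject)


def bonferroni_directional(pvals, signs, level: float) -> np.ndarray:
    """Bonferroni: reject comparison i iff p_i <= level/q; directions by sign."""
    p = np.asarray(pvals, dtype=float)
    reject = p <= level / p.size
    return _directions(signs, reject)


def bonferroni_screening_pvalue(two_sided_t_pvals: np.ndarray) -> np.ndarray:
    """Bonferroni global-test screening p-value, min(1, q * min_i p_i).

    Accepts a (q,) vector (returns a scalar) or an (m, q) matrix (returns a
    length-m vector). This is the screening stage of the comparator pipeline
    that pairs Bonferroni screening with Bonferroni pairwise decisions.
    """
    p = np.asarray(two_sided_t_pvals, dtype=float)
    if p.ndim == 1:
        return float(min(1.0, p.size * p.min()))
    return np.minimum(1.0, p.shape[1] * p.min(axis=1))


def apply_rows(name: str, pvals: np.ndarray, signs: np.ndarray, level: float) -> np.ndarray:
    """Apply a named mdFWER procedure independently to every row of ``pvals``.

    Vectorized equivalent of calling holm/hochberg/bonferroni_directional on
    each (q,) row; used on the selected features of a whole dataset at once.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim == 1:
        p = p[None, :]
        signs = np.asarray(signs)[None, :]
    n, q = p.shape
    if name == "bonferroni":
        reject = p <= level / q
    else:
        order = np.argsort(p, axis=1, kind="stable")
        thresholds = level / (q - np.arange(q))
        below = np.take_along_axis(p, order, axis=1) <= thresholds
        if name == "holm":
            # number rejected = position of first failure (step-down)
            k = np.where(below.all(axis=1), q, np.argmin(below, axis=1))
        elif name == "hochberg":
            # largest i with p_(i) below its threshold (step-up)
            k = np.where(below.any(axis=1), q - np.argmax(below[:, ::-1], axis=1), 0)
        else:
            raise ValueError(f"unknown mdFWER procedure {name!r}")
        reject = np.zeros_like(below)
        np.put_along_axis(reject, order, np.arange(q) < k[:, None], axis=1)
    return _directions(signs, reject)


MDFWER_PROCEDURES = {
    "holm": holm_directional,
    "hochberg": hochberg_directional,
    "bonferroni": bonferroni_directional,
}
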