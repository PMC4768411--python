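"""Delimited-text readers/writers and per-comparison summaries.

Expression matrices are delimited text (TSV or CSV, autodetected from the
extension), first column the feature id, header row the sample ids. Group
assignments are two-column files (sample id, group label). Results tables
are TSV in long format, one record per (feature, comparison).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, GroupDesign

__all__ = [
    "read_matrix",
    "read_groups",
    "write_results",
    "read_results",
    "summarize_by_comparison",
]

RESULT_COLUMNS = [
    "feature_id",
    "comparison",
    "T",
    "screening_p",
    "pairwise_p",
    "call",
    "selected",
    "undirected",
]


def _sep(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_matrix(path, return_samples: bool = False):
    """Read a features x samples matrix; feature order is preserved.

    With ``return_samples=True`` also returns the header's sample ids (for
    aligning a group-assignment file).
    """
    frame = pd.read_csv(path, sep=_sep(path), index_col=0)
    if frame.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns found")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & frame.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {frame.iat[r, c]!r} at feature "
            f"{frame.index[r]!r}, sample {frame.columns[c]!r}"
        )
    matrix = ExpressionMatrix(numeric.to_numpy(dtype=float), frame.index)
    if return_samples:
        return matrix, [str(c) for c in frame.columns]
    return matrix


def read_groups(path, reference: str, sample_ids=None) -> GroupDesign:
    """Read a two-column (sample id, group label) file into a GroupDesign.

    When ``sample_ids`` is given (the matrix's column order), labels are
    aligned to it and every sample must be assigned exactly once.
    """
    frame = pd.read_csv(path, sep=_sep(path), header=None, dtype=str, comment="#")
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (sample id, group label)")
    frame = frame.iloc[:, :2]
    frame.columns = ["sample", "group"]
    if frame["sample"].duplicated().any():
        dup = frame.loc[frame["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"{path}: duplicate sample ids {dup}")
    mapping = dict(zip(frame["sample"], frame["group"]))
    if sample_ids is not None:
        missing = [s for s in sample_ids if s not in mapping]
        if missing:
            raise ValueError(f"{path}: no group label for samples {missing}")
        labels = [mapping[s] for s in sample_ids]
    else:
        labels = frame["group"].tolist()
    return GroupDesign(labels, reference)


def write_results(table: pd.DataFrame, path) -> None:
    """Write a long-format results table as TSV.

    P-values keep full float precision so that re-reading the table
    reproduces every call exactly.
    """
    table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_results(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in RESULT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing result columns {missing}")
    return table


def summarize_by_comparison(table: pd.DataFrame) -> pd.DataFrame:
    """Count features per Venn cell of the comparisons they are called in.

    Each feature with at least one up/down call lands in exactly one of the
    2^q - 1 cells (the nonempty subsets of comparisons), so the cell counts
    partition the directed features. Also appends per-comparison up/down
    totals. Returns a table with columns (kind, cell, count).
    """
    comparisons = list(dict.fromkeys(table["comparison"]))
    called = table[table["call"].isin(["up", "down"])]
    cells: dict[frozenset, int] = {}
    for _, grp in called.groupby("feature_id", sort=False):
        key = frozenset(grp["comparison"])
        cells[key] = cells.get(key, 0) + 1

    rows = []
    for key in sorted(cells, key=lambda k: (len(k), sorted(comparisons.index(c) for c in k))):
        label = "&".join(sorted(key, key=comparisons.index))
        rows.append({"kind": "venn_cell", "cell": label, "count": cells[key]})
    rows.append(
        {
            "kind": "total",
            "cell": "any_comparison",
            "count": int(sum(cells.values())),
        }
    )
    for comp in comparisons:
        sub = called[called["comparison"] == comp]
        rows.append(
            {"kind": "up", "cell": comp, "count": int((sub["call"] == "up").sum())}
        )
        rows.append(
            {"kind": "down", "cell": comp, "count": int((sub["call"] == "down").sum())}
        )
    return pd.DataFrame(rows, columns=["kind", "cell", "count"])
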