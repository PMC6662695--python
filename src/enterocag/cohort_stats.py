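"""Cohort contingency tables and chi-square tests over the three disease groups.

Pearson chi-square without continuity correction; the literal level
"Unknown" is kept as a category by default.  A transcription of the
283-subject cohort characteristics table ships with the package as
``data/table1_metadata.tsv``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .abundance_io import GROUP3_LEVELS, CohortMetadata, ValidationError

__all__ = [
    "ContingencyTable",
    "build_contingency",
    "chi_square_test",
    "load_table1_metadata",
]

_NON_COVARIATE_COLUMNS = {"stage6", "group3"}


@dataclass
class ContingencyTable:
    """Covariate-level x disease-group count matrix, plus test results
    once :func:`chi_square_test` has been run."""

    variable: str
    row_labels: list
    col_labels: list
    counts: np.ndarray
    statistic: float | None = None
    df: int | None = None
    p_value: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels, columns=self.col_labels)


def load_table1_metadata() -> CohortMetadata:
    """The packaged 283-subject cohort-characteristics fixture."""
    path = resources.files("enterocag").joinpath("data/table1_metadata.tsv")
    with resources.as_file(path) as p:
        return CohortMetadata.from_tsv(p)


def build_contingency(
    metadata: CohortMetadata, variable: str, include_unknown: bool = True
) -> ContingencyTable:
    """Counts of each covariate level per disease group (counts only; run
    :func:`chi_square_test` for the statistic)."""
    frame = metadata.frame
    covariates = [c for c in frame.columns if c not in _NON_COVARIATE_COLUMNS]
    if variable not in covariates:
        raise ValidationError(
            f"unknown variable {variable!r}; available: {covariates}"
        )
    col = frame[variable].astype(str)
    groups = frame["group3"]
    if not include_unknown:
        keep = col != "Unknown"
        col, groups = col[keep], groups[keep]
    levels = list(pd.unique(col))
    # deterministic order: appearance order, Unknown last
    if "Unknown" in levels:
        levels = [lv for lv in levels if lv != "Unknown"] + ["Unknown"]
    counts = np.array(
        [[int(((col == lv) & (groups == g)).sum()) for g in GROUP3_LEVELS] for lv in levels]
    )
    return ContingencyTable(
        variable=variable,
        row_labels=levels,
        col_labels=list(GROUP3_LEVELS),
        counts=counts,
    )


def chi_square_test(ct: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) on a contingency table.

    Returns ``(statistic, df, p)`` and records them on ``ct``.
    """
    counts = np.asarray(ct.counts)
    if counts.ndim != 2:
        raise ValidationError("contingency counts must be a 2-D matrix")
    rows = counts[counts.sum(axis=1) > 0, :]
    if rows.shape[0] != counts.shape[0] or (counts.sum(axis=0) == 0).any():
        raise ValidationError("contingency table has a zero row or column margin")
    df = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    if df < 1:
        raise ValidationError("degenerate contingency table (df = 0)")
    statistic, p, dof, _ = chi2_contingency(counts, correction=False)
    ct.statistic, ct.df, ct.p_value = float(statistic), int(dof), float(p)
    return float(statistic), int(dof), float(p)
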