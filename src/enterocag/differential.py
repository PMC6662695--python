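"""Rank-based two-group differential abundance with a cancer-prevalence filter.

The test is the two-sided Mann-Whitney rank test: exact enumeration when
the smaller sample has at most 8 observations and there are no ties,
otherwise the normal approximation with tie and continuity corrections.
Raw p-values are thresholded at 0.01 with no multiple-testing correction
by default; a Benjamini-Hochberg mode is available.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .abundance_io import (
    CohortMetadata,
    GenusAbundanceTable,
    ValidationError,
    prevalence,
)

__all__ = [
    "DifferentialResult",
    "mann_whitney_two_sided",
    "filter_by_prevalence",
    "differential_genera",
    "transition_analysis",
    "results_to_frame",
    "DEFAULT_ALPHA",
]

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.01
EXACT_MAX_N = 8

_CANCER_STAGES = ("crc_stage0", "crc_early", "crc_late")


@dataclass(frozen=True)
class DifferentialResult:
    """Outcome of one two-group rank test on one genus (or CAG)."""

    genus: str
    comparison: tuple[str, str]
    stratum: str
    u_statistic: float
    p_value: float
    prevalence_in_reference: float
    direction: str  # up_in_second | down_in_second | none
    significant: bool


def mann_whitney_two_sided(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of x, p).

    Exact when min(n) <= 8 with no ties in the pooled data, otherwise
    normal approximation with tie correction and continuity correction.
    Completely tied data (all pooled values identical) returns p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("mann_whitney_two_sided requires non-empty samples")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("mann_whitney_two_sided requires finite values")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        logger.info("all pooled values identical; returning p = 1 by convention")
        return x.size * y.size / 2.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if min(x.size, y.size) <= EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def filter_by_prevalence(
    table: GenusAbundanceTable,
    metadata: CohortMetadata,
    reference_group: str = "cancer",
    threshold: float = 0.5,
) -> list[str]:
    """Genera strictly exceeding ``threshold`` prevalence in the reference
    group, in original column order."""
    samples = metadata.samples_in_group(reference_group)
    samples = [s for s in samples if s in table.data.index]
    if not samples:
        raise ValidationError(f"reference group {reference_group!r} has no samples in table")
    prev = prevalence(table, samples)
    return [g for g in table.genus_names if prev[g] > threshold]


def _bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    n = len(pvalues)
    order = np.argsort(pvalues)
    adjusted = np.empty(n)
    cummin = 1.0
    for rank in range(n - 1, -1, -1):
        idx = order[rank]
        cummin = min(cummin, pvalues[idx] * n / (rank + 1))
        adjusted[idx] = cummin
    return adjusted


def _run_tests(
    values: pd.DataFrame,
    groups: pd.Series,
    comparisons: list[tuple[str, str]],
    stratum_name: str,
    ref_prevalence: pd.Series,
    alpha: float,
    bh: bool,
) -> list[DifferentialResult]:
    results = []
    for a, b in comparisons:
        sa = groups.index[groups == a]
        sb = groups.index[groups == b]
        if len(sa) < 2 or len(sb) < 2:
            warnings.warn(
                f"comparison ({a}, {b}) in stratum {stratum_name!r} skipped: "
                f"group sizes {len(sa)} vs {len(sb)}",
                stacklevel=3,
            )
            continue
        for genus in values.columns:
            va = values.loc[sa, genus].to_numpy(dtype=float)
            vb = values.loc[sb, genus].to_numpy(dtype=float)
            u, p = mann_whitney_two_sided(va, vb)
            diff = float(np.median(vb) - np.median(va))
            direction = (
                "up_in_second" if diff > 0 else "down_in_second" if diff < 0 else "none"
            )
            results.append(
                DifferentialResult(
                    genus=genus,
                    comparison=(a, b),
                    stratum=stratum_name,
                    u_statistic=u,
                    p_value=p,
                    prevalence_in_reference=float(ref_prevalence[genus]),
                    direction=direction,
                    significant=p < alpha,
                )
            )
    if bh and results:
        adjusted = _bh_adjust(np.array([r.p_value for r in results]))
        results = [
            DifferentialResult(
                r.genus, r.comparison, r.stratum, r.u_statistic, float(q),
                r.prevalence_in_reference, r.direction, bool(q < alpha),
            )
            for r, q in zip(results, adjusted)
        ]
    return sorted(results, key=lambda r: r.p_value)


def differential_genera(
    table: GenusAbundanceTable,
    metadata: CohortMetadata,
    comparisons: list[tuple[str, str]] | None = None,
    stratum: str | None = None,
    enterotype_labels: pd.Series | None = None,
    alpha: float = DEFAULT_ALPHA,
    apply_prevalence_filter: bool = True,
    reference_group: str = "cancer",
    prevalence_threshold: float = 0.5,
    bh: bool = False,
) -> list[DifferentialResult]:
    """Per-genus rank tests for the listed group pairs, optionally within
    one enterotype stratum.

    The prevalence filter (reference group, default cancer, strict > 50%)
    is computed on the full cohort before any stratification, then tests
    run on the stratum's samples.  Results are sorted by p-value.
    """
    if table.kind != "relative":
        raise ValidationError("differential_genera requires a relative table")
    if comparisons is None:
        comparisons = [("normal", "adenoma"), ("normal", "cancer"), ("adenoma", "cancer")]
    if not comparisons:
        return []
    if apply_prevalence_filter:
        kept = filter_by_prevalence(table, metadata, reference_group, prevalence_threshold)
    else:
        kept = table.genus_names
    if not kept:
        return []
    ref_samples = [
        s for s in metadata.samples_in_group(reference_group) if s in table.data.index
    ]
    ref_prev = prevalence(table, ref_samples)
    values = table.data[kept]
    groups = metadata.group3.reindex(values.index)
    stratum_name = "all"
    if stratum is not None:
        if enterotype_labels is None:
            raise ValidationError("stratum given but enterotype_labels missing")
        in_stratum = enterotype_labels.reindex(values.index) == stratum
        values = values.loc[in_stratum[in_stratum].index]
        groups = groups.loc[values.index]
        stratum_name = stratum
    return _run_tests(values, groups, comparisons, stratum_name, ref_prev, alpha, bh)


def transition_analysis(
    table: GenusAbundanceTable,
    metadata: CohortMetadata,
    ordered_stages: tuple[str, ...] = ("advanced_adenoma", "crc_stage0", "crc_early"),
    alpha: float = DEFAULT_ALPHA,
    prevalence_threshold: float = 0.5,
) -> list[DifferentialResult]:
    """Consecutive-stage rank tests along the adenoma-to-carcinoma sequence.

    The prevalence filter is referenced to the pooled cancer stages.
    """
    if table.kind != "relative":
        raise ValidationError("transition_analysis requires a relative table")
    if len(ordered_stages) < 2:
        raise ValidationError("transition_analysis requires at least 2 stages")
    cancer_samples = [
        s
        for s in metadata.frame.index[metadata.stage6.isin(_CANCER_STAGES)]
        if s in table.data.index
    ]
    if not cancer_samples:
        raise ValidationError("no pooled cancer-stage samples for the prevalence filter")
    prev = prevalence(table, cancer_samples)
    kept = [g for g in table.genus_names if prev[g] > prevalence_threshold]
    if not kept:
        return []
    values = table.data[kept]
    stages = metadata.stage6.reindex(values.index)
    comparisons = [
        (ordered_stages[i], ordered_stages[i + 1]) for i in range(len(ordered_stages) - 1)
    ]
    return _run_tests(values, stages, comparisons, "stages", prev, alpha, bh=False)


def results_to_frame(results: list[DifferentialResult]) -> pd.DataFrame:
    """Flatten a result list to the output-TSV column layout."""
    return pd.DataFrame(
        [
            {
                "genus": r.genus,
                "group_a": r.comparison[0],
                "group_b": r.comparison[1],
                "stratum": r.stratum,
                "u_statistic": r.u_statistic,
                "p_value": r.p_value,
                "prevalence_in_reference": r.prevalence_in_reference,
                "direction": r.direction,
                "significant": r.significant,
            }
            for r in results
        ]
    )
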