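"""Per-sample alpha diversity (genus richness, Shannon index) and group comparisons."""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd

from .abundance_io import CohortMetadata, GenusAbundanceTable, ValidationError
from .differential import DEFAULT_ALPHA, mann_whitney_two_sided

__all__ = ["richness", "shannon", "diversity_table", "compare_diversity"]


def richness(sample) -> int:
    """Count of genera with strictly positive abundance."""
    v = np.asarray(sample, dtype=float)
    if (v < 0).any():
        raise ValidationError("abundance vector has negative entries")
    r = int((v > 0).sum())
    if r == 0:
        raise ValidationError("all-zero abundance vector")
    return r


def shannon(sample, base: float | None = None) -> float:
    """Shannon index H = -sum p ln p over positive entries, in nats by
    default; pass ``base`` for another logarithm base."""
    v = np.asarray(sample, dtype=float)
    if (v < 0).any():
        raise ValidationError("abundance vector has negative entries")
    total = v.sum()
    if total <= 0:
        raise ValidationError("all-zero abundance vector")
    p = v[v > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= float(np.log(base))
    return max(h, 0.0)


def diversity_table(table: GenusAbundanceTable) -> pd.DataFrame:
    """Richness, Shannon (nats), and log2 richness for every sample."""
    records = []
    for sid in table.sample_ids:
        row = table.data.loc[sid].to_numpy(dtype=float)
        r = richness(row)
        records.append(
            {
                "sample_id": sid,
                "richness": r,
                "shannon": shannon(row),
                "log2_richness": float(np.log2(r)),
            }
        )
    return pd.DataFrame(records).set_index("sample_id")


def compare_diversity(
    results: pd.DataFrame,
    metadata: CohortMetadata,
    metric: str = "richness",
    stratum: str | None = None,
    enterotype_labels: pd.Series | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney comparisons of a diversity metric
    between the three disease groups, optionally within one enterotype.

    Pairs where either group has fewer than 2 samples are skipped with a
    warning.  Returns one row per tested pair.
    """
    if metric not in results.columns:
        raise ValidationError(f"metric {metric!r} not in results columns")
    values = results[metric]
    groups = metadata.group3.reindex(values.index)
    stratum_name = "all"
    if stratum is not None:
        if enterotype_labels is None:
            raise ValidationError("stratum given but enterotype_labels missing")
        mask = enterotype_labels.reindex(values.index) == stratum
        values, groups = values[mask], groups[mask]
        stratum_name = stratum
    rows = []
    for a, b in combinations(pd.unique(groups.dropna()), 2):
        va = values[groups == a].to_numpy(dtype=float)
        vb = values[groups == b].to_numpy(dtype=float)
        if len(va) < 2 or len(vb) < 2:
            warnings.warn(
                f"diversity pair ({a}, {b}) in stratum {stratum_name!r} skipped: "
                f"sizes {len(va)} vs {len(vb)}",
                stacklevel=2,
            )
            continue
        u, p = mann_whitney_two_sided(va, vb)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "stratum": stratum_name,
                "metric": metric,
                "median_a": float(np.median(va)),
                "median_b": float(np.median(vb)),
                "u_statistic": u,
                "p_value": p,
                "significant": p < alpha,
            }
        )
    return pd.DataFrame(rows)
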