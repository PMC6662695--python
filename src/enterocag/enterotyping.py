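"""Threshold enterotyping and supporting ordination.

A sample is enterotype I when its Bacteroides relative abundance is at
least 40% and exceeds Prevotella's; enterotype II when Prevotella reaches
30% and is at least Bacteroides'; everything else is enterotype III (the
Escherichia-mixed residual class).  Assignment never depends on the
ordination, which is descriptive only.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon, pdist, squareform

from .abundance_io import CohortMetadata, GenusAbundanceTable, GROUP3_LEVELS, ValidationError

__all__ = [
    "EnterotypeLabel",
    "assign_enterotype",
    "enterotype_cohort",
    "pcoa_ordination",
    "BACTEROIDES",
    "PREVOTELLA",
]

BACTEROIDES = "Bacteroides"
PREVOTELLA = "Prevotella"

RA_B_THRESHOLD = 0.40
RA_P_THRESHOLD = 0.30


@dataclass(frozen=True)
class EnterotypeLabel:
    label: str  # "I" | "II" | "III"
    ra_b: float
    ra_p: float


def assign_enterotype(composition: Mapping[str, float] | pd.Series) -> EnterotypeLabel:
    """Classify one relative-abundance composition by the threshold rule.

    Missing Bacteroides/Prevotella keys read as 0.  The composition must
    be non-negative and sum to 1 within 1e-6.
    """
    if isinstance(composition, pd.Series):
        values = composition.astype(float)
    else:
        values = pd.Series(dict(composition), dtype=float)
    arr = values.to_numpy()
    if arr.size == 0:
        raise ValidationError("empty composition")
    if (arr < 0).any():
        bad = values.index[int(np.argmax(arr < 0))]
        raise ValidationError(f"negative relative abundance for {bad!r}")
    total = arr.sum()
    if abs(total - 1.0) > 1e-6:
        raise ValidationError(f"composition sums to {total!r}, not 1")
    ra_b = float(values.get(BACTEROIDES, 0.0))
    ra_p = float(values.get(PREVOTELLA, 0.0))
    if ra_b >= RA_B_THRESHOLD and ra_b > ra_p:
        label = "I"
    elif ra_p >= RA_P_THRESHOLD and ra_p >= ra_b:
        label = "II"
    else:
        label = "III"
    return EnterotypeLabel(label, ra_b, ra_p)


def enterotype_cohort(
    table: GenusAbundanceTable, metadata: CohortMetadata
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label every sample and tabulate group3 x enterotype counts.

    Returns ``(labels, contingency)`` where ``labels`` has one row per
    sample (enterotype, ra_b, ra_p) and ``contingency`` is the 3x3
    group3 x enterotype count matrix.
    """
    if table.kind != "relative":
        raise ValidationError("enterotype_cohort requires a relative table")
    missing = [s for s in table.sample_ids if s not in metadata.frame.index]
    if missing:
        raise ValidationError(f"samples missing from metadata: {missing[:5]}")
    if not table.sample_ids:
        raise ValidationError("table and metadata share no samples")
    records = []
    for sid in table.sample_ids:
        lab = assign_enterotype(table.data.loc[sid])
        records.append(
            {"sample_id": sid, "enterotype": lab.label, "ra_b": lab.ra_b, "ra_p": lab.ra_p}
        )
    labels = pd.DataFrame(records).set_index("sample_id")
    groups = metadata.group3.loc[labels.index]
    contingency = (
        pd.crosstab(groups, labels["enterotype"])
        .reindex(index=list(GROUP3_LEVELS), columns=["I", "II", "III"], fill_value=0)
    )
    contingency.index.name = "group3"
    return labels, contingency


def _distance_matrix(rel: np.ndarray, distance: str) -> np.ndarray:
    if distance == "bray_curtis":
        return squareform(pdist(rel, metric="braycurtis"))
    if distance == "jensen_shannon":
        return squareform(pdist(rel, metric=lambda u, v: jensenshannon(u, v, base=np.e)))
    raise ValueError(f"unknown distance {distance!r}")


def pcoa_ordination(
    table: GenusAbundanceTable, distance: str = "bray_curtis", axes: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical metric scaling (PCoA) of pairwise sample distances.

    Returns per-sample coordinates on the first ``axes`` axes and the
    eigenvalue fractions (negative eigenvalues clipped to 0).
    """
    n = len(table.sample_ids)
    if n < 3:
        raise ValidationError("pcoa_ordination requires at least 3 samples")
    rel = table.data.to_numpy(dtype=float)
    row_sums = rel.sum(axis=1, keepdims=True)
    if (row_sums <= 0).any():
        raise ValidationError("sample with zero total abundance")
    rel = rel / row_sums
    d = _distance_matrix(rel, distance)
    # Gower double-centering: B = -1/2 J D^2 J
    d2 = d**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = np.clip(eigvals, 0.0, None)
    coords = eigvecs * np.sqrt(pos)
    fractions = pos / pos.sum() if pos.sum() > 0 else pos
    k = min(axes, n)
    frame = pd.DataFrame(
        coords[:, :k],
        index=table.data.index,
        columns=[f"axis{i + 1}" for i in range(k)],
    )
    frame.index.name = "sample_id"
    return frame, fractions
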