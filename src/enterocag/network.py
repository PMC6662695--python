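"""Per-group Pearson correlation networks and the stable-anchor analysis.

The anchor is the largest cluster whose member set is identical in every
supplied partition (strict reading; an optional Jaccard-relaxed mode is
available).  Genera outside the anchor are profiled by their per-group
mean Pearson correlation to anchor members, and flagged when the range
of that profile across groups reaches the variability threshold.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd

from .abundance_io import CohortMetadata, GenusAbundanceTable, ValidationError
from .cag import CAGPartition, correlation_matrix

__all__ = [
    "pearson_network",
    "find_stable_cag",
    "anchor_correlation_profile",
    "variable_genera",
    "network_to_edgelist",
    "DEFAULT_EDGE_THRESHOLD",
    "DEFAULT_VARIABILITY_THRESHOLD",
]

DEFAULT_EDGE_THRESHOLD = 0.5
DEFAULT_VARIABILITY_THRESHOLD = 0.4


def pearson_network(
    table: GenusAbundanceTable,
    sample_subset=None,
    genus_subset=None,
    edge_threshold: float = DEFAULT_EDGE_THRESHOLD,
    group: str = "",
    stratum: str = "",
) -> nx.Graph:
    """Undirected network with an edge wherever |Pearson r| >= threshold.

    Constant genera are excluded with a warning.  ``group``/``stratum``
    are recorded as graph attributes for provenance.
    """
    sub = table.subset(sample_ids=sample_subset, genus_names=genus_subset).data
    if len(sub) < 3:
        raise ValidationError("pearson_network requires at least 3 samples")
    constant = sub.columns[sub.nunique() <= 1].tolist()
    if constant:
        warnings.warn(f"excluding constant genera from network: {constant}")
        sub = sub.drop(columns=constant)
    if sub.shape[1] < 2:
        raise ValidationError("fewer than 2 non-constant genera")
    corr = sub.corr(method="pearson")
    graph = nx.Graph(group=group, stratum=stratum, edge_threshold=edge_threshold)
    graph.add_nodes_from(corr.columns)
    cols = list(corr.columns)
    values = corr.to_numpy()
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            r = float(values[i, j])
            if abs(r) >= edge_threshold:
                graph.add_edge(cols[i], cols[j], r=r)
    return graph


def network_to_edgelist(graph: nx.Graph) -> pd.DataFrame:
    rows = [
        {
            "genus_a": a,
            "genus_b": b,
            "r": d["r"],
            "group": graph.graph.get("group", ""),
            "stratum": graph.graph.get("stratum", ""),
        }
        for a, b, d in graph.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["genus_a", "genus_b", "r", "group", "stratum"])


def _jaccard(a: frozenset, b: frozenset) -> float:
    return len(a & b) / len(a | b) if a | b else 0.0


def find_stable_cag(
    partitions: list[CAGPartition],
    relaxed: bool = False,
    jaccard_threshold: float = 0.8,
) -> tuple[str, ...]:
    """Largest cluster whose member set recurs in every partition.

    Strict mode requires exact member-set identity; relaxed mode accepts a
    Jaccard match >= ``jaccard_threshold`` in each other partition (the
    returned set is the first partition's version).  Returns an empty
    tuple when no cluster is stable.  Ties break toward the
    lexicographically smallest member.
    """
    if len(partitions) < 2:
        raise ValidationError("find_stable_cag requires at least 2 partitions")
    universes = [set(p.assignments) for p in partitions]
    if not set.intersection(*universes):
        raise ValidationError("partitions share no genera")
    cluster_sets = [
        {frozenset(members) for members in p.clusters().values()} for p in partitions
    ]
    candidates = []
    for cand in cluster_sets[0]:
        if relaxed:
            ok = all(
                any(_jaccard(cand, other) >= jaccard_threshold for other in others)
                for others in cluster_sets[1:]
            )
        else:
            ok = all(cand in others for others in cluster_sets[1:])
        if ok:
            candidates.append(cand)
    if not candidates:
        return ()
    best = sorted(candidates, key=lambda s: (-len(s), min(s)))[0]
    return tuple(sorted(best))


def anchor_correlation_profile(
    table: GenusAbundanceTable,
    metadata: CohortMetadata,
    anchor,
    genus: str,
    groups=("normal", "adenoma", "cancer"),
) -> dict[str, float]:
    """Per-group mean Pearson correlation of one genus to the anchor members.

    Groups where the genus (or an anchor member) is constant yield NaN and
    are excluded from downstream variability scoring.
    """
    anchor = [g for g in anchor]
    if genus in anchor:
        raise ValidationError(f"genus {genus!r} is an anchor member")
    missing = [g for g in anchor + [genus] if g not in table.data.columns]
    if missing:
        raise ValidationError(f"genera absent from table: {missing}")
    profile: dict[str, float] = {}
    for group in groups:
        samples = [s for s in metadata.samples_in_group(group) if s in table.data.index]
        if len(samples) < 3:
            raise ValidationError(f"group {group!r} has fewer than 3 samples")
        sub = table.data.loc[samples, anchor + [genus]]
        if sub[genus].nunique() <= 1:
            profile[group] = float("nan")
            continue
        rs = []
        for member in anchor:
            if sub[member].nunique() <= 1:
                continue
            rs.append(float(np.corrcoef(sub[genus], sub[member])[0, 1]))
        profile[group] = float(np.mean(rs)) if rs else float("nan")
    return profile


def variable_genera(
    profiles: pd.DataFrame,
    variability_threshold: float = DEFAULT_VARIABILITY_THRESHOLD,
) -> pd.DataFrame:
    """Flag genera whose per-group anchor correlation varies widely.

    ``profiles`` is genus x group (values may contain NaN for undefined
    groups); a genus is scored only when >= 2 groups are defined, by
    max - min across defined groups, and flagged when the score reaches
    the threshold.  Output is sorted by score descending.
    """
    if profiles.empty:
        return pd.DataFrame(columns=["genus", "variability", "flagged"])
    rows = []
    for genus, row in profiles.iterrows():
        defined = row.dropna()
        if len(defined) < 2:
            continue
        score = float(defined.max() - defined.min())
        rows.append(
            {
                "genus": genus,
                "variability": score,
                "flagged": score >= variability_threshold,
            }
        )
    out = pd.DataFrame(rows, columns=["genus", "variability", "flagged"])
    return out.sort_values("variability", ascending=False).reset_index(drop=True)
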