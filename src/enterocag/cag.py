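"""Co-abundance groups: correlation matrices, hierarchical clustering,
per-sample CAG abundances, group comparisons, and training-set selection.

CAGs are clusters of an agglomerative tree built on distance d = 1 - r
(r = Spearman by default, Pearson selectable).  The cluster count is
either fixed or chosen by a silhouette scan over K = 2..12.  Combination
selection scores each candidate training set by leave-one-out
nearest-centroid accuracy on the target group pair in CAG-abundance space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .abundance_io import CohortMetadata, GenusAbundanceTable, ValidationError
from .differential import (
    DEFAULT_ALPHA,
    DifferentialResult,
    filter_by_prevalence,
    mann_whitney_two_sided,
)

__all__ = [
    "CAGPartition",
    "correlation_matrix",
    "define_cags",
    "cag_abundance",
    "compare_cag_abundance",
    "select_training_combination",
]

K_SCAN_RANGE = (2, 12)


@dataclass(frozen=True)
class CAGPartition:
    """Genus -> cluster-id mapping plus the parameters that produced it."""

    assignments: dict  # genus -> int in 1..k
    correlation_method: str
    linkage: str
    distance: str
    k: int
    source_groups: tuple[str, ...] = ()
    correlation: pd.DataFrame | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        ids = sorted(set(self.assignments.values()))
        if ids != list(range(1, self.k + 1)):
            raise ValidationError(f"cluster ids {ids} are not contiguous 1..{self.k}")

    def members(self, cluster_id: int) -> tuple[str, ...]:
        return tuple(g for g, c in self.assignments.items() if c == cluster_id)

    def clusters(self) -> dict[int, tuple[str, ...]]:
        return {cid: self.members(cid) for cid in range(1, self.k + 1)}


def correlation_matrix(
    table: GenusAbundanceTable,
    sample_subset=None,
    genus_subset=None,
    method: str = "spearman",
) -> pd.DataFrame:
    """Symmetric genus x genus correlation matrix over a sample subset."""
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method {method!r}")
    sub = table.subset(sample_ids=sample_subset, genus_names=genus_subset).data
    if len(sub) < 3:
        raise ValidationError("correlation_matrix requires at least 3 samples")
    if sub.shape[1] < 2:
        raise ValidationError("correlation_matrix requires at least 2 genera")
    constant = sub.columns[(sub.nunique() <= 1)].tolist()
    if constant:
        raise ValidationError(f"constant genera in subset: {constant}")
    corr = sub.corr(method=method)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def _contiguous_relabel(labels: np.ndarray) -> np.ndarray:
    """Relabel cluster ids to 1..K by order of first appearance."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def define_cags(
    corr: pd.DataFrame,
    linkage: str = "average",
    k: int | None = None,
    k_range: tuple[int, int] = K_SCAN_RANGE,
    correlation_method: str = "spearman",
    source_groups: tuple[str, ...] = (),
) -> CAGPartition:
    """Cut an agglomerative tree on d = 1 - r into K co-abundance groups.

    With ``k=None`` the cut is chosen by maximizing the mean silhouette
    over ``k_range`` (ties -> smaller K); degenerate matrices fall back
    to K = 2 with a warning.
    """
    genera = list(corr.index)
    n = len(genera)
    if k is not None and (k < 1 or k > n):
        raise ValidationError(f"k={k} out of range for {n} genera")
    dist = 1.0 - corr.to_numpy(dtype=float)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    condensed = squareform(dist, checks=False)
    tree = hierarchy.linkage(condensed, method=linkage)
    if k is not None:
        # cut_tree returns exactly k clusters even under tied merge heights
        labels = hierarchy.cut_tree(tree, n_clusters=k).ravel() + 1
        chosen = k
    elif condensed.size and np.allclose(condensed, condensed[0]):
        # all pairwise correlations equal: no structure for the scan to find
        warnings.warn("silhouette scan degenerate (all correlations equal); returning K=2")
        labels = hierarchy.cut_tree(tree, n_clusters=2).ravel() + 1
        chosen = 2
    else:
        lo, hi = k_range
        hi = min(hi, n - 1)
        best, chosen, labels = -np.inf, None, None
        for cand in range(lo, hi + 1):
            cand_labels = hierarchy.fcluster(tree, t=cand, criterion="maxclust")
            if len(set(cand_labels)) < 2:
                continue
            try:
                score = silhouette_score(dist, cand_labels, metric="precomputed")
            except ValueError:
                continue
            if score > best + 1e-12:
                best, chosen, labels = score, cand, cand_labels
        if labels is None:
            warnings.warn("degenerate correlation matrix; falling back to K=2")
            labels = hierarchy.fcluster(tree, t=2, criterion="maxclust")
            chosen = 2
        elif best <= 1e-9:
            warnings.warn(
                "silhouette scan degenerate (no separation); returning smallest K"
            )
    labels = _contiguous_relabel(np.asarray(labels))
    chosen = int(labels.max())
    return CAGPartition(
        assignments=dict(zip(genera, (int(x) for x in labels))),
        correlation_method=correlation_method,
        linkage=linkage,
        distance="1 - r",
        k=chosen,
        source_groups=tuple(source_groups),
        correlation=corr,
    )


def cag_abundance(
    table: GenusAbundanceTable, partition: CAGPartition
) -> pd.DataFrame:
    """Per-sample summed relative abundance of each CAG's member genera.

    Columns are ``CAG1..CAGK``; mass is conserved exactly (the row total
    equals the summed relative abundance of clustered genera).
    """
    if table.kind != "relative":
        raise ValidationError("cag_abundance requires a relative table")
    missing = [g for g in partition.assignments if g not in table.data.columns]
    if missing:
        raise ValidationError(f"partition references genera absent from table: {missing}")
    profile = pd.DataFrame(index=table.data.index)
    for cid, members in partition.clusters().items():
        profile[f"CAG{cid}"] = table.data[list(members)].sum(axis=1)
    profile.index.name = "sample_id"
    return profile


def compare_cag_abundance(
    profiles: pd.DataFrame,
    metadata: CohortMetadata,
    comparisons: list[tuple[str, str]] | None = None,
    stratum: str | None = None,
    enterotype_labels: pd.Series | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> list[DifferentialResult]:
    """Mann-Whitney comparison of each CAG's abundance between group pairs."""
    if comparisons is None:
        comparisons = [("normal", "adenoma"), ("normal", "cancer"), ("adenoma", "cancer")]
    values = profiles
    groups = metadata.group3.reindex(values.index)
    stratum_name = "all"
    if stratum is not None:
        if enterotype_labels is None:
            raise ValidationError("stratum given but enterotype_labels missing")
        mask = enterotype_labels.reindex(values.index) == stratum
        values, groups = values.loc[mask[mask].index], groups[mask]
        stratum_name = stratum
    results = []
    for a, b in comparisons:
        sa = groups.index[groups == a]
        sb = groups.index[groups == b]
        if len(sa) < 2 or len(sb) < 2:
            warnings.warn(
                f"CAG comparison ({a}, {b}) in stratum {stratum_name!r} skipped",
                stacklevel=2,
            )
            continue
        for cag in values.columns:
            va = values.loc[sa, cag].to_numpy(dtype=float)
            vb = values.loc[sb, cag].to_numpy(dtype=float)
            u, p = mann_whitney_two_sided(va, vb)
            diff = float(np.median(vb) - np.median(va))
            results.append(
                DifferentialResult(
                    genus=cag,
                    comparison=(a, b),
                    stratum=stratum_name,
                    u_statistic=u,
                    p_value=p,
                    prevalence_in_reference=1.0,
                    direction=(
                        "up_in_second" if diff > 0 else "down_in_second" if diff < 0 else "none"
                    ),
                    significant=p < alpha,
                )
            )
    return sorted(results, key=lambda r: r.p_value)


def _loo_nearest_centroid_accuracy(
    profiles: pd.DataFrame, groups: pd.Series, target_pair: tuple[str, str]
) -> float:
    """Leave-one-out nearest-centroid accuracy on the two target groups."""
    a, b = target_pair
    idx_a = groups.index[groups == a]
    idx_b = groups.index[groups == b]
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValidationError(f"target pair {target_pair} needs >= 2 samples per group")
    xa = profiles.loc[idx_a].to_numpy(dtype=float)
    xb = profiles.loc[idx_b].to_numpy(dtype=float)
    sum_a, sum_b = xa.sum(axis=0), xb.sum(axis=0)
    na, nb = len(xa), len(xb)
    correct = 0
    for x in xa:
        ca = (sum_a - x) / (na - 1)
        cb = sum_b / nb
        correct += int(np.linalg.norm(x - ca) <= np.linalg.norm(x - cb))
    for x in xb:
        ca = sum_a / na
        cb = (sum_b - x) / (nb - 1)
        correct += int(np.linalg.norm(x - cb) < np.linalg.norm(x - ca))
    return correct / (na + nb)


def select_training_combination(
    table: GenusAbundanceTable,
    metadata: CohortMetadata,
    combinations: list[tuple[str, ...]],
    target_pair: tuple[str, str] = ("adenoma", "cancer"),
    correlation_method: str = "spearman",
    linkage: str = "average",
    k: int | None = None,
    prevalence_threshold: float = 0.5,
) -> tuple[pd.DataFrame, CAGPartition]:
    """Score candidate group combinations for building the CAG partition.

    For each combination, CAGs are built from that combination's samples
    only; profiles are computed for *all* samples, and the combination is
    scored by leave-one-out nearest-centroid accuracy on the target pair.
    Ties break toward fewer source groups, then lexicographic name.
    Returns the ranking table and the winning partition.
    """
    if not combinations:
        raise ValidationError("empty combination list")
    if table.kind != "relative":
        raise ValidationError("select_training_combination requires a relative table")
    kept = filter_by_prevalence(table, metadata, threshold=prevalence_threshold)
    if len(kept) < 2:
        raise ValidationError("fewer than 2 genera pass the prevalence filter")
    groups = metadata.group3.reindex(table.data.index)
    rows = []
    partitions = {}
    for combo in combinations:
        combo = tuple(combo)
        samples = [s for s in table.data.index if groups[s] in combo]
        if not samples:
            raise ValidationError(f"combination {combo} selects no samples")
        # genera constant within the training samples cannot be correlated
        sub = table.data.loc[samples, kept]
        usable = [g for g in kept if sub[g].nunique() > 1]
        corr = correlation_matrix(table, samples, usable, method=correlation_method)
        part = define_cags(
            corr,
            linkage=linkage,
            k=k,
            correlation_method=correlation_method,
            source_groups=combo,
        )
        profiles = cag_abundance(table, part)
        score = _loo_nearest_centroid_accuracy(profiles, groups, target_pair)
        name = "+".join(combo)
        partitions[name] = part
        rows.append({"combination": name, "n_groups": len(combo), "k": part.k, "score": score})
    ranking = pd.DataFrame(rows).sort_values(
        by=["score", "n_groups", "combination"], ascending=[False, True, True]
    ).reset_index(drop=True)
    winner = partitions[ranking.iloc[0]["combination"]]
    return ranking, winner
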