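"""Genus-level abundance tables and cohort metadata: reading, validation, transforms.

The two container types defined here (:class:`GenusAbundanceTable`,
:class:`CohortMetadata`) are the substrate of every downstream stage.
Tables are held samples-in-rows; TSV files are expected in the same
orientation (first column = sample id) unless ``transpose=True``.
"""

from __future__ import annotations

import json
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenusAbundanceTable",
    "CohortMetadata",
    "STAGE6_LEVELS",
    "GROUP3_LEVELS",
    "STAGE6_TO_GROUP3",
    "read_abundance_table",
    "write_abundance_table",
    "merge_to_genus",
    "to_relative",
    "prevalence",
    "log2_transform",
]

STAGE6_LEVELS = (
    "normal",
    "small_adenoma",
    "advanced_adenoma",
    "crc_stage0",
    "crc_early",
    "crc_late",
)
GROUP3_LEVELS = ("normal", "adenoma", "cancer")
STAGE6_TO_GROUP3 = {
    "normal": "normal",
    "small_adenoma": "adenoma",
    "advanced_adenoma": "adenoma",
    "crc_stage0": "cancer",
    "crc_early": "cancer",
    "crc_late": "cancer",
}

UNCLASSIFIED = "unclassified"

#: rows summing to 1 within this tolerance are taken as relative abundances
_RELATIVE_ROWSUM_TOL = 0.01


class ValidationError(ValueError):
    """Raised when a table or metadata object violates its invariants."""


@dataclass(frozen=True)
class GenusAbundanceTable:
    """Samples x genera abundance matrix with a counts/relative kind flag.

    ``data`` is indexed by sample id with genus names as columns.  All
    values are non-negative and finite; for ``kind='relative'`` every row
    sums to 1 within 1e-9.
    """

    data: pd.DataFrame
    kind: str  # "counts" | "relative"

    def __post_init__(self) -> None:
        if self.kind not in ("counts", "relative"):
            raise ValidationError(f"unknown table kind {self.kind!r}")
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate genus names: {dups}")
        values = df.to_numpy(dtype=float)
        if values.size and not np.isfinite(values).all():
            raise ValidationError("table contains non-finite or missing entries")
        if values.size and (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative abundance at sample {df.index[i]!r}, genus {df.columns[j]!r}"
            )
        if self.kind == "relative" and len(df):
            sums = values.sum(axis=1)
            bad = np.abs(sums - 1.0) > 1e-9
            if bad.any():
                sid = df.index[np.argmax(bad)]
                raise ValidationError(
                    f"relative table row {sid!r} sums to {sums[np.argmax(bad)]!r}, not 1"
                )

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def genus_names(self) -> list:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def composition(self, sample_id) -> pd.Series:
        """Relative-abundance vector of one sample (normalized on the fly)."""
        row = self.data.loc[sample_id].astype(float)
        total = row.sum()
        if total <= 0:
            raise ValidationError(f"sample {sample_id!r} has zero total abundance")
        return row / total

    def subset(self, sample_ids=None, genus_names=None) -> "GenusAbundanceTable":
        df = self.data
        if sample_ids is not None:
            missing = [s for s in sample_ids if s not in df.index]
            if missing:
                raise KeyError(f"unknown sample ids: {missing}")
            df = df.loc[list(sample_ids)]
        if genus_names is not None:
            missing = [g for g in genus_names if g not in df.columns]
            if missing:
                raise KeyError(f"unknown genera: {missing}")
            df = df[list(genus_names)]
        # subsetting a relative table breaks the row-sum invariant
        kind = self.kind if genus_names is None else "counts"
        return GenusAbundanceTable(df.copy(), kind)


@dataclass
class CohortMetadata:
    """Per-sample clinical metadata with the six-stage / three-group labels.

    ``frame`` is indexed by sample id and carries ``stage6`` plus any
    covariate columns; ``group3`` is derived deterministically from
    ``stage6`` (small/advanced adenoma -> adenoma, all crc_* -> cancer).
    The literal string ``"Unknown"`` is a covariate level, not missing data.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates:
            dups = self.frame.index[self.frame.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids in metadata: {dups}")
        if "stage6" not in self.frame.columns:
            raise ValidationError("metadata requires a 'stage6' column")
        bad = set(self.frame["stage6"]) - set(STAGE6_LEVELS)
        if bad:
            raise ValidationError(f"unknown stage6 levels: {sorted(bad)}")
        self.frame = self.frame.copy()
        self.frame["group3"] = self.frame["stage6"].map(STAGE6_TO_GROUP3)

    @property
    def sample_ids(self) -> list:
        return list(self.frame.index)

    @property
    def stage6(self) -> pd.Series:
        return self.frame["stage6"]

    @property
    def group3(self) -> pd.Series:
        return self.frame["group3"]

    def samples_in_group(self, group: str) -> list:
        if group in GROUP3_LEVELS:
            mask = self.frame["group3"] == group
        elif group in STAGE6_LEVELS:
            mask = self.frame["stage6"] == group
        else:
            raise KeyError(
                f"unknown group label {group!r}; expected one of "
                f"{GROUP3_LEVELS + STAGE6_LEVELS}"
            )
        return list(self.frame.index[mask])

    @classmethod
    def from_tsv(cls, path) -> "CohortMetadata":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        if df.columns[0] != "sample_id":
            raise ValidationError(
                f"first metadata column must be 'sample_id', got {df.columns[0]!r}"
            )
        df = df.set_index("sample_id")
        return cls(df)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# reading / writing


def _infer_kind(values: np.ndarray) -> str:
    if values.size == 0:
        raise ValidationError("cannot infer kind of an empty table")
    if np.allclose(values, np.round(values)) and values.max(initial=0.0) > 1.0 + 1e-9:
        return "counts"
    row_sums = values.sum(axis=1)
    if np.all(np.abs(row_sums - 1.0) <= _RELATIVE_ROWSUM_TOL):
        return "relative"
    if np.allclose(values, np.round(values)):
        return "counts"
    raise ValidationError(
        "ambiguous table: values are not integer counts and rows do not sum to 1; "
        "pass kind explicitly"
    )


def read_abundance_table(
    path, format: str = "tsv", kind: str | None = None, transpose: bool = False
) -> GenusAbundanceTable:
    """Read a genus abundance table from TSV or BIOM 1.0 (JSON).

    TSV orientation is samples-in-rows (first column = sample id); set
    ``transpose=True`` for genera-in-rows files.  BIOM files use the
    format's native observations x samples orientation.  ``kind`` is
    inferred when omitted: integer-valued tables are counts, tables whose
    rows sum to ~1 are relative; anything else is rejected.
    """
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
            raise ValidationError(f"malformed TSV {path}: {exc}") from exc
        non_numeric = df.columns[
            [not np.issubdtype(dt, np.number) for dt in df.dtypes]
        ].tolist()
        if non_numeric:
            raise ValidationError(f"non-numeric columns in {path}: {non_numeric}")
    elif format == "biom":
        df = _read_biom_json(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    if transpose:
        df = df.T
    values = df.to_numpy(dtype=float)
    if values.size and (values < 0).any():
        raise ValidationError(f"negative entries in {path}")
    if kind is None:
        kind = _infer_kind(values)
    return GenusAbundanceTable(df, kind)


def write_abundance_table(table: GenusAbundanceTable, path, format: str = "tsv") -> None:
    if format == "tsv":
        table.data.to_csv(path, sep="\t", index_label="sample_id")
    elif format == "biom":
        _write_biom_json(table, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _read_biom_json(path) -> pd.DataFrame:
    """Minimal BIOM 1.0 (JSON) reader; dense and sparse matrix types."""
    with open(path) as fh:
        doc = json.load(fh)
    try:
        n_obs, n_samp = doc["shape"]
        obs_ids = [r["id"] for r in doc["rows"]]
        samp_ids = [c["id"] for c in doc["columns"]]
        matrix_type = doc["matrix_type"]
        data = doc["data"]
    except KeyError as exc:
        raise ValidationError(f"malformed BIOM file {path}: missing field {exc}") from exc
    mat = np.zeros((n_obs, n_samp), dtype=float)
    if matrix_type == "dense":
        mat[:] = np.asarray(data, dtype=float)
    elif matrix_type == "sparse":
        for i, j, v in data:
            mat[int(i), int(j)] = v
    else:
        raise ValidationError(f"unsupported BIOM matrix_type {matrix_type!r}")
    # BIOM is observations x samples; flip to samples-in-rows
    return pd.DataFrame(mat.T, index=samp_ids, columns=obs_ids)


def _write_biom_json(table: GenusAbundanceTable, path) -> None:
    values = table.data.to_numpy(dtype=float)
    data = [
        [int(i), int(j), float(values[j, i])]
        for i in range(values.shape[1])
        for j in range(values.shape[0])
        if values[j, i] != 0
    ]
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "enterocag",
        "date": "",
        "matrix_type": "sparse",
        "matrix_element_type": "int" if table.kind == "counts" else "float",
        "shape": [table.shape[1], table.shape[0]],
        "rows": [{"id": g, "metadata": None} for g in table.genus_names],
        "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
        "data": data,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


# ---------------------------------------------------------------------------
# transforms


def merge_to_genus(
    otu_values: pd.DataFrame, taxonomy: Mapping[str, str]
) -> GenusAbundanceTable:
    """Collapse a samples x OTUs matrix to genus level by summing member OTUs.

    OTUs missing from ``taxonomy`` are routed to the reserved genus
    ``"unclassified"`` rather than dropped, so per-sample totals are
    conserved exactly.
    """
    if not len(taxonomy):
        raise ValidationError("empty taxonomy map")
    genus_of = {otu: taxonomy.get(otu, UNCLASSIFIED) for otu in otu_values.columns}
    merged = otu_values.T.groupby(
        otu_values.columns.map(genus_of.get), sort=False
    ).sum().T
    kind = _infer_kind(merged.to_numpy(dtype=float))
    return GenusAbundanceTable(merged, kind)


def to_relative(table: GenusAbundanceTable) -> GenusAbundanceTable:
    """Normalize every sample row to sum to 1 (idempotent on relative input)."""
    values = table.data.to_numpy(dtype=float)
    sums = values.sum(axis=1)
    if (sums <= 0).any():
        sid = table.data.index[int(np.argmax(sums <= 0))]
        raise ValidationError(f"sample {sid!r} has zero total abundance")
    rel = values / sums[:, None]
    # renormalize exactly so the 1e-9 row-sum invariant holds under float error
    rel = rel / rel.sum(axis=1)[:, None]
    df = pd.DataFrame(rel, index=table.data.index, columns=table.data.columns)
    return GenusAbundanceTable(df, "relative")


def prevalence(
    table: GenusAbundanceTable, sample_subset: Iterable | None = None
) -> pd.Series:
    """Per-genus fraction of (subset) samples where the genus is present (> 0)."""
    if sample_subset is None:
        sub = table.data
    else:
        subset = list(sample_subset)
        if not subset:
            raise ValidationError("empty sample subset")
        missing = [s for s in subset if s not in table.data.index]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        sub = table.data.loc[subset]
    if not len(sub):
        raise ValidationError("empty sample subset")
    return (sub > 0).sum(axis=0) / len(sub)


def log2_transform(values, zero_policy: str = "pseudocount") -> np.ndarray:
    """log2 of a non-negative vector; zeros dropped or replaced by half the
    smallest positive value, per ``zero_policy``."""
    v = np.asarray(values, dtype=float)
    if (v < 0).any():
        raise ValidationError("log2_transform requires non-negative values")
    positive = v[v > 0]
    if zero_policy == "drop":
        return np.log2(positive)
    if zero_policy == "pseudocount":
        if positive.size == 0:
            raise ValidationError("all-zero input: no positive minimum for pseudocount")
        pseudo = positive.min() / 2.0
        return np.log2(np.where(v > 0, v, pseudo))
    raise ValueError(f"unknown zero_policy {zero_policy!r}")
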