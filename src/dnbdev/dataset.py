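"""Expression matrices bound to sample metadata.

The central container is :class:`ExpressionDataset`: a gene x sample numeric
matrix together with per-sample metadata (species, age in years).  Columns are
kept in ascending-age order within species, which is the order every
downstream sliding-window computation assumes.

Normalisation maps each sample (column) to a uniform distribution on (0, 1)
by the rank transform ``value -> rank / (G + 1)`` with average ranks for ties.
The raw matrix is retained alongside the normalised one because fold changes
are only meaningful on the original measurement scale.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger("dnbdev")

SPECIES = ("human", "chimpanzee", "macaque", "synthetic")

__all__ = [
    "SampleMeta",
    "ExpressionDataset",
    "load_expression",
    "read_geo_series_matrix",
    "normalize_uniform",
    "filter_by_age",
]


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sample: identifier, species and age in years."""

    sample_id: str
    species: str
    age_years: float

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(
                f"unknown species {self.species!r}; expected one of {SPECIES}"
            )
        if not np.isfinite(self.age_years) or self.age_years < 0:
            raise ValueError(
                f"age_years must be finite and >= 0, got {self.age_years!r} "
                f"for sample {self.sample_id!r}"
            )


class ExpressionDataset:
    """A gene x sample expression matrix with aligned sample metadata.

    Parameters
    ----------
    values : pandas.DataFrame
        Numeric matrix, genes as rows (unique index), samples as columns.
    meta : pandas.DataFrame
        One row per sample with columns ``sample_id``, ``species``,
        ``age_years``.  Row order must match the column order of ``values``.
    normalized : bool
        Whether ``values`` holds per-sample uniform ranks rather than raw
        measurements.
    raw : pandas.DataFrame, optional
        The pre-normalisation matrix; carried along after
        :meth:`normalize_uniform` so fold changes and ANOVA stay on the
        measurement scale.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        meta: pd.DataFrame,
        *,
        normalized: bool = False,
        raw: pd.DataFrame | None = None,
    ) -> None:
        meta = meta.reset_index(drop=True)
        required = {"sample_id", "species", "age_years"}
        missing = required - set(meta.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        if values.shape[1] != len(meta):
            raise ValueError(
                f"matrix has {values.shape[1]} samples but metadata has {len(meta)}"
            )
        if list(values.columns) != list(meta["sample_id"]):
            raise ValueError("matrix column order does not match metadata order")
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if meta["sample_id"].duplicated().any():
            dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        # validates species / age invariants
        self.sample_meta = [
            SampleMeta(str(r.sample_id), str(r.species), float(r.age_years))
            for r in meta.itertuples()
        ]
        if normalized:
            arr = values.to_numpy()
            if arr.min() <= 0.0 or arr.max() >= 1.0:
                raise ValueError("normalized values must lie strictly in (0, 1)")
        self.values = values
        self.meta = meta
        self.normalized = normalized
        self.raw = raw if raw is not None else (None if normalized else values)

    # -- basic introspection -------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def ages(self) -> np.ndarray:
        return self.meta["age_years"].to_numpy(dtype=float)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        sp = ", ".join(
            f"{s}={n}" for s, n in self.meta["species"].value_counts().items()
        )
        tag = "normalized" if self.normalized else "raw"
        return (
            f"<ExpressionDataset {self.n_genes} genes x {self.n_samples} "
            f"samples ({sp}); {tag}>"
        )

    # -- transformations -----------------------------------------------------

    def normalize_uniform(self) -> "ExpressionDataset":
        """Rank-transform each sample to a uniform distribution on (0, 1)."""
        return normalize_uniform(self)

    def filter_by_age(self, species: str, max_age: float) -> "ExpressionDataset":
        return filter_by_age(self, species, max_age)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionDataset":
        """Column subset (order taken from ``sample_ids``); raw kept aligned."""
        ids = list(sample_ids)
        unknown = [s for s in ids if s not in self.values.columns]
        if unknown:
            raise KeyError(f"unknown sample ids: {unknown[:5]}")
        meta = (
            self.meta.set_index("sample_id").loc[ids].reset_index()
        )
        raw = None if self.raw is None else self.raw[ids]
        return ExpressionDataset(
            self.values[ids], meta, normalized=self.normalized, raw=raw
        )

    def to_tsv(self, matrix_path, meta_path=None) -> None:
        self.values.to_csv(matrix_path, sep="\t", index_label="gene_id")
        if meta_path is not None:
            self.meta.to_csv(meta_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# loading


def _read_meta(meta_path) -> pd.DataFrame:
    sep = None  # sniff TSV vs CSV
    with open(meta_path) as fh:
        head = fh.readline()
    sep = "\t" if "\t" in head else ","
    meta = pd.read_csv(meta_path, sep=sep)
    required = {"sample_id", "species", "age_years"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata file missing columns: {sorted(missing)}")
    meta["sample_id"] = meta["sample_id"].astype(str)
    return meta


def load_expression(matrix_path, meta_path) -> ExpressionDataset:
    """Load a TSV expression matrix plus metadata table.

    The matrix has gene ids in the first column and a header row of sample
    ids.  Rows containing missing or non-numeric entries are dropped (and
    counted in the load report); samples are reordered to ascending age
    within species.  Sample ids must match one-to-one between the two files.
    """
    table = pd.read_csv(matrix_path, sep="\t", index_col=0)
    table.index = table.index.astype(str)
    table.columns = table.columns.astype(str)
    if table.shape[0] == 0 or table.shape[1] == 0:
        raise ValueError(f"empty expression matrix in {matrix_path}")
    if table.index.has_duplicates:
        dups = table.index[table.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {matrix_path}: {dups[:5]}")

    meta = _read_meta(meta_path)
    matrix_samples = set(table.columns)
    meta_samples = set(meta["sample_id"])
    only_matrix = sorted(matrix_samples - meta_samples)
    only_meta = sorted(meta_samples - matrix_samples)
    if only_matrix or only_meta:
        raise ValueError(
            "sample id mismatch between matrix and metadata: "
            f"in matrix only {only_matrix[:5]}, in metadata only {only_meta[:5]}"
        )

    numeric = table.apply(pd.to_numeric, errors="coerce")
    keep = numeric.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    numeric = numeric.loc[keep]
    if numeric.shape[0] == 0:
        raise ValueError("no gene rows left after dropping incomplete rows")

    meta = meta.sort_values(
        ["species", "age_years", "sample_id"], kind="stable"
    ).reset_index(drop=True)
    numeric = numeric[list(meta["sample_id"])]

    report = {
        "genes_kept": int(numeric.shape[0]),
        "genes_dropped": n_dropped,
        "samples_per_species": {
            str(k): int(v) for k, v in meta["species"].value_counts().items()
        },
    }
    logger.info(
        "loaded %d genes (%d dropped) x %d samples: %s",
        report["genes_kept"],
        n_dropped,
        len(meta),
        report["samples_per_species"],
    )
    ds = ExpressionDataset(numeric, meta, normalized=False)
    ds.load_report = report
    return ds


def read_geo_series_matrix(path) -> pd.DataFrame:
    """Read a GEO series-matrix-style expression table.

    Comment/metadata lines beginning with ``!`` are skipped; the remaining
    block is parsed as a tab-separated table with gene/probe ids in the first
    column.  Returns the numeric matrix only; sample metadata (species, age)
    must be supplied separately.
    """
    with open(path) as fh:
        lines = [ln for ln in fh if not ln.startswith("!") and ln.strip()]
    table = pd.read_csv(io.StringIO("".join(lines)), sep="\t", index_col=0)
    table.index = table.index.astype(str).str.strip('"')
    table.columns = table.columns.astype(str).str.strip('"')
    return table.apply(pd.to_numeric, errors="coerce")


# ---------------------------------------------------------------------------
# transforms


def normalize_uniform(ds: ExpressionDataset) -> ExpressionDataset:
    """Per-sample rank transform ``value -> rank / (G + 1)`` (average ties)."""
    if ds.normalized:
        raise ValueError(
            "dataset is already normalized; double rank-normalisation would "
            "silently corrupt downstream fold-change inputs"
        )
    arr = ds.values.to_numpy(dtype=float)
    g = arr.shape[0]
    ranks = np.apply_along_axis(rankdata, 0, arr)
    out = pd.DataFrame(
        ranks / (g + 1), index=ds.values.index, columns=ds.values.columns
    )
    return ExpressionDataset(out, ds.meta, normalized=True, raw=ds.values)


def filter_by_age(
    ds: ExpressionDataset, species: str, max_age: float
) -> ExpressionDataset:
    """Keep samples of ``species`` with age <= ``max_age`` (ascending age)."""
    if max_age <= 0:
        raise ValueError("max_age must be > 0")
    if species not in SPECIES:
        raise ValueError(f"unknown species {species!r}")
    mask = (ds.meta["species"] == species) & (ds.meta["age_years"] <= max_age)
    kept = ds.meta.loc[mask].sort_values(
        ["age_years", "sample_id"], kind="stable"
    )
    if len(kept) < 3:
        raise ValueError(
            f"only {len(kept)} {species} samples with age <= {max_age}; "
            "at least 3 are required for window correlations"
        )
    return ds.subset_samples(list(kept["sample_id"]))


def write_load_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
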