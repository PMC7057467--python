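"""Differential expression around the tipping point.

Genes are tested with a per-gene one-way fixed-effects ANOVA on
``log2(raw + 1)`` values, p-values are adjusted by Benjamini–Hochberg, and a
direction-symmetric fold change is computed on the raw (linear) scale.  A
gene is called differentially expressed (DEG) when adjusted q < 0.01 and
fold change exceeds 2 in either direction — the conventional thresholds for
this kind of developmental comparison.

The fit/results surface mirrors the DNB scan: ``DEGModel(ds, split_age=0.2)``
builds the before/after design, ``fit()`` returns :class:`DEGResults` with a
per-gene table and summary.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dataset import ExpressionDataset

logger = logging.getLogger("dnbdev")

__all__ = [
    "DEGModel",
    "DEGResults",
    "anova_pvalues",
    "bh_fdr",
    "fold_changes",
    "call_degs",
    "overlap_sets",
]


def _raw_matrix(ds: ExpressionDataset) -> pd.DataFrame:
    if ds.raw is None:
        raise ValueError(
            "dataset carries no raw values; differential expression must be "
            "computed on the measurement scale, not on uniform ranks"
        )
    return ds.raw


def anova_pvalues(
    ds: ExpressionDataset, groups: Mapping[str, Sequence[str]]
) -> pd.Series:
    """One-way ANOVA p-value per gene across >= 2 labelled sample groups.

    Computed on ``log2(raw + 1)``.  Genes with zero between- and
    within-group variance get p = 1 (no evidence of change).
    """
    raw = _raw_matrix(ds)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for label, ids in groups.items():
        if len(ids) < 2:
            raise ValueError(f"group {label!r} has {len(ids)} samples; need >= 2")
        missing = [s for s in ids if s not in raw.columns]
        if missing:
            raise KeyError(f"group {label!r} references unknown samples {missing}")

    log = np.log2(raw.to_numpy(dtype=float) + 1.0)
    cols = {s: i for i, s in enumerate(raw.columns)}
    group_idx = [np.asarray([cols[s] for s in ids]) for ids in groups.values()]

    n_total = sum(len(ix) for ix in group_idx)
    k = len(group_idx)
    grand = log[:, np.concatenate(group_idx)].mean(axis=1)
    ss_between = np.zeros(log.shape[0])
    ss_within = np.zeros(log.shape[0])
    for ix in group_idx:
        sub = log[:, ix]
        m = sub.mean(axis=1)
        ss_between += ix.size * (m - grand) ** 2
        ss_within += ((sub - m[:, None]) ** 2).sum(axis=1)

    df1, df2 = k - 1, n_total - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df1) / (ss_within / df2)
    p = stats.f.sf(f, df1, df2)
    degenerate = (ss_between <= 1e-300) & (ss_within <= 1e-300)
    p = np.where(degenerate, 1.0, p)
    # zero within-group variance but real between-group difference: F -> inf
    p = np.where(np.isnan(p) & ~degenerate, 0.0, p)
    return pd.Series(p, index=raw.index, name="p_value")


def bh_fdr(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in the input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_changes(
    ds: ExpressionDataset,
    before: Sequence[str],
    after: Sequence[str],
    pseudocount: float | None = None,
) -> pd.Series:
    """Per-gene linear fold change, (mean after + c) / (mean before + c).

    Computed on raw values.  The default pseudocount is the smallest
    positive entry of the raw matrix, which guards ratios of near-zero
    means without distorting well-expressed genes.
    """
    raw = _raw_matrix(ds)
    if len(before) == 0 or len(after) == 0:
        raise ValueError("both sample sets must be nonempty")
    for s in list(before) + list(after):
        if s not in raw.columns:
            raise KeyError(f"unknown sample id {s!r}")
    arr = raw.to_numpy(dtype=float)
    if pseudocount is None:
        positive = arr[arr > 0]
        pseudocount = float(positive.min()) if positive.size else 1.0
    mb = raw[list(before)].mean(axis=1).to_numpy()
    ma = raw[list(after)].mean(axis=1).to_numpy()
    fc = (ma + pseudocount) / (mb + pseudocount)
    return pd.Series(fc, index=raw.index, name="fold_change")


def call_degs(
    records: pd.DataFrame,
    fdr_threshold: float = 0.01,
    fc_threshold: float = 2.0,
) -> pd.DataFrame:
    """Flag DEGs: q below the FDR threshold and |fold change| beyond the
    fold threshold in either direction (max(FC, 1/FC) > fc_threshold)."""
    if fdr_threshold <= 0 or fc_threshold <= 0:
        raise ValueError("thresholds must be positive")
    out = records.copy()
    sym_fc = np.maximum(out["fold_change"], 1.0 / out["fold_change"])
    out["is_deg"] = (out["q_value"] < fdr_threshold) & (sym_fc > fc_threshold)
    return out


def overlap_sets(a: Iterable[str], b: Iterable[str]):
    """Partition two gene sets into (intersection, a_only, b_only)."""
    a, b = set(a), set(b)
    return a & b, a - b, b - a


class DEGModel:
    """Differential expression before vs after a developmental split age.

    Parameters
    ----------
    dataset : ExpressionDataset
        Must carry raw values (a raw dataset, or a normalised one that
        retains its raw matrix).
    split_age : float, optional
        Samples with age <= split_age form the "before" group, the rest
        "after".  Typically the tipping age from a DNB scan.
    groups : mapping, optional
        Explicit label -> sample-id lists; overrides ``split_age`` and
        allows a multi-period ANOVA.  Fold change is then computed between
        the first and last group in mapping order.
    """

    def __init__(
        self,
        dataset: ExpressionDataset,
        split_age: float | None = None,
        groups: Mapping[str, Sequence[str]] | None = None,
    ) -> None:
        if groups is None:
            if split_age is None:
                raise ValueError("provide either split_age or explicit groups")
            meta = dataset.meta
            before = list(meta.loc[meta["age_years"] <= split_age, "sample_id"])
            after = list(meta.loc[meta["age_years"] > split_age, "sample_id"])
            groups = {"before": before, "after": after}
        self.dataset = dataset
        self.groups = dict(groups)
        labels = list(self.groups)
        self.before_ids = list(self.groups[labels[0]])
        self.after_ids = list(self.groups[labels[-1]])

    def fit(
        self,
        fdr_threshold: float = 0.01,
        fc_threshold: float = 2.0,
        pseudocount: float | None = None,
    ) -> "DEGResults":
        p = anova_pvalues(self.dataset, self.groups)
        q = bh_fdr(p.to_numpy())
        fc = fold_changes(
            self.dataset, self.before_ids, self.after_ids, pseudocount
        )
        table = pd.DataFrame(
            {"p_value": p, "q_value": q, "fold_change": fc}, index=p.index
        )
        table = call_degs(table, fdr_threshold, fc_threshold)
        return DEGResults(self, table, fdr_threshold, fc_threshold)


class DEGResults:
    """Per-gene differential-expression table with threshold calls."""

    def __init__(self, model, table: pd.DataFrame, fdr_threshold, fc_threshold):
        self.model = model
        self.table = table
        self.fdr_threshold = fdr_threshold
        self.fc_threshold = fc_threshold

    @property
    def deg_genes(self) -> frozenset:
        return frozenset(self.table.index[self.table["is_deg"]])

    def summary(self) -> str:
        t = self.table
        n = len(t)
        n_deg = int(t["is_deg"].sum())
        lines = [
            "Differential expression (one-way ANOVA + BH-FDR)",
            "================================================",
            f"genes tested:   {n}",
            f"groups:         "
            + ", ".join(f"{k} (n={len(v)})" for k, v in self.model.groups.items()),
            f"thresholds:     FDR < {self.fdr_threshold:g}, "
            f"fold change > {self.fc_threshold:g} (either direction)",
            f"DEGs called:    {n_deg}",
        ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()
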