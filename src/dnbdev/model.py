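"""Dynamic network biomarker (DNB) tipping-point detection.

A system approaching a critical transition develops a *dominant group* of
molecules satisfying three criteria within the observation window: their
mutual Pearson correlations rise sharply in absolute value, their
correlations to all other molecules fall, and their standard deviations
rise.  The three are combined into the composite index

    CI = SD_d * PCC_d / PCC_o

where SD_d is the mean standard deviation of the group's genes across the
window's samples, PCC_d the mean absolute Pearson correlation over group
pairs, and PCC_o the mean absolute correlation between group and non-group
genes.  Because replicate counts per developmental period are small (1-5),
age-adjacent samples are pooled into sliding windows and CI is tracked along
the age axis; the window of maximal CI is the tipping point.

The user-facing surface follows the fit/results idiom: build a
:class:`DNBModel` from a normalised :class:`~dnbdev.dataset.ExpressionDataset`,
call :meth:`~DNBModel.fit`, and read the trajectory, tipping window, DNB gene
set and significance off the returned :class:`DNBResults`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .dataset import ExpressionDataset

logger = logging.getLogger("dnbdev")

__all__ = [
    "SampleWindow",
    "DNBScore",
    "DNBModel",
    "DNBResults",
    "build_windows",
    "dnb_statistics",
    "select_dominant_group",
    "dnb_scan",
    "peak_significance",
]


@dataclass(frozen=True)
class SampleWindow:
    """An age-contiguous run of samples; the unit of all DNB statistics."""

    window_index: int
    sample_ids: tuple
    age_label: float  # median age of members, in years

    @property
    def n(self) -> int:
        return len(self.sample_ids)


@dataclass(frozen=True)
class DNBScore:
    """The three DNB criteria plus their composite for one group/window."""

    sd_d: float
    pcc_d: float
    pcc_o: float
    ci: float


# ---------------------------------------------------------------------------
# windows


def build_windows(
    ds: ExpressionDataset, window_size: int = 7, step: int = 1
) -> list[SampleWindow]:
    """Slide a fixed-size window along the age-sorted samples.

    Starts are ``0, step, 2*step, ...``; the final stretch is covered by
    anchoring a last window at ``S - window_size`` so no window is ever
    smaller than ``window_size``.  Each window is labelled with the median
    age of its members.
    """
    if window_size < 3:
        raise ValueError("window_size must be >= 3 (correlations need >= 3 points)")
    if not (1 <= step <= window_size):
        raise ValueError("step must satisfy 1 <= step <= window_size")
    s = ds.n_samples
    if s < window_size:
        raise ValueError(f"need at least window_size={window_size} samples, have {s}")
    ages = ds.ages
    if np.any(np.diff(ages) < 0):
        raise ValueError("samples must be in ascending age order")
    starts = list(range(0, s - window_size + 1, step))
    if starts[-1] != s - window_size:
        starts.append(s - window_size)  # anchor the tail
    sample_ids = ds.sample_ids
    windows = []
    for idx, start in enumerate(starts):
        members = tuple(sample_ids[start : start + window_size])
        label = float(np.median(ages[start : start + window_size]))
        windows.append(SampleWindow(idx, members, label))
    return windows


# ---------------------------------------------------------------------------
# statistics


def _window_arrays(ds: ExpressionDataset, window: SampleWindow):
    """Per-window |r| matrix, per-gene sds, and row sums of |r|.

    Genes constant within the window get zero rows/columns (their pairs
    contribute |r| = 0) and a zero diagonal; variable genes have diagonal 1.
    """
    x = ds.values[list(window.sample_ids)].to_numpy(dtype=float)
    sds = x.std(axis=1, ddof=1)
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt((xc**2).sum(axis=1))
    ok = norms > 0
    y = np.zeros_like(xc)
    y[ok] = xc[ok] / norms[ok, None]
    corr = np.abs(y @ y.T)
    np.clip(corr, 0.0, 1.0, out=corr)
    return corr, sds, ok


def _score_group(
    corr: np.ndarray, sds: np.ndarray, idx: np.ndarray, row_sums: np.ndarray
) -> DNBScore:
    g = corr.shape[0]
    k = idx.size
    sd_d = float(sds[idx].mean())
    if k == 1:
        pcc_d = 1.0
        internal = float(corr[idx[0], idx[0]])
    else:
        sub = corr[np.ix_(idx, idx)]
        internal = float(sub.sum())
        diag = float(np.trace(sub))
        pcc_d = (internal - diag) / (k * (k - 1))
    out_sum = float(row_sums[idx].sum()) - internal
    n_out = k * (g - k)
    if n_out == 0:
        raise ValueError("group must be a strict subset of the genes")
    pcc_o = out_sum / n_out
    if pcc_o > 0:
        ci = sd_d * pcc_d / pcc_o
    else:
        warnings.warn("PCC_o is zero; CI reported as +inf", stacklevel=3)
        ci = float("inf")
    return DNBScore(sd_d=sd_d, pcc_d=pcc_d, pcc_o=pcc_o, ci=ci)


def dnb_statistics(
    ds: ExpressionDataset, group: Iterable[str], window: SampleWindow
) -> DNBScore:
    """Compute (SD_d, PCC_d, PCC_o, CI) for one gene group in one window.

    A singleton group has PCC_d = 1 by convention; pairs involving a gene
    that is constant within the window contribute |r| = 0.
    """
    group = set(group)
    if not group:
        raise ValueError("group must be nonempty")
    gene_index = {gid: i for i, gid in enumerate(ds.gene_ids)}
    missing = group - gene_index.keys()
    if missing:
        raise KeyError(f"group genes not in dataset: {sorted(missing)[:5]}")
    if len(group) >= ds.n_genes:
        raise ValueError("group must be a strict subset of the dataset's genes")
    if window.n < 3:
        raise ValueError("window must contain at least 3 samples")
    corr, sds, _ = _window_arrays(ds, window)
    idx = np.fromiter(sorted(gene_index[gid] for gid in group), dtype=int)
    row_sums = corr.sum(axis=1)
    return _score_group(corr, sds, idx, row_sums)


# ---------------------------------------------------------------------------
# dominant-group search


def _candidate_clusters(z: np.ndarray, n: int):
    """Yield member-index tuples for every merge of a linkage matrix."""
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for m in range(z.shape[0]):
        a, b = int(z[m, 0]), int(z[m, 1])
        merged = members[a] + members[b]
        members[n + m] = merged
        yield merged


def _select_dominant(
    ds: ExpressionDataset,
    window: SampleWindow,
    min_size: int,
    max_size: int,
    candidate_pool: int = 100,
) -> tuple[frozenset, DNBScore | None]:
    corr, sds, ok = _window_arrays(ds, window)
    gene_ids = np.asarray(ds.gene_ids)
    var_idx = np.flatnonzero(ok)
    if var_idx.size < min_size:
        warnings.warn(
            f"window {window.window_index}: only {var_idx.size} non-constant "
            f"genes (< min_size={min_size}); no dominant group",
            stacklevel=3,
        )
        return frozenset(), None
    row_sums = corr.sum(axis=1)

    # With few samples per window, pairwise correlation estimates are too
    # noisy to cluster the whole transcriptome (chance |r| is heavy-tailed
    # and the dendrogram becomes chance-dominated).  Rising standard
    # deviation is itself one of the three DNB criteria, so candidate genes
    # are pre-selected as the highest-SD genes within the window.
    if var_idx.size > candidate_pool:
        order = np.argsort(sds[var_idx], kind="stable")[::-1]
        var_idx = np.sort(var_idx[order[:candidate_pool]])

    sub_corr = corr[np.ix_(var_idx, var_idx)]
    dist = squareform(1.0 - sub_corr, checks=False)
    z = linkage(dist, method="average")

    best: tuple | None = None  # (ci, -size, min_gene_id, idx, score)
    for merged in _candidate_clusters(z, var_idx.size):
        k = len(merged)
        if not (min_size <= k <= max_size):
            continue
        idx = var_idx[np.asarray(merged, dtype=int)]
        score = _score_group(corr, sds, idx, row_sums)
        if not np.isfinite(score.ci):
            continue
        key = (score.ci, -k, min(gene_ids[idx]))
        if best is None or (key[0], key[1]) > (best[0], best[1]) or (
            key[0] == best[0] and key[1] == best[1] and key[2] < best[2]
        ):
            best = (*key, idx, score)
    if best is None:
        warnings.warn(
            f"window {window.window_index}: no candidate cluster with size in "
            f"[{min_size}, {max_size}]",
            stacklevel=3,
        )
        return frozenset(), None
    idx, score = best[3], best[4]
    return frozenset(gene_ids[idx]), score


def select_dominant_group(
    ds: ExpressionDataset,
    window: SampleWindow,
    min_size: int = 5,
    max_size: int | None = None,
    candidate_pool: int = 100,
) -> frozenset:
    """Find the gene cluster maximising CI within one window.

    Genes are average-linkage clustered on the distance 1 - |r| computed
    within the window; every dendrogram merge whose size falls in
    ``[min_size, max_size]`` is scored with :func:`dnb_statistics` and the
    cluster of maximal finite CI is returned (ties: smaller cluster, then
    lexicographically smallest member id).  Returns an empty set, with a
    warning, if the size band contains no candidate.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    if not ds.normalized:
        raise ValueError("dominant-group search requires a normalized dataset")
    if max_size is None:
        max_size = max(min_size, ds.n_genes // 5)
    group, _ = _select_dominant(ds, window, min_size, max_size, candidate_pool)
    return group


# ---------------------------------------------------------------------------
# significance


def peak_significance(
    ci_trajectory: Sequence[float], z_threshold: float = 4.5
) -> tuple[bool, float]:
    """Leave-peak-out z-score of the trajectory maximum.

    ``z = (max CI - mean of remaining CIs) / sd of remaining CIs`` (sample
    sd).  Significant when ``z >= z_threshold``.  With fewer than 3 finite
    values the verdict is not-significant with a NaN z.  If the remaining
    values have zero spread, the peak is significant iff it strictly exceeds
    them (z reported as +inf in that case, 0 otherwise).
    """
    ci = np.asarray(list(ci_trajectory), dtype=float)
    finite = ci[np.isfinite(ci)]
    if finite.size < 3:
        if np.isinf(ci).any() and finite.size >= 2:
            # an infinite peak over a finite rest is unambiguously separated
            warnings.warn("CI trajectory contains +inf; peak treated as separated")
            return True, float("inf")
        warnings.warn("need >= 3 finite CI values for peak significance")
        return False, float("nan")
    if np.isinf(ci).any():
        warnings.warn("CI trajectory contains +inf; peak treated as separated")
        return True, float("inf")
    peak_pos = int(np.argmax(finite))
    rest = np.delete(finite, peak_pos)
    peak = float(finite[peak_pos])
    sd = float(rest.std(ddof=1))
    if sd == 0.0:
        if peak > rest[0]:
            return True, float("inf")
        return False, 0.0
    z = (peak - float(rest.mean())) / sd
    return bool(z >= z_threshold), float(z)


# ---------------------------------------------------------------------------
# model / results


class DNBModel:
    """Sliding-window DNB scan of an age-ordered expression dataset.

    Parameters
    ----------
    dataset : ExpressionDataset
        Rank-normalised, single-species, age-sorted.
    window_size, step : int
        Sliding-window geometry (defaults 7 and 1).  Pearson correlations
        from fewer than ~6 points are so noisy that the null |r| is nearly
        uniform on [0, 1]; seven pooled samples keep window correlations
        informative while preserving a multi-window trajectory for courses
        of a dozen samples.
    min_size, max_size : int
        Size band of the dominant-group search; ``max_size`` defaults to a
        fifth of the gene count.
    z_threshold : float
        Leave-peak-out z-score above which the CI peak is called
        significant.  The default (4.5) is calibrated on flat-schedule
        synthetic nulls: because each window's CI is itself a maximum over
        many candidate clusters, the null peak z is far larger than
        pointwise Gaussian intuition suggests (null median ~2.4, 95th
        percentile ~4.0).  For real data prefer ``fit(permutations=...)``.
    """

    def __init__(
        self,
        dataset: ExpressionDataset,
        window_size: int = 7,
        step: int = 1,
        min_size: int = 5,
        max_size: int | None = None,
        candidate_pool: int = 100,
        z_threshold: float = 4.5,
    ) -> None:
        if not dataset.normalized:
            raise ValueError(
                "DNBModel requires a normalized dataset; call "
                "ExpressionDataset.normalize_uniform() first"
            )
        n_species = dataset.meta["species"].nunique()
        if n_species > 1:
            raise ValueError(
                "DNBModel scans one species at a time; filter the dataset first"
            )
        self.dataset = dataset
        self.window_size = int(window_size)
        self.step = int(step)
        self.min_size = int(min_size)
        self.max_size = int(
            max_size if max_size is not None else max(min_size, dataset.n_genes // 5)
        )
        self.candidate_pool = int(candidate_pool)
        self.z_threshold = float(z_threshold)

    def fit(self, permutations: int = 0, seed: int | None = None) -> "DNBResults":
        """Run the scan; optionally add an age-permutation test of the peak."""
        windows = build_windows(self.dataset, self.window_size, self.step)
        groups, scores = self._scan(self.dataset, windows)
        ci = np.asarray([s.ci if s is not None else np.nan for s in scores])
        if np.all(np.isnan(ci)):
            raise ValueError("no DNB candidates in any window")
        tipping = int(np.nanargmax(np.where(np.isinf(ci), np.inf, ci)))
        if len(windows) >= 3:
            significant, zstat = peak_significance(
                ci[~np.isnan(ci)], self.z_threshold
            )
        else:
            warnings.warn("fewer than 3 windows; significance not assessable")
            significant, zstat = False, float("nan")

        perm_p = None
        if permutations > 0:
            finite = ci[np.isfinite(ci)]
            observed = float(finite.max()) if finite.size else float("inf")
            perm_p = self._permutation_pvalue(
                observed_peak=observed, permutations=permutations, seed=seed
            )
        return DNBResults(
            model=self,
            windows=windows,
            per_window_group=groups,
            per_window_score=scores,
            tipping_index=tipping,
            significant=significant,
            significance_stat=zstat,
            permutation_pvalue=perm_p,
        )

    # internal ------------------------------------------------------------

    def _scan(self, ds: ExpressionDataset, windows):
        groups, scores = [], []
        for w in windows:
            grp, score = _select_dominant(
                ds, w, self.min_size, self.max_size, self.candidate_pool
            )
            groups.append(grp)
            scores.append(score)
        return groups, scores

    def _permutation_pvalue(
        self, observed_peak: float, permutations: int, seed: int | None
    ) -> float:
        """Shuffle sample ages, rebuild windows, rescan; fraction of
        permutation peaks reaching the observed peak CI."""
        rng = np.random.default_rng(seed)
        ds = self.dataset
        hits = 0
        for _ in range(permutations):
            perm = rng.permutation(ds.n_samples)
            shuffled = ds.subset_samples([ds.sample_ids[i] for i in perm])
            # ages travel with samples; windows are positional, which is
            # exactly the null of no age structure
            meta = shuffled.meta.copy()
            meta["age_years"] = np.sort(meta["age_years"].to_numpy())
            null_ds = ExpressionDataset(
                shuffled.values, meta, normalized=True, raw=shuffled.raw
            )
            windows = build_windows(null_ds, self.window_size, self.step)
            _, scores = self._scan(null_ds, windows)
            peaks = [s.ci for s in scores if s is not None and np.isfinite(s.ci)]
            if peaks and max(peaks) >= observed_peak:
                hits += 1
        return hits / permutations


class DNBResults:
    """Outcome of a DNB scan: trajectory, tipping window, gene set, verdict."""

    def __init__(
        self,
        model: DNBModel,
        windows,
        per_window_group,
        per_window_score,
        tipping_index: int,
        significant: bool,
        significance_stat: float,
        permutation_pvalue: float | None = None,
    ) -> None:
        self.model = model
        self.windows = windows
        self.per_window_group = per_window_group
        self.per_window_score = per_window_score
        self.tipping_index = tipping_index
        self.significant = significant
        self.significance_stat = significance_stat
        self.permutation_pvalue = permutation_pvalue

    @property
    def dnb_genes(self) -> frozenset:
        return self.per_window_group[self.tipping_index]

    @property
    def tipping_age(self) -> float:
        return self.windows[self.tipping_index].age_label

    @property
    def ci_trajectory(self) -> np.ndarray:
        return np.asarray(
            [s.ci if s is not None else np.nan for s in self.per_window_score]
        )

    def to_frame(self) -> pd.DataFrame:
        """Per-window table: age label, the three criteria, CI, group size."""
        rows = []
        for w, grp, s in zip(
            self.windows, self.per_window_group, self.per_window_score
        ):
            rows.append(
                {
                    "window_index": w.window_index,
                    "age_label": w.age_label,
                    "n_samples": w.n,
                    "sd_d": s.sd_d if s else np.nan,
                    "pcc_d": s.pcc_d if s else np.nan,
                    "pcc_o": s.pcc_o if s else np.nan,
                    "ci": s.ci if s else np.nan,
                    "group_size": len(grp),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.to_frame()
        lines = [
            "Dynamic network biomarker scan",
            "==============================",
            f"windows:        {len(self.windows)} "
            f"(size {self.model.window_size}, step {self.model.step})",
            f"tipping window: index {self.tipping_index}, "
            f"age {self.tipping_age:.3g} years",
            f"DNB genes:      {len(self.dnb_genes)}",
            f"peak z-score:   {self.significance_stat:.3g} "
            f"(threshold {self.model.z_threshold:g}) -> "
            f"{'significant' if self.significant else 'not significant'}",
        ]
        if self.permutation_pvalue is not None:
            lines.append(f"permutation p:  {self.permutation_pvalue:.3g}")
        lines.append("")
        lines.append(df.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)

    def plot_trajectory(self, ax=None):
        """CI vs window age, tipping window highlighted."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        df = self.to_frame()
        ax.plot(df["age_label"], df["ci"], "o-", color="tab:blue", label="CI")
        ax.plot(
            [self.tipping_age],
            [df.loc[self.tipping_index, "ci"]],
            "o",
            color="tab:red",
            markersize=10,
            label="tipping window",
        )
        ax.set_xlabel("age (years)")
        ax.set_ylabel("composite index CI")
        ax.legend()
        return ax

    def to_json_dict(self) -> dict:
        return {
            "tipping_index": int(self.tipping_index),
            "tipping_age_years": float(self.tipping_age),
            "n_windows": len(self.windows),
            "n_dnb_genes": len(self.dnb_genes),
            "significant": bool(self.significant),
            "peak_z": float(self.significance_stat),
            "permutation_pvalue": self.permutation_pvalue,
            "parameters": {
                "window_size": self.model.window_size,
                "step": self.model.step,
                "min_size": self.model.min_size,
                "max_size": self.model.max_size,
                "candidate_pool": self.model.candidate_pool,
                "z_threshold": self.model.z_threshold,
            },
        }


def dnb_scan(
    ds: ExpressionDataset,
    window_size: int = 7,
    step: int = 1,
    min_size: int = 5,
    max_size: int | None = None,
    candidate_pool: int = 100,
    z_threshold: float = 4.5,
) -> DNBResults:
    """Functional wrapper: ``DNBModel(ds, ...).fit()``."""
    return DNBModel(
        ds,
        window_size=window_size,
        step=step,
        min_size=min_size,
        max_size=max_size,
        candidate_pool=candidate_pool,
        z_threshold=z_threshold,
    ).fit()
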