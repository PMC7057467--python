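import types
import warnings

import numpy as np
import pytest

from dnbdev.dataset import normalize_uniform
from dnbdev.model import (
    DNBModel,
    build_windows,
    dnb_statistics,
    peak_significance,
    select_dominant_group,
)

from conftest import ci_brute, make_dataset


class TestBuildWindows:
    def test_thirteen_samples_window_four(self):
        ds = make_dataset(np.zeros((2, 13)))
        ws = build_windows(ds, window_size=4, step=1)
        assert len(ws) == 10
        assert ws[0].sample_ids == ("s0", "s1", "s2", "s3")

    def test_single_window_when_equal(self):
        ds = make_dataset(np.zeros((2, 4)))
        assert len(build_windows(ds, 4, 1)) == 1

    def test_tail_anchoring_with_step_two(self):
        ds = make_dataset(np.zeros((2, 9)))
        ws = build_windows(ds, 4, 2)
        starts = [w.sample_ids[0] for w in ws]
        assert starts == ["s0", "s2", "s4", "s5"]
        assert all(w.n == 4 for w in ws)

    def test_age_label_is_median(self):
        ds = make_dataset(np.zeros((2, 5)), ages=[0, 1, 2, 10, 20])
        ws = build_windows(ds, 5, 1)
        assert ws[0].age_label == 2

    def test_too_few_samples_rejected(self):
        ds = make_dataset(np.zeros((2, 3)))
        with pytest.raises(ValueError):
            build_windows(ds, 4, 1)

    def test_unsorted_ages_rejected(self):
        ds = make_dataset(np.zeros((2, 4)), ages=[0.3, 0.1, 0.2, 0.4])
        with pytest.raises(ValueError, match="ascending"):
            build_windows(ds, 4, 1)


class TestDNBStatistics:
    def test_perfectly_collinear_group(self):
        ds = make_dataset([[1, 2, 3], [2, 4, 6], [3, 2, 1]], gene_ids=list("abo"))
        w = build_windows(ds, 3, 1)[0]
        s = dnb_statistics(ds, {"a", "b"}, w)
        assert s.sd_d == pytest.approx(1.5)
        assert s.pcc_d == pytest.approx(1.0)
        assert s.pcc_o == pytest.approx(1.0)
        assert s.ci == pytest.approx(1.5)

    def test_singleton_group_convention(self):
        ds = make_dataset([[1, 2, 3], [1, 2, 3]], gene_ids=["g", "o"])
        w = build_windows(ds, 3, 1)[0]
        s = dnb_statistics(ds, {"g"}, w)
        assert s.pcc_d == 1.0
        assert s.ci == pytest.approx(1.0)

    def test_matches_bruteforce_on_random_matrix(self):
        rng = np.random.default_rng(11)
        arr = rng.normal(size=(6, 5))
        ds = make_dataset(arr)
        w = build_windows(ds, 5, 1)[0]
        s = dnb_statistics(ds, {"g0", "g1", "g2"}, w)
        sd, pd_, po, ci = ci_brute(arr, [0, 1, 2])
        assert s.sd_d == pytest.approx(sd, abs=1e-10)
        assert s.pcc_d == pytest.approx(pd_, abs=1e-10)
        assert s.pcc_o == pytest.approx(po, abs=1e-10)
        assert s.ci == pytest.approx(ci, abs=1e-10)

    def test_constant_gene_pairs_contribute_zero(self):
        ds = make_dataset([[1, 2, 3], [5, 5, 5], [3, 1, 2]])
        w = build_windows(ds, 3, 1)[0]
        s = dnb_statistics(ds, {"g0", "g1"}, w)
        # pair (g0, g1) has a constant member -> |r| = 0
        assert s.pcc_d == 0.0

    def test_group_must_be_strict_subset(self):
        ds = make_dataset(np.random.default_rng(0).normal(size=(3, 4)))
        w = build_windows(ds, 4, 1)[0]
        with pytest.raises(ValueError):
            dnb_statistics(ds, {"g0", "g1", "g2"}, w)

    def test_unknown_gene_rejected(self):
        ds = make_dataset(np.random.default_rng(0).normal(size=(3, 4)))
        w = build_windows(ds, 4, 1)[0]
        with pytest.raises(KeyError):
            dnb_statistics(ds, {"nope"}, w)

    def test_scale_behavior(self):
        # scaling group genes by k scales sd_d and ci by k, leaves both
        # correlation terms unchanged — the reason the scan mandates
        # rank-normalised input
        rng = np.random.default_rng(5)
        arr = rng.normal(size=(8, 6))
        ds = make_dataset(arr)
        w = build_windows(ds, 6, 1)[0]
        base = dnb_statistics(ds, {"g0", "g1", "g2"}, w)
        arr2 = arr.copy()
        arr2[:3] *= 3.0
        s2 = dnb_statistics(make_dataset(arr2), {"g0", "g1", "g2"}, w)
        assert s2.sd_d == pytest.approx(3 * base.sd_d)
        assert s2.pcc_d == pytest.approx(base.pcc_d)
        assert s2.pcc_o == pytest.approx(base.pcc_o)
        assert s2.ci == pytest.approx(3 * base.ci)

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(9)
        arr = rng.normal(size=(10, 5))
        ds = make_dataset(arr)
        w = build_windows(ds, 5, 1)[0]
        s1 = dnb_statistics(ds, {"g2", "g5", "g7"}, w)
        perm = rng.permutation(10)
        ds2 = make_dataset(arr[perm], gene_ids=[f"g{i}" for i in perm])
        s2 = dnb_statistics(ds2, {"g2", "g5", "g7"}, w)
        for field in ("sd_d", "pcc_d", "pcc_o", "ci"):
            assert getattr(s1, field) == pytest.approx(getattr(s2, field), abs=1e-12)


class TestSelectDominantGroup:
    def test_planted_copies_win(self):
        rng = np.random.default_rng(0)
        # latent series spanning the noise range, so the copies' ranks
        # swing strongly between samples
        latent = np.array([-2.0, 1.9, -1.5, 2.1, -1.8, 1.6])
        arr = rng.normal(size=(23, 6))
        for i in range(3):
            arr[i] = latent
        ds = normalize_uniform(
            make_dataset(arr, gene_ids=[f"g{i:02d}" for i in range(23)])
        )
        w = build_windows(ds, 6, 1)[0]
        group = select_dominant_group(ds, w, min_size=3, max_size=5)
        assert group == {"g00", "g01", "g02"}

    def test_noise_group_bounded_by_random_baseline(self):
        rng = np.random.default_rng(12)
        arr = rng.normal(size=(40, 6))
        ds = normalize_uniform(make_dataset(arr))
        w = build_windows(ds, 6, 1)[0]
        group = select_dominant_group(ds, w, min_size=5, max_size=8)
        found = dnb_statistics(ds, group, w).ci
        best_random = 0.0
        for _ in range(100):
            pick = rng.choice(40, size=5, replace=False)
            ci = dnb_statistics(ds, {f"g{i}" for i in pick}, w).ci
            best_random = max(best_random, ci)
        assert found <= 2 * best_random and found >= best_random / 2

    def test_empty_band_warns_and_returns_empty(self):
        ds = normalize_uniform(
            make_dataset(np.random.default_rng(0).normal(size=(4, 5)))
        )
        w = build_windows(ds, 5, 1)[0]
        with pytest.warns(UserWarning):
            group = select_dominant_group(ds, w, min_size=5, max_size=8)
        assert group == frozenset()

    def test_requires_normalized_input(self):
        ds = make_dataset(np.random.default_rng(0).normal(size=(10, 5)))
        w = build_windows(ds, 5, 1)[0]
        with pytest.raises(ValueError, match="normalized"):
            select_dominant_group(ds, w)


class TestPeakSignificance:
    def test_zero_spread_peak_is_infinitely_separated(self):
        sig, z = peak_significance([1, 1, 1, 5])
        assert sig is True and z == np.inf

    def test_constant_trajectory_not_significant(self):
        sig, z = peak_significance([2, 2, 2, 2])
        assert sig is False

    def test_small_fluctuations_not_significant(self):
        # max 1.1; remaining {1, 0.9, 1.05} have mean 0.9833, sd 0.0764
        sig, z = peak_significance([1, 1.1, 0.9, 1.05], z_threshold=2.0)
        assert z == pytest.approx(1.5275, abs=1e-3)
        assert sig is False

    def test_too_few_values_warns(self):
        with pytest.warns(UserWarning):
            sig, z = peak_significance([1.0, 2.0])
        assert sig is False and np.isnan(z)

    def test_clear_spike_detected(self):
        traj = [1.0, 1.01, 0.99, 1.02, 0.98, 1.0, 8.0]
        sig, z = peak_significance(traj)
        assert sig is True and z > 100


class TestDNBModelFit:
    def _small_planted(self, seed=0):
        from dnbdev.simulate import SimConfig, generate_dataset

        cfg = SimConfig(n_genes=200, n_dnb=20, n_de=10, seed=seed)
        ds, truth = generate_dataset(cfg)
        return normalize_uniform(ds), truth

    def test_single_window_degenerate(self):
        rng = np.random.default_rng(1)
        ds = normalize_uniform(make_dataset(rng.normal(size=(30, 7))))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = DNBModel(ds, window_size=7, min_size=3).fit()
        assert res.tipping_index == 0
        assert res.significant is False

    def test_trajectory_frame_shape_and_summary(self):
        ds, _ = self._small_planted()
        res = DNBModel(ds, min_size=3).fit()
        df = res.to_frame()
        assert list(df.columns) == [
            "window_index",
            "age_label",
            "n_samples",
            "sd_d",
            "pcc_d",
            "pcc_o",
            "ci",
            "group_size",
        ]
        assert len(df) == len(res.windows)
        assert str(len(res.dnb_genes)) in res.summary()

    def test_fit_rejects_unnormalized(self):
        from dnbdev.simulate import SimConfig, generate_dataset

        ds, _ = generate_dataset(SimConfig(n_genes=50, n_dnb=5, n_de=5, seed=0))
        with pytest.raises(ValueError, match="normalized"):
            DNBModel(ds)

    def test_fit_rejects_mixed_species(self):
        import pandas as pd

        ds, _ = self._small_planted()
        meta = ds.meta.copy()
        meta.loc[0, "species"] = "human"
        from dnbdev.dataset import ExpressionDataset

        mixed = ExpressionDataset(ds.values, meta, normalized=True, raw=ds.raw)
        with pytest.raises(ValueError, match="one species"):
            DNBModel(mixed)

    def test_permutation_pvalue_small_for_planted_peak(self):
        ds, _ = self._small_planted(seed=3)
        res = DNBModel(ds, min_size=3).fit(permutations=19, seed=5)
        assert res.permutation_pvalue is not None
        assert 0.0 <= res.permutation_pvalue <= 1.0

    def test_tipping_at_planted_age(self):
        from dnbdev.simulate import evaluate_recovery

        ds, truth = self._small_planted(seed=1)
        res = DNBModel(ds).fit()
        hit, offset, _ = evaluate_recovery(res, truth)
        assert hit, f"tipping window offset {offset}"
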