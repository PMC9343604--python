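"""EHH/iHH/iHS, Hudson Fst, drift tree and the differentiation LRT."""

import numpy as np
import pytest

import sweepscan as ss
from sweepscan import selstats
from sweepscan.selstats import (
    DriftTree,
    EhhUndefinedError,
    compute_ehh,
    estimate_drift_tree,
    genome_fst,
    hudson_fst,
    ihs_raw,
    integrate_ihh,
    standardize_ihs,
    treeselect_lrt,
    treeselect_lrt_batch,
)

from conftest import make_hap
from _oracles import brute_ehh, grid_lrt


class TestEhh:
    def test_focal_point_is_one(self):
        m = np.array([[1, 1, 0], [1, 0, 0], [1, 1, 1], [0, 0, 1]], dtype=np.int8)
        curve = compute_ehh(make_hap(m), 0, "derived")
        assert curve.left_ehh[0] == 1.0
        assert curve.right_ehh[0] == 1.0

    def test_two_by_two_split_gives_one_third(self):
        # 4 derived carriers splitting 2/2 into two distinct extended
        # haplotypes: identical pairs = 1 + 1 of C(4,2) = 6
        m = np.array(
            [[1, 0], [1, 0], [1, 1], [1, 1], [0, 0], [0, 1]], dtype=np.int8
        )
        curve = compute_ehh(make_hap(m), 0, "derived")
        assert curve.right_ehh[1] == pytest.approx(1 / 3)

    def test_homogeneous_carriers_stay_at_one(self):
        m = np.tile(np.array([[1, 1, 1, 1]], dtype=np.int8), (4, 1))
        m = np.vstack([m, np.zeros((2, 4), dtype=np.int8)])
        curve = compute_ehh(make_hap(m), 1, "derived")
        assert np.all(curve.right_ehh == 1.0)
        assert np.all(curve.left_ehh == 1.0)

    def test_fewer_than_two_carriers_undefined(self):
        m = np.array([[1, 0], [0, 0], [0, 1], [0, 0]], dtype=np.int8)
        with pytest.raises(EhhUndefinedError):
            compute_ehh(make_hap(m), 0, "derived")

    def test_monotone_nonincreasing_each_side(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            m = rng.integers(0, 2, size=(20, 40)).astype(np.int8)
            focal = 20
            if (m[:, focal] == 1).sum() < 2:
                continue
            curve = compute_ehh(make_hap(m), focal, "derived")
            assert np.all(np.diff(curve.left_ehh) <= 1e-12)
            assert np.all(np.diff(curve.right_ehh) <= 1e-12)

    def test_missing_allele_breaks_homozygosity(self):
        # carriers 0 and 1 identical except a missing allele in carrier 0
        m = np.array(
            [[1, -1, 1], [1, 1, 1], [0, 0, 0], [0, 1, 0]], dtype=np.int8
        )
        curve = compute_ehh(make_hap(m), 0, "derived")
        assert curve.right_ehh[1] == 0.0

    def test_max_gap_truncates(self):
        m = np.array([[1, 1], [1, 0], [0, 1], [0, 0]], dtype=np.int8)
        hap = make_hap(m, positions=[1000, 500_000])
        curve = compute_ehh(hap, 0, "derived", max_gap_bp=200_000)
        assert curve.right_truncated

    def test_brute_force_oracle_equivalence(self):
        rng = np.random.default_rng(99)
        checked = 0
        while checked < 25:
            m = rng.integers(0, 2, size=(20, 50)).astype(np.int8)
            m[rng.random(m.shape) < 0.02] = -1
            focal = int(rng.integers(5, 45))
            allele = 1 if rng.random() < 0.5 else 0
            carriers = np.flatnonzero(m[:, focal] == allele)
            if carriers.size < 2:
                continue
            hap = make_hap(m)
            curve = compute_ehh(
                hap, focal, "derived" if allele else "ancestral", ehh_cutoff=0.0
            )
            for k, cm in enumerate(curve.right_cm):
                upto = focal + k
                assert curve.right_ehh[k] == pytest.approx(
                    brute_ehh(m, carriers, focal, upto)
                )
            for k in range(len(curve.left_cm)):
                assert curve.left_ehh[k] == pytest.approx(
                    brute_ehh(m, carriers, focal, focal - k)
                )
            checked += 1


class TestIntegrateIhh:
    def _flat_curve(self):
        # EHH = 1 over exactly 1 cM on the right, 0 at the next marker
        from sweepscan.selstats import EhhCurve

        return EhhCurve(
            focal_index=0,
            allele="derived",
            n_carriers=4,
            cutoff=0.05,
            left_cm=np.array([0.0]),
            left_ehh=np.array([1.0]),
            right_cm=np.array([0.0, 0.5, 1.0, 1.2]),
            right_ehh=np.array([1.0, 1.0, 1.0, 0.0]),
            left_truncated=False,
            right_truncated=False,
        )

    def test_hand_trapezoid(self):
        # clipped values: .95, .95, .95, 0 -> .95*1 + .5*.95*.2
        area = integrate_ihh(self._flat_curve())
        assert area == pytest.approx(0.95 * 1.0 + 0.5 * 0.95 * 0.2)

    def test_no_flanking_markers_gives_zero(self):
        c = self._flat_curve()
        c.right_cm, c.right_ehh = np.array([0.0]), np.array([1.0])
        assert integrate_ihh(c) == 0.0

    def test_linear_in_genetic_scale(self):
        c1 = self._flat_curve()
        c2 = self._flat_curve()
        c2.right_cm = 2 * c2.right_cm
        assert integrate_ihh(c2) == pytest.approx(2 * integrate_ihh(c1))


class TestIhsRaw:
    def test_symmetry_and_log_identity(self):
        assert ihs_raw(2.0, 2.0) == 0.0
        assert ihs_raw(np.e * 3.0, 3.0) == pytest.approx(1.0)

    def test_zero_side_undefined(self):
        with pytest.raises(ValueError):
            ihs_raw(1.0, 0.0)


class TestStandardizeIhs:
    def test_two_point_bin_population_sd(self):
        out = standardize_ihs(np.array([-1.0, 1.0]), np.array([0.5, 0.51]), 0.025)
        np.testing.assert_allclose(np.sort(out), [-1.0, 1.0])

    def test_constant_bin_undefined(self):
        out = standardize_ihs(np.array([2.0, 2.0]), np.array([0.5, 0.51]), 0.025)
        assert np.all(np.isnan(out))

    def test_singleton_bin_undefined(self):
        out = standardize_ihs(np.array([1.0]), np.array([0.5]), 0.025)
        assert np.isnan(out[0])

    def test_bin_moments_on_simulated_scores(self):
        rng = np.random.default_rng(4)
        freq = rng.uniform(0.05, 0.95, size=20_000)
        raw = rng.normal(0.2 * freq, 1.0)  # frequency-dependent mean
        std = standardize_ihs(raw, freq)
        bins = np.floor(freq / 0.025)
        for b in np.unique(bins):
            sel = (bins == b) & np.isfinite(std)
            if sel.sum() < 2:
                continue
            assert abs(std[sel].mean()) < 1e-10
            assert std[sel].std(ddof=0) == pytest.approx(1.0)


class TestHudsonFst:
    def test_fixed_difference(self):
        num, den = hudson_fst(1.0, 1000, 0.0, 1000)
        assert genome_fst(np.atleast_1d(num), np.atleast_1d(den)) == pytest.approx(
            1.0, abs=1e-2
        )

    def test_no_differentiation_large_n(self):
        num, den = hudson_fst(0.3, 10**7, 0.3, 10**7)
        assert num / den == pytest.approx(0.0, abs=1e-5)

    def test_hand_value(self):
        # p1=.3, p2=.7, n -> inf: 0.16/0.58
        num, den = hudson_fst(0.3, 10**9, 0.7, 10**9)
        assert num / den == pytest.approx(0.16 / 0.58, abs=1e-6)

    def test_zero_denominator_skipped(self):
        num = np.array([0.1, np.nan])
        den = np.array([0.5, 0.0])
        assert genome_fst(num, den) == pytest.approx(0.2)

    def test_small_allele_count_rejected(self):
        with pytest.raises(ValueError):
            hudson_fst(0.5, 1, 0.5, 10)


class TestDriftTree:
    def test_additivity_algebra(self):
        tree = estimate_drift_tree(0.2, 0.3, 0.4)
        np.testing.assert_allclose(tree.c, [0.05, 0.15, 0.25])

    def test_symmetric_case(self):
        tree = estimate_drift_tree(0.1, 0.1, 0.1)
        np.testing.assert_allclose(tree.c, [0.05, 0.05, 0.05])

    def test_degenerate_geometry_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            tree = estimate_drift_tree(0.01, 0.01, 0.5)
        assert tree.c[0] == pytest.approx(1e-6)
        assert tree.clamped


class TestTreeselectLrt:
    tree = DriftTree(("t", "r1", "r2"), np.array([0.02, 0.02, 0.02]))

    def test_identical_frequencies_give_zero(self):
        lrt = treeselect_lrt((0.5, 0.5, 0.5), (100, 100, 100), self.tree)
        assert lrt <= 1e-6

    def test_monotone_in_target_deviation(self):
        prev = treeselect_lrt((0.80, 0.5, 0.5), (50, 50, 50), self.tree)
        for x in (0.9, 0.95, 0.99):
            cur = treeselect_lrt((x, 0.5, 0.5), (50, 50, 50), self.tree)
            assert cur > prev > 0
            prev = cur

    def test_fixed_case_matches_grid_oracle(self):
        lrt = treeselect_lrt((0.9, 0.5, 0.5), (50, 50, 50), self.tree)
        oracle = grid_lrt((0.9, 0.5, 0.5), (50, 50, 50), self.tree.c)
        assert lrt == pytest.approx(oracle, abs=1e-3)

    def test_batch_matches_scalar(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0.01, 0.99, size=(50, 3))
        n = np.full((50, 3), 60.0)
        batch = treeselect_lrt_batch(x, n, self.tree)
        for i in range(50):
            scalar = treeselect_lrt(tuple(x[i]), tuple(n[i]), self.tree)
            assert batch[i] == pytest.approx(scalar, abs=1e-6)

    def test_nonnegative_everywhere(self):
        rng = np.random.default_rng(21)
        x = rng.uniform(0, 1, size=(300, 3))
        n = rng.integers(10, 200, size=(300, 3)).astype(float)
        lrt = treeselect_lrt_batch(x, n, self.tree)
        assert np.all(lrt >= 0)

    def test_invalid_frequency_rejected(self):
        with pytest.raises(ValueError):
            treeselect_lrt((1.2, 0.5, 0.5), (50, 50, 50), self.tree)


class TestScanLevel:
    def test_numba_and_numpy_scan_paths_identical(self, neutral_dataset):
        from sweepscan import _ehh_kernel

        sub = neutral_dataset.target_hap.subset_variants(np.arange(400))
        fast = selstats.ihs_scan(sub, neutral_dataset.gmap)
        had = _ehh_kernel.HAVE_NUMBA
        _ehh_kernel.HAVE_NUMBA = False
        try:
            slow = selstats.ihs_scan(sub, neutral_dataset.gmap)
        finally:
            _ehh_kernel.HAVE_NUMBA = had
        import pandas as pd

        pd.testing.assert_frame_equal(fast, slow)

    def test_sweep_makes_focal_ihs_negative(self):
        # long derived haplotypes inflate iHH_D -> ln(iHH_A/iHH_D) < 0
        hits = 0
        total = 0
        for seed in range(10):
            ds = ss.simulate_dataset(ss.sweep_config(3000 + seed, n_sweeps=5))
            tab = selstats.ihs_scan(ds.target_hap, ds.gmap)
            for row in ds.truth.itertuples():
                sel = (tab["chrom"] == row.chrom) & (tab["pos_bp"] == row.focal_pos)
                val = tab.loc[sel, "ihs_raw"].iloc[0]
                if np.isfinite(val):
                    total += 1
                    hits += val < 0
        assert total >= 40
        assert hits / total >= 0.95

    def test_lrt_scan_elevated_at_target_specific_sweep(self, neutral_dataset):
        ds = ss.simulate_dataset(ss.sweep_config(4001, n_sweeps=5))
        lrt, tree = selstats.lrt_scan(ds.haps, "target", "ref_sa", "ref_global")
        tab = ds.target_hap.variants
        q99 = np.quantile(lrt, 0.99)
        hits = 0
        for row in ds.truth.itertuples():
            sel = np.flatnonzero(
                (tab["chrom"].to_numpy() == row.chrom)
                & (tab["pos_bp"].to_numpy() == row.focal_pos)
            )
            hits += lrt[sel[0]] > q99
        assert hits >= 4

    def test_fst_recovers_effective_drift_sum_halved(self, neutral_dataset):
        # Hudson Fst estimates the mean of the two branch drifts; the
        # founder-mosaic adds ~1/founder_count of drift per population
        ds = neutral_dataset
        cfg = ds.config
        f = cfg.founder_count
        labels = [p.label for p in cfg.populations]
        c_eff = {
            p.label: 1 - (1 - p.drift) * (1 - 1 / f) for p in cfg.populations
        }
        for i in range(3):
            for j in range(i + 1, 3):
                a, b = ds.haps[labels[i]], ds.haps[labels[j]]
                num, den = hudson_fst(
                    a.derived_freq(), a.called_allele_count(),
                    b.derived_freq(), b.called_allele_count(),
                )
                fst = genome_fst(num, den)
                expected = (c_eff[labels[i]] + c_eff[labels[j]]) / 2
                assert fst == pytest.approx(expected, rel=0.15)
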