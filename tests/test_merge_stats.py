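"""Merging statistics: R factors, CC1/2, ISa, completeness, shells,
resolution rule."""

import numpy as np
import pandas as pd
import pytest

from edbatch.formats import UnitCell
from edbatch.merge_stats import (ShellStats, StatisticUndefined, bin_shells,
                                 cc_half, completeness, dataset_summary,
                                 estimate_resolution, fit_error_model,
                                 group_equivalents, r_int, r_meas)
from edbatch.symmetry import laue_operators
from edbatch.synthetic import WedgeSpec, make_dataset, make_ground_truth


def frame_from_groups(groups):
    """Build a reflection frame with one distinct unique index per group."""
    rows = []
    for g, intensities in enumerate(groups):
        for i in intensities:
            rows.append((g + 1, 2 * g + 1, 1, i, 1.0, 1.0))
    return pd.DataFrame(rows, columns=["h", "k", "l", "intensity",
                                       "sigma", "frame"])


def brute_force_r(groups, redundancy_independent):
    """Loop-based oracle for the merging R factors."""
    num = den = 0.0
    for intensities in groups:
        n = len(intensities)
        if n < 2:
            continue
        mean = sum(intensities) / n
        f = (n / (n - 1)) ** 0.5 if redundancy_independent else 1.0
        num += f * sum(abs(i - mean) for i in intensities)
        den += sum(intensities)
    return num / den


class TestGroupEquivalents:
    def test_friedel_pair_one_group(self, laue_p1):
        df = frame_from_groups([[10.0]])
        df2 = df.copy()
        df2[["h", "k", "l"]] = -df2[["h", "k", "l"]]
        both = pd.concat([df, df2], ignore_index=True)
        assert group_equivalents(both, laue_p1).n_unique == 1

    def test_distinct_indices_stay_singletons(self, laue_p1):
        df = frame_from_groups([[1.0], [2.0], [3.0]])
        g = group_equivalents(df, laue_p1)
        assert g.n_unique == 3 and np.all(g.sizes == 1)

    def test_group_count_matches_orbit_oracle(self, laue_mmm):
        rng = np.random.default_rng(4)
        hkl = rng.integers(-5, 6, (200, 3))
        hkl = hkl[hkl.any(axis=1)]
        df = pd.DataFrame({"h": hkl[:, 0], "k": hkl[:, 1], "l": hkl[:, 2],
                           "intensity": 1.0, "sigma": 1.0, "frame": 1.0})
        orbits = {frozenset(tuple(op @ h) for op in laue_mmm.operators)
                  for h in hkl}
        assert group_equivalents(df, laue_mmm).n_unique == len(orbits)


class TestRFactors:
    def test_hand_evaluated_pair(self, laue_p1):
        g = group_equivalents(frame_from_groups([[10.0, 12.0]]), laue_p1)
        assert r_int(g) == pytest.approx(2.0 / 22.0, abs=1e-15)
        assert r_meas(g) == pytest.approx(np.sqrt(2.0) * 2.0 / 22.0, abs=1e-15)

    def test_identical_equivalents_zero(self, laue_p1):
        g = group_equivalents(frame_from_groups([[5.0] * 4, [7.0] * 3]),
                              laue_p1)
        assert r_int(g) == 0.0 and r_meas(g) == 0.0

    def test_matches_brute_force_on_random_groups(self, laue_p1):
        rng = np.random.default_rng(9)
        groups = [list(rng.uniform(1, 100, rng.integers(1, 7)))
                  for _ in range(1000)]
        g = group_equivalents(frame_from_groups(groups), laue_p1)
        assert r_int(g) == pytest.approx(brute_force_r(groups, False),
                                         abs=1e-12)
        assert r_meas(g) == pytest.approx(brute_force_r(groups, True),
                                          abs=1e-12)

    @pytest.mark.parametrize("n", [2, 3, 5, 8])
    def test_ratio_is_sqrt_n_over_n_minus_1(self, n, laue_p1):
        rng = np.random.default_rng(n)
        g = group_equivalents(
            frame_from_groups([list(rng.uniform(10, 20, n))]), laue_p1)
        assert r_meas(g) / r_int(g) == pytest.approx(np.sqrt(n / (n - 1)))

    def test_r_meas_always_at_least_r_int(self, std_dataset, laue_mmm):
        g = group_equivalents(std_dataset.reflections, laue_mmm)
        assert r_meas(g) >= r_int(g)

    def test_all_singletons_undefined_not_zero(self, laue_p1):
        g = group_equivalents(frame_from_groups([[1.0], [2.0]]), laue_p1)
        with pytest.raises(StatisticUndefined):
            r_int(g)


class TestCcHalf:
    def test_identical_duplicates_exactly_100(self, laue_p1):
        rng = np.random.default_rng(0)
        groups = [[v, v] for v in rng.uniform(1, 100, 50)]
        cc, sig = cc_half(group_equivalents(frame_from_groups(groups),
                                            laue_p1))
        assert cc == 100.0 and sig

    def test_null_distribution_centred_on_zero(self, laue_p1):
        rng = np.random.default_rng(1)
        groups = [list(10.0 + rng.normal(0, 1, 4)) for _ in range(200)]
        g = group_equivalents(frame_from_groups(groups), laue_p1)
        ccs = [cc_half(g, seed=s)[0] for s in range(100)]
        # mean over seeds within 3 standard errors of zero
        se = np.std(ccs, ddof=1) / np.sqrt(len(ccs))
        assert abs(np.mean(ccs)) < max(3 * se, 3 * 100 / np.sqrt(200))

    def test_planted_variance_ratio_matches_pearson_expectation(self, laue_p1):
        # half-means: T_g + noise with Var(T)=sigma_s^2, Var(noise)=sigma_n^2
        sigma_s, sigma_n = 10.0, 5.0
        expected = 100.0 * sigma_s ** 2 / (sigma_s ** 2 + sigma_n ** 2)
        rng = np.random.default_rng(2)
        ccs = []
        for trial in range(200):
            t = rng.normal(100, sigma_s, 400)
            groups = [[tv + rng.normal(0, sigma_n), tv + rng.normal(0, sigma_n)]
                      for tv in t]
            g = group_equivalents(frame_from_groups(groups), laue_p1)
            ccs.append(cc_half(g, seed=trial)[0])
        se = np.std(ccs, ddof=1) / np.sqrt(len(ccs))
        assert np.mean(ccs) == pytest.approx(expected, abs=3 * se)

    def test_too_few_groups_undefined(self, laue_p1):
        g = group_equivalents(frame_from_groups([[1, 2], [3, 4]]), laue_p1)
        with pytest.raises(StatisticUndefined):
            cc_half(g)


class TestErrorModel:
    def _synthetic_groups(self, a, b, seed, n_groups=4000, mult=8):
        rng = np.random.default_rng(seed)
        rows = []
        for g in range(n_groups):
            i_true = rng.exponential(1000.0)
            sigma = np.sqrt(i_true + 100.0)
            sd = np.sqrt(a * (sigma ** 2 + b * i_true ** 2))
            for _ in range(mult):
                rows.append((g + 1, 1, 1, i_true + rng.normal(0, sd),
                             sigma, 1.0))
        return pd.DataFrame(rows, columns=["h", "k", "l", "intensity",
                                           "sigma", "frame"])

    @pytest.mark.parametrize("isa_true,a,b", [
        (100.0, 1.0, 1e-4), (33.33, 2.25, 4e-4), (20.0, 1.0, 2.5e-3)])
    def test_planted_isa_recovered_within_10_percent(self, isa_true, a, b,
                                                     laue_p1):
        df = self._synthetic_groups(a, b, seed=int(isa_true))
        model = fit_error_model(group_equivalents(df, laue_p1))
        assert model.isa is not None
        assert model.isa == pytest.approx(isa_true, rel=0.10)

    def test_noise_free_fit_degenerates_with_diagnostic(self, laue_p1):
        groups = [[float(v)] * 3 for v in range(10, 60)]
        model = fit_error_model(group_equivalents(frame_from_groups(groups),
                                                  laue_p1))
        assert model.isa is None and "degenerate" in model.diagnostic

    def test_too_few_groups_undefined(self, laue_p1):
        g = group_equivalents(frame_from_groups([[1, 2]] * 4), laue_p1)
        with pytest.raises(StatisticUndefined):
            fit_error_model(g)


class TestCompleteness:
    def test_full_unique_set_is_100(self, ortho_cell, laue_mmm):
        from edbatch.symmetry import enumerate_unique
        hkl = enumerate_unique(ortho_cell, laue_mmm, 20.0, 1.5)
        df = pd.DataFrame({"h": hkl[:, 0], "k": hkl[:, 1], "l": hkl[:, 2],
                           "intensity": 1.0, "sigma": 1.0, "frame": 1.0})
        g = group_equivalents(df, laue_mmm)
        assert completeness(g, ortho_cell, laue_mmm, 20.0, 1.5) == \
            pytest.approx(100.0)

    def test_half_the_set_is_50(self, ortho_cell, laue_mmm):
        from edbatch.symmetry import enumerate_unique
        hkl = enumerate_unique(ortho_cell, laue_mmm, 20.0, 1.5)
        half = hkl[: len(hkl) // 2]
        df = pd.DataFrame({"h": half[:, 0], "k": half[:, 1], "l": half[:, 2],
                           "intensity": 1.0, "sigma": 1.0, "frame": 1.0})
        g = group_equivalents(df, laue_mmm)
        expected = 100.0 * len(half) / len(hkl)
        assert completeness(g, ortho_cell, laue_mmm, 20.0, 1.5) == \
            pytest.approx(expected)

    def test_additive_over_disjoint_unique_sets(self, ortho_cell, laue_mmm):
        from edbatch.symmetry import enumerate_unique
        hkl = enumerate_unique(ortho_cell, laue_mmm, 20.0, 1.5)
        a, b = hkl[::2], hkl[1::2]
        def comp(sub):
            df = pd.DataFrame({"h": sub[:, 0], "k": sub[:, 1],
                               "l": sub[:, 2], "intensity": 1.0,
                               "sigma": 1.0, "frame": 1.0})
            return completeness(group_equivalents(df, laue_mmm), ortho_cell,
                                laue_mmm, 20.0, 1.5)
        assert comp(a) + comp(b) == pytest.approx(100.0)


class TestShells:
    def test_single_shell_equals_overall(self, std_dataset, ortho_cell,
                                         laue_mmm):
        shells = bin_shells(std_dataset.reflections, ortho_cell, laue_mmm,
                            n_shells=1)
        assert len(shells) == 2
        only, overall = shells
        assert only.n_obs == overall.n_obs
        assert only.r_meas == pytest.approx(overall.r_meas)
        assert only.cc_half == pytest.approx(overall.cc_half)

    def test_boundaries_monotone_decreasing(self, std_dataset, ortho_cell,
                                            laue_mmm):
        shells = bin_shells(std_dataset.reflections, ortho_cell, laue_mmm,
                            n_shells=8)
        ds = [s.d_max for s in shells if not s.overall]
        assert all(a > b for a, b in zip(ds, ds[1:]))
        for s in shells:
            assert s.d_max > s.d_min

    def test_equal_volume_binning_balances_counts(self, ortho_cell, laue_p1):
        # uniform density in 1/d^3 <=> uniform reciprocal-space density:
        # synthesize indices and check shell counts are multinomial-flat
        rng = np.random.default_rng(3)
        from edbatch.symmetry import enumerate_unique
        hkl = enumerate_unique(ortho_cell, laue_p1, 20.0, 0.9)
        df = pd.DataFrame({"h": hkl[:, 0], "k": hkl[:, 1], "l": hkl[:, 2],
                           "intensity": 1.0, "sigma": 1.0, "frame": 1.0})
        shells = bin_shells(df, ortho_cell, laue_p1, n_shells=6)
        counts = np.array([s.n_obs for s in shells if not s.overall])
        expected = counts.sum() / len(counts)
        # within 4 sigma of multinomial sampling error
        assert np.all(np.abs(counts - expected) < 4 * np.sqrt(expected))


def make_shell(d_max, d_min, cc, sig=True, i_sig=10.0, rint=0.1):
    return ShellStats(d_max=d_max, d_min=d_min, n_obs=100, n_unique=50,
                      cc_half=cc, cc_significant=sig,
                      mean_i_over_sigma=i_sig, r_int=rint, r_meas=rint * 1.2)


class TestResolutionRule:
    def test_cutoff_at_last_passing_shell(self):
        ccs = [99, 95, 60, 20, 5]
        shells = [make_shell(10 - i, 9 - i, cc) for i, cc in enumerate(ccs)]
        assert estimate_resolution(shells) == shells[2].d_min

    def test_all_pass_returns_data_d_min(self):
        shells = [make_shell(10 - i, 9 - i, 90) for i in range(5)]
        assert estimate_resolution(shells) == shells[-1].d_min

    def test_first_shell_fail_returns_inner_d_max_with_warning(self):
        shells = [make_shell(10 - i, 9 - i, 5) for i in range(5)]
        with pytest.warns(UserWarning, match="no resolution shell"):
            assert estimate_resolution(shells) == shells[0].d_max

    def test_insignificant_cc_fails_shell(self):
        shells = [make_shell(10, 9, 99), make_shell(9, 8, 95, sig=False),
                  make_shell(8, 7, 90)]
        assert estimate_resolution(shells) == shells[0].d_min

    def test_monotone_in_cc_threshold(self):
        rng = np.random.default_rng(5)
        ccs = sorted(rng.uniform(0, 100, 8), reverse=True)
        shells = [make_shell(10 - i, 9 - i, cc) for i, cc in enumerate(ccs)]
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")   # high thresholds fail all shells
            cuts = [estimate_resolution(shells, cc_half_min=t)
                    for t in (10, 30, 50, 70, 90)]
        assert all(a <= b for a, b in zip(cuts, cuts[1:]))


class TestDatasetSummary:
    def test_good_dataset_fills_everything(self, std_dataset, laue_mmm):
        row = dataset_summary(std_dataset, laue_mmm)
        assert row.r_meas is not None and row.r_meas < 0.1
        assert row.cc_half is not None and row.cc_half > 95
        assert row.isa is not None
        assert row.completeness is not None
        assert row.resolution_estimate is not None

    def test_sparse_dataset_partial_row_no_abort(self, mmm_truth, laue_mmm):
        wedge = WedgeSpec(0.0, 3.0, orientation=(5, 5, 5))
        rec = make_dataset(mmm_truth, wedge, seed=3, dataset_id="tiny")
        row = dataset_summary(rec, laue_mmm)
        assert row.dataset_id == "tiny"       # row produced despite failures

    def test_batch_of_12_yields_12_rows(self, mmm_truth, laue_mmm):
        rng = np.random.default_rng(8)
        rows = []
        for i in range(12):
            start = float(rng.uniform(0, 200))
            wedge = WedgeSpec(start, start + 40.0,
                              orientation=tuple(rng.uniform(0, 360, 3)))
            rec = make_dataset(mmm_truth, wedge,
                               seed=int(rng.integers(2 ** 31)),
                               dataset_id=f"e{i}")
            rows.append(dataset_summary(rec, laue_mmm))
        assert len(rows) == 12
        assert len({r.dataset_id for r in rows}) == 12


class TestInvariances:
    def test_statistics_invariant_under_global_scale(self, std_dataset,
                                                     laue_mmm):
        df = std_dataset.reflections.copy()
        g1 = group_equivalents(df, laue_mmm)
        df2 = df.copy()
        df2["intensity"] *= 37.5
        df2["sigma"] *= 37.5
        g2 = group_equivalents(df2, laue_mmm)
        assert r_meas(g2) == pytest.approx(r_meas(g1), rel=1e-12)
        assert cc_half(g2, seed=5)[0] == pytest.approx(
            cc_half(g1, seed=5)[0], rel=1e-9)
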