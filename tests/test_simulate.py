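"""Tests of the synthetic testcross trial generator and splitting rules."""

import numpy as np
import pytest

from gpkern.exceptions import (
    AlignmentError,
    InvalidConfigError,
    InvalidDesignError,
    ShapeError,
)
from gpkern.simulate import (
    SimConfig,
    derive_hybrid_genotypes,
    make_testcross_design,
    make_validation_splits,
    simulate_environments,
    simulate_inbred_panel,
    simulate_phenotypes,
    split_train_test,
)

FRACS = {"additive": 0.5, "residual": 0.5}


def _cfg(**kw):
    base = dict(
        n_inbreds=30, n_testers=2, n_snps=80, n_sites=3, n_years=1,
        variance_fractions=FRACS, seed=0,
    )
    base.update(kw)
    return SimConfig(**base)


class TestConfigValidation:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(InvalidConfigError):
            _cfg(variance_fractions={"additive": 0.6, "residual": 0.6})

    def test_negative_fraction_rejected(self):
        with pytest.raises(InvalidConfigError):
            _cfg(variance_fractions={"additive": 1.2, "residual": -0.2})

    @pytest.mark.parametrize("bad", [dict(n_snps=0), dict(n_inbreds=0),
                                     dict(maf_range=(0.0, 0.5)),
                                     dict(maf_range=(0.1, 0.6))])
    def test_invalid_counts_and_maf(self, bad):
        with pytest.raises(InvalidConfigError):
            _cfg(**bad)


class TestInbredPanel:
    def test_calls_homozygous(self, small_panel):
        assert set(np.unique(small_panel.calls)) <= {0, 2}

    def test_symmetric_maf_centers_calls(self):
        cfg = _cfg(n_inbreds=4000, n_snps=50, maf_range=(0.5, 0.5))
        panel = simulate_inbred_panel(cfg)
        mean = panel.calls.mean(axis=0)
        se = 3 * 2 * np.sqrt(0.25 / cfg.n_inbreds)
        assert np.all(np.abs(mean - 1.0) <= se)

    def test_deterministic_given_seed(self):
        cfg = _cfg(seed=9)
        a = simulate_inbred_panel(cfg)
        b = simulate_inbred_panel(cfg)
        assert np.array_equal(a.calls, b.calls)

    def test_maf_rejection_floor(self):
        cfg = _cfg(n_inbreds=100, n_snps=500, maf_range=(0.03, 0.5))
        panel = simulate_inbred_panel(cfg)
        # brute-force frequency scan of the emitted panel
        freqs = panel.calls.mean(axis=0) / 2.0
        maf = np.minimum(freqs, 1 - freqs)
        assert np.all(maf >= 0.03)


class TestTestcrossDesign:
    def test_single_tester_column_all_one(self):
        d = make_testcross_design(1, 3, 1)
        assert d.M.shape == (3, 4)
        assert np.all(d.M[:, 0] == 1)

    def test_row_sums_are_two(self, small_design):
        assert np.all(small_design.M.sum(axis=1) == 2)

    def test_mtm_diagonal_counts_progeny(self, small_design):
        MtM = small_design.M.T @ small_design.M
        counts = np.zeros(len(small_design.inbred_ids), dtype=int)
        idx = {iid: j for j, iid in enumerate(small_design.inbred_ids)}
        for tester, line in small_design.parent_pairs:
            counts[idx[tester]] += 1
            counts[idx[line]] += 1
        assert np.array_equal(np.diag(MtM), counts)

    def test_overlapping_tester_line_sets_rejected(self):
        with pytest.raises(InvalidDesignError):
            make_testcross_design(1, 2, 1, tester_ids=["a"], line_ids=["a", "b"])


class TestHybridGenotypes:
    def test_parental_average_values(self, small_hybrids):
        assert set(np.unique(small_hybrids.calls)) <= {0.0, 1.0, 2.0}

    def test_matches_explicit_loop(self, small_panel, small_design, small_hybrids):
        idx = {iid: j for j, iid in enumerate(small_panel.individual_ids)}
        for k, (t, l) in enumerate(small_design.parent_pairs):
            expect = 0.5 * (small_panel.calls[idx[t]] + small_panel.calls[idx[l]])
            np.testing.assert_allclose(small_hybrids.calls[k], expect)

    def test_misaligned_ids_raise(self, small_panel):
        d = make_testcross_design(2, 3, 1, tester_ids=["x", "y"],
                                  line_ids=["u", "v", "w"])
        with pytest.raises((AlignmentError, ShapeError)):
            derive_hybrid_genotypes(small_panel, d)


class TestEnvironments:
    def test_day_count_inclusive(self, small_trial, small_config):
        assert small_trial.weather.shape[2] == 280 == small_config.n_days

    def test_years_of_site_share_soil(self, small_trial):
        by_sy = small_trial.soil_by_site_year()
        s0 = [sy for sy in small_trial.site_years if sy.startswith("S00")]
        assert len(s0) == 2
        np.testing.assert_array_equal(by_sy.loc[s0[0]], by_sy.loc[s0[1]])

    def test_deterministic(self, small_config):
        a = simulate_environments(small_config)
        b = simulate_environments(small_config)
        np.testing.assert_array_equal(a.weather, b.weather)


class TestPhenotypes:
    def test_pure_additive_is_perfectly_linear(self, small_hybrids, small_trial):
        cfg = _cfg(n_inbreds=33, n_testers=3, n_snps=120, n_sites=4, n_years=2,
                   variance_fractions={"additive": 1.0})
        tab = simulate_phenotypes(small_hybrids, small_trial, cfg)
        # y is an exact linear function of the additive component
        a = tab.components["additive"]
        y = tab.data["yield"].to_numpy()
        r = np.corrcoef(a, y)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_realized_fractions_match_request(self, small_phenotypes, small_config):
        total = sum(np.var(v) for v in small_phenotypes.components.values())
        for name, frac in small_config.fractions().items():
            realized = np.var(small_phenotypes.components[name]) / total
            assert realized == pytest.approx(frac, abs=0.02)

    def test_no_genetics_leaves_residual_only_within_env(self, small_hybrids, small_trial):
        cfg = _cfg(n_inbreds=33, n_testers=3, n_snps=120, n_sites=4, n_years=2,
                   variance_fractions={"environment": 0.5, "residual": 0.5})
        tab = simulate_phenotypes(small_hybrids, small_trial, cfg)
        # within any environment only residual variance remains (ANOVA view)
        df = tab.data.assign(resid=tab.components["residual"])
        for _, grp in df.groupby("site_year"):
            y = grp["yield"].to_numpy()
            y = (y - 150.0) / 25.0  # back to the standardized scale
            np.testing.assert_allclose(np.var(y), np.var(grp["resid"]), rtol=1e-8)

    def test_all_zero_fractions_rejected(self, small_hybrids, small_trial):
        with pytest.raises(InvalidConfigError):
            SimConfig(
                n_inbreds=33, n_testers=3, n_snps=120, n_sites=4, n_years=2,
                variance_fractions={"additive": 0.0, "residual": 0.0}, seed=0,
            )


class TestSplitting:
    def test_no_cap_drops_nothing(self, small_phenotypes):
        out = split_train_test(small_phenotypes, test_site_year_count=2, cap=None, seed=0)
        assert out.n_records == small_phenotypes.n_records

    def test_cap_downsamples_to_exactly_cap(self, small_phenotypes):
        out = split_train_test(small_phenotypes, test_site_year_count=2, cap=40, seed=0)
        counts = out.data.groupby("site_year").size()
        assert counts.max() == 40

    def test_test_site_years_absent_from_train(self, split_table):
        train_sy = set(split_table.data.loc[split_table.train_mask(), "site_year"])
        test_sy = set(split_table.data.loc[~split_table.train_mask(), "site_year"])
        assert not train_sy & test_sy

    def test_standardization_contract(self, split_table):
        y = split_table.data.loc[split_table.train_mask(), "y_std"]
        assert abs(y.mean()) < 1e-10
        assert abs(y.std(ddof=0) - 1.0) < 1e-10

    def test_bit_identical_under_seed(self, small_phenotypes):
        a = split_train_test(small_phenotypes, 2, cap=40, seed=7)
        b = split_train_test(small_phenotypes, 2, cap=40, seed=7)
        assert a.data.equals(b.data)


class TestValidationSplits:
    def test_requested_number_and_reproducibility(self, split_table):
        a = make_validation_splits(split_table, n_splits=10, n_env_per_split=2, seed=1)
        b = make_validation_splits(split_table, n_splits=10, n_env_per_split=2, seed=1)
        assert len(a) == 10
        for sa, sb in zip(a, b):
            assert sa["val_site_years"] == sb["val_site_years"]

    def test_partition_structure(self, split_table):
        splits = make_validation_splits(split_table, n_splits=5, n_env_per_split=2, seed=0)
        train_all = split_table.train_mask()
        for s in splits:
            # validation disjoint from that split's training portion
            assert not np.any(s["train_index"] & s["val_index"])
            # union restores the full training set
            np.testing.assert_array_equal(s["train_index"] | s["val_index"], train_all)
            # validation = all records of the sampled site-years
            sy = split_table.data["site_year"].isin(s["val_site_years"]).to_numpy()
            np.testing.assert_array_equal(s["val_index"], sy & train_all)

    def test_too_many_envs_rejected(self, split_table):
        with pytest.raises(InvalidConfigError):
            make_validation_splits(split_table, n_splits=2, n_env_per_split=99, seed=0)
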