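import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phylorates import ltt, simulate
from phylorates.rates import (
    FamilyRecord,
    binned_rates,
    doubling_time,
    family_table_path,
    load_family_table,
    mean_rate,
    normalize_ltt,
    overall_rate,
    rate_table,
    round_half_up,
    tabulated_doubling_time,
)

from conftest import yule_tree


class TestOverallRate:
    @pytest.mark.parametrize(
        "n, age, expected",
        [(5, 5500, 0.00029), (1268, 5230, 0.00137), (35, 6500, 0.00055)],
    )
    def test_published_rows(self, n, age, expected):
        assert round_half_up(overall_rate(n, age), 5) == expected

    def test_trivial_single_lineage(self):
        assert overall_rate(1, 1000) == 0.0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            overall_rate(0, 1000)
        with pytest.raises(ValueError):
            overall_rate(5, 0)


class TestDoublingTime:
    def test_ln2_inverse(self):
        assert doubling_time(math.log(2)) == pytest.approx(1.0)

    @pytest.mark.parametrize("r, expected", [(0.00029, 2390), (0.00082, 845)])
    def test_published_doubling_times(self, r, expected):
        assert tabulated_doubling_time(r) == expected

    def test_domain_error(self):
        with pytest.raises(ValueError):
            doubling_time(0.0)

    @given(st.floats(min_value=1e-6, max_value=1.0))
    @settings(max_examples=100, deadline=None)
    def test_inverse_identity(self, r):
        assert r * doubling_time(r) == pytest.approx(math.log(2), rel=1e-12)


class TestRateTable:
    def test_fixture_shape_and_order(self):
        records = load_family_table()
        table = rate_table(records)
        assert len(table) == 36  # 18 families x 2 catalogs
        eth = [e for e in table if e.catalog == "ethnologue"]
        assert [e.r_e for e in eth] == sorted(e.r_e for e in eth)

    def test_permutation_invariant(self):
        records = load_family_table()
        fwd = rate_table(records)
        rev = rate_table(records[::-1])
        assert [(e.family, e.catalog, e.r_e) for e in fwd] == [
            (e.family, e.catalog, e.r_e) for e in rev
        ]

    def test_direct_formula_oracle_random_fixture(self, rng):
        records = [
            FamilyRecord(
                family=f"f{i}",
                root_age=float(rng.uniform(500, 9000)),
                n_ethnologue=int(rng.integers(2, 2000)),
                n_glottolog=int(rng.integers(2, 2000)),
            )
            for i in range(25)
        ]
        by_key = {(e.family, e.catalog): e for e in rate_table(records)}
        for rec in records:
            for cat, n in [("ethnologue", rec.n_ethnologue), ("glottolog", rec.n_glottolog)]:
                e = by_key[(rec.family, cat)]
                assert e.r_e == math.log(n) / rec.root_age
                assert e.doubling_time == round(math.log(2) / round_half_up(e.r_e, 5))

    def test_self_inverse_pair(self):
        T = math.log(2) * 1e5
        rec = FamilyRecord(family="x", root_age=T, n_ethnologue=2)
        (e,) = rate_table([rec], catalogs=("ethnologue",), rate_decimals=None)
        assert e.r_e == pytest.approx(math.log(2) / T)
        assert e.doubling_time == pytest.approx(T, rel=1e-5)

    def test_record_without_counts_skipped_with_warning(self):
        recs = [
            FamilyRecord(family="ok", root_age=1000, n_ethnologue=5),
            FamilyRecord(family="empty", root_age=1000, n_sample=3),
        ]
        with pytest.warns(UserWarning, match="empty"):
            table = rate_table(recs)
        assert {e.family for e in table} == {"ok"}


class TestNormalize:
    def test_endpoint_definitions(self, rng):
        tree = yule_tree(rng, lam=0.002, max_time=2000)
        s = ltt.compute_ltt(tree)
        norm = normalize_ltt(s, tree.n_tips, tree.root_age)
        assert norm.value_at(0.0) == pytest.approx(1.0)
        assert norm.t_prime[0] == pytest.approx(1.0)

    def test_cherry(self):
        s = ltt.LTTSeries(np.array([2.0]), np.array([2]))
        norm = normalize_ltt(s, 2, 2.0)
        assert norm.value_at(1.0) == pytest.approx(1.0)
        assert norm.value_at(0.3) == pytest.approx(1.0)

    def test_denormalize_roundtrip(self, rng):
        tree = yule_tree(rng, lam=0.002, max_time=2500)
        s = ltt.compute_ltt(tree)
        norm = normalize_ltt(s, tree.n_tips, tree.root_age)
        np.testing.assert_allclose(norm.t_prime * tree.root_age, s.times, rtol=1e-12)
        np.testing.assert_allclose(norm.n_prime * tree.n_tips, s.counts, rtol=1e-12)

    def test_n_max_below_tip_count_rejected(self):
        s = ltt.LTTSeries(np.array([2.0, 1.0]), np.array([2, 5]))
        with pytest.raises(ValueError, match="configuration mistake"):
            normalize_ltt(s, 3, 2.0)


class TestBinnedRates:
    def test_exact_exponential_constant_rate(self):
        # N doubles every 10% of the depth: every bin rate is ln(N_max)/T
        T, n_bins = 5000.0, 10
        times = T * (1.0 - np.arange(n_bins + 1) / n_bins)
        counts = 2 ** np.arange(1, n_bins + 2)
        s = ltt.LTTSeries(times, counts)
        norm = normalize_ltt(s, int(counts[-1]), T)
        b = binned_rates(norm, T, n_bins=n_bins)
        np.testing.assert_allclose(b.rates, math.log(2) / (T / n_bins), rtol=1e-12)

    def test_constant_counts_zero_rates(self):
        s = ltt.LTTSeries(np.array([3000.0]), np.array([7]))
        b = binned_rates(normalize_ltt(s, 7, 3000.0), 3000.0)
        np.testing.assert_array_equal(b.rates, np.zeros(10))

    def test_telescoping_and_direct_oracle(self, rng):
        for _ in range(10):
            tree = yule_tree(rng, lam=0.002, max_time=rng.uniform(1500, 3500))
            s = ltt.compute_ltt(tree)
            norm = normalize_ltt(s, tree.n_tips, tree.root_age)
            b = binned_rates(norm, tree.root_age)
            total = np.sum(b.rates) * 0.1 * tree.root_age
            assert total == pytest.approx(
                math.log(s.counts[-1] / s.counts[0]), rel=1e-12, abs=1e-12
            )
            # direct recomputation from the raw series at the bin edges
            edges_bp = b.bin_edges * tree.root_age
            n_edges = np.asarray(s.value_at(edges_bp), dtype=float)
            direct = np.diff(np.log(n_edges)) / (0.1 * tree.root_age)
            np.testing.assert_allclose(b.rates, direct, rtol=1e-12)

    def test_min_bins(self):
        s = ltt.LTTSeries(np.array([3000.0]), np.array([7]))
        with pytest.raises(ValueError):
            binned_rates(normalize_ltt(s, 7, 3000.0), 3000.0, n_bins=1)


class TestMeanRate:
    def test_all_equal_degenerate_ci(self):
        rates = [0.002] * 5
        out = mean_rate(rates, reps=1000, seed=0)
        assert out.mean == pytest.approx(0.002)
        assert out.ci_low == out.ci_high == pytest.approx(0.002)

    def test_deterministic_given_seed(self):
        vals = list(np.linspace(0.0005, 0.002, 18))
        a = mean_rate(vals, reps=10_000, seed=42)
        b = mean_rate(vals, reps=10_000, seed=42)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_subsampling_widens_interval(self):
        vals = list(np.linspace(0.0005, 0.002, 18))
        full = mean_rate(vals, reps=10_000, seed=1)
        small = mean_rate(vals, reps=10_000, seed=1, subsample=6)
        assert (small.ci_high - small.ci_low) > (full.ci_high - full.ci_low)

    def test_coverage_against_normal_theory(self, rng):
        # on Gaussian synthetic rates the percentile CI matches the t interval
        from scipy import stats

        x = rng.normal(0.001, 0.0002, size=200)
        boot = mean_rate(x, reps=10_000, seed=7)
        se = x.std(ddof=1) / math.sqrt(x.size)
        lo, hi = stats.t.interval(0.95, df=x.size - 1, loc=x.mean(), scale=se)
        assert boot.ci_low == pytest.approx(lo, abs=0.25 * (hi - lo))
        assert boot.ci_high == pytest.approx(hi, abs=0.25 * (hi - lo))

    def test_rejects_tiny_inputs(self):
        with pytest.raises(ValueError):
            mean_rate([0.001], reps=1000)
        with pytest.raises(ValueError):
            mean_rate([0.001, 0.002], reps=10)


class TestFamilyTable:
    def test_packaged_fixture_loads(self):
        records = load_family_table()
        assert len(records) == 18
        by_name = {r.family: r for r in records}
        assert by_name["Austronesian"].n_ethnologue == 1268
        assert by_name["Indo-European"].root_age == 8700
        assert by_name["Lezgic"].has_dialects
        ages = [r.root_age for r in records]
        assert min(ages) == 1000 and max(ages) == 8700

    def test_missing_columns_rejected(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text("family\tn_ethnologue\nX\t4\n")
        with pytest.raises(ValueError, match="missing columns"):
            load_family_table(bad)

    def test_fixture_path_exists(self):
        assert family_table_path().is_file()

    def test_pure_birth_recovery_bias_bounded(self, rng):
        # ln(tips)/crown age is within 25% of lambda on average at lambda*T >= 3
        lam, T = 0.001, 4000.0
        rates = []
        for _ in range(500):
            res = simulate.simulate_tree(
                simulate.BDParams(lambda0=lam, max_time=T), rng=rng
            )
            rates.append(overall_rate(res.n_extant, res.tree.root_age))
        assert np.mean(rates) == pytest.approx(lam, rel=0.25)
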