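"""Summary statistics, exceedance accounting, rank tests, correlations."""

import itertools

import numpy as np
import pytest
from scipy import stats

from pahkit.descriptive import (
    summarize, exceedance, mw_proportions, correlation_matrix, compare_groups,
)
from pahkit.synthetic import SyntheticSpec, default_profiles, generate_samples
from tests.conftest import make_record


def records_with_pm(values, year=2019):
    return [make_record(date=f"{year}-{1 + (i // 28) % 12:02d}-{(i % 28)+1:02d}",
                        pm25=v)
            for i, v in enumerate(values)]


class TestSummarize:
    def test_small_sample_quartiles(self):
        recs = records_with_pm([1, 2, 3, 4, 5])
        row = summarize(recs, "pm25", by="all").iloc[0]
        assert (row["median"], row["p25"], row["p75"]) == (3, 2, 4)

    def test_single_value_degenerate(self):
        row = summarize(records_with_pm([7]), "pm25", by="all").iloc[0]
        assert (row["median"], row["p25"], row["p75"]) == (7, 7, 7)

    def test_constant_series(self):
        recs = [make_record(date=f"2022-02-{i+1:02d}",
                            **{c: 3.60 / 16 for c in
                               ("Nap", "Acy", "Flu", "Ace", "Phe", "Ant", "Flua",
                                "Pyr", "Chr", "BaA", "BbF", "BkF", "BaP", "DahA",
                                "BghiP", "IcdP")})
                for i in range(10)]
        row = summarize(recs, "total_pah", by="year").iloc[0]
        assert row["median"] == pytest.approx(3.60)

    @pytest.mark.parametrize("n", range(1, 9))
    def test_matches_sort_based_oracle(self, n):
        rng = np.random.default_rng(n)
        vals = rng.uniform(0, 100, n)
        row = summarize(records_with_pm(vals), "pm25", by="all").iloc[0]

        def oracle(q):  # linear interpolation between order statistics
            v = np.sort(vals)
            h = (n - 1) * q
            lo = int(np.floor(h))
            hi = min(lo + 1, n - 1)
            return v[lo] + (h - lo) * (v[hi] - v[lo])

        assert row["median"] == pytest.approx(oracle(0.5))
        assert row["p25"] == pytest.approx(oracle(0.25))
        assert row["p75"] == pytest.approx(oracle(0.75))


class TestExceedance:
    def test_printed_rate_arithmetic(self):
        # 213 strict exceedances among 892 samples -> 23.88%
        recs = [make_record(date=f"{2017 + i % 6}-{1 + (i // 6) % 12:02d}"
                            f"-{1 + (i // 72) % 28:02d}",
                            pm25=36.0 if i < 213 else 30.0)
                for i in range(892)]
        rep = exceedance(recs, 35.0, "pm25")
        row = rep.table.iloc[0]
        assert row["n_exceed"] == 213 and row["n_total"] == 892
        assert row["rate"] == 23.88

    def test_zero_exceedances(self):
        rep = exceedance(records_with_pm([10.0] * 100), 35.0, "pm25")
        assert rep.table.iloc[0]["rate"] == 0.00

    def test_strict_inequality_convention(self):
        rep = exceedance(records_with_pm([36, 35, 34]), 35.0, "pm25")
        assert rep.table.iloc[0]["n_exceed"] == 1

    def test_order_invariance_and_stratified_sum(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 80, 60)
        recs = [make_record(date=f"{2019 + (i % 3)}-03-{(i % 28)+1:02d}", pm25=v)
                for i, v in enumerate(vals)]
        pooled = exceedance(recs, 35.0, "pm25").table.iloc[0]["n_exceed"]
        by_year = exceedance(recs, 35.0, "pm25", by="year").table
        assert by_year["n_exceed"].sum() == pooled
        shuffled = [recs[i] for i in rng.permutation(len(recs))]
        assert exceedance(shuffled, 35.0, "pm25").table.iloc[0]["n_exceed"] == pooled


class TestMwProportions:
    def test_all_mass_on_bap_is_hmw(self, catalog):
        rec = make_record(**{c: 0.0 for c in
                             "Nap Acy Flu Ace Phe Ant Flua Pyr Chr BaA BbF BkF DahA BghiP IcdP".split()},
                          BaP=5.0)
        row = mw_proportions([rec], catalog).iloc[0]
        assert row["HMW"] == pytest.approx(1.0)

    def test_equal_mass_nap_and_pyr(self, catalog):
        rec = make_record(**{c: 0.0 for c in
                             "Acy Flu Ace Phe Ant Flua Chr BaA BbF BkF BaP DahA BghiP IcdP".split()},
                          Nap=2.0, Pyr=2.0)
        row = mw_proportions([rec], catalog).iloc[0]
        assert row["LMW"] == pytest.approx(0.5)
        assert row["MMW"] == pytest.approx(0.5)
        assert row["HMW"] == pytest.approx(0.0)

    def test_fractions_sum_to_one(self, catalog, small_campaign):
        _, records, _, _ = small_campaign
        tab = mw_proportions(records, catalog)
        np.testing.assert_allclose(tab[["LMW", "MMW", "HMW"]].sum(axis=1), 1.0,
                                   atol=1e-9)

    def test_doubled_mmw_profiles_double_the_fraction_ratio(self, catalog):
        """Forward-model check: scaling 4-ring species mass by 2 in year 2
        roughly doubles the MMW:other odds."""
        prof = default_profiles()
        spec1 = SyntheticSpec(n_days=120, n_sites=1, seed=8, censor=False,
                              noise_cv=0.1, n_years=1, true_profiles=prof)
        from pahkit.species import SPECIES_ORDER
        prof2 = prof.copy()
        for j, c in enumerate(SPECIES_ORDER):
            if catalog[c].mw_class == "MMW":
                prof2[:, j] *= 2
        spec2 = SyntheticSpec(n_days=120, n_sites=1, seed=8, censor=False,
                              noise_cv=0.1, n_years=1, start_year=2018,
                              true_profiles=prof2)
        r1, _, _ = generate_samples(spec1)
        r2, _, _ = generate_samples(spec2)
        t1 = mw_proportions(r1, catalog).iloc[0]
        t2 = mw_proportions(r2, catalog).iloc[0]
        odds1 = t1["MMW"] / (1 - t1["MMW"])
        odds2 = t2["MMW"] / (1 - t2["MMW"])
        assert odds2 / odds1 == pytest.approx(2.0, rel=0.1)


class TestCorrelation:
    def test_monotone_pairs(self):
        recs = [make_record(date=f"2019-01-{i+1:02d}", pm25=float(i + 1),
                            temp=2.0 * (i + 1), pressure=-float(i + 1))
                for i in range(10)]
        rho, _ = correlation_matrix(recs, ["pm25", "temp", "pressure"])
        assert rho.loc["pm25", "temp"] == pytest.approx(1.0)
        assert rho.loc["pm25", "pressure"] == pytest.approx(-1.0)
        assert np.allclose(np.diag(rho), 1.0)
        assert rho.equals(rho.T)

    def test_independent_shuffle_is_near_zero(self):
        rng = np.random.default_rng(0)
        n = 400
        x = rng.normal(size=n)
        recs = [make_record(date=f"{2015 + i // 336}-{1 + (i // 28) % 12:02d}"
                            f"-{(i % 28)+1:02d}",
                            pm25=abs(x[i]) + 1, temp=float(rng.normal()))
                for i in range(n)]
        rho, _ = correlation_matrix(recs, ["pm25", "temp"])
        assert abs(rho.loc["pm25", "temp"]) < 2 / np.sqrt(n)

    def test_constant_variable_flagged_not_raised(self):
        recs = [make_record(date=f"2019-01-{i+1:02d}", pm25=float(i), temp=5.0)
                for i in range(10)]
        rho, sig = correlation_matrix(recs, ["pm25", "temp"])
        assert np.isnan(rho.loc["pm25", "temp"])
        assert not sig.loc["pm25", "temp"]


def exact_mwu_pvalue(a, b):
    """Two-sided exact Mann-Whitney p by enumerating all group splits."""
    pooled = np.concatenate([a, b])
    n = len(a)
    u_obs = stats.mannwhitneyu(a, b, alternative="two-sided",
                               method="exact").statistic
    us = []
    for idx in itertools.combinations(range(len(pooled)), n):
        grp = pooled[list(idx)]
        rest = np.delete(pooled, list(idx))
        u = sum((x > y) + 0.5 * (x == y) for x in grp for y in rest)
        us.append(u)
    us = np.array(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(p, 1.0)


class TestCompareGroups:
    @staticmethod
    def _recs(groups):
        recs = []
        for site, vals in zip("ABCD", groups):
            recs += [make_record(date=f"2019-01-{i+1:02d}", site=site, pm25=v)
                     for i, v in enumerate(vals)]
        return recs

    def test_identical_groups_give_p_one(self):
        _, p = compare_groups(self._recs([[1, 2, 3], [1, 2, 3]]), "site")
        assert p == pytest.approx(1.0)

    def test_fully_separated_small_groups_reach_minimal_p(self):
        # all C(6,3)=20 rank splits; extreme split has exact p = 2/20
        _, p = compare_groups(self._recs([[1, 2, 3], [101, 102, 103]]), "site")
        assert p == pytest.approx(0.1)

    def test_three_identical_groups_h_zero(self):
        h, p = compare_groups(self._recs([[1, 2, 3]] * 3), "site")
        assert h == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_exact_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=4) + 10, rng.normal(size=5) + 10.5
        _, p = compare_groups(self._recs([a, b]), "site")
        assert p == pytest.approx(exact_mwu_pvalue(a, b))

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups(self._recs([[1, 2, 3]]), "site")
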