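import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from progmet.analysis import (
    combinatorial_profile,
    compare_profiles,
    conditional_analysis,
    multivariable_models,
    profile_table,
)
from progmet.cluster import assign_tertiles, tertile_cutpoints

from conftest import make_clinical


def tertiles_of(values, index):
    s = pd.Series(values, index=index)
    return assign_tertiles(s, tertile_cutpoints(s))


def simulate_tertile_cohort(rng, n=600, beta=(0.0, 0.0), shared=False, prolif_beta=0.5):
    """Clinical frame + tertile dict driven by latent factors (test-local
    generator, independent of the package simulator)."""
    f_p = rng.normal(size=n)
    f1 = rng.normal(size=n)
    f2 = 0.98 * f1 + np.sqrt(1 - 0.98**2) * rng.normal(size=n) if shared else rng.normal(size=n)
    f3 = rng.normal(size=n)
    eta = prolif_beta * f_p + beta[0] * f1 + beta[1] * f2
    t = rng.exponential(1 / (0.1 * np.exp(eta)))
    c = np.minimum(rng.exponential(15.0, n), 10.0)
    time, ev = np.minimum(t, c), (t <= c).astype(int)
    clin = make_clinical(time, ev)
    ids = clin["sample_id"]
    terts = {
        "proliferation": tertiles_of(f_p + 0.3 * rng.normal(size=n), ids),
        "m1": tertiles_of(f1 + 0.3 * rng.normal(size=n), ids),
        "m2": tertiles_of(f2 + 0.3 * rng.normal(size=n), ids),
        "m3": tertiles_of(f3 + 0.3 * rng.normal(size=n), ids),
    }
    return clin, terts


class TestConditionalAnalysis:
    def test_strata_partition_cohort(self, rng):
        clin, terts = simulate_tertile_cohort(rng)
        results = conditional_analysis(terts, clin)
        by_metagene = {}
        for r in results:
            by_metagene.setdefault(r.metagene, 0)
            by_metagene[r.metagene] += r.n
        assert set(by_metagene.values()) == {len(clin)}

    def test_zero_event_stratum_skipped(self, rng):
        clin, terts = simulate_tertile_cohort(rng, n=90)
        # kill all events in the low proliferation tertile
        low_ids = terts["proliferation"][terts["proliferation"] == 1].index
        clin.loc[clin["sample_id"].isin(low_ids), "dmfs_event"] = 0
        results = conditional_analysis(terts, clin)
        low = [r for r in results if r.stratum["proliferation_tertile"] == "P_L"]
        assert low and all(r.skipped and "events" in r.reason for r in low)

    def test_small_stratum_skipped(self, rng):
        clin, terts = simulate_tertile_cohort(rng, n=60)
        results = conditional_analysis(terts, clin, min_n=50)
        assert all(r.skipped for r in results)
        assert all(r.n > 0 for r in results)

    def test_unknown_stratum_key(self, rng):
        clin, terts = simulate_tertile_cohort(rng, n=60)
        with pytest.raises(KeyError, match="unknown stratum"):
            conditional_analysis(terts, clin, strata_by="bogus")

    def test_subtype_stratification(self, rng):
        clin, terts = simulate_tertile_cohort(rng, n=300)
        clin["subtype"] = np.where(np.arange(len(clin)) % 2 == 0, "LumA", "Basal")
        results = conditional_analysis(terts, clin, strata_by="subtype")
        strata = {r.stratum["subtype"] for r in results}
        assert strata == {"LumA", "Basal"}

    def test_null_false_positive_rate(self):
        rng = np.random.default_rng(15)
        n_sig = n_tot = 0
        for _ in range(100):
            clin, terts = simulate_tertile_cohort(rng, n=240, beta=(0.0, 0.0), prolif_beta=0.0)
            results = conditional_analysis(
                {"proliferation": terts["proliferation"], "m1": terts["m1"]}, clin
            )
            for r in results:
                if not r.skipped and r.cox is not None:
                    n_tot += 1
                    n_sig += r.cox.lrt_p < 0.05
        # binomial band around 0.05 with ~300 tests
        assert 0.02 <= n_sig / n_tot <= 0.09


class TestMultivariableModels:
    def test_independent_metagenes_both_significant(self):
        wins = 0
        for r in range(20):
            rng = np.random.default_rng(500 + r)
            clin, terts = simulate_tertile_cohort(rng, beta=(-0.5, -0.5))
            models = multivariable_models(terts, clin, metagenes=["m1", "m2", "m3"],
                                          stratum_level=3)
            m1 = models["model_1"]  # m1 + m2 pairwise
            wins += (m1.wald_p[0] < 0.05) and (m1.wald_p[1] < 0.05)
        assert wins >= 12

    def test_shared_factor_collinearity(self):
        at_most_one, wider = 0, 0
        for r in range(10):
            rng = np.random.default_rng(700 + r)
            clin, terts = simulate_tertile_cohort(rng, beta=(-0.25, -0.25), shared=True)
            models = multivariable_models(terts, clin, metagenes=["m1", "m2", "m3"],
                                          stratum_level=3)
            joint = models["model_1"]
            at_most_one += (joint.wald_p[0] < 0.05) + (joint.wald_p[1] < 0.05) <= 1
            uni = multivariable_models(
                {"m1": terts["m1"], "m2": terts["m2"], "m3": terts["m3"]},
                clin, metagenes=["m1", "m2", "m3"], stratum_level=3,
            )
            # joint CI for m1 wider than its CI in... compare to pairwise with
            # the independent m3 instead
            m1_with_m3 = models["model_2"]  # m1 + m3
            w_joint = np.log(joint.ci95_high[0] / joint.ci95_low[0])
            w_indep = np.log(m1_with_m3.ci95_high[0] / m1_with_m3.ci95_low[0])
            wider += w_joint > w_indep
        assert at_most_one >= 7
        assert wider >= 9

    def test_table4_style_conventional_model(self, rng):
        clin, terts = simulate_tertile_cohort(rng, beta=(-0.4, -0.3))
        n = len(clin)
        clin["er_status"] = np.where(rng.random(n) < 0.25, "negative", "positive")
        clin["ln_status"] = np.where(rng.random(n) < 0.25, "positive", "negative")
        clin["treatment"] = rng.choice(["none", "tamoxifen", "chemotherapy"], size=n)
        clin["tumor_size_class"] = rng.choice(["T1", "T2", "T3"], size=n)
        clin["grade"] = rng.choice(["1", "2", "3"], size=n)
        clin["age_years"] = rng.normal(50, 12, size=n).round(1)
        models = multivariable_models(terts, clin, metagenes=["m1", "m2", "m3"],
                                      include_conventional=True)
        res = models["conventional"]
        assert set(res.names) == {"m1 (L,I,H)", "m2 (L,I,H)", "m3 (L,I,H)",
                                  "ln_positive", "tumor_size", "grade", "age_le_40",
                                  "er_negative", "treated"}
        assert res.meta["codings"]["er_negative"].startswith("er_status")
        assert res.meta["tertile_coding"].startswith("low=1")

    def test_all_censored_error(self, rng):
        clin, terts = simulate_tertile_cohort(rng, n=120)
        clin["dmfs_event"] = 0
        with pytest.raises(ValueError, match="no events"):
            multivariable_models(terts, clin, metagenes=["m1", "m2", "m3"])


class TestCombinatorialProfile:
    def test_all_low(self):
        p = combinatorial_profile((1, 1, 1))
        assert p.n_low == 3 and p.group == "ge1_low"

    def test_all_high(self):
        p = combinatorial_profile((3, 3, 3))
        assert p.n_high == 3 and p.group == "all_high"

    def test_two_high_plus_intermediate(self):
        assert combinatorial_profile((3, 3, 2)).group == "two_high_plus_intermediate"

    def test_two_high_plus_low(self):
        assert combinatorial_profile((3, 3, 1)).group == "two_high_plus_low"

    def test_invalid_level(self):
        with pytest.raises(ValueError):
            combinatorial_profile((0, 2, 3))

    @given(st.tuples(st.integers(1, 3), st.integers(1, 3), st.integers(1, 3)))
    def test_permutation_invariant(self, levels):
        base = combinatorial_profile(levels)
        for perm in itertools.permutations(levels):
            p = combinatorial_profile(perm)
            assert (p.n_low, p.n_high, p.group) == (base.n_low, base.n_high, base.group)

    def test_consistency_invariant(self):
        for levels in itertools.product((1, 2, 3), repeat=3):
            p = combinatorial_profile(levels)
            assert p.n_low + p.n_high <= 3
            assert p.n_low == sum(1 for l in levels if l == 1)
            assert p.n_high == sum(1 for l in levels if l == 3)


class TestCompareProfiles:
    def _min_effect_cohort(self, rng, n=600, gamma=-0.6):
        f = rng.normal(size=(3, n))
        eta = gamma * f.min(axis=0)
        t = rng.exponential(1 / (0.12 * np.exp(eta)))
        c = np.minimum(rng.exponential(15.0, n), 10.0)
        clin = make_clinical(np.minimum(t, c), (t <= c).astype(int))
        ids = clin["sample_id"]
        terts = {f"m{k + 1}": tertiles_of(f[k], ids) for k in range(3)}
        return clin, terts

    def test_min_effect_pattern(self):
        good = 0
        reps = 15
        for r in range(reps):
            rng = np.random.default_rng(800 + r)
            clin, terts = self._min_effect_cohort(rng)
            profs = profile_table(terts, ["m1", "m2", "m3"])
            separates = compare_profiles(profs, clin, "all_high_vs_ge1_low").logrank_p < 0.05
            # pairwise comparisons among 1/2/3-low groups: none significant
            pair_ps = []
            for a, b in itertools.combinations(["one_low", "two_low", "three_low"], 2):
                grouping = {
                    a: {"one_low": lambda p: p["n_low"] == 1,
                        "two_low": lambda p: p["n_low"] == 2,
                        "three_low": lambda p: p["n_low"] == 3}[a],
                    b: {"one_low": lambda p: p["n_low"] == 1,
                        "two_low": lambda p: p["n_low"] == 2,
                        "three_low": lambda p: p["n_low"] == 3}[b],
                }
                pair_ps.append(compare_profiles(profs, clin, grouping).logrank_p)
            good += separates and all(p > 0.05 for p in pair_ps)
        assert good >= int(0.7 * reps)

    def test_single_group_error(self, rng):
        clin, terts = self._min_effect_cohort(rng, n=100)
        profs = profile_table(terts, ["m1", "m2", "m3"])
        with pytest.raises(ValueError, match="at least 2"):
            compare_profiles(profs, clin, {"only": lambda p: True})

    def test_empty_group_error(self, rng):
        clin, terts = self._min_effect_cohort(rng, n=100)
        profs = profile_table(terts, ["m1", "m2", "m3"])
        grouping = {
            "impossible": lambda p: p["n_low"] > 5,
            "rest": lambda p: True,
        }
        with pytest.raises(ValueError, match="empty"):
            compare_profiles(profs, clin, grouping)

    def test_stratum_mask_restricts(self, rng):
        clin, terts = self._min_effect_cohort(rng, n=300)
        profs = profile_table(terts, ["m1", "m2", "m3"])
        mask = pd.Series(False, index=profs.index)
        mask.iloc[:150] = True
        res = compare_profiles(profs, clin, "all_high_vs_rest", stratum_mask=mask)
        assert res.n == 150
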