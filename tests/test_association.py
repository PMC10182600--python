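import math

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test

from mifspatial.association import (
    compare_groups,
    compare_regions_paired,
    correlation_matrix,
    fit_lnm_logistic,
    fit_rfs_cox,
    hypoxia_proximity_compare,
    km_logrank,
    logrank_chi2,
    prepare_model_frame,
    stratify_cutpoint,
)
from mifspatial.phenotyping import default_scheme
from mifspatial.synthetic_cohort import simulate_association_cohort

from .conftest import site_from_points


# -- rank tests -------------------------------------------------------------

def test_mann_whitney_complete_separation_and_symmetry():
    res = compare_groups([1, 2, 3], [4, 5, 6])
    assert res.statistic == 0.0          # U of the first group
    assert res.p_value == pytest.approx(0.1)  # 2 / C(6,3)
    assert compare_groups([1, 2, 3], [1, 2, 3]).p_value == 1.0


def test_mann_whitney_power_under_shift(rng):
    rejections = 0
    for _ in range(100):
        x = rng.normal(0, 1, 50)
        y = rng.normal(1, 1, 50)
        if compare_groups(x, y).p_value < 0.05 and len(x):
            rejections += 1
    assert rejections > 90


def test_mann_whitney_requires_non_empty_groups():
    with pytest.raises(ValueError):
        compare_groups([], [1.0])


def test_wilcoxon_one_sided_extreme_configuration():
    im = np.arange(1, 11) + np.arange(1, 11) ** 1.5  # distinct positive diffs
    tc = np.arange(1, 11, dtype=float)
    res = compare_regions_paired(im, tc)
    assert res.p_value == pytest.approx(2 / 1024)


def test_wilcoxon_drops_incomplete_pairs_and_rejects_all_zeros():
    res = compare_regions_paired([1.0, np.nan, 3.0, 5.0], [0.5, 2.0, np.nan, 4.0])
    assert res.n1 == 2
    with pytest.raises(ValueError, match="no informative"):
        compare_regions_paired([1.0, 2.0], [1.0, 2.0])
    with pytest.raises(ValueError, match="no complete"):
        compare_regions_paired([np.nan], [1.0])


def test_wilcoxon_type_i_error_on_exchangeable_pairs(rng):
    rejections = 0
    reps = 200
    for _ in range(reps):
        a = rng.normal(0, 1, 50)
        b = a + rng.normal(0, 1, 50)  # exchangeable differences around 0
        if compare_regions_paired(b, a).p_value < 0.05:
            rejections += 1
    assert rejections / reps < 0.10


# -- logistic ---------------------------------------------------------------

def test_logistic_recovers_injected_odds_ratio(rng):
    covered = 0
    reps = 20
    for i in range(reps):
        df = simulate_association_cohort(400, true_or=5.8, random_state=rng)
        res = fit_lnm_logistic(df, adjusted=True)
        assert res.converged
        assert not res.vif_flagged
        if res.ci_low <= 5.8 <= res.ci_high:
            covered += 1
    assert covered >= reps * 0.8


def test_logistic_null_exposure_covers_one(rng):
    covered = 0
    reps = 20
    for _ in range(reps):
        df = simulate_association_cohort(400, true_or=None, random_state=rng)
        res = fit_lnm_logistic(df, adjusted=True)
        if res.ci_low <= 1.0 <= res.ci_high:
            covered += 1
    assert covered >= reps * 0.8


def test_logistic_degenerate_exposure_is_an_error():
    df = simulate_association_cohort(100, random_state=0)
    df["exposure"] = 1.0
    with pytest.raises(ValueError, match="degenerate exposure"):
        fit_lnm_logistic(df)


def test_logistic_complete_separation_reported_not_raised():
    df = pd.DataFrame({"lnm": [0.0] * 20 + [1.0] * 20,
                       "exposure": [0.0] * 20 + [1.0] * 20})
    res = fit_lnm_logistic(df, adjusted=False)
    assert not res.converged
    assert res.message


def test_logistic_backward_elimination_keeps_exposure():
    df = simulate_association_cohort(500, true_or=3.0, random_state=7)
    df["noise"] = np.random.default_rng(0).normal(size=len(df))
    res = fit_lnm_logistic(df, covariates=["noise", "diameter_gt3"], adjusted=True)
    assert "exposure" in res.terms.index
    assert "noise" in res.dropped


# -- Cox --------------------------------------------------------------------

def test_cox_recovers_injected_hazard_ratio(rng):
    covered = 0
    reps = 15
    for _ in range(reps):
        df = simulate_association_cohort(300, true_hr=2.5, random_state=rng)
        res = fit_rfs_cox(df, adjusted=True)
        assert res.converged
        if res.ci_low <= 2.5 <= res.ci_high:
            covered += 1
    assert covered >= reps * 0.8


def test_cox_errors_without_events_or_variation():
    df = simulate_association_cohort(100, random_state=1)
    censored = df.assign(rfs_event=0.0)
    with pytest.raises(ValueError, match="no events"):
        fit_rfs_cox(censored)
    with pytest.raises(ValueError, match="degenerate exposure"):
        fit_rfs_cox(df.assign(exposure=0.0))


# -- log-rank / KM / cutpoint ----------------------------------------------

def test_logrank_statistic_matches_lifelines(rng):
    for _ in range(20):
        n = int(rng.integers(20, 150))
        t = np.round(rng.exponential(100, n), 1)  # rounding induces ties
        e = rng.random(n) < 0.7
        g = rng.random(n) < 0.5
        if g.all() or not g.any():
            continue
        ours = logrank_chi2(t, e, g)
        ref = logrank_test(t[~g], t[g], e[~g], e[g]).test_statistic
        assert ours == pytest.approx(ref, abs=1e-8)


def test_km_product_limit_and_identical_groups():
    res = km_logrank({
        "a": ([1, 2, 3, 4, 5], [1, 1, 1, 1, 1]),
        "b": ([1, 2, 3, 4, 5], [1, 1, 1, 1, 1]),
    })
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)
    # S(3) after deaths at 1, 2, 3 of 5 subjects
    assert res.curves["a"].loc[3].iloc[0] == pytest.approx(0.4)


def test_km_detects_proportional_hazards_difference(rng):
    t1 = rng.exponential(100, 200)
    t2 = rng.exponential(50, 200)
    res = km_logrank({"lo": (t1, np.ones(200)), "hi": (t2, np.ones(200))})
    assert res.p_value < 1e-6


def test_km_rejects_degenerate_groups():
    with pytest.raises(ValueError):
        km_logrank({"a": ([1], [1])})
    with pytest.raises(ValueError):
        km_logrank({"a": ([1], [1]), "b": ([], [])})


def test_cutpoint_recovers_mixture_boundary(rng):
    hits = 0
    reps = 10
    for _ in range(reps):
        lo = rng.normal(0, 1, 60)
        hi = rng.normal(3, 1, 60)
        values = np.r_[lo, hi]
        t = np.r_[rng.exponential(150, 60), rng.exponential(40, 60)]
        res = stratify_cutpoint(values, t, np.ones(120), n_permutations=99,
                                random_state=rng)
        if abs(res.cutpoint - 1.5) <= 1.5:
            hits += 1
        assert res.p_value < 0.05
    assert hits >= 9


def test_cutpoint_null_permutation_p_is_not_anticonservative(rng):
    pvals = []
    for _ in range(20):
        values = rng.normal(0, 1, 60)
        t = rng.exponential(100, 60)
        res = stratify_cutpoint(values, t, np.ones(60), n_permutations=99,
                                random_state=rng)
        pvals.append(res.p_value)
    assert np.mean(np.asarray(pvals) < 0.05) <= 0.25


def test_cutpoint_input_guards(rng):
    t = rng.exponential(100, 50)
    with pytest.raises(ValueError, match="constant"):
        stratify_cutpoint(np.ones(50), t, np.ones(50))
    with pytest.raises(ValueError, match="at least 20"):
        stratify_cutpoint(np.arange(10), t[:10], np.ones(10))
    with pytest.raises(ValueError, match="events"):
        stratify_cutpoint(np.arange(50), t, np.zeros(50))


def test_cutpoint_respects_minimum_group_size(rng):
    values = np.r_[np.zeros(3), np.ones(47)]  # only split leaves 3 < 10% of 50
    t = rng.exponential(100, 50)
    with pytest.raises(ValueError, match="minimum group size"):
        stratify_cutpoint(values, t, np.ones(50))


# -- correlations -----------------------------------------------------------

def test_spearman_matrix_monotone_and_tiers():
    x = np.arange(20.0)
    df = pd.DataFrame({"a": x, "b": np.exp(x / 5), "c": -x, "d": np.ones(20)})
    res = correlation_matrix(df)
    assert res.rho.loc["a", "b"] == 1.0
    assert res.rho.loc["a", "c"] == -1.0
    assert res.tiers.loc["a", "b"] == "***"
    assert math.isnan(res.rho.loc["a", "d"])
    assert res.tiers.loc["a", "d"] == "undef"


def test_spearman_null_distribution(rng):
    rhos = [
        correlation_matrix(pd.DataFrame(rng.uniform(size=(50, 2)), columns=["a", "b"]))
        .rho.loc["a", "b"]
        for _ in range(200)
    ]
    assert abs(float(np.mean(rhos))) < 0.05
    # 95th percentile of |rho| near the exact null quantile ~ 1.96/sqrt(49)
    assert float(np.quantile(np.abs(rhos), 0.95)) == pytest.approx(0.28, abs=0.07)


# -- hypoxia proximity ------------------------------------------------------

def test_hypoxia_contrast_by_construction():
    ring = [(15 * math.cos(a), 15 * math.sin(a)) for a in np.linspace(0, 2 * math.pi, 8)]
    site = site_from_points(
        {"cancer_hypoxic": [(0, 0)], "cancer_normoxic": [(500, 500)], "CMV": ring},
        panel="combined",
    )
    res = hypoxia_proximity_compare([site], default_scheme("combined"), target="CMV")
    assert res.per_site["hypoxic"].iloc[0] == 8.0
    assert res.per_site["normoxic"].iloc[0] == 0.0
    zero = hypoxia_proximity_compare([site], default_scheme("combined"),
                                     target="CMV", r=0.0)
    assert (zero.per_site[["hypoxic", "normoxic"]] == 0).all().all()


def test_hypoxia_sites_missing_a_subpopulation_are_dropped():
    site = site_from_points({"cancer_hypoxic": [(0, 0)], "CMV": [(5, 0)]},
                            panel="combined")
    with pytest.raises(ValueError, match="no site"):
        hypoxia_proximity_compare([site], default_scheme("combined"))


# -- model frame ------------------------------------------------------------

def test_model_frame_dichotomizes_as_specified():
    clinical = pd.DataFrame(
        {
            "age": [55, 65, 70], "gender": ["male", "female", "male"],
            "histology": ["LUSC", "LUAD", "other"],
            "tumor_diameter": [2.5, 3.5, 3.0], "lnm": [False, True, True],
        },
        index=["a", "b", "c"],
    )
    exposure = pd.Series([1.0, 5.0, 9.0], index=["a", "b", "c"])
    frame = prepare_model_frame(clinical, exposure, dichotomize="median")
    assert list(frame["age_gt60"]) == [0.0, 1.0, 1.0]
    assert list(frame["diameter_gt3"]) == [0.0, 1.0, 0.0]
    assert math.isnan(frame.loc["c", "lusc"])  # 'other' histology drops out
    assert list(frame["exposure"]) == [0.0, 0.0, 1.0]
    continuous = prepare_model_frame(clinical, exposure, dichotomize=None)
    assert list(continuous["exposure"]) == [1.0, 5.0, 9.0]
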