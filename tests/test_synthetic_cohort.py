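import json
import math

import numpy as np
import pandas as pd
import pytest

from mifspatial.io_cells import Disc
from mifspatial.phenotyping import assign_phenotypes, default_scheme
from mifspatial.spatial_metrics import compute_ccps, compute_mnnd
from mifspatial.synthetic_cohort import (
    BarrierSpec,
    Interaction,
    SyntheticConfig,
    barrier_recovery_config,
    generate_cohort,
    generate_site,
    homogeneous_poisson_site,
    intensities_from_counts,
    reference_clinical_table,
    simulate_association_cohort,
)


def single_leaf_config(leaf="other", lam=1.27e-3, **kwargs):
    return SyntheticConfig(
        intensities={"IM": {"node_negative": {leaf: lam}}},
        regions=("IM",), cores_per_region=1, barrier=None, **kwargs,
    )


def test_poisson_expected_count_on_the_disc(rng):
    lam = 1.27e-3
    cfg = single_leaf_config(lam=lam)
    counts = [generate_site(cfg, "P1", "IM", 1, rng).n_cells for _ in range(5)]
    expected = lam * math.pi * 500**2  # ~997.5
    sd = math.sqrt(expected)
    assert abs(np.mean(counts) - expected) < 3 * sd


def test_generated_labels_recovered_exactly_by_default_scheme(rng):
    cfg = SyntheticConfig(seed=0)
    site = generate_site(cfg, "P1", "IM", 1, rng, stratum="node_positive",
                         panel="combined")
    labelled = assign_phenotypes(site, default_scheme("combined"))
    assert (labelled.df["phenotype"] == labelled.df["true_phenotype"]).all()
    for panel in ("panel1", "panel2"):
        site = generate_site(cfg, "P1", "TC", 1, rng, panel=panel)
        labelled = assign_phenotypes(site, default_scheme(panel))
        assert (labelled.df["phenotype"] == labelled.df["true_phenotype"]).all()


def test_same_seed_reproduces_site_different_seed_does_not():
    cfg = SyntheticConfig(seed=0)
    a = generate_site(cfg, "P1", "IM", 1, np.random.default_rng(42))
    b = generate_site(cfg, "P1", "IM", 1, np.random.default_rng(42))
    c = generate_site(cfg, "P1", "IM", 1, np.random.default_rng(43))
    pd.testing.assert_frame_equal(a.df, b.df)
    assert len(a.df) != len(c.df) or not a.df["x"].equals(c.df["x"])


def test_all_cells_inside_core_extent(rng):
    cfg = SyntheticConfig(seed=0)
    site = generate_site(cfg, "P1", "IM", 1, rng)
    assert isinstance(site.extent, Disc)
    r = np.hypot(site.df["x"], site.df["y"])
    assert (r <= site.extent.radius).all()


def test_resource_guard_refuses_absurd_intensity(rng):
    cfg = single_leaf_config(lam=10.0)
    with pytest.raises(ValueError, match="guard"):
        generate_site(cfg, "P1", "IM", 1, rng)


def test_pure_poisson_pattern_passes_quadrat_dispersion(rng):
    """Complete spatial randomness: quadrat variance/mean ratio near 1."""
    cfg = single_leaf_config(lam=2e-3)
    ratios = []
    for _ in range(5):
        site = generate_site(cfg, "P1", "IM", 1, rng)
        # interior square inscribed in the disc, 8x8 quadrats
        half = 500 / math.sqrt(2)
        df = site.df[(site.df.x.abs() < half) & (site.df.y.abs() < half)]
        gx = np.digitize(df.x, np.linspace(-half, half, 9)) - 1
        gy = np.digitize(df.y, np.linspace(-half, half, 9)) - 1
        counts = np.zeros((8, 8))
        np.add.at(counts, (gx.clip(0, 7), gy.clip(0, 7)), 1)
        ratios.append(counts.var(ddof=1) / counts.mean())
    # index of dispersion ~ chi2_63/63; the mean of 5 should sit near 1
    assert 0.8 < np.mean(ratios) < 1.25


def test_attraction_strengthens_with_parameter(rng):
    """Stronger attraction of Tregs to CD8 cells shortens mNND(CD8-Treg)."""
    mnnds = []
    for strength in (0.0, 0.5, 2.0):
        cfg = SyntheticConfig(
            intensities=intensities_from_counts(
                {"IM": {"node_negative": {"CD8_Ttotal": 150, "CD4_Treg": 60}}}
            ),
            regions=("IM",), cores_per_region=1, barrier=None,
            interactions=(Interaction("CD8_Ttotal", "CD4_Treg", "attract",
                                      strength, 15.0),),
        )
        vals = []
        for _ in range(4):
            site = generate_site(cfg, "P1", "IM", 1, rng)
            labelled = assign_phenotypes(site, default_scheme("combined"))
            vals.append(compute_mnnd(labelled, "CD8_Ttotal", "CD4_Treg").mnnd)
        mnnds.append(np.mean(vals))
    assert mnnds[0] > mnnds[1] > mnnds[2]


def test_repulsion_thins_targets_near_sources(rng):
    base = {"IM": {"node_negative": {"cancer_normoxic": 400, "CD8_Ttotal": 200}}}
    cfg_rep = SyntheticConfig(
        intensities=intensities_from_counts(base), regions=("IM",),
        cores_per_region=1, barrier=None,
        interactions=(Interaction("cancer_normoxic", "CD8_Ttotal", "repel",
                                  0.95, 80.0),),
    )
    cfg_null = SyntheticConfig(
        intensities=intensities_from_counts(base), regions=("IM",),
        cores_per_region=1, barrier=None,
    )
    scheme = default_scheme("combined")
    cc_rep, cc_null = [], []
    for _ in range(4):
        s = assign_phenotypes(generate_site(cfg_rep, "P", "IM", 1, rng), scheme)
        cc_rep.append(compute_ccps(s, "CD8_Ttotal", scheme=scheme).score)
        s = assign_phenotypes(generate_site(cfg_null, "P", "IM", 1, rng), scheme)
        cc_null.append(compute_ccps(s, "CD8_Ttotal", scheme=scheme).score)
    assert np.mean(cc_rep) < 0.6 * np.mean(cc_null)


def test_barrier_thins_cd8_but_not_cd4_near_cancer(rng):
    cfg = barrier_recovery_config(seed=0)
    scheme = default_scheme("combined")
    strong = {"count_scale": {}, "cd8_thinning": 0.85}
    weak = {"count_scale": {}, "cd8_thinning": 0.0}
    cd8 = {True: [], False: []}
    cd4 = {True: [], False: []}
    for is_strong, mods in ((True, strong), (False, weak)):
        for _ in range(4):
            s = generate_site(cfg, "P", "IM", 1, rng, modifiers=mods)
            s = assign_phenotypes(s, scheme)
            cd8[is_strong].append(compute_ccps(s, "CD8_Ttotal", scheme=scheme).score)
            cd4[is_strong].append(compute_ccps(s, "CD4_Ttotal", scheme=scheme).score)
    assert np.mean(cd8[True]) < 0.5 * np.mean(cd8[False])
    assert np.mean(cd4[True]) > 0.6 * np.mean(cd4[False])


def test_cohort_shapes_strata_and_ground_truth():
    cfg = SyntheticConfig(n_patients=8, cores_per_region=2, seed=5)
    cohort = generate_cohort(cfg)
    assert len(cohort.patients) == 8
    assert len(cohort.sites) == 8 * 2 * 2  # regions x cores (one combined panel)
    assert {s.region for s in cohort.sites} == {"IM", "TC"}
    truth = cohort.ground_truth
    assert truth["n_patients"] == 8 and len(truth["patients"]) == 8
    json.dumps(truth, default=str)  # serializable
    for p in cohort.patients:
        assert p.rfs_time > 0
        assert p.lnm == (p.n_stage != "N0")


def test_cohort_injects_stratum_density_contrast():
    """Node-positive patients get more dysfunctional CD8 cells in the margin."""
    cfg = SyntheticConfig(n_patients=30, cores_per_region=1, seed=11,
                          lnm_fraction=0.5, barrier=None)
    cohort = generate_cohort(cfg)
    scheme = default_scheme("combined")
    lnm = {p.patient_id: p.lnm for p in cohort.patients}
    dens = {True: [], False: []}
    for site in cohort.sites:
        if site.region != "IM":
            continue
        labelled = assign_phenotypes(site, scheme)
        n = labelled.n_cells
        dens[lnm[site.patient_id]].append(
            1000 * labelled.phenotype_mask("CD8_Tdys").sum() / n
        )
    assert np.mean(dens[True]) > 1.5 * np.mean(dens[False])


def test_invalid_configs_rejected():
    with pytest.raises(ValueError, match="lnm_fraction"):
        SyntheticConfig(lnm_fraction=1.5)
    with pytest.raises(ValueError, match="negative intensity"):
        SyntheticConfig(intensities={"IM": {"node_negative": {"CAF": -1.0}}})
    with pytest.raises(ValueError, match="mode"):
        Interaction("a", "b", "orbit", 1.0, 10.0)
    with pytest.raises(ValueError, match="thinning"):
        BarrierSpec(cd8_thinning=1.5)


def test_null_cohort_density_comparison_is_calibrated(rng):
    """With no stratum effect the LNM density contrast rejects at ~5%."""
    from mifspatial.association import compare_groups

    counts = {
        "IM": {s: {"cancer_normoxic": 150, "CD8_Ttotal": 80, "other": 250}
               for s in ("node_negative", "node_positive")}
    }
    rejections = 0
    reps = 40
    scheme = default_scheme("combined")
    for i in range(reps):
        cfg = SyntheticConfig(
            n_patients=14, lnm_fraction=0.5, cores_per_region=1, regions=("IM",),
            intensities=intensities_from_counts(counts), barrier=None,
            seed=1000 + i,
        )
        cohort = generate_cohort(cfg)
        lnm = {p.patient_id: p.lnm for p in cohort.patients}
        groups = {True: [], False: []}
        for site in cohort.sites:
            labelled = assign_phenotypes(site, scheme)
            groups[lnm[site.patient_id]].append(
                1000 * labelled.phenotype_mask("CD8_Ttotal").sum() / labelled.n_cells
            )
        if not groups[True] or not groups[False]:
            continue
        if compare_groups(groups[True], groups[False]).p_value < 0.05:
            rejections += 1
    assert rejections <= 7  # ~5% nominal; binomial(40, .05) upper tail


def test_clinical_simulator_hits_target_prevalences():
    df = simulate_association_cohort(4000, true_or=5.8, true_hr=2.5, random_state=3)
    assert df["lnm"].mean() == pytest.approx(0.308, abs=0.06)
    assert 0.4 < df["rfs_event"].mean() < 0.8
    assert df["rfs_time"].min() > 0


def test_reference_table_is_deterministic():
    pd.testing.assert_frame_equal(reference_clinical_table(), reference_clinical_table())
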