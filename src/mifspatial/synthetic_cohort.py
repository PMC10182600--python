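"""Synthetic mIF-like cohorts with known ground truth.

Real per-cell mIF cohorts of this kind are rarely deposited, so every
pipeline stage is validated against simulated tissue-microarray cores whose
generating structure is known exactly:

* each core is a 1 mm diameter disc of cells;
* cancer cells form nests via a Thomas (parent-offspring) cluster process;
* immune and stromal phenotypes are homogeneous Poisson, optionally
  modulated by pairwise *attraction* (extra target points scattered around
  source points) or *repulsion* (distance-dependent thinning);
* an optional *barrier* places cancer-associated fibroblasts in an annulus
  around cancer nests and selectively thins CD8+ (not CD4+) T cells near
  the nests - the spatial signature of immune exclusion;
* marker flags are synthesized consistently with the default gating scheme,
  so phenotype assignment recovers the generating labels exactly;
* patient-level structure: lymph-node status drawn at the cohort prevalence
  (0.308 by default, the prevalence of the NSCLC surgical cohort whose
  marginals the clinical sampler mimics), per-stratum intensity differences
  (lower predysfunctional CD8 density in tumor center and higher
  dysfunctional CD8 density in invasive margin for node-positive patients),
  and recurrence-free survival from an exponential proportional-hazards
  model with independent uniform censoring.

All randomness flows through one ``numpy.random.Generator`` (PCG64), so a
fixed seed reproduces a cohort bit-for-bit across platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io_cells import Disc, PANEL_MARKERS, PatientRecord, Rect, TissueSite

CANCER_LEAVES = ("cancer", "cancer_normoxic", "cancer_hypoxic")

#: Which panels can carry each generated leaf phenotype.
LEAF_PANELS: Mapping[str, tuple[str, ...]] = {
    "cancer": ("panel1",),
    "cancer_normoxic": ("panel2", "combined"),
    "cancer_hypoxic": ("panel2", "combined"),
    "CD8_Ttotal": ("panel1", "combined"),
    "CD8_Tpredys": ("panel1", "combined"),
    "CD8_Tdys": ("panel1", "combined"),
    "CD4_Tcon": ("panel2", "combined"),
    "CD4_Treg": ("panel2", "combined"),
    "CMV": ("panel2", "combined"),
    "CAF": ("panel2", "combined"),
    "other": ("panel1", "panel2", "combined"),
}

CD8_LEAVES = ("CD8_Ttotal", "CD8_Tpredys", "CD8_Tdys")

MAX_EXPECTED_CELLS = 1_000_000  # per-core resource guard


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Interaction:
    """Pairwise spatial coupling between two generated phenotypes."""

    source: str
    target: str
    mode: str           # "attract" | "repel"
    strength: float     # attract: expected extra targets per source point;
                        # repel: deletion probability at zero distance
    scale: float        # microns (Gaussian scale of the coupling)

    def __post_init__(self) -> None:
        if self.mode not in ("attract", "repel"):
            raise ValueError(f"unknown interaction mode {self.mode!r}")
        if self.mode == "repel" and not 0 <= self.strength <= 1:
            raise ValueError("repulsion strength is a probability")


@dataclass(frozen=True)
class BarrierSpec:
    """Fibroblast barrier around cancer nests with selective CD8 thinning."""

    phenotype: str = "CAF"
    annulus_width: float = 40.0        # microns beyond the nest radius
    annulus_fraction: float = 0.7      # share of barrier cells placed in the annulus
    cd8_thinning: float = 0.6          # deletion probability for CD8 cells near nests
    thinned_leaves: tuple = CD8_LEAVES
    # per-patient heterogeneity: strength b ~ U(range) scales thinning and,
    # through the couplings below, barrier-cell abundance and CD4 recruitment
    patient_strength_range: tuple = (0.0, 1.0)
    caf_coupling: tuple = (0.25, 1.5)  # barrier-cell count multiplier 0.25 + 1.5 b
    cd4_coupling: float = 0.8          # CD4 count multiplier 1 + 0.8 b

    def __post_init__(self) -> None:
        if not 0 <= self.cd8_thinning <= 1:
            raise ValueError("thinning probability must lie in [0, 1]")


@dataclass(frozen=True)
class SurvivalModel:
    """Exponential proportional-hazards recurrence model with uniform censoring."""

    baseline_hazard: float = 1.0 / 1500.0  # events per day
    log_hr: Mapping[str, float] = field(
        default_factory=lambda: {"lnm": math.log(2.2)}
    )
    censor_low: float = 300.0
    censor_high: float = 2200.0


def _default_counts() -> dict:
    """Expected cells per core, per region and lymph-node stratum.

    Magnitudes emulate 1 mm NSCLC TMA cores (~1500-1700 segmented cells,
    roughly 40% epithelial); the region and stratum contrasts encode the
    qualitative biology the pipeline is meant to detect: CD8 subsets and
    microvessels enriched at the invasive margin, fibroblasts in the tumor
    center, node-positive patients with fewer predysfunctional CD8 cells in
    the tumor center and more dysfunctional CD8 cells at the margin.
    """
    im_neg = {
        "cancer_normoxic": 450, "cancer_hypoxic": 150,
        "CD8_Ttotal": 80, "CD8_Tpredys": 55, "CD8_Tdys": 35,
        "CD4_Tcon": 60, "CD4_Treg": 25, "CMV": 45, "CAF": 60, "other": 700,
    }
    tc_neg = {
        "cancer_normoxic": 500, "cancer_hypoxic": 200,
        "CD8_Ttotal": 55, "CD8_Tpredys": 40, "CD8_Tdys": 15,
        "CD4_Tcon": 60, "CD4_Treg": 30, "CMV": 30, "CAF": 80, "other": 700,
    }
    im_pos = im_neg | {"CD8_Ttotal": 55, "CD8_Tpredys": 45, "CD8_Tdys": 80}
    tc_pos = tc_neg | {"CD8_Ttotal": 40, "CD8_Tpredys": 22, "CD8_Tdys": 18}
    return {
        "IM": {"node_negative": im_neg, "node_positive": im_pos},
        "TC": {"node_negative": tc_neg, "node_positive": tc_pos},
    }


def intensities_from_counts(counts: Mapping, core_diameter: float = 1000.0) -> dict:
    """Convert expected per-core counts to intensities in points/um^2."""
    area = math.pi * (core_diameter / 2) ** 2
    return {
        region: {
            stratum: {leaf: n / area for leaf, n in leaves.items()}
            for stratum, leaves in strata.items()
        }
        for region, strata in counts.items()
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """Full specification of a synthetic cohort.

    ``intensities[region][stratum][leaf]`` are in points/um^2; use
    :func:`intensities_from_counts` to express them as expected per-core
    counts. Defaults encode the emulated study design: 279 patients at
    lymph-node prevalence 0.308, two cores per patient and region, 1 mm
    discs, a moderate fibroblast barrier, and a node-status hazard on
    recurrence.
    """

    n_patients: int = 279
    lnm_fraction: float = 0.308
    cores_per_region: int = 2
    core_diameter: float = 1000.0
    regions: tuple = ("IM", "TC")
    panels: tuple = ("combined",)
    intensities: Mapping = field(
        default_factory=lambda: intensities_from_counts(_default_counts())
    )
    interactions: tuple = ()
    barrier: Optional[BarrierSpec] = field(default_factory=BarrierSpec)
    survival: SurvivalModel = field(default_factory=SurvivalModel)
    n_nests: float = 8.0        # mean cancer nests per core
    nest_sigma: float = 60.0    # Gaussian nest spread, microns
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.lnm_fraction < 1:
            raise ValueError("lnm_fraction must lie strictly between 0 and 1")
        for strata in self.intensities.values():
            for leaves in strata.values():
                for leaf, lam in leaves.items():
                    if lam < 0:
                        raise ValueError(f"negative intensity for {leaf!r}")

    @property
    def nest_radius(self) -> float:
        return 2.0 * self.nest_sigma


# ---------------------------------------------------------------------------
# point placement helpers
# ---------------------------------------------------------------------------

def _uniform_disc(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    r = radius * np.sqrt(rng.random(n))
    theta = rng.uniform(0, 2 * math.pi, n)
    return np.c_[r * np.cos(theta), r * np.sin(theta)]


def _clamp_disc(points: np.ndarray, radius: float) -> np.ndarray:
    """Radially project stray points back inside the core boundary."""
    if not len(points):
        return points
    r = np.hypot(points[:, 0], points[:, 1])
    out = r > radius
    if out.any():
        points = points.copy()
        scale = (0.999 * radius) / r[out]
        points[out] *= scale[:, None]
    return points


def _panel_rates(leaf_rates: Mapping[str, float], panel: str) -> dict:
    """Restrict leaf intensities to a panel; for panel1 the hypoxia split is
    invisible (no Hif-1a), so cancer sub-leaves collapse into ``cancer``."""
    out: dict[str, float] = {}
    for leaf, lam in leaf_rates.items():
        if panel == "panel1" and leaf in ("cancer_normoxic", "cancer_hypoxic"):
            out["cancer"] = out.get("cancer", 0.0) + lam
            continue
        if panel in LEAF_PANELS.get(leaf, ()):
            out[leaf] = out.get(leaf, 0.0) + lam
    return out


def _marker_flags(leaf: str, n: int, panel: str, rng: np.random.Generator) -> dict:
    """Boolean marker arrays consistent with the default gating scheme.

    Non-defining markers (GZMB everywhere; PD-1/CD103 on dysfunctional CD8
    cells; aSMA on a pericyte-like share of vessels) are randomized for
    realism without breaking label recovery.
    """
    flags = {m: np.zeros(n, dtype=bool) for m in PANEL_MARKERS[panel]}

    def set_if(marker: str, value) -> None:
        if marker in flags:
            flags[marker] = np.broadcast_to(value, (n,)).copy() if np.ndim(value) else np.full(n, value)

    if leaf in ("cancer", "cancer_normoxic"):
        set_if("PANCK", True)
    elif leaf == "cancer_hypoxic":
        set_if("PANCK", True)
        set_if("HIF1A", True)
    elif leaf == "CD8_Ttotal":
        set_if("CD8", True)
    elif leaf == "CD8_Tpredys":
        set_if("CD8", True)
        pd1 = rng.random(n) < 0.75
        cd103 = rng.random(n) < 0.6
        pd1 |= ~(pd1 | cd103)  # the state requires at least one of the two
        set_if("PD1", pd1)
        set_if("CD103", cd103)
    elif leaf == "CD8_Tdys":
        set_if("CD8", True)
        set_if("TIM3", True)
        set_if("PD1", rng.random(n) < 0.5)
        set_if("CD103", rng.random(n) < 0.3)
    elif leaf == "CD4_Tcon":
        set_if("CD4", True)
    elif leaf == "CD4_Treg":
        set_if("CD4", True)
        set_if("FOXP3", True)
    elif leaf == "CMV":
        set_if("CD31", True)
        set_if("ASMA", rng.random(n) < 0.3)
    elif leaf == "CAF":
        set_if("ASMA", True)
    elif leaf != "other":
        raise ValueError(f"no marker synthesis defined for leaf {leaf!r}")
    if leaf in CD8_LEAVES:
        set_if("GZMB", rng.random(n) < 0.35)
    return flags


# ---------------------------------------------------------------------------
# site generation
# ---------------------------------------------------------------------------

def generate_site(
    config: SyntheticConfig,
    patient_id: str,
    region: str,
    core_index: int,
    rng: np.random.Generator,
    stratum: str = "node_negative",
    panel: Optional[str] = None,
    modifiers: Optional[Mapping] = None,
) -> TissueSite:
    """Simulate one TMA core as a marked point pattern.

    ``modifiers`` carries per-patient heterogeneity: ``count_scale`` (leaf ->
    intensity multiplier) and ``cd8_thinning`` (overrides the barrier's
    deletion probability). The returned site stores the generating label in
    ``df['true_phenotype']``; ``df['phenotype']`` is left unset for the
    gating stage.
    """
    panel = panel or config.panels[0]
    rates = _panel_rates(config.intensities[region][stratum], panel)
    mods = dict(modifiers or {})
    count_scale = dict(mods.get("count_scale", {}))
    R = config.core_diameter / 2.0
    disc = Disc(0.0, 0.0, R)
    expected = sum(lam * disc.area * count_scale.get(l, 1.0) for l, lam in rates.items())
    if expected > MAX_EXPECTED_CELLS:
        raise ValueError(
            f"expected cell count {expected:.0f} exceeds the per-core guard "
            f"of {MAX_EXPECTED_CELLS}"
        )

    nest_centers: Optional[np.ndarray] = None
    if any(l in CANCER_LEAVES for l in rates):
        n_nests = max(1, int(rng.poisson(config.n_nests)))
        nest_centers = _uniform_disc(n_nests, 0.7 * R, rng)

    barrier = config.barrier
    points: dict[str, np.ndarray] = {}
    for leaf in rates:  # insertion order: deterministic for a given config
        lam = rates[leaf] * count_scale.get(leaf, 1.0)
        n = int(rng.poisson(lam * disc.area))
        if n == 0:
            points[leaf] = np.empty((0, 2))
            continue
        if leaf in CANCER_LEAVES:
            parents = nest_centers[rng.integers(0, len(nest_centers), n)]
            pts = _clamp_disc(parents + rng.normal(0, config.nest_sigma, (n, 2)), R)
        elif barrier is not None and leaf == barrier.phenotype and nest_centers is not None:
            n_ann = int(rng.binomial(n, barrier.annulus_fraction))
            centers = nest_centers[rng.integers(0, len(nest_centers), n_ann)]
            rad = config.nest_radius + rng.uniform(0, barrier.annulus_width, n_ann)
            ang = rng.uniform(0, 2 * math.pi, n_ann)
            ann = _clamp_disc(centers + np.c_[rad * np.cos(ang), rad * np.sin(ang)], R)
            pts = np.vstack([ann, _uniform_disc(n - n_ann, R, rng)])
        else:
            pts = _uniform_disc(n, R, rng)
        points[leaf] = pts

    for spec in config.interactions:
        if spec.source not in points or spec.target not in points:
            continue
        src = points[spec.source]
        if spec.mode == "attract" and len(src):
            n_extra = int(rng.poisson(spec.strength * len(src)))
            if n_extra:
                centers = src[rng.integers(0, len(src), n_extra)]
                extra = _clamp_disc(centers + rng.normal(0, spec.scale, (n_extra, 2)), R)
                points[spec.target] = np.vstack([points[spec.target], extra])
        elif spec.mode == "repel" and len(src) and len(points[spec.target]):
            d, _ = cKDTree(src).query(points[spec.target])
            p_del = spec.strength * np.exp(-(d**2) / (2 * spec.scale**2))
            points[spec.target] = points[spec.target][rng.random(len(d)) >= p_del]

    if barrier is not None and nest_centers is not None:
        thin = float(mods.get("cd8_thinning", barrier.cd8_thinning))
        if thin > 0:
            reach = config.nest_radius + barrier.annulus_width
            for leaf in barrier.thinned_leaves:
                pts = points.get(leaf)
                if pts is None or not len(pts):
                    continue
                d, _ = cKDTree(nest_centers).query(pts)
                drop = (d <= reach) & (rng.random(len(pts)) < thin)
                points[leaf] = pts[~drop]

    frames = []
    offset = 0
    for leaf, pts in points.items():
        n = len(pts)
        flags = _marker_flags(leaf, n, panel, rng)
        compartment = np.where(
            np.isin(leaf, CANCER_LEAVES) | (rng.random(n) < 0.2), "tumor", "stroma"
        )
        frame = pd.DataFrame(
            {
                "cell_id": [
                    f"{patient_id}-{region}{core_index}-{panel}-{offset + i}" for i in range(n)
                ],
                "x": pts[:, 0],
                "y": pts[:, 1],
                "compartment": compartment,
                "true_phenotype": leaf,
            }
        )
        for m, arr in flags.items():
            frame[m] = arr
        frames.append(frame)
        offset += n
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["cell_id", "x", "y", "compartment", "true_phenotype",
                                   *PANEL_MARKERS[panel]])
    )
    return TissueSite(
        patient_id=patient_id,
        region=region,
        core_index=core_index,
        panel_id=panel,
        df=df,
        extent=disc,
    )


def homogeneous_poisson_site(
    rates: Mapping[str, float],
    window: Union[Disc, Rect],
    rng: np.random.Generator,
    panel: str = "combined",
    patient_id: str = "SIM",
    region: str = "IM",
    core_index: int = 1,
) -> TissueSite:
    """Complete-spatial-randomness pattern on an arbitrary window; used for
    closed-form checks (mean NND -> 1/(2 sqrt(lambda)), CCPS -> lambda pi r^2)."""
    frames = []
    offset = 0
    for leaf, lam in rates.items():
        n = int(rng.poisson(lam * window.area))
        if isinstance(window, Disc):
            pts = _uniform_disc(n, window.radius, rng) + [window.cx, window.cy]
        else:
            pts = np.c_[
                window.x0 + rng.uniform(0, window.width, n),
                window.y0 + rng.uniform(0, window.height, n),
            ]
        flags = _marker_flags(leaf, n, panel, rng)
        frame = pd.DataFrame(
            {
                "cell_id": [f"{patient_id}-{offset + i}" for i in range(n)],
                "x": pts[:, 0] if n else np.empty(0),
                "y": pts[:, 1] if n else np.empty(0),
                "compartment": "stroma",
                "true_phenotype": leaf,
                "phenotype": leaf,
            }
        )
        for m, arr in flags.items():
            frame[m] = arr
        frames.append(frame)
        offset += n
    df = pd.concat(frames, ignore_index=True)
    return TissueSite(patient_id, region, core_index, panel, df, extent=window)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

class CohortData(NamedTuple):
    sites: list
    patients: list
    ground_truth: dict


def _sample_clinical(pid: str, lnm: bool, rng: np.random.Generator) -> dict:
    """Clinical covariates with marginals close to the emulated cohort."""
    age = float(np.clip(round(rng.normal(59.0 if lnm else 62.0, 8.0)), 30, 88))
    gender = "male" if rng.random() < 0.652 else "female"
    smoking = float(rng.uniform(0, 399) if rng.random() < 0.559 else rng.uniform(400, 1600))
    ecog = 1 if rng.random() < 0.724 else 2
    hist = rng.choice(["LUSC", "LUAD", "other"], p=[0.341, 0.642, 0.017])
    diameter = float(round(rng.lognormal(math.log(3.5 if lnm else 3.0), 0.33), 1))
    if lnm:
        t = rng.choice(["T1", "T2", "T3", "T4"], p=[0.174, 0.710, 0.058, 0.058])
        n = rng.choice(["N1", "N2"], p=[0.57, 0.43])
        ajcc = rng.choice(["IIB", "IIIA", "IIIB"], p=[0.488, 0.465, 0.047])
    else:
        t = rng.choice(["T1", "T2", "T3", "T4"], p=[0.378, 0.518, 0.057, 0.047])
        n = "N0"
        ajcc = rng.choice(["IA", "IB", "IIA", "IIB", "IIIA"],
                          p=[0.373, 0.430, 0.093, 0.052, 0.052])
    return dict(
        patient_id=pid, age=age, gender=str(gender), smoking_index=smoking,
        ecog=ecog, tumor_diameter=diameter, histology=str(hist),
        t_stage=str(t), n_stage=str(n), ajcc_stage=str(ajcc), lnm=bool(lnm),
    )


def _survival_covariate(record: Mapping, name: str) -> float:
    if name in record and record[name] is not None:
        return float(record[name])
    derived = {
        "age_gt60": float(record.get("age", 0) > 60),
        "male": float(record.get("gender") == "male"),
        "lusc": float(record.get("histology") == "LUSC"),
        "diameter_gt3": float(record.get("tumor_diameter", 0) > 3),
    }
    if name in derived:
        return derived[name]
    raise KeyError(f"unknown survival covariate {name!r}")


def generate_cohort(config: SyntheticConfig) -> CohortData:
    """Generate all sites and patient records of a synthetic cohort."""
    rng = np.random.default_rng(config.seed)
    sites: list[TissueSite] = []
    patients: list[PatientRecord] = []
    truth_patients = []
    barrier = config.barrier
    surv = config.survival
    for i in range(config.n_patients):
        pid = f"P{i + 1:04d}"
        lnm = bool(rng.random() < config.lnm_fraction)
        stratum = "node_positive" if lnm else "node_negative"
        clin = _sample_clinical(pid, lnm, rng)

        modifiers: dict = {}
        b = 0.0
        if barrier is not None:
            b = float(rng.uniform(*barrier.patient_strength_range))
            base, slope = barrier.caf_coupling
            modifiers = {
                "count_scale": {
                    barrier.phenotype: base + slope * b,
                    "CD4_Tcon": 1 + barrier.cd4_coupling * b,
                    "CD4_Treg": 1 + barrier.cd4_coupling * b,
                },
                "cd8_thinning": barrier.cd8_thinning * b,
            }

        lp = sum(beta * _survival_covariate(clin, name) for name, beta in surv.log_hr.items())
        t_event = float(rng.exponential(1.0 / (surv.baseline_hazard * math.exp(lp))))
        t_censor = float(rng.uniform(surv.censor_low, surv.censor_high))
        rfs_time = max(min(t_event, t_censor), 1.0)
        rfs_event = bool(t_event <= t_censor)

        patients.append(PatientRecord(**clin, rfs_time=rfs_time, rfs_event=rfs_event))
        truth_patients.append({"patient_id": pid, "stratum": stratum, "barrier_strength": b})

        for region in config.regions:
            for core in range(1, config.cores_per_region + 1):
                for panel in config.panels:
                    sites.append(
                        generate_site(
                            config, pid, region, core, rng,
                            stratum=stratum, panel=panel, modifiers=modifiers,
                        )
                    )

    ground_truth = {
        "seed": config.seed,
        "n_patients": config.n_patients,
        "lnm_fraction": config.lnm_fraction,
        "regions": list(config.regions),
        "panels": list(config.panels),
        "cores_per_region": config.cores_per_region,
        "core_diameter_um": config.core_diameter,
        "survival_log_hr": dict(surv.log_hr),
        "barrier": None if barrier is None else vars(barrier).copy()
        if not hasattr(barrier, "__dataclass_fields__")
        else {f: getattr(barrier, f) for f in barrier.__dataclass_fields__},
        "patients": truth_patients,
    }
    return CohortData(sites=sites, patients=patients, ground_truth=ground_truth)


def barrier_recovery_config(n_patients: int = 30, seed: int = 0) -> SyntheticConfig:
    """Single-region scenario for recovering the barrier sign pattern.

    Patients differ only in barrier strength b ~ U(0, 1), which jointly
    raises fibroblast abundance near nests, thins CD8+ T cells there, and
    mildly recruits CD4+ T cells - so across patients the cancer proximity
    of CAFs must anti-correlate with that of CD8+ T cells and correlate
    non-negatively with that of CD4+ T cells.
    """
    counts = {
        "IM": {
            stratum: {
                "cancer_normoxic": 300, "cancer_hypoxic": 100,
                "CD8_Ttotal": 60, "CD8_Tpredys": 30, "CD8_Tdys": 30,
                "CD4_Tcon": 70, "CD4_Treg": 30, "CMV": 30, "CAF": 60,
                "other": 350,
            }
            for stratum in ("node_negative", "node_positive")
        }
    }
    return SyntheticConfig(
        n_patients=n_patients,
        regions=("IM",),
        cores_per_region=1,
        panels=("combined",),
        intensities=intensities_from_counts(counts),
        barrier=BarrierSpec(
            annulus_width=40.0, annulus_fraction=0.7, cd8_thinning=0.8,
            patient_strength_range=(0.0, 1.0), caf_coupling=(0.25, 1.5),
            cd4_coupling=0.8,
        ),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# clinical-layer simulation (no point patterns)
# ---------------------------------------------------------------------------

#: Mild clinical effects used by :func:`simulate_association_cohort`;
#: directions follow the emulated cohort (older age and larger tumors lean
#: node-positive).
_COVARIATE_LOG_OR = {
    "age_gt60": math.log(1.5), "male": math.log(1.1),
    "lusc": math.log(1.3), "diameter_gt3": math.log(2.0),
}
_COVARIATE_LOG_HR = {
    "age_gt60": math.log(1.2), "lusc": math.log(1.1),
    "diameter_gt3": math.log(1.3), "lnm": math.log(1.6),
}


def simulate_association_cohort(
    n_patients: int,
    true_or: Optional[float] = None,
    true_hr: Optional[float] = None,
    exposure_prevalence: float = 0.5,
    lnm_prevalence: float = 0.308,
    baseline_hazard: float = 1.0 / 2500.0,
    censor: tuple = (200.0, 2200.0),
    random_state: Union[int, np.random.Generator, None] = None,
) -> pd.DataFrame:
    """Patient-level cohort with a known exposure effect, for recovery tests.

    The exposure is a dichotomous marker status (e.g. "high dysfunctional
    CD8 density"). ``true_or`` injects a log-odds effect on lymph-node
    metastasis on top of mild clinical effects; ``true_hr`` injects a
    proportional hazard on recurrence. Returns the model-frame columns
    consumed by :func:`mifspatial.association.fit_lnm_logistic` /
    :func:`~mifspatial.association.fit_rfs_cox`.
    """
    rng = np.random.default_rng(random_state)
    n = int(n_patients)
    df = pd.DataFrame(
        {
            "exposure": (rng.random(n) < exposure_prevalence).astype(float),
            "age_gt60": (rng.random(n) < 0.556).astype(float),
            "male": (rng.random(n) < 0.652).astype(float),
            "lusc": (rng.random(n) < 0.347).astype(float),
            "diameter_gt3": (rng.random(n) < 0.45).astype(float),
        }
    )
    lp = sum(beta * df[name] for name, beta in _COVARIATE_LOG_OR.items())
    if true_or is not None:
        lp = lp + math.log(true_or) * df["exposure"]
    intercept = math.log(lnm_prevalence / (1 - lnm_prevalence)) - float(np.mean(lp))
    p_lnm = 1.0 / (1.0 + np.exp(-(intercept + lp)))
    df["lnm"] = (rng.random(n) < p_lnm).astype(float)

    lp_surv = sum(beta * df[name] for name, beta in _COVARIATE_LOG_HR.items())
    if true_hr is not None:
        lp_surv = lp_surv + math.log(true_hr) * df["exposure"]
    hazard = baseline_hazard * np.exp(lp_surv)
    t_event = rng.exponential(1.0 / hazard)
    t_censor = rng.uniform(*censor, size=n)
    df["rfs_time"] = np.maximum(np.minimum(t_event, t_censor), 1.0)
    df["rfs_event"] = (t_event <= t_censor).astype(float)
    return df


# ---------------------------------------------------------------------------
# published-marginal clinical fixture
# ---------------------------------------------------------------------------

def _spread_bool(n: int, k: int, offset: int) -> np.ndarray:
    """Exactly-k True values spread evenly over n positions (Bresenham)."""
    i = np.arange(n)
    return ((i * k + offset) % n) < k


def _spread_cat(counts: Mapping[str, int], offset: int) -> np.ndarray:
    values = np.repeat(list(counts.keys()), list(counts.values()))
    return np.roll(values, offset)


def reference_clinical_table() -> pd.DataFrame:
    """A 279-patient clinical table reproducing the marginal counts of the
    emulated NSCLC surgical cohort, per lymph-node stratum.

    Only the published stratum-level marginals are faithful (86 of 279
    node-positive, of whom 49 N1 and 37 N2; 182 male; 155 stage I; 179
    adenocarcinomas; ...). The joint distribution within a stratum is not
    published, so attributes are assigned by deterministic even spreading -
    the table is a fixture for count arithmetic, not a resampling target.
    """
    strata = []
    specs = [
        # (n, lnm, age<=60, male, smoking<400, ecog 0-1, histology, T, N, AJCC)
        (193, False, 77, 125, 109, 144,
         {"LUSC": 61, "LUAD": 128, "other": 4},
         {"T1": 73, "T2": 100, "T3": 11, "T4": 9},
         {"N0": 193},
         {"IA": 72, "IB": 83, "IIA": 18, "IIB": 10, "IIIA": 10}),
        (86, True, 47, 57, 47, 58,
         {"LUSC": 34, "LUAD": 51, "other": 1},
         {"T1": 15, "T2": 61, "T3": 5, "T4": 5},
         {"N1": 49, "N2": 37},
         {"IIB": 42, "IIIA": 40, "IIIB": 4}),
    ]
    start = 1
    for n, lnm, n_young, n_male, n_light, n_fit, hist, tstage, nstage, ajcc in specs:
        young = _spread_bool(n, n_young, 0)
        male = _spread_bool(n, n_male, 7)
        light = _spread_bool(n, n_light, 13)
        fit = _spread_bool(n, n_fit, 23)
        diam_small = _spread_bool(n, int(round(n * (0.55 if not lnm else 0.40))), 31)
        strata.append(
            pd.DataFrame(
                {
                    "patient_id": [f"R{start + i:04d}" for i in range(n)],
                    "age": np.where(young, 55.0, 68.0),
                    "gender": np.where(male, "male", "female"),
                    "smoking_index": np.where(light, 200.0, 600.0),
                    "ecog": np.where(fit, 1, 2),
                    "tumor_diameter": np.where(diam_small, 2.5, 4.0),
                    "histology": _spread_cat(hist, 3),
                    "t_stage": _spread_cat(tstage, 5),
                    "n_stage": _spread_cat(nstage, 0),
                    "ajcc_stage": _spread_cat(ajcc, 11),
                    "lnm": lnm,
                    "rfs_time": 1064.0,
                    "rfs_event": False,
                }
            )
        )
        start += n
    return pd.concat(strata, ignore_index=True)
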