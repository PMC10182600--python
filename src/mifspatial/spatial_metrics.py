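"""The three per-site spatial statistics and their patient-level aggregation.

* **Density** (per mille): ``1000 * n(A) / n(total cells)``, where the total
  counts every segmented cell including "other".
* **mNND** (microns): mean over source cells A of the Euclidean
  nucleus-to-nucleus distance to the closest target cell B in the same site;
  a cell never counts itself when A and B overlap. Undefined when either
  population is absent.
* **CCPS** (mean count): mean number of A cells within a closed ball of
  radius ``r`` (default 30 um) of each cancer cell; a cancer cell that is
  itself A-labelled does not count itself.

Distances are computed across the whole site regardless of tumor/stroma
compartment, and no edge correction is applied at the core boundary (a small
bias shared with conventional TMA analyses; see docs/methods.md).

Undefined values are returned as NaN and propagate as missing - never as
zero. Neighbor queries use a k-d tree and agree with the O(n^2) definition
to the last bit, which the test suite checks against a brute-force oracle.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io_cells import TissueSite
from .phenotyping import PhenotypeScheme

Labels = Union[str, Iterable[str]]

DEFAULT_RADIUS = 30.0
DEFAULT_DENSITY_THRESHOLD = 5.0  # per mille


class DensityResult(NamedTuple):
    density: float  # per mille; NaN when the site is empty
    n_pheno: int
    n_total: int


class MNNDResult(NamedTuple):
    mnnd: float  # microns; NaN when undefined
    n_source: int
    sum_min_dist: float


class ProximityResult(NamedTuple):
    score: float  # mean neighbor count; NaN when undefined
    n_reference: int
    sum_counts: int
    radius: float


def _resolve(labels: Labels, scheme: Optional[PhenotypeScheme]) -> frozenset:
    if scheme is not None:
        return scheme.resolve(labels)
    if isinstance(labels, str):
        return frozenset({labels})
    return frozenset(labels)


def _indices(site: TissueSite, labels: Labels, scheme: Optional[PhenotypeScheme]) -> np.ndarray:
    return np.flatnonzero(site.phenotype_mask(_resolve(labels, scheme)))


# ---------------------------------------------------------------------------
# per-site metrics
# ---------------------------------------------------------------------------

def compute_density(
    site: TissueSite, phenotype: Labels, scheme: Optional[PhenotypeScheme] = None
) -> DensityResult:
    """Per-mille density of a phenotype among all segmented cells of a site."""
    n_total = site.n_cells
    n_pheno = int(site.phenotype_mask(_resolve(phenotype, scheme)).sum())
    if n_total == 0:
        return DensityResult(math.nan, n_pheno, 0)
    return DensityResult(1000.0 * n_pheno / n_total, n_pheno, n_total)


def compute_mnnd(
    site: TissueSite,
    source: Labels,
    target: Labels,
    scheme: Optional[PhenotypeScheme] = None,
) -> MNNDResult:
    """Mean nearest-neighbor distance from source cells to target cells."""
    src_idx = _indices(site, source, scheme)
    tgt_idx = _indices(site, target, scheme)
    n_source = len(src_idx)
    if n_source == 0 or len(tgt_idx) == 0:
        return MNNDResult(math.nan, n_source, math.nan)

    xy = site.df[["x", "y"]].to_numpy(dtype=float)
    src_xy = xy[src_idx]
    tgt_xy = xy[tgt_idx]
    tgt_set = set(tgt_idx.tolist())
    overlap = np.array([i in tgt_set for i in src_idx])

    tree = cKDTree(tgt_xy)
    if not overlap.any():
        dmin, _ = tree.query(src_xy, k=1)
    else:
        if len(tgt_idx) == 1:
            # the only target is the source cell itself -> no neighbor exists
            return MNNDResult(math.nan, n_source, math.nan)
        dist, nbr = tree.query(src_xy, k=2)
        # the self-match is identified by cell index, not by zero distance,
        # so coincident distinct cells are still legitimate neighbors
        self_first = overlap & (tgt_idx[nbr[:, 0]] == src_idx)
        dmin = np.where(self_first, dist[:, 1], dist[:, 0])
    total = float(np.sum(dmin))
    return MNNDResult(total / n_source, n_source, total)


def mean_neighbor_count(
    site: TissueSite,
    reference: Labels,
    target: Labels,
    r: float = DEFAULT_RADIUS,
    scheme: Optional[PhenotypeScheme] = None,
) -> ProximityResult:
    """Mean number of target cells within a closed ball of radius ``r`` of
    each reference cell (reference cells never count themselves)."""
    if not r >= 0:
        raise ValueError("radius must be non-negative")
    ref_idx = _indices(site, reference, scheme)
    tgt_idx = _indices(site, target, scheme)
    n_ref = len(ref_idx)
    if n_ref == 0:
        return ProximityResult(math.nan, 0, 0, r)
    if len(tgt_idx) == 0:
        return ProximityResult(0.0, n_ref, 0, r)
    xy = site.df[["x", "y"]].to_numpy(dtype=float)
    tree = cKDTree(xy[tgt_idx])
    counts = tree.query_ball_point(xy[ref_idx], r, return_length=True)
    tgt_set = set(tgt_idx.tolist())
    self_hits = np.array([i in tgt_set for i in ref_idx])
    counts = counts - self_hits.astype(int)
    total = int(counts.sum())
    return ProximityResult(total / n_ref, n_ref, total, r)


def compute_ccps(
    site: TissueSite,
    phenotype: Labels,
    r: float = DEFAULT_RADIUS,
    scheme: Optional[PhenotypeScheme] = None,
    reference: Labels = "cancer",
) -> ProximityResult:
    """Cancer-cell proximity score of a phenotype at radius ``r``."""
    return mean_neighbor_count(site, reference, phenotype, r=r, scheme=scheme)


# ---------------------------------------------------------------------------
# tidy per-site tables and patient-level aggregation
# ---------------------------------------------------------------------------

_SITE_KEY = ["patient_id", "region", "core", "panel"]
_METRIC_KEY = ["metric", "phenotype", "target", "radius"]


def site_metrics(
    sites: Sequence[TissueSite],
    scheme_by_panel: Mapping[str, PhenotypeScheme],
    density_phenotypes: Mapping[str, Sequence[str]],
    nnd_pairs: Mapping[str, Sequence[tuple[str, str]]] = (),
    ccps_phenotypes: Mapping[str, Sequence[str]] = (),
    radii: Sequence[float] = (DEFAULT_RADIUS,),
    ccps_reference: str = "cancer",
) -> pd.DataFrame:
    """Tidy per-core metric table with numerators and denominators.

    ``density_phenotypes`` / ``nnd_pairs`` / ``ccps_phenotypes`` map a panel id
    to the labels (or source-target pairs) evaluated for sites of that panel.
    Keeping the raw numerator/denominator per core is what makes the
    patient-level aggregation exact (cores are disjoint tissue, so
    coordinates are never pooled across cores).
    """
    rows = []
    for site in sites:
        scheme = scheme_by_panel[site.panel_id]
        base = dict(
            patient_id=site.patient_id,
            region=site.region,
            core=site.core_index,
            panel=site.panel_id,
        )
        for ph in density_phenotypes.get(site.panel_id, ()):
            res = compute_density(site, ph, scheme)
            rows.append(
                base | dict(metric="density_permille", phenotype=ph, target=pd.NA,
                            radius=np.nan, numerator=float(res.n_pheno),
                            denominator=float(res.n_total), value=res.density)
            )
        if nnd_pairs:
            for src, tgt in nnd_pairs.get(site.panel_id, ()):
                res = compute_mnnd(site, src, tgt, scheme)
                rows.append(
                    base | dict(metric="mnnd_um", phenotype=src, target=tgt,
                                radius=np.nan, numerator=res.sum_min_dist,
                                denominator=float(res.n_source) if res.n_source else np.nan,
                                value=res.mnnd)
                )
        if ccps_phenotypes:
            for ph in ccps_phenotypes.get(site.panel_id, ()):
                for r in radii:
                    res = compute_ccps(site, ph, r=r, scheme=scheme, reference=ccps_reference)
                    rows.append(
                        base | dict(metric=f"ccps_r{r:g}", phenotype=ph, target=pd.NA,
                                    radius=float(r),
                                    numerator=float(res.sum_counts) if res.n_reference else np.nan,
                                    denominator=float(res.n_reference) if res.n_reference else np.nan,
                                    value=res.score)
                    )
    df = pd.DataFrame(rows)
    return df


def aggregate_patient(core_metrics: pd.DataFrame) -> pd.DataFrame:
    """Combine per-core metrics to patient x region values.

    Counts and distance sums are pooled across cores (sum of numerators over
    sum of denominators); cores where a metric is undefined contribute
    nothing. A patient-region with no analyzable core yields a missing value.
    """
    if core_metrics.empty:
        return pd.DataFrame(columns=["patient_id", "region", *_METRIC_KEY, "value"])
    df = core_metrics.copy()
    valid = df["denominator"].notna() & (df["denominator"] > 0) & df["numerator"].notna()
    df.loc[~valid, ["numerator", "denominator"]] = np.nan
    grouped = (
        df.groupby(["patient_id", "region", *_METRIC_KEY], dropna=False)[
            ["numerator", "denominator"]
        ]
        .sum(min_count=1)
        .reset_index()
    )
    ratio = grouped["numerator"] / grouped["denominator"]
    scale = np.where(grouped["metric"] == "density_permille", 1000.0, 1.0)
    grouped["value"] = ratio * scale
    return grouped.drop(columns=["numerator", "denominator"])


def filter_populations(
    patient_metrics: pd.DataFrame,
    threshold: float = DEFAULT_DENSITY_THRESHOLD,
    metric: str = "density_permille",
) -> dict[str, set[str]]:
    """Phenotypes whose cohort-median patient-level density reaches the
    inclusion threshold (inclusive boundary), per region.

    The population-inclusion rule is applied to the cohort median of
    patient-level densities; with ``threshold=0`` every phenotype with any
    cells qualifies.
    """
    dens = patient_metrics[patient_metrics["metric"] == metric]
    out: dict[str, set[str]] = {}
    for region, sub in dens.groupby("region"):
        medians = sub.groupby("phenotype")["value"].median()
        out[str(region)] = set(medians.index[medians >= threshold].astype(str))
    return out
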