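"""Cohort-level statistics: group comparisons, regression models, survival.

The analysis unit is a patient x region x metric table joined with clinical
covariates. Conventions follow common oncology-cohort practice:

* two independent samples: two-sided Mann-Whitney U (exact enumeration for
  small samples, tie-corrected normal approximation otherwise);
* paired region comparison (IM vs TC): Wilcoxon signed-rank, zero
  differences dropped;
* lymph-node-metastasis models: logistic regression with backward
  elimination (exposure locked in, covariates leave at p > 0.05),
  adjusted for age (<=60 vs >60 y), gender, histology (LUSC vs LUAD) and
  tumor diameter (<=3 vs >3 cm); variance inflation factors are reported
  and flagged at VIF >= 10 (tolerance <= 0.1);
* recurrence-free survival: Cox proportional hazards with the same
  elimination and collinearity contract, adjustment set additionally
  containing lymph node status; Kaplan-Meier / log-rank for grouped curves;
* continuous exposures are stratified with a maximally selected log-rank
  cutpoint whose p-value is permutation-adjusted (a published-method
  substitute for interactive cutpoint software such as X-tile, with a 10%
  minimum group size);
* monotone association between proximity scores: Spearman rank correlation
  with significance tiers (* 0.01<=p<0.05, ** 0.001<=p<0.01, *** p<0.001).

Undefined metric values are excluded listwise per analysis, never imputed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.stats.outliers_influence import variance_inflation_factor
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .io_cells import TissueSite
from .phenotyping import PhenotypeScheme
from .spatial_metrics import mean_neighbor_count

EXACT_N_MAX = 20          # exact Mann-Whitney enumeration up to this group size
STAY_P = 0.05             # backward-elimination stay threshold
VIF_FLAG = 10.0           # collinearity flag (tolerance 1/VIF <= 0.1)

#: Adjustment sets; the model frame encodes them as the dichotomies stated in
#: the docstring above.
LNM_ADJUSTMENT = ("age_gt60", "male", "lusc", "diameter_gt3")
RFS_ADJUSTMENT = ("age_gt60", "male", "lusc", "diameter_gt3", "lnm")


# ---------------------------------------------------------------------------
# two-sample and paired comparisons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComparisonResult:
    statistic: float
    p_value: float
    method: str
    n1: int
    n2: int


def compare_groups(x: Sequence[float], y: Sequence[float]) -> ComparisonResult:
    """Two-sided Mann-Whitney U test; ``statistic`` is U of the first group."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    method = "exact" if max(len(x), len(y)) <= EXACT_N_MAX else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return ComparisonResult(float(res.statistic), float(min(res.pvalue, 1.0)),
                            f"mann-whitney-{method}", len(x), len(y))


def compare_regions_paired(
    values_im: Sequence[float], values_tc: Sequence[float]
) -> ComparisonResult:
    """Two-sided Wilcoxon signed-rank test on patient-paired IM/TC values.

    Pairs with either side missing are excluded; zero differences are
    dropped (Wilcoxon's convention). All-zero differences are an error, not
    a p-value of 1.
    """
    im = np.asarray(values_im, dtype=float)
    tc = np.asarray(values_tc, dtype=float)
    if im.shape != tc.shape:
        raise ValueError("paired samples must have equal length")
    keep = ~np.isnan(im) & ~np.isnan(tc)
    im, tc = im[keep], tc[keep]
    if len(im) == 0:
        raise ValueError("no complete pairs")
    nonzero = im != tc
    if not nonzero.any():
        raise ValueError("all paired differences are zero; no informative pairs")
    im, tc = im[nonzero], tc[nonzero]
    res = stats.wilcoxon(im, tc, zero_method="wilcox", alternative="two-sided")
    return ComparisonResult(float(res.statistic), float(res.pvalue),
                            "wilcoxon-signed-rank", len(im), len(tc))


# ---------------------------------------------------------------------------
# model frame preparation
# ---------------------------------------------------------------------------

def prepare_model_frame(
    clinical: pd.DataFrame,
    exposure: pd.Series,
    dichotomize: Union[None, str, float] = "median",
) -> pd.DataFrame:
    """Join an exposure onto dichotomized clinical covariates.

    ``clinical`` is indexed by patient id with columns ``age``, ``gender``,
    ``histology``, ``tumor_diameter``, ``lnm`` and (optionally) ``rfs_time``
    / ``rfs_event``. Histologies other than LUSC/LUAD are left missing and
    therefore drop out of adjusted models listwise.
    """
    df = pd.DataFrame(index=clinical.index)
    df["age_gt60"] = (clinical["age"] > 60).astype(float).where(clinical["age"].notna())
    df["male"] = clinical["gender"].map({"male": 1.0, "female": 0.0})
    hist = clinical["histology"]
    df["lusc"] = hist.map({"LUSC": 1.0, "LUAD": 0.0})
    df["diameter_gt3"] = (
        (clinical["tumor_diameter"] > 3).astype(float).where(clinical["tumor_diameter"].notna())
    )
    df["lnm"] = clinical["lnm"].astype(float)
    for col in ("rfs_time", "rfs_event"):
        if col in clinical.columns:
            df[col] = pd.to_numeric(clinical[col], errors="coerce")
    x = pd.to_numeric(exposure.reindex(clinical.index), errors="coerce")
    if dichotomize is None:
        df["exposure"] = x
    else:
        cut = float(x.median()) if dichotomize == "median" else float(dichotomize)
        df["exposure"] = (x > cut).astype(float).where(x.notna())
    return df


# ---------------------------------------------------------------------------
# regression models with backward elimination
# ---------------------------------------------------------------------------

@dataclass
class ModelResult:
    kind: str                  # "logistic" | "cox"
    exposure: str
    estimate: float            # OR or HR for the exposure
    ci_low: float
    ci_high: float
    p_value: float
    n_used: int
    n_events: int
    terms: pd.DataFrame        # per-term estimate / CI / p / VIF of final model
    dropped: tuple = ()
    vif: Mapping[str, float] = field(default_factory=dict)
    vif_flagged: tuple = ()
    converged: bool = True
    message: str = ""

    def forest_frame(self) -> pd.DataFrame:
        """Terms table in forest-plot CSV layout."""
        out = self.terms.reset_index().rename(columns={"index": "term"})
        out.insert(0, "model", self.kind)
        out["n"] = self.n_used
        return out


def _vif_table(X: pd.DataFrame) -> dict[str, float]:
    """VIF per column of a design matrix (an intercept is added internally)."""
    if X.shape[1] < 2:
        return {c: 1.0 for c in X.columns}
    design = sm.add_constant(X.astype(float), has_constant="add")
    cols = [c for c in design.columns if c != "const"]
    arr = design.to_numpy()
    out = {}
    for c in cols:
        j = list(design.columns).index(c)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                out[c] = float(variance_inflation_factor(arr, j))
            except Exception:
                out[c] = math.nan
    return out


def _complete_cases(df: pd.DataFrame, cols: Sequence[str]) -> pd.DataFrame:
    return df[list(cols)].dropna()


def fit_lnm_logistic(
    data: pd.DataFrame,
    exposure: str = "exposure",
    adjusted: bool = True,
    covariates: Sequence[str] = LNM_ADJUSTMENT,
    outcome: str = "lnm",
    stay_p: float = STAY_P,
) -> ModelResult:
    """Odds ratio of lymph node metastasis for an exposure.

    Backward elimination removes adjustment covariates (never the exposure)
    while their Wald p exceeds ``stay_p``. Complete separation is reported as
    a non-converged result, not an exception.
    """
    covs = list(covariates) if adjusted else []
    frame = _complete_cases(data, [outcome, exposure, *covs])
    y = frame[outcome].astype(float)
    if frame[exposure].nunique() < 2:
        raise ValueError("degenerate exposure: no variation in complete cases")
    if y.nunique() < 2:
        raise ValueError("degenerate outcome: only one class present")

    kept = list(covs)
    while True:
        X = frame[[exposure, *kept]].astype(float)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, sm.add_constant(X, has_constant="add")).fit(
                    disp=0, maxiter=200
                )
            params, bse, pvals = fit.params, fit.bse, fit.pvalues
            conf = fit.conf_int()
            ok = (
                np.isfinite(params).all()
                and np.isfinite(bse).all()
                and float(np.abs(params).max()) < 50
            )
        except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
            ok = False
            message = f"separation or singular design: {exc}"
        if not ok:
            return ModelResult(
                kind="logistic", exposure=exposure, estimate=math.nan,
                ci_low=math.nan, ci_high=math.nan, p_value=math.nan,
                n_used=len(frame), n_events=int(y.sum()),
                terms=pd.DataFrame(), dropped=tuple(set(covs) - set(kept)),
                converged=False,
                message=locals().get("message", "estimates diverged (likely complete separation)"),
            )
        removable = {c: pvals[c] for c in kept}
        if removable and max(removable.values()) > stay_p:
            kept.remove(max(removable, key=removable.get))
            continue
        break

    vif = _vif_table(frame[[exposure, *kept]])
    flagged = tuple(c for c, v in vif.items() if v >= VIF_FLAG)
    # a CI bound may legitimately overflow to +inf near separation
    with np.errstate(over="ignore"):
        terms = pd.DataFrame(
            {
                "estimate": np.exp(params.drop("const")),
                "ci_low": np.exp(conf[0].drop("const")),
                "ci_high": np.exp(conf[1].drop("const")),
                "p_value": pvals.drop("const"),
                "vif": pd.Series(vif),
            }
        )
    with np.errstate(over="ignore"):
        est = float(np.exp(params[exposure]))
        lo = float(np.exp(np.float64(conf.loc[exposure, 0])))
        hi = float(np.exp(np.float64(conf.loc[exposure, 1])))
    return ModelResult(
        kind="logistic", exposure=exposure,
        estimate=est, ci_low=lo, ci_high=hi,
        p_value=float(pvals[exposure]),
        n_used=len(frame), n_events=int(y.sum()), terms=terms,
        dropped=tuple(c for c in covs if c not in kept),
        vif=vif, vif_flagged=flagged,
    )


def fit_rfs_cox(
    data: pd.DataFrame,
    exposure: str = "exposure",
    adjusted: bool = True,
    covariates: Sequence[str] = RFS_ADJUSTMENT,
    duration: str = "rfs_time",
    event: str = "rfs_event",
    stay_p: float = STAY_P,
) -> ModelResult:
    """Hazard ratio for recurrence-free survival, same contract as the
    logistic model (exposure locked, covariates leave at p > ``stay_p``)."""
    covs = list(covariates) if adjusted else []
    frame = _complete_cases(data, [duration, event, exposure, *covs])
    if len(frame) == 0:
        raise ValueError("no complete cases")
    if not (frame[duration] > 0).all():
        raise ValueError("rfs_time must be positive")
    n_events = int(frame[event].sum())
    if n_events == 0:
        raise ValueError("no events observed (all subjects censored)")
    if frame[exposure].nunique() < 2:
        raise ValueError("degenerate exposure: no variation in complete cases")

    kept = list(covs)
    while True:
        cols = [duration, event, exposure, *kept]
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(frame[cols], duration_col=duration, event_col=event)
            summary = cph.summary
            ok = np.isfinite(summary["coef"]).all() and float(np.abs(summary["coef"]).max()) < 50
        except (ConvergenceError, np.linalg.LinAlgError, ValueError) as exc:
            ok = False
            message = f"Cox model failed to converge: {exc}"
        if not ok:
            return ModelResult(
                kind="cox", exposure=exposure, estimate=math.nan,
                ci_low=math.nan, ci_high=math.nan, p_value=math.nan,
                n_used=len(frame), n_events=n_events, terms=pd.DataFrame(),
                dropped=tuple(set(covs) - set(kept)), converged=False,
                message=locals().get("message", "estimates diverged"),
            )
        pvals = summary["p"]
        removable = {c: pvals[c] for c in kept}
        if removable and max(removable.values()) > stay_p:
            kept.remove(max(removable, key=removable.get))
            continue
        break

    vif = _vif_table(frame[[exposure, *kept]])
    flagged = tuple(c for c, v in vif.items() if v >= VIF_FLAG)
    terms = pd.DataFrame(
        {
            "estimate": summary["exp(coef)"],
            "ci_low": summary["exp(coef) lower 95%"],
            "ci_high": summary["exp(coef) upper 95%"],
            "p_value": summary["p"],
            "vif": pd.Series(vif),
        }
    )
    return ModelResult(
        kind="cox", exposure=exposure,
        estimate=float(summary.loc[exposure, "exp(coef)"]),
        ci_low=float(summary.loc[exposure, "exp(coef) lower 95%"]),
        ci_high=float(summary.loc[exposure, "exp(coef) upper 95%"]),
        p_value=float(summary.loc[exposure, "p"]),
        n_used=len(frame), n_events=n_events, terms=terms,
        dropped=tuple(c for c in covs if c not in kept),
        vif=vif, vif_flagged=flagged,
    )


# ---------------------------------------------------------------------------
# log-rank machinery, cutpoint stratification, Kaplan-Meier
# ---------------------------------------------------------------------------

def logrank_chi2(time: np.ndarray, event: np.ndarray, in_group2: np.ndarray) -> float:
    """Two-group log-rank chi-square statistic (1 df), fully vectorized.

    Matches ``lifelines.statistics.logrank_test`` (checked in the test
    suite); implemented directly because the permutation-adjusted cutpoint
    search below evaluates it tens of thousands of times.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    g2 = np.asarray(in_group2, dtype=bool)
    order = np.argsort(time, kind="mergesort")
    t, e, g = time[order], event[order], g2[order]
    n = len(t)
    # risk sets just before each unique event time
    uniq, first = np.unique(t, return_index=True)
    # cumulative counts from the right
    at_risk_total = n - first
    csum_g = np.concatenate([[0], np.cumsum(g)])
    at_risk_g2 = csum_g[n] - csum_g[first]
    # events at each unique time
    d_total = np.add.reduceat(e.astype(float), first)
    d_g2 = np.add.reduceat((e & g).astype(float), first)
    has_event = d_total > 0
    nt = at_risk_total[has_event].astype(float)
    n2 = at_risk_g2[has_event].astype(float)
    d = d_total[has_event]
    d2 = d_g2[has_event]
    expected = d * n2 / nt
    with np.errstate(invalid="ignore", divide="ignore"):
        var = d * (n2 / nt) * (1 - n2 / nt) * (nt - d) / np.where(nt > 1, nt - 1, np.nan)
    var = np.nan_to_num(var)
    v = var.sum()
    if v <= 0:
        return 0.0
    return float((d2.sum() - expected.sum()) ** 2 / v)


@dataclass(frozen=True)
class CutpointResult:
    cutpoint: float
    statistic: float
    p_value: float            # permutation-adjusted for the cutpoint search
    n_low: int
    n_high: int
    n_candidates: int
    method: str = "maximally selected log-rank (permutation-adjusted)"


def stratify_cutpoint(
    values: Sequence[float],
    time: Sequence[float],
    event: Sequence[float],
    min_group_frac: float = 0.10,
    n_permutations: int = 1000,
    random_state: Union[int, np.random.Generator, None] = None,
) -> CutpointResult:
    """Split a continuous marker at the cutpoint maximizing the log-rank
    statistic, with a permutation p-value that accounts for the search.

    Candidate cutpoints are midpoints between adjacent distinct values for
    which both groups retain at least ``min_group_frac`` of patients.
    """
    values = np.asarray(values, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    keep = ~np.isnan(values) & ~np.isnan(time)
    values, time, event = values[keep], time[keep], event[keep]
    n = len(values)
    if n < 20:
        raise ValueError("cutpoint search requires at least 20 patients")
    if event.mean() < 0.10:
        raise ValueError("cutpoint search requires at least 10% events")
    uniq = np.unique(values)
    if len(uniq) < 2:
        raise ValueError("constant marker values: no admissible split")
    min_n = int(math.ceil(min_group_frac * n))
    sorted_vals = np.sort(values)
    candidates = []
    for lo, hi in zip(uniq[:-1], uniq[1:]):
        c = 0.5 * (lo + hi)
        n_low = int(np.searchsorted(sorted_vals, c))
        if n_low >= min_n and n - n_low >= min_n:
            candidates.append(c)
    if not candidates:
        raise ValueError("no admissible split satisfies the minimum group size")
    candidates = np.asarray(candidates)

    def max_stat(v: np.ndarray) -> tuple[float, float]:
        best, best_c = -1.0, candidates[0]
        for c in candidates:
            s = logrank_chi2(time, event, v > c)
            if s > best:
                best, best_c = s, c
        return best, best_c

    observed, best_cut = max_stat(values)
    rng = np.random.default_rng(random_state)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(values)
        s, _ = max_stat(perm)
        if s >= observed:
            exceed += 1
    p = (1 + exceed) / (n_permutations + 1)
    n_high = int((values > best_cut).sum())
    return CutpointResult(
        cutpoint=float(best_cut), statistic=float(observed), p_value=float(p),
        n_low=n - n_high, n_high=n_high, n_candidates=len(candidates),
    )


@dataclass
class KMResult:
    curves: Mapping[str, pd.DataFrame]  # label -> survival_function_ frame
    statistic: float
    p_value: float


def km_logrank(
    groups: Mapping[str, tuple[Sequence[float], Sequence[float]]]
) -> KMResult:
    """Kaplan-Meier product-limit curves per group plus the log-rank test."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    curves = {}
    times, events, labels = [], [], []
    for label, (t, e) in groups.items():
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=bool)
        if len(t) == 0:
            raise ValueError(f"group {label!r} is empty")
        if np.all((t <= 0) & ~e) or np.all(t <= 0):
            raise ValueError(f"group {label!r} carries no follow-up time")
        km = KaplanMeierFitter()
        km.fit(t, event_observed=e, label=str(label))
        curves[str(label)] = km.survival_function_
        times.append(t)
        events.append(e)
        labels.append(np.full(len(t), str(label), dtype=object))
    res = multivariate_logrank_test(
        np.concatenate(times), np.concatenate(labels), np.concatenate(events)
    )
    return KMResult(curves=curves, statistic=float(res.test_statistic),
                    p_value=float(res.p_value))


# ---------------------------------------------------------------------------
# correlations and the hypoxia proximity contrast
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    rho: pd.DataFrame
    p_value: pd.DataFrame
    n: pd.DataFrame
    tiers: pd.DataFrame  # "", "*", "**", "***" or "undef"


def _tier(p: float) -> str:
    if math.isnan(p):
        return "undef"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def correlation_matrix(
    data: pd.DataFrame, columns: Optional[Sequence[str]] = None, min_pairs: int = 3
) -> CorrelationResult:
    """Pairwise Spearman rank correlations with listwise deletion per pair."""
    cols = list(columns) if columns is not None else list(data.columns)
    k = len(cols)
    rho = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    pv = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    nn = pd.DataFrame(0, index=cols, columns=cols, dtype=int)
    for i, a in enumerate(cols):
        nn.loc[a, a] = int(data[a].notna().sum())
        for b in cols[i + 1:]:
            sub = data[[a, b]].dropna()
            nn.loc[a, b] = nn.loc[b, a] = len(sub)
            if len(sub) < min_pairs or sub[a].nunique() < 2 or sub[b].nunique() < 2:
                r, p = math.nan, math.nan
            else:
                r, p = stats.spearmanr(sub[a], sub[b])
            rho.loc[a, b] = rho.loc[b, a] = r
            pv.loc[a, b] = pv.loc[b, a] = p
    tiers = pv.map(_tier)
    np.fill_diagonal(tiers.values, "")
    return CorrelationResult(rho=rho, p_value=pv, n=nn, tiers=tiers)


@dataclass
class HypoxiaComparison:
    per_site: pd.DataFrame  # patient_id, region, core, hypoxic, normoxic
    test: ComparisonResult
    n_sites_dropped: int


def hypoxia_proximity_compare(
    sites: Sequence[TissueSite],
    scheme: PhenotypeScheme,
    target: str = "CMV",
    r: float = 30.0,
    hypoxic_label: str = "cancer_hypoxic",
    normoxic_label: str = "cancer_normoxic",
) -> HypoxiaComparison:
    """Mean target count within ``r`` around hypoxic vs normoxic cancer cells.

    Sites lacking either cancer subpopulation are dropped; the cohort-level
    contrast uses the two-sample Mann-Whitney U test on per-site scores.
    """
    rows = []
    dropped = 0
    for site in sites:
        hyp = mean_neighbor_count(site, hypoxic_label, target, r=r, scheme=scheme)
        nor = mean_neighbor_count(site, normoxic_label, target, r=r, scheme=scheme)
        if hyp.n_reference == 0 or nor.n_reference == 0:
            dropped += 1
            continue
        rows.append(
            dict(patient_id=site.patient_id, region=site.region,
                 core=site.core_index, hypoxic=hyp.score, normoxic=nor.score)
        )
    per_site = pd.DataFrame(rows)
    if per_site.empty:
        raise ValueError("no site contains both hypoxic and normoxic cancer cells")
    test = compare_groups(per_site["hypoxic"], per_site["normoxic"])
    return HypoxiaComparison(per_site=per_site, test=test, n_sites_dropped=dropped)
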