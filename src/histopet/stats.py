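"""Nonparametric statistical surface and the cohort study driver.

Implements the analysis applied to co-registered tumour volumes (pathway 1)
and tumour areas (pathway 2): Spearman rank correlations with bootstrap or
Fisher-z confidence intervals, Kruskal-Wallis with Dunn's post-hoc test
(unadjusted by default; Holm/Bonferroni selectable), through-origin linear
regression of SUV on H-Score with the uncentered R² convention, Fisher-z
comparison of independent correlations, and ``run_study``, which executes
both pathways end to end on a cohort of patient bundles and emits tidy
tables: per-unit metrics, correlations over the configured subsets
(all / per-cohort / size-filtered), expression-group comparisons and the
fixed-intercept regressions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .coregistration import (
    build_tumour_areas,
    build_tumour_volume,
    chain_lesions,
    refine_rigid,
)
from .histology import DEFAULT_GROUP_SCHEME, HScoreGroupScheme
from .pet_metrics import extract_uptake_stats, gtv_agreement

logger = logging.getLogger("histopet")

__all__ = [
    "DegenerateDataError",
    "CorrelationResult",
    "GroupComparisonResult",
    "OriginRegressionResult",
    "AnalysisConfig",
    "StudyResult",
    "spearman",
    "kruskal_wallis",
    "dunn_posthoc",
    "regress_through_origin",
    "compare_correlations",
    "run_study",
    "correlation_by_size_tertile",
]


class DegenerateDataError(ValueError):
    """Statistic undefined on the given data (e.g. constant input)."""


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    ci_low: float
    ci_high: float
    n: int
    ci_method: str


@dataclass(frozen=True)
class GroupComparisonResult:
    kw_statistic: float
    kw_p: float
    pairwise: pd.DataFrame  # group_a, group_b, z, p_raw, p_adjusted


@dataclass(frozen=True)
class OriginRegressionResult:
    """Through-origin fit y = slope * x; R² uses the uncentered convention."""

    slope: float
    slope_se: float
    r_squared: float
    p_value: float
    n: int


def _bootstrap_rho_ci(
    x: np.ndarray, y: np.ndarray, n_boot: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Seeded percentile bootstrap of Spearman's rho (vectorized over resamples)."""
    n = len(x)
    idx = rng.integers(0, n, size=(n_boot, n))
    xr = sps.rankdata(x[idx], axis=1)
    yr = sps.rankdata(y[idx], axis=1)
    xc = xr - xr.mean(axis=1, keepdims=True)
    yc = yr - yr.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, (xc * yc).sum(axis=1) / denom, np.nan)
    lo, hi = np.nanpercentile(rho, [2.5, 97.5])
    return float(lo), float(hi)


def spearman(
    x,
    y,
    ci_method: str = "bootstrap",
    n_boot: int = 10_000,
    seed: int = 0,
) -> CorrelationResult:
    """Spearman rank correlation with 95% CI.

    Average-rank tie handling; the p-value comes from the standard
    large-sample approximation.  The CI is a seeded percentile bootstrap
    (default, 10,000 resamples) or the Fisher-z interval with the
    Bonett-Wright standard error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("Spearman correlation requires n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("Spearman's rho is undefined for constant input")
    rho, p = sps.spearmanr(x, y)
    rho, p = float(rho), float(p)
    if ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        lo, hi = _bootstrap_rho_ci(x, y, n_boot, rng)
    elif ci_method == "fisher":
        if n < 4:
            raise ValueError("Fisher-z CI requires n >= 4")
        se = np.sqrt((1 + rho**2 / 2) / (n - 3))
        z = np.arctanh(np.clip(rho, -1 + 1e-12, 1 - 1e-12))
        lo, hi = np.tanh(z - 1.959963984540054 * se), np.tanh(z + 1.959963984540054 * se)
        lo, hi = float(lo), float(hi)
    else:
        raise ValueError("ci_method must be 'bootstrap' or 'fisher'")
    return CorrelationResult(rho, p, lo, hi, n, ci_method)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with the chi-square p (k-1 df)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis requires at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("all groups must be nonempty")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def dunn_posthoc(groups: dict, adjustment: str = "none") -> pd.DataFrame:
    """Dunn's rank-based post-hoc test for all unordered group pairs.

    z statistics use the pooled tie-corrected rank variance
    ``(N(N+1)/12 - T/(12(N-1))) * (1/n_i + 1/n_j)`` with
    ``T = sum(t^3 - t)`` over tie groups.  ``adjustment`` is "none"
    (default), "holm" or "bonferroni".
    """
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    if len(labels) < 2:
        return pd.DataFrame(columns=["group_a", "group_b", "z", "p_raw", "p_adjusted"])
    if any(len(a) == 0 for a in arrays):
        raise ValueError("all groups must be nonempty")
    pooled = np.concatenate(arrays)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    sizes = [len(a) for a in arrays]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [
        ranks[bounds[i] : bounds[i + 1]].mean() for i in range(len(labels))
    ]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            var = base_var * (1.0 / sizes[i] + 1.0 / sizes[j])
            if var <= 0:
                z = 0.0
            else:
                z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(var)
            p = 2.0 * sps.norm.sf(abs(z))
            rows.append((labels[i], labels[j], float(z), float(min(p, 1.0))))
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_raw"])
    if adjustment == "none":
        df["p_adjusted"] = df["p_raw"]
    elif adjustment in ("holm", "bonferroni"):
        df["p_adjusted"] = multipletests(df["p_raw"], method=adjustment)[1]
    else:
        raise ValueError("adjustment must be 'none', 'holm' or 'bonferroni'")
    return df


def regress_through_origin(x, y) -> OriginRegressionResult:
    """Least-squares line with fixed zero intercept.

    ``slope = sum(xy) / sum(x^2)``, SE from the residual variance with n-1
    degrees of freedom, and ``R^2 = 1 - RSS / sum(y^2)`` (uncentered
    convention, the only well-defined one for a fit through the origin).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D of equal length")
    n = len(x)
    if n < 2:
        if n == 1 and x[0] != 0:
            slope = float(y[0] / x[0])
            return OriginRegressionResult(slope, float("nan"), 1.0, float("nan"), 1)
        raise ValueError("through-origin regression requires n >= 2")
    sxx = float((x**2).sum())
    if sxx == 0:
        raise DegenerateDataError("slope undefined: all x are zero")
    slope = float((x * y).sum() / sxx)
    resid = y - slope * x
    rss = float((resid**2).sum())
    s2 = rss / (n - 1)
    se = float(np.sqrt(s2 / sxx))
    syy = float((y**2).sum())
    r2 = 1.0 - rss / syy if syy > 0 else float("nan")
    if se > 0:
        t = slope / se
        p = float(2.0 * sps.t.sf(abs(t), df=n - 1))
    else:
        p = 0.0
    return OriginRegressionResult(slope, se, float(r2), p, n)


def compare_correlations(r1: float, n1: int, r2: float, n2: int) -> float:
    """Two-sided Fisher-z test for equality of two independent correlations."""
    for r in (r1, r2):
        if abs(r) >= 1:
            raise DegenerateDataError("|r| = 1 gives an infinite Fisher z")
    if n1 < 4 or n2 < 4:
        raise ValueError("Fisher-z comparison requires n >= 4 in each sample")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    return float(2.0 * sps.norm.sf(abs(z)))


def correlation_by_size_tertile(
    units: pd.DataFrame, size_col: str, x_col: str = "hscore_mean", y_col: str = "suv_mean"
) -> dict[str, float]:
    """Spearman rho within the smallest and largest size tertiles."""
    df = units.dropna(subset=[size_col, x_col, y_col])
    if len(df) < 9:
        raise ValueError("tertile analysis needs at least 9 units")
    q1, q2 = df[size_col].quantile([1 / 3, 2 / 3])
    small = df[df[size_col] <= q1]
    large = df[df[size_col] >= q2]
    rho_s = float(sps.spearmanr(small[x_col], small[y_col])[0])
    rho_l = float(sps.spearmanr(large[x_col], large[y_col])[0])
    return {"rho_small": rho_s, "rho_large": rho_l, "n_small": len(small), "n_large": len(large)}


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the cohort analysis.

    Size-filter defaults follow the source protocol: tumour volumes over
    1 ml, tumour areas over 400 (in the histology area unit), patients with
    a GTV over 5 ml.
    """

    scheme: HScoreGroupScheme = DEFAULT_GROUP_SCHEME
    sub_factor: int = 4
    refine: bool = True
    refine_max_shift_mm: float = 16.0
    refine_max_rot_deg: float = 5.0
    ci_method: str = "bootstrap"
    n_boot: int = 10_000
    seed: int = 0
    dunn_adjustment: str = "none"
    min_volume_ml: float = 1.0
    min_area_um2: float = 400.0
    min_gtv_ml: float = 5.0
    max_occupancy_floor: float = 0.0


_UNIT_COLUMNS = [
    "patient", "cohort", "kind", "unit_id", "group", "hscore_mean", "hscore_sd",
    "area_um2", "suv_mean", "suv_max", "volume_ml", "gtv_agreement", "gtv_ml",
    "constituents",
]
_CORR_COLUMNS = ["kind", "subset", "metric", "rho", "p_value", "ci_low", "ci_high", "n"]
_GROUPTEST_COLUMNS = [
    "metric", "comparison", "kw_statistic", "kw_p", "group_a", "group_b", "z",
    "p_raw", "p_adjusted",
]
_REGR_COLUMNS = ["kind", "subset", "metric", "slope", "slope_se", "r_squared", "p_value", "n"]


@dataclass
class StudyResult:
    """Tidy tables produced by :func:`run_study`."""

    units: pd.DataFrame
    correlations: pd.DataFrame
    group_tests: pd.DataFrame
    regressions: pd.DataFrame
    cohort_comparisons: pd.DataFrame
    skipped: list = field(default_factory=list)

    def to_dir(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("units", "correlations", "group_tests", "regressions", "cohort_comparisons"):
            getattr(self, name).to_csv(out / f"{name}.csv", index=False, float_format="%.10g")


def _empty_result() -> StudyResult:
    return StudyResult(
        units=pd.DataFrame(columns=_UNIT_COLUMNS),
        correlations=pd.DataFrame(columns=_CORR_COLUMNS),
        group_tests=pd.DataFrame(columns=_GROUPTEST_COLUMNS),
        regressions=pd.DataFrame(columns=_REGR_COLUMNS),
        cohort_comparisons=pd.DataFrame(columns=["metric", "rho_i", "n_i", "rho_ii", "n_ii", "p_value"]),
    )


def _process_patient(bundle, config: AnalysisConfig) -> list[dict]:
    rows: list[dict] = []
    grid = bundle.pet.grid
    gtv_ml = bundle.gtv.volume_ml()

    def refined(mask):
        if not config.refine:
            return mask
        res = refine_rigid(
            mask,
            bundle.pet,
            max_shift_mm=config.refine_max_shift_mm,
            max_rot_deg=config.refine_max_rot_deg,
        )
        return res.mask

    t_areas = build_tumour_areas(
        bundle.areas,
        config.scheme,
        geom=bundle.geom,
        chain=bundle.chain,
        grid=grid,
        sub_factor=config.sub_factor,
    )
    for ta in t_areas:
        mask = refined(ta.mask)
        st = extract_uptake_stats(mask, bundle.pet, config.max_occupancy_floor)
        agr = gtv_agreement(mask, bundle.gtv)
        rows.append(
            dict(
                patient=bundle.patient_id, cohort=bundle.cohort, kind="tumour_area",
                unit_id=f"{bundle.patient_id}:{ta.group}", group=ta.group,
                hscore_mean=ta.hscore.mean, hscore_sd=ta.hscore.sd,
                area_um2=ta.area_um2, suv_mean=st.suv_mean, suv_max=st.suv_max,
                volume_ml=st.volume_ml, gtv_agreement=agr.agreement, gtv_ml=gtv_ml,
                constituents=";".join(ta.constituent_ids),
            )
        )

    for li, lesion_areas in enumerate(chain_lesions(bundle.areas)):
        tv = build_tumour_volume(
            lesion_areas, bundle.geom, bundle.chain, grid, config.sub_factor
        )
        mask = refined(tv.mask)
        st = extract_uptake_stats(mask, bundle.pet, config.max_occupancy_floor)
        rows.append(
            dict(
                patient=bundle.patient_id, cohort=bundle.cohort, kind="tumour_volume",
                unit_id=f"{bundle.patient_id}:V{li}", group="",
                hscore_mean=tv.hscore.mean, hscore_sd=tv.hscore.sd,
                area_um2=float(sum(a.area_um2 for a in lesion_areas)),
                suv_mean=st.suv_mean, suv_max=st.suv_max, volume_ml=st.volume_ml,
                gtv_agreement=np.nan, gtv_ml=gtv_ml,
                constituents=";".join(sorted(a.area_id for a in lesion_areas)),
            )
        )
    return rows


def _correlation_row(df, kind, subset, metric, x_col, y_col, config, seed) -> dict | None:
    sub = df.dropna(subset=[x_col, y_col])
    if len(sub) < 3 or (config.ci_method == "fisher" and len(sub) < 4):
        return None
    try:
        res = spearman(
            sub[x_col].to_numpy(), sub[y_col].to_numpy(),
            ci_method=config.ci_method, n_boot=config.n_boot, seed=seed,
        )
    except DegenerateDataError:
        logger.warning("degenerate correlation input for %s/%s/%s", kind, subset, metric)
        return None
    return dict(
        kind=kind, subset=subset, metric=metric, rho=res.rho, p_value=res.p_value,
        ci_low=res.ci_low, ci_high=res.ci_high, n=res.n,
    )


def run_study(bundles, config: AnalysisConfig = AnalysisConfig()) -> StudyResult:
    """Execute pathways 1 and 2 end to end on a cohort of patient bundles.

    Patients missing an input layer are skipped with a logged reason (never
    silently).  Fully deterministic given bundles, config and seed.
    """
    result = _empty_result()
    rows: list[dict] = []
    for b in bundles:
        missing = [
            name
            for name in ("areas", "pet", "gtv", "chain", "geom")
            if getattr(b, name, None) is None
        ]
        if missing or not b.areas:
            reason = f"missing input layers: {missing or ['areas (empty)']}"
            logger.warning("skipping patient %s: %s", b.patient_id, reason)
            result.skipped.append((b.patient_id, reason))
            continue
        rows.extend(_process_patient(b, config))
    if not rows:
        return result
    units = pd.DataFrame(rows, columns=_UNIT_COLUMNS)
    areas = units[units["kind"] == "tumour_area"]
    vols = units[units["kind"] == "tumour_volume"]

    area_subsets = {
        "all": areas,
        "cohort_I": areas[areas["cohort"] == "I"],
        "cohort_II": areas[areas["cohort"] == "II"],
        "area_gt_threshold": areas[areas["area_um2"] > config.min_area_um2],
        "gtv_gt_threshold": areas[areas["gtv_ml"] > config.min_gtv_ml],
    }
    vol_subsets = {
        "all": vols,
        "volume_gt_threshold": vols[vols["volume_ml"] > config.min_volume_ml],
    }
    corr_rows = []
    seed_counter = config.seed
    for kind, subsets, metrics in (
        ("tumour_area", area_subsets, ("suv_mean", "suv_max", "gtv_agreement")),
        ("tumour_volume", vol_subsets, ("suv_mean", "suv_max")),
    ):
        for subset, df in subsets.items():
            for metric in metrics:
                if metric == "gtv_agreement" and subset != "all":
                    continue
                seed_counter += 1
                row = _correlation_row(
                    df, kind, subset, metric, "hscore_mean", metric, config, seed_counter
                )
                if row is not None:
                    corr_rows.append(row)
    correlations = pd.DataFrame(corr_rows, columns=_CORR_COLUMNS)

    gt_rows = []
    for metric in ("suv_mean", "suv_max", "gtv_agreement"):
        groups = {
            lab: areas.loc[areas["group"] == lab, metric].dropna().to_numpy()
            for lab in config.scheme.labels
        }
        groups = {k: v for k, v in groups.items() if len(v) > 0}
        if len(groups) >= 2:
            h, p = kruskal_wallis(list(groups.values()))
            pair = dunn_posthoc(groups, adjustment=config.dunn_adjustment)
            for _, r in pair.iterrows():
                gt_rows.append(
                    dict(metric=metric, comparison="hscore_groups", kw_statistic=h,
                         kw_p=p, **r.to_dict())
                )
        coh = {
            lab: areas.loc[areas["cohort"] == lab, metric].dropna().to_numpy()
            for lab in ("I", "II")
        }
        coh = {k: v for k, v in coh.items() if len(v) > 0}
        if len(coh) == 2:
            h, p = kruskal_wallis(list(coh.values()))
            pair = dunn_posthoc(coh, adjustment=config.dunn_adjustment)
            for _, r in pair.iterrows():
                gt_rows.append(
                    dict(metric=metric, comparison="cohorts", kw_statistic=h, kw_p=p,
                         **r.to_dict())
                )
    group_tests = pd.DataFrame(gt_rows, columns=_GROUPTEST_COLUMNS)

    regr_rows = []
    for subset_name, df in (
        ("area_gt_threshold", area_subsets["area_gt_threshold"]),
        ("all", areas),
    ):
        for metric in ("suv_mean", "suv_max"):
            sub = df.dropna(subset=["hscore_mean", metric])
            if len(sub) >= 2 and (sub["hscore_mean"] != 0).any():
                res = regress_through_origin(
                    sub["hscore_mean"].to_numpy(), sub[metric].to_numpy()
                )
                regr_rows.append(
                    dict(kind="tumour_area", subset=subset_name, metric=metric,
                         slope=res.slope, slope_se=res.slope_se,
                         r_squared=res.r_squared, p_value=res.p_value, n=res.n)
                )
    regressions = pd.DataFrame(regr_rows, columns=_REGR_COLUMNS)

    cc_rows = []
    for metric in ("suv_mean", "suv_max"):
        r_i = correlations.query(
            "kind == 'tumour_area' and subset == 'cohort_I' and metric == @metric"
        )
        r_ii = correlations.query(
            "kind == 'tumour_area' and subset == 'cohort_II' and metric == @metric"
        )
        if len(r_i) == 1 and len(r_ii) == 1:
            ri, ni = float(r_i["rho"].iloc[0]), int(r_i["n"].iloc[0])
            rii, nii = float(r_ii["rho"].iloc[0]), int(r_ii["n"].iloc[0])
            if ni >= 4 and nii >= 4 and abs(ri) < 1 and abs(rii) < 1:
                p = compare_correlations(ri, ni, rii, nii)
                cc_rows.append(
                    dict(metric=metric, rho_i=ri, n_i=ni, rho_ii=rii, n_ii=nii, p_value=p)
                )
    cohort_comparisons = pd.DataFrame(
        cc_rows, columns=["metric", "rho_i", "n_i", "rho_ii", "n_ii", "p_value"]
    )

    return StudyResult(
        units=units,
        correlations=correlations,
        group_tests=group_tests,
        regressions=regressions,
        cohort_comparisons=cohort_comparisons,
        skipped=result.skipped,
    )
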