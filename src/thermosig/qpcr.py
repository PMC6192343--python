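"""qPCR validation statistics.

Assay amplification efficiency is estimated from a serial-dilution
standard curve: ordinary least squares of Ct on log10(relative template
concentration) gives a slope near -3.32 for a perfectly doubling assay,
and E = 10^(-1/slope) - 1. Assays with E in [0.8, 1.1] pass; E in
[0.65, 1.5] is the wider reporting range.

Relative expression uses the 2^-ddCt method: dCt subtracts the arithmetic
mean Ct of the housekeeping (reference) genes per sample, ddCt subtracts
the control-group mean dCt per gene, and relative expression is
2^(-ddCt). Group comparisons run on log2 relative expression: Bartlett's
homogeneity test, Kolmogorov-Smirnov normality per group (with a
Lilliefors-corrected p, since naive KS with estimated parameters is
anticonservative), one-way ANOVA with Tukey HSD post hoc, significance
stars at 0.05/0.01/0.001, and a headline P < 0.01 call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .core import ThermosigError

PASS_BAND = (0.8, 1.1)
REPORTING_RANGE = (0.65, 1.5)
HEADLINE_ALPHA = 0.01
STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass
class DilutionSeries:
    """One assay's standard curve: (relative concentration, Ct) pairs."""

    assay: str
    species: str
    concentrations: np.ndarray  # relative, strictly decreasing, positive
    ct: np.ndarray  # NaN marks "no amplification"

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.ct = np.asarray(self.ct, dtype=float)
        if self.concentrations.size != self.ct.size:
            raise ThermosigError("concentration and Ct arrays differ in length")
        if self.concentrations.size < 3:
            raise ThermosigError("dilution series needs at least 3 points")
        if (self.concentrations <= 0).any():
            raise ThermosigError("concentrations must be positive")
        if (np.diff(self.concentrations) >= 0).any():
            raise ThermosigError("concentrations must be strictly decreasing")


@dataclass
class EfficiencyResult:
    assay: str
    species: str
    slope: float
    intercept: float
    r_squared: float
    efficiency: float  # proportion; 1.0 = perfect doubling; NaN if invalid
    valid: bool
    passed: bool = field(init=False)
    in_reporting_range: bool = field(init=False)

    def __post_init__(self) -> None:
        e = self.efficiency
        self.passed = bool(self.valid and PASS_BAND[0] <= e <= PASS_BAND[1])
        self.in_reporting_range = bool(
            self.valid and REPORTING_RANGE[0] <= e <= REPORTING_RANGE[1]
        )


@dataclass
class CtTable:
    """Per sample x gene Ct values with reference-gene designations."""

    ct: pd.DataFrame  # samples (rows, indexed by sample_id) x genes
    reference_genes: list[str]
    meta: pd.DataFrame  # sample_id plus grouping columns

    def __post_init__(self) -> None:
        missing_ref = [g for g in self.reference_genes if g not in self.ct.columns]
        if missing_ref:
            raise ThermosigError(f"reference genes absent from Ct table: {missing_ref}")
        ref = self.ct[self.reference_genes]
        if ref.isna().all(axis=1).any():
            bad = list(self.ct.index[ref.isna().all(axis=1)])
            raise ThermosigError(f"samples with no reference-gene Ct: {bad}")
        if "sample_id" not in self.meta.columns:
            raise ThermosigError("meta needs a sample_id column")

    @property
    def target_genes(self) -> list[str]:
        return [g for g in self.ct.columns if g not in self.reference_genes]


@dataclass
class RelExprTable:
    """Per sample x target gene dCt / ddCt / 2^-ddCt values."""

    dct: pd.DataFrame
    ddct: pd.DataFrame
    rel_expr: pd.DataFrame  # 2^-ddCt
    log2_rel: pd.DataFrame  # == -ddCt
    meta: pd.DataFrame
    control_group: str
    group_col: str


def estimate_efficiency(series: DilutionSeries) -> EfficiencyResult:
    """Amplification efficiency from the standard-curve slope.

    With x = log10(relative concentration) the slope is negative and
    E = 10^(-1/slope) - 1; this is arithmetically identical to the
    dilution-axis convention E = 10^(1/slope') - 1 with slope' = -slope.
    """
    ok = np.isfinite(series.ct)
    if ok.sum() < 3:
        raise ThermosigError(
            f"assay {series.assay}: needs >= 3 finite Ct points, got {int(ok.sum())}"
        )
    x = np.log10(series.concentrations[ok])
    y = series.ct[ok]
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(((y - yhat) ** 2).sum()) / sst if sst > 0 else 1.0
    if slope >= 0:
        warnings.warn(f"assay {series.assay}: non-negative slope; E invalid", stacklevel=2)
        return EfficiencyResult(series.assay, series.species, float(slope),
                                float(intercept), r2, float("nan"), valid=False)
    e = 10.0 ** (-1.0 / slope) - 1.0
    return EfficiencyResult(series.assay, series.species, float(slope),
                            float(intercept), r2, float(e), valid=True)


def pass_filter(result: EfficiencyResult) -> dict[str, bool]:
    """Pass band [0.8, 1.1]; wider reporting range [0.65, 1.5]."""
    return {"passed": result.passed, "in_reporting_range": result.in_reporting_range}


def efficiency_report(results: list[EfficiencyResult]) -> pd.DataFrame:
    """Assay x species efficiency table with pass flags."""
    rows = [
        (r.assay, r.species, r.slope, r.intercept, r.r_squared, r.efficiency,
         r.passed, r.in_reporting_range)
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=["assay", "species", "slope", "intercept", "r_squared",
                 "efficiency", "passed", "in_reporting_range"],
    )


def delta_delta_ct(
    ct: CtTable, control_group: str, group_col: str = "temperature_group"
) -> RelExprTable:
    """Relative expression by the 2^-ddCt method.

    The reference aggregate is the arithmetic mean Ct of the reference
    genes per sample (the geometric mean of the linear quantities).
    Samples missing all reference Ct are excluded per gene with a
    warning; missing target Ct propagates as missing output.
    """
    meta = ct.meta.set_index("sample_id")
    if group_col not in meta.columns:
        raise ThermosigError(f"grouping column {group_col!r} not in metadata")
    groups = meta.loc[ct.ct.index, group_col]
    if not (groups == control_group).any():
        raise ThermosigError(f"control group {control_group!r} has no samples")
    ref_agg = ct.ct[ct.reference_genes].mean(axis=1, skipna=True)
    partial_ref = ct.ct[ct.reference_genes].isna().any(axis=1) & ref_agg.notna()
    if partial_ref.any():
        warnings.warn(
            f"{int(partial_ref.sum())} sample(s) with partially missing reference "
            "Ct; aggregate uses the available reference genes",
            stacklevel=2,
        )
    targets = ct.target_genes
    dct = ct.ct[targets].sub(ref_agg, axis=0)
    calibrator = dct.loc[groups == control_group].mean(axis=0, skipna=True)
    ddct = dct.sub(calibrator, axis=1)
    rel = np.power(2.0, -ddct)
    return RelExprTable(
        dct=dct,
        ddct=ddct,
        rel_expr=rel,
        log2_rel=-ddct,
        meta=ct.meta,
        control_group=control_group,
        group_col=group_col,
    )


def _stars(p: float) -> str:
    for cut, s in STAR_LEVELS:
        if p < cut:
            return s
    return ""


def _anova_f(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA F and p from explicit sums of squares."""
    k = len(groups)
    ns = [len(g) for g in groups]
    n = sum(ns)
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb, dfw = k - 1, n - k
    if ssw == 0:
        if ssb == 0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f = (ssb / dfb) / (ssw / dfw)
    return float(f), float(stats.f.sf(f, dfb, dfw))


def group_stats(rel: RelExprTable, group_col: str | None = None) -> pd.DataFrame:
    """Per-gene group comparison on log2 relative expression.

    Reports group means/SDs, Bartlett homogeneity, per-group KS normality
    (naive and Lilliefors-corrected), one-way ANOVA F/p, Tukey HSD pairwise
    adjusted p, significance stars, warm-vs-cool direction, and the
    headline P < 0.01 call.
    """
    gcol = group_col or rel.group_col
    meta = rel.meta.set_index("sample_id")
    labels = meta.loc[rel.log2_rel.index, gcol].astype(str)
    levels = list(dict.fromkeys(labels))
    if len(levels) < 2:
        raise ThermosigError("need at least 2 groups")
    rows = []
    for gene in rel.log2_rel.columns:
        vals = rel.log2_rel[gene]
        groups, used_levels = [], []
        for lv in levels:
            g = vals[labels == lv].dropna().to_numpy(float)
            if g.size >= 2:
                groups.append(g)
                used_levels.append(lv)
        if len(groups) < 2:
            warnings.warn(f"gene {gene}: fewer than 2 usable groups; skipped", stacklevel=2)
            continue
        f, p = _anova_f(groups)
        degenerate = not np.isfinite(f)
        if all(g.var(ddof=1) > 0 for g in groups):
            bart_stat, bart_p = stats.bartlett(*groups)
        else:
            bart_stat, bart_p = 0.0, 1.0
        ks_ps, lillie_ps = [], []
        for g in groups:
            sd = g.std(ddof=1)
            if sd > 0 and g.size >= 4:
                ks_ps.append(float(stats.kstest(g, "norm", args=(g.mean(), sd)).pvalue))
                lillie_ps.append(float(lilliefors(g, dist="norm")[1]))
        ks_min = min(ks_ps) if ks_ps else np.nan
        lil_min = min(lillie_ps) if lillie_ps else np.nan
        if len(groups) == 2:
            tk = stats.tukey_hsd(*groups)
            tukey = {f"{used_levels[0]}|{used_levels[1]}": float(tk.pvalue[0, 1])}
        else:
            tk = stats.tukey_hsd(*groups)
            tukey = {
                f"{used_levels[i]}|{used_levels[j]}": float(tk.pvalue[i, j])
                for i in range(len(groups))
                for j in range(i + 1, len(groups))
            }
        means = {lv: float(g.mean()) for lv, g in zip(used_levels, groups)}
        sds = {lv: float(g.std(ddof=1)) for lv, g in zip(used_levels, groups)}
        warm_like = [lv for lv in used_levels if "warm" in lv]
        cool_like = [lv for lv in used_levels if "cool" in lv]
        if warm_like and cool_like:
            direction = int(np.sign(means[warm_like[0]] - means[cool_like[0]]))
        else:
            direction = int(np.sign(means[used_levels[-1]] - means[used_levels[0]]))
        rows.append(
            {
                "gene": gene,
                "group_means": means,
                "group_sds": sds,
                "bartlett_stat": float(bart_stat),
                "bartlett_p": float(bart_p),
                "ks_p_min": ks_min,
                "lilliefors_p_min": lil_min,
                "anova_f": f,
                "anova_p": p,
                "tukey_p": tukey,
                "stars": _stars(p),
                "significant": bool(p < HEADLINE_ALPHA),
                "direction": direction,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)


def validate_panel(
    comparisons: dict[str, dict[str, pd.DataFrame]],
    required_strata: tuple[str, ...] = ("survivor", "moribund"),
    alpha: float = HEADLINE_ALPHA,
) -> pd.DataFrame:
    """Cross-cohort panel validation.

    ``comparisons[cohort][stratum]`` is a group_stats table. A gene is
    validated when it is significant at ``alpha`` with a consistent
    direction in every required stratum of every cohort; per-cohort
    outcomes (both / survivor-only / moribund-only / none / unevaluable)
    are reported alongside.
    """
    if len(comparisons) < 2:
        raise ThermosigError("panel validation needs >= 2 cohorts")
    genes: set[str] = set()
    for strata in comparisons.values():
        for tab in strata.values():
            genes |= set(tab["gene"])
    rows = []
    for gene in sorted(genes):
        cohort_status: dict[str, str] = {}
        validated = True
        directions: set[int] = set()
        for cohort, strata in comparisons.items():
            hits: dict[str, tuple[bool, int]] = {}
            unevaluable = False
            for st in required_strata:
                tab = strata.get(st)
                row = tab[tab["gene"] == gene] if tab is not None else None
                if row is None or row.empty:
                    unevaluable = True
                    continue
                r = row.iloc[0]
                hits[st] = (bool(r["significant"] and r["anova_p"] < alpha), int(r["direction"]))
            if unevaluable and not hits:
                cohort_status[cohort] = "unevaluable"
                validated = False
                continue
            sig_strata = [st for st, (sig, _) in hits.items() if sig]
            if unevaluable:
                cohort_status[cohort] = "unevaluable"
                validated = False
            elif len(sig_strata) == len(required_strata):
                cohort_status[cohort] = "both"
                directions |= {d for st, (sig, d) in hits.items() if sig}
            elif sig_strata:
                cohort_status[cohort] = f"{sig_strata[0]}-only"
                validated = False
            else:
                cohort_status[cohort] = "none"
                validated = False
        if len(directions) > 1:
            validated = False
        rows.append(
            {
                "gene": gene,
                "validated": bool(validated and cohort_status and
                                  all(v == "both" for v in cohort_status.values())),
                **{f"status_{c}": s for c, s in cohort_status.items()},
            }
        )
    return pd.DataFrame(rows)
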