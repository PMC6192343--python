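"""Per-dataset moderated differential expression.

Each probe is fit with an ordinary one-way linear model (the contrast of
interest is warm minus cool on the log2 scale); residual variances are then
shrunk toward a common prior by empirical Bayes. The gene-wise residual
variance s2_g on d_g df is modelled as s2_g ~ s0^2 * F(d_g, d0): the prior
is a scaled inverse chi-square with df d0 and scale s0^2, and (d0, s0^2)
are estimated by moment matching on log s2_g using the digamma/trigamma
relations of the log scaled-F law. The moderated t uses the posterior
variance s2_post = (d0*s0^2 + d_g*s2_g)/(d0 + d_g) on d0 + d_g df.

The "robust" variant winsorizes log-variances before moment matching and
assigns variance-outlier probes a reduced per-probe prior df, so a handful
of wildly variable probes neither inflate the prior nor get over-shrunk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .core import ExpressionMatrix, Signature, ThermosigError

DEFAULT_FDR = 0.01
DEFAULT_WINSOR_TAILS = (0.05, 0.1)


@dataclass
class GeneFit:
    """Per-probe linear-model fits: contrast, unscaled SE, s2_g, d_g."""

    table: pd.DataFrame  # probe_id, coef, stdev_unscaled, s2, df_resid, n_eff
    contrast: tuple[str, str]  # (treatment, control): coef = treatment - control
    excluded: list[str]  # probes dropped for zero residual df


@dataclass
class EBayesPrior:
    d0: float  # prior df; np.inf allowed
    s0_2: float  # prior variance scale
    df_prior_per_probe: np.ndarray | None = None  # set by robust estimation
    outlier: np.ndarray | None = None

    def __post_init__(self) -> None:
        # d0 = 0 is the no-moderation limit (ordinary t); estimation always
        # returns d0 > 0, but the limit is accepted for cross-checks
        if not (self.d0 >= 0):
            raise ThermosigError(f"prior df must be >= 0, got {self.d0}")
        if not (self.s0_2 > 0):
            raise ThermosigError(f"prior scale must be > 0, got {self.s0_2}")


@dataclass
class ModeratedStats:
    """Per-probe log2FC, posterior variance, moderated t, p and BH q."""

    table: pd.DataFrame  # probe_id, log2fc, s2_post, t, p, q, df_total
    prior: EBayesPrior
    contrast: tuple[str, str]


def _pick_contrast(levels: list[str]) -> tuple[str, str]:
    # warm - cool whenever both are present; otherwise last vs first level
    if "warm" in levels and "cool" in levels:
        return "warm", "cool"
    return levels[-1], levels[0]


def fit_gene_linear_models(matrix: ExpressionMatrix, group_labels) -> GeneFit:
    """One-way fits per probe: group means, pooled variance, contrast.

    For the two-group case the coefficient is the difference of group means,
    s2_g the pooled within-group variance and d_g = n - (#groups). Probes
    with missing values use listwise per-probe deletion (effective n
    recorded); probes left with zero residual df are excluded with a
    warning.
    """
    labels = np.asarray([str(g) for g in group_labels])
    if len(labels) != matrix.shape[1]:
        raise ThermosigError("group_labels length does not match sample count")
    levels = list(dict.fromkeys(labels))
    if len(levels) < 2:
        raise ThermosigError("need at least two groups")
    counts = {lv: int((labels == lv).sum()) for lv in levels}
    small = [lv for lv, c in counts.items() if c < 2]
    if small:
        raise ThermosigError(f"groups with fewer than 2 samples: {small}")
    trt, ctl = _pick_contrast(levels)

    X = matrix.values
    rows = []
    excluded: list[str] = []
    masks = {lv: labels == lv for lv in levels}
    for i, pid in enumerate(matrix.probe_ids):
        x = X[i]
        ok = ~np.isnan(x)
        n_eff = int(ok.sum())
        present = [lv for lv in levels if (masks[lv] & ok).sum() > 0]
        d = n_eff - len(present)
        g_trt, g_ctl = masks[trt] & ok, masks[ctl] & ok
        if d < 1 or g_trt.sum() < 2 or g_ctl.sum() < 2:
            excluded.append(pid)
            continue
        ss = 0.0
        for lv in present:
            vals = x[masks[lv] & ok]
            ss += float(((vals - vals.mean()) ** 2).sum())
        s2 = ss / d
        coef = float(x[g_trt].mean() - x[g_ctl].mean())
        sdu = float(np.sqrt(1.0 / g_trt.sum() + 1.0 / g_ctl.sum()))
        rows.append((pid, coef, sdu, s2, d, n_eff))
    if excluded:
        warnings.warn(
            f"{len(excluded)} probe(s) excluded for insufficient residual df",
            stacklevel=2,
        )
    table = pd.DataFrame(
        rows, columns=["probe_id", "coef", "stdev_unscaled", "s2", "df_resid", "n_eff"]
    )
    return GeneFit(table=table, contrast=(trt, ctl), excluded=excluded)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the standard scheme)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _winsorized_var_factor(lo: float, hi: float, n_grid: int = 20001) -> float:
    """Variance of a standard normal winsorized at quantiles (lo, 1-hi)."""
    zlo, zhi = stats.norm.ppf(lo), stats.norm.ppf(1.0 - hi)
    z = np.linspace(-10, 10, n_grid)
    w = np.clip(z, zlo, zhi)
    pdf = stats.norm.pdf(z)
    mu = np.trapezoid(w * pdf, z)
    return float(np.trapezoid((w - mu) ** 2 * pdf, z))


def estimate_prior(
    fits: GeneFit,
    robust: bool = False,
    winsor_tails: tuple[float, float] = DEFAULT_WINSOR_TAILS,
) -> EBayesPrior:
    """Moment-match (d0, s0^2) on log s2_g against the log scaled-F law.

    d0 is declared infinite when the empirical spread of log s2_g does not
    exceed the spread explained by the finite residual df alone (the
    trigamma-matching equation has no positive solution).
    """
    t = fits.table
    pos = t["s2"] > 0
    if pos.sum() < 2:
        if (t["s2"] >= 0).all() and t["s2"].nunique() == 1 and len(t) >= 1:
            v = float(t["s2"].iloc[0])
            return EBayesPrior(d0=np.inf, s0_2=v if v > 0 else 1e-12)
        raise ThermosigError("need >= 2 probes with positive residual variance")
    s2 = t.loc[pos, "s2"].to_numpy(float)
    d = t.loc[pos, "df_resid"].to_numpy(float)
    if np.all(s2 == s2[0]):
        # degenerate but valid: a point mass of variances IS the prior
        return EBayesPrior(d0=np.inf, s0_2=float(s2[0]))
    z = np.log(s2)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    n = len(e)

    if robust:
        lo_q, hi_q = np.quantile(e, [winsor_tails[0], 1.0 - winsor_tails[1]])
        ew = np.clip(e, lo_q, hi_q)
        emean = float(ew.mean())
        # winsorizing deflates spread; rescale by the normal-law factor
        factor = _winsorized_var_factor(*winsor_tails)
        evar_w = float(((ew - emean) ** 2).sum() / (n - 1))
        evar = evar_w / factor
    else:
        emean = float(e.mean())
        evar = float(((e - emean) ** 2).sum() / (n - 1))

    evar_excess = evar - float(np.mean(special.polygamma(1, d / 2.0)))
    if evar_excess <= 0:
        d0 = np.inf
        s0_2 = float(np.exp(emean))
        return EBayesPrior(d0=d0, s0_2=s0_2)
    d0 = 2.0 * _trigamma_inverse(evar_excess)
    s0_2 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    prior = EBayesPrior(d0=d0, s0_2=s0_2)

    if robust:
        # variance outliers get a reduced per-probe prior df: the largest d0
        # consistent with that probe's own excess spread
        hi_lim = np.quantile(e, 1.0 - winsor_tails[1])
        out = e > hi_lim
        df_pp = np.full(n, d0)
        for i in np.where(out)[0]:
            excess_i = (e[i] - emean) ** 2 - float(special.polygamma(1, d[i] / 2.0))
            if excess_i > evar_excess:
                df_pp[i] = 2.0 * _trigamma_inverse(excess_i)
        full = np.full(len(t), d0)
        full[pos.to_numpy()] = df_pp
        out_full = np.zeros(len(t), dtype=bool)
        out_full[pos.to_numpy()] = out
        prior.df_prior_per_probe = full
        prior.outlier = out_full
    return prior


def moderate(fits: GeneFit, prior: EBayesPrior) -> ModeratedStats:
    """Moderated t, p and BH q from fits and the empirical-Bayes prior.

    Limits: d0 -> inf gives s2_post = s0^2 (normal reference); d0 = 0 gives
    the ordinary pooled two-sample t on d_g df.
    """
    t = fits.table
    coef = t["coef"].to_numpy(float)
    sdu = t["stdev_unscaled"].to_numpy(float)
    s2 = t["s2"].to_numpy(float)
    d = t["df_resid"].to_numpy(float)
    d0 = (
        prior.df_prior_per_probe
        if prior.df_prior_per_probe is not None
        else np.full(len(t), prior.d0)
    )
    s0_2 = prior.s0_2

    s2_post = np.where(
        np.isinf(d0), s0_2, (d0 * s0_2 + d * s2) / np.where(np.isinf(d0), 1.0, d0 + d)
    )
    df_total = d0 + d
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = coef / (sdu * np.sqrt(s2_post))
    degenerate = s2_post == 0
    tstat = np.where(degenerate & (coef == 0), 0.0, tstat)
    p = np.where(
        np.isinf(df_total),
        2.0 * stats.norm.sf(np.abs(tstat)),
        2.0 * stats.t.sf(np.abs(tstat), np.where(np.isinf(df_total), 1.0, df_total)),
    )
    p = np.where(degenerate & (coef == 0), 1.0, p)
    if (degenerate & (coef != 0)).any():
        warnings.warn(
            "zero posterior variance with nonzero coefficient: p set to 0 "
            "(degenerate)",
            stacklevel=2,
        )
        p = np.where(degenerate & (coef != 0), 0.0, p)
        tstat = np.where(degenerate & (coef != 0), np.sign(coef) * np.inf, tstat)
    q = bh_fdr(p, tiebreak=t["probe_id"].to_numpy())
    out = pd.DataFrame(
        {
            "probe_id": t["probe_id"],
            "log2fc": coef,
            "s2_post": s2_post,
            "t": tstat,
            "p": p,
            "q": q,
            "df_total": df_total,
        }
    )
    return ModeratedStats(table=out, prior=prior, contrast=fits.contrast)


def bh_fdr(p_values, tiebreak=None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j: p_(j) >= p_(i)} p_(j) * m / rank(j), computed by a
    reverse cumulative minimum over the sorted p-values. Ties broken by a
    stable sort on (p, tiebreak). NaN p propagates to NaN q with a warning.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    nan = np.isnan(p)
    if nan.any():
        warnings.warn(f"{int(nan.sum())} NaN p-value(s) propagated to q", stacklevel=2)
    ok = ~nan
    pv = p[ok]
    if (pv < 0).any() or (pv > 1).any():
        raise ThermosigError("p-values must lie in [0, 1]")
    m = pv.size
    q = np.full(p.shape, np.nan)
    if m:
        if tiebreak is not None:
            tb = np.asarray(tiebreak)[ok]
            order = np.lexsort((tb, pv))
        else:
            order = np.argsort(pv, kind="stable")
        ranked = pv[order] * m / np.arange(1, m + 1)
        qs = np.minimum.accumulate(ranked[::-1])[::-1]
        qs = np.clip(qs, 0.0, 1.0)
        qq = np.empty(m)
        qq[order] = qs
        q[ok] = qq
    return q


def extract_signature(
    stats_: ModeratedStats,
    name: str,
    q_threshold: float = DEFAULT_FDR,
    dataset: str = "",
) -> Signature:
    """FDR-thresholded signature with fold-change directions."""
    t = stats_.table
    sel = t[t["q"] < q_threshold]
    direction = {
        pid: (1 if fc > 0 else -1)
        for pid, fc in zip(sel["probe_id"], sel["log2fc"])
        if fc != 0
    }
    provenance = (
        f"dataset={dataset or 'unknown'}; method=moderated-t empirical Bayes; "
        f"contrast={stats_.contrast[0]}-{stats_.contrast[1]}; q<{q_threshold}"
    )
    return Signature(name, frozenset(sel["probe_id"]), direction or None, provenance)


def run_de(
    matrix: ExpressionMatrix,
    group_labels,
    name: str,
    q_threshold: float = DEFAULT_FDR,
    robust: bool = True,
) -> tuple[ModeratedStats, Signature]:
    """Convenience: fit, estimate prior, moderate, and threshold in one call."""
    fits = fit_gene_linear_models(matrix, group_labels)
    prior = estimate_prior(fits, robust=robust)
    stats_ = moderate(fits, prior)
    sig = extract_signature(stats_, name, q_threshold, dataset=name)
    return stats_, sig


def write_de_table(stats_: ModeratedStats, path) -> None:
    cols = ["probe_id", "log2fc", "t", "p", "q", "s2_post"]
    stats_.table[cols].to_csv(path, sep="\t", index=False)
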