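"""Moderated-statistics correctness: hand oracles, limits, recovery, robustness."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import thermosig as ts
from thermosig.diffexpr import bh_fdr

from conftest import brute_force_bh


def _simulated_fits(n_probes, d, d0, s0_2, coefs=None, seed=0) -> ts.GeneFit:
    rng = np.random.default_rng(seed)
    sigma2 = s0_2 * d0 / rng.chisquare(d0, n_probes)
    s2 = sigma2 * rng.chisquare(d, n_probes) / d
    table = pd.DataFrame(
        {
            "probe_id": [f"p{i:05d}" for i in range(n_probes)],
            "coef": coefs if coefs is not None else np.zeros(n_probes),
            "stdev_unscaled": np.full(n_probes, np.sqrt(2.0 / 6.0)),
            "s2": s2,
            "df_resid": np.full(n_probes, d),
            "n_eff": np.full(n_probes, d + 2),
        }
    )
    return ts.GeneFit(table=table, contrast=("warm", "cool"), excluded=[])


def test_two_group_fit_hand_values(two_group_matrix):
    """A={1,2,3}, B={3,4,5}: coef 2, pooled s2 = 1, d = 4, t(d0=0) = 2.449."""
    m, labels = two_group_matrix
    fit = ts.fit_gene_linear_models(m, labels)
    row = fit.table.iloc[0]
    assert row["coef"] == pytest.approx(2.0)
    assert row["s2"] == pytest.approx(1.0)
    assert row["df_resid"] == 4
    stats = ts.moderate(fit, ts.EBayesPrior(d0=0.0, s0_2=1.0))
    assert stats.table["t"].iloc[0] == pytest.approx(2.0 / np.sqrt(2.0 / 3.0), abs=1e-3)


def test_fit_constant_probe_and_exchangeability():
    m = ts.ExpressionMatrix(["p1"], list("abcdef"), np.full((1, 6), 2.5))
    fit = ts.fit_gene_linear_models(m, ["cool"] * 3 + ["warm"] * 3)
    assert fit.table["coef"].iloc[0] == 0.0
    assert fit.table["s2"].iloc[0] == 0.0

    rng = np.random.default_rng(1)
    vals = rng.standard_normal((5, 8))
    labels = ["cool"] * 4 + ["warm"] * 4
    m1 = ts.ExpressionMatrix([f"p{i}" for i in range(5)], [f"s{j}" for j in range(8)], vals)
    perm = [2, 0, 1, 3, 5, 4, 7, 6]  # within-group shuffles only
    m2 = ts.ExpressionMatrix(
        m1.probe_ids, [m1.sample_ids[j] for j in perm], vals[:, perm]
    )
    f1 = ts.fit_gene_linear_models(m1, labels)
    f2 = ts.fit_gene_linear_models(m2, labels)
    pd.testing.assert_frame_equal(f1.table, f2.table)


def test_missing_values_listwise_deletion():
    vals = np.array([[1.0, 2.0, np.nan, 3.0, 4.0, 5.0], [1, 2, 3, 3, 4, 5]])
    m = ts.ExpressionMatrix(["p1", "p2"], list("abcdef"), vals)
    fit = ts.fit_gene_linear_models(m, ["cool"] * 3 + ["warm"] * 3)
    assert fit.table.loc[fit.table["probe_id"] == "p1", "n_eff"].iloc[0] == 5
    assert fit.table.loc[fit.table["probe_id"] == "p2", "df_resid"].iloc[0] == 4
    # a probe unusable in one contrast group is excluded with a warning
    vals2 = np.array([[np.nan, np.nan, 1.0, 3.0, 4.0, 5.0]])
    m2 = ts.ExpressionMatrix(["p1"], list("abcdef"), vals2)
    with pytest.warns(UserWarning, match="excluded"):
        fit2 = ts.fit_gene_linear_models(m2, ["cool"] * 3 + ["warm"] * 3)
    assert fit2.excluded == ["p1"]


def test_prior_recovery_within_20_percent():
    fits = _simulated_fits(5000, d=10, d0=4.0, s0_2=0.05, seed=2)
    prior = ts.estimate_prior(fits)
    assert abs(prior.d0 - 4.0) / 4.0 < 0.2
    assert abs(prior.s0_2 - 0.05) / 0.05 < 0.2


def test_prior_degenerate_equal_variances():
    table = pd.DataFrame(
        {
            "probe_id": ["a", "b", "c"],
            "coef": [0.0] * 3,
            "stdev_unscaled": [1.0] * 3,
            "s2": [0.5] * 3,
            "df_resid": [4] * 3,
            "n_eff": [6] * 3,
        }
    )
    prior = ts.estimate_prior(ts.GeneFit(table, ("warm", "cool"), []))
    assert np.isinf(prior.d0)
    assert prior.s0_2 == pytest.approx(0.5, rel=0.3)


def test_robust_prior_resists_contamination():
    """1% variance spikes: robust d0 moves <25%, plain estimate moves more."""
    clean = _simulated_fits(5000, d=10, d0=4.0, s0_2=0.05, seed=7)
    spiked = ts.GeneFit(clean.table.copy(), clean.contrast, [])
    idx = np.arange(0, 5000, 100)
    spiked.table.loc[idx, "s2"] *= 100.0
    d0_clean = ts.estimate_prior(clean, robust=True).d0
    d0_rob = ts.estimate_prior(spiked, robust=True).d0
    d0_plain = ts.estimate_prior(spiked, robust=False).d0
    assert abs(d0_rob - d0_clean) / d0_clean < 0.25
    assert abs(d0_plain - d0_clean) > abs(d0_rob - d0_clean)


def test_moderate_limits(two_group_matrix):
    m, labels = two_group_matrix
    fit = ts.fit_gene_linear_models(m, labels)
    inf_stats = ts.moderate(fit, ts.EBayesPrior(d0=np.inf, s0_2=1.0))
    assert (inf_stats.table["s2_post"] == 1.0).all()
    zero = ts.ExpressionMatrix(["p1"], list("abcdef"), np.array([[1, 2, 3, 1, 2, 3]], float))
    zfit = ts.fit_gene_linear_models(zero, labels)
    zstats = ts.moderate(zfit, ts.EBayesPrior(d0=0.0, s0_2=1.0))
    assert zstats.table["t"].iloc[0] == 0.0
    assert zstats.table["p"].iloc[0] == 1.0


def test_moderated_t_matches_limma_oracle(tmp_path):
    """Independent cross-check of (d0, s0^2, t, p) against Bioconductor limma."""
    import subprocess

    rng = np.random.default_rng(4)
    n, per = 300, 4
    vals = rng.standard_normal((n, 2 * per)) * rng.uniform(0.2, 1.5, n)[:, None]
    vals[:20, per:] += 1.5
    m = ts.ExpressionMatrix(
        [f"p{i:03d}" for i in range(n)], [f"s{j}" for j in range(2 * per)], vals
    )
    labels = ["cool"] * per + ["warm"] * per
    fit = ts.fit_gene_linear_models(m, labels)
    prior = ts.estimate_prior(fit, robust=False)
    stats = ts.moderate(fit, prior)

    mat_path = tmp_path / "m.tsv"
    out_path = tmp_path / "limma.tsv"
    ts.write_expression_matrix(m, mat_path)
    script = f"""
    suppressMessages(library(limma))
    x <- as.matrix(read.delim("{mat_path}", row.names=1))
    design <- cbind(1, c(rep(0,{per}), rep(1,{per})))
    fit <- eBayes(lmFit(x, design), robust=FALSE)
    out <- data.frame(probe_id=rownames(x), t=fit$t[,2], p=fit$p.value[,2],
                      d0=fit$df.prior, s02=fit$s2.prior)
    write.table(out, "{out_path}", sep="\\t", row.names=FALSE, quote=FALSE)
    """
    subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
    ref = pd.read_csv(out_path, sep="\t")
    assert prior.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-4)
    assert prior.s0_2 == pytest.approx(ref["s02"].iloc[0], rel=1e-4)
    np.testing.assert_allclose(stats.table["t"], ref["t"], rtol=1e-6)
    np.testing.assert_allclose(stats.table["p"], ref["p"], rtol=1e-6)


def test_bh_hand_example_and_oracle_equivalence():
    np.testing.assert_allclose(
        bh_fdr(np.array([0.01, 0.02, 0.03, 0.04])), [0.04, 0.04, 0.04, 0.04]
    )
    np.testing.assert_allclose(bh_fdr(np.array([1.0])), [1.0])
    rng = np.random.default_rng(12)
    from statsmodels.stats.multitest import multipletests

    for _ in range(1000):
        p = rng.random(rng.integers(1, 40))
        q = bh_fdr(p)
        np.testing.assert_allclose(q, brute_force_bh(p), atol=1e-12)
        np.testing.assert_allclose(q, multipletests(p, method="fdr_bh")[1], atol=1e-12)


def test_bh_nan_propagation():
    with pytest.warns(UserWarning, match="NaN"):
        q = bh_fdr(np.array([0.5, np.nan]))
    assert np.isnan(q[1]) and q[0] == 0.5


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
def test_bh_monotone_and_bounded(pvals):
    p = np.asarray(pvals)
    q = bh_fdr(p)
    assert ((q >= p - 1e-12) & (q <= 1.0)).all()
    order = np.argsort(p, kind="stable")
    assert (np.diff(q[order]) >= -1e-12).all()


def test_monotonicity_of_t_in_coefficient(two_group_matrix):
    m, labels = two_group_matrix
    fit = ts.fit_gene_linear_models(m, labels)
    prior = ts.EBayesPrior(d0=4.0, s0_2=1.0)
    base = abs(ts.moderate(fit, prior).table["t"].iloc[0])
    bigger = ts.GeneFit(fit.table.assign(coef=fit.table["coef"] * 2), fit.contrast, [])
    assert abs(ts.moderate(bigger, prior).table["t"].iloc[0]) > base


def test_extract_signature_thresholds(small_study):
    year = small_study.params.years[0]
    mat = small_study.matrices[year]
    labels, _ = ts.join_design(mat, small_study.metadata, ["temperature_group"])
    stats, sig = ts.run_de(mat, labels, name="y1")
    assert all(sig.direction[p] in (1, -1) for p in sig.direction)
    everything = ts.extract_signature(stats, "all", q_threshold=1.0)
    assert len(everything) == len(stats.table)
    none = ts.extract_signature(
        ts.ModeratedStats(stats.table.assign(q=1.0), stats.prior, stats.contrast), "none"
    )
    assert len(none) == 0


def test_planted_signature_recovery():
    """Planted-truth recovery at q<0.01: sensitivity >= 0.9, FDP <= 0.05 (5 seeds)."""
    sens, fdp = [], []
    for seed in range(5):
        study = ts.simulate_multiyear_study(
            ts.SimulationParams(n_probes=1500, n_up=150, n_down=150, rng_seed=seed,
                               years=("2007",), species=("sockeye",),
                               dataset_multipliers=(1.0,))
        )
        mat = study.matrices["2007"]
        labels, _ = ts.join_design(mat, study.metadata, ["temperature_group"])
        _, sig = ts.run_de(mat, labels, name="y")
        planted = set(study.planted_signature().probe_ids)
        hits = planted & sig.probe_ids
        sens.append(len(hits) / len(planted))
        fdp.append(len(sig.probe_ids - planted) / max(len(sig), 1))
    assert np.mean(sens) >= 0.9
    assert np.mean(fdp) <= 0.05


def test_robust_signature_more_stable_under_outliers():
    """Outlier samples move the robust signature less (Jaccard to clean)."""
    base = ts.SimulationParams(n_probes=1200, n_up=80, n_down=80, samples_per_group=8,
                               years=("2007",), species=("sockeye",),
                               dataset_multipliers=(1.0,), outlier_fraction=0.0, rng_seed=21)
    study = ts.simulate_multiyear_study(base)
    mat = study.matrices["2007"]
    labels, _ = ts.join_design(mat, study.metadata, ["temperature_group"])
    vals = mat.values.copy()
    rng = np.random.default_rng(22)
    vals[:, 0] += rng.standard_normal(vals.shape[0]) * 2.0  # one wrecked sample
    dirty = ts.ExpressionMatrix(mat.probe_ids, mat.sample_ids, vals)

    def jaccard(a, b):
        return len(a & b) / max(len(a | b), 1)

    _, clean_r = ts.run_de(mat, labels, name="c", robust=True)
    _, dirty_r = ts.run_de(dirty, labels, name="d", robust=True)
    _, clean_p = ts.run_de(mat, labels, name="cp", robust=False)
    _, dirty_p = ts.run_de(dirty, labels, name="dp", robust=False)
    d_rob = 1 - jaccard(clean_r.probe_ids, dirty_r.probe_ids)
    d_plain = 1 - jaccard(clean_p.probe_ids, dirty_p.probe_ids)
    assert d_rob <= d_plain
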