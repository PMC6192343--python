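"""Synthetic multi-year expression studies and qPCR data with planted truth.

The expression generator emulates a multi-year salmonid thermal-holding
design: each "year" dataset has two temperature groups (cool, warm), a
species label, and a planted set of concordantly up-/down-regulated
probes. Per-probe residual variances are drawn from a scaled inverse
chi-square law s0^2 * d0 / chisq(d0) — exactly the prior the
empirical-Bayes differential-expression stage assumes — so hyperparameter
recovery is testable. A fraction of samples are "outliers" whose noise sd
is inflated, exercising the robust estimation path. Responsive probes
share their sign across all datasets, so the planted set is fold-change
concordant by construction.

The qPCR generators emulate serial-dilution standard curves
(Ct = c0 - log10(conc)/log10(1+E)) and Ct tables with planted per-gene
fold changes between temperature groups, unresponsive reference genes,
and optional survivor/moribund strata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, SampleMetadata, Signature, ThermosigError
from .qpcr import CtTable, DilutionSeries

DEFAULT_YEARS = ("2007", "2008", "2009")
DEFAULT_SPECIES = ("sockeye", "sockeye", "pink")


@dataclass
class SimulationParams:
    """Study-design and noise parameters for the expression generator.

    Defaults mirror the kind of design the pipeline targets: three annual
    datasets over two species, ~10 samples per temperature group, strong
    planted effects (|log2FC| uniform on [1, 3] with per-year magnitude
    multipliers), and gene-wise variances from the scaled inverse
    chi-square law with d0=4 prior df and scale s0^2=0.05.
    """

    n_probes: int = 3000
    years: tuple[str, ...] = DEFAULT_YEARS
    species: tuple[str, ...] = DEFAULT_SPECIES
    samples_per_group: int = 10
    n_up: int = 150
    n_down: int = 150
    fc_lo: float = 1.0
    fc_hi: float = 3.0
    dataset_multipliers: tuple[float, ...] = (1.0, 0.75, 1.25)
    d0: float = 4.0
    s0_2: float = 0.05
    outlier_fraction: float = 0.05
    outlier_multiplier: float = 3.0
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_up + self.n_down > self.n_probes:
            raise ThermosigError("n_up + n_down exceeds n_probes")
        if min(self.n_up, self.n_down, self.n_probes) < 0:
            raise ThermosigError("counts must be >= 0")
        if self.fc_lo > self.fc_hi:
            raise ThermosigError("fc_lo must be <= fc_hi")
        if not (self.d0 > 0 and self.s0_2 > 0):
            raise ThermosigError("d0 and s0_2 must be positive")
        if len(self.species) != len(self.years):
            raise ThermosigError("species must be given per year dataset")
        if len(self.dataset_multipliers) != len(self.years):
            raise ThermosigError("one magnitude multiplier per dataset required")
        if self.samples_per_group < 2:
            raise ThermosigError("need >= 2 samples per group (variance undefined below)")


@dataclass
class SimulatedStudy:
    matrices: dict[str, ExpressionMatrix]  # keyed by year
    metadata: SampleMetadata
    truth: pd.DataFrame  # per probe: responsive, sign, fc_<year>, var_<year>
    params: SimulationParams

    def planted_signature(self, name: str = "planted") -> Signature:
        """The planted responsive set as a directed signature.

        Doubles as a synthetic stand-in for an externally published
        signature when exercising the candidate-ranking stage.
        """
        resp = self.truth[self.truth["responsive"]]
        return Signature(
            name,
            frozenset(resp["probe_id"]),
            dict(zip(resp["probe_id"], resp["sign"].astype(int))),
            "synthetic planted truth",
        )


def simulate_multiyear_study(params: SimulationParams) -> SimulatedStudy:
    """Generate one expression matrix per year with planted ground truth.

    For a responsive probe g in dataset y the warm-group mean exceeds the
    cool-group mean by sign_g * |FC_g| * multiplier_y on the log2 scale;
    residual noise is Gaussian with the gene's drawn variance, inflated by
    the outlier multiplier for outlier samples. Deterministic under
    rng_seed.
    """
    rng = np.random.default_rng(params.rng_seed)
    p = params.n_probes
    probe_ids = [f"P{i:05d}" for i in range(p)]
    sign = np.zeros(p, dtype=int)
    sign[: params.n_up] = 1
    sign[params.n_up : params.n_up + params.n_down] = -1
    responsive = sign != 0
    abs_fc = np.zeros(p)
    abs_fc[responsive] = rng.uniform(params.fc_lo, params.fc_hi, responsive.sum())
    baseline = rng.normal(params.baseline_mean, params.baseline_sd, p)

    matrices: dict[str, ExpressionMatrix] = {}
    meta_rows = []
    truth = pd.DataFrame({"probe_id": probe_ids, "responsive": responsive, "sign": sign,
                          "abs_log2fc": abs_fc})
    n_g = params.samples_per_group
    for year, spec, mult in zip(params.years, params.species, params.dataset_multipliers):
        # gene-wise variances: scaled inverse chi-square, s0^2 * d0 / chisq_d0
        var = params.s0_2 * params.d0 / rng.chisquare(params.d0, p)
        fc = sign * abs_fc * mult
        sample_ids = [f"{year}_cool_{i:02d}" for i in range(n_g)] + [
            f"{year}_warm_{i:02d}" for i in range(n_g)
        ]
        groups = np.array(["cool"] * n_g + ["warm"] * n_g)
        means = np.where(
            (groups == "warm")[None, :], baseline[:, None] + fc[:, None], baseline[:, None]
        )
        sd = np.sqrt(var)[:, None] * np.ones((1, 2 * n_g))
        outlier = rng.random(2 * n_g) < params.outlier_fraction
        sd[:, outlier] *= params.outlier_multiplier
        values = means + rng.standard_normal((p, 2 * n_g)) * sd
        matrices[year] = ExpressionMatrix(probe_ids, sample_ids, values)
        for sid, g, out in zip(sample_ids, groups, outlier):
            meta_rows.append((sid, spec, year, g, "survivor", bool(out)))
        truth[f"fc_{year}"] = fc
        truth[f"var_{year}"] = var
    meta = SampleMetadata(
        pd.DataFrame(
            meta_rows,
            columns=["sample_id", "species", "year", "temperature_group",
                     "survival_status", "outlier"],
        )
    )
    return SimulatedStudy(matrices=matrices, metadata=meta, truth=truth, params=params)


@dataclass
class QpcrSimParams:
    """Parameters for the dilution-series and Ct-table generators."""

    genes: tuple[str, ...] = tuple(f"G{i:02d}" for i in range(12))
    reference_genes: tuple[str, ...] = ("REF1", "REF2", "REF3")
    efficiencies: dict[str, float] = field(default_factory=dict)  # per assay; default 1.0
    dilution_factors: tuple[float, ...] = (1 / 5, 1 / 25, 1 / 125, 1 / 625, 1 / 3125)
    ct_noise_sd: float = 0.15
    fold_changes: dict[str, float] = field(default_factory=dict)  # per gene, warm vs cool
    replicates_per_group: int = 8
    groups: tuple[str, ...] = ("cool", "warm")
    control_group: str = "cool"
    baseline_ct_lo: float = 18.0
    baseline_ct_hi: float = 26.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for a, e in self.efficiencies.items():
            if not (0 < e <= 2):
                raise ThermosigError(f"efficiency for {a} must be in (0, 2], got {e}")
        if self.ct_noise_sd < 0:
            raise ThermosigError("Ct noise sd must be >= 0")
        if len(self.dilution_factors) < 3:
            raise ThermosigError("need >= 3 dilution points")
        if any(np.diff(self.dilution_factors) >= 0):
            raise ThermosigError("dilution factors must be strictly decreasing")
        if self.replicates_per_group < 1:
            raise ThermosigError("zero replicates in a group")

    def efficiency_of(self, assay: str) -> float:
        return self.efficiencies.get(assay, 1.0)


def simulate_dilution_series(
    params: QpcrSimParams, assay: str, species: str = "sockeye", c0: float = 18.0
) -> DilutionSeries:
    """Standard curve: Ct = c0 - log10(conc) / log10(1 + E_true) + noise."""
    e_true = params.efficiency_of(assay)
    if e_true <= 0:
        raise ThermosigError("E_true must be positive")
    rng = np.random.default_rng(params.rng_seed)
    conc = np.asarray(params.dilution_factors, dtype=float)
    ct = c0 - np.log10(conc) / np.log10(1.0 + e_true)
    if params.ct_noise_sd > 0:
        ct = ct + rng.normal(0.0, params.ct_noise_sd, ct.size)
    return DilutionSeries(assay=assay, species=species, concentrations=conc, ct=ct)


def simulate_qpcr_expression(
    params: QpcrSimParams,
    cohort: str = "sockeye",
    strata: tuple[str, ...] = ("survivor",),
) -> tuple[CtTable, pd.DataFrame]:
    """Ct table with planted warm-vs-cool fold changes.

    Target-gene Ct in a non-control group is shifted by -log2(FC)
    (assuming doubling per cycle); reference genes are unshifted. Returns
    the table plus the planted truth (gene, fold_change). Strata replicate
    the design per survival status.
    """
    rng = np.random.default_rng(params.rng_seed)
    all_genes = list(params.genes) + list(params.reference_genes)
    base_ct = {g: rng.uniform(params.baseline_ct_lo, params.baseline_ct_hi) for g in all_genes}
    rows, meta_rows = [], []
    for stratum in strata:
        for grp in params.groups:
            for r in range(params.replicates_per_group):
                sid = f"{cohort}_{stratum}_{grp}_{r:02d}"
                rec = {}
                for g in all_genes:
                    ct = base_ct[g]
                    fc = params.fold_changes.get(g, 1.0)
                    if g in params.genes and grp != params.control_group:
                        ct = ct - np.log2(fc)
                    if params.ct_noise_sd > 0:
                        ct += rng.normal(0.0, params.ct_noise_sd)
                    rec[g] = ct
                rows.append(pd.Series(rec, name=sid))
                meta_rows.append((sid, cohort, grp, stratum))
    ct_df = pd.DataFrame(rows)
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "species", "temperature_group", "survival_status"]
    )
    truth = pd.DataFrame(
        {"gene": list(params.genes),
         "fold_change": [params.fold_changes.get(g, 1.0) for g in params.genes]}
    )
    table = CtTable(ct=ct_df, reference_genes=list(params.reference_genes), meta=meta)
    return table, truth


def write_study(study: SimulatedStudy, outdir) -> None:
    """Write matrices, metadata and truth in the TSV formats the readers accept."""
    from pathlib import Path

    from .core import write_expression_matrix, write_metadata

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for year, mat in study.matrices.items():
        write_expression_matrix(mat, out / f"expression_{year}.tsv")
    write_metadata(study.metadata, out / "metadata.tsv")
    study.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
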