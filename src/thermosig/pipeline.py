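"""Config-driven orchestration of the discovery and validation stages.

``discover`` and ``validate_cohorts`` are the in-memory entry points the
tests exercise; ``run_discovery`` / ``run_validation`` wrap them with
file I/O, a YAML/JSON config, logging and a reproducibility manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .core import (
    ExpressionMatrix,
    SampleMetadata,
    Signature,
    ThermosigError,
    join_design,
    read_expression_matrix,
    read_metadata,
    read_signature,
    write_signature,
)
from .diffexpr import DEFAULT_FDR, ModeratedStats, run_de, write_de_table
from .qpcr import (
    CtTable,
    DilutionSeries,
    delta_delta_ct,
    efficiency_report,
    estimate_efficiency,
    group_stats,
    validate_panel,
)
from .signatures import (
    ConcordanceReport,
    build_membership,
    intersect_concordant,
    rank_candidates,
    union_signatures,
    venn_counts,
)
from .unsupervised import (
    ShavingParams,
    components_to_signature,
    gene_shave,
    select_separating_components,
    sparse_pca,
)

log = logging.getLogger("thermosig")


@dataclass
class PipelineConfig:
    """Validated pipeline settings with the study's thresholds as defaults."""

    datasets: list[dict] = field(default_factory=list)  # {name, matrix, platform}
    metadata: str | None = None
    published_signature: str | None = None
    fdr: float = DEFAULT_FDR
    p_cutoff: float = 0.01
    efficiency_pass_band: tuple[float, float] = (0.8, 1.1)
    shave_alpha: float = 0.10
    shave_permutations: int = 20
    spca_k: int = 100
    spca_n_components: int = 5
    spca_components: tuple[int, ...] | str = "auto"  # "auto": pick by separation
    unsupervised_method: dict[str, str] = field(default_factory=dict)  # per dataset name
    discovery_groups: tuple[str, ...] = ("cool", "warm")
    seed: int | None = None
    outdir: str = "thermosig_out"

    def __post_init__(self) -> None:
        if not (0 < self.fdr < 1) or not (0 < self.p_cutoff < 1):
            raise ThermosigError("thresholds must lie in (0, 1)")
        lo, hi = self.efficiency_pass_band
        if not (0 < lo < hi):
            raise ThermosigError("invalid efficiency pass band")
        names = [d.get("name") for d in self.datasets]
        if len(set(names)) != len(names):
            raise ThermosigError("duplicate dataset names in config")
        stochastic = bool(self.datasets)
        if stochastic and self.seed is None:
            raise ThermosigError("seed is mandatory when stochastic stages are enabled")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ThermosigError(f"config {path} is not a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ThermosigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("efficiency_pass_band", "spca_components", "discovery_groups"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class DiscoveryResult:
    stats: dict[str, ModeratedStats]
    de_signatures: dict[str, Signature]
    intersection: Signature | None
    concordance: ConcordanceReport | None
    union: Signature | None
    unsupervised: dict[str, Signature]
    venn: dict[str, int] | None
    candidates: pd.DataFrame | None


def discover(
    matrices: dict[str, ExpressionMatrix],
    metadata: SampleMetadata,
    published: Signature | None = None,
    config: PipelineConfig | None = None,
    sequence_available: dict[str, bool] | None = None,
) -> DiscoveryResult:
    """Run per-dataset moderated DE, combine signatures, rank candidates.

    The discovery contrast uses the cool and warm temperature groups only
    (moderate-temperature samples are excluded). Unsupervised exploration
    runs per dataset on the union-signature probe subset; the default
    method is gene shaving (config selects sparse PCA per dataset).
    """
    cfg = config or PipelineConfig(seed=0)
    stats: dict[str, ModeratedStats] = {}
    sigs: dict[str, Signature] = {}
    for name, mat in matrices.items():
        meta_rows = metadata.for_samples(mat.sample_ids)
        keep = meta_rows["temperature_group"].isin(cfg.discovery_groups)
        sub = mat.subset_samples(list(meta_rows.loc[keep, "sample_id"]))
        labels, counts = join_design(sub, metadata, ["temperature_group"])
        log.info("dataset %s: groups %s", name, counts)
        st, sig = run_de(sub, labels, name=f"DS_{name}", q_threshold=cfg.fdr, robust=True)
        stats[name] = st
        sigs[name] = sig
        log.info("dataset %s: %d significant probes at q<%g", name, len(sig), cfg.fdr)

    intersection = concordance = union = None
    if len(sigs) >= 2:
        nonempty = [s for s in sigs.values() if len(s) > 0]
        if len(nonempty) == len(sigs):
            intersection, concordance = intersect_concordant(list(sigs.values()), name="CSi")
            log.info(
                "intersection: %d probes, %.1f%% concordant",
                len(intersection), concordance.percent_concordant,
            )
        union = union_signatures(list(sigs.values()), name="CSu")
    else:
        log.info("single dataset: intersection/union stages skipped")

    unsup: dict[str, Signature] = {}
    if union is not None and len(union) >= 3:
        for i, (name, mat) in enumerate(matrices.items()):
            meta_rows = metadata.for_samples(mat.sample_ids)
            keep = meta_rows["temperature_group"].isin(cfg.discovery_groups)
            sub = mat.subset_samples(list(meta_rows.loc[keep, "sample_id"]))
            sub = sub.subset_probes(sorted(union.probe_ids))
            method = cfg.unsupervised_method.get(name, "spca")
            if method == "spca":
                res = sparse_pca(sub, n_components=cfg.spca_n_components, k=cfg.spca_k)
                if cfg.spca_components == "auto":
                    labels, _ = join_design(sub, metadata, ["temperature_group"])
                    dims = select_separating_components(res, labels)
                else:
                    dims = list(cfg.spca_components)
                unsup[name] = components_to_signature(res, dims, name=f"EX_{name}_spca")
            else:
                params = ShavingParams(
                    alpha=cfg.shave_alpha,
                    n_permutations=cfg.shave_permutations,
                    rng_seed=None if cfg.seed is None else cfg.seed + i,
                )
                res = gene_shave(sub, params)
                unsup[name] = components_to_signature(res, [1], name=f"EX_{name}_shave")
            log.info("dataset %s: unsupervised (%s) signature of %d probes",
                     name, method, len(unsup[name]))

    venn = venn_counts(list(sigs.values())) if len(sigs) == 3 else None

    candidates = None
    if intersection is not None and published is not None and unsup:
        probe_universe = sorted(union.probe_ids | published.probe_ids)
        membership = build_membership(
            probe_universe,
            intersection=intersection,
            published=published,
            unsupervised=list(unsup.values()),
            sequence_available=sequence_available,
        )
        candidates = rank_candidates(membership)
        n1 = int((candidates["tier"] == 1).sum())
        log.info("candidates: %d probes at tier 1", n1)
    return DiscoveryResult(stats, sigs, intersection, concordance, union, unsup, venn, candidates)


def run_discovery(config: PipelineConfig, outdir: str | Path | None = None) -> DiscoveryResult:
    """File-based wrapper: read declared inputs, run discovery, write outputs."""
    if len(config.datasets) < 1:
        raise ThermosigError("no datasets declared")
    out = Path(outdir or config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    if config.metadata is None:
        raise ThermosigError("metadata path required")
    metadata = read_metadata(config.metadata)
    matrices = {
        d["name"]: read_expression_matrix(d["matrix"], d.get("dialect", "tsv"))
        for d in config.datasets
    }
    published = (
        read_signature(config.published_signature) if config.published_signature else None
    )
    try:
        result = discover(matrices, metadata, published=published, config=config)
    except Exception as exc:  # annotate failing stage, keep partial outputs
        raise ThermosigError(f"discovery failed: {exc}") from exc
    for name, st in result.stats.items():
        write_de_table(st, out / f"de_{name}.tsv")
        write_signature(result.de_signatures[name], out / f"signature_{name}.tsv")
    if result.intersection is not None:
        write_signature(result.intersection, out / "signature_intersection.tsv")
        result.concordance.table.to_csv(out / "concordance.tsv", sep="\t", index=False)
    if result.union is not None:
        write_signature(result.union, out / "signature_union.tsv")
    for name, sig in result.unsupervised.items():
        write_signature(sig, out / f"signature_unsupervised_{name}.tsv")
    if result.venn is not None:
        pd.Series(result.venn, name="count").rename_axis("region").to_csv(
            out / "venn_counts.tsv", sep="\t"
        )
    if result.candidates is not None:
        result.candidates.to_csv(out / "candidates.tsv", sep="\t", index=False)
    _write_manifest(out, config, stage="discovery")
    return result


@dataclass
class ValidationResult:
    efficiency: pd.DataFrame
    rel_expr: dict[str, dict[str, pd.DataFrame]]  # cohort -> stratum -> group_stats
    panel: pd.DataFrame | None


def validate_cohorts(
    ct_tables: dict[str, CtTable],
    dilution_series: list[DilutionSeries] | None = None,
    control_group: str = "cool",
    strata: tuple[str, ...] = ("survivor", "moribund"),
    config: PipelineConfig | None = None,
) -> ValidationResult:
    """Efficiency screening plus per-cohort, per-stratum group statistics."""
    cfg = config or PipelineConfig()
    eff = efficiency_report([estimate_efficiency(s) for s in (dilution_series or [])])
    comparisons: dict[str, dict[str, pd.DataFrame]] = {}
    for cohort, table in ct_tables.items():
        rel = delta_delta_ct(table, control_group=control_group)
        comparisons[cohort] = {}
        present = set(table.meta["survival_status"]) if "survival_status" in table.meta else set()
        for stratum in strata:
            if stratum not in present:
                log.warning("cohort %s: stratum %s missing", cohort, stratum)
                continue
            sel = table.meta.loc[table.meta["survival_status"] == stratum, "sample_id"]
            sub = RelSubset(rel, list(sel))
            comparisons[cohort][stratum] = group_stats(sub)
    panel = None
    if len(comparisons) >= 2:
        usable_strata = tuple(
            st for st in strata if all(st in c for c in comparisons.values())
        )
        if usable_strata:
            panel = validate_panel(comparisons, required_strata=usable_strata,
                                   alpha=cfg.p_cutoff)
    return ValidationResult(efficiency=eff, rel_expr=comparisons, panel=panel)


def RelSubset(rel, sample_ids):
    """Restrict a RelExprTable to a sample subset (stratum)."""
    from dataclasses import replace

    keep = [s for s in rel.log2_rel.index if s in set(sample_ids)]
    meta = rel.meta[rel.meta["sample_id"].isin(keep)].reset_index(drop=True)
    return replace(
        rel,
        dct=rel.dct.loc[keep],
        ddct=rel.ddct.loc[keep],
        rel_expr=rel.rel_expr.loc[keep],
        log2_rel=rel.log2_rel.loc[keep],
        meta=meta,
    )


def _write_manifest(outdir: Path, config: PipelineConfig, stage: str) -> None:
    manifest = {
        "package": "thermosig",
        "version": __version__,
        "stage": stage,
        "seed": config.seed,
        "thresholds": {
            "fdr": config.fdr,
            "p_cutoff": config.p_cutoff,
            "efficiency_pass_band": list(config.efficiency_pass_band),
        },
        "shave": {"alpha": config.shave_alpha, "B": config.shave_permutations},
        "spca": {
            "k": config.spca_k,
            "n_components": config.spca_n_components,
            "components": (
                config.spca_components
                if isinstance(config.spca_components, str)
                else list(config.spca_components)
            ),
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
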