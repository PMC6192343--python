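"""Signature algebra: intersection with concordance, union, overlaps,
Venn regions, and sequential candidate ranking.

The consensus logic: per-dataset FDR signatures are intersected, and a
probe is fold-change concordant when its direction is identical and
nonzero in every signature. Candidate biomarkers are then ranked by
sequential criteria — (1) intersection membership plus presence in the
designated published signature plus membership in at least two of three
unsupervised exploratory signatures; (2) platform support; (3)
cross-study robustness; (4) sequence availability gates final selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .core import MappingTable, Signature, ThermosigError


@dataclass
class ConcordanceReport:
    table: pd.DataFrame  # probe_id, dir_<name>..., concordant
    n_concordant_up: int
    n_concordant_down: int
    percent_concordant: float


@dataclass
class OverlapMatrix:
    names: list[str]
    counts: pd.DataFrame  # square, counts of shared probes (target space if mapped)
    unmapped: pd.DataFrame | None = None  # per cell, unmapped source probes


def intersect_concordant(
    signatures: list[Signature],
    name: str = "intersection",
    drop_discordant: bool = False,
) -> tuple[Signature, ConcordanceReport]:
    """Set intersection with per-probe fold-change concordance.

    Discordant probes are retained in the intersection but flagged
    (``drop_discordant=True`` removes them instead). The summary percent
    is computed over the intersection.
    """
    if len(signatures) < 2:
        raise ThermosigError("need at least 2 signatures to intersect")
    for s in signatures:
        if s.direction is None:
            raise ThermosigError(f"signature {s.name!r} lacks directions; concordance undefined")
    common = frozenset.intersection(*[s.probe_ids for s in signatures])
    rows = []
    direction: dict[str, int] = {}
    for p in sorted(common):
        dirs = [s.direction.get(p, 0) for s in signatures]
        concordant = all(d == dirs[0] and d != 0 for d in dirs)
        rows.append((p, *dirs, concordant))
        if concordant:
            direction[p] = dirs[0]
    table = pd.DataFrame(
        rows, columns=["probe_id", *[f"dir_{s.name}" for s in signatures], "concordant"]
    )
    n_up = int(sum(1 for d in direction.values() if d > 0))
    n_down = int(sum(1 for d in direction.values() if d < 0))
    pct = 100.0 * len(direction) / len(common) if common else 0.0
    report = ConcordanceReport(table, n_up, n_down, pct)
    probes = frozenset(direction) if drop_discordant else common
    prov = (
        f"intersection of {[s.name for s in signatures]}; "
        f"{pct:.1f}% concordant ({n_up} up, {n_down} down)"
    )
    sig = Signature(name, probes, {p: d for p, d in direction.items() if p in probes} or None, prov)
    return sig, report


def union_signatures(signatures: list[Signature], name: str = "union") -> Signature:
    """Set union; direction kept only where unanimous among holders."""
    if not signatures:
        raise ThermosigError("need at least 1 signature")
    probes = frozenset.union(*[s.probe_ids for s in signatures])
    direction: dict[str, int] = {}
    for p in probes:
        dirs = {
            s.direction[p]
            for s in signatures
            if p in s.probe_ids and s.direction is not None and p in s.direction
        }
        if len(dirs) == 1:
            direction[p] = dirs.pop()
    prov = f"union of {[s.name for s in signatures]}"
    return Signature(name, probes, direction or None, prov)


def overlap_matrix(
    signatures: list[Signature],
    mapping: MappingTable | None = None,
    platforms: dict[str, str] | None = None,
) -> OverlapMatrix:
    """Pairwise overlap counts, optionally across platforms via mapping.

    Cell (i, j) counts |map(S_i) ∩ S_j| in S_j's (target) ID space;
    source probes with no mapping are counted separately.
    """
    names = [s.name for s in signatures]
    n = len(signatures)
    counts = np.zeros((n, n), dtype=int)
    unmapped = np.zeros((n, n), dtype=int)
    for i, si in enumerate(signatures):
        for j, sj in enumerate(signatures):
            if i == j:
                counts[i, j] = len(si)
                continue
            if mapping is not None:
                if platforms is None or si.name not in platforms or sj.name not in platforms:
                    raise ThermosigError("platform labels required when mapping is supplied")
                pi, pj = platforms[si.name], platforms[sj.name]
                if pi == pj:
                    counts[i, j] = len(si.probe_ids & sj.probe_ids)
                else:
                    mapped, unm = mapping.map_probes(si.probe_ids, pi, pj)
                    counts[i, j] = len(mapped & set(sj.probe_ids))
                    unmapped[i, j] = len(unm)
            else:
                counts[i, j] = len(si.probe_ids & sj.probe_ids)
    cdf = pd.DataFrame(counts, index=names, columns=names)
    udf = pd.DataFrame(unmapped, index=names, columns=names) if mapping is not None else None
    return OverlapMatrix(names=names, counts=cdf, unmapped=udf)


def venn_counts(signatures: list[Signature]) -> dict[str, int]:
    """Counts of the 7 regions of a 3-set Venn diagram.

    Keys name the member sets, e.g. ``"A"`` (A only), ``"A&B"``,
    ``"A&B&C"`` using the signature names. Regions partition the union.
    """
    if len(signatures) != 3:
        raise ThermosigError("venn_counts needs exactly 3 signatures")
    sets = {s.name: set(s.probe_ids) for s in signatures}
    names = [s.name for s in signatures]
    out: dict[str, int] = {}
    for r in (1, 2, 3):
        for combo in combinations(names, r):
            inside = set.intersection(*[sets[n] for n in combo])
            outside = set.union(*[sets[n] for n in names if n not in combo], set())
            out["&".join(combo)] = len(inside - outside)
    return out


def rank_candidates(membership: pd.DataFrame) -> pd.DataFrame:
    """Sequential candidate ranking.

    ``membership`` needs boolean columns ``in_intersection``,
    ``in_published``, ``platform_support``, ``robustness_support``,
    ``sequence_available`` and an integer ``n_unsupervised`` (how many of
    the three per-year unsupervised signatures contain the probe), indexed
    or keyed by ``probe_id``. Tier 1 = intersection AND published AND
    >= 2 of 3 unsupervised; tier 2 = platform support; tier 3 =
    cross-study robustness; tier 4 otherwise. Selection additionally
    requires sequence availability. Stable ordering by (tier, probe_id).
    """
    required = [
        "probe_id",
        "in_intersection",
        "in_published",
        "n_unsupervised",
        "platform_support",
        "robustness_support",
        "sequence_available",
    ]
    missing = [c for c in required if c not in membership.columns]
    if missing:
        raise ThermosigError(f"membership table missing columns: {missing}")
    t = membership.copy()
    tier1 = t["in_intersection"] & t["in_published"] & (t["n_unsupervised"] >= 2)
    tier = np.where(tier1, 1, np.where(t["platform_support"], 2, np.where(t["robustness_support"], 3, 4)))
    t["tier"] = tier
    t["selected"] = (t["tier"] <= 3) & t["sequence_available"]
    return t.sort_values(["tier", "probe_id"], kind="stable").reset_index(drop=True)


def build_membership(
    probe_ids,
    intersection: Signature,
    published: Signature,
    unsupervised: list[Signature],
    platform_support: dict[str, bool] | None = None,
    robustness_support: dict[str, bool] | None = None,
    sequence_available: dict[str, bool] | None = None,
) -> pd.DataFrame:
    """Assemble the membership table rank_candidates consumes.

    Availability/support flags default to False/False/True when no table
    is supplied (sequence availability is an external input; absent
    knowledge passes the gate so it can be applied later).
    """
    rows = []
    for p in probe_ids:
        rows.append(
            (
                p,
                p in intersection,
                p in published,
                sum(p in u for u in unsupervised),
                bool(platform_support.get(p, False)) if platform_support else False,
                bool(robustness_support.get(p, False)) if robustness_support else False,
                bool(sequence_available.get(p, True)) if sequence_available else True,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "probe_id",
            "in_intersection",
            "in_published",
            "n_unsupervised",
            "platform_support",
            "robustness_support",
            "sequence_available",
        ],
    )
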