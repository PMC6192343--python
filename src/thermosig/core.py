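"""Domain types and tabular I/O shared by every pipeline stage.

The pipeline works on log2-scale expression matrices (probes x samples),
sample metadata tables, probe-ID signatures with optional fold-change
directions, cross-platform probe mapping tables, and probe annotations.
All on-disk formats are TSV with a header row; expression matrices may
additionally arrive in the GEO series-matrix dialect (``!``-prefixed
metadata lines around a delimited data block).

Missing values are written and read as the explicit sentinel ``NA``;
operations that cannot tolerate missing data refuse rather than dropping
rows silently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = "NA"

#: The pipeline assumes matrices are already normalised on log2 scale;
#: no background correction or normalisation is performed here.
ASSUMED_SCALE = "log2"

TEMPERATURE_GROUPS = ("cool", "moderate", "warm")
SURVIVAL_STATUSES = ("survivor", "moribund")


class ThermosigError(ValueError):
    """Raised on contract violations (malformed input, broken invariants)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Log2 intensities, probes x samples.

    ``values`` is a float array with NaN as the in-memory missing sentinel.
    Probe and sample identifiers are unique, order-significant, and compared
    case-sensitively after whitespace trimming.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    header: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.probe_ids = [str(p).strip() for p in self.probe_ids]
        self.sample_ids = [str(s).strip() for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.probe_ids, "probe")
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ThermosigError(
                f"value array shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        finite = np.isfinite(self.values) | np.isnan(self.values)
        if not finite.all():
            bad = np.argwhere(~finite)[0]
            raise ThermosigError(
                f"non-finite value at probe {self.probe_ids[bad[0]]}, "
                f"sample {self.sample_ids[bad[1]]}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)

    def subset_probes(self, probe_ids) -> "ExpressionMatrix":
        idx = {p: i for i, p in enumerate(self.probe_ids)}
        keep = [p for p in probe_ids if p in idx]
        rows = [idx[p] for p in keep]
        return ExpressionMatrix(keep, list(self.sample_ids), self.values[rows, :])

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise ThermosigError(f"samples not in matrix: {missing}")
        cols = [idx[s] for s in sample_ids]
        return ExpressionMatrix(list(self.probe_ids), list(sample_ids), self.values[:, cols])


@dataclass
class SampleMetadata:
    """One row per sample: species, year, temperature group, survival status."""

    table: pd.DataFrame

    REQUIRED = ("sample_id", "species", "year", "temperature_group")

    def __post_init__(self) -> None:
        t = self.table.copy()
        for col in self.REQUIRED:
            if col not in t.columns:
                raise ThermosigError(f"metadata missing required column {col!r}")
        t["sample_id"] = t["sample_id"].astype(str).str.strip()
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ThermosigError(f"duplicate sample_id in metadata: {dup!r}")
        if (t["temperature_group"].astype(str).str.len() == 0).any():
            raise ThermosigError("empty temperature_group in metadata")
        self.table = t.reset_index(drop=True)

    def for_samples(self, sample_ids) -> pd.DataFrame:
        t = self.table.set_index("sample_id")
        missing = [s for s in sample_ids if s not in t.index]
        if missing:
            raise ThermosigError(f"samples without metadata rows: {missing}")
        return t.loc[list(sample_ids)].reset_index()


@dataclass
class Signature:
    """A named set of probe IDs with optional per-probe direction (+1/-1)."""

    name: str
    probe_ids: frozenset[str]
    direction: dict[str, int] | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        self.probe_ids = frozenset(str(p).strip() for p in self.probe_ids)
        if self.direction is not None:
            self.direction = {str(k).strip(): int(v) for k, v in self.direction.items()}
            bad = [v for v in self.direction.values() if v not in (1, -1)]
            if bad:
                raise ThermosigError(f"direction values must be +1/-1, got {bad[0]}")
            extra = set(self.direction) - set(self.probe_ids)
            if extra:
                raise ThermosigError(f"direction keys not in probe set: {sorted(extra)[:3]}")

    def __len__(self) -> int:
        return len(self.probe_ids)

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self.probe_ids


@dataclass
class MappingTable:
    """Many-to-many probe mapping between two array platforms."""

    pairs: pd.DataFrame  # columns: source_probe_id, target_probe_id, source_platform, target_platform

    COLUMNS = ("source_probe_id", "target_probe_id", "source_platform", "target_platform")

    def __post_init__(self) -> None:
        t = self.pairs.copy()
        for col in self.COLUMNS:
            if col not in t.columns:
                raise ThermosigError(f"mapping table missing column {col!r}")
        for col in ("source_probe_id", "target_probe_id"):
            t[col] = t[col].astype(str).str.strip()
        self_map = (t["source_platform"] == t["target_platform"]) & (
            t["source_probe_id"] == t["target_probe_id"]
        )
        if self_map.any():
            raise ThermosigError("self-mapping within one platform is not allowed")
        self.pairs = t.drop_duplicates().reset_index(drop=True)

    def map_probes(self, probe_ids, source_platform: str, target_platform: str):
        """Map a probe set into the target platform's ID space.

        Returns ``(mapped_targets, unmapped_sources)``; the relation may be
        many-to-many, so one source probe can contribute several targets.
        """
        sel = self.pairs[
            (self.pairs["source_platform"] == source_platform)
            & (self.pairs["target_platform"] == target_platform)
        ]
        by_source: dict[str, set[str]] = {}
        for s, t in zip(sel["source_probe_id"], sel["target_probe_id"]):
            by_source.setdefault(s, set()).add(t)
        mapped: set[str] = set()
        unmapped: set[str] = set()
        for p in probe_ids:
            p = str(p).strip()
            if p in by_source:
                mapped |= by_source[p]
            else:
                unmapped.add(p)
        return mapped, unmapped


@dataclass
class ProbeAnnotation:
    """Probe -> gene annotation; gene fields may be missing (unannotated)."""

    table: pd.DataFrame  # columns: probe_id, gene_id, gene_symbol, chromosome

    def __post_init__(self) -> None:
        t = self.table.copy()
        if "probe_id" not in t.columns:
            raise ThermosigError("annotation missing column 'probe_id'")
        t["probe_id"] = t["probe_id"].astype(str).str.strip()
        if t["probe_id"].duplicated().any():
            dup = t.loc[t["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise ThermosigError(f"duplicate probe_id in annotation: {dup!r}")
        self.table = t.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _check_unique(ids, kind: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ThermosigError(f"duplicate {kind} ID: {i!r}")
        seen.add(i)


def _parse_cell(token: str, row_label: str, col_label: str) -> float:
    token = token.strip().strip('"')
    if token == MISSING or token == "":
        return np.nan
    try:
        return float(token)
    except ValueError:
        raise ThermosigError(
            f"non-numeric cell {token!r} at probe {row_label!r}, sample {col_label!r}"
        ) from None


def read_expression_matrix(path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read a probes-x-samples log2 matrix from TSV or GEO series-matrix dialect.

    In the series-matrix dialect, lines starting with ``!`` are captured as a
    free-text header and the data block sits between the
    ``!series_matrix_table_begin`` / ``!series_matrix_table_end`` markers.
    """
    if dialect not in ("tsv", "geo_series_matrix"):
        raise ThermosigError(f"unknown dialect {dialect!r}")
    with open(path) as fh:
        lines = fh.read().splitlines()

    header_meta: list[str] = []
    if dialect == "geo_series_matrix":
        data_lines: list[str] = []
        in_table = False
        for ln in lines:
            if ln.startswith("!series_matrix_table_begin"):
                in_table = True
            elif ln.startswith("!series_matrix_table_end"):
                in_table = False
            elif ln.startswith("!"):
                header_meta.append(ln)
            elif in_table and ln.strip():
                data_lines.append(ln)
        lines = data_lines
    else:
        lines = [ln for ln in lines if ln.strip()]

    if not lines:
        raise ThermosigError(f"no data rows found in {path}")
    header = [h.strip().strip('"') for h in lines[0].split("\t")]
    sample_ids = header[1:]
    n_cols = len(header)
    probe_ids: list[str] = []
    rows: list[list[float]] = []
    for i, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) != n_cols:
            raise ThermosigError(
                f"row {i} has {len(parts)} columns, expected {n_cols} (probe "
                f"{parts[0].strip()!r})"
            )
        pid = parts[0].strip().strip('"')
        probe_ids.append(pid)
        rows.append([_parse_cell(c, pid, s) for c, s in zip(parts[1:], sample_ids)])
    values = np.array(rows, dtype=float) if rows else np.empty((0, len(sample_ids)))
    return ExpressionMatrix(probe_ids, sample_ids, values, header=header_meta)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    df = matrix.to_frame()
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t", na_rep=MISSING)


def read_metadata(path) -> SampleMetadata:
    return SampleMetadata(pd.read_csv(path, sep="\t", dtype=str))


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.table.to_csv(path, sep="\t", index=False, na_rep=MISSING)


def read_mapping_table(path) -> MappingTable:
    return MappingTable(pd.read_csv(path, sep="\t", dtype=str))


def write_mapping_table(mapping: MappingTable, path) -> None:
    mapping.pairs.to_csv(path, sep="\t", index=False)


def read_annotation(path) -> ProbeAnnotation:
    return ProbeAnnotation(pd.read_csv(path, sep="\t", dtype=str))


def write_annotation(ann: ProbeAnnotation, path) -> None:
    ann.table.to_csv(path, sep="\t", index=False, na_rep=MISSING)


def join_design(matrix: ExpressionMatrix, meta: SampleMetadata, grouping):
    """Per-sample group labels, aligned to matrix column order.

    ``grouping`` is a list of metadata factor names; multi-factor groupings
    produce composite ``a:b`` labels. Returns ``(labels, counts)``.
    """
    rows = meta.for_samples(matrix.sample_ids)
    for g in grouping:
        if g not in rows.columns:
            raise ThermosigError(f"grouping factor {g!r} not in metadata")
    labels = rows[list(grouping)].astype(str).agg(":".join, axis=1).tolist()
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    return labels, counts


# --- signature files: one-line header "name<TAB>provenance", then one probe
#     per line with an optional +1/-1 direction column -----------------------


def write_signature(sig: Signature, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#signature\t{sig.name}\t{sig.provenance}\n")
        for p in sorted(sig.probe_ids):
            if sig.direction is not None and p in sig.direction:
                fh.write(f"{p}\t{sig.direction[p]:+d}\n")
            else:
                fh.write(f"{p}\n")


def read_signature(path) -> Signature:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines or not lines[0].startswith("#signature"):
        raise ThermosigError(f"{path}: missing '#signature' header line")
    head = lines[0].split("\t")
    name = head[1] if len(head) > 1 else ""
    provenance = head[2] if len(head) > 2 else ""
    probes: set[str] = set()
    direction: dict[str, int] = {}
    for ln in lines[1:]:
        parts = ln.split("\t")
        pid = parts[0].strip()
        if pid in probes:
            warnings.warn(f"duplicate probe {pid!r} in {path}; deduplicated", stacklevel=2)
        probes.add(pid)
        if len(parts) > 1 and parts[1].strip():
            d = int(parts[1])
            if d not in (1, -1):
                raise ThermosigError(f"{path}: direction {d} for {pid!r} not in {{+1,-1}}")
            direction[pid] = d
    return Signature(name, frozenset(probes), direction or None, provenance)
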