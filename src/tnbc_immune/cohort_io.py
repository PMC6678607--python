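"""Readers, writers and validated containers for every table the pipeline touches.

Expression comes in as a genes x samples matrix (plain TSV or GCT 1.2), gene
sets as GMT, blood counts and clinical follow-up as CSV.  All loaders validate
eagerly and report what they silently repaired (duplicate gene symbols, dropped
rows) so a run is auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "CBCRecord",
    "ClinicalRecord",
    "LoadReport",
    "read_expression_matrix",
    "read_gene_sets_gmt",
    "read_cbc_table",
    "read_clinical_table",
    "write_results_bundle",
]


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


class ValidationError(ValueError):
    """Structurally parsable input that violates a domain invariant."""


@dataclasses.dataclass
class LoadReport:
    """What a loader changed or dropped while reading a file."""

    source: str
    collapsed_genes: dict[str, int] = dataclasses.field(default_factory=dict)
    dropped_rows: list[str] = dataclasses.field(default_factory=list)
    messages: list[str] = dataclasses.field(default_factory=list)


@dataclasses.dataclass
class ExpressionMatrix:
    """Genes x samples matrix of normalized expression.

    ``values`` is indexed by gene symbol (rows) and sample id (columns).
    ``scale_tag`` records whether entries are log2 intensities (the native
    scale of RMA/quantile-normalized array data) or linear; consumers that
    need a specific scale convert explicitly via :meth:`to_log2` /
    :meth:`to_linear` instead of guessing from value ranges.
    """

    values: pd.DataFrame
    scale_tag: Literal["log2", "linear"] = "log2"

    def __post_init__(self) -> None:
        v = self.values
        if v.isna().any().any():
            raise ValidationError("expression matrix contains missing values")
        if v.shape[0] < 2 or v.shape[1] < 2:
            raise ValidationError(
                f"expression matrix needs >= 2 genes and >= 2 samples, got {v.shape}"
            )
        for axis, name in ((v.index, "gene"), (v.columns, "sample")):
            labels = list(axis)
            if any(not str(x) for x in labels):
                raise ValidationError(f"empty {name} label")
            if len(set(labels)) != len(labels):
                dupes = sorted({x for x in labels if labels.count(x) > 1})
                raise ValidationError(f"duplicate {name} ids: {dupes[:5]}")
        if self.scale_tag not in ("log2", "linear"):
            raise ValidationError(f"unknown scale_tag {self.scale_tag!r}")
        self.values = v.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_log2(self) -> "ExpressionMatrix":
        if self.scale_tag == "log2":
            return self
        return ExpressionMatrix(np.log2(self.values), scale_tag="log2")

    def to_linear(self) -> "ExpressionMatrix":
        if self.scale_tag == "linear":
            return self
        return ExpressionMatrix(2.0 ** self.values, scale_tag="linear")

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        present = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[present], scale_tag=self.scale_tag)


@dataclasses.dataclass
class GeneSetCollection:
    """Named gene sets with one-line descriptions, as read from GMT."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets


@dataclasses.dataclass
class CBCRecord:
    """Pre-surgical complete blood count, absolute counts in 10^9 cells/L."""

    sample_id: str
    neutrophils: float
    lymphocytes: float
    platelets: float
    monocytes: float | None = None

    def __post_init__(self) -> None:
        for field in ("neutrophils", "lymphocytes", "platelets"):
            v = getattr(self, field)
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(
                    f"sample {self.sample_id}: {field} must be > 0, got {v}"
                )
        if self.monocytes is not None and self.monocytes <= 0:
            raise ValidationError(
                f"sample {self.sample_id}: monocytes must be > 0 when present"
            )


@dataclasses.dataclass
class ClinicalRecord:
    """Age, stromal TILs density and disease-free-survival follow-up."""

    sample_id: str
    age_years: float
    tils_percent: float
    time_to_event_days: float
    event_flag: int

    def __post_init__(self) -> None:
        if self.age_years <= 0:
            raise ValidationError(f"sample {self.sample_id}: nonpositive age")
        if not 0 <= self.tils_percent <= 100:
            raise ValidationError(
                f"sample {self.sample_id}: TILs% {self.tils_percent} outside [0, 100]"
            )
        if self.time_to_event_days < 0:
            raise ValidationError(f"sample {self.sample_id}: negative follow-up time")
        if self.event_flag not in (0, 1):
            raise ValidationError(
                f"sample {self.sample_id}: event flag must be 0/1, got {self.event_flag}"
            )


def _collapse_duplicate_genes(
    df: pd.DataFrame, report: LoadReport
) -> pd.DataFrame:
    """Collapse duplicated gene symbols by per-gene maximum, logging each."""
    if df.index.is_unique:
        return df
    counts = df.index.value_counts()
    for gene, n in counts[counts > 1].items():
        report.collapsed_genes[str(gene)] = int(n)
    return df.groupby(level=0, sort=False).max()


def read_expression_matrix(
    path: str | Path,
    format: Literal["tsv", "gct"] | None = None,
    scale_tag: Literal["log2", "linear"] = "log2",
) -> tuple[ExpressionMatrix, LoadReport]:
    """Read a genes x samples expression table from TSV or GCT 1.2.

    ``format=None`` infers from the suffix (``.gct`` vs anything else).
    Duplicate gene symbols are collapsed by per-gene maximum and listed in the
    returned :class:`LoadReport`; duplicate sample ids are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"
    report = LoadReport(source=str(path))

    def _check_sample_header(names: list[str], lineno: int) -> None:
        # checked on the raw header because pandas mangles duplicate names
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(
                f"{path}:{lineno}: duplicate sample ids: {dupes[:5]}"
            )

    if format == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise ParseError(
                    f"{path}:1: expected GCT version line '#1.2', got {version!r}"
                )
            dims = fh.readline().split()
            if len(dims) < 2 or not all(d.isdigit() for d in dims[:2]):
                raise ParseError(f"{path}:2: malformed GCT dimensions line")
            n_genes, n_samples = int(dims[0]), int(dims[1])
            header = fh.readline().rstrip("\n").split("\t")
            if len(header) < 3 or header[1] != "Description":
                raise ParseError(
                    f"{path}:3: GCT header must start 'Name\\tDescription'"
                )
            _check_sample_header(header[2:], 3)
            df = pd.read_csv(fh, sep="\t", header=None, index_col=0,
                             float_precision="round_trip")
            df.columns = header[1:]
        df = df.drop(columns="Description")
        if df.shape != (n_genes, n_samples):
            raise ParseError(
                f"{path}: dimensions line says {(n_genes, n_samples)}, "
                f"table is {df.shape}"
            )
    elif format == "tsv":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if len(header) < 2:
                raise ParseError(f"{path}:1: no sample columns found in TSV header")
            _check_sample_header(header[1:], 1)
            df = pd.read_csv(fh, sep="\t", header=None, index_col=0,
                             float_precision="round_trip")
            df.columns = header[1:]
    else:
        raise ValueError(f"unknown expression format {format!r}")

    df.index = df.index.map(str)
    df.index.name = None
    df.columns.name = None
    df = _collapse_duplicate_genes(df, report)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric expression value ({exc})") from None
    return ExpressionMatrix(df, scale_tag=scale_tag), report


def read_gene_sets_gmt(path: str | Path, min_genes: int = 2) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>genes...``.

    Duplicate genes within a set are removed (first occurrence kept); sets
    with fewer than ``min_genes`` distinct symbols are rejected with a warning.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name, desc, *genes = fields
            genes = list(dict.fromkeys(g for g in genes if g.strip()))
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            if len(genes) < min_genes:
                warnings.warn(
                    f"{path}:{lineno}: set {name!r} has < {min_genes} genes; skipped",
                    stacklevel=2,
                )
                continue
            sets[name] = genes
            descriptions[name] = desc
    if not sets:
        warnings.warn(f"{path}: no usable gene sets found", stacklevel=2)
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def _read_records_csv(
    path: str | Path,
    required: list[str],
    builder,
    optional: list[str] = (),
) -> tuple[list, LoadReport]:
    path = Path(path)
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: mandatory column 'sample_id' missing")
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ParseError(f"{path}: missing columns {missing_cols}")
    report = LoadReport(source=str(path))
    records = []
    for _, row in df.iterrows():
        sid = str(row["sample_id"])
        if row[required].isna().any():
            report.dropped_rows.append(sid)
            continue
        kwargs = {c: row[c] for c in required}
        for c in optional:
            if c in df.columns and pd.notna(row[c]):
                kwargs[c] = row[c]
        records.append(builder(sample_id=sid, **kwargs))
    seen: set[str] = set()
    for rec in records:
        if rec.sample_id in seen:
            raise ValidationError(f"{path}: duplicate sample_id {rec.sample_id!r}")
        seen.add(rec.sample_id)
    if report.dropped_rows:
        report.messages.append(
            f"dropped {len(report.dropped_rows)} rows with missing mandatory fields"
        )
    return records, report


def read_cbc_table(path: str | Path) -> tuple[list[CBCRecord], LoadReport]:
    """Read complete-blood-count records; monocytes are optional."""
    return _read_records_csv(
        path,
        required=["neutrophils", "lymphocytes", "platelets"],
        optional=["monocytes"],
        builder=CBCRecord,
    )


def read_clinical_table(path: str | Path) -> tuple[list[ClinicalRecord], LoadReport]:
    """Read clinical records (age, TILs %, DFS time and event flag)."""
    def build(sample_id, age_years, tils_percent, time_to_event_days, event_flag):
        return ClinicalRecord(
            sample_id=sample_id,
            age_years=float(age_years),
            tils_percent=float(tils_percent),
            time_to_event_days=float(time_to_event_days),
            event_flag=int(event_flag),
        )

    return _read_records_csv(
        path,
        required=["age_years", "tils_percent", "time_to_event_days", "event_flag"],
        builder=build,
    )


def cbc_to_frame(records: list[CBCRecord]) -> pd.DataFrame:
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    return df.set_index("sample_id")


def clinical_to_frame(records: list[ClinicalRecord]) -> pd.DataFrame:
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    return df.set_index("sample_id")


def write_results_bundle(
    out_dir: str | Path,
    panel: pd.DataFrame,
    clusters: pd.DataFrame,
    associations: pd.DataFrame | None = None,
    manifest_extra: dict | None = None,
    seed: int | None = None,
) -> dict:
    """Write the scores table, cluster labels and association tables plus a
    JSON manifest (config hash + seed); returns the file manifest.

    Sample ids must agree between the score panel and the cluster labels, so
    a bundle is always internally joinable.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    missing = set(panel.index) - set(clusters.index)
    if missing:
        raise ValidationError(
            f"cluster labels missing for samples: {sorted(missing)[:5]}"
        )
    files: dict[str, str] = {}

    def _write(name: str, df: pd.DataFrame) -> None:
        p = out_dir / name
        df.to_csv(p, float_format="%.10g")
        files[name] = hashlib.sha256(p.read_bytes()).hexdigest()

    _write("signature_scores.csv", panel)
    _write("cluster_labels.csv", clusters)
    if associations is not None:
        _write("associations.csv", associations)
    manifest = {
        "seed": seed,
        "files": files,
        "config_hash": hashlib.sha256(
            json.dumps(manifest_extra or {}, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "extra": manifest_extra or {},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    files["manifest.json"] = "-"
    return {"out_dir": str(out_dir), "files": files}
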