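"""Readers and writers for every external table the pipeline touches.

All matrix-like inputs are tab-separated text with a header row, decimal
point only.  Missing values are encoded as the literal ``NA`` and surfaced
in memory as ``NaN``; downstream statistics exclude them pairwise.
Floats are written with ``%.17g`` so that every write/read round trip is
exact.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: chromosome labels allowed in annotation tables (no coordinates anywhere)
CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y", "MT")

SCALE_INTENSITY = "intensity"
SCALE_LOG2RATIO = "log2ratio"
_SCALES = (SCALE_INTENSITY, SCALE_LOG2RATIO)

CLS_CONTROL = "control"
CLS_TUMOR = "tumor"

_FLOAT_FMT = "%.17g"
_NA = "NA"


class ValidationError(ValueError):
    """A table violated a documented invariant."""


class ParseError(ValueError):
    """A file could not be parsed as the documented format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionStudy:
    """One platform's genes x samples matrix plus identifiers.

    ``values`` holds non-negative intensities or real log2 ratios
    (``scale`` says which); ``NaN`` marks masked entries.
    """

    platform_id: str
    probe_ids: list[str]
    values: np.ndarray
    sample_ids: list[str]
    scale: str

    def __post_init__(self) -> None:
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.scale not in _SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            dup = _first_duplicate(self.probe_ids)
            raise ValidationError(f"duplicate probe id {dup!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = _first_duplicate(self.sample_ids)
            raise ValidationError(f"duplicate sample id {dup!r}")
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if self.scale == SCALE_INTENSITY and np.nanmin(self.values, initial=0.0) < 0:
            raise ValidationError("intensity-scale study contains negative values")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class SampleMeta:
    """Class and group assignment of one array/sample."""

    sample_id: str
    platform_id: str
    cls: str  # "control" | "tumor"
    group: str  # tumor group label; empty for controls

    def __post_init__(self) -> None:
        if self.cls not in (CLS_CONTROL, CLS_TUMOR):
            raise ValidationError(f"unknown sample class {self.cls!r}")
        if self.cls == CLS_CONTROL and self.group:
            raise ValidationError(
                f"control sample {self.sample_id!r} carries group {self.group!r}"
            )


@dataclass
class GeneAnnotation:
    """Probe -> NCBI Gene ID map (with symbol and chromosome) for one platform.

    Probes without a positive integer Gene ID are rejected at load time,
    because the common gene list is keyed by Gene ID.
    """

    platform_id: str
    table: pd.DataFrame  # columns: probe_id, gene_id, symbol, chromosome

    def __post_init__(self) -> None:
        required = ["probe_id", "gene_id", "symbol", "chromosome"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValidationError(f"annotation is missing columns {missing}")
        t = self.table.reset_index(drop=True).copy()
        t["probe_id"] = t["probe_id"].astype(str)
        try:
            t["gene_id"] = t["gene_id"].astype(int)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-integer gene_id in annotation: {exc}") from exc
        if t["probe_id"].duplicated().any():
            dup = t.loc[t["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise ValidationError(f"duplicate probe id {dup!r} in annotation")
        if (t["gene_id"] <= 0).any():
            bad = t.loc[t["gene_id"] <= 0, "probe_id"].iloc[0]
            raise ValidationError(f"probe {bad!r} has non-positive gene id")
        bad_chrom = set(t["chromosome"].astype(str)) - set(CHROMOSOMES)
        if bad_chrom:
            raise ValidationError(f"unknown chromosome labels {sorted(bad_chrom)}")
        t["chromosome"] = t["chromosome"].astype(str)
        self.table = t

    @property
    def gene_ids(self) -> frozenset[int]:
        return frozenset(self.table["gene_id"].tolist())

    def probe_to_gene(self) -> pd.Series:
        return self.table.set_index("probe_id")["gene_id"]

    def gene_to_chromosome(self) -> pd.Series:
        return (
            self.table.drop_duplicates("gene_id").set_index("gene_id")["chromosome"]
        )


@dataclass(frozen=True)
class TermSet:
    """One annotation term (GO category, pathway, or TF binding motif)."""

    term_id: str
    term_name: str
    gene_ids: frozenset[int]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValidationError(f"term {self.term_id!r} has no genes")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _first_duplicate(items) -> str:
    seen: set = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""


def _read_header(path) -> list[str]:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n")
    return first.split("\t")


def _parse_numeric_frame(path) -> pd.DataFrame:
    """Read a TSV matrix (first column = row ids) with strict numeric cells."""
    header = _read_header(path)
    sample_ids = header[1:]
    dup = _first_duplicate(sample_ids)
    if dup:
        raise ValidationError(f"duplicate sample id {dup!r} in header of {path}")
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=[_NA], keep_default_na=False,
        dtype=str,
    )
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"duplicate probe id {dup!r} in {path}")
    out = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            # element-wise strtod (correctly rounded), unlike pandas' fast parser
            out[:, j] = df[col].astype(float)
        except (TypeError, ValueError):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ParseError(
                f"non-numeric cell at row {row!r}, column {col!r} in {path}"
            ) from None
    return pd.DataFrame(out, index=df.index, columns=[str(c) for c in df.columns])


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression_tsv(path, scale: str, platform_id: str = "") -> ExpressionStudy:
    """Read a genes x samples matrix (probe ids in the first column)."""
    frame = _parse_numeric_frame(path)
    return ExpressionStudy(
        platform_id=platform_id or str(path),
        probe_ids=list(frame.index),
        values=frame.to_numpy(),
        sample_ids=list(frame.columns),
        scale=scale,
    )


def write_expression_tsv(study: ExpressionStudy, path) -> None:
    study.to_frame().to_csv(
        path, sep="\t", na_rep=_NA, float_format=_FLOAT_FMT, index_label="probe_id"
    )


def write_matrix_tsv(frame: pd.DataFrame, path, index_label: str = "id") -> None:
    """Write any numeric matrix in the canonical TSV dialect."""
    frame.to_csv(path, sep="\t", na_rep=_NA, float_format=_FLOAT_FMT,
                 index_label=index_label)


def read_matrix_tsv(path) -> pd.DataFrame:
    return _parse_numeric_frame(path)


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

def read_sample_meta(path, require_groups: bool = True) -> list[SampleMeta]:
    """Read sample metadata (columns sample_id, platform_id, class, group)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["sample_id", "platform_id", "class", "group"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"sample metadata {path} is missing columns {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"duplicate sample id {dup!r} in {path}")
    rows: list[SampleMeta] = []
    for _, r in df.iterrows():
        if r["class"] == CLS_TUMOR and require_groups and not r["group"]:
            raise ValidationError(
                f"tumor sample {r['sample_id']!r} has an empty group"
            )
        rows.append(
            SampleMeta(
                sample_id=r["sample_id"],
                platform_id=r["platform_id"],
                cls=r["class"],
                group=r["group"],
            )
        )
    return rows


def write_sample_meta(meta: list[SampleMeta], path) -> None:
    pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in meta],
            "platform_id": [m.platform_id for m in meta],
            "class": [m.cls for m in meta],
            "group": [m.group for m in meta],
        }
    ).to_csv(path, sep="\t", index=False)


def meta_to_frame(meta: list[SampleMeta]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in meta],
            "platform_id": [m.platform_id for m in meta],
            "class": [m.cls for m in meta],
            "group": [m.group for m in meta],
        }
    ).set_index("sample_id")


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def read_annotation_tsv(path, platform_id: str = "") -> GeneAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "gene_id" in df.columns:
        df["gene_id"] = pd.to_numeric(df["gene_id"], errors="raise")
    return GeneAnnotation(platform_id=platform_id or str(path), table=df)


def write_annotation_tsv(annotation: GeneAnnotation, path) -> None:
    annotation.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT term sets
# ---------------------------------------------------------------------------

def read_gmt(path) -> list[TermSet]:
    """Read GMT (term, description, member genes; tab-separated)."""
    terms: list[TermSet] = []
    seen: set[str] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has <3 columns")
            term_id, term_name = cols[0], cols[1]
            if term_id in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate term {term_id!r}")
            seen.add(term_id)
            try:
                genes = frozenset(int(g) for g in cols[2:] if g)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer gene id") from exc
            terms.append(TermSet(term_id=term_id, term_name=term_name, gene_ids=genes))
    return terms


def write_gmt(terms: list[TermSet], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in terms:
            genes = "\t".join(str(g) for g in sorted(t.gene_ids))
            fh.write(f"{t.term_id}\t{t.term_name}\t{genes}\n")


# ---------------------------------------------------------------------------
# motif incidence tables (motif, incidence, member gene ids)
# ---------------------------------------------------------------------------

def read_motif_tsv(path) -> tuple[list[TermSet], pd.Series]:
    """Read a TF-binding-motif incidence table.

    Columns: ``motif`` (term id), ``incidence`` (the published per-motif gene
    count, kept so computed tallies can be checked against it), ``gene_ids``
    (comma-separated NCBI Gene IDs).  Returns the motif gene sets plus the
    recorded incidence column indexed by motif.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["motif", "incidence", "gene_ids"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"motif table {path} is missing columns {missing}")
    terms = [
        TermSet(
            term_id=r["motif"],
            term_name="TFBM",
            gene_ids=frozenset(int(g) for g in r["gene_ids"].split(",") if g),
        )
        for _, r in df.iterrows()
    ]
    recorded = pd.Series(
        pd.to_numeric(df["incidence"]).to_numpy(dtype=int),
        index=df["motif"].tolist(),
        name="incidence",
    )
    return terms, recorded


def write_motif_tsv(terms: list[TermSet], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("motif\tincidence\tgene_ids\n")
        for t in terms:
            genes = ",".join(str(g) for g in sorted(t.gene_ids))
            fh.write(f"{t.term_id}\t{len(t.gene_ids)}\t{genes}\n")


# ---------------------------------------------------------------------------
# ground truth (gene_id, label)
# ---------------------------------------------------------------------------

def write_gene_labels(labels: dict[int, str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tlabel\n")
        for gid in sorted(labels):
            fh.write(f"{gid}\t{labels[gid]}\n")


def read_gene_labels(path) -> dict[int, str]:
    # keep_default_na: the label "null" is data, not a missing value
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": int, "label": str},
                     keep_default_na=False)
    return dict(zip(df["gene_id"], df["label"]))
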