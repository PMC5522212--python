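"""Readers, writers and validation for the study's external formats.

The pipeline exchanges five plain-text formats:

* expression matrix — TSV, first column probe identifiers, remaining columns
  one sample each, numeric intensities;
* sample sheet — TSV with columns ``sample_id``, ``condition``,
  ``time_point``, ``replicate`` describing the 2-condition (radioresistant
  case vs parental control) x 3-time-point (0/2/48 h post-irradiation) x
  triplicate design;
* transcript annotation — either a flat TSV (0-based half-open coordinates)
  or a GTF subset restricted to ``transcript``/``exon``/``three_prime_utr``
  features (1-based inclusive, converted on read);
* FASTA for lncRNA transcript sequences and mRNA 3'UTR sequences (record
  ids are probe ids);
* GMT gene sets for over-representation analysis.

All genomic intervals are stored 0-based half-open (BED convention)
regardless of the input dialect, so downstream interval arithmetic (the
10 kb cis window in particular) is unambiguous.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

CONDITIONS = ("case", "control")
TIME_POINTS = ("T0", "T2", "T48")

#: Accepted spellings for the time-point field of a sample sheet. Tokens are
#: lower-cased and stripped of spaces before lookup, so "2 hrs" and "2h"
#: both map to T2.
TIME_POINT_ALIASES: dict[str, str] = {
    "t0": "T0", "0": "T0", "0h": "T0", "0hr": "T0", "0hrs": "T0", "0hour": "T0",
    "t2": "T2", "2": "T2", "2h": "T2", "2hr": "T2", "2hrs": "T2", "2hour": "T2",
    "t48": "T48", "48": "T48", "48h": "T48", "48hr": "T48", "48hrs": "T48",
    "48hour": "T48",
}

#: Accepted spellings for the condition field. The paper labels the
#: radioresistant subclone the case group and the parental line the control.
CONDITION_ALIASES: dict[str, str] = {
    "case": "case", "rs": "case", "resistant": "case", "radioresistant": "case",
    "control": "control", "parental": "control", "parent": "control",
}

_MISSING_TOKENS = {"", "na", "nan", "none", "null"}


class StudyFormatError(ValueError):
    """Raised when an input file violates its documented schema."""


class EmptyDesignCellError(StudyFormatError):
    """Raised when an analysis requests a (condition, time point) cell with no samples."""


# ---------------------------------------------------------------------------
# study design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Sample:
    sample_id: str
    condition: str
    time_point: str
    replicate: int


@dataclass
class StudyDesign:
    """Sample metadata; group membership is defined here, never by column order."""

    samples: list[Sample]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise StudyFormatError(f"duplicate sample_id(s): {', '.join(dupes)}")
        for s in self.samples:
            if s.condition not in CONDITIONS:
                raise StudyFormatError(f"unknown condition {s.condition!r} for {s.sample_id}")
            if s.time_point not in TIME_POINTS:
                raise StudyFormatError(f"unknown time_point {s.time_point!r} for {s.sample_id}")
            if s.replicate < 1:
                raise StudyFormatError(f"replicate must be a positive integer ({s.sample_id})")

    def sample_ids(self, condition: str | None = None, time_point: str | None = None) -> list[str]:
        return [
            s.sample_id
            for s in self.samples
            if (condition is None or s.condition == condition)
            and (time_point is None or s.time_point == time_point)
        ]

    def cell(self, condition: str, time_point: str) -> list[str]:
        """Sample ids of one design cell; empty cells are an error on request."""
        ids = self.sample_ids(condition, time_point)
        if not ids:
            raise EmptyDesignCellError(f"empty design cell ({condition}, {time_point})")
        return ids

    def require_replicates(self, time_point: str, minimum: int = 2) -> None:
        """Validate that both groups at ``time_point`` support statistics."""
        for condition in CONDITIONS:
            n = len(self.cell(condition, time_point))
            if n < minimum:
                raise StudyFormatError(
                    f"({condition}, {time_point}) has {n} replicate(s); "
                    f"statistical operations need >= {minimum}"
                )

    @property
    def time_points(self) -> list[str]:
        return [tp for tp in TIME_POINTS if any(s.time_point == tp for s in self.samples)]


def _canon_time_point(token: str) -> str:
    key = token.strip().lower().replace(" ", "")
    if key in TIME_POINT_ALIASES:
        return TIME_POINT_ALIASES[key]
    raise StudyFormatError(f"unknown time_point token {token!r}")


def _canon_condition(token: str) -> str:
    key = token.strip().lower()
    if key in CONDITION_ALIASES:
        return CONDITION_ALIASES[key]
    raise StudyFormatError(f"unknown condition token {token!r}")


def read_sample_sheet(path: str | Path) -> StudyDesign:
    """Read a TSV sample sheet into a validated :class:`StudyDesign`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "condition", "time_point", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise StudyFormatError(f"sample sheet missing column(s): {', '.join(sorted(missing))}")
    samples = []
    for row in df.itertuples(index=False):
        try:
            replicate = int(row.replicate)
        except ValueError:
            raise StudyFormatError(
                f"non-integer replicate {row.replicate!r} for sample {row.sample_id!r}"
            ) from None
        samples.append(
            Sample(
                sample_id=row.sample_id,
                condition=_canon_condition(row.condition),
                time_point=_canon_time_point(row.time_point),
                replicate=replicate,
            )
        )
    return StudyDesign(samples)


def write_sample_sheet(design: StudyDesign, path: str | Path) -> None:
    df = pd.DataFrame(
        [(s.sample_id, s.condition, s.time_point, s.replicate) for s in design.samples],
        columns=["sample_id", "condition", "time_point", "replicate"],
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------

@dataclass
class LoadReport:
    n_rows_read: int = 0
    n_dropped_missing: int = 0
    dropped_probe_ids: list[str] = field(default_factory=list)


@dataclass
class ExpressionMatrix:
    """Probes x samples intensity table with an explicit scale flag.

    ``scale`` is ``"linear"`` (raw or quantile-normalized intensities) or
    ``"log2"``. Fold changes are computed on linear normalized means,
    t-tests/correlations/clustering on log2 values, so the flag travels with
    the data.
    """

    values: pd.DataFrame  # index = probe_ids, columns = sample_ids
    scale: str
    normalized: bool = False
    load_report: LoadReport | None = None

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"scale must be 'linear' or 'log2', got {self.scale!r}")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise StudyFormatError(f"duplicate probe_id(s): {', '.join(map(str, dupes))}")
        if self.values.columns.has_duplicates:
            raise StudyFormatError("duplicate sample ids in expression matrix")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise StudyFormatError("expression matrix body must be numeric")
        if np.isnan(arr).any():
            raise StudyFormatError("expression matrix contains missing values")
        if self.scale == "linear" and (arr < 0).any():
            raise StudyFormatError("linear intensities must be >= 0")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples absent from matrix: {', '.join(missing)}")
        return ExpressionMatrix(self.values[list(sample_ids)], self.scale, self.normalized)


def read_expression_matrix(path: str | Path, scale: str) -> ExpressionMatrix:
    """Read an expression TSV.

    Rows with any missing cell are dropped (never imputed) and counted in the
    returned matrix's :class:`LoadReport`; a non-numeric non-missing cell is
    an error naming the offending row and column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise StudyFormatError(f"empty expression matrix: {path}")
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise StudyFormatError(f"duplicate probe_id(s): {', '.join(map(str, dupes))}")

    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    missing_mask = pd.DataFrame(False, index=df.index, columns=df.columns)
    for col in df.columns:
        raw = df[col].str.strip()
        is_missing = raw.str.lower().isin(_MISSING_TOKENS)
        coerced = pd.to_numeric(raw.mask(is_missing), errors="coerce")
        bad = coerced.isna() & ~is_missing
        if bad.any():
            probe = df.index[bad.to_numpy().nonzero()[0][0]]
            raise StudyFormatError(
                f"non-numeric cell at probe {probe!r}, sample {col!r}: {raw[bad].iloc[0]!r}"
            )
        numeric[col] = coerced
        missing_mask[col] = is_missing

    has_missing = missing_mask.any(axis=1)
    report = LoadReport(
        n_rows_read=len(df),
        n_dropped_missing=int(has_missing.sum()),
        dropped_probe_ids=list(df.index[has_missing]),
    )
    if report.n_dropped_missing:
        log.info(
            "dropped %d row(s) with missing intensities: %s",
            report.n_dropped_missing,
            ", ".join(report.dropped_probe_ids[:10]),
        )
    kept = numeric.loc[~has_missing]
    return ExpressionMatrix(kept, scale=scale, normalized=False, load_report=report)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# transcript annotation
# ---------------------------------------------------------------------------

Interval = tuple[int, int]  # 0-based half-open


@dataclass
class TranscriptRecord:
    probe_id: str
    rna_type: str  # "lncRNA" | "mRNA"
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str  # "+" | "-"
    start: int  # 0-based inclusive
    end: int    # exclusive
    exons: list[Interval] = field(default_factory=list)
    utr3: Interval | None = None
    class_label: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise StudyFormatError(
                f"strand required ('+' or '-') for {self.probe_id}, got {self.strand!r}"
            )
        if not self.start < self.end:
            raise StudyFormatError(f"start < end violated for {self.probe_id}")
        if not self.exons:
            log.warning("transcript %s has no exons; using span as single exon", self.probe_id)
            self.exons = [(self.start, self.end)]
        self.exons = sorted(self.exons)
        prev_end = None
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise StudyFormatError(f"exon ({s},{e}) outside span for {self.probe_id}")
            if prev_end is not None and s < prev_end:
                raise StudyFormatError(f"overlapping exons for {self.probe_id}")
            prev_end = e
        if self.utr3 is not None:
            us, ue = self.utr3
            if not (self.start <= us < ue <= self.end):
                raise StudyFormatError(f"3'UTR outside span for {self.probe_id}")

    @property
    def span(self) -> Interval:
        return (self.start, self.end)

    def introns(self) -> list[Interval]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i][1] < self.exons[i + 1][0]
        ]


@dataclass
class TranscriptAnnotation:
    records: dict[str, TranscriptRecord]

    def __getitem__(self, probe_id: str) -> TranscriptRecord:
        return self.records[probe_id]

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self.records

    def __len__(self) -> int:
        return len(self.records)

    def get(self, probe_id: str) -> TranscriptRecord | None:
        return self.records.get(probe_id)

    def probes_of_type(self, rna_type: str) -> list[str]:
        return [p for p, r in self.records.items() if r.rna_type == rna_type]


_FLAT_COLUMNS = [
    "probe_id", "rna_type", "transcript_id", "gene_id", "chrom", "strand",
    "start", "end", "exons", "utr3", "class",
]


def _parse_interval_list(text: str) -> list[Interval]:
    text = text.strip()
    if not text:
        return []
    out = []
    for part in text.split(";"):
        s, e = part.split("-")
        out.append((int(s), int(e)))
    return out


def _format_interval_list(intervals: Iterable[Interval]) -> str:
    return ";".join(f"{s}-{e}" for s, e in intervals)


def _normalize_strand(token: str) -> str:
    # tolerate the typographic minus that table extractions produce
    return {"−": "-", "-": "-", "+": "+"}.get(token.strip(), token.strip())


def read_annotation(path: str | Path) -> TranscriptAnnotation:
    """Read annotation from a flat TSV or a GTF subset.

    Flat TSV coordinates are already 0-based half-open; GTF coordinates are
    1-based inclusive and are shifted (-1 on start) on read, so both dialects
    load to identical internal records.
    """
    path = Path(path)
    if path.suffix.lower() in (".gtf", ".gff"):
        return _read_annotation_gtf(path)
    return _read_annotation_flat(path)


def _read_annotation_flat(path: Path) -> TranscriptAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_FLAT_COLUMNS[:8]) - set(df.columns)
    if missing:
        raise StudyFormatError(f"annotation missing column(s): {', '.join(sorted(missing))}")
    records: dict[str, TranscriptRecord] = {}
    for row in df.to_dict("records"):
        strand = _normalize_strand(row["strand"])
        if strand not in ("+", "-"):
            raise StudyFormatError(f"strand required for probe {row['probe_id']!r}")
        utr3_list = _parse_interval_list(row.get("utr3", ""))
        rec = TranscriptRecord(
            probe_id=row["probe_id"],
            rna_type=row["rna_type"],
            transcript_id=row["transcript_id"],
            gene_id=row["gene_id"],
            chrom=row["chrom"],
            strand=strand,
            start=int(row["start"]),
            end=int(row["end"]),
            exons=_parse_interval_list(row.get("exons", "")),
            utr3=utr3_list[0] if utr3_list else None,
            class_label=row.get("class") or None,
        )
        if rec.probe_id in records:
            raise StudyFormatError(f"duplicate probe_id in annotation: {rec.probe_id}")
        records[rec.probe_id] = rec
    return TranscriptAnnotation(records)


def _parse_gtf_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().rstrip(";").split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def _read_annotation_gtf(path: Path) -> TranscriptAnnotation:
    transcripts: dict[str, dict] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise StudyFormatError(f"{path}:{ln}: expected 9 GTF fields")
            chrom, _source, feature, start, end, _score, strand, _frame, attr_text = fields
            if feature not in ("transcript", "exon", "three_prime_utr"):
                continue
            start_i, end_i = int(start), int(end)
            if start_i > end_i:
                raise StudyFormatError(f"{path}:{ln}: GTF start > end")
            attrs = _parse_gtf_attributes(attr_text)
            tid = attrs.get("transcript_id")
            if tid is None:
                raise StudyFormatError(f"{path}:{ln}: transcript_id attribute required")
            entry = transcripts.setdefault(
                tid, {"exons": [], "utr3": None, "span": None, "attrs": {}}
            )
            iv = (start_i - 1, end_i)  # 1-based inclusive -> 0-based half-open
            if feature == "transcript":
                entry["span"] = iv
                entry["attrs"] = {**attrs, "chrom": chrom, "strand": _normalize_strand(strand)}
            elif feature == "exon":
                entry["exons"].append(iv)
            else:
                entry["utr3"] = iv

    records: dict[str, TranscriptRecord] = {}
    for tid, entry in transcripts.items():
        if entry["span"] is None:
            raise StudyFormatError(f"transcript {tid} has exon/UTR lines but no transcript line")
        attrs = entry["attrs"]
        probe_id = attrs.get("probe_id", tid)
        rec = TranscriptRecord(
            probe_id=probe_id,
            rna_type=attrs.get("rna_type", "mRNA"),
            transcript_id=tid,
            gene_id=attrs.get("gene_id", tid),
            chrom=attrs["chrom"],
            strand=attrs["strand"],
            start=entry["span"][0],
            end=entry["span"][1],
            exons=entry["exons"],
            utr3=entry["utr3"],
            class_label=attrs.get("class") or None,
        )
        if probe_id in records:
            raise StudyFormatError(f"duplicate probe_id in annotation: {probe_id}")
        records[probe_id] = rec
    return TranscriptAnnotation(records)


def write_annotation(annotation: TranscriptAnnotation, path: str | Path) -> None:
    rows = []
    for rec in annotation.records.values():
        rows.append(
            (
                rec.probe_id, rec.rna_type, rec.transcript_id, rec.gene_id,
                rec.chrom, rec.strand, rec.start, rec.end,
                _format_interval_list(rec.exons),
                _format_interval_list([rec.utr3]) if rec.utr3 else "",
                rec.class_label or "",
            )
        )
    pd.DataFrame(rows, columns=_FLAT_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: frozenset[str]


@dataclass
class GeneSetCollection:
    sets: list[GeneSet]

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            raise StudyFormatError("gene set names must be unique")
        for s in self.sets:
            if not s.members:
                raise StudyFormatError(f"gene set {s.name!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (name, description, tab-separated members; members deduplicated)."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise StudyFormatError(f"{path}:{ln}: GMT line needs >= 3 tab-separated fields")
            name, description = fields[0], fields[1]
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise StudyFormatError(f"{path}:{ln}: gene set {name!r} has no members")
            sets.append(GeneSet(name, description, members))
    return GeneSetCollection(sets)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in collection.sets:
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into {record_id: sequence}; ids are probe/transcript ids."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")
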