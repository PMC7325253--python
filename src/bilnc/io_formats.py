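"""Readers and writers for the standard formats the pipeline touches.

One coordinate convention holds throughout the package: exon intervals are
0-based half-open in memory, converted from/to the 1-based closed convention
at the GTF/GFF boundary.  RNA sequences are normalised to the DNA alphabet
(``U`` -> ``T``, uppercased) at ingest so genomic, transcript and
mature-miRNA sequences can be aligned against each other directly.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """A file could not be parsed."""


class ValidationError(ValueError):
    """Parsed content violates a model invariant."""


VALID_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

BIOTYPES = ("mRNA", "lncRNA", "candidate", "unknown")


def revcomp(seq: str) -> str:
    """Reverse complement on the internal DNA alphabet (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_seq(seq: str) -> str:
    return seq.upper().replace("U", "T")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence (uppercase DNA alphabet)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence record with empty id")
        if not self.seq:
            raise ValidationError(f"sequence record {self.id!r} has empty sequence")
        bad = set(self.seq) - VALID_ALPHABET
        if bad:
            raise ValidationError(
                f"sequence record {self.id!r} contains invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class TranscriptModel:
    """A strand-aware exon-structured transcript locus.

    ``exons`` are 0-based half-open genomic intervals, sorted ascending and
    non-overlapping; this is the unit of all interval logic in the package.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    biotype: str = "unknown"
    assembly_coverage: float = 0.0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"transcript {self.transcript_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.biotype not in BIOTYPES:
            raise ValidationError(
                f"transcript {self.transcript_id!r}: unknown biotype {self.biotype!r}"
            )
        if not self.exons:
            raise ValidationError(f"transcript {self.transcript_id!r} has no exons")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        for s, e in self.exons:
            if s >= e:
                raise ValidationError(
                    f"transcript {self.transcript_id!r}: exon with start >= end ({s}, {e})"
                )
            if s < 0:
                raise ValidationError(
                    f"transcript {self.transcript_id!r}: negative exon start {s}"
                )
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValidationError(
                    f"transcript {self.transcript_id!r}: overlapping exons"
                )
        if self.assembly_coverage < 0:
            raise ValidationError(
                f"transcript {self.transcript_id!r}: negative assembly coverage"
            )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]

    def extract_sequence(self, chrom_seq: str) -> str:
        """Spliced transcript sequence, reverse-complemented on the minus strand."""
        parts = [chrom_seq[s:e] for s, e in self.exons]
        seq = "".join(parts)
        return revcomp(seq) if self.strand == "-" else seq


@dataclass(frozen=True)
class SampleDesign:
    """One sequencing library: a (line, replicate) cell of the design."""

    sample_id: str
    line: str
    replicate: int

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValidationError(
                f"sample {self.sample_id!r}: replicate must be a positive integer"
            )


# ---------------------------------------------------------------------------
# GTF / GFF
# ---------------------------------------------------------------------------


def _prevalidate_gtf(path: Path) -> None:
    # cheap structural pass so parse errors can name the offending line
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start > end:
                raise ValidationError(
                    f"{path}: line {lineno}: feature start > end ({start} > {end})"
                )


def _feature_transcript_id(feat) -> str | None:
    for key in ("transcript_id", "Parent", "ID"):
        if key in feat.attributes:
            value = feat.attributes[key][0]
            return value.split(":", 1)[-1] if key == "Parent" else value
    return None


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read transcript models from a GTF2.2 or GFF3 file.

    Exon features are grouped per transcript; 1-based closed coordinates are
    converted to the internal 0-based half-open convention.  Transcript-level
    features may carry ``cov``/``coverage`` (assembly read coverage) and
    ``biotype`` attributes; absent annotations default to coverage 0 and
    biotype ``unknown``.
    """
    path = Path(path)
    _prevalidate_gtf(path)
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises a zoo of types
        raise FormatError(f"{path}: could not parse annotation: {exc}") from exc

    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, dict] = {}
    for feat in db.all_features():
        tid = _feature_transcript_id(feat)
        if tid is None:
            continue
        if feat.featuretype == "exon":
            exons.setdefault(tid, []).append((feat.start - 1, feat.end))
            info = meta.setdefault(tid, {"chrom": feat.seqid, "strand": feat.strand})
            if "gene_id" in feat.attributes and "gene_id" not in info:
                info["gene_id"] = feat.attributes["gene_id"][0]
        elif feat.featuretype in ("transcript", "mRNA", "lnc_RNA", "lncRNA"):
            info = meta.setdefault(tid, {"chrom": feat.seqid, "strand": feat.strand})
            if "gene_id" in feat.attributes:
                info["gene_id"] = feat.attributes["gene_id"][0]
            for key in ("cov", "coverage"):
                if key in feat.attributes:
                    info["coverage"] = float(feat.attributes[key][0])
            if "biotype" in feat.attributes:
                info["biotype"] = feat.attributes["biotype"][0]

    models = []
    for tid in sorted(exons):
        info = meta[tid]
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=info.get("gene_id", tid),
                chrom=info["chrom"],
                strand=info["strand"] if info["strand"] in "+-" else "+",
                exons=exons[tid],
                biotype=info.get("biotype", "unknown"),
                assembly_coverage=info.get("coverage", 0.0),
            )
        )
    return models


def write_gtf(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write transcript models as GTF (one transcript line plus exon lines).

    Rows are sorted by transcript id so output is diffable across runs.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for t in sorted(transcripts, key=lambda t: t.transcript_id):
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'cov "{t.assembly_coverage:g}"; biotype "{t.biotype}";'
            )
            fh.write(
                "\t".join(
                    [
                        t.chrom,
                        "bilnc",
                        "transcript",
                        str(t.start + 1),
                        str(t.end),
                        ".",
                        t.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
            for i, (s, e) in enumerate(t.exons, start=1):
                exon_attrs = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'exon_number "{i}";'
                )
                fh.write(
                    "\t".join(
                        [
                            t.chrom,
                            "bilnc",
                            "exon",
                            str(s + 1),
                            str(e),
                            ".",
                            t.strand,
                            ".",
                            exon_attrs,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into normalised :class:`SequenceRecord` objects."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = normalize_seq(str(rec.seq))
        if not seq:
            raise ValidationError(f"{path}: record {rec.id!r} has no sequence")
        records.append(SequenceRecord(rec.id, seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    recs = sorted(records, key=lambda r: r.id)
    SeqIO.write(
        [SeqRecord(Seq(r.seq), id=r.id, description="") for r in recs],
        str(path),
        "fasta",
    )


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------


def read_table(
    path: str | Path,
    required: Sequence[str] = (),
    dtypes: Mapping[str, type] | None = None,
) -> pd.DataFrame:
    """Read a tab-separated table with a header row.

    ``required`` columns must be present; a ragged row raises an error naming
    the row.  Missing values remain NaN and are the caller's concern.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", engine="python", on_bad_lines="error")
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if dtypes:
        for col, typ in dtypes.items():
            if col in df.columns:
                try:
                    df[col] = df[col].astype(typ)
                except (TypeError, ValueError) as exc:
                    raise FormatError(
                        f"{path}: column {col!r} not coercible to {typ}"
                    ) from exc
    return df


def read_design(path: str | Path) -> pd.DataFrame:
    """Read a sample design table (sample_id, line, replicate)."""
    df = read_table(path, required=("sample_id", "line", "replicate"))
    df["replicate"] = df["replicate"].astype(int)
    return validate_design(df)


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    if design["sample_id"].duplicated().any():
        raise ValidationError("design: duplicated sample_id")
    if design.duplicated(subset=["line", "replicate"]).any():
        raise ValidationError("design: (line, replicate) pairs must be unique")
    if (design["replicate"] < 1).any():
        raise ValidationError("design: replicate must be a positive integer")
    return design.reset_index(drop=True)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Deterministic TSV writer (fixed float format, no index by default)."""
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")
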