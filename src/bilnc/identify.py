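"""Candidate filtering and coding-potential consensus voting for lncRNAs.

A novel transcript enters the candidate set when it is expressed (max FPKM
across samples >= 0.5), assembled with read coverage > 1 and longer than
200 nt.  Four coding-potential verdicts (CPC-style score, CNCI-style score,
txCdsPredict-style score, Pfam hit) then vote: at least three consistent
verdicts classify the transcript as mRNA or lncRNA; a 2-2 split stays
unresolved and belongs to neither set.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import TranscriptModel, ValidationError

CODING, NONCODING = "coding", "noncoding"


@dataclass(frozen=True)
class IdentificationThresholds:
    min_fpkm: float = 0.5  # inclusive
    min_coverage: float = 1.0  # strict >
    min_length: int = 200  # strict >
    votes_required: int = 3
    cpc_threshold: float = 0.0  # strict > => coding
    cnci_threshold: float = 0.0
    txcds_threshold: float = 500.0


def filter_candidates(
    transcripts: list[TranscriptModel],
    fpkm: pd.DataFrame,
    thresholds: IdentificationThresholds = IdentificationThresholds(),
) -> tuple[list[TranscriptModel], dict[str, list[str]]]:
    """Split transcripts into candidates and failures with reasons.

    Returns (candidates, failures) where failures maps transcript_id to the
    list of criteria it failed ("fpkm", "coverage", "length").
    """
    missing = [t.transcript_id for t in transcripts if t.transcript_id not in fpkm.index]
    if missing:
        raise ValidationError(f"transcripts missing from the FPKM matrix: {missing[:10]}")
    max_fpkm = fpkm.max(axis=1)
    candidates, failures = [], {}
    for t in transcripts:
        reasons = []
        if max_fpkm[t.transcript_id] < thresholds.min_fpkm:
            reasons.append("fpkm")
        if not t.assembly_coverage > thresholds.min_coverage:
            reasons.append("coverage")
        if not t.length > thresholds.min_length:
            reasons.append("length")
        if reasons:
            failures[t.transcript_id] = reasons
        else:
            candidates.append(t)
    return candidates, failures


def verdicts_from_scores(
    cpc_score: float,
    cnci_score: float,
    txcds_score: float,
    pfam_hit: bool,
    thresholds: IdentificationThresholds = IdentificationThresholds(),
) -> tuple[str, str, str, str]:
    """Map the four predictor scores to coding/noncoding verdicts.

    All score thresholds are strict "greater than": a score exactly at the
    threshold is noncoding.
    """
    return (
        CODING if cpc_score > thresholds.cpc_threshold else NONCODING,
        CODING if cnci_score > thresholds.cnci_threshold else NONCODING,
        CODING if txcds_score > thresholds.txcds_threshold else NONCODING,
        CODING if pfam_hit else NONCODING,
    )


def consensus_classify(
    verdicts: tuple[str, ...], votes_required: int = 3
) -> str:
    """3-of-4 consensus: >=3 noncoding -> lncRNA, >=3 coding -> mRNA, else unresolved."""
    if len(verdicts) != 4:
        raise ValidationError(f"need exactly 4 verdicts, got {len(verdicts)}")
    bad = set(verdicts) - {CODING, NONCODING}
    if bad:
        raise ValidationError(f"unknown verdicts {sorted(bad)}")
    votes = Counter(verdicts)
    if votes[NONCODING] >= votes_required:
        return "lncRNA"
    if votes[CODING] >= votes_required:
        return "mRNA"
    return "unresolved"


def classify_transcripts(
    verdict_table: pd.DataFrame,
    thresholds: IdentificationThresholds = IdentificationThresholds(),
) -> pd.DataFrame:
    """Consensus class for every row of a predictor verdict table.

    Expects columns (transcript_id, cpc, cnci, txcds, pfam); returns the
    table with per-predictor verdicts and a ``consensus`` column in
    {lncRNA, mRNA, unresolved}.
    """
    for col in ("transcript_id", "cpc", "cnci", "txcds", "pfam"):
        if col not in verdict_table.columns:
            raise ValidationError(f"verdict table missing column {col!r}")
    out = verdict_table.copy()
    verdicts = [
        verdicts_from_scores(r.cpc, r.cnci, r.txcds, bool(r.pfam), thresholds)
        for r in out.itertuples()
    ]
    out[["v_cpc", "v_cnci", "v_txcds", "v_pfam"]] = pd.DataFrame(verdicts, index=out.index)
    out["consensus"] = [
        consensus_classify(v, thresholds.votes_required) for v in verdicts
    ]
    return out


_STOPS = {"TAA", "TAG", "TGA"}


def builtin_orf_predictor(seq: str) -> int:
    """Longest ATG..stop open reading frame (nt, stop included) on forward frames.

    A stand-in score when external coding-potential predictions are
    unavailable: coding means longest ORF >= 300 nt (about 100 aa).  Returns
    0 when no complete ORF exists.
    """
    if len(seq) < 3:
        raise ValidationError("sequence shorter than one codon")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValidationError(f"invalid characters in sequence: {sorted(bad)}")
    best = 0
    for frame in range(3):
        starts: list[int] = []
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if codon == "ATG":
                starts.append(i)
            elif codon in _STOPS and starts:
                best = max(best, i + 3 - starts[0])
                starts.clear()
    return best


ORF_CODING_MIN_NT = 300


def orf_verdict(seq: str) -> str:
    return CODING if builtin_orf_predictor(seq) >= ORF_CODING_MIN_NT else NONCODING


def sequence_feature_summary(
    transcripts: list[TranscriptModel],
    sequences: dict[str, str],
    length_bins: tuple[int, ...] = (0, 500, 1000, 2000, 5000, 10_000, 20_000),
    expressed_ids: set[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-biotype sequence characteristics.

    Returns tables for transcript-length histogram and mean, exon-count
    histogram, transcripts-per-gene histogram, per-gene GC% (GC of the
    concatenated exonic sequence of the gene's transcripts) and, when
    ``expressed_ids`` is supplied, per-chromosome expressed-transcript counts.
    """
    missing = [t.transcript_id for t in transcripts if t.transcript_id not in sequences]
    if missing:
        raise ValidationError(f"transcripts without sequence: {missing[:10]}")

    rows = [
        {
            "transcript_id": t.transcript_id,
            "gene_id": t.gene_id,
            "chrom": t.chrom,
            "biotype": t.biotype,
            "length": t.length,
            "exon_count": t.exon_count,
        }
        for t in transcripts
    ]
    df = pd.DataFrame(rows)
    out: dict[str, pd.DataFrame] = {}

    labels = [
        f"{a}-{b}" for a, b in zip(length_bins, length_bins[1:])
    ] + [f">{length_bins[-1]}"]
    cut = pd.cut(
        df["length"],
        bins=list(length_bins) + [np.inf],
        labels=labels,
        right=True,
    )
    out["length_hist"] = (
        df.assign(length_bin=cut)
        .groupby(["biotype", "length_bin"], observed=False)
        .size()
        .rename("n")
        .reset_index()
    )
    out["length_mean"] = (
        df.groupby("biotype")["length"].agg(["mean", "min", "max"]).reset_index()
    )
    out["exon_hist"] = (
        df.groupby(["biotype", "exon_count"]).size().rename("n").reset_index()
    )
    per_gene = (
        df.groupby(["biotype", "gene_id"]).size().rename("n_transcripts").reset_index()
    )
    out["transcripts_per_gene_hist"] = (
        per_gene.groupby(["biotype", "n_transcripts"]).size().rename("n").reset_index()
    )

    gc_rows = []
    for (biotype, gene_id), sub in df.groupby(["biotype", "gene_id"]):
        seq = "".join(sequences[tid] for tid in sub["transcript_id"])
        gc = 100.0 * sum(seq.count(b) for b in "GC") / len(seq)
        gc_rows.append({"biotype": biotype, "gene_id": gene_id, "gc_percent": gc})
    out["gc_per_gene"] = pd.DataFrame(gc_rows)

    if expressed_ids is not None:
        expressed = df[df["transcript_id"].isin(expressed_ids)]
        out["expressed_per_chrom"] = (
            expressed.groupby(["biotype", "chrom"]).size().rename("n").reset_index()
        )
    return out
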