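"""miRNA precursors in lncRNAs, miRNA targeting, and the tripartite network.

A lncRNA is called a miRNA-precursor host when a local alignment of the
precursor hairpin sequence against the lncRNA covers more than 90% of the
precursor at high identity.  miRNA -> transcript target edges come either
from a supplied edge table or from a plant-style complementarity scan
(Allen-type penalty: mismatch 1.0, G:U wobble 0.5, gap 2.0, doubled at
miRNA positions 2-13; sites with penalty <= 4.0 are kept).  The network
stage classifies each miRNA by the kinds of targets it reaches and reports
miRNAs that target their own precursor lncRNAs.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from Bio import Align

from .io_formats import ValidationError

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}


# ---------------------------------------------------------------------------
# local alignment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LocalAlignment:
    score: float
    query_start: int
    query_end: int  # half-open on the query
    subject_start: int
    subject_end: int
    alignment_length: int  # aligned span on the query, nt
    identity: float  # matches / aligned columns (gap columns excluded)


def smith_waterman(
    query: str,
    subject: str,
    match: float = 1.0,
    mismatch: float = -2.0,
    gap: float = -2.0,
) -> LocalAlignment | None:
    """Optimal local alignment (blastn-flavoured scoring by default).

    Returns None when no alignment scores above 0.  When several optimal
    alignments exist the aligner's first one is reported (deterministic).
    """
    if not query or not subject:
        raise ValidationError("smith_waterman needs nonempty sequences")
    bad = (set(query) | set(subject)) - set("ACGTN")
    if bad:
        raise ValidationError(f"invalid characters in sequences: {sorted(bad)}")
    aligner = Align.PairwiseAligner(
        mode="local",
        match_score=match,
        mismatch_score=mismatch,
        open_gap_score=gap,
        extend_gap_score=gap,
    )
    score = aligner.score(query, subject)
    if score <= 0:
        return None
    aln = aligner.align(query, subject)[0]
    qblocks, sblocks = aln.aligned
    matches = 0
    columns = 0
    for (qs, qe), (ss, se) in zip(qblocks, sblocks):
        columns += qe - qs
        matches += sum(1 for a, b in zip(query[qs:qe], subject[ss:se]) if a == b)
    q_start, q_end = int(qblocks[0][0]), int(qblocks[-1][1])
    s_start, s_end = int(sblocks[0][0]), int(sblocks[-1][1])
    return LocalAlignment(
        score=float(score),
        query_start=q_start,
        query_end=q_end,
        subject_start=s_start,
        subject_end=s_end,
        alignment_length=q_end - q_start,
        identity=matches / columns if columns else 0.0,
    )


# ---------------------------------------------------------------------------
# precursor detection
# ---------------------------------------------------------------------------


def find_precursors(
    precursor_seqs: dict[str, str],
    lncrna_seqs: dict[str, str],
    min_ratio: float = 0.9,
    min_identity: float = 0.9,
    lncrna_chroms: dict[str, str] | None = None,
    de_lncrnas: set[str] | None = None,
) -> pd.DataFrame:
    """Align each miRNA precursor to each lncRNA and keep near-full covers.

    coverage_ratio = aligned precursor span / precursor length; a hit is
    retained when the ratio exceeds ``min_ratio`` (strict) and identity is at
    least ``min_identity``.  Precursor ids are expected to name their mature
    miRNA (one precursor sequence per miRNA id).
    """
    rows = []
    for mirna_id in sorted(precursor_seqs):
        pre = precursor_seqs[mirna_id]
        for lnc_id in sorted(lncrna_seqs):
            aln = smith_waterman(pre, lncrna_seqs[lnc_id])
            if aln is None:
                continue
            ratio = aln.alignment_length / len(pre)
            if ratio > min_ratio and aln.identity >= min_identity:
                rows.append(
                    {
                        "mirna_id": mirna_id,
                        "lncrna_id": lnc_id,
                        "alignment_length": aln.alignment_length,
                        "coverage_ratio": ratio,
                        "identity": aln.identity,
                        "location": (
                            lncrna_chroms.get(lnc_id, "") if lncrna_chroms else ""
                        ),
                        "de_lncrna": bool(de_lncrnas and lnc_id in de_lncrnas),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "mirna_id",
            "lncrna_id",
            "alignment_length",
            "coverage_ratio",
            "identity",
            "location",
            "de_lncrna",
        ],
    )


def precursor_census(hits: pd.DataFrame) -> dict:
    """Summary counts over a precursor-hit table (fixture or computed)."""
    de_col = "de_lncrna"
    per_lnc = hits.groupby("lncrna_id")["mirna_id"].nunique() if len(hits) else pd.Series(dtype=int)
    n_lnc = int(hits["lncrna_id"].nunique()) if len(hits) else 0
    chrom_of = (
        hits.drop_duplicates("lncrna_id").set_index("lncrna_id")["location"]
        if len(hits)
        else pd.Series(dtype=str)
    )
    chrom_counts = chrom_of.value_counts().to_dict()
    return {
        "n_hits": len(hits),
        "n_lncrnas": n_lnc,
        "n_mirnas": int(hits["mirna_id"].nunique()) if len(hits) else 0,
        "n_de_lncrnas": int(
            hits.loc[hits[de_col].astype(bool), "lncrna_id"].nunique()
        )
        if len(hits)
        else 0,
        "n_multi_mirna_lncrnas": int((per_lnc > 1).sum()),
        "lncrnas_per_chrom": chrom_counts,
    }


# ---------------------------------------------------------------------------
# Allen-style target scoring
# ---------------------------------------------------------------------------

MISMATCH_PENALTY = 1.0
WOBBLE_PENALTY = 0.5
CORE_START, CORE_END = 2, 13  # 1-based miRNA positions with doubled weight
DEFAULT_MAX_PENALTY = 4.0


def _site_penalties(mature: str, transcript: str) -> np.ndarray:
    """Penalty of every gapless antisense site of the miRNA on a transcript."""
    L = len(mature)
    t = np.frombuffer(transcript.encode(), dtype=np.uint8)
    m = np.frombuffer(mature.encode(), dtype=np.uint8)
    if len(t) < L:
        return np.array([])
    # miRNA position p (0-based from its 5' end) pairs site base L-1-p:
    # reversing each window aligns site base indices with miRNA indices
    windows = np.lib.stride_tricks.sliding_window_view(t, L)[:, ::-1]
    comp = np.zeros(256, dtype=np.uint8)
    for a, b in _WC:
        comp[ord(a)] = ord(b)
    wc = windows == comp[m][None, :]
    gpos = np.zeros((len(m),), dtype=bool)
    wobble = np.zeros_like(wc)
    for a, b in _WOBBLE:
        wobble |= (m == ord(a))[None, :] & (windows == ord(b))
    penalty = np.where(wc, 0.0, np.where(wobble, WOBBLE_PENALTY, MISMATCH_PENALTY))
    weights = np.ones(L)
    weights[CORE_START - 1 : CORE_END] = 2.0
    return penalty @ weights


def mirna_target_score(
    mature: str, transcript: str
) -> tuple[float, int]:
    """Best (lowest-penalty) antisense site of a mature miRNA on a transcript.

    Returns (penalty, site start on the transcript).  Gapless scan; the
    penalty doubles at miRNA positions 2-13 (the cleavage-critical core).
    """
    if not 18 <= len(mature) <= 26:
        raise ValidationError("mature miRNA length must be 18-26 nt")
    scores = _site_penalties(mature, transcript)
    if scores.size == 0:
        return float("inf"), -1
    best = int(np.argmin(scores))
    return float(scores[best]), best


def find_target_edges(
    matures: dict[str, str],
    transcript_seqs: dict[str, str],
    transcript_kinds: dict[str, str],
    max_penalty: float = DEFAULT_MAX_PENALTY,
) -> pd.DataFrame:
    """Scan all transcripts for miRNA target sites; keep penalty <= max_penalty."""
    rows = []
    for mirna_id in sorted(matures):
        for tid in sorted(transcript_seqs):
            score, pos = mirna_target_score(matures[mirna_id], transcript_seqs[tid])
            if score <= max_penalty:
                rows.append(
                    {
                        "mirna_id": mirna_id,
                        "target_id": tid,
                        "target_kind": transcript_kinds.get(tid, "unknown"),
                        "score": score,
                        "site_start": pos,
                    }
                )
    return pd.DataFrame(
        rows, columns=["mirna_id", "target_id", "target_kind", "score", "site_start"]
    )


# ---------------------------------------------------------------------------
# tripartite network
# ---------------------------------------------------------------------------


def build_network(
    target_edges: pd.DataFrame, precursor_hits: pd.DataFrame
) -> tuple[nx.MultiDiGraph, pd.DataFrame, dict]:
    """Assemble the miRNA/lncRNA/mRNA network and classify each miRNA.

    Classes: only-mRNA / only-lncRNA / both, the latter sub-classified into
    more-mRNAs / more-lncRNAs / equal by target counts.  Returns the graph,
    a per-miRNA classification table, and a census dict (a partition of the
    miRNAs with any target edge).
    """
    g = nx.MultiDiGraph()
    for row in target_edges.itertuples():
        g.add_node(row.mirna_id, kind="miRNA")
        g.add_node(row.target_id, kind=row.target_kind)
        g.add_edge(row.mirna_id, row.target_id, etype="target", score=row.score)
    for row in precursor_hits.itertuples():
        g.add_node(row.mirna_id, kind="miRNA")
        g.add_node(row.lncrna_id, kind="lncRNA")
        g.add_edge(
            row.lncrna_id, row.mirna_id, etype="precursor", ratio=row.coverage_ratio
        )

    rows = []
    for mirna_id, sub in target_edges.groupby("mirna_id"):
        n_mrna = int((sub["target_kind"] == "mRNA").sum())
        n_lnc = int((sub["target_kind"] == "lncRNA").sum())
        if n_mrna and not n_lnc:
            cls, subcls = "only-mRNA", ""
        elif n_lnc and not n_mrna:
            cls, subcls = "only-lncRNA", ""
        else:
            cls = "both"
            subcls = (
                "more-mRNAs"
                if n_mrna > n_lnc
                else "more-lncRNAs" if n_lnc > n_mrna else "equal"
            )
        rows.append(
            {
                "mirna_id": mirna_id,
                "n_mrna_targets": n_mrna,
                "n_lncrna_targets": n_lnc,
                "mirna_class": cls,
                "both_subclass": subcls,
            }
        )
    classes = pd.DataFrame(
        rows,
        columns=[
            "mirna_id",
            "n_mrna_targets",
            "n_lncrna_targets",
            "mirna_class",
            "both_subclass",
        ],
    )
    census = {
        "n_mirnas": len(classes),
        "only_mrna": int((classes["mirna_class"] == "only-mRNA").sum()),
        "only_lncrna": int((classes["mirna_class"] == "only-lncRNA").sum()),
        "both": int((classes["mirna_class"] == "both").sum()),
        "both_more_mrnas": int((classes["both_subclass"] == "more-mRNAs").sum()),
        "both_more_lncrnas": int((classes["both_subclass"] == "more-lncRNAs").sum()),
        "both_equal": int((classes["both_subclass"] == "equal").sum()),
        "n_lncrna_targets": int(
            target_edges.loc[target_edges["target_kind"] == "lncRNA", "target_id"].nunique()
        ),
        "n_mrna_targets": int(
            target_edges.loc[target_edges["target_kind"] == "mRNA", "target_id"].nunique()
        ),
    }
    return g, classes, census


def self_targeting(
    target_edges: pd.DataFrame, precursor_hits: pd.DataFrame
) -> pd.DataFrame:
    """miRNAs that target at least one of their own precursor lncRNAs.

    Returns the full miRNA -> lncRNA target list restricted to miRNAs with a
    self-target, with ``self_pair`` flagging the (miRNA, lncRNA) pairs that
    are both a precursor hit and a target edge.
    """
    precursor_pairs = set(
        zip(precursor_hits["mirna_id"], precursor_hits["lncrna_id"])
    )
    lnc_edges = target_edges[target_edges["target_kind"] == "lncRNA"]
    flagged = lnc_edges.assign(
        self_pair=[
            (m, t) in precursor_pairs
            for m, t in zip(lnc_edges["mirna_id"], lnc_edges["target_id"])
        ]
    )
    self_mirnas = set(flagged.loc[flagged["self_pair"], "mirna_id"])
    out = flagged[flagged["mirna_id"].isin(self_mirnas)].copy()
    return out[["mirna_id", "target_id", "self_pair"]].reset_index(drop=True)


def export_edge_list(g: nx.MultiDiGraph, path) -> None:
    rows = [
        {"source": u, "target": v, "etype": data.get("etype", "")}
        for u, v, data in sorted(
            g.edges(data=True), key=lambda e: (e[0], e[1], e[2].get("etype", ""))
        )
    ]
    pd.DataFrame(rows, columns=["source", "target", "etype"]).to_csv(
        path, sep="\t", index=False
    )


def export_graphml(g: nx.MultiDiGraph, path) -> None:
    nx.write_graphml(g, path)
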