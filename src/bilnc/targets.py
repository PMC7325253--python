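"""lncRNA -> mRNA target prediction.

The procedure runs in three steps: (1) expression correlation across all
samples (Spearman >= 0.6 AND Pearson >= 0.6); (2) positional classification
of correlated pairs — overlapping spans are cis with one of 10 subclasses
({sense, antisense} x 5 geometries), non-overlapping pairs within 10 kb
upstream or 20 kb downstream of the mRNA (strand-aware, inclusive windows)
are cis_mRNA_up10k / cis_mRNA_dw20k; (3) remaining distal correlated pairs
are trans targets when the predicted lncRNA:mRNA duplex energy is below
-30 kcal/mol.

The default duplex scorer is a gapless antisense nearest-neighbour model:
the best (most negative) sum of RNA stacking energies over any contiguous
antiparallel complementary run.  Watson-Crick stacks use a published
Turner-style 10-parameter table; stacks involving G:U wobbles are
approximated by a flat -0.5 kcal/mol (+0.3 when two wobbles stack).
Initiation and terminal terms are omitted.  Precomputed energies can be
supplied as a table and then take precedence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_formats import TranscriptModel, ValidationError

logger = logging.getLogger(__name__)

CIS_UP, CIS_OVERLAP, CIS_DOWN = "cis_mRNA_up10k", "cis_mRNA_overlap", "cis_mRNA_dw20k"
TRANS, DISTAL = "trans", "distal"

GEOMETRIES = ("partial5", "partial3", "lnc_in_mrna", "lnc_in_intron", "mrna_in_lnc")
STRAND_RELATIONS = ("sense", "antisense")

_DEFAULT_LABELS = {
    ("sense", "partial5"): "lnc-overlap-mRNA-5p",
    ("sense", "partial3"): "lnc-overlap-mRNA-3p",
    ("sense", "lnc_in_mrna"): "lnc-complete in-mRNA",
    ("sense", "lnc_in_intron"): "lnc-complete in-mRNA intron",
    ("sense", "mrna_in_lnc"): "mRNA-complete in-lnc",
    ("antisense", "partial5"): "lnc-anti overlap-mRNA-5p",
    ("antisense", "partial3"): "lnc-anti overlap-mRNA-3p",
    ("antisense", "lnc_in_mrna"): "lnc-anti complete in-mRNA",
    ("antisense", "lnc_in_intron"): "lnc-anti complete in-mRNA intron",
    ("antisense", "mrna_in_lnc"): "mRNA-anti complete in-lnc",
}


@dataclass(frozen=True)
class PositionTaxonomy:
    """The 4-class / 10-subclass positional taxonomy.

    Windows are inclusive and measured span-edge to span-edge; upstream and
    downstream are relative to the mRNA's strand.  Subclass labels are
    configurable strings keyed by (strand relation, geometry).
    """

    window_up: int = 10_000
    window_down: int = 20_000
    labels: dict = field(default_factory=lambda: dict(_DEFAULT_LABELS))

    def label(self, strand_relation: str, geometry: str) -> str:
        return self.labels[(strand_relation, geometry)]


@dataclass(frozen=True)
class PositionCall:
    reg_class: str  # cis_mRNA_up10k | cis_mRNA_overlap | cis_mRNA_dw20k | distal
    strand_relation: str | None = None
    geometry: str | None = None
    subclass: str | None = None
    distance: int | None = None  # signed: upstream negative, downstream positive, 0 overlap


def classify_position(
    lnc: TranscriptModel,
    mrna: TranscriptModel,
    taxonomy: PositionTaxonomy = PositionTaxonomy(),
) -> PositionCall:
    """Positional class of a lncRNA relative to a candidate target mRNA.

    Overlap geometry (priority order): lncRNA span within one mRNA intron;
    lncRNA span within the mRNA span; mRNA span within the lncRNA span;
    otherwise a partial overlap sided by which mRNA end (5' or 3',
    strand-relative) the lncRNA overhangs.  The lncRNA's own exon structure
    is not consulted (span-based geometry).
    """
    if lnc.chrom != mrna.chrom:
        return PositionCall(DISTAL)
    ls, le = lnc.span
    ms, me = mrna.span
    if ls < me and ms < le:  # spans intersect
        rel = "sense" if lnc.strand == mrna.strand else "antisense"
        if any(ls >= i0 and le <= i1 for i0, i1 in mrna.introns):
            geom = "lnc_in_intron"
        elif ls >= ms and le <= me:
            geom = "lnc_in_mrna"
        elif ls <= ms and le >= me:
            geom = "mrna_in_lnc"
        else:
            overhang_left = ls < ms
            five_prime_is_left = mrna.strand == "+"
            if overhang_left == five_prime_is_left:
                geom = "partial5"
            else:
                geom = "partial3"
        return PositionCall(CIS_OVERLAP, rel, geom, taxonomy.label(rel, geom), 0)
    # disjoint spans: gap between nearest edges
    if le <= ms:
        gap, lnc_is_left = ms - le, True
    else:
        gap, lnc_is_left = ls - me, False
    upstream = lnc_is_left == (mrna.strand == "+")
    if upstream and gap <= taxonomy.window_up:
        return PositionCall(CIS_UP, distance=-gap)
    if not upstream and gap <= taxonomy.window_down:
        return PositionCall(CIS_DOWN, distance=gap)
    return PositionCall(DISTAL)


# ---------------------------------------------------------------------------
# correlation filter
# ---------------------------------------------------------------------------


def _standardized(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = matrix.mean(axis=1, keepdims=True)
    sd = matrix.std(axis=1, keepdims=True)
    constant = sd[:, 0] == 0
    sd[constant] = 1.0
    return (matrix - mean) / sd, constant


def correlation_filter(
    fpkm: pd.DataFrame,
    lnc_ids: list[str],
    mrna_ids: list[str],
    min_pearson: float = 0.6,
    min_spearman: float = 0.6,
    log_transform: bool = True,
) -> pd.DataFrame:
    """All (lncRNA, mRNA) pairs passing both correlation thresholds.

    Correlations are computed on log2(FPKM+1) jointly across all samples.
    Pairs involving a constant expression vector are skipped and logged.
    """
    if fpkm.shape[1] < 3:
        raise ValidationError("correlation filter needs at least 3 samples")
    x = np.log2(fpkm + 1.0).values if log_transform else fpkm.values
    idx = {tid: i for i, tid in enumerate(fpkm.index)}
    missing = [t for t in list(lnc_ids) + list(mrna_ids) if t not in idx]
    if missing:
        raise ValidationError(f"ids missing from FPKM matrix: {missing[:10]}")
    li = np.array([idx[t] for t in lnc_ids])
    mi = np.array([idx[t] for t in mrna_ids])
    n = x.shape[1]

    zl, const_l = _standardized(x[li])
    zm, const_m = _standardized(x[mi])
    pearson = zl @ zm.T / n
    ranks = rankdata(x, axis=1)
    rl, _ = _standardized(ranks[li])
    rm, _ = _standardized(ranks[mi])
    spearman = rl @ rm.T / n

    n_const = int(const_l.sum() + const_m.sum())
    if n_const:
        logger.info("correlation filter: %d constant vector(s) skipped", n_const)
    ok = (
        (pearson >= min_pearson)
        & (spearman >= min_spearman)
        & ~const_l[:, None]
        & ~const_m[None, :]
    )
    ii, jj = np.nonzero(ok)
    return pd.DataFrame(
        {
            "lncrna_id": [lnc_ids[i] for i in ii],
            "mrna_id": [mrna_ids[j] for j in jj],
            "pearson": pearson[ii, jj],
            "spearman": spearman[ii, jj],
        }
    )


# ---------------------------------------------------------------------------
# duplex energy
# ---------------------------------------------------------------------------

# pair codes on (lnc base, mrna base): WC then G:U wobble
_PAIRS = {("A", "T"): 0, ("T", "A"): 1, ("G", "C"): 2, ("C", "G"): 3,
          ("G", "T"): 4, ("T", "G"): 5}

# Turner-style Watson-Crick nearest-neighbour stacks, kcal/mol at 37 C,
# keyed (5'-X1X2-3', 3'-Y1Y2-5') with U written as T.
_WC_STACKS = {
    ("AA", "TT"): -0.93,
    ("AT", "TA"): -1.10,
    ("TA", "AT"): -1.33,
    ("CT", "GA"): -2.08,
    ("CA", "GT"): -2.11,
    ("GT", "CA"): -2.24,
    ("GA", "CT"): -2.35,
    ("CG", "GC"): -2.36,
    ("GG", "CC"): -3.26,
    ("GC", "CG"): -3.42,
}
# symmetric completion: XY/ZW == rev(ZW)/rev(XY)
for (top, bot), e in list(_WC_STACKS.items()):
    _WC_STACKS[(bot[::-1], top[::-1])] = e

WOBBLE_STACK = -0.5
WOBBLE_WOBBLE_STACK = 0.3

_PAIR_BASES = {v: k for k, v in _PAIRS.items()}


def _build_stack_matrix() -> np.ndarray:
    stack = np.zeros((6, 6))
    for p1 in range(6):
        for p2 in range(6):
            x1, y1 = _PAIR_BASES[p1]
            x2, y2 = _PAIR_BASES[p2]
            if p1 < 4 and p2 < 4:
                stack[p1, p2] = _WC_STACKS[(x1 + x2, y1 + y2)]
            elif p1 >= 4 and p2 >= 4:
                stack[p1, p2] = WOBBLE_WOBBLE_STACK
            else:
                stack[p1, p2] = WOBBLE_STACK
    return stack


_STACK = _build_stack_matrix()

_CODE = np.full(256, -1, dtype=np.int8)
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i
_CODE[ord("N")] = 4  # N never pairs

_PAIRCODE = np.full((5, 5), -1, dtype=np.int8)
for (a, b), code in _PAIRS.items():
    _PAIRCODE["ACGTN".index(a), "ACGTN".index(b)] = code

_BREAK = 1e9  # sentinel blocking subarrays from crossing a non-stackable step


def _seq_codes(seq: str) -> np.ndarray:
    codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (codes < 0).any():
        raise ValidationError("sequence contains characters outside ACGTN")
    return codes


def duplex_energy(lnc_seq: str, mrna_seq: str) -> float:
    """Best gapless antisense duplex energy (kcal/mol; 0 when nothing pairs).

    Scans every antiparallel alignment register of the two transcripts and
    returns the most negative contiguous run of nearest-neighbour stacking
    energies.  A duplex needs at least two adjacent base pairs; otherwise
    the energy is 0.
    """
    if len(lnc_seq) < 10 or len(mrna_seq) < 10:
        raise ValidationError("duplex_energy needs sequences of length >= 10")
    ql = _seq_codes(lnc_seq)
    qm = _seq_codes(mrna_seq)[::-1]  # reversed: antiparallel registers become diagonals
    pair = _PAIRCODE[ql[:, None], qm[None, :]]
    n, m = pair.shape
    best = 0.0
    for offset in range(-(n - 2), m - 1):
        d = np.diagonal(pair, offset=offset)
        if d.size < 2:
            continue
        valid = d >= 0
        steps = np.where(
            valid[:-1] & valid[1:],
            _STACK[np.clip(d[:-1], 0, None), np.clip(d[1:], 0, None)],
            _BREAK,
        )
        # min non-empty subarray sum: prefix minus running max of prefixes
        prefix = np.concatenate(([0.0], np.cumsum(steps)))
        run = prefix[1:] - np.maximum.accumulate(prefix[:-1])
        low = run.min()
        if low < best:
            best = low
    return float(best)


# ---------------------------------------------------------------------------
# the three-step pipeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TargetThresholds:
    min_pearson: float = 0.6
    min_spearman: float = 0.6
    max_trans_energy: float = -30.0  # strict <


@dataclass
class RegulatoryPair:
    lncrna_id: str
    mrna_id: str
    pearson: float
    spearman: float
    reg_class: str
    subclass: str | None = None
    binding_energy: float | None = None
    distance: int | None = None


def predict_targets(
    lncs: list[TranscriptModel],
    mrnas: list[TranscriptModel],
    fpkm: pd.DataFrame,
    sequences: dict[str, str] | None = None,
    energies: dict[tuple[str, str], float] | None = None,
    taxonomy: PositionTaxonomy = PositionTaxonomy(),
    thresholds: TargetThresholds = TargetThresholds(),
) -> tuple[pd.DataFrame, dict]:
    """Run correlation -> position -> energy and report pairs plus a census.

    Positional cis classes are accepted directly; distal correlated pairs
    are kept as trans only when the duplex energy (precomputed table first,
    otherwise the gapless scorer on ``sequences``) is below the threshold.
    """
    lnc_by_id = {t.transcript_id: t for t in lncs}
    mrna_by_id = {t.transcript_id: t for t in mrnas}
    corr = correlation_filter(
        fpkm,
        sorted(lnc_by_id),
        sorted(mrna_by_id),
        thresholds.min_pearson,
        thresholds.min_spearman,
    )
    pairs: list[RegulatoryPair] = []
    for row in corr.itertuples():
        lnc, mrna = lnc_by_id[row.lncrna_id], mrna_by_id[row.mrna_id]
        call = classify_position(lnc, mrna, taxonomy)
        if call.reg_class in (CIS_UP, CIS_OVERLAP, CIS_DOWN):
            pairs.append(
                RegulatoryPair(
                    row.lncrna_id,
                    row.mrna_id,
                    row.pearson,
                    row.spearman,
                    call.reg_class,
                    call.subclass,
                    None,
                    call.distance,
                )
            )
            continue
        if energies is not None and (row.lncrna_id, row.mrna_id) in energies:
            energy = float(energies[(row.lncrna_id, row.mrna_id)])
        elif sequences is not None:
            energy = duplex_energy(sequences[row.lncrna_id], sequences[row.mrna_id])
        else:
            continue  # no energy source: distal pair cannot be promoted to trans
        if energy < thresholds.max_trans_energy:
            pairs.append(
                RegulatoryPair(
                    row.lncrna_id,
                    row.mrna_id,
                    row.pearson,
                    row.spearman,
                    TRANS,
                    None,
                    energy,
                    None,
                )
            )

    table = pd.DataFrame(
        [
            {
                "lncrna_id": p.lncrna_id,
                "mrna_id": p.mrna_id,
                "pearson": p.pearson,
                "spearman": p.spearman,
                "reg_class": p.reg_class,
                "subclass": p.subclass if p.subclass is not None else "",
                "distance": p.distance if p.distance is not None else "",
                "energy": p.binding_energy if p.binding_energy is not None else "",
            }
            for p in pairs
        ],
        columns=[
            "lncrna_id",
            "mrna_id",
            "pearson",
            "spearman",
            "reg_class",
            "subclass",
            "distance",
            "energy",
        ],
    )
    per_lnc = table.groupby("lncrna_id").size() if len(table) else pd.Series(dtype=int)
    census = {
        "n_pairs": len(table),
        "per_class": table["reg_class"].value_counts().to_dict() if len(table) else {},
        "per_subclass": (
            table[table["subclass"] != ""]["subclass"].value_counts().to_dict()
            if len(table)
            else {}
        ),
        "n_lncrnas": int(table["lncrna_id"].nunique()) if len(table) else 0,
        "n_mrnas": int(table["mrna_id"].nunique()) if len(table) else 0,
        "n_lncrnas_multi_target": int((per_lnc > 1).sum()),
    }
    return table, census
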