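"""Pairwise between-line differential expression on pooled fragment counts.

The test is an exact conditional binomial: replicates of each line are
pooled, and conditional on the total k = k1 + k2 the count k1 follows
Binomial(k, p0) with p0 = N1/(N1+N2) under the null of equal relative
expression.  Two-sided p-values sum all outcomes no more likely than the
observation (minimum-likelihood rule).  Replicate overdispersion is not
modelled; the fold-change filter is what screens small relative differences.

A transcript is called differentially expressed when |log2FC| >= 1 and
Benjamini-Hochberg FDR <= 0.001 (both thresholds configurable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ValidationError
from .quantify import ExpressionMatrix

logger = logging.getLogger(__name__)

# above this pooled total the exact enumeration is replaced by a
# continuity-corrected normal approximation
_EXACT_LIMIT = 200_000


def de_test(k1: int, k2: int, n1: float, n2: float) -> float:
    """Two-sided exact conditional binomial p-value for pooled counts.

    Returns NaN when k1 + k2 == 0 (no information; callers skip and log).
    """
    if min(k1, k2) < 0 or n1 <= 0 or n2 <= 0:
        raise ValidationError("counts must be nonnegative and library totals positive")
    k = k1 + k2
    if k == 0:
        return float("nan")
    p0 = n1 / (n1 + n2)
    if k > _EXACT_LIMIT:
        mu, sd = k * p0, np.sqrt(k * p0 * (1 - p0))
        z = (abs(k1 - mu) - 0.5) / sd
        return float(min(1.0, 2.0 * stats.norm.sf(z)))
    pmf = stats.binom.pmf(np.arange(k + 1), k, p0)
    obs = pmf[k1]
    # tolerance so exact ties (symmetric outcomes) are included despite fp error
    p = pmf[pmf <= obs * (1.0 + 1e-10)].sum()
    return float(min(1.0, p))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, ties share a q)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class DEThresholds:
    min_abs_log2fc: float = 1.0
    max_fdr: float = 0.001
    pseudocount: float = 1e-3


def call_de(
    counts: ExpressionMatrix,
    comparisons: list[tuple[str, str]],
    thresholds: DEThresholds = DEThresholds(),
) -> pd.DataFrame:
    """Differential-expression calls for a list of (line1, line2) comparisons.

    log2FC is line1 over line2, computed from mean FPKM with a pseudocount;
    the p-value from the pooled exact binomial; FDR by Benjamini-Hochberg per
    comparison; status up/down only when both thresholds are met.
    """
    if counts.kind != "counts":
        raise ValidationError("call_de needs a counts matrix")
    fpkm = counts.to_fpkm().values
    eps = thresholds.pseudocount
    frames = []
    for line1, line2 in comparisons:
        s1 = counts.samples_of_line(line1)
        s2 = counts.samples_of_line(line2)
        k1 = counts.values[s1].sum(axis=1).astype(np.int64)
        k2 = counts.values[s2].sum(axis=1).astype(np.int64)
        n1 = float(counts.library_sizes[s1].sum())
        n2 = float(counts.library_sizes[s2].sum())
        log2fc = np.log2((fpkm[s1].mean(axis=1) + eps) / (fpkm[s2].mean(axis=1) + eps))
        pvals = np.array([de_test(a, b, n1, n2) for a, b in zip(k1, k2)])
        skipped = np.isnan(pvals)
        if skipped.any():
            logger.info(
                "%s vs %s: %d transcript(s) with zero pooled counts skipped",
                line1,
                line2,
                int(skipped.sum()),
            )
        fdr = np.full_like(pvals, np.nan)
        fdr[~skipped] = bh_fdr(pvals[~skipped])
        sig = (~skipped) & (np.abs(log2fc) >= thresholds.min_abs_log2fc) & (
            fdr <= thresholds.max_fdr
        )
        status = np.where(sig & (log2fc > 0), "up", np.where(sig, "down", "ns"))
        frames.append(
            pd.DataFrame(
                {
                    "transcript_id": counts.transcripts,
                    "line1": line1,
                    "line2": line2,
                    "log2fc": log2fc.values,
                    "p_value": pvals,
                    "fdr": fdr,
                    "status": status,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def de_census(de: pd.DataFrame) -> pd.DataFrame:
    """Per-comparison counts of up- and down-regulated transcripts."""
    rows = []
    for (l1, l2), sub in de.groupby(["line1", "line2"], sort=False):
        rows.append(
            {
                "comparison": f"{l1}:{l2}",
                "up": int((sub["status"] == "up").sum()),
                "down": int((sub["status"] == "down").sum()),
                "total_de": int((sub["status"] != "ns").sum()),
            }
        )
    return pd.DataFrame(rows)


def de_sets(de: pd.DataFrame) -> dict[str, dict[str, str]]:
    """Per-comparison {transcript_id: direction} for DE transcripts."""
    out: dict[str, dict[str, str]] = {}
    for (l1, l2), sub in de.groupby(["line1", "line2"], sort=False):
        hit = sub[sub["status"] != "ns"]
        out[f"{l1}:{l2}"] = dict(zip(hit["transcript_id"], hit["status"]))
    return out


@dataclass
class CommonDECensus:
    regions: dict[frozenset, int]
    common: set[str]
    common_consistent_up: set[str]
    common_consistent_down: set[str]


def common_de(sets: dict[str, dict[str, str]]) -> CommonDECensus:
    """Region census across >= 2 DE sets plus the all-way intersection.

    The all-way intersection is split by direction consistency (same status
    in every comparison).
    """
    if len(sets) < 2:
        raise ValidationError("common_de needs at least two DE sets")
    names = list(sets)
    universe = set().union(*(set(s) for s in sets.values()))
    regions: dict[frozenset, int] = {}
    common, up, down = set(), set(), set()
    for tid in universe:
        member = frozenset(n for n in names if tid in sets[n])
        regions[member] = regions.get(member, 0) + 1
        if len(member) == len(names):
            common.add(tid)
            statuses = {sets[n][tid] for n in names}
            if statuses == {"up"}:
                up.add(tid)
            elif statuses == {"down"}:
                down.add(tid)
    return CommonDECensus(regions, common, up, down)


def fc_bin_counts(
    de: pd.DataFrame, bins: tuple[float, ...] = (2, 10, 50, 100, 200)
) -> pd.DataFrame:
    """Per-comparison counts of DE transcripts with |FC| above each bin.

    Bins must be ascending; counts are monotone non-increasing across bins.
    """
    if list(bins) != sorted(bins):
        raise ValidationError("fold-change bins must be ascending")
    rows = []
    for (l1, l2), sub in de.groupby(["line1", "line2"], sort=False):
        hit = sub[sub["status"] != "ns"]
        fc = np.power(2.0, np.abs(hit["log2fc"].values))
        row = {"comparison": f"{l1}:{l2}"}
        for b in bins:
            row[f"fc_gt_{b:g}"] = int((fc > b).sum())
        rows.append(row)
    return pd.DataFrame(rows)
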