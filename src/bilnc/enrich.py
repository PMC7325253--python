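"""Hypergeometric term enrichment for target-gene sets.

Terms (for example GO assignments) are supplied as a table mapping term ids
to gene sets; enrichment of a target gene set against a background is the
one-sided hypergeometric upper-tail probability of the observed overlap.
P-values are reported raw by default (correction available behind a flag).
"""

from __future__ import annotations

import logging

import pandas as pd
from scipy.stats import hypergeom

from .diffexp import bh_fdr
from .io_formats import ValidationError

logger = logging.getLogger(__name__)


def read_term_table(path) -> pd.DataFrame:
    """Term table TSV with columns (term_id, term_name, category, gene_id)."""
    from .io_formats import read_table

    return read_table(path, required=("term_id", "term_name", "category", "gene_id"))


def hypergeometric_enrichment(
    target_set: set[str],
    background: set[str],
    terms: pd.DataFrame,
    p_cut: float = 0.001,
    correct: bool = False,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``target_set`` per term.

    ``terms`` has one row per (term, gene); genes outside the background are
    dropped with a warning.  Reports the overlap, P, fold enrichment
    (target fraction / background fraction) and a significance flag
    (P < p_cut, strict).  With ``correct=True`` a BH-adjusted q column is
    added and used for the flag instead.
    """
    extra_targets = target_set - background
    if extra_targets:
        raise ValidationError(
            f"target genes outside the background: {sorted(extra_targets)[:10]}"
        )
    m_total = len(background)
    n_target = len(target_set)
    rows = []
    for (term_id, term_name, category), sub in terms.groupby(
        ["term_id", "term_name", "category"], sort=True
    ):
        genes = set(sub["gene_id"])
        outside = genes - background
        if outside:
            logger.warning(
                "term %s: %d gene(s) outside the background dropped",
                term_id,
                len(outside),
            )
            genes -= outside
        if not genes:
            continue
        overlap = len(genes & target_set)
        p = float(hypergeom.sf(overlap - 1, m_total, len(genes), n_target))
        fold = (
            (overlap / n_target) / (len(genes) / m_total)
            if n_target and genes
            else float("nan")
        )
        rows.append(
            {
                "term_id": term_id,
                "term_name": term_name,
                "category": category,
                "term_size": len(genes),
                "overlap": overlap,
                "p_value": min(p, 1.0),
                "fold": fold,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["term_id", "term_name", "category", "term_size", "overlap", "p_value", "fold"],
    )
    if correct and len(out):
        out["q_value"] = bh_fdr(out["p_value"].values)
        out["significant"] = out["q_value"] < p_cut
    elif len(out):
        out["significant"] = out["p_value"] < p_cut
    return out
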