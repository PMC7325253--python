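"""Bundled worked-example tables.

Two small TSVs transcribe the printed miRNA-precursor and miRNA-target
tables of a rice backcross-introgression-line lncRNA survey; they serve as
fixtures for the precursor-census and self-targeting operations.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    path = resources.files(__package__).joinpath("data", name)
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")


def load_precursor_hits() -> pd.DataFrame:
    """Published miRNA-precursor hits in lncRNAs.

    Columns: mirna_id, lncrna_id, alignment_length (nt), alignment_ratio
    (aligned span / precursor length), location (chromosome), de_lncrna
    (1 if the lncRNA was differentially expressed).  Renames the ratio
    column to ``coverage_ratio`` to match computed hit tables.
    """
    df = _load("rice_bil_precursor_hits.tsv")
    df = df.rename(columns={"alignment_ratio": "coverage_ratio"})
    df["de_lncrna"] = df["de_lncrna"].astype(bool)
    return df


def load_mirna_lncrna_targets() -> pd.DataFrame:
    """Published miRNA -> lncRNA target relationships.

    Columns: mirna_id, target_lncrna_id, precursor_of_same_mirna (1 when the
    lncRNA is also a precursor of that miRNA, i.e. a self-targeting pair).
    """
    df = _load("rice_bil_mirna_lncrna_targets.tsv")
    df["precursor_of_same_mirna"] = df["precursor_of_same_mirna"].astype(bool)
    return df


def targets_as_edge_table(targets: pd.DataFrame) -> pd.DataFrame:
    """Convert the published target table to a generic target-edge table."""
    return pd.DataFrame(
        {
            "mirna_id": targets["mirna_id"],
            "target_id": targets["target_lncrna_id"],
            "target_kind": "lncRNA",
            "score": float("nan"),
            "site_start": -1,
        }
    )
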